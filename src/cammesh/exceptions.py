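"""Exception hierarchy for cammesh.

Every error raised by the package derives from :class:`CamMeshError` so
callers can catch pipeline failures with a single except clause while the
subclasses keep the failure stage identifiable.
"""


class CamMeshError(Exception):
    """Base class for all cammesh errors."""


class InputError(CamMeshError):
    """A file could not be read or decoded (names the offending path)."""


class ValidationError(CamMeshError):
    """An input violated a documented precondition or invariant."""


class RegistrationError(CamMeshError):
    """Frame alignment failed (names the frame index where possible)."""


class PipelineError(CamMeshError):
    """A pipeline stage failed; wraps the stage name and the original error."""
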