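# cammesh

Quantitative analysis of intravital video recordings of the chick
chorioallantoic membrane (CAM) microvasculature — the transparent, nearly
two-dimensional capillary mesh that serves as the chick embryo's
respiratory organ and as a classic in vivo model of angiogenesis and
vascular remodeling.

Individual bright-field frames of the CAM show almost no capillary
contrast: vessels become visible only through the motion of red blood
cells, which absorb light as they pass. `cammesh` turns that temporal
signal into quantitative structure:

1. **Movement correction.** Every frame is aligned to the first by
   zero-normalized cross-correlation (ZNCC) of a high-contrast reference
   square, searched over integer shifts around the previous frame's
   displacement. The stack is cropped to the region covered by all
   shifted frames.
2. **Vessel image.** The per-pixel temporal standard deviation
   `SD(x) = sqrt(mean_t[(I_t(x) - mean_t I(x))^2])` is high inside
   perfused lumen and low in avascular tissue; it depends on the extent of
   intensity changes, not their frequency.
3. **Perfusion image.** The per-pixel cumulative intensity change
   `P(x) = sum_t |I_{t+1}(x) - I_t(x)|` grows with both amplitude and
   frequency of fluctuations — a semi-quantitative relative perfusion map,
   rendered in pseudo-color. Both products are normalized to their image
   maximum and are therefore relative quantities per recording.
4. **Segmentation and morphometry.** Gaussian enhancement, a double
   threshold (global Otsu for main vessels OR a local mean-offset
   threshold for small ones), topology-preserving skeletonization
   (component count and Euler number conserved), morphological extraction
   of the enclosed avascular *tissue islands*, and per-ROI descriptors:
   vessel area fraction, skeleton length density, island count and
   island-area CV, distance-transform vessel diameters, and perfusion
   heterogeneity.
5. **Area dynamics.** Shoelace areas of four user-placed landmarks track
   relative CAM area and in-region capillary density across repeated
   scans.

Because real recordings of this kind are not publicly deposited, the
package ships a first-class synthetic generator: a Voronoi capillary mesh
with tissue islands, red cells as advected absorbance particles, scripted
global drift, tissue flicker and sensor noise — with exact ground truth
(lumen raster, island labels, drift script) so every pipeline stage can be
scored. Four phase presets encode the maturation of a mesh into a vessel:
isotropic mesh (I), preferential pathway (II), emergent vessel with
residual tissue islands (III) and established vessel (IV).

## Worked example

```python
import cammesh as cm

scene = cm.generate_mesh_scene((512, 512), 48, "I", seed=1)
stack, truth = cm.render_video(
    scene, cm.RenderParams(n_frames=100, seed=1,
                           drift_script=cm.default_drift_script(100)))
res = cm.run_pipeline(stack, cm.AnalysisConfig(max_shift_px=4))
m = cm.truth_metrics(truth, res.segmentation, trace=res.trace,
                     valid_region=res.valid_region)
rec = res.records[0]
print(f"dice={m['dice']:.3f} islands={rec.n_islands} "
      f"diam={rec.diam_mean_px:.2f}px cv={rec.diam_cv:.2f} "
      f"drift_exact={m['trace_exact']}")
```

prints

```
dice=0.828 islands=64 diam=3.58px cv=0.25 drift_exact=True
```

meaning: the recovered vessel mask overlaps the true lumen with Dice 0.83,
all 64 enclosed tissue islands were found, the mean vessel measures about
3.6 px across (the rendered capillaries are ~3 px wide plus the
threshold's point-spread), and the scripted stage drift was recovered
exactly, frame for frame.

The same pipeline is available from the shell:

```bash
cammesh simulate --phase I --seed 1 --out sim/
cammesh analyze sim/video.tif --out analysis/
cammesh area --landmarks landmarks.csv --out trace.csv
```

`analyze` writes the vessel SD image, the pseudo-colored perfusion image,
the vessel mask, skeleton and island labels (PNG/16-bit TIFF), the
displacement trace and morphometry tables (CSV), and a QC report (JSON)
that includes the fraction of perfusion signal outside the vessel mask —
the tell-tale of residual tissue flicker that alignment cannot remove.

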