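# psdblocks

Quantitative analysis of postsynaptic density (PSD) nano-organization in
cryo-electron tomograms.

The PSD of excitatory synapses is not a homogeneous slab of protein: in
tomograms it resolves into discrete, membrane-associated **nanoblocks** of
varying size. `psdblocks` is a reusable pipeline for segmenting those
nanoblocks from reconstructed tomographic volumes and for quantifying how
receptor-like particles and putative presynaptic release sites organize
around them. It is aimed at cryo-ET practitioners who already have
reconstructed (and optionally denoised) volumes plus point annotations, and
at methods developers who want a fully testable, synthetic-ground-truth
version of this analysis.

## What it computes

1. **Slab projection.** A total-least-squares plane is fitted to membrane
   annotations. Every voxel whose signed distance to that plane lies in
   (0, 40] nm on the cytoplasmic side is column-averaged onto the membrane
   plane, giving a 2D gray-value map of the PSD layer (darker = denser).
2. **Thresholding.** With background gray value *b* estimated from empty
   ice, the darkest fraction *f* (default 25%) of below-background pixels is
   selected — deterministically, with lexicographic tie-breaks.
3. **Nanoblock segmentation.** The selected pixel cloud is clustered with
   DBSCAN (eps = 6 px, minPts = 32, minPts counting the query point; border
   points resolved in deterministic scan order). Each cluster is a
   nanoblock with convex-hull area *A*, width (maximal x-extent, chosen to
   avoid missing-wedge distortion), equal-weight centroid, height beneath
   the membrane, and radius *D* = centroid-to-farthest-hull-vertex.
4. **Alignment statistics.** Annotated particles (types A/B/undefined) and
   docked/tethered/partially-fused vesicles are projected into the membrane
   plane; each point's distance *d* to its nearest nanoblock centroid is
   normalized as *d/D* (ratio < 1 = "within nanoblock range"). Blocks are
   typed A/B/mixed/none by point-in-hull membership. A randomization null
   re-draws each point uniformly over the PSD pixel domain 100 times.
5. **Statistics.** Self-contained two-sample Kolmogorov–Smirnov (exact
   lattice-path p for moderate n, corrected asymptotic otherwise),
   Mann–Whitney U (exact enumeration for small n) and Kruskal–Wallis with
   Dunn–Bonferroni post-hoc tests compare the ratio and area distributions.

A fully tested synthetic-tomogram generator (`psdblocks.synthgen`) renders
membrane + super-ellipsoidal PSD blobs + Gaussian noise with complete
ground truth, so every stage is verifiable without microscope data.

## Worked example

```bash
psdblocks simulate --seed 5 --out run/sim
cat > run/analyze.yaml <<EOF
volume: run/sim/volume.mrc
annotations: run/sim/annotations.csv
output_dir: run/out
EOF
psdblocks analyze --config run/analyze.yaml
cat run/out/report.txt
```

On this phantom (7 planted blocks, noise-to-contrast 0.1) the report reads:

```
nanoblocks detected: 7
  median area  : 1082.9 nm^2
  median width : 46.2 nm
  median D     : 24.0 nm
  median centroid-centroid NN: 40.5 nm
  median edge-edge NN        : 6.6 nm

statistical tests:
  typeA_vs_typeB_ks: statistic=1 p=7.37e-05 (exact)
  typeA_vs_typeB_mw: statistic=0 p=0.000734 (asymptotic)
  vesicle_vs_null_ks: statistic=0.508 p=0.104 (asymptotic_corrected)
  ...
```

All seven planted nanoblocks are recovered; type A particles (planted at
*d1/D* ~ U(0, 0.8)) separate sharply from type B (U(0.8, 1.6)) in the KS and
Mann–Whitney comparisons, while this phantom's five vesicles do not reach
significance against their 100-fold randomization (small n). Alongside the
report, `run/out/` contains `nanoblocks.csv` (per-block morphometrics),
`distances.csv` (nearest-neighbor centroid/edge distances), `alignment.csv`
(per-point *d/D* records), `null_ratios.csv`, `tests.json`, and a
`manifest.json` whose hash is embedded in every output for provenance.

`psdblocks sweep` tabulates cluster counts and area distributions over a
grid of DBSCAN parameters, and `psdblocks stats` compares value columns of
CSV files with the built-in tests.

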