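# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `psdblocks` pipeline. The package analyzes the
postsynaptic density (PSD) of excitatory synapses in reconstructed cryo-ET
volumes: a 40-nm protein-dense layer beneath the postsynaptic membrane that
resolves into discrete nanoblocks.

## Coordinate and gray-value conventions

Volumes are indexed `(x, y, z)` with `z` the tomographic slice axis; voxel
`(i, j, k)` sits at `origin + (i, j, k) * voxel_size` nm (0-based, voxel
centers). Gray values are arbitrary density units with darker = denser
protein. All annotation coordinates are physical nanometres, never voxel
indices, so they survive rebinning. The reference pixel size is 1.32 nm
(3.3 Å acquisition pixels at binning 4); any isotropic MRC2014 volume is
accepted.

The membrane is modeled as a plane fitted by total least squares (SVD) to
user-supplied membrane points, oriented by a cytoplasm-side hint so the PSD
lies at positive signed distance. The in-plane frame `(u, w)` takes `u`
from the projection of the volume x-axis and `w` completing the basis
toward positive `z`. The plane model generalizes the common case of a
membrane roughly normal to `y`; strongly curved membranes are outside the
model (the fit's RMS residual is reported so users can judge).

## Slab projection and thresholding

Each projection pixel is the arithmetic mean of all voxels whose signed
plane distance lies in the half-open interval (0, depth] (default depth
40 nm). The open lower bound excludes the membrane itself. Voxels are
binned to their nearest in-plane pixel without interpolation, preserving
the gray-value statistics that the clustering consumes. Pixel indices use
`floor(x + 1/2)` rather than banker's rounding: with round-half-to-even, a
plane origin exactly half a pixel off the voxel grid would merge adjacent
columns.

Thresholding implements "the darkest fraction f of pixels below
background": candidates are unmasked pixels strictly darker than the
empty-ice background estimate; the `floor(f * n_candidates)` darkest are
kept, with gray-value ties broken by lexicographic pixel order so the
selection is reproducible bit-for-bit. Defaults follow the synaptosome
operating point (f = 0.25); f = 0.20 and a `global_fraction` mode (for
normalization-corrected volumes without a meaningful external background)
are one config key away. An alternative reading of the rule — keep
below-background pixels up to the f-quantile of their values — is exposed
as `below_background_percentile` but is not the default.

A practical semantic of the darkest-fraction rule worth knowing: the
fraction budget presumes that the dense layer covers a comparable share of
the analysis plane. If the projected region is dominated by empty
background, the budget is spent on scattered noise pixels which DBSCAN then
attaches to block rims as border points, biasing widths upward. Analyses
should therefore crop the projection to the membrane patch of interest, as
is standard practice for synaptosome data; the synthetic defaults are sized
accordingly.

## Nanoblock segmentation (DBSCAN) and morphometrics

DBSCAN runs on integer pixel coordinates with Euclidean metric; the
operating point is eps = 6 px, minPts = 32, with minPts counting the query
point itself (the MATLAB convention under which that operating point was
established). Semantics are pinned exactly: a point is core iff its closed
eps-ball holds ≥ minPts points; clusters are connected components of core
points; border points join the cluster of the first core point reaching
them after lexicographic pre-sorting, making the labeling independent of
input order; cluster ids are canonicalized by smallest member in scan
order. A quadratic-time reference implementation in the test suite pins
these semantics, and scikit-learn's DBSCAN cross-checks core-point sets.
Parameter choice is data-dependent in practice; `parameter_sweep` tabulates
block counts and area distributions over an (eps, minPts) grid but the
package deliberately does not automate the choice.

Morphometrics per block: area = convex-hull area of member pixel centers
(shoelace on hull vertices; degenerate collinear clusters keep area 0);
width = maximal extent along u only (the beam-tilt axis projection is
unreliable due to the missing wedge, so widths are never measured as 2D
diameters); centroid = unweighted mean of member pixels; D = centroid to
farthest hull vertex; height = depth extent of the contiguous
below-background run at the block's widest column, on the slice-averaged
(u, depth) image, reported as the outer edge of the last run bin (undefined
and flagged when no below-background bin adjoins the membrane). Nearest
edge-to-edge distances use member pixel centers, the conservative choice
that differs from hull-polygon distance by at most one pixel.

## Alignment analysis and the randomization null

Annotated points are orthogonally projected into the membrane plane. Each
point is paired with the nanoblock minimizing the raw centroid distance d
(ties to the lowest block id); the normalized ratio d/D < 1 defines "within
nanoblock range" (strict inequality). An `all_pairs` mode serves analyses
grouped by block type, where each point contributes one record per block.
Pairing by nearest normalized ratio instead of nearest raw distance is a
defensible alternative; nearest-raw-distance is the default because it is
parameter-free and independent of block size. Blocks with D = 0
(single-pixel) are excluded from ratio analyses and logged.

Block typing is point-in-convex-hull membership of type A/B particles,
boundary-inclusive (tolerance 1e-9 nm): A (only A inside), B (only B),
mixed, none.

The randomization null re-draws every point position independently and
uniformly over the eligible PSD pixel set, 100 replicates by default, and
recomputes ratios with the same pairing mode. The default domain is all
pixels inside the convex hull of the union of nanoblock member pixels
("the PSD bounds"); the thresholded pixel cloud itself is available as an
alternative domain. Calibration was validated: when experimental points
are themselves drawn from the domain, the KS comparison against the pooled
null rejects at the nominal 5% rate (measured 0.02–0.08 over seeded
repetitions at around 100 points per comparison).

## Nonparametric tests

All tests are implemented in the package (scipy supplies only the normal
CDF and chi-square survival primitives) and cross-checked against
exhaustive enumeration and scipy in the test suite.

- **Kolmogorov–Smirnov (two-sample, two-sided).** D is the supremum ECDF
  difference over pooled data. The exact p-value counts lattice
  interleavings in integer units `|i*n2 − j*n1|`, avoiding all floating
  boundary comparisons; it is used for n1·n2 ≤ 10⁴ and refused (with a
  flag, falling back to the corrected asymptotic) in the presence of ties.
  The asymptotic p uses the Kolmogorov series at
  `lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D`. At a representative
  receptor-comparison scale (D = 0.2551, n = 207/93) this evaluates to
  3.56e-4.
- **Mann–Whitney U.** Midranks; exact two-sided p by enumeration for
  n1+n2 ≤ 12 without ties, else the normal approximation with tie and
  continuity corrections; group medians reported.
- **Kruskal–Wallis.** H with tie correction; chi-square p on k−1 df; the
  all-values-identical degenerate case returns H = 0, p = 1. Pairwise
  post-hoc comparisons are Dunn z-tests on pooled midranks with Bonferroni
  adjustment (the multiple-comparison procedure is a package choice).

Measured type-I error at alpha = 0.05 over 2,000 null replicates: 0.039
(KS exact, n = 50/50 — slightly conservative from discreteness), 0.051
(MW, n = 40/40), 0.053 (KW, 3 × 25).

## Synthetic data: what it emulates and what it does not

The generator renders: a 2-voxel dark membrane band placed on the
extracellular side of the nominal plane (so the (0, depth] slab rule
excludes it, mimicking a plane fitted to the cytoplasmic membrane face); a
PSD layer of flattened super-ellipsoid blobs, each an in-plane ellipse
(width along u; width × 0.75 along w) whose local depth thins toward the
rim as `t(r) = depth * (1 − r^4)^(1/4)`; and i.i.d. Gaussian noise over a
constant background. The graded rim is deliberate: it gives each block a
spread of projected column contrasts so that darkest-fraction thresholding
trims rims gracefully rather than deleting whole shallow blocks, which is
how real PSD density behaves. A uniform-depth "cylinder" profile is
available for constructing exactly piecewise-constant oracle volumes.

Defaults (all overridable): 160×80×160 voxels at 1.32 nm; background 0;
noise sigma 1.0 against block contrast −10 (noise-to-contrast 0.1) and
membrane contrast −12; 7 blocks; widths from the bimodal mixture
0.6·N(30, 5) + 0.4·N(55, 8) nm (median ≈ 34.8 nm); depths uniform in
(16, 40) nm; minimum edge gap 6.6 nm with typical gaps N(18, 4) nm placed
by chained sampling (each new block at a drawn gap from a random existing
block, all pairwise gaps rejection-checked). Particles: 13 type A at
planted d1/D ~ U(0, 0.8), 6 type B at U(0.8, 1.6), 20 undefined at
U(0, 1.6), placed 7 nm extracellular; 5 vesicles at d2/D ~ U(0, 1.5),
45 nm presynaptic, states cycling docked/tethered/partially-fused. Particle
and vesicle counts approximate per-tomogram averages of the study data this
pipeline is designed for. All outputs are pure functions of (params, seed)
via four spawned random streams (layout, particles, vesicles, noise).

Known emulation limits:

- **Packing.** Real synaptosome PSDs pack nanoblocks with median
  edge-to-edge gaps around 6.6 nm — below the eps = 7.9 nm reach of the
  clustering, where adjacent solid blobs are inherently unresolvable and
  are (correctly) reported as one larger block. The default phantom uses
  separable 18 ± 4 nm gaps so that planted-recovery scoring is meaningful;
  tight, realistic packing is reachable by lowering `gap_mean`, with the
  expected under-segmentation.
- **Vesicle planting is block-associated** (each vesicle is generated at a
  controlled d2/D of a real block), so on phantoms the vesicle-vs-null KS
  test rejects — by design, demonstrating sensitivity; a null-consistent
  vesicle population is produced by drawing positions from the domain, as
  the calibration tests do.
- No CTF, no missing wedge, no macromolecular crowding, no membrane
  curvature: the pipeline consumes post-processed (deconvolved /
  wedge-corrected) tomograms, and passing synthetic tests shows algorithmic
  correctness, not robustness to those acquisition effects.

Planted-recovery performance at the defaults (50 seeds): detection recall
0.99, precision 1.0 (centroid match within eps·voxel = 7.9 nm), median
width error −2%, noise-free heights within one voxel, noiseless planted
block typing reproduced exactly.

## Numerical and degenerate-input conventions

Selection and clustering are deterministic (stable sorts, lexicographic
tie-breaks, canonical cluster numbering); full pipeline reruns are
byte-identical. Empty candidate sets yield empty clouds (flagged), not
errors; zero detected blocks yields a complete report, not a crash. Peak
fitting for 1-D density profiles and histograms uses a constant plus
sum-of-Gaussians least-squares fit with the component count chosen by BIC
(seeded from residual maxima); the flat-profile case selects zero
components. Sum-of-Gaussians with BIC is a modeling choice for the
dip/peak fits, not a claim about the true functional form. Nanoblock area
histograms support the display convention of truncating at 3,500 nm²
(medians always use all values).

## Problem sizes

Test-suite and acceptance-script simulations use the default 160×80×160
phantom (≈ 2 M voxels, ≈ 3,500 selected pixels, 7 blocks), panels of
10–50 seeds for recovery statistics, 100–200 repetitions for calibration
rates, and 2,000 replicates for type-I levels — sizes at which the reported
rates have standard errors comfortably inside the asserted bands.
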