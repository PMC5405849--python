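# Methods

This note documents the models, algorithms and numerical choices behind
`surseg`, the assumptions they make, and what the synthetic tests do and do
not demonstrate about real tomographic data.

## Volumes and on-disk layout

Volumes are 3D scalar grids in fixed `(z, y, x)` order. The MRC2014 reader
honours the header's `mapc/mapr/maps` axis words and permutes the on-disk
(section, row, column) block accordingly; files are written with the
identity mapping (`mapc,mapr,maps = 1,2,3`) in modes 0/1/2/6
(int8/int16/float32/uint16). Non-finite voxels are rejected at load time by
default; an explicit `on_nonfinite="median"` policy imputes them with the
median of the finite voxels and warns. Indices are 0-based, ranges
half-open. All derived products persist in one HDF5 sidecar with groups
`/data`, `/features/<name>`, `/superregions/{supervoxels,megavoxels}`,
`/annotations/<level>`, `/predictions/{labels,probs}`. Voxel spacing is
carried as metadata but defaults to isotropic and does not currently
influence filters or supervoxel shape (a known limitation for strongly
anisotropic acquisitions).

## Feature channels

All filters use reflect padding, run internally in float64 and store
float32 channels; recomputing a channel from its stored parameter record is
bit-identical. Gaussian filtering over-smooths but is the best driver for
super-region extraction; total-variation denoising (Chambolle dual
projection, ROF model, defaults `weight=0.1`, `tol=1e-4`, `max_iter=200`)
yields piecewise-smooth regions better suited to classification features.
Second-derivative filters (Laplacian of Gaussian, Hessian) inherit a
~1e-4 relative residual on constant regions from kernel truncation at 4σ;
tests assert zero at that tolerance rather than exactly. Scale-invariant
responses are the voxelwise maximum over scales of γ-normalised responses
(`σ^order · |response|`); rotation invariance comes from using
rotation-invariant bases (gradient magnitude, LoG). Note that for a 3D
Gaussian blob of scale `s` the σ²-normalised LoG peaks at `σ = √(2/3)·s`,
not at `σ = s` — the best-scale channel is a detector, not an unbiased
scale estimator.

## Supervoxels (SLIC)

A localized k-means in joint (intensity, z, y, x) space. Intensities are
linearly rescaled to [0, 100] so that the compactness weight is comparable
across datasets; seeds sit on a fixed lattice with per-axis count
`round(extent/spacing)`, each cluster searching a window of ±spacing around
its centre. The distance is `D = sqrt(d_int² + m²·d_sp²/S²)` with `S` the
geometric-mean seed spacing; defaults: spacing 10×10×10, compactness 30,
5 assignment/update sweeps. After clustering, connectivity is enforced:
connected components of each label are found at 26-connectivity, the
largest keeps the label, and every orphan fragment merges into the
face-adjacent region with the closest mean intensity (ties to the lowest
label id, making the whole module deterministic with no randomness at
all). On a 100³ volume the defaults give exactly 1000 seeds and ≈1000
voxels per supervoxel.

## Region graph and megavoxels

The region adjacency graph connects regions with at least one adjacent
voxel pair under a chosen 6/18/26 neighbourhood; `boundary_count` is the
exact number of spanning pairs under that same neighbourhood (face pairs
for the default 6). Megavoxels are built by greedy agglomeration on this
graph: repeatedly merge the most similar adjacent pair (Euclidean distance
between supervoxel descriptors) while the distance is below a threshold,
updating merged distances with the Lance–Williams average-linkage rule.
Merging only along graph edges guarantees connected megavoxels; a
`min_size` pass then absorbs undersized megavoxels into their most similar
neighbour. This agglomerative scheme is this package's own construction —
simple, deterministic and sufficient for the two roles megavoxels play
here (coarse annotation and large-region merging).

## Descriptors

Four supervoxel descriptor families: per-channel means; histograms of
k-means-quantised voxel features; textons (PCA to `pca_dims`, then a
k-means codebook); and sigma sets, the concatenation of the channel means
with the lower triangle of `chol(Σ + εI)` where `Σ` is the within-region
sample covariance (ddof 1) and `ε = max(1e-6·tr(Σ)/C, 1e-6)` guarantees a
positive-definite factor even for constant or single-voxel regions.
Codebooks are fitted on a seeded 5% voxel sample with k-means++ and 10
restarts; all seeded operations are bit-reproducible. The default
normalisation is per-column z-scoring. Neighbour augmentation appends the
unweighted mean of the graph neighbours' descriptors (an isolated region
uses its own); augmentation is single-ring only — neighbours of neighbours
are not recursed.

## Classification

Training uses only the annotated regions; voxel annotations are lifted to
supervoxels by majority vote among each region's annotated voxels (regions
without annotated voxels stay unlabelled; ties go to the lowest label id).
The default classifier is an extremely randomized forest — 100 trees,
√-features per split, inverse-frequency class weights (annotation strokes
are tiny and unbalanced), fixed seed — chosen because it needs no
parameter tuning and tolerates heterogeneous descriptor scales. SVM
probabilities come from cross-validated calibration and are documented as
slower. Confidence is the per-region maximum class probability; the
acceptance tool turns confident unannotated predictions into annotations
without ever overwriting existing ones, so the iterative
annotate→train→accept loop grows the training set monotonically.

## MRF refinement

The energy is `E(c) = Σ ψ_p(c_p) + λ Σ w_pq·[c_p ≠ c_q]` with
`ψ_p = −log max(p, 10⁻⁶)` (the floor keeps unaries finite) and
`w_pq = (b_pq/b_max) · exp(−‖φ_p−φ_q‖²/(2σ_w²))`. The boundary counts are
normalised by the per-graph maximum; `σ_w` defaults to the median pairwise
descriptor distance over the edges, a self-tuning bandwidth that keeps the
exponential well-scaled for any descriptor family. The pairwise indicator
penalises *disagreement*: a smoothing Potts term is the only reading
consistent with encouraging similar neighbours to share a label. Default
`λ = 1`.

Inference is alpha-expansion: each move is a binary min-cut (solved with
networkx maximum-flow; graphs are supervoxel-level, so hundreds of nodes),
moves are accepted only if the independently recomputed energy strictly
decreases, and sweeps repeat until no label improves. For two labels an
expansion-stable labelling is globally optimal (submodularity of the
attractive Potts pair term gives `2E(c) ≤ E(c∨c*) + E(c∧c*) ≤ E(c) +
E(c*)`), which the tests verify against exhaustive enumeration on random
problems of up to 12 nodes. ICM is provided as a cheap fallback and as a
quality bound. At `λ = 0` the solver returns the per-region argmax
bit-exactly. Voxel-level refinement uses the chosen 6/18/26 neighbourhood
with unit boundary counts.

## Labels, post-processing, measurement

Labels form a forest; a region belongs to a parent label when a strict
majority of its voxels lies inside the parent mask (ties excluded, keeping
children conservative). Painting at supervoxel/megavoxel level assigns
every voxel of every region the pen path touches. Post-processing fills
holes in 3D (background components not reaching the grid border) and
smooths edges with ball-element opening/closing; per-label results are
recombined largest-first so labels never overlap. The label splitter
measures maximal connected components (default 26-connectivity) — voxel
count, bounding box, centroid and bbox centre, and mean/variance/standard
deviation of a chosen channel ("average variation" is implemented as the
within-object variance) — and assigns objects to the first matching
AND-chained rule set; contradictory bounds are rejected at parse time.
Splitting and recombining is lossless by construction.

## Synthetic phantoms and what the tests show

The phantom is a piecewise-smooth cell: background, cytoplasm, organelles,
nucleus and nucleoli with class means 0–4 spaced 1.0 apart, within-phase
smooth variation bounded below half that gap (so the noiseless limit is
exactly recoverable by thresholding), and Gaussian noise with
`sd = min class gap / SNR` — at the default SNR 5 the means sit five noise
standard deviations apart, well-posed but not voxelwise trivial. An
optional z-axis blur mimics missing-wedge elongation. Stroke annotations
are straight runs sampled inside each class, capped so the labelled
fraction never exceeds the requested value.

The end-to-end harness (64³ phantom, SNR 5, 1% strokes, all defaults)
reaches ≥0.90 voxel accuracy with refinement never below the raw argmax.
Problem sizes throughout the suite (32–100³ volumes, ≤12-node exhaustive
MRF oracles) were chosen so the whole suite runs in well under a minute on
one core while still exercising every stage at realistic granularity.
What passing tests do *not* show: performance on real contrast-transfer
artefacts, reconstruction streaks, membrane-thin structures below the
supervoxel scale, or anisotropic voxel spacing — the phantom has none of
these, and real volumes will generally need per-dataset tuning of
channels, supervoxel spacing and λ.

## Design choices made where the design was open

- Boundary handling for all filters: reflect padding.
- Supervoxel intensity term: a single configurable channel, default the
  Gaussian-denoised volume.
- Megavoxel similarity: Euclidean distance between supervoxel descriptors
  with average linkage (fully owned by this package, see above).
- Confidence: maximum class probability (not margin).
- `w_pq` normalisation: per-graph maximum boundary count.
- Hole filling: 3D, not per-slice.
- Structuring element: ball.
- Object location: centroid, with bbox centre also reported.
- Parent constraint at voxel level honours the parent mask directly, by
  symmetry with the region rule.
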