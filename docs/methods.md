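# Methods

## Problem and model

Single-particle tracking (SPT) with localization microscopy — MINFLUX in
particular — produces per-particle streams of coordinates (x, y[, z], t).
Immobilized fluorescent markers contaminate these datasets with "blobs":
dense, nearly isotropic point clouds that are not trajectories of freely
moving particles and must be removed before diffusion analysis. blobsieve
separates blobs from free trajectories without any training data, using
only the geometry of each trajectory's point cloud.

For a trajectory `P = {x_1, …, x_N}` the package computes five descriptors:

| feature | definition | units (2D / 3D) |
|---|---|---|
| `d_max` | max pairwise Euclidean distance | nm |
| `hull_measure` | convex-hull area / volume (Qhull) | nm² / nm³ |
| `ellipticity` | `hull / (π·d_max·d_mean)` (2D), `hull / (4π/3·d_max·d_mean²)` (3D) | — |
| `sphericality` | `hull / (π·d_mean²)` (2D), `hull / (4π/3·d_mean³)` (3D) | — |
| `density` | `N / hull_measure` | nm⁻² / nm⁻³ |

with `d_mean` the mean distance of the points to their center of mass.
Blobs have small `d_max`, high `sphericality` and `density`; free tracks
have elongated, irregular hulls. All five descriptors are invariant under
rigid motion and point permutation; the two ratios are also
scale-invariant. The diameter `d_max` is computed on convex-hull vertices
only (the diameter of a point set is attained there), with a full pairwise
fallback for small or hull-degenerate clouds; the test suite checks
equality with the O(N²) brute-force scan.

Each feature axis is z-scored on the dataset at hand (population 1/N
variance; the statistics are retained so the transform is invertible), and
the standardized 5D cloud is split by one greedy k-means++ initialization
followed by Lloyd iterations to convergence ("single-shot": `n_init=1`, no
restarts, no training). The seed is an explicit, logged parameter
(default 42). Which of the two clusters holds the artifacts is decided by
the Blob score

    B_cluster = mean over member tracks of (sphericality / d_max)

computed on the **raw** features — standardized values can be negative,
which would make the ratio meaningless. The cluster with the larger B is
annotated `blob`; `b_score_ratio = max(B)/min(B)` measures how unambiguous
the call is (a tie within 1e-12 raises rather than guessing). Because
sphericality is scale-invariant and `d_max` scales linearly, uniform
rescaling of the coordinates rescales both cluster scores by the same
factor and leaves the ratio unchanged.

## Synthetic ground truth

The simulator emulates the validation conditions the method was designed
for, working internally in nm and µs (1 µm²/s ≡ 1 nm²/µs):

- **Free tracks** (default 250): random walks of 400–600 steps at
  Δt = 500 µs. Each step has radial length `r = u·sqrt(2·D·Δt)` with
  `u ~ U(0,1)` and an isotropic direction (uniform angle in 2D, uniform on
  the sphere in 3D); the per-track diffusion coefficient is drawn from
  U(0.1, 1) µm²/s. Starts are uniform in a 1 µm sandbox; tracks may leave
  it (no reflecting boundary — only starts are constrained). With this
  step law the mean squared step is `(2/3)·D·Δt`, so the ensemble MSD grows
  linearly with an effective coefficient of `D/(3·dim)`; a test verifies
  both the closed form and the linearity.
- **Blobs** (default 250): 400–600 i.i.d. draws from a multivariate normal
  with *diagonal* covariance. Per-axis σ is drawn from
  Normal(5.1 nm, 0.8 nm), truncated at 0.5 nm. The 5.1 nm default is the
  calibration that puts the median localization radius of an isotropic 2D
  blob at 6 nm (`r50 = σ·sqrt(2 ln 2)`), with ~94% of localizations within
  12 nm, matching bead observations; independent per-axis draws give the
  slight anisotropy real blobs show. Centers are uniform in the sandbox
  shrunk by 0.8 per side, avoiding edge effects.

What the simulator does **not** model: localization noise on free tracks,
photon statistics, confined/hopping diffusion, drift. Passing tests
therefore demonstrate that the pipeline separates ideal Brownian tracks
from ideal Gaussian blobs under realistic MINFLUX geometry parameters —
not that it handles drifting or interacting particles (drift should be
corrected upstream by dedicated methods).

## Evaluation

With ground truth available the package reports: the 2×2 confusion matrix
and F1 (blob = positive class), the adjusted Rand index and V-measure
(β = 1) between truth and raw cluster assignments, and the mean silhouette
coefficient. Silhouette is computed in the standardized 5D feature space —
the space that was actually clustered, not the PCA plane. Feature-space
structure is summarized by the 5×5 Pearson correlation matrix and the
top-2 PCA eigenvectors with explained-variance ratios; eigenvector signs
are fixed so each vector's largest-magnitude entry is positive, making the
output deterministic. The standard metrics are delegated to scikit-learn,
and the test suite validates each against an independent oracle (explicit
pair enumeration for ARI, contingency-table entropies for V-measure,
per-sample distance means for silhouette) to 1e-12 on small instances.

## Numerical and design choices

- **Degenerate tracks** (fewer than dim+1 points, collinear/coplanar, all
  points coincident) cannot support the descriptors. They are excluded
  from clustering with a logged warning carrying the track id — never
  silently dropped, never given sentinel values.
- **Qhull options**: library defaults; no joggle tuning.
- **Units**: features are computed in the input's native unit (nm
  default). No internal conversion: the two ratios are unit-free and
  clustering standardizes the rest.
- **Tie-breaking**: k-means assignment uses nearest center, lowest index
  on exact ties (scikit-learn's convention), so runs are reproducible for
  a fixed seed.
- **Minimum-localization filter**: "at least 500" is inclusive — a track
  with exactly 500 localizations survives. The default threshold targets
  real data curation; simulated data (400–600 points by construction) are
  run unfiltered.
- **k** is exposed (default 2) for exploratory use on heterogeneous data,
  but B-score annotation applies only to k = 2.
- **Input formats**: plain CSV with header `track_id,t,x,y[,z]` (a `z`
  column switches to 3D), plus a JSON sidecar for provenance. Vendor
  binary exports are out of scope; convert to CSV first.

## Problem sizes

The default validation runs use the full study conditions (500 tracks of
400–600 localizations per dataset); a complete 2D + 3D pipeline pass takes
well under a second, so nothing is scaled down. Monte-Carlo checks use
10⁵–10⁶ draws.

## Known limitations

- The B-score ratio (unlike the classification metrics) is sensitive to
  the exact blob-size statistics; with the 6 nm-median calibration the 2D
  ratio lands around 22–27:1 and the 3D ratio around 43:1 — both far above
  the >10 margin needed for unambiguous annotation.
- Heavily imbalanced datasets, additional diffusion modes, or drift will
  erode the two-cluster separation; more clusters (larger k) can help, but
  annotation then requires inspection.
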