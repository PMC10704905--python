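# blobsieve

Training-free removal of immobile-particle "blob" artifacts from
single-particle-tracking (SPT) trajectory datasets.

Localization-microscopy tracking modes — MINFLUX in particular — emit
nanometre-precision coordinate streams per particle, but immobilized
fluorescent markers leave behind dense, near-isotropic point clouds
("blobs") that corrupt downstream diffusion analysis. blobsieve flags them
automatically, with no training data: it describes every trajectory by
five geometric features of its point cloud, splits the standardized
feature space with a single k-means++ run, and annotates which cluster
holds the artifacts by a Blob score.

For a trajectory `P` with `N` localizations, center of mass `μ`, diameter
`d_max = max‖x_i − x_j‖` and mean center distance
`d_mean = mean‖x_i − μ‖`, the features are

```
d_max,   A_hull (or V_hull),
ELLI = A_hull / (π·d_max·d_mean)          SPHE = A_hull / (π·d_mean²)        (2D)
ELLI = V_hull / (4π/3·d_max·d_mean²)      SPHE = V_hull / (4π/3·d_mean³)     (3D)
ρ    = N / hull measure
```

Each axis is z-scored, one greedy k-means++ initialization plus Lloyd
iterations splits the dataset into two clusters, and the cluster with the
larger Blob score `B = mean(SPHE / d_max)` (on raw features) is labeled
`blob`; the ratio of the two scores reports how clear-cut the call is.

The package also ships the calibrated ground-truth simulator used to
validate the method (free Brownian tracks with per-track
`D ~ U(0.1, 1) µm²/s` at `Δt = 500 µs`, plus multivariate-normal blobs
with bead-calibrated 5.1 ± 0.8 nm axis sigmas) and an evaluation layer
(confusion matrix, F1, silhouette, adjusted Rand index, V-measure, PCA,
feature correlations). See `docs/methods.md` for the full model account.

## Worked example

Simulate a labeled 2D validation dataset and run the full pipeline:

```console
$ blobsieve simulate --dim 2 --seed 7 -o demo_tracks.csv
wrote 500 tracks (2D, seed=7) to demo_tracks.csv
$ blobsieve run demo_tracks.csv --seed 7 -o demo_out
F1=0.996  silhouette=0.683  ARI=0.984  V=0.966  B-ratio=25.6
outputs in demo_out
```

Of the 500 tracks (250 simulated free walkers, 250 blobs), 499 received
the correct annotation (F1 = 0.996 with blob as the positive class); the
clusters are cleanly separated in feature space (mean silhouette 0.683)
and the blob cluster's Blob score exceeds the free cluster's by a factor
of 25.6, so the automatic annotation is unambiguous. `demo_out/` contains
`labels.csv` (per-track `track_id,cluster,annotation`), `clusters.json`
(centers, B-scores, ratio, seed), `report.json` (all metrics, PCA and
correlation matrices) and `run_manifest.json` (provenance).

The same works from Python:

```python
from blobsieve import SimulationConfig, run_pipeline

res = run_pipeline(SimulationConfig(dim=3, seed=7), seed=7)
print(res.report.f1, res.report.b_score_ratio)
```

Real data enter as a CSV with header `track_id,t,x,y[,z]` (coordinates in
nm); `blobsieve run tracks.csv --min-loc 500 -o out` applies the standard
short-fragment filter before separation, and `blobsieve extract` /
`blobsieve evaluate` expose the intermediate steps.

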