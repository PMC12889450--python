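# organelletrack

Quantitative analysis of organelle behaviour in two-channel fluorescence
time-lapse microscopy.  Given a multichannel TIFF stack — by convention
mitochondria in channel 0 and lysosomes in channel 1, though any pair of
labelled compartments works — the package segments both organelle
populations in every frame, counts lysosomes, classifies mitochondria as
elongated or punctate, extracts shape descriptors, reconstructs
trajectories and motility statistics, quantifies mitochondria–lysosome
colocalization, and merges everything into an integrated per-frame
correlation summary.  A companion comparison tool performs adaptive
two-sample statistics between two recordings (cells, conditions).

It is aimed at cell biologists doing live-cell imaging of organelle
dynamics — e.g. mitochondrial fission/fusion balance, lysosomal
positioning, or mitochondria–lysosome contacts in neurons — who want
reproducible, scriptable quantification with standardized CSV/PNG outputs
instead of ad-hoc point-and-click measurements.

## Methods at a glance

* **Segmentation** — per-frame global Otsu threshold scaled by a
  stringency factor *thr_factor*; foreground is `I ≥ thr_factor · t_Otsu`,
  followed by morphological opening (disc radius *r*), removal of
  components with area < *min_size*, and optional border clearing.
  Components use 8-connectivity throughout.
* **Morphology** — per object: area *A*, perimeter *P*, eccentricity *e*
  of the moment-equivalent ellipse, circularity `4πA/P²`, solidity
  (contour area / convex-hull area), aspect ratio (major/minor axis) and
  orientation.  A mitochondrion is **elongated** iff
  `e ≥ ecc_thresh ∧ A ≥ area_thresh`, otherwise **punctate**.
* **Tracking** — greedy nearest-neighbour linking of centroids between
  consecutive frames, gated at *max_dist* pixels; no gap closing.  Per
  track: cumulative path length `Σᵢ‖xᵢ₊₁−xᵢ‖`, net start→end displacement,
  and mean velocity = path length / elapsed time (px/s, or µm/s when the
  pixel size is calibrated).
* **Colocalization** (from binary masks A = mito, B = lyso) — Manders
  `M1 = |A∩B|/|A|`, `M2 = |A∩B|/|B|`; Pearson *r* of the 0/1 pixel
  vectors (the phi coefficient); percent overlap = Jaccard index
  `100·|A∩B|/|A∪B|`.
* **Integration** — per-frame metrics joined on the frame index; pairwise
  Pearson (or Spearman) correlation matrix; difference maps between two
  runs' matrices.
* **Comparison** — Shapiro–Wilk on each group; if either p < α use
  Mann–Whitney U, else median-centered Levene; if p < α use Welch's t,
  else Student's t.  Effect sizes follow the test: Cohen's *d*, Hedges'
  *g* = d·(1 − 3/(4n−9)), or rank-biserial r = 1 − 2U/(n₁n₂).

A synthetic-fixture generator (`organelletrack.synthetic`) renders
two-channel stacks of moving ellipses with exact pixel-level ground truth
(counts, shapes, trajectories, planted overlap fractions), so every stage
is testable without microscope data.

## Worked example

Generate a synthetic recording (5 mitochondria + 7 lysosomes, 12 frames),
run the pipeline, and compare two recordings with different planted
motility:

```
$ organelletrack simulate counting -o demo/sim
wrote counting.tif and ground-truth CSVs to demo/sim

$ organelletrack run demo/sim/counting.tif -o demo/run --max-dist 8
wrote 25 files to demo/run

$ head -4 demo/run/Lysosome_Counts.csv
frame,count
0,7
1,7
2,7

$ head -2 demo/run/Colocalization.csv
frame,m1,m2,pearson_r,percent_overlap,n_mito_px,n_lyso_px,n_overlap_px
0,0.12883435582822086,0.2916666666666667,0.17784332760287935,9.813084112149532,489,216,63
```

All 7 planted lysosomes are found in every frame.  In frame 0 the
segmented mitochondrial mask covers 489 px, the lysosomal mask 216 px, and
63 px overlap, giving M1 = 63/489 ≈ 0.129 (12.9% of mitochondrial area
touched by lysosomes), M2 = 63/216 ≈ 0.292, and a Jaccard overlap of 9.8%.

Comparing two runs whose organelles were planted at 3 vs 1 px/frame:

```
$ organelletrack compare demo/fast demo/slow --metrics mean_velocity,m1 -o demo/cmp
mean_velocity: mann_whitney_u p=0.0001135 rank_biserial_r=-1
m1: mann_whitney_u p=1 rank_biserial_r=0
```

The velocity difference is detected (p ≈ 1e-4; rank-biserial −1 means
every track in the first run is faster than every track in the second,
negative by the `1 − 2U/(n₁n₂)` sign convention), while colocalization —
identical by construction — shows no difference.

The same functionality is importable: `organelletrack.run_pipeline`,
`segment_stack`, `build_tracks`, `coloc_timeseries`, `compare_runs`, …

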