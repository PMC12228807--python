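# Methods

## The problem

Liquid-biopsy immunofluorescence slides image every nucleated cell from a
few milliliters of blood — several million cells across 2304 scanner frames
in four channels (DAPI `D`, a cytokeratin cocktail `CK`, vimentin `V`, and
CD45/CD31 multiplexed as `CD`). Biologically interesting events —
circulating tumor cells, circulating endothelial cells, oncosome-like
DAPI-negative CK objects — occur at rates down to one in a million against
a leukocyte supermajority. `redetect` isolates a small cohort of candidate
events without any model of what the events look like, using only the
premise that they are rare.

## The model

The slide is split into non-overlapping 32 x 32 x 4 tiles `x_i` (about 2.5
million per slide at full scale; ~1-4 cells per tile). A denoising
autoencoder `r(·)` is trained, per slide, on that slide's own tiles to
minimize

    L(r) = (1/N) Σ_i || x_i − r(x_i + ε) ||²₂ ,    ε ~ N(0, σ²I), σ = 0.05,

with intensities normalized to [0, 1] by the fixed bit-depth maximum
(scanner gain is set for consistent background, so a fixed scale keeps
slides comparable). For such a model the reconstruction residual
approximates σ² ∇log p(x), the score of the tile distribution, whose
magnitude is small where probability mass concentrates and large in the
tails — a principled rarity measure that requires no labels.

Per tile, the residual against the reconstruction of a corrupted copy is
reduced to one Euclidean norm per channel, `e_c`, and combined as

    ρ = Σ_c w_c e_c ,    (w_D, w_CK, w_V, w_CD) = (⅓, ⅓, ⅓, 0).

The CD channel is zero-weighted because CD45/CD31 marks the leukocyte
majority: scoring it would reward the common population. ρ is also reported
normalized by the slide's mean tile magnitude (the average L2 norm of the
clean 4096-value tile), which puts slides on a common scale without
changing the ranking. Tiles are ranked by descending ρ, ties broken by
ascending tile id, and the top N̄ = 2500 (a 1000-fold reduction) form the
rare cohort.

### Architecture and training

Encoder: Conv(4→32)+ReLU, then four stages of dense-block + Conv +
AvgPool(2,2) + ReLU at widths 64/128/256/512, flatten (2·2·512 = 2048),
Linear(2048→1536)+ReLU+BN, Linear(1536→512)+ReLU, Linear(512→512). The
decoder mirrors it with nearest-neighbour upsampling and a final
Conv(32→4)+sigmoid, so reconstructions lie in (0,1). A dense-block(k, n) is
n 3x3 convolutions, each producing k maps from the concatenation of the
block input and all previous outputs (ReLU between). Batch norm appears
exactly where listed; it runs on batch statistics while training and on
running averages when scoring. Training: one epoch over all tiles, Adam,
learning rate 1e-5, batch size 500, fresh noise per tile per step, all
seeded. Pooling is 2x2 stride 2 (forced by the 2048 flatten arithmetic).

The network is implemented on numpy: 3x3 convolutions run as nine
shift-accumulate BLAS matmuls in channels-last layout, with manual
reverse-mode gradients and a standard Adam update. Every layer's backward
pass is verified against central finite differences in float64.

`width_scale` multiplies every internal width (ceil, minimum 1) so the
identical layer sequence runs at desk scale; 1.0 reproduces the reference
widths. A fully connected variant with the same loss and latent contract
(`build_dense_denoiser`) serves low-dimensional analytic fixtures.

### Artifact filtering

Imaging artifacts (bright CK specks; multi-channel blurs and streaks) are
rare in pixel terms but, unlike biology, regionally clustered. Counting is
per scanner frame (1362 x 1004 px, predefined and non-overlapping):

* speck rule — connected components (8-connectivity) of CK pixels above
  0.5 with area ≤ 10 px are counted; a frame with strictly more than 500
  is flagged (the speck detector's cutoff and area are this package's
  operationalization, validated on the synthetic fixture);
* concentration rule — a frame holding strictly more than 25 of the
  top-10,000 ranked tiles is flagged.

Both flag sets are unioned, all tiles of flagged frames are deleted from
the ranking (order-preserving), and the cohort is re-drawn from survivors,
so each removed slot is filled by the next-ranked clean tile. Both flag
sets are computed on the unfiltered ranking. `FilterConfig.for_slide`
rescales the concentration rule for smaller slides by preserving the
full-scale proportions (top_k = N/250; threshold = 5.76x the uniform
per-frame share).

### Evaluation

Ground truth is a set of labeled event centroids; a tile is positive iff it
contains at least one centroid (half-open footprints give a unique
assignment). TPR and FPR at a cohort are computed against all positive and
negative tiles of the slide; the ROC sweeps the cohort size from 0 to N in
one ordered pass, with tied rarity values entering as single diagonal
segments so the trapezoidal AUROC equals the Mann–Whitney probability with
ties counted ½ (asserted against a brute-force pairwise oracle and
scikit-learn). Quartile summaries across slides interpolate each curve onto
a common FPR grid (taking the maximal TPR on vertical segments) and report
pointwise 25th/50th/75th percentiles with linear interpolation between
order statistics.

## The synthetic simulator

The simulator emulates what matters to rarity detection, not optics: a low
noisy background (level 0.02, Gaussian σ 0.01); ~1.2 leukocyte-like cells
per tile (D 0.55, CD 0.6, blob σ 2.5 px); a handful of rare cells from the
seven phenotype categories rendered as isotropic Gaussian blobs with peak
CK or V intensity ≥ 0.7 (high-contrast, emulating cultured
SK-BR-3/HPAE cells spiked into normal-donor blood), ±10% intensity jitter,
radius σ ≈ 2.5–3.5 px; and, in designated frames only, hundreds of 1–4 px
CK specks plus one multi-channel streak. Frame dimensions are multiples of
32 so tiling discards nothing. Rare cells are re-drawn until pairwise
separated by a tile so each occupies a distinct ground-truth tile;
everything is reproducible bit for bit from one seed.

What it does not model: nuclear texture and cell morphology, optical blur
and vignetting, staining variability, platelet-coated or clustered
phenotypes, and the long-tailed heterogeneity of real blood. Passing on
synthetic slides therefore demonstrates the pipeline's mechanics (ranking,
filtering, bookkeeping, determinism) and the score-function principle — not
clinical performance.

A 2-D Gaussian-mixture reference provides closed-form `|∇log p|`,
log-density, HDR membership, and seeded ancestral sampling for validating
the theory directly.

## Desk-scale study protocols

Full-scale slides (2.5M tiles; 5000 Adam steps) need a GPU-day class
budget; the canned studies in `redetect.studies` reproduce the protocol's
structure at CPU-minutes scale. Spiked-recovery study: three slides of 24
frames x 672² px = 10,584 tiles, four spiked cells each (two epithelial
D|CK, two endothelial D|V|CD), width_scale 0.25 (latent 128), batch 500,
σ 0.05, cohort N/1000 = 10, concentration filter rescaled by
`FilterConfig.for_slide`. The learning rate is *path-matched*: Adam moves
each parameter ~lr per step, so a corpus yielding S steps uses
lr = (5000 · 1e-5)/S to traverse the full-scale protocol's total
displacement. (Measured on these fixtures, a 10x finer discretization of
the same path — smaller batches, more steps — leaves scores essentially
unchanged, so the protocol is converged at its path length.)

Known desk-scale limitation: with only ~10 cohort slots and 4 cells per
slide, TPR is extremely granular (one miss costs 0.25), and a cell whose
centroid lands within a few pixels of a tile corner splits its energy four
ways so that no tile carries a strong signal — the same "smaller pieces"
failure mode seen with real spiked cells. The ranking AUROC is robust to
this (≥ 0.999 in the shipped study seeds); worst-slide TPR at the
1000-fold cutoff is not, and the test suite reports it against the
full-scale floors without relaxation.

Score-function study: the dense denoiser is trained to convergence (100
epochs, Adam 1e-3, batch 500) on 5000 samples of a two-component 2-D
mixture with σ = 0.2 — about a third of the within-component spread, large
enough that the σ²-scaled score dominates the network's approximation
error. The probe is the clean-input residual ‖x − r(x)‖ ≈ σ²|∇log p(x)|:
in two dimensions the corrupted-input error would be dominated by the
added noise itself (‖ε‖ concentrates only in high dimension), so the
clean-input residual is the faithful low-dimensional probe of the same
property. Reported: Spearman correlation of the residual with the
closed-form |∇log p|, and the ratio of mean |∇log p| outside vs inside the
50% highest-density region.

## Numerical and design choices

* "Magnitude of the difference" per channel is the L2 norm, consistent
  with the squared-L2 training loss; the normalization magnitude is the L2
  norm over all four channels jointly.
* Noise is not clipped after addition; the clean tile is the target.
* Scoring may average channel errors over K seeded noise draws (default
  1). On 4096-value tiles a single draw's norm concentrates and the score
  variance contribution is negligible (measured: zero to three decimals),
  so K = 1 loses nothing at full tile dimension.
* Ties in rarity are broken by ascending tile id; tile ids are assigned
  row-major within frames, frames ascending — manifests and cohorts are
  byte-reproducible.
* Both "exceeded" thresholds in the artifact filter are strict
  inequalities; residual right/bottom frame margins are discarded, not
  padded; coordinates are 0-based with half-open footprints.
* Per-stage seeds derive from one global seed by stage-name hashing;
  corruption noise is counter-based (Philox keyed by seed, tile id, draw),
  so any tile's noise is reproducible in isolation.
* Weight init: He-normal for ReLU layers, variance-1/fan-in for the linear
  latent head and the sigmoid output conv; biases zero.
* Degenerate inputs are errors, not silent defaults: empty batches,
  all-black slides (undefined normalized rarity), a latent dimension
  exceeding the flattened encoder width, cohort sizes beyond N.

## Limitations

* The per-slide training cost at full width/scale is a GPU workload; the
  numpy engine is tuned for desk-scale widths (it reaches a few GFLOPS on
  one CPU, not cuDNN rates).
* The rarity metric inherits the score function's blind spots: events that
  are common-looking per tile (e.g., V-positive cells inside a V-expressing
  leukocyte background) score low; the channel weights are fixed inputs,
  not learned.
* Centroid-containment labeling charges a detection to exactly one tile;
  events straddling tile boundaries dilute their own signal (see above).
* The speck detector's intensity/area parameters are package conventions
  validated on synthetic artifacts only.
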