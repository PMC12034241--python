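# Methods

## Problem setting

Given a sparse intra-chromosomal Hi-C contact map `H_sparse` at 10 Kbp
resolution (and optionally five binned ChIP-seq tracks), impute the dense
contact map `H_target` that a deeply sequenced experiment would produce.
Imputation runs along the diagonal in 256-bin (2.56 Mbp) windows with a
30-bin (0.3 Mbp) stride; overlapping window predictions are averaged to
suppress border effects, and the final window is right-anchored at the
chromosome end so the tail is covered without padding.

## Preprocessing

Raw binned counts are KR-balanced (Knight–Ruiz inexact-Newton iteration
with an inner conjugate-gradient solve; all-zero rows are masked out of the
balancing and returned as zero; non-masked rows of the balanced matrix sum
to 1 within `tol = 1e-8`, `max_iter = 1000`), then clip-normalized: values
above the per-chromosome 99.9th percentile are clipped and the map divided
by that cutoff, giving entries in [0, 1]. The percentile is computed over
the nonzero upper-triangle entries within one window size of the diagonal —
the region the model actually sees; the far field would otherwise dominate
the order statistics with near-zero noise. KR precedes clipping. Tracks
are binned as coverage-weighted means per 10 Kbp bin (uncovered bins are
0) and normalized by the same 0–99.9th-percentile rule. Downstream losses
and metrics operate on the clipped scale; raw counts are recoverable only
up to the clipping constant (a documented limitation).

Coordinates are 0-based bin indices with half-open genomic spans, matching
cooler conventions. Supported formats: coordinate-triplet text, a minimal
single-resolution `.cool` (HDF5) reader/writer, bedGraph, and bigWig
(read). Asymmetric triplet input is symmetrized by the maximum with a
warning.

## Graph construction

Each window becomes a weighted graph: nodes are bins; every nonzero entry
contributes both edge orientations with the normalized contact value as
the scalar edge weight. Self-loops (diagonal entries) are kept in the edge
list — they stabilise degrees in the Laplacian — but are excluded from the
attention sums, which run over each node's neighbour set.

Positional encodings come from the symmetric normalized Laplacian
`L = I − D^{−1/2} H D^{−1/2}` (weighted degrees). "Top components" is read
as the eigenvectors of the `k = 8` *smallest non-trivial* eigenvalues —
the standard Laplacian-PE convention in which low-frequency eigenvectors
carry structure (compartments, TADs) and high-frequency ones noise; a
config switch (`smallest` being the default ordering) would flip this.
One zero eigenvalue per connected component is skipped as trivial.
Eigenvector sign is fixed so each column's largest-magnitude entry is
positive (determinism); columns are unit-norm. Zero-degree (isolated) bins
get zero PE rows — no spectral information exists for them — and if fewer
than `k` non-trivial eigenvectors exist the remaining columns are zero, so
the feature width is always `k`. PEs are computed per window, not per
chromosome: the Laplacian is defined on the model's actual input graph.

Node features are `[PE | tracks]` per the ablation flags: the full model
uses both (width 13 at defaults), the PE-only variant drops tracks, and
the edges-only baseline substitutes a single constant column.

The expected-contact prior (used when no Hi-C input exists) is a matrix
whose entries depend only on genomic distance: either `exp(−α·|i−j|)` or
an empirical mean-by-distance profile estimated from training maps
(the default, with a least-squares exponential fit as fallback), scaled to
[0, 1] with unit diagonal.

## Model

**Encoder.** A linear input projection followed by `n_layers`
graph-transformer convolutions with residual connections
(`x ← x + relu(layer(x))`). Each layer computes, per head,

    x'_i = W1 x_i + Σ_{j≠i} a_ij (W2 x_j + W5 e_ij)
    a_ij = softmax_j( (W3 x_i)ᵀ (W4 x_j + W5 e_ij) / √d )

with `W5` (the edge-weight embedding) shared between the attention logits
and the messages, and `d` the per-head width. The softmax runs over the
observed neighbour set by default — consistent with message passing on a
sparse input — with a dense variant attending over all other nodes
available behind `dense_attention` (the two coincide on complete graphs,
which the tests exploit). Multi-head attention (4 heads, concatenated) is
used; head count, hidden width (32) and layer count (2) are configuration
with these defaults, as the architecture's fine detail is not otherwise
pinned down.

**Decoder.** The contact-probability map `P = X′X′ᵀ` (symmetric positive
semi-definite) enters a UNet: a stem conv, three Down blocks
(3×3 conv + group norm + swish, then a stride-2 conv) halving the spatial
size three times (256 → 32), a Middle block wrapping token self-attention
`softmax(QKᵀ/√d_k)V` between two conv blocks, and three Up blocks
(nearest-neighbour upsample + conv — the functional equivalent of a
deconvolution — then fusion with the same-level Down features). Fusion is
cross-attention (queries from the up path, keys/values from the skip) at
levels whose token count is at most `max_attn_tokens` (1024 by default,
i.e. spatial size ≤ 32); coarser levels use concatenation + conv, since
dense token attention at 256×256 (65 536 tokens) is computationally
infeasible. The fusion mode per level is fixed at construction so every
parameter participates in training. A group-norm / swish / 3×3-conv head
produces the window, which is symmetrized as `(O + Oᵀ)/2` before the loss.

**Loss and optimisation.** Plain MSE — the *sum* of squared entry
differences over the window (a mean-reduction flag exists; the two differ
only by a scale absorbed into the learning rate). Adam, lr 1e-4 at full
scale. Early stopping tracks validation SSIM with patience 10; the
best-validation checkpoint is returned. All randomness (initialisation,
per-epoch shuffling) is seeded; two runs with the same seed produce
identical losses.

The whole network runs on a compact reverse-mode autodiff engine over
float64 numpy arrays written for this package (`hicformer/nn.py`);
gradients of every primitive are verified against central finite
differences in the test suite.

## Synthetic data

The generator emulates the contact-map features the model must recover:

* expected counts `∝ exp(−α·|i−j|)` with `α = 0.05`/bin by default —
  a decay length of ~20 bins (200 Kbp), giving TAD-scale contrast;
* multiplicative TAD blocks (enrichment 2–4×, sizes 20–45 bins, tiled with
  small gaps), with ~60 % of TADs carrying a corner loop;
* loops as Gaussian bumps of 1-bin scale multiplying the local rate by
  25–50× at the anchor pair — strong focal dots, chosen so planted
  structure is unambiguously detectable by a kernel caller;
* Poisson counts on the upper triangle (mirrored), scaled to an expected
  300 000 read pairs per 256-bin chromosome — a deeply-sequenced target at
  this matrix size; low-read-count inputs are binomial thinnings (1/50 by
  default, mirroring a deep→shallow sparsity ratio);
* tracks: a CTCF-like track with sharp peaks at loop anchors and TAD
  boundaries, active-mark-like tracks enriched over TAD bodies,
  repressed-mark-like tracks anti-enriched, all with log-normal
  multiplicative noise (positive, right-skewed, like real coverage).

What the generator does *not* emulate: restriction-fragment/ligation
artefacts, coverage bias along the genome (so KR balancing is exercised
but not stressed), inter-chromosomal contacts, compartment-scale
checkerboards beyond TAD blocks, and replicate-level biological
variability. Passing tests therefore demonstrate that the pipeline and
model behave as specified on data with known planted structure — not that
the desk-scale model reaches published performance on real Hi-C.

## Evaluation

All metrics are restricted to the 2 Mbp diagonal band the model predicts
(entries beyond it are masked to zero in both maps).

* **SSIM**: windowed structural similarity, 11-pixel Gaussian windows,
  data range fixed at 1.0 on the clipped scale.
* **GenomeDISCO**: each map is row-normalized to a transition matrix; for
  walk lengths t = 1..3 the L1 difference of the t-step matrices is scaled
  by the mean number of non-empty rows; the score is 1 minus the mean
  scaled difference (uniform t-weighting). Identical inputs score exactly
  1; the score is invariant to global rescaling of either map.
* **Loop calling**: a donut-kernel detector — a pixel is a candidate when
  its 3×3 core mean exceeds 1.5× the surrounding ring mean (7×7 kernel),
  its patch correlates with a Gaussian focal-peak template above 0.45
  (rejecting Poisson ratio noise), and at least 60 % of the kernel pixels
  are non-empty (rejecting isolated spikes on sparse maps); candidates are
  non-maximum-suppressed on the template correlation. Externally called
  loop sets can be injected as BEDPE.
* **Loop F1**: `2TP / (2TP + FP + FN)` with greedy one-to-one anchor
  matching within ±1 bin (Chebyshev); two empty sets score 1 with a
  warning.

## Desk-scale protocols

The experiment module scales the study down to one CPU: 20 simulated
chromosomes of 256 bins (12 train / 4 validation / 4 test), 64-bin windows
with stride 64, encoder hidden width 32 (4 heads, 2 layers), UNet channels
(8, 12, 16), lr 2e-3, 8 epochs with validation every second epoch; ~45 s
per training run. The recovery
protocol repeats this over 10 independent seeds; the ablation compares
full / PE-only / edges-only over 5 seeds; the prior protocol trains the
no-Hi-C mode once, with the prior's decay profile estimated from the
training split's dense maps.

Known limitations at this scale: the model reliably recovers distance
decay and TAD blocks (imputed SSIM exceeds the sparse input's SSIM on
held-out chromosomes across seeds, and climbs further with longer
training), but focal loop recovery is weak — MSE-trained small models blur
corner peaks, while the 1/50-thinned input retains sharp high-count loop
pixels that the kernel caller rewards. Reproducing published-scale loop
recovery requires the full 256-bin windows, a wider model and
hours-long training, which is outside this package's test envelope.

## Numerical choices

* float64 throughout; Laplacian construction agrees with the dense formula
  to 1e-12; eigenvalues of the normalized Laplacian lie in [0, 2].
* KR tolerance 1e-8 on the squared residual of unit row sums; failure
  raises an error carrying the last residual rather than returning an
  unconverged map.
* Softmax logits are max-shifted and floored at −60 before
  exponentiation — weights below e^−60 are numerically irrelevant but
  subnormal arithmetic is pathologically slow on some CPUs.
* Eigenvector sign fixing (largest-magnitude entry positive) makes PEs
  deterministic; sign-flip augmentation during training is off by default.
* Degenerate inputs: all-zero matrices are returned unchanged from clip
  normalization (warning), produce zero PE rows and empty edge lists, and
  are rejected by GenomeDISCO (undefined).
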