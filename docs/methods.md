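# Methods

`neurofuse` implements a site-adversarial multimodal classifier for major
depressive disorder (MDD) built from two pathway-specific encoders, a
bidirectional cross-attention fusion stage, and a pair of task heads trained
as a min–max game against acquisition-site information. This note records
the model, the training procedure, the synthetic cohort it is validated on,
and the design decisions that were genuinely open.

## Inputs and notation

Each subject contributes two modalities:

* **ROI time series** `X_ts ∈ R^{T×d}` — per-region average BOLD traces
  (consortium data: d = 116 AAL parcels, T between 90 and 240 depending on
  the site's protocol). Variable lengths are zero-padded per batch with a
  per-timestep validity mask `M ∈ {0,1}^{B×T}`. The mask is per-timestep,
  broadcast over regions: padding removes whole timesteps, so a per-feature
  mask would be redundant.
* **Gray-matter volume (GMV)** `X_gm ∈ R^{D×H×W}` — a voxelwise structural
  map (nominal 121×145×121; the desk-scale default is 16×20×16).

Labels are binary (HC = 0, MDD = 1); every subject also carries a site id
in `0..S−1`, densely re-indexed from the manifest.

## Dual-pathway encoders

**Functional pathway.** A bidirectional LSTM (hidden size `h` per
direction, default `h = d`) reads the padded sequence; forward and backward
states are concatenated into `H_lstm ∈ R^{B×T×2h}`. At masked timesteps the
recurrent state carries over unchanged and the output is zeroed, so padding
cannot influence valid positions. A stack of `L` pre-norm Transformer
encoder layers (default 4; the compact preset uses 2) models global
temporal structure; self-attention adds `−∞` to the scores of masked key
positions before the softmax, so masked keys receive exactly zero weight
and every attention row is a probability distribution over valid keys only.
Sinusoidal positional encodings are added before the Transformer (the
recurrence already provides order, but the encoder follows standard
practice; a flag disables them). A masked mean pool (sum over valid
timesteps divided by the sequence length) and an affine projection produce
`z_ts ∈ R^{d_out}`. The pooled mean is the masked one — an unmasked `1/T`
average would leak padding into the embedding. The whole pathway is padding
invariant to 1e−6: appending arbitrary extra padding leaves `z_ts`
unchanged, which the suite checks with an unpadded re-run oracle.

**Structural pathway.** A 3-D residual CNN: stem convolution, four
cascaded stages of basic residual blocks (two 3×3×3 convolutions with batch
norm and ReLU; identity shortcut, or a 1×1×1 projection when shape
changes), stride-2 downsampling at stages 2–4, global average pooling, and
an affine projection to `z_gm ∈ R^{d_out}`. No softmax is applied to the
representation: a softmax-ed embedding would destroy the residual fusion
geometry and the linear heads downstream. Batch norm uses batch statistics
in training and running averages (momentum 0.1) in evaluation. The default
channel schedule (16, 32, 64, 128) with one block per stage targets
desk-scale volumes; a `resnet18_3d` preset ((2,2,2,2) blocks,
(64,128,256,512) channels) is provided for full-size images.

## Bidirectional cross-attention fusion (BCAF)

Cross-attention between two per-sample *vectors* read literally is a 1×1
attention whose softmax is identically one. To keep the mechanism
non-degenerate while preserving the published formulas, each embedding is
reinterpreted as `n_tokens` tokens of width `d_in = d_out / n_tokens`
(default 8 tokens). One direction computes single-head scaled dot-product
attention of the time-series tokens (queries) over the GMV tokens (keys,
values) with scaling `1/√d_in`, and updates residually:

    z'_ts = z_ts + Attention(z_ts W_Q1, z_gm W_K1) · (z_gm W_V1)

The mirrored direction uses an independent parameter triple. `n_tokens = 1`
reproduces the literal one-token equation (`z' = z + z_c W_V`) and is kept
as a tested special case. A Modality Weighting Allocation Module —
`ω = softmax(W4 · ReLU(W3 [z'_ts ‖ z'_gm]))`, hidden width 64 — yields
per-sample weights, and the fused embedding is the convex combination
`z_fusion = ω1 z'_ts + ω2 z'_gm`, which therefore lies componentwise
between its two inputs. No layer norm is used inside the fusion stage. An
ablation switch bypasses the stage entirely (embeddings pass through, fixed
weights ½/½).

## Adversarial multitask objective

Two affine heads read the embeddings: the disease classifier on the
concatenation `[z_ts ‖ z_gm ‖ z_fusion]` (2 logits) and the site classifier
on `z_fusion` behind a gradient-reversal layer — identity in the forward
pass, gradient multiplied by −1 in the backward pass. With cross-entropies
`L_D` (disease) and `L_S` (site) and trade-off `β ∈ [0,1)` (default 0.1),
the optimizer descends on the backprop scalar

    total = (1 − β)·L_D + β·L_S(through GRL),

which yields exactly the coupled updates of a min–max objective: the site
head descends on `β L_S`, the disease head on `(1−β) L_D`, and every shared
parameter receives `(1−β)∂L_D − β∂L_S`. The literal min–max value
`(1−β)L_D − βL_S` is reported for logging. A finite-difference oracle on a
dense toy model verifies each parameter group's gradient to 1e−4 relative.

**Inner maximization.** With a single optimizer the affine site head lags
the moving embedding: at desk scale the reversed gradient then drives
features to be *confidently wrong* about site (site loss far above
`ln S`) — a permuted site structure that a freshly fitted linear probe still
decodes. The trainer therefore refits the site head to near-optimality
before each epoch (a multinomial logistic regression on the current fused
embeddings of the training subjects), so the reversed gradient pushes
against a strong adversary and the game settles at the intended
equilibrium, site loss ≈ `ln S`. Per-batch updates in between keep the
exact coupled semantics above. `TrainConfig.site_head_refit` disables this
to recover plain alternating updates. The reversal strength is fixed at 1
(`β` carries all weighting); `TrainConfig.grl_strength` is the schedule
hook, default constant.

## Training protocol

AdamW with decoupled weight decay 0.01 and global-norm gradient clipping at
5.0. The full-scale defaults follow the consortium protocol: learning rate
5e-5, batch size 16, 50 epochs, `β = 0.1`, 5-fold stratified
cross-validation. For the bundled synthetic cohorts (a few hundred
subjects) those rates barely move the weights, so `TrainConfig.desk_scale`
uses learning rate 1e-3 and batch size 32 with short schedules; `β` and the
architecture are unchanged. Batches are bucketed by sequence length
(shuffle, stable sort by length, shuffle batch order) so each mini-batch
pads to roughly its own scan length; this regroups the stochastic updates
but does not change the data seen per epoch. Normalization statistics
(per-region z-score for time series over valid timesteps; one global
z-score for GMV) are computed on the training portion of each split only.
Prediction thresholds the positive-class softmax probability at 0.5; AUC is
the Mann–Whitney rank statistic with midrank ties, cross-checked against
trapezoidal ROC integration. Training is deterministic given the seed
(initialization, batch order and dropout all derive from it).

## Evaluation protocols

* **Stratified k-fold** (default k = 5) over diagnosis labels; folds
  partition the cohort exactly; summary is mean ± SD across folds.
* **Leave-one-site-out (LOSO):** each site in turn is the held-out test
  set; the model trains on the remaining sites only (audited by index).
  Within the held-out site the majority diagnosis class is down-sampled at
  random (seeded, without replacement) to the minority count, so a site
  with 50/33 class counts is evaluated on exactly 33/33 and per-site
  accuracy is chance-corrected by construction.
* **Site probe:** a post-hoc multinomial logistic regression trained on
  frozen fused embeddings, scored by stratified 5-fold accuracy; with
  balanced sites its chance level is 1/S. A silhouette-based probe
  (`site_separability_probe`) serves the same purpose for raw feature
  matrices. Embedding tables export per subject with seeded 2-D t-SNE
  (perplexity 30, reduced automatically for small cohorts) for the
  site-mixing visualizations.

## Synthetic multi-site cohort

The simulator emulates the *structure* of a multi-site consortium release,
not BOLD physiology. For site `s`, subject `i` with diagnosis `y`, region
`r`:

    x_t = g_{s,r} · (a_{i,r} + u_t + y·δ_r) + o_{s,r}

with `u_t` a stationary AR(1) process (coefficient 0.5, innovation SD 1 —
a stand-in for band-limited resting-state signal), `a_{i,r} ~ N(0, 1)` a
between-subject intercept, `δ_r` the disease amplitude shift (default 0.6
on 4 of the regions, i.e. Cohen's d ≈ 0.6 on subject-level region means),
and linear scanner effects `g_{s,r} ~ 1 + N(0, 0.1)`,
`o_{s,r} ~ N(0, 0.5)` — the standard gain/offset model of site effects.
GMV volumes are a smooth radial template partitioned into `d` equal-size
radial-shell parcels (so region attribution has a defined voxel→region
map), plus `y·Δ` on the affected parcels, a per-subject field, per-site
gain/offset, and white voxel noise. Per-site scan length is drawn from a
site-specific 10-volume window; the desk default spreads the windows over
T ∈ [90, 140] (typical short-scan protocols), while the full consortium
range [90, 240] is supported and exercised in tests. The default cohort is
6 sites × (20 MDD + 20 HC), 32 regions, 16×20×16 volumes — it trains in a
few minutes per run on one CPU.

What the simulator does *not* model: hemodynamics, head motion, spatial
autocorrelation of BOLD noise, anatomical realism, nonlinear site effects,
or site-by-disease confounding (sites have identical case mixes by
default). Passing tests therefore show that the architecture and the
adversarial objective behave as designed under linear gain/offset site
effects and additive group effects — not that the pipeline reaches any
particular accuracy on real consortium data.

## Region attribution and statistics

Region-level attribution treats each region as a player in a cooperative
game whose payoff is the mean predicted MDD probability over the evaluated
subjects. "Absent" regions are occluded with their training-set mean (the
pooled per-region mean trace for time series; the per-voxel mean volume
within the parcel for GMV). Shapley values are estimated by Monte-Carlo
sampling of region orderings (default 128 permutations; small games are
enumerated exactly, where efficiency, symmetry and dummy axioms hold to
1e−6). Signed means are retained and rows are ranked by |attribution|,
with a two-sided Welch test on each region's subject-level feature reported
alongside; no multiple-testing correction is applied to these p-values.

Demographic comparisons use Welch's unequal-variance t (with
Welch–Satterthwaite degrees of freedom), recomputable from published
summary statistics via `t = (m1−m2)/√(s1²/n1 + s2²/n2)`, and a Yates
continuity-corrected chi-square on the 2×2 sex-by-group table (the
correction clamps `|O−E|−0.5` at zero; the uncorrected variant is available
by flag). The published consortium sex split reproduces the printed
statistic only with the correction applied — 7.4757 corrected versus 7.708
uncorrected.

## Numerical and engineering notes

* All computation runs on an in-repo reverse-mode autodiff core over
  float64 numpy arrays (tensors record their producing op and replay it
  backwards). Every hand-written backward rule — including the fused
  BPTT LSTM and the 3-D convolution — is verified against central finite
  differences. Backward closures capture plain arrays, never their own
  output tensor, so computation graphs free by reference counting.
* Masked softmax uses true `−∞` score offsets; a fully masked sample is a
  validation error upstream.
* Degenerate inputs: zero-variance regions normalize to zero with a
  warning; a single-class evaluation set reports AUC as missing; sites with
  a single sample are excluded from the silhouette probe; a held-out LOSO
  site with one class is skipped with a warning.
* Weight initialization: Xavier-uniform for projections and convolutions,
  uniform ±1/√h for recurrent weights, zeros for biases and LSTM states —
  all drawn from the seeded generator in a fixed order.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 2–3-site cohorts of 8 regions and 10×12×10 volumes. The
disentanglement experiment (tests and `scripts/acceptance.py`) uses the
default cohort above with the compact model preset (embedding width 32,
two Transformer layers, ResNet channels (8,16,16,32) with a stride-2 stem),
14 training epochs for the probe comparison and 6 epochs per LOSO fit —
sizes chosen so a full run completes on a single CPU in minutes while
leaving the adversarial game enough steps to reach its equilibrium.

## Known limitations

* The inner-maximization refit assumes an affine site head; a deeper
  adversary would need a different solver for the same role.
* Table-style LOSO reports on real consortium data print distinct
  accuracy/balanced-accuracy/AUC values; standard definitions are
  implemented, under which they coincide only in special cases (balanced
  test sets make accuracy and balanced accuracy equal in expectation, not
  identically).
* Normalization statistics are global across sites by default (per-site
  normalization is a config option); the source protocol does not state
  which was used.
* The consortium-scale architecture (116 regions, 121×145×121 volumes,
  hidden = 116) is supported by the same code paths but is not exercised by
  the test suite on CPU budgets.
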