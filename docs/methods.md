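# Methods

## Sequence representation

UTR sequences of 25–100 nt over {A, C, G, T} (U is accepted and mapped to
T) are one-hot encoded into an `L × 5` matrix with the fixed channel order
**A, T, C, G, pad**. Shorter sequences are left-padded with pad one-hots;
longer ones keep only their last `L` nucleotides, since the region adjacent
to the start codon carries most of the translational signal. Two dialects
exist: `L = 100` (variable-length model) and `L = 50` (fixed-length model;
inputs longer than 50 nt are truncated to their last 50 nt). Decoding is a
per-position argmax with ties broken toward the lowest channel index and
pad positions dropped. Reported positions use upstream coordinates:
position 1 is the nucleotide immediately upstream of the start codon,
counting away from it.

## Synthetic MPRA oracle

To give every stage a ground truth at desk scale, the package generates
reporter-assay-style libraries from a known scoring function

```
score(s) = base_level + Σ_i w(pos_i, s_i) − uaug_penalty · count_ATG(s)  [+ N(0, noise_sd)]
```

with defaults: `base_level = 5`, per-occurrence `uaug_penalty = 1`, and
position weights over the 20 positions nearest the start codon of
A: +0.12, T: −0.10, G: −0.08, C: 0. These plant the two robust,
interpretable determinants of initiation efficiency — upstream AUGs
creating ribosome-capturing uORFs, and Kozak-like A preference / T-G
disfavor near the start codon — with the penalty (1.0) deliberately larger
than the maximum positional gain of writing one ATG (0.22 + 0 + 0 = 0.22
per base, ≤ 0.66 per codon), so planting an extra ATG always lowers the
noiseless score. The default `noise_sd = 0.3` leaves the oracle explaining
roughly 90% of label variance for a random 50-nt library (signal variance
≈ 0.85 from ~0.15 positional plus ~0.7 uAUG-count variance). The oracle
makes no attempt to match the marginal MRL distribution or the polysome
generative process of a real experiment; libraries are uniform random
sequences, so real-data features like length–composition coupling, GC
structure and secondary-structure effects are absent. Tests passing on
this oracle demonstrate that the machinery recovers planted signal, not
that it matches wet-lab effect sizes.

## Discriminative model

`MrlPredictor` is a residual conv → GRU → residual dense regressor.
Convolutions are stride-1, same-padding, length-preserving; each block adds
an identity skip (1×1 projection where channel widths differ). The GRU
consumes the convolutional feature sequence position by position — one
recurrence step per position — and its final hidden state feeds the dense
blocks and a single linear output. Labels are standardized internally;
predictions are returned in original MRL units.

Training: MSE loss, Adam, batch 128, initial learning rate 10⁻³ multiplied
by 0.1 after 5 epochs without validation improvement, early stop after 12,
best-validation weights restored. Data are split 10% test, remainder
80:20 train:validation, all seeded.

Default widths are `conv_filters = 32, kernel = 5, gru = 32, dense = 32`
(3 conv and 3 dense blocks). Exact widths are a free choice — the
reference architecture leaves them to hyperparameter search — and these
defaults were sized for single-core numpy training: they reach held-out
Spearman ≈ 0.97 on the noiseless 5,000-sequence oracle library in about a
dozen epochs (~1 minute), where doubling every width quadruples cost for
marginal gain on this oracle.

Hyperparameter search is successive halving: `pool_size` random
configurations (paper-scale default 8000; desk-scale constant 27 with
epoch budgets 1/2/4), each round training survivors for the round's budget
(doubling 2, 4, 8, … by default) and keeping the best
`ceil(n · (1 − drop_ratio))` by validation MSE — with the default
`drop_ratio = 2/3`, two-thirds are dropped per round; a small epsilon in
the ceiling guards float noise (9 · (1 − 2/3) must keep 3, not 4).

Greedy model soups average weights across identically structured models:
members are ranked by held-out MSE and merged one at a time, keeping a
candidate only if the ranking-set loss does not worsen; the soup therefore
never ranks below its best member. Ranking uses a held-out validation
split, never the final test set.

## Generative model

`UtrGenerator` is an autoencoder: encoder = three convolutions + dense to a
latent vector (default length 128); decoder = dense + three stride-1
transposed convolutions (length restored exactly) + row softmax over the
five channels. The composite loss per batch is

```
RE  = CCE(y_true, y_pred)  +  BCE(y_true[pad], y_pred[pad])
RL  = exp(MRL(input) − MRL(decoded))
L   = RE + λ · RL,    default λ = 100
```

Choices where the design was genuinely open:

* The BCE operand is the **pad channel across all positions** (that channel
  is what encodes padding), not the last position.
* `MRL(y_true)` is the predictor's score of the *input* sequence, not a
  measured label, so the loss is self-contained at inference time.
* Both CCE and BCE are **averaged over positions**, and pad positions are
  masked out of the CCE average so padding cannot dominate short
  sequences. Averaging versus summing over positions rescales RE by the
  sequence length; that scale ambiguity folds into λ (see the λ sweep
  below).
* Gradients of the RL term flow through the frozen predictor into the
  decoder's **continuous softmax output** — a continuous relaxation;
  discrete argmax decoding happens only at inference. The predictor's
  weights are excluded from the optimizer and verified unchanged.
* At inference, pad positions are masked and only the four nucleotide
  channels compete in the argmax, so the rewritten sequence always has the
  input's exact length; the generator is trained once per library and
  applied to arbitrary queries without per-query fine-tuning.

Behavior on the synthetic oracle (50-nt libraries): λ = 0 recovers a plain
autoencoder (≈ 99% positional identity given ~30 training epochs);
increasing λ over {0, 1, 100} monotonically raises the mean predicted MRL
of outputs. At λ = 1 rewrites touch a median of ~5 positions; at the
default λ = 100 the RL term dominates and rewrites touch most of the
20-position effect window plus composition-level uAUG avoidance (median
~35 of 50 positions) while erasing essentially all upstream AUGs. Note the
oracle's planted effects make even the *optimal* rewrite broad: ~15
expected non-A positions in the effect window plus uAUG repairs. λ trades
closeness for gain and should be tuned per application; the package
deliberately keeps the reference default.

## Attribution

Shapley values are estimated by permutation sampling: features are the
(position, channel) entries of the encoded input; for each sampled feature
order (one background draw per order) the marginal change in model output
as each feature switches from the background's value to the explained
input's value is accumulated, and the average over orders is reported.
For additive models this equals `w_i (x_i − E[b_i])`; with a single
background sample the efficiency, symmetry and dummy axioms hold exactly
under exhaustive enumeration (verified against an enumeration oracle in
the tests). The default background is a sample of training-library
encodings. Dataset-level rankings report mean |value| across explained
instances with a signed mean as direction summary, labeled in upstream
coordinates (e.g. `3-A`).

## Analytics

Substitution matrices count position-wise mismatches normalized by total
mismatches; composition shift restricts to mutated sites; uAUG counting
uses a sliding window (overlaps counted); edit count is Hamming distance.
The Hausdorff distance is computed on caller-supplied embedding points
(generator latents, or any 2-D projection applied upstream) in its
directed form `max_a min_b ‖a − b‖`, with a symmetric variant also
exposed; keeping the metric embedding-agnostic keeps it deterministic,
unlike distances measured inside a stochastic t-SNE space.

## Numerical and implementation notes

Networks run on a small reverse-mode autodiff engine over float64 numpy
arrays (iterative topological-order backprop, exact softmax and GRU
Jacobian-vector products; convolution as a K-term shifted-matmul with a
matching scatter backward). Gradients of every layer and of the composite
generator loss are verified against central finite differences to ~1e-8
relative error in the test suite. Probability logs are clipped at 1e-12;
validation-loss improvement uses a 1e-12 tolerance so bit-identical
plateaus register as no improvement. Library sampling, weight
initialization, batch order, splits and Shapley permutations all derive
from explicit integer seeds.

## Problem sizes used in the shipped runs

The test suite and `scripts/acceptance.py` train on a 5,000-sequence
noiseless 50-nt oracle library (3,600 train / 900 validation / 500 test),
predictor capped at 12 epochs, generators trained on 2,000 sequences for
30 epochs at batch 128, and evaluate on 200 held-out sequences; these sizes were
chosen so a full pipeline run completes in minutes on one core while
leaving the planted signal comfortably recoverable.

## Known limitations

* The oracle is additive; epistasis, secondary structure and
  length-dependent effects are out of scope, so attribution and
  optimization results on real MPRA data will be harder than the synthetic
  tests suggest.
* The RL term's exponential can dominate at large λ, driving broad
  rewrites; there is no constraint forbidding uORF creation — uORF loss is
  an emergent, statistically tested property.
* Sampled Shapley error decays as 1/√n_perm; the defaults favor speed.
* No latent-space sampling/interpolation, no variational term, and no
  re-implementation of external baseline predictors.
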