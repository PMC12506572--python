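# utropt

Predict the translation efficiency of a 5′ UTR and rewrite it — minimally —
for higher efficiency.

The 5′ untranslated region controls how efficiently ribosomes initiate on an
mRNA: upstream AUGs capture scanning ribosomes, and the nucleotide context
just upstream of the start codon (the Kozak region) tunes initiation.
`utropt` couples two models around this biology:

* **A discriminative regressor** (`MrlPredictor`) that maps a one-hot
  encoded UTR (25–100 nt, left-padded; channels A, T, C, G, pad) to its
  **mean ribosome loading** (MRL), the polysome-profiling readout of
  translation efficiency. Architecture: three residual-connected 1-D
  convolution blocks → a GRU consuming the convolutional feature sequence →
  three residual-connected dense blocks → one linear output. Training uses
  MSE, an initial learning rate of 10⁻³ cut to 1/10 after 5 epochs without
  validation improvement, and early stopping after 12.
* **A generative autoencoder** (`UtrGenerator`) trained against the *frozen*
  predictor with the composite loss

  ```
  RE_loss    = CCE(y_true, y_pred) + BCE(y_true[pad], y_pred[pad])
  RL_loss    = exp(MRL(y_true) − MRL(y_pred))
  Total_loss = RE_loss + λ · RL_loss        (default λ = 100)
  ```

  The reconstruction term keeps the rewritten sequence close to the input;
  the ribosome-loading term rewards any gain in the predictor's score of
  the decoded output. Inference masks pad positions, so the optimized
  sequence always has the input's exact length.

Also included: HyperBand-style successive halving over the architecture
space (default pool 8000; a desk-scale pool of 27 with epoch budgets
1/2/4), greedy **model soups** (weight averaging that accepts a member only
if held-out loss does not worsen), permutation-sampling **Shapley
attribution** of predictions to (position, nucleotide) features, a
**synthetic MPRA oracle** with planted Kozak-like and upstream-AUG effects
that provides ground truth at desk scale, and set-level analytics
(substitution spectra, composition shift at mutated sites, uAUG counts,
directed Hausdorff distance between embedding clouds).

All networks run on a compact numpy reverse-mode autodiff engine that ships
with the package; there is no GPU code path.

## Worked example

```python
import numpy as np
from utropt import (MrlPredictor, UtrGenerator, make_oracle, sample_library,
                    split_dataset, evaluate_spearman)

oracle = make_oracle(noise_sd=0.0, seed=1)          # known ground truth
lib = sample_library(oracle, 5000, (50, 50), seed=1)
train, val, test = split_dataset(lib, seed=1)        # 10% test, rest 80:20

model = MrlPredictor(input_len=50, max_epochs=12, random_state=0)
model.fit(train["seq"].tolist(), train["mrl"].to_numpy(),
          X_val=val["seq"].tolist(), y_val=val["mrl"].to_numpy())
print(round(evaluate_spearman(model, test["seq"].tolist(),
                              test["mrl"].to_numpy()), 3))
# 0.971

gen = UtrGenerator(predictor=model, lambda_rl=100.0, seq_len=50,
                   n_epochs=12, random_state=2)
gen.fit(train["seq"].tolist()[:2000])
res = gen.optimize(test["seq"].iloc[0])
print(round(res.mrl_orig, 2), "->", round(res.mrl_opt, 2),
      f"({res.n_substitutions} substitutions)")
# 4.11 -> 6.43 (41 substitutions)
```

The Spearman correlation of 0.971 says the regressor has recovered the
oracle's ranking of sequences almost perfectly from 3,600 training
examples; the optimizer then rewrites a held-out UTR from well below to
well above the library mean (≈ 3.95), mostly by removing upstream AUGs
and enriching A in the window upstream of the start codon. At the default
λ = 100 the ribosome-loading term dominates and rewrites are aggressive;
lower λ (e.g. 1) stays much closer to the input at a smaller gain.

The same pipeline is scriptable from the shell:

```bash
utropt simulate --n 5000 --min-len 50 --max-len 50 --seed 1 --out lib.tsv
utropt train --library lib.tsv --out-prefix pred --seed 0
utropt train-generator --library lib.tsv --predictor-ckpt pred --out-prefix gen
utropt predict  queries.fa --model-choice fixed50 --checkpoint pred --out scores.tsv
utropt optimize queries.fa --predictor-ckpt pred --generator-ckpt gen --out optimized.tsv
```

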