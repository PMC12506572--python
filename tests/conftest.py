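"""Shared fixtures.

The expensive end-to-end artifacts (a trained predictor and trained
generators) are session-scoped so the acceptance-style tests share one
pipeline run instead of retraining per test.
"""

import numpy as np
import pytest

from utropt import (MrlPredictor, UtrGenerator, make_oracle, sample_library,
                    split_dataset)

RANDOM_NT = np.array(list("ACGT"))


def random_seq(rng, length):
    return "".join(RANDOM_NT[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def oracle():
    """Noiseless synthetic MPRA oracle (planted Kozak-like and uAUG effects)."""
    return make_oracle(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def library(oracle):
    """5,000 oracle-labeled 50-nt sequences, split 72/18/10."""
    lib = sample_library(oracle, 5000, (50, 50), seed=1)
    return split_dataset(lib, seed=1)


@pytest.fixture(scope="session")
def trained_predictors(library):
    """Three seeds of the default predictor trained on the noiseless library."""
    train, val, _ = library
    models = []
    for seed in (0, 1, 2):
        m = MrlPredictor(input_len=50, max_epochs=12, random_state=seed)
        m.fit(train["seq"].tolist(), train["mrl"].to_numpy(),
              X_val=val["seq"].tolist(), y_val=val["mrl"].to_numpy())
        models.append(m)
    return models


@pytest.fixture(scope="session")
def trained_predictor(trained_predictors):
    return trained_predictors[0]


@pytest.fixture(scope="session")
def generators(library, trained_predictor):
    """Generators trained at lambda in {0, 1, 100} against the frozen predictor."""
    train, _, _ = library
    seqs = train["seq"].tolist()[:2000]
    out = {}
    for lam in (0.0, 1.0, 100.0):
        g = UtrGenerator(predictor=trained_predictor, lambda_rl=lam, seq_len=50,
                         random_state=2)
        g.fit(seqs)
        out[lam] = g
    return out


@pytest.fixture(scope="session")
def held_out_results(library, generators):
    """OptimizationResults of each generator on 200 held-out sequences."""
    _, _, test = library
    held = test["seq"].tolist()[:200]
    return {lam: g.optimize_batch(held) for lam, g in generators.items()}
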