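"""Permutation-sampling Shapley attribution for sequence models.

Each entry of the encoded input — a (position, channel) pair — is treated as
one feature.  The Shapley value of a feature is its marginal contribution to
the prediction averaged over the orders in which features can be introduced;
here the average is estimated by Monte-Carlo sampling of uniform random
permutations.  "Introducing" a feature means the hybrid input takes the
explained instance's value at that entry instead of a background sample's
value, so the attribution is relative to an expectation baseline drawn from
the background set.

For an additive model the estimate is exact in expectation
(``attr_i = w_i * (x_i - E[b_i])``), and the efficiency axiom — attributions
summing to ``f(x)`` minus the baseline — holds in expectation over the
background draw (exactly, when the background is a single sample).

Dataset-level feature ranking averages absolute attributions over a
collection of explained instances, with a signed mean as direction summary,
mirroring how MPRA-trained predictors are interrogated for nucleotide
preferences (e.g. negative T/G effects just upstream of the start codon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import CHANNELS, PAD, upstream_position

__all__ = ["AttributionMap", "shap_values", "rank_features", "feature_label"]


@dataclass
class AttributionMap:
    """Per-feature Shapley estimates for one explained input.

    ``values`` has the shape of the explained input; ``baseline`` is the
    mean model output over the background set, so ``values.sum()`` is close
    to ``f(x) - baseline`` (exactly, in expectation)."""

    values: np.ndarray
    baseline: float
    prediction: float


def shap_values(predict_fn, x: np.ndarray, background: np.ndarray,
                n_perm: int = 200, seed: int | None = None) -> AttributionMap:
    """Monte-Carlo permutation Shapley attribution.

    Parameters
    ----------
    predict_fn : callable
        Maps a batch of inputs shaped like ``x`` (with a leading batch axis)
        to a 1-D array of scalar predictions.  For an :class:`MrlPredictor`
        pass ``model.predict``.
    x : ndarray
        The instance to explain (any shape; features are its entries).
    background : ndarray
        Non-empty batch of background samples with ``x``'s shape.
    n_perm : int
        Number of sampled feature orders; one background sample is drawn
        per order.
    seed : int or None
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    background = np.asarray(background, dtype=np.float64)
    if background.ndim == x.ndim:
        background = background[None]
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float64)
    flat_x = x.ravel()
    n_feat = flat_x.size
    values = np.zeros(n_feat)
    for _ in range(n_perm):
        order = rng.permutation(n_feat)
        b = background[rng.integers(len(background))].ravel()
        # hybrids[k] has the first k features (in this order) taken from x
        hybrids = np.tile(b, (n_feat + 1, 1))
        mask = np.zeros(n_feat, dtype=bool)
        for k, f in enumerate(order, start=1):
            mask[f] = True
            hybrids[k:, f] = flat_x[f]
        preds = np.asarray(predict_fn(hybrids.reshape((n_feat + 1,) + x.shape)))
        values[order] += preds[1:] - preds[:-1]
    values /= n_perm
    baseline = float(np.mean(predict_fn(background)))
    prediction = float(np.asarray(predict_fn(x[None]))[0])
    return AttributionMap(values=values.reshape(x.shape), baseline=baseline,
                          prediction=prediction)


def feature_label(position_index: int, channel: int, length: int) -> str:
    """Label in upstream coordinates, e.g. ``'3-A'`` = adenine three
    nucleotides upstream of the start codon."""
    name = CHANNELS[channel] if channel != PAD else "pad"
    return f"{upstream_position(position_index, length)}-{name}"


def rank_features(maps: list[AttributionMap], k: int = 20,
                  sequence_length: int | None = None) -> pd.DataFrame:
    """Rank (position, channel) features by mean absolute attribution.

    Returns the top ``k`` features (all of them if ``k`` exceeds the feature
    count) as a DataFrame with columns ``feature``, ``position``,
    ``channel``, ``mean_shap``, ``mean_abs_shap``, sorted by
    ``mean_abs_shap`` descending.  Positions are upstream coordinates over
    the encoded length (``sequence_length`` defaults to the encoded length,
    appropriate when inputs are unpadded).
    """
    if not maps:
        raise ValueError("no attribution maps supplied")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("attribution maps have mismatching shapes")
    stack = np.stack([m.values for m in maps])
    mean_signed = stack.mean(axis=0)
    mean_abs = np.abs(stack).mean(axis=0)
    L = shape[0]
    seq_len = sequence_length if sequence_length is not None else L
    rows = []
    for pos in range(L):
        for ch in range(shape[1]):
            rows.append({
                "feature": feature_label(pos, ch, seq_len),
                "position": upstream_position(pos, seq_len),
                "channel": CHANNELS[ch] if ch != PAD else "pad",
                "mean_shap": mean_signed[pos, ch],
                "mean_abs_shap": mean_abs[pos, ch],
            })
    table = pd.DataFrame(rows).sort_values(
        "mean_abs_shap", ascending=False, kind="mergesort").reset_index(drop=True)
    return table.head(min(k, len(table)))
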