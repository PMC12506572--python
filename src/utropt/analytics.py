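"""Sequence-pair and set-level analytics for optimized UTR libraries:
substitution spectra, composition shift at mutated sites, upstream-AUG
counts, edit counts and Hausdorff distances between embedding clouds."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff as _scipy_dh

NUCLEOTIDES = "ACGT"

__all__ = ["substitution_matrix", "content_shift_at_mutated_sites",
           "count_uaugs", "edit_count", "directed_hausdorff",
           "symmetric_hausdorff"]


def _check_pair(original: str, optimized: str) -> None:
    if len(original) != len(optimized):
        raise ValueError("sequence pair has mismatching lengths")


def substitution_matrix(pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """4x4 table of substitution proportions indexed (from-nt, to-nt).

    Counts every position-wise mismatch across all pairs and normalizes by
    the total number of substitutions; the diagonal is structurally zero.
    All-identical input yields an all-zero matrix.
    """
    counts = pd.DataFrame(0.0, index=list(NUCLEOTIDES), columns=list(NUCLEOTIDES))
    total = 0
    for original, optimized in pairs:
        original, optimized = str(original), str(optimized)
        _check_pair(original, optimized)
        for a, b in zip(original, optimized):
            if a != b:
                counts.loc[a, b] += 1
                total += 1
    if total:
        counts /= total
    return counts


def content_shift_at_mutated_sites(pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Nucleotide composition (percent) before and after optimization,
    restricted to the positions that changed.

    Returns a DataFrame indexed by nucleotide with columns ``before_pct``
    and ``after_pct`` (each summing to 100 when any site mutated); empty
    when no position differs.
    """
    before: dict[str, int] = {nt: 0 for nt in NUCLEOTIDES}
    after: dict[str, int] = {nt: 0 for nt in NUCLEOTIDES}
    total = 0
    for original, optimized in pairs:
        original, optimized = str(original), str(optimized)
        _check_pair(original, optimized)
        for a, b in zip(original, optimized):
            if a != b:
                before[a] += 1
                after[b] += 1
                total += 1
    if total == 0:
        return pd.DataFrame(columns=["before_pct", "after_pct"])
    return pd.DataFrame({
        "before_pct": {nt: 100.0 * before[nt] / total for nt in NUCLEOTIDES},
        "after_pct": {nt: 100.0 * after[nt] / total for nt in NUCLEOTIDES},
    })


def count_uaugs(s: str) -> int:
    """Number of (possibly overlapping) ATG occurrences — each one is a
    potential upstream open reading frame start."""
    s = str(s)
    return sum(1 for i in range(len(s) - 2) if s[i:i + 3] == "ATG")


def edit_count(original: str, optimized: str) -> int:
    """Hamming distance between two equal-length sequences."""
    original, optimized = str(original), str(optimized)
    _check_pair(original, optimized)
    return sum(a != b for a, b in zip(original, optimized))


def directed_hausdorff(A: np.ndarray, B: np.ndarray,
                       seed: int = 0) -> float:
    """Directed Hausdorff distance from point set ``A`` to ``B``:
    ``max over a of min over b of ||a - b||``.  Zero iff every point of
    ``A`` occurs in ``B``."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.size == 0 or B.size == 0:
        raise ValueError("point sets must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("point sets must share dimensionality")
    return float(_scipy_dh(A, B, seed=seed)[0])


def symmetric_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """max(directed(A→B), directed(B→A))."""
    return max(directed_hausdorff(A, B), directed_hausdorff(B, A))
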