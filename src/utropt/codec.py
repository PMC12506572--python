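"""Validation and one-hot codec for 5' UTR sequences.

Sequences are one-hot encoded into an ``L x 5`` matrix with channel order
``A, T, C, G, pad`` (constant :data:`CHANNELS`).  Sequences shorter than the
target length are left-padded with pad one-hots; longer sequences keep only
their last ``target_len`` nucleotides, because the region adjacent to the
start codon carries most of the translational signal.  Two dialects exist:
the variable-length model encodes to 100 positions, the fixed-length model
to 50.

Positions in reports use upstream coordinates: position 1 is the first
nucleotide upstream of the start codon (the 3'-most base of the UTR),
counting away from the codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

CHANNELS = "ATCG"  # channel 4 is pad
N_CHANNELS = 5
PAD = 4
MIN_LEN = 25
MAX_LEN = 100
VALID_TARGETS = (50, 100)

__all__ = [
    "CHANNELS", "MIN_LEN", "MAX_LEN", "PAD",
    "UtrSequence", "UtrValidationError", "SequenceOneHotEncoder",
    "validate_input", "encode_utr", "decode_encoding", "encode_batch",
    "read_fasta", "write_fasta", "upstream_position",
]


class UtrValidationError(ValueError):
    """Raised when an input string is not a valid 5' UTR sequence."""


@dataclass(frozen=True)
class UtrSequence:
    """A validated 5' UTR: 25-100 nt over the A/C/G/T alphabet."""

    seq: str
    id: str = field(default="")

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq


def validate_input(raw: str, id: str = "") -> UtrSequence:
    """Uppercase, map U to T, and validate length and alphabet.

    Raises
    ------
    UtrValidationError
        If the sequence is shorter than 25 nt, longer than 100 nt, or
        contains characters outside ``{A, C, G, T, U}``.
    """
    if not isinstance(raw, str) or not raw:
        raise UtrValidationError("empty input sequence")
    seq = raw.strip().upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise UtrValidationError(
            f"invalid characters {sorted(bad)} in sequence {id or raw[:20]!r}; "
            "only A, C, G, T (or U) are accepted")
    if not MIN_LEN <= len(seq) <= MAX_LEN:
        raise UtrValidationError(
            f"sequence {id or seq[:20]!r} has length {len(seq)}; "
            f"accepted range is {MIN_LEN} to {MAX_LEN} nt")
    return UtrSequence(seq=seq, id=id)


def encode_utr(s: UtrSequence | str, target_len: int = 100) -> np.ndarray:
    """One-hot encode to a ``target_len x 5`` matrix, left-padded.

    Sequences longer than ``target_len`` keep only their last ``target_len``
    nucleotides (the region nearest the start codon).
    """
    if target_len not in VALID_TARGETS:
        raise ValueError(f"target_len must be one of {VALID_TARGETS}, got {target_len}")
    seq = s.seq if isinstance(s, UtrSequence) else s
    seq = seq[-target_len:]
    mat = np.zeros((target_len, N_CHANNELS))
    offset = target_len - len(seq)
    mat[:offset, PAD] = 1.0
    for i, nt in enumerate(seq):
        mat[offset + i, CHANNELS.index(nt)] = 1.0
    return mat


def encode_batch(seqs: Iterable[UtrSequence | str], target_len: int = 100) -> np.ndarray:
    return np.stack([encode_utr(s, target_len) for s in seqs])


def decode_encoding(e: np.ndarray) -> str:
    """Per-position argmax decode; pad positions dropped, ties to the lowest
    channel index (A < T < C < G < pad)."""
    e = np.asarray(e)
    if e.ndim != 2 or e.shape[1] != N_CHANNELS:
        raise ValueError(f"expected an Lx{N_CHANNELS} matrix, got shape {e.shape}")
    idx = e.argmax(axis=1)  # numpy argmax takes the first (lowest) index on ties
    return "".join(CHANNELS[i] for i in idx if i != PAD)


def upstream_position(i: int, length: int) -> int:
    """Map a 0-based 5'-to-3' string index to the 1-based upstream coordinate
    (position 1 = nucleotide immediately upstream of the start codon)."""
    return length - i


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, raw_sequence)`` records; id is the token before the first
    whitespace, wrapped lines are joined."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class SequenceOneHotEncoder:
    """scikit-learn style transformer from sequence strings to one-hot arrays.

    Parameters
    ----------
    target_len : int, default=100
        Encoded length; 100 for the variable-length dialect, 50 for the
        fixed-length one.
    validate : bool, default=True
        Run full UTR validation on every input string.
    """

    def __init__(self, target_len: int = 100, validate: bool = True):
        self.target_len = target_len
        self.validate = validate

    def get_params(self, deep: bool = True) -> dict:
        return {"target_len": self.target_len, "validate": self.validate}

    def set_params(self, **params) -> "SequenceOneHotEncoder":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "SequenceOneHotEncoder":
        if self.target_len not in VALID_TARGETS:
            raise ValueError(f"target_len must be one of {VALID_TARGETS}")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        seqs = [validate_input(x).seq if self.validate else str(x) for x in X]
        return encode_batch(seqs, self.target_len)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, X: np.ndarray) -> list[str]:
        return [decode_encoding(m) for m in np.asarray(X)]
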