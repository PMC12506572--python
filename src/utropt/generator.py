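"""Generative autoencoder that rewrites a 5' UTR into a nearby sequence with
higher predicted mean ribosome loading.

The encoder maps a one-hot ``L x 5`` sequence through three convolutional
layers and a fully connected layer to a latent vector (default length 128);
the decoder reconstructs an ``L x 5`` row-wise probability matrix through a
fully connected layer and three deconvolutional layers (stride-1 transposed
convolutions, restoring the full length exactly) with a row softmax.

Training minimizes a composite loss against a *frozen* MRL predictor::

    RE_loss    = CCE(y_true, y_pred) + BCE(y_true[pad], y_pred[pad])
    RL_loss    = exp(MRL(y_true) - MRL(y_pred))
    Total_loss = RE_loss + lambda * RL_loss

The reconstruction term keeps the output close to the input (categorical
cross-entropy over the five channels, with the pad channel additionally
scored by a binary cross-entropy so padding structure is preserved); the RL
term rewards any increase of the predictor's score of the decoded output and
is strictly decreasing in it.  ``MRL(y_true)`` is the predictor's score of
the *input* sequence, so the loss compares output to input under the same
model.  The default weight is ``lambda = 100``.

Gradients of the RL term flow through the predictor into the decoder's
continuous softmax output (the predictor's own weights stay fixed);
discrete argmax decoding happens only at inference, where pad positions are
masked so the optimized sequence always has the input's exact length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Tensor, softmax
from ._nn import Adam, Conv1d, Dense, Module, apply_activation
from .codec import (CHANNELS, N_CHANNELS, PAD, UtrSequence, encode_batch,
                    encode_utr, upstream_position, validate_input)
from .predictor import MrlPredictor

_EPS = 1e-12

__all__ = ["UtrGenerator", "OptimizationResult", "reconstruction_loss",
           "rl_loss", "total_loss", "build_generator"]


# -- loss primitives -----------------------------------------------------

def _check_prob_rows(y_pred: np.ndarray) -> None:
    if np.any(y_pred < -1e-9) or not np.allclose(y_pred.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("y_pred rows must be probability vectors over the 5 channels")


def reconstruction_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Categorical cross-entropy over the 5 channels (pad positions masked
    out of the average) plus binary cross-entropy on the pad channel,
    averaged over positions.  Zero iff the reconstruction is exact."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    _check_prob_rows(y_pred)
    p = np.clip(y_pred, _EPS, 1.0)
    nonpad = y_true[..., PAD] == 0
    cce_all = -(y_true * np.log(p)).sum(axis=-1)
    cce = cce_all[nonpad].mean() if nonpad.any() else 0.0
    t = y_true[..., PAD]
    q = np.clip(y_pred[..., PAD], _EPS, 1.0 - _EPS)
    bce = -(t * np.log(q) + (1 - t) * np.log(1 - q)).mean()
    return float(cce + bce)


def rl_loss(mrl_true: float, mrl_pred: float) -> float:
    """``exp(MRL(input) - MRL(output))``: strictly decreasing in the output
    score, 1 when the two scores match."""
    return float(np.exp(np.asarray(mrl_true) - np.asarray(mrl_pred)))


def total_loss(re: float, rl: float, lambda_rl: float) -> float:
    """Composite objective ``RE + lambda * RL``."""
    return float(re + lambda_rl * rl)


def _reconstruction_loss_t(y_true: np.ndarray, y_pred: Tensor) -> Tensor:
    """Differentiable batch reconstruction loss (same definition as
    :func:`reconstruction_loss`, averaged over the batch)."""
    nonpad = y_true[..., PAD] == 0
    logp = (y_pred + _EPS).log()
    cce = -(Tensor(y_true * nonpad[..., None]) * logp).sum() * (1.0 / max(nonpad.sum(), 1))
    t = y_true[..., PAD]
    q = y_pred[..., PAD]
    bce_terms = Tensor(t) * (q + _EPS).log() + Tensor(1 - t) * (1 - q + _EPS).log()
    bce = -bce_terms.mean()
    return cce + bce


# -- result record -------------------------------------------------------

@dataclass(frozen=True)
class OptimizationResult:
    """One optimized UTR: the rewritten sequence has the input's exact
    length, and ``substitutions`` enumerates every differing position in
    upstream coordinates (1 = adjacent to the start codon)."""

    original: UtrSequence
    optimized: UtrSequence
    mrl_orig: float
    mrl_opt: float
    substitutions: tuple[tuple[int, str, str], ...]

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)


def _enumerate_substitutions(original: str, optimized: str):
    L = len(original)
    subs = [(upstream_position(i, L), a, b)
            for i, (a, b) in enumerate(zip(original, optimized)) if a != b]
    return tuple(subs)


# -- network -------------------------------------------------------------

class _GeneratorNet(Module):
    def __init__(self, rng, seq_len: int, latent_dim: int, n_conv: int,
                 n_deconv: int, conv_filters: int, conv_kernel: int,
                 activation: str):
        F = conv_filters
        self.activation = activation
        self.seq_len = seq_len
        self.enc_convs = []
        c_in = N_CHANNELS
        for _ in range(n_conv):
            self.enc_convs.append(Conv1d(rng, c_in, F, conv_kernel))
            c_in = F
        self.enc_dense = Dense(rng, seq_len * F, latent_dim)
        self.dec_dense = Dense(rng, latent_dim, seq_len * F)
        self.dec_convs = []
        for i in range(n_deconv):
            c_out = N_CHANNELS if i == n_deconv - 1 else F
            self.dec_convs.append(Conv1d(rng, F, c_out, conv_kernel))
        self.filters = conv_filters

    def encode(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.enc_convs:
            h = apply_activation(conv(h), self.activation)
        B = h.shape[0]
        return self.enc_dense(h.reshape(B, -1))

    def decode(self, z: Tensor) -> Tensor:
        B = z.shape[0]
        h = apply_activation(self.dec_dense(z), self.activation)
        h = h.reshape(B, self.seq_len, self.filters)
        for i, conv in enumerate(self.dec_convs):
            h = conv(h)
            if i < len(self.dec_convs) - 1:
                h = apply_activation(h, self.activation)
        return softmax(h, axis=-1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))


# -- estimator -----------------------------------------------------------

class UtrGenerator(TransformerMixin, BaseEstimator):
    """Predictor-guided autoencoder over one-hot encoded 5' UTRs.

    Parameters
    ----------
    predictor : MrlPredictor
        A *fitted* MRL regressor; frozen during generator training and used
        to score both the input and the decoded output.
    lambda_rl : float, default=100.0
        Weight of the ribosome-loading term in the composite loss.  0 gives
        a plain autoencoder; larger values trade reconstruction fidelity
        for predicted-MRL gain.
    latent_dim : int, default=128
    n_conv, n_deconv : int, default=3
        Encoder convolution count and decoder deconvolution count.
    conv_filters, conv_kernel : int
    activation : str, default='relu'
    seq_len : int or None
        Encoded length; defaults to the predictor's ``input_len``.
    identity : bool, default=False
        Skip the network entirely and copy inputs through (useful as a
        do-nothing baseline); MRL scores are still computed.
    learning_rate, batch_size, n_epochs, random_state :
        Optimization settings (Adam).

    Attributes
    ----------
    net_ : trained autoencoder
    history_ : per-epoch DataFrame (epoch, recon_loss, rl_loss, total_loss)
    seq_len_ : resolved encoded length
    """

    def __init__(self, predictor: MrlPredictor | None = None,
                 lambda_rl: float = 100.0, latent_dim: int = 128,
                 n_conv: int = 3, n_deconv: int = 3, conv_filters: int = 32,
                 conv_kernel: int = 7, activation: str = "relu",
                 seq_len: int | None = None, identity: bool = False,
                 learning_rate: float = 2e-3, batch_size: int = 128,
                 n_epochs: int = 30, random_state: int | None = None):
        self.predictor = predictor
        self.lambda_rl = lambda_rl
        self.latent_dim = latent_dim
        self.n_conv = n_conv
        self.n_deconv = n_deconv
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.activation = activation
        self.seq_len = seq_len
        self.identity = identity
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.random_state = random_state

    # -- plumbing --------------------------------------------------------
    def _resolve_seq_len(self) -> int:
        if self.seq_len is not None:
            return int(self.seq_len)
        if self.predictor is not None:
            return int(self.predictor.input_len)
        return 100

    def _require_predictor(self) -> MrlPredictor:
        if self.predictor is None:
            raise ValueError("a fitted MrlPredictor must be supplied as `predictor`")
        check_is_fitted(self.predictor, "net_",
                        msg="the attached MRL predictor is untrained; fit it first")
        return self.predictor

    def initialize(self) -> "UtrGenerator":
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.lambda_rl < 0:
            raise ValueError("lambda_rl must be nonnegative")
        self.seq_len_ = self._resolve_seq_len()
        rng = np.random.default_rng(self.random_state)
        self.net_ = _GeneratorNet(rng, self.seq_len_, self.latent_dim, self.n_conv,
                                  self.n_deconv, self.conv_filters,
                                  self.conv_kernel, self.activation)
        self.history_ = pd.DataFrame(
            columns=["epoch", "recon_loss", "rl_loss", "total_loss"])
        return self

    def _as_encoded(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return X.astype(np.float64)
        return encode_batch([str(s) for s in X], target_len=self.seq_len_)

    # -- training --------------------------------------------------------
    def fit(self, X, y=None) -> "UtrGenerator":
        """Train on a library of sequences against the frozen predictor."""
        predictor = self._require_predictor()
        self.initialize()
        if self.identity:
            return self
        if predictor.input_len != self.seq_len_:
            raise ValueError("generator seq_len must match predictor input_len")
        Xe = self._as_encoded(X)
        if len(Xe) == 0:
            raise ValueError("empty training set")
        mrl_in = predictor._forward_raw(Xe)

        predictor.net_.set_trainable(False)
        try:
            params = self.net_.parameters()
            opt = Adam(params, lr=self.learning_rate)
            rng = np.random.default_rng(
                None if self.random_state is None else self.random_state + 1)
            rows = []
            for epoch in range(1, self.n_epochs + 1):
                idx = rng.permutation(len(Xe))
                tot_re = tot_rl = tot = 0.0
                for start in range(0, len(Xe), self.batch_size):
                    b = idx[start:start + self.batch_size]
                    xb = Xe[b]
                    probs = self.net_(Tensor(xb))
                    re = _reconstruction_loss_t(xb, probs)
                    mrl_out = predictor.forward_tensor(probs)
                    rl = (Tensor(mrl_in[b]) - mrl_out).exp().mean()
                    loss = re + self.lambda_rl * rl
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    tot_re += float(re.data) * len(b)
                    tot_rl += float(rl.data) * len(b)
                    tot += float(loss.data) * len(b)
                rows.append({"epoch": epoch, "recon_loss": tot_re / len(Xe),
                             "rl_loss": tot_rl / len(Xe), "total_loss": tot / len(Xe)})
            self.history_ = pd.DataFrame(rows)
        finally:
            predictor.net_.set_trainable(True)
        return self

    # -- inference -------------------------------------------------------
    def _decode_preserving_length(self, probs: np.ndarray, length: int) -> str:
        """Argmax decode of the last ``length`` positions over the four
        nucleotide channels only; pad is masked so length is preserved."""
        tail = probs[self.seq_len_ - length:, :PAD]
        return "".join(CHANNELS[i] for i in tail.argmax(axis=1))

    def optimize(self, s: str | UtrSequence) -> OptimizationResult:
        """Rewrite one UTR; returns original/optimized sequences, both MRL
        scores, and the substitution list in upstream coordinates."""
        check_is_fitted(self, "net_")
        predictor = self._require_predictor()
        utr = s if isinstance(s, UtrSequence) else validate_input(str(s))
        if self.identity:
            opt_seq = utr.seq
        else:
            x = encode_utr(utr, target_len=self.seq_len_)[None]
            probs = self.net_(Tensor(x)).data[0]
            opt_seq = self._decode_preserving_length(probs, len(utr))
        mrl_orig, mrl_opt = predictor.predict([utr.seq, opt_seq])
        return OptimizationResult(
            original=utr,
            optimized=UtrSequence(seq=opt_seq, id=utr.id),
            mrl_orig=float(mrl_orig), mrl_opt=float(mrl_opt),
            substitutions=_enumerate_substitutions(utr.seq, opt_seq))

    def optimize_batch(self, seqs) -> list[OptimizationResult]:
        return [self.optimize(s) for s in seqs]

    def transform(self, X) -> list[str]:
        """Optimized sequence strings, one per input, lengths preserved."""
        return [self.optimize(s).optimized.seq for s in X]

    def reconstruct_probs(self, X) -> np.ndarray:
        """Decoder probability matrices for a batch (n, seq_len, 5)."""
        check_is_fitted(self, "net_")
        return self.net_(Tensor(self._as_encoded(X))).data

    # -- persistence -----------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        check_is_fitted(self, "net_")
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), **self.net_.state_dict())
        meta = {k: v for k, v in self.get_params(deep=False).items()
                if k != "predictor"}
        meta["seq_len_"] = self.seq_len_
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path,
             predictor: MrlPredictor | None = None) -> "UtrGenerator":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        seq_len = meta.pop("seq_len_")
        gen = cls(predictor=predictor, **meta)
        gen.seq_len = seq_len
        gen.initialize()
        with np.load(prefix.with_suffix(".npz")) as archive:
            gen.net_.load_state_dict({k: archive[k] for k in archive.files})
        return gen


def build_generator(predictor: MrlPredictor | None = None,
                    seed: int | None = None, **config) -> UtrGenerator:
    """Construct an initialized (untrained) :class:`UtrGenerator`."""
    return UtrGenerator(predictor=predictor, random_state=seed,
                        **config).initialize()
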