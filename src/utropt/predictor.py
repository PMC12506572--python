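"""Discriminative MRL regressor: residual convolutions → GRU → residual
dense head, trained with MSE, learning-rate plateau decay and early stopping.

The architecture follows the lightweight design for 5' UTR translation
efficiency prediction: one-hot encoded sequence features pass through three
residual-connected 1-D convolution blocks (length preserved), a single GRU
layer whose number of steps equals the length of the convolutional feature
sequence, and three residual-connected fully connected blocks ending in one
linear output — the predicted mean ribosome loading.

Also provided: the 10% / 80:20 dataset split, HyperBand-style successive
halving over the architecture hyperparameters, and greedy model soups
(weight averaging across independently trained models, accepting each
candidate only if held-out loss does not worsen).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Tensor
from ._nn import (ACTIVATIONS, Adam, Dense, GRU, Module, ResidualConvBlock,
                  ResidualDenseBlock)
from .codec import N_CHANNELS, VALID_TARGETS, encode_batch

DEFAULT_POOL_SIZE = 8000          # full-scale HyperBand pool
DESK_POOL_SIZE = 27               # desk-scale pool for CPU runs
DESK_EPOCH_SCHEDULE = (1, 2, 4)   # desk-scale per-round epoch budgets

__all__ = [
    "MrlPredictor", "build_predictor", "split_dataset", "evaluate_spearman",
    "hyperband_search", "greedy_soup", "HyperbandResult",
    "DEFAULT_POOL_SIZE", "DESK_POOL_SIZE", "DESK_EPOCH_SCHEDULE",
]


class _PredictorNet(Module):
    def __init__(self, rng: np.random.Generator, input_len: int, n_conv_blocks: int,
                 conv_filters: int, conv_kernel: int, gru_dim: int,
                 n_dense_blocks: int, dense_units: int, activation: str):
        self.input_len = input_len
        c_in = N_CHANNELS
        self.conv_blocks = []
        for _ in range(n_conv_blocks):
            self.conv_blocks.append(
                ResidualConvBlock(rng, c_in, conv_filters, conv_kernel, activation))
            c_in = conv_filters
        self.gru = GRU(rng, c_in, gru_dim)
        d_in = gru_dim
        self.dense_blocks = []
        for _ in range(n_dense_blocks):
            self.dense_blocks.append(ResidualDenseBlock(rng, d_in, dense_units, activation))
            d_in = dense_units
        self.out = Dense(rng, d_in, 1)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for blk in self.conv_blocks:
            h = blk(h)
        h = self.gru(h)
        for blk in self.dense_blocks:
            h = blk(h)
        return self.out(h)


class MrlPredictor(RegressorMixin, BaseEstimator):
    """Mean-ribosome-loading regressor over one-hot encoded 5' UTRs.

    Parameters
    ----------
    input_len : {100, 50}, default=100
        Encoded sequence length; 100 for the variable-length model,
        50 for the fixed-length dialect.
    n_conv_blocks, conv_filters, conv_kernel : int
        Residual convolution stack (length-preserving, stride 1).
    gru_dim : int
        Hidden width of the GRU consuming the convolutional features.
    n_dense_blocks, dense_units : int
        Residual fully connected head.
    activation : {'relu', 'elu', 'tanh'}
    learning_rate : float, default=0.001
        Initial Adam learning rate.
    lr_factor : float, default=0.1
        Multiplier applied to the learning rate after ``plateau_patience``
        epochs without validation-loss improvement.
    plateau_patience : int, default=5
    stop_patience : int, default=12
        Training terminates after this many epochs without improvement;
        the best-validation-loss weights are restored.
    batch_size : int, default=128
    max_epochs : int, default=100
    validation_fraction : float, default=0.2
        Used when no explicit validation set is passed to :meth:`fit`.
    random_state : int or None
        Seeds weight initialization, the internal split and batch order.

    Attributes
    ----------
    net_ : trained network
    history_ : per-epoch DataFrame (epoch, lr, train_loss, val_loss)
    y_mean_, y_std_ : float
        Label standardization constants (predictions are returned in the
        original MRL units).
    """

    def __init__(self, input_len: int = 100, n_conv_blocks: int = 3,
                 conv_filters: int = 32, conv_kernel: int = 5, gru_dim: int = 32,
                 n_dense_blocks: int = 3, dense_units: int = 32,
                 activation: str = "relu", learning_rate: float = 0.001,
                 lr_factor: float = 0.1, plateau_patience: int = 5,
                 stop_patience: int = 12, batch_size: int = 128,
                 max_epochs: int = 100, validation_fraction: float = 0.2,
                 random_state: int | None = None):
        self.input_len = input_len
        self.n_conv_blocks = n_conv_blocks
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.gru_dim = gru_dim
        self.n_dense_blocks = n_dense_blocks
        self.dense_units = dense_units
        self.activation = activation
        self.learning_rate = learning_rate
        self.lr_factor = lr_factor
        self.plateau_patience = plateau_patience
        self.stop_patience = stop_patience
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- config / data validation ---------------------------------------
    def _check_config(self) -> None:
        if self.input_len not in VALID_TARGETS:
            raise ValueError(f"input_len must be one of {VALID_TARGETS}")
        for name in ("n_conv_blocks", "conv_filters", "conv_kernel", "gru_dim",
                     "n_dense_blocks", "dense_units", "batch_size", "max_epochs"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.stop_patience <= self.plateau_patience:
            raise ValueError("stop_patience must exceed plateau_patience")

    def _as_encoded(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            if X.shape[1] != self.input_len or X.shape[2] != N_CHANNELS:
                raise ValueError(
                    f"expected encodings of shape (n, {self.input_len}, {N_CHANNELS}), "
                    f"got {X.shape}")
            return X.astype(np.float64)
        return encode_batch([str(s) for s in X], target_len=self.input_len)

    # -- construction ----------------------------------------------------
    def initialize(self) -> "MrlPredictor":
        """Build the network with seeded initial weights (without training);
        :meth:`predict` becomes usable immediately."""
        self._check_config()
        rng = np.random.default_rng(self.random_state)
        self.net_ = _PredictorNet(
            rng, self.input_len, self.n_conv_blocks, self.conv_filters,
            self.conv_kernel, self.gru_dim, self.n_dense_blocks,
            self.dense_units, self.activation)
        self.y_mean_, self.y_std_ = 0.0, 1.0
        self.history_ = pd.DataFrame(columns=["epoch", "lr", "train_loss", "val_loss"])
        return self

    # -- training --------------------------------------------------------
    def _epoch(self, opt: Adam, X: np.ndarray, y: np.ndarray,
               rng: np.random.Generator) -> float:
        idx = rng.permutation(len(X))
        total = 0.0
        for start in range(0, len(X), self.batch_size):
            b = idx[start:start + self.batch_size]
            pred = self.net_(Tensor(X[b])).reshape(-1)
            diff = pred - Tensor(y[b])
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(b)
        return total / len(X)

    def _eval_mse(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self._forward_raw(X)
        return float(np.mean((pred - y) ** 2))

    def fit(self, X, y, X_val=None, y_val=None) -> "MrlPredictor":
        """Train with MSE loss; ``X`` may be sequence strings or pre-encoded
        ``(n, input_len, 5)`` arrays.  If no validation set is given, a
        seeded ``validation_fraction`` split is carved from the data."""
        y = np.asarray(y, dtype=np.float64)
        if len(X) == 0 or len(y) != len(X):
            raise ValueError("training data is empty or X/y lengths differ")
        Xe = self._as_encoded(X)
        if X_val is None:
            Xe, Xv, y, yv = train_test_split(
                Xe, y, test_size=self.validation_fraction,
                random_state=self.random_state)
        else:
            Xv = self._as_encoded(X_val)
            yv = np.asarray(y_val, dtype=np.float64)
        if len(Xv) == 0:
            raise ValueError("validation set is empty")

        self.initialize()
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0
        ys = (y - self.y_mean_) / self.y_std_
        yvs = (yv - self.y_mean_) / self.y_std_

        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1)
        opt = Adam(self.net_.parameters(), lr=self.learning_rate)
        best_loss = np.inf
        best_state = self.net_.state_dict()
        since_improve = 0
        since_lr_drop = 0
        rows = []
        for epoch in range(1, self.max_epochs + 1):
            train_loss = self._epoch(opt, Xe, ys, rng)
            val_loss = float(np.mean((self._forward_std(Xv) - yvs) ** 2))
            rows.append({"epoch": epoch, "lr": opt.lr,
                         "train_loss": train_loss, "val_loss": val_loss})
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_state = self.net_.state_dict()
                since_improve = 0
                since_lr_drop = 0
            else:
                since_improve += 1
                since_lr_drop += 1
                if since_improve >= self.stop_patience:
                    break
                if since_lr_drop >= self.plateau_patience:
                    opt.lr *= self.lr_factor
                    since_lr_drop = 0
        self.net_.load_state_dict(best_state)
        self.history_ = pd.DataFrame(rows)
        self.best_val_loss_ = best_loss
        self.n_features_in_ = self.input_len * N_CHANNELS
        return self

    # -- inference -------------------------------------------------------
    def _forward_std(self, X: np.ndarray, chunk: int = 512) -> np.ndarray:
        out = [self.net_(Tensor(X[i:i + chunk])).data[:, 0]
               for i in range(0, len(X), chunk)]
        return np.concatenate(out)

    def _forward_raw(self, X: np.ndarray) -> np.ndarray:
        return self._forward_std(X) * self.y_std_ + self.y_mean_

    def forward_tensor(self, x: Tensor) -> Tensor:
        """Differentiable forward pass in original MRL units; gradients flow
        through into ``x`` (used by the generative model's RL loss)."""
        check_is_fitted(self, "net_")
        return self.net_(x).reshape(-1) * self.y_std_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self._forward_raw(self._as_encoded(X))

    def spearman(self, X, y) -> float:
        return evaluate_spearman(self, X, y)

    # -- persistence -----------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npz`` (weight archive) and ``<prefix>.json``
        (key-value config sidecar)."""
        check_is_fitted(self, "net_")
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), **self.net_.state_dict())
        meta = dict(self.get_params())
        meta["y_mean_"] = self.y_mean_
        meta["y_std_"] = self.y_std_
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "MrlPredictor":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        y_mean = meta.pop("y_mean_")
        y_std = meta.pop("y_std_")
        model = cls(**meta).initialize()
        with np.load(prefix.with_suffix(".npz")) as archive:
            model.net_.load_state_dict({k: archive[k] for k in archive.files})
        model.y_mean_, model.y_std_ = y_mean, y_std
        return model


def build_predictor(seed: int | None = None, **config) -> MrlPredictor:
    """Construct an initialized (untrained) :class:`MrlPredictor` from
    architecture keyword arguments."""
    return MrlPredictor(random_state=seed, **config).initialize()


def split_dataset(lib: pd.DataFrame, test_frac: float = 0.10,
                  val_frac_of_rest: float = 0.20,
                  seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a library into (train, val, test): ``test_frac`` of the records
    held out for testing, the remainder divided 80:20 into train and val."""
    if len(lib) < 3:
        raise ValueError("need at least 3 records to make a three-way split")
    rest, test = train_test_split(lib, test_size=test_frac, random_state=seed)
    train, val = train_test_split(rest, test_size=val_frac_of_rest,
                                  random_state=None if seed is None else seed + 1)
    return (train.reset_index(drop=True), val.reset_index(drop=True),
            test.reset_index(drop=True))


def evaluate_spearman(model: MrlPredictor, X, y) -> float:
    """Spearman rank correlation (average ranks on ties) between predictions
    and labels; raises on constant inputs where the correlation is undefined."""
    y = np.asarray(y, dtype=np.float64)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    pred = model.predict(X)
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant vectors")
    rho, _ = stats.spearmanr(pred, y)
    return float(rho)


# -- HyperBand-style successive halving ---------------------------------

@dataclass
class HyperbandResult:
    best_config: dict
    best_val_loss: float
    rounds: list[dict] = field(default_factory=list)


def _doubling_schedule(start: int = 2):
    budget = start
    while True:
        yield budget
        budget *= 2


def hyperband_search(space: dict, X_train, y_train, X_val, y_val,
                     pool_size: int = DEFAULT_POOL_SIZE, drop_ratio: float = 2 / 3,
                     epoch_schedule=None, seed: int | None = None,
                     base_params: dict | None = None) -> HyperbandResult:
    """Successive halving over randomly sampled configurations.

    ``pool_size`` configurations are drawn uniformly from ``space`` (a dict
    of parameter name → list of choices).  Each round trains every surviving
    candidate for the round's epoch budget (continuing from its current
    weights), then keeps the best ``ceil(n * (1 - drop_ratio))`` by
    validation MSE — with the default ratio, two-thirds of the pool is
    dropped per round.  Budgets double round over round (2, 4, 8, ...)
    unless ``epoch_schedule`` overrides them.  The search ends when a single
    candidate has been trained on its final budget.
    """
    if not space:
        raise ValueError("empty hyperparameter space")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = np.random.default_rng(seed)
    base_params = dict(base_params or {})

    configs = []
    for _ in range(pool_size):
        configs.append({k: v[rng.integers(len(v))] for k, v in space.items()})

    candidates = []
    for cfg in configs:
        params = {**base_params, **cfg,
                  "random_state": int(rng.integers(2 ** 31))}
        model = MrlPredictor(**params)
        candidates.append({"config": cfg, "model": model, "opt": None, "loss": np.inf})
    encoded_cache: dict[int, tuple] = {}

    y_train = np.asarray(y_train, dtype=np.float64)
    yv = np.asarray(y_val, dtype=np.float64)
    schedule = iter(epoch_schedule) if epoch_schedule is not None else _doubling_schedule()
    result = HyperbandResult(best_config={}, best_val_loss=np.inf)
    epoch_rng = np.random.default_rng(None if seed is None else seed + 1)

    while True:
        try:
            budget = next(schedule)
        except StopIteration:  # finite schedule exhausted before one survivor
            candidates.sort(key=lambda c: c["loss"])
            candidates = candidates[:1]
            break
        for cand in candidates:
            model = cand["model"]
            if cand["opt"] is None:
                model.initialize()
                model.y_mean_ = float(y_train.mean())
                model.y_std_ = float(y_train.std()) or 1.0
                cand["opt"] = Adam(model.net_.parameters(), lr=model.learning_rate)
                if model.input_len not in encoded_cache:
                    encoded_cache[model.input_len] = (
                        model._as_encoded(X_train), model._as_encoded(X_val))
                cand["Xe"], cand["Xv"] = encoded_cache[model.input_len]
            ys = (y_train - model.y_mean_) / model.y_std_
            yvs = (yv - model.y_mean_) / model.y_std_
            for _ in range(budget):
                model._epoch(cand["opt"], cand["Xe"], ys, epoch_rng)
            cand["loss"] = float(np.mean((model._forward_std(cand["Xv"]) - yvs) ** 2))
        result.rounds.append({"n_candidates": len(candidates), "epochs": budget,
                              "best_loss": min(c["loss"] for c in candidates)})
        if len(candidates) == 1:
            break
        # epsilon guards float noise, e.g. 9 * (1 - 2/3) = 3.0000000000000004
        keep = max(1, int(np.ceil(len(candidates) * (1.0 - drop_ratio) - 1e-9)))
        candidates.sort(key=lambda c: c["loss"])
        candidates = candidates[:keep]
        if len(candidates) == 1:
            # the survivor still gets its final (doubled) training round
            continue
    best = candidates[0]
    result.best_config = best["config"]
    result.best_val_loss = best["loss"]
    result.best_model = best["model"]
    return result


# -- greedy model soup ---------------------------------------------------

def greedy_soup(models: list[MrlPredictor], X_val, y_val) -> MrlPredictor:
    """Greedy weight averaging across identically structured models.

    Models are ranked by validation MSE; starting from the best, each next
    model is tentatively averaged in (uniformly over accepted members) and
    kept only if validation MSE does not worsen.  The soup therefore never
    scores worse than the best single model on the ranking data.
    """
    if not models:
        raise ValueError("no models to soup")
    states = []
    ref_keys = None
    for m in models:
        check_is_fitted(m, "net_")
        state = m.net_.state_dict()
        keys = {k: v.shape for k, v in state.items()}
        if ref_keys is None:
            ref_keys = keys
        elif keys != ref_keys:
            raise ValueError("models have mismatching architectures")
        if not (np.isclose(m.y_mean_, models[0].y_mean_)
                and np.isclose(m.y_std_, models[0].y_std_)):
            raise ValueError("models have mismatching label standardization")
        states.append(state)
    y_val = np.asarray(y_val, dtype=np.float64)

    soup = copy.deepcopy(models[0])
    Xe = soup._as_encoded(X_val)

    def loss_of(state) -> float:
        soup.net_.load_state_dict(state)
        return float(np.mean((soup._forward_raw(Xe) - y_val) ** 2))

    order = np.argsort([loss_of(s) for s in states])
    members = [states[order[0]]]
    best_loss = loss_of(states[order[0]])
    for i in order[1:]:
        trial = states[i]
        avg = {k: np.mean([s[k] for s in members + [trial]], axis=0) for k in trial}
        trial_loss = loss_of(avg)
        if trial_loss <= best_loss:
            members.append(trial)
            best_loss = trial_loss
    final = {k: np.mean([s[k] for s in members], axis=0) for k in members[0]}
    soup.net_.load_state_dict(final)
    soup.soup_size_ = len(members)
    soup.best_val_loss_ = best_loss
    return soup
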