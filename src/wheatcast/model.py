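"""Sequence regression models for county-yield estimation.

Two statsmodels-style model classes are provided:

* :class:`CNNBiLSTMYield` — the CNN-BiLSTM regressor: 1-D convolution
  over the composite axis (features as channels), max pooling, a
  bidirectional LSTM, and a two-layer dense head with a linear scalar
  output.
* :class:`LSTMYield` — the baseline: one unidirectional LSTM layer and
  the same dense head.

Both are constructed from data (``model = CNNBiLSTMYield(y, X)`` or
``from_samples``), and ``fit()`` returns a :class:`YieldFitResults`
carrying the trained state, loss history, predictions and a ``summary()``
table.  Training minimizes mean-squared error on z-scored targets with
Adam, mini-batched with seeded shuffling, and early-stops on an internal
20% validation split.

The module also exposes the reference gate equations
(:func:`lstm_cell_step`, :func:`bilstm_forward`) as plain per-step
functions; the vectorized training engine is tested against them.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, SequenceRegressorNet, sigmoid
from .containers import SampleSet
from .preprocess import NormalizationParams

__all__ = [
    "LSTMCellWeights",
    "lstm_cell_step",
    "bilstm_forward",
    "BCBLConfig",
    "ModelState",
    "CNNBiLSTMYield",
    "LSTMYield",
    "YieldFitResults",
    "bcbl_forward",
]


# ---------------------------------------------------------------------------
# reference gate equations


@dataclass
class LSTMCellWeights:
    """Weights of one LSTM cell.

    Each gate matrix has shape (H, H + F_in) and multiplies the
    concatenation [h_{t-1}, x_t]; biases have length H.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        mats = [self.W_f, self.W_i, self.W_c, self.W_o]
        self.W_f, self.W_i, self.W_c, self.W_o = (np.atleast_2d(np.asarray(m, float)) for m in mats)
        self.b_f, self.b_i, self.b_c, self.b_o = (
            np.atleast_1d(np.asarray(b, float)) for b in (self.b_f, self.b_i, self.b_c, self.b_o)
        )
        H = self.W_f.shape[0]
        for m in (self.W_i, self.W_c, self.W_o):
            if m.shape != self.W_f.shape:
                raise ValueError("all gate matrices must share shape (H, H + F_in)")
        for b in (self.b_f, self.b_i, self.b_c, self.b_o):
            if b.shape != (H,):
                raise ValueError("biases must have length H")

    @property
    def hidden(self) -> int:
        return self.W_f.shape[0]

    @property
    def n_in(self) -> int:
        return self.W_f.shape[1] - self.hidden


def lstm_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, w: LSTMCellWeights
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the LSTM gate equations.

    f_t = sigma(W_f [h, x] + b_f), i_t = sigma(W_i [h, x] + b_i),
    c~_t = tanh(W_c [h, x] + b_c), C_t = f_t * C_{t-1} + i_t * c~_t,
    o_t = sigma(W_o [h, x] + b_o), h_t = o_t * tanh(C_t)
    (elementwise products throughout).
    """
    x_t = np.atleast_1d(np.asarray(x_t, float))
    h_prev = np.atleast_1d(np.asarray(h_prev, float))
    c_prev = np.atleast_1d(np.asarray(c_prev, float))
    if x_t.shape != (w.n_in,) or h_prev.shape != (w.hidden,) or c_prev.shape != (w.hidden,):
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"for H={w.hidden}, F_in={w.n_in}"
        )
    z = np.concatenate([h_prev, x_t])
    f = sigmoid(w.W_f @ z + w.b_f)
    i = sigmoid(w.W_i @ z + w.b_i)
    g = np.tanh(w.W_c @ z + w.b_c)
    c_t = f * c_prev + i * g
    o = sigmoid(w.W_o @ z + w.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def bilstm_forward(
    sequence: np.ndarray, forward_weights: LSTMCellWeights, backward_weights: LSTMCellWeights
) -> np.ndarray:
    """Reference bidirectional LSTM pass over one (T x F) sequence.

    Row t of the output concatenates the forward hidden state at time t
    with the hidden state of an LSTM run over the reversed sequence,
    re-reversed so it also aligns with time t.  Output is (T x 2H).
    """
    seq = np.atleast_2d(np.asarray(sequence, float))
    if seq.shape[0] == 0:
        raise ValueError("empty sequence")
    if forward_weights.hidden != backward_weights.hidden:
        raise ValueError("forward and backward cells must share H")
    H = forward_weights.hidden
    T = seq.shape[0]

    def run(cell: LSTMCellWeights, rows: np.ndarray) -> np.ndarray:
        h = np.zeros(H)
        c = np.zeros(H)
        out = np.empty((rows.shape[0], H))
        for t in range(rows.shape[0]):
            h, c = lstm_cell_step(rows[t], h, c, cell)
            out[t] = h
        return out

    fw = run(forward_weights, seq)
    bw = run(backward_weights, seq[::-1])[::-1]
    return np.concatenate([fw, bw], axis=1)


# ---------------------------------------------------------------------------
# configuration and trained state


@dataclass
class BCBLConfig:
    """Architecture and training hyperparameters.

    Defaults are modest CPU-friendly sizes; the search space used for
    Bayesian tuning brackets them.
    """

    conv_filters: int = 32
    conv_kernel: int = 3
    pool_size: int = 2
    bilstm_units: int = 32
    dense1_units: int = 32
    dense2_units: int = 16
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.conv_filters, self.conv_kernel, self.pool_size, self.bilstm_units,
            self.dense1_units, self.dense2_units, self.batch_size, self.max_epochs,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all architecture counts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


CHECKPOINT_VERSION = 1


@dataclass
class ModelState:
    """Everything needed to reproduce predictions from a trained model."""

    params: dict
    config: BCBLConfig
    front_end: str
    n_features: int
    y_mean: float
    y_sd: float
    loss_history: list = field(default_factory=list)
    val_loss_history: list = field(default_factory=list)
    norm_params: NormalizationParams | None = None

    def save(self, path: str | Path) -> None:
        """Versioned binary checkpoint (.npz) plus a JSON sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "front_end": self.front_end,
            "n_features": self.n_features,
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "loss_history": list(map(float, self.loss_history)),
            "val_loss_history": list(map(float, self.val_loss_history)),
        }
        if self.norm_params is not None:
            sidecar["norm_params"] = {
                "minima": self.norm_params.minima.tolist(),
                "maxima": self.norm_params.maxima.tolist(),
                "feature_names": list(self.norm_params.feature_names),
            }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if sidecar["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {sidecar['version']}")
        with np.load(path.with_suffix(".npz")) as npz:
            params = {k: npz[k] for k in npz.files}
        norm = None
        if "norm_params" in sidecar:
            np_ = sidecar["norm_params"]
            norm = NormalizationParams(np_["minima"], np_["maxima"], tuple(np_["feature_names"]))
        return cls(
            params=params,
            config=BCBLConfig(**sidecar["config"]),
            front_end=sidecar["front_end"],
            n_features=sidecar["n_features"],
            y_mean=sidecar["y_mean"],
            y_sd=sidecar["y_sd"],
            loss_history=sidecar["loss_history"],
            val_loss_history=sidecar["val_loss_history"],
            norm_params=norm,
        )


def _build_net(config: BCBLConfig, n_features: int, front_end: str) -> SequenceRegressorNet:
    return SequenceRegressorNet(
        n_features=n_features,
        conv_filters=config.conv_filters,
        conv_kernel=config.conv_kernel,
        pool_size=config.pool_size,
        hidden=config.bilstm_units,
        dense1=config.dense1_units,
        dense2=config.dense2_units,
        front_end=front_end,
    )


def bcbl_forward(sample: np.ndarray, state: ModelState) -> float:
    """Yield estimate for one (T x F) sample, in standardized units."""
    sample = np.asarray(sample, float)
    if sample.ndim != 2 or sample.shape[1] != state.n_features:
        raise ValueError(f"expected (T, {state.n_features}); got {sample.shape}")
    net = _build_net(state.config, state.n_features, state.front_end)
    yhat, _ = net.forward(sample[None], state.params)
    return float(yhat[0])


# ---------------------------------------------------------------------------
# Model / Results


class _SequenceYieldModel:
    """Shared statsmodels-style scaffolding for the two regressors."""

    front_end = "conv_bilstm"

    def __init__(self, endog: np.ndarray, exog: np.ndarray, config: BCBLConfig | None = None):
        self.endog = np.asarray(endog, float)
        self.exog = np.asarray(exog, float)
        if self.exog.ndim != 3:
            raise ValueError("exog must be an (N, T, F) tensor")
        if len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog and exog disagree on N")
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("targets must be finite")
        self.config = config or BCBLConfig()
        self.norm_params: NormalizationParams | None = None

    @classmethod
    def from_samples(cls, samples: SampleSet, config: BCBLConfig | None = None):
        model = cls(samples.y, samples.X, config)
        return model

    def fit(self, val_fraction: float = 0.2) -> "YieldFitResults":
        """Train with Adam + early stopping; return the best-validation state.

        Targets are z-scored on the training samples for optimization and
        de-standardized for reporting.  An internal ``val_fraction`` split
        of the supplied samples drives early stopping with the configured
        patience; the parameters at the best validation loss are returned.
        """
        cfg = self.config
        X, y = self.exog, self.endog
        N = len(y)
        if N < cfg.batch_size:
            raise ValueError(f"need at least batch_size={cfg.batch_size} samples; got {N}")

        y_mean = float(y.mean())
        y_sd = float(y.std())
        if y_sd == 0:
            # constant targets: the z-scored problem is "predict 0"
            y_sd = 1.0
        yz = (y - y_mean) / y_sd

        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(N)
        n_val = max(1, int(round(val_fraction * N))) if N >= 5 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[train_idx], yz[train_idx]
        Xva, yva = X[val_idx], yz[val_idx]

        net = _build_net(cfg, X.shape[2], self.front_end)
        params = net.init_params(rng)
        opt = Adam(params, lr=cfg.learning_rate)

        best_val = np.inf
        best_params = copy.deepcopy(params)
        wait = 0
        loss_hist: list[float] = []
        val_hist: list[float] = []
        n_tr = len(ytr)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n_tr)
            epoch_loss = 0.0
            for start in range(0, n_tr, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                loss, grads = net.loss_and_grads(Xtr[batch], ytr[batch], params)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate or check the inputs"
                    )
                opt.step(params, grads)
                epoch_loss += loss * len(batch)
            loss_hist.append(epoch_loss / n_tr)

            if n_val:
                pv, _ = net.forward(Xva, params)
                val_loss = float(np.mean((pv - yva) ** 2))
            else:
                val_loss = loss_hist[-1]
            val_hist.append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = copy.deepcopy(params)
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break

        state = ModelState(
            params=best_params,
            config=cfg,
            front_end=self.front_end,
            n_features=X.shape[2],
            y_mean=y_mean,
            y_sd=y_sd,
            loss_history=loss_hist,
            val_loss_history=val_hist,
            norm_params=self.norm_params,
        )
        return YieldFitResults(self, state)


class CNNBiLSTMYield(_SequenceYieldModel):
    """CNN-BiLSTM yield regressor (conv -> pool -> BiLSTM -> dense head)."""

    front_end = "conv_bilstm"


class LSTMYield(_SequenceYieldModel):
    """Baseline regressor: one unidirectional LSTM layer + dense head."""

    front_end = "lstm"


class YieldFitResults:
    """Results of fitting a sequence yield model.

    Carries the trained :class:`ModelState`; ``predict`` maps (N, T, F)
    tensors to yields in kg/ha (de-standardized with the training target
    statistics).
    """

    def __init__(self, model: _SequenceYieldModel, state: ModelState):
        self.model = model
        self.state = state
        self._net = _build_net(state.config, state.n_features, state.front_end)

    @property
    def loss_history(self) -> list[float]:
        return self.state.loss_history

    @property
    def n_epochs(self) -> int:
        return len(self.state.loss_history)

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, float)
        yz, _ = self._net.forward(X, self.state.params)
        return yz * self.state.y_sd + self.state.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def rsquared(self) -> float:
        resid = self.model.endog - self.fittedvalues
        tot = self.model.endog - self.model.endog.mean()
        return 1.0 - float(resid @ resid) / float(tot @ tot)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.state.params.values()))

    def summary(self) -> str:
        s = self.state
        cfg = s.config
        arch = (
            f"conv({cfg.conv_filters}x{cfg.conv_kernel}) -> pool({cfg.pool_size}) -> "
            f"BiLSTM({cfg.bilstm_units}) -> dense({cfg.dense1_units},{cfg.dense2_units}) -> 1"
            if s.front_end == "conv_bilstm"
            else f"LSTM({cfg.bilstm_units}) -> dense({cfg.dense1_units},{cfg.dense2_units}) -> 1"
        )
        lines = [
            "Sequence Yield Regression Results",
            "=" * 58,
            f"{'Front end:':<24}{s.front_end}",
            f"{'Architecture:':<24}{arch}",
            f"{'No. observations:':<24}{len(self.model.endog)}",
            f"{'No. parameters:':<24}{self.n_parameters()}",
            f"{'Epochs run:':<24}{self.n_epochs} (max {cfg.max_epochs}, patience {cfg.patience})",
            f"{'Final train MSE (z):':<24}{s.loss_history[-1]:.4f}",
            f"{'Best val MSE (z):':<24}{min(s.val_loss_history):.4f}",
            f"{'Train R^2:':<24}{self.rsquared:.4f}",
            f"{'Target mean/sd (kg/ha):':<24}{s.y_mean:.1f} / {s.y_sd:.1f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_fit(self, observed=None, estimated=None, ax=None):
        """Observed-vs-estimated scatter with the 1:1 line."""
        import matplotlib.pyplot as plt

        obs = self.model.endog if observed is None else np.asarray(observed)
        est = self.fittedvalues if estimated is None else np.asarray(estimated)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(obs, est, s=12, alpha=0.7)
        lo, hi = min(obs.min(), est.min()), max(obs.max(), est.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("official yield (kg/ha)")
        ax.set_ylabel("estimated yield (kg/ha)")
        return ax

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.state.loss_history, label="train")
        ax.plot(self.state.val_loss_history, label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (z-scored yield)")
        ax.legend()
        return ax
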