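"""Encoder-bottleneck-decoder networks, training, the k-sweep and k-selection.

A fully connected network compresses the I normalized model parameters
through a narrow linear bottleneck of width k before decoding them into the
D-dimensional model output.  If the network at width k matches the error of
wider networks, k latent parameters suffice to determine the outputs; the
smallest such k estimates the number of uniquely identifiable parameter
combinations.

The network engine here is a compact numpy implementation of dense layers
(Glorot-uniform init, tanh / ReLU / linear activations, manual backprop)
trained with Adam on mean squared error, full-shuffle minibatches and early
stopping on validation loss with best-weight restoration.  Everything is
seeded and single-threaded deterministic.

``select_k`` implements the saturation rule: take the k with minimal mean
replicate validation error, then choose the smallest k whose replicate errors
are not statistically worse (one-sided Welch t-test, default alpha = 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainResult",
    "SweepResult",
    "BottleneckNet",
    "TrainingDivergedError",
    "build_network",
    "train",
    "sweep",
    "select_k",
]

logger = logging.getLogger("fixfit.bottleneck")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: widths and activations around the bottleneck."""

    input_width: int
    encoder_widths: tuple
    k: int
    decoder_widths: tuple
    output_width: int
    encoder_activation: str = "relu"
    decoder_activation: str = "relu"
    bottleneck_activation: str = "linear"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("bottleneck width k must be >= 1")
        widths = (self.input_width, *self.encoder_widths, *self.decoder_widths, self.output_width)
        if any(w < 1 for w in widths):
            raise ValueError("all layer widths must be positive")

    # preset factories -----------------------------------------------------
    @classmethod
    def kepler(cls, k: int, input_width: int = 4, output_width: int = 100) -> "NetworkSpec":
        return cls(input_width, (14, 14), k, (110, 110), output_width,
                   encoder_activation="tanh", decoder_activation="tanh")

    @classmethod
    def glucose(cls, k: int, input_width: int = 6, output_width: int = 289) -> "NetworkSpec":
        return cls(input_width, (50, 50), k, (150, 300, 300), output_width)

    @classmethod
    def brain(cls, k: int, n_regions: int = 78, input_width: int = 11) -> "NetworkSpec":
        # decoder hidden width tracks the FC vector length (3013 for 78 regions)
        d = n_regions * (n_regions - 1) // 2
        return cls(input_width, (21, 21), k, (d + 10,), d)

    @classmethod
    def preset(cls, name: str, k: int, **kwargs) -> "NetworkSpec":
        try:
            return {"kepler": cls.kepler, "glucose": cls.glucose, "brain": cls.brain}[name](k, **kwargs)
        except KeyError:
            raise ValueError(f"unknown preset {name!r}") from None

    @property
    def layer_widths(self) -> tuple:
        return (self.input_width, *self.encoder_widths, self.k,
                *self.decoder_widths, self.output_width)

    @property
    def layer_activations(self) -> tuple:
        return (
            *(self.encoder_activation,) * len(self.encoder_widths),
            self.bottleneck_activation,
            *(self.decoder_activation,) * len(self.decoder_widths),
            self.output_activation,
        )

    @property
    def n_parameters(self) -> int:
        w = self.layer_widths
        return int(sum(w[i] * w[i + 1] + w[i + 1] for i in range(len(w) - 1)))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 5000
    batch_size: int = 256
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    patience: int = 200
    restore_best: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.patience < 1:
            raise ValueError("epochs, batch_size and patience must be positive")
        if self.patience >= self.epochs:
            raise ValueError("patience must be smaller than epochs")


_ACT = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(a.dtype)),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


class BottleneckNet:
    """Dense network with an explicit encoder/decoder split at the bottleneck."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        widths = spec.layer_widths
        self.activations = spec.layer_activations
        for act in self.activations:
            if act not in _ACT:
                raise ValueError(f"unknown activation {act!r}")
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, (fan_in, fan_out)).astype(np.float32))
            self.b.append(np.zeros(fan_out, dtype=np.float32))
        #: index of the bottleneck layer in the layer list (its output is the latent code)
        self.bottleneck_index = len(spec.encoder_widths)

    # forward --------------------------------------------------------------
    def _forward(self, X: np.ndarray, start: int = 0, stop: int | None = None):
        A = np.asarray(X, dtype=np.float32)
        if A.ndim == 1:
            A = A[None, :]
        activations = [A]
        stop = len(self.W) if stop is None else stop
        for i in range(start, stop):
            Z = activations[-1] @ self.W[i] + self.b[i]
            activations.append(_ACT[self.activations[i]][0](Z))
        return activations

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)[-1]

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent coordinates: forward pass through the bottleneck layer."""
        return self._forward(X, stop=self.bottleneck_index + 1)[-1]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Decoder forward pass from latent coordinates to outputs."""
        Z = np.asarray(Z, dtype=np.float32)
        if Z.ndim == 1:
            Z = Z[None, :]
        if Z.shape[1] != self.spec.k:
            raise ValueError(f"latent width {Z.shape[1]} != bottleneck k={self.spec.k}")
        return self._forward(Z, start=self.bottleneck_index + 1)[-1]

    def decode_with_grad(self, z: np.ndarray, target: np.ndarray):
        """RSS between decode(z) and target, with its gradient wrt z.

        Analytic backprop through the decoder layers; used by the latent
        fitting objective.
        """
        z = np.asarray(z, dtype=np.float32)[None, :]
        start = self.bottleneck_index + 1
        acts = self._forward(z, start=start)
        out = acts[-1]
        resid = out - np.asarray(target, dtype=np.float32)[None, :]
        rss = float((resid**2).sum())
        delta = 2.0 * resid
        for i in range(len(self.W) - 1, start - 1, -1):
            a_idx = i - start  # activation feeding layer i
            delta = delta * _ACT[self.activations[i]][1](acts[a_idx + 1])
            delta = delta @ self.W[i].T
        return rss, delta[0].astype(float)

    # training -------------------------------------------------------------
    def _backprop(self, X: np.ndarray, Y: np.ndarray, gW=None, gb=None):
        """Gradients of the mean-squared error; writes into gW/gb if given."""
        acts = self._forward(X)
        out = acts[-1]
        n_el = out.size
        delta = (2.0 / n_el) * (out - Y)
        if gW is None:
            gW = [np.empty_like(w) for w in self.W]
            gb = [np.empty_like(b) for b in self.b]
        for i in range(len(self.W) - 1, -1, -1):
            act = self.activations[i]
            if act == "relu":
                delta *= acts[i + 1] > 0
            elif act == "tanh":
                delta *= 1.0 - acts[i + 1] ** 2
            np.matmul(acts[i].T, delta, out=gW[i])
            np.sum(delta, axis=0, out=gb[i])
            if i > 0:
                delta = delta @ self.W[i].T
        return gW, gb

    def copy_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights) -> None:
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [bb.copy() for bb in b]

    def save(self, path) -> None:
        arrays = {}
        for i, (w, bb) in enumerate(zip(self.W, self.b)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = bb
        spec = self.spec
        np.savez(
            path, **arrays,
            widths=np.array(spec.layer_widths),
            k=spec.k,
            n_encoder=len(spec.encoder_widths),
            activations=np.array(self.activations),
        )

    @classmethod
    def load(cls, path) -> "BottleneckNet":
        data = np.load(path, allow_pickle=False)
        widths = data["widths"]
        n_enc = int(data["n_encoder"])
        acts = [str(a) for a in data["activations"]]
        k = int(data["k"])
        n_dec = len(widths) - n_enc - 3  # minus input, bottleneck, output
        spec = NetworkSpec(
            input_width=int(widths[0]),
            encoder_widths=tuple(int(w) for w in widths[1:1 + n_enc]),
            k=k,
            decoder_widths=tuple(int(w) for w in widths[2 + n_enc:2 + n_enc + n_dec]),
            output_width=int(widths[-1]),
            encoder_activation=acts[0],
            decoder_activation=acts[n_enc + 1] if n_dec else acts[-1],
            bottleneck_activation=acts[n_enc],
            output_activation=acts[-1],
        )
        net = cls(spec, seed=0)
        net.W = [data[f"W{i}"] for i in range(len(spec.layer_widths) - 1)]
        net.b = [data[f"b{i}"] for i in range(len(spec.layer_widths) - 1)]
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> BottleneckNet:
    """Deterministically initialized network for a spec."""
    return BottleneckNet(spec, seed=seed)


def _mse(pred: np.ndarray, Y: np.ndarray) -> float:
    return float(np.mean((pred - Y) ** 2))


@dataclass
class TrainResult:
    k: int
    replicate: int
    min_val_mse: float
    epochs_run: int
    curve: np.ndarray
    model: BottleneckNet


def train(model, data, config: TrainConfig, replicate: int = 0) -> TrainResult:
    """Train with Adam + minibatches + early stopping on validation MSE.

    ``model`` is a BottleneckNet or a NetworkSpec (initialized with the config
    seed).  ``data`` is a SampleBatch-like object with train_X/train_Y/
    val_X/val_Y, or a tuple (Xtr, Ytr, Xval, Yval).
    """
    if isinstance(model, NetworkSpec):
        model = BottleneckNet(model, seed=config.seed)
    if isinstance(data, tuple):
        Xtr, Ytr, Xval, Yval = data
    else:
        Xtr, Ytr, Xval, Yval = data.train_X, data.train_Y, data.val_X, data.val_Y
    Xtr = np.ascontiguousarray(Xtr, dtype=np.float32)
    Ytr = np.ascontiguousarray(Ytr, dtype=np.float32)
    Xval = np.ascontiguousarray(Xval, dtype=np.float32)
    Yval = np.ascontiguousarray(Yval, dtype=np.float32)
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("training needs non-empty train and validation rows")

    rng = np.random.default_rng(config.seed)

    # flat parameter/gradient/moment buffers with per-layer views keep the
    # Adam update a handful of vectorized operations per minibatch
    sizes = [w.size for w in model.W] + [b.size for b in model.b]
    n_par = int(np.sum(sizes))
    theta = np.empty(n_par, dtype=np.float32)
    grad = np.zeros(n_par, dtype=np.float32)
    m_t = np.zeros(n_par, dtype=np.float32)
    v_t = np.zeros(n_par, dtype=np.float32)
    scratch = np.empty(n_par, dtype=np.float32)
    views_W, views_b, gW, gb = [], [], [], []
    offset = 0
    for w in model.W:
        views_W.append(theta[offset:offset + w.size].reshape(w.shape))
        gW.append(grad[offset:offset + w.size].reshape(w.shape))
        offset += w.size
    for b in model.b:
        views_b.append(theta[offset:offset + b.size])
        gb.append(grad[offset:offset + b.size])
        offset += b.size
    for view, w in zip(views_W, model.W):
        view[...] = w
    for view, b in zip(views_b, model.b):
        view[...] = b
    model.W, model.b = views_W, views_b

    t_step = 0
    lr, b1, b2, eps = config.learning_rate, config.beta1, config.beta2, config.eps

    best_val = np.inf
    best_weights = model.copy_weights()
    best_epoch = 0
    curve = []
    n = len(Xtr)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        Xs, Ys = Xtr[order], Ytr[order]
        for lo in range(0, n, config.batch_size):
            model._backprop(Xs[lo:lo + config.batch_size], Ys[lo:lo + config.batch_size], gW, gb)
            t_step += 1
            step = np.float32(lr * np.sqrt(1.0 - b2**t_step) / (1.0 - b1**t_step))
            m_t *= b1
            m_t += (1 - b1) * grad
            np.square(grad, out=scratch)
            v_t *= b2
            v_t += (1 - b2) * scratch
            np.sqrt(v_t, out=scratch)
            scratch += eps
            np.divide(m_t, scratch, out=scratch)
            scratch *= step
            theta -= scratch
        val_mse = _mse(model.predict(Xval), Yval)
        if not np.isfinite(val_mse):
            raise TrainingDivergedError(f"validation loss non-finite at epoch {epoch} (replicate {replicate})")
        curve.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_epoch = epoch
            best_weights = model.copy_weights()
        elif epoch - best_epoch >= config.patience:
            break
    if config.restore_best:
        model.set_weights(best_weights)
    return TrainResult(
        k=model.spec.k,
        replicate=replicate,
        min_val_mse=best_val,
        epochs_run=len(curve),
        curve=np.asarray(curve),
        model=model,
    )


@dataclass
class SweepResult:
    """Replicate validation errors per bottleneck width plus the selected k*."""

    ks: tuple
    errors: dict                      # k -> list of replicate min val MSE
    results: dict = field(default_factory=dict)  # k -> list of TrainResult
    alpha: float = 0.05
    k_star: int | None = None

    @property
    def means(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.errors.items()}

    @property
    def sems(self) -> dict:
        return {k: float(stats.sem(v)) if len(v) > 1 else 0.0 for k, v in self.errors.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.ks:
            for r, err in enumerate(self.errors[k]):
                epochs = self.results[k][r].epochs_run if self.results.get(k) else None
                rows.append({"k": k, "replicate": r, "min_val_mse": err, "epochs": epochs})
        return pd.DataFrame(rows)


def sweep(
    spec_factory,
    data,
    k_range,
    replicates: int = 10,
    base_seed: int = 0,
    config: TrainConfig | None = None,
) -> SweepResult:
    """Train ``replicates`` networks at every bottleneck width in ``k_range``.

    ``spec_factory`` maps k -> NetworkSpec (e.g. ``lambda k:
    NetworkSpec.kepler(k)``).  Replicate r uses seed ``base_seed + r`` so runs
    are independent of execution order.  Diverged replicates are recorded as
    NaN and excluded from selection statistics.
    """
    k_range = tuple(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    config = config or TrainConfig()
    errors: dict = {k: [] for k in k_range}
    results: dict = {k: [] for k in k_range}
    for k in k_range:
        for r in range(replicates):
            cfg = replace(config, seed=base_seed + r)
            try:
                res = train(spec_factory(k), data, cfg, replicate=r)
            except TrainingDivergedError as exc:
                logger.warning("k=%d replicate %d diverged: %s", k, r, exc)
                res = None
            errors[k].append(res.min_val_mse if res else np.nan)
            if res:
                results[k].append(res)
                logger.info("k=%d replicate %d: min val MSE %.3e after %d epochs",
                            k, r, res.min_val_mse, res.epochs_run)
    out = SweepResult(ks=k_range, errors=errors, results=results)
    out.k_star = select_k(out)
    return out


def select_k(sweep_result, alpha: float = 0.05) -> int:
    """Smallest k whose errors are not significantly above the best k's.

    One-sided Welch t-test of each k's replicate errors against those of the
    k with minimal mean error; the first k (in increasing order) with
    p >= alpha is selected.  Ties / zero-variance cases fall back on the mean
    comparison itself.
    """
    if isinstance(sweep_result, SweepResult):
        errors = sweep_result.errors
    else:
        errors = dict(sweep_result)
    clean = {k: np.asarray([e for e in v if np.isfinite(e)]) for k, v in errors.items()}
    clean = {k: v for k, v in clean.items() if len(v) >= 2}
    if not clean:
        raise ValueError("select_k needs at least 2 finite replicates for some k")
    means = {k: v.mean() for k, v in clean.items()}
    k_min = min(means, key=means.get)
    for k in sorted(clean):
        if k == k_min:
            return k
        with np.errstate(divide="ignore", invalid="ignore"):
            _t, p = stats.ttest_ind(clean[k], clean[k_min], equal_var=False, alternative="greater")
        if np.isnan(p):
            p = 0.0 if means[k] > means[k_min] else 1.0
        if p >= alpha:
            return k
    return k_min
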