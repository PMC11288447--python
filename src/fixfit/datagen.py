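"""Quasi-random sampling, admissibility filtering, transforms and splits.

This module produces the :class:`SampleBatch` — aligned matrices of raw
parameters, unit-hypercube-normalized parameters, raw simulator outputs and
NN-ready transformed outputs — that the bottleneck module trains on.

Sampling uses an unscrambled Sobol sequence with the first (all-zeros) point
skipped, so batches are fully deterministic.  Per model:

* kepler — samples are kept only when the orbit eccentricity satisfies
  0.7 <= e <= 0.95 (moderate ellipses); outputs are log radii ln r(theta).
* glucose — all samples are admissible; glucose traces are min-max rescaled
  to [0, 1] with a single dataset-wide (train-pool) min and max, preserving
  relative scale across samples, and downsampled to a 5-minute grid.
* brain — simulations failing the oscillation / mean-FC exclusion criteria
  are discarded; FC upper-triangle vectors pass through untransformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from . import brain, glucose, kepler

__all__ = [
    "ParameterSpace",
    "SampleBatch",
    "sobol_parameters",
    "admissibility_filter",
    "transform_outputs",
    "inverse_transform_outputs",
    "split",
    "generate_kepler_batch",
    "generate_glucose_batch",
    "generate_brain_batch",
]

logger = logging.getLogger("fixfit.datagen")


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered free parameters with (low, high) ranges plus fixed values.

    Provides the normalization contract used everywhere: free parameters map
    affinely onto the unit hypercube [0, 1]^I.
    """

    names: tuple
    lows: np.ndarray
    highs: np.ndarray
    fixed: dict = field(default_factory=dict)

    @classmethod
    def from_ranges(cls, ranges: dict, fixed: dict | None = None) -> "ParameterSpace":
        names = tuple(ranges)
        lows = np.array([ranges[n][0] for n in names], dtype=float)
        highs = np.array([ranges[n][1] for n in names], dtype=float)
        if np.any(lows >= highs):
            raise ValueError("every free parameter needs low < high")
        return cls(names=names, lows=lows, highs=highs, fixed=dict(fixed or {}))

    @classmethod
    def kepler(cls) -> "ParameterSpace":
        lo, hi = kepler.SAMPLING_RANGE
        return cls.from_ranges(
            {n: (lo, hi) for n in ("m1", "m2", "r0", "omega0")},
            fixed={"G": kepler.G_DEFAULT},
        )

    @classmethod
    def glucose(cls) -> "ParameterSpace":
        return cls.from_ranges(
            {n: glucose.SAMPLING_RANGES[n] for n in glucose.PARAM_NAMES},
            fixed={"mu_plus": glucose.MU_PLUS, "mu_minus": glucose.MU_MINUS},
        )

    @classmethod
    def brain(cls) -> "ParameterSpace":
        return cls.from_ranges(dict(brain.LB_RANGES), fixed=dict(brain.LB_FIXED))

    @property
    def dim(self) -> int:
        return len(self.names)

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        return (raw - self.lows) / (self.highs - self.lows)

    def denormalize(self, unit: np.ndarray) -> np.ndarray:
        unit = np.asarray(unit, dtype=float)
        return self.lows + unit * (self.highs - self.lows)


def sobol_parameters(space: ParameterSpace, n: int, engine: qmc.Sobol | None = None) -> np.ndarray:
    """Draw ``n`` deterministic Sobol points scaled into the parameter ranges.

    Unscrambled sequence with the first (all-zeros) point skipped.  Pass an
    existing engine to continue a sequence across calls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if engine is None:
        engine = sobol_engine(space.dim)
    unit = engine.random(n)
    return space.denormalize(unit)


def sobol_engine(dim: int) -> qmc.Sobol:
    """Fresh unscrambled Sobol engine with the all-zeros point skipped."""
    eng = qmc.Sobol(d=dim, scramble=False)
    eng.fast_forward(1)
    return eng


@dataclass
class SampleBatch:
    """Aligned parameter/output matrices plus transform metadata and splits."""

    param_names: tuple
    raw_params: np.ndarray      # (N, I)
    norm_params: np.ndarray     # (N, I) in [0, 1]
    raw_outputs: np.ndarray     # (N, D_raw)
    outputs: np.ndarray         # (N, D) transformed, NN-ready
    meta: dict = field(default_factory=dict)
    split_labels: np.ndarray | None = None  # 'train' / 'val' per row

    def __post_init__(self) -> None:
        n = self.raw_params.shape[0]
        for name in ("norm_params", "raw_outputs", "outputs"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} is not row-aligned with raw_params")
        if not np.all(np.isfinite(self.outputs)):
            raise ValueError("transformed outputs contain non-finite values")

    @property
    def n(self) -> int:
        return self.raw_params.shape[0]

    def _mask(self, label: str) -> np.ndarray:
        if self.split_labels is None:
            raise ValueError("batch has no train/val split yet; call datagen.split")
        return self.split_labels == label

    @property
    def train_X(self) -> np.ndarray:
        return self.norm_params[self._mask("train")]

    @property
    def train_Y(self) -> np.ndarray:
        return self.outputs[self._mask("train")]

    @property
    def val_X(self) -> np.ndarray:
        return self.norm_params[self._mask("val")]

    @property
    def val_Y(self) -> np.ndarray:
        return self.outputs[self._mask("val")]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        params = pd.DataFrame(self.raw_params, columns=list(self.param_names))
        if self.split_labels is not None:
            params["split"] = self.split_labels
        params.to_csv(outdir / "params.csv", index=False)
        pd.DataFrame(self.outputs).to_csv(outdir / "outputs.csv", index=False)
        meta = dict(self.meta)
        meta["param_names"] = list(self.param_names)
        with open(outdir / "meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, outdir) -> "SampleBatch":
        outdir = Path(outdir)
        with open(outdir / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        names = tuple(meta.pop("param_names"))
        params = pd.read_csv(outdir / "params.csv")
        split_labels = params.pop("split").to_numpy() if "split" in params else None
        raw = params[list(names)].to_numpy(dtype=float)
        outputs = pd.read_csv(outdir / "outputs.csv").to_numpy(dtype=float)
        space = _space_for(meta.get("model", ""))
        norm = space.normalize(raw) if space is not None else raw
        return cls(
            param_names=names,
            raw_params=raw,
            norm_params=norm,
            raw_outputs=outputs,
            outputs=outputs,
            meta=meta,
            split_labels=split_labels,
        )


def _space_for(tag: str) -> ParameterSpace | None:
    return {
        "kepler": ParameterSpace.kepler,
        "glucose": ParameterSpace.glucose,
        "brain": ParameterSpace.brain,
    }.get(tag, lambda: None)()


# ---------------------------------------------------------------------------
# admissibility
# ---------------------------------------------------------------------------

#: kepler retention band for the orbit eccentricity
ECCENTRICITY_BAND = (0.7, 0.95)


def admissibility_filter(model_tag: str, raw_params: np.ndarray, raw_outputs=None):
    """Boolean keep-mask plus per-sample rejection reasons.

    kepler  — keep iff 0.7 <= e <= 0.95 (e computed from the parameters).
    glucose — keep everything.
    brain   — ``raw_outputs`` must be a sequence of (V_series, FCMatrix)
              pairs; verdicts come from :func:`brain.exclusion_filter`.
    """
    raw_params = np.atleast_2d(np.asarray(raw_params, dtype=float))
    n = raw_params.shape[0]
    if model_tag == "kepler":
        m2, r0, w0 = raw_params[:, 1], raw_params[:, 2], raw_params[:, 3]
        e = np.abs(r0**3 * w0**2 / (kepler.G_DEFAULT * m2) - 1.0)
        lo, hi = ECCENTRICITY_BAND
        mask = (e >= lo) & (e <= hi)
        reasons = [None if m else (f"e<{lo}" if ev < lo else f"e>{hi}") for m, ev in zip(mask, e)]
        return mask, reasons
    if model_tag == "glucose":
        return np.ones(n, dtype=bool), [None] * n
    if model_tag == "brain":
        if raw_outputs is None:
            raise ValueError("brain filtering needs (V_series, FCMatrix) pairs as raw_outputs")
        mask = np.zeros(n, dtype=bool)
        reasons = []
        for i, (v_series, fc) in enumerate(raw_outputs):
            keep, reason = brain.exclusion_filter(v_series, fc)
            mask[i] = keep
            reasons.append(reason)
        return mask, reasons
    raise ValueError(f"unknown model tag {model_tag!r}")


# ---------------------------------------------------------------------------
# output transforms
# ---------------------------------------------------------------------------

def transform_outputs(model_tag: str, raw_outputs: np.ndarray, meta: dict | None = None,
                      downsample_step: int = 1):
    """NN output transform per model; returns (transformed, metadata).

    Passing an existing ``meta`` (e.g. the training-pool min/max for glucose)
    freezes the transform so that validation or measured data are rescaled
    identically rather than re-fit.
    """
    raw_outputs = np.asarray(raw_outputs, dtype=float)
    if model_tag == "kepler":
        if np.any(raw_outputs <= 0):
            raise ValueError("log transform requires strictly positive radii")
        return np.log(raw_outputs), {"model": "kepler", "transform": "log"}
    if model_tag == "glucose":
        x = raw_outputs[:, ::downsample_step]
        if meta is None:
            meta = {
                "model": "glucose",
                "transform": "global-minmax",
                "gmin": float(x.min()),
                "gmax": float(x.max()),
                "downsample_step": int(downsample_step),
            }
        gmin, gmax = meta["gmin"], meta["gmax"]
        if gmax <= gmin:
            raise ValueError("degenerate glucose range; cannot rescale")
        return (x - gmin) / (gmax - gmin), meta
    if model_tag == "brain":
        return raw_outputs, {"model": "brain", "transform": "identity"}
    raise ValueError(f"unknown model tag {model_tag!r}")


def inverse_transform_outputs(transformed: np.ndarray, meta: dict) -> np.ndarray:
    """Invert the value transform (downsampling is not invertible)."""
    transformed = np.asarray(transformed, dtype=float)
    kind = meta.get("transform")
    if kind == "log":
        return np.exp(transformed)
    if kind == "global-minmax":
        return transformed * (meta["gmax"] - meta["gmin"]) + meta["gmin"]
    if kind == "identity":
        return transformed
    raise ValueError(f"unknown transform {kind!r}")


def split(batch: SampleBatch, val_fraction: float = 0.1, seed: int = 0) -> SampleBatch:
    """Deterministic shuffled train/validation split, labelled in place."""
    if not (0.0 < val_fraction < 1.0):
        raise ValueError("val_fraction must lie in (0, 1)")
    if batch.n == 0:
        raise ValueError("cannot split an empty batch")
    rng = np.random.default_rng(seed)
    order = rng.permutation(batch.n)
    n_val = int(round(batch.n * val_fraction))
    labels = np.full(batch.n, "train", dtype=object)
    labels[order[:n_val]] = "val"
    batch.split_labels = labels
    batch.meta["val_fraction"] = val_fraction
    batch.meta["split_seed"] = seed
    return batch


# ---------------------------------------------------------------------------
# per-model batch generators (the study conditions)
# ---------------------------------------------------------------------------

def generate_kepler_batch(
    n_target: int = 2529,
    theta_points: int = 100,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> SampleBatch:
    """Eccentricity-filtered Kepler training batch with ln r(theta) outputs.

    Sobol-samples (m1, m2, r0, omega0) on [0.1, 1]^4, keeps orbits with
    0.7 <= e <= 0.95, and oversamples adaptively until ``n_target`` samples
    are retained.  The default target matches a ~9:1 split of 2276 train and
    253 validation samples.
    """
    space = ParameterSpace.kepler()
    engine = sobol_engine(space.dim)
    kept, rejected = [], 0
    while sum(len(k) for k in kept) < n_target:
        raw = sobol_parameters(space, 1024, engine=engine)
        mask, _ = admissibility_filter("kepler", raw)
        rejected += int((~mask).sum())
        kept.append(raw[mask])
    raw = np.vstack(kept)[:n_target]
    logger.info("kepler sampling: retained %d, rejected %d on the eccentricity band", n_target, rejected)
    m2, r0, w0 = raw[:, 1], raw[:, 2], raw[:, 3]
    x = r0**3 * w0**2 / (kepler.G_DEFAULT * m2)
    e, l = np.abs(x - 1.0), x * r0
    grid = kepler.default_theta_grid(theta_points)
    radii = kepler.orbit_radii_batch(e, l, grid)
    outputs, meta = transform_outputs("kepler", radii)
    meta.update(theta_points=theta_points, n_rejected=rejected)
    batch = SampleBatch(space.names, raw, space.normalize(raw), radii, outputs, meta)
    return split(batch, val_fraction, seed)


def generate_glucose_batch(
    n_samples: int = 4000,
    duration: float = 1440.0,
    dt_out: float = 5.0,
    dt: float = 0.1,
    val_fraction: float = 0.1,
    seed: int = 0,
    meals: glucose.MealSchedule | None = None,
) -> SampleBatch:
    """Simulated betaIG glucose traces over 24 h with the three-meal schedule.

    Outputs are the glucose series on the 5-minute grid, min-max rescaled
    with a single dataset-wide range fitted on the training pool and frozen
    (the same scaling is applied to validation rows to avoid leakage).
    """
    space = ParameterSpace.glucose()
    raw = sobol_parameters(space, n_samples)
    t, G, _I, _beta = glucose.simulate_batch(raw, meals=meals, duration=duration, dt_out=dt_out, dt=dt)
    batch = SampleBatch(
        space.names, raw, space.normalize(raw), G, G,
        meta={"model": "glucose", "t_grid_min": [float(t[0]), float(t[-1]), float(dt_out)]},
    )
    split(batch, val_fraction, seed)
    train_meta = transform_outputs("glucose", G[batch._mask("train")])[1]
    outputs, _ = transform_outputs("glucose", G, meta=train_meta)
    batch.outputs = outputs
    batch.meta.update(train_meta)
    logger.info("glucose batch: %d samples on a %d-point 5-min grid", batch.n, outputs.shape[1])
    return batch


def generate_brain_batch(
    n_samples: int = 64,
    n_regions: int = 10,
    duration: float = 250_000.0,
    dt: float = 0.1,
    burn_in: float = 10_000.0,
    record_dt: float = 10.0,
    TR: float = 0.8,
    connectome: brain.Connectome | None = None,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> SampleBatch:
    """Larter-Breakspear FC batch on a synthetic connectome.

    Desk-scale defaults (10 regions, ~4 simulated minutes per sample); the
    full 78-region configuration is supported but computationally heavy.
    Samples failing the oscillation / mean-FC criteria are discarded, so the
    retained count can be below ``n_samples``.
    """
    space = ParameterSpace.brain()
    if connectome is None:
        connectome = brain.synthetic_connectome(n_regions, seed=seed)
    raw = sobol_parameters(space, n_samples)
    fc_rows, verdicts = [], []
    for row in raw:
        params = brain.LBParams.from_vector(row)
        try:
            _t, V = brain.simulate_network(params, connectome, duration=duration, dt=dt,
                                           burn_in=burn_in, record_dt=record_dt, seed=seed)
            _tb, bold = brain.bold_transform(V, dt=record_dt / 1000.0, TR=TR)
            fc = brain.fc_pipeline(bold, fs=1.0 / TR)
            keep, reason = brain.exclusion_filter(V, fc)
        except RuntimeError as exc:  # divergent integration counts as exclusion
            keep, reason, fc = False, str(exc), None
        verdicts.append((keep, reason))
        fc_rows.append(fc.vector if keep else None)
    mask = np.array([k for k, _ in verdicts])
    logger.info("brain batch: retained %d / %d simulations", int(mask.sum()), n_samples)
    kept_outputs = np.array([v for v in fc_rows if v is not None])
    raw = raw[mask]
    batch = SampleBatch(
        space.names, raw, space.normalize(raw), kept_outputs, kept_outputs,
        meta={"model": "brain", "n_regions": connectome.n,
              "reject_reasons": [r for k, r in verdicts if not k]},
    )
    return split(batch, val_fraction, seed)
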