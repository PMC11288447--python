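"""Larter-Breakspear coupled neural-mass network with a BOLD/FC readout.

Each brain region is a neural mass with three states — mean excitatory
voltage V, mean inhibitory voltage Z, and open-K+ channel fraction W — driven
by voltage-gated Ca2+/Na+/K+ currents, leak currents and synaptic terms, and
coupled to other regions through a connectome-weighted average of excitatory
firing rates.  The model is unitless with parameters scaled so that one time
step corresponds to 1 ms.

The readout chain mirrors an fMRI experiment: regional excitatory voltages
are standardized and passed through the Balloon-Windkessel hemodynamic model
to produce BOLD signals sampled at the repetition time TR, bandpass filtered
(0.01-0.1 Hz, zero-phase), and summarized as a functional-connectivity (FC)
matrix of all-to-all Pearson correlations whose upper triangle is the network
output vector (length n(n-1)/2; 3003 for the full 78-region atlas).

Note: the inhibitory firing rate Q_Z is implemented as a sigmoid of the
excitatory voltage V with threshold Z_T, following the source formulation
adopted here; the classical variant gates Q_Z on Z instead.  See the methods
note for discussion.

A synthetic-connectome generator stands in for a measured DTI matrix: it
produces symmetric, nonnegative, seed-deterministic weight matrices with
positive row sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "LBParams",
    "Connectome",
    "RegionState",
    "FCMatrix",
    "LB_FIXED",
    "LB_RANGES",
    "LB_PARAM_NAMES",
    "firing_rates",
    "gating",
    "network_drive",
    "lb_derivatives",
    "simulate_network",
    "bold_transform",
    "fc_pipeline",
    "exclusion_filter",
    "synthetic_connectome",
    "write_connectome",
    "read_connectome",
]

#: the 19 fixed parameters, at the standard defaults of the whole-brain
#: literature for this model (unitless; 1 step = 1 ms)
LB_FIXED = {
    "VL": -0.5,    # leak reversal potential
    "gL": 0.5,     # leak conductance
    "TNa": 0.3,    # Na+ channel threshold
    "TK": 0.0,     # K+ channel threshold
    "TCa": -0.01,  # Ca2+ channel threshold
    "dNa": 0.15,   # Na+ threshold variance
    "dK": 0.3,     # K+ threshold variance
    "dCa": 0.15,   # Ca2+ threshold variance
    "VT": 0.0,     # excitatory firing threshold
    "ZT": 0.0,     # inhibitory firing threshold
    "QVmax": 1.0,  # max excitatory firing rate
    "QZmax": 1.0,  # max inhibitory firing rate
    "aie": 2.0,    # inhibitory-to-excitatory strength
    "ane": 1.0,    # nonspecific-to-excitatory strength
    "ani": 0.4,    # nonspecific-to-inhibitory strength
    "I0": 0.3,     # subcortical excitatory input
    "b": 0.1,      # time scaling of the inhibitory population
    "phi": 0.7,    # temperature scaling of the K+ channel
    "tauK": 1.0,   # K+ relaxation time
}

#: sampling ranges of the 11 free parameters
LB_RANGES = {
    "c": (0.2, 0.5),
    "delta": (0.64, 0.7),
    "gCa": (0.95, 1.05),
    "VCa": (0.95, 1.01),
    "gK": (1.95, 2.05),
    "VK": (-0.75, -0.65),
    "gNa": (6.6, 6.8),
    "VNa": (0.48, 0.58),
    "aee": (0.33, 0.39),
    "aei": (1.95, 2.05),
    "rNMDA": (0.20, 0.30),
}

LB_PARAM_NAMES = list(LB_RANGES)


@dataclass(frozen=True)
class LBParams:
    """The 11 free Larter-Breakspear parameters plus the fixed background set."""

    c: float = 0.35
    delta: float = 0.67
    gCa: float = 1.0
    VCa: float = 0.98
    gK: float = 2.0
    VK: float = -0.7
    gNa: float = 6.7
    VNa: float = 0.53
    aee: float = 0.36
    aei: float = 2.0
    rNMDA: float = 0.25
    fixed: dict = field(default_factory=lambda: dict(LB_FIXED))

    @classmethod
    def from_vector(cls, values: np.ndarray) -> "LBParams":
        """Build from an 11-vector ordered as LB_PARAM_NAMES."""
        return cls(**dict(zip(LB_PARAM_NAMES, map(float, values))))


@dataclass
class Connectome:
    """Symmetric nonnegative inter-regional weight matrix with labels."""

    weights: np.ndarray
    labels: list = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("connectome must be symmetric")
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        row_sums = w.sum(axis=1)
        if np.any(row_sums <= 0):
            bad = int(np.argmin(row_sums))
            raise ValueError(f"connectome row {bad} has nonpositive sum")
        self.weights = w
        if self.labels is None:
            self.labels = [f"R{i:02d}" for i in range(w.shape[0])]

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class RegionState:
    """Per-region state arrays (V, Z, W); W is a channel fraction in [0, 1]."""

    V: np.ndarray
    Z: np.ndarray
    W: np.ndarray


@dataclass
class FCMatrix:
    """Functional-connectivity matrix and its upper-triangle vector."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("FC matrix must be square")
        self.matrix = m

    @property
    def vector(self) -> np.ndarray:
        """Row-major upper triangle excluding the diagonal, length n(n-1)/2."""
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]

    @property
    def mean_offdiagonal(self) -> float:
        return float(self.vector.mean())


# ---------------------------------------------------------------------------
# model equations
# ---------------------------------------------------------------------------

def gating(V, T_ion: float, delta_ion: float):
    """Sigmoid channel activation m(V) = 0.5 (1 + tanh((V - T) / delta))."""
    if delta_ion <= 0:
        raise ValueError("gating requires delta_ion > 0")
    return 0.5 * (1.0 + np.tanh((np.asarray(V, dtype=float) - T_ion) / delta_ion))


def firing_rates(V, Z, params: LBParams):
    """Mean excitatory and inhibitory firing rates (Q_V, Q_Z).

    Both sigmoids are driven by the excitatory voltage V (see module note);
    Q_V uses threshold V_T and Q_Z threshold Z_T, sharing the variance delta.
    The Z argument is accepted for signature symmetry with the state.
    """
    fx = params.fixed
    if params.delta <= 0:
        raise ValueError("firing_rates requires delta > 0")
    V = np.asarray(V, dtype=float)
    QV = 0.5 * fx["QVmax"] * (1.0 + np.tanh((V - fx["VT"]) / params.delta))
    QZ = 0.5 * fx["QZmax"] * (1.0 + np.tanh((V - fx["ZT"]) / params.delta))
    return QV, QZ


def network_drive(QV: np.ndarray, connectome: Connectome) -> np.ndarray:
    """Connectome-weighted average of afferent excitatory firing rates."""
    w = connectome.weights
    return w @ np.asarray(QV, dtype=float) / w.sum(axis=1)


def lb_derivatives(state: RegionState, params: LBParams, connectome: Connectome):
    """Time derivatives (dV, dZ, dW) for all regions simultaneously."""
    V, Z, W = np.asarray(state.V, float), np.asarray(state.Z, float), np.asarray(state.W, float)
    n = connectome.n
    if not (V.shape == Z.shape == W.shape == (n,)):
        raise ValueError(
            f"state arrays must all have shape ({n},) matching the connectome, "
            f"got {V.shape}, {Z.shape}, {W.shape}"
        )
    fx = params.fixed
    QV, QZ = firing_rates(V, Z, params)
    Qnet = network_drive(QV, connectome)
    mixed = (1.0 - params.c) * QV + params.c * Qnet
    mCa = gating(V, fx["TCa"], fx["dCa"])
    mNa = gating(V, fx["TNa"], fx["dNa"])
    mK = gating(V, fx["TK"], fx["dK"])
    dV = (
        -(params.gCa + params.rNMDA * params.aee * mixed) * mCa * (V - params.VCa)
        - (params.gNa * mNa + params.aee * mixed) * (V - params.VNa)
        - params.gK * W * (V - params.VK)
        - fx["gL"] * (V - fx["VL"])
        - fx["aie"] * Z * QZ
        + fx["ane"] * fx["I0"]
    )
    dZ = fx["b"] * (fx["ani"] * fx["I0"] + params.aei * V * QV)
    dW = fx["phi"] * (mK - W) / fx["tauK"]
    return dV, dZ, dW


def simulate_network(
    params: LBParams,
    connectome: Connectome,
    duration: float = 10_000.0,
    dt: float = 0.1,
    burn_in: float = 2_000.0,
    record_dt: float = 1.0,
    seed: int = 0,
):
    """Integrate the coupled network with fixed-step RK4.

    Parameters are in milliseconds (duration, dt, burn_in, record_dt).
    Initial conditions are small seed-deterministic perturbations around
    (V, Z, W) = (0, 0, 0.5).  Returns (t_ms, V_series) where V_series has
    shape (T, n); the burn-in transient is discarded.
    """
    if duration <= burn_in:
        raise ValueError("duration must exceed burn_in")
    n = connectome.n
    rng = np.random.default_rng(seed)
    V = 0.05 * rng.standard_normal(n)
    Z = 0.05 * rng.standard_normal(n)
    W = np.clip(0.5 + 0.01 * rng.standard_normal(n), 0.0, 1.0)

    def rhs(y):
        dV, dZ, dW = lb_derivatives(RegionState(*y), params, connectome)
        return np.stack([dV, dZ, dW])

    y = np.stack([V, Z, W])
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_dt / dt)))
    rec_t, rec_V = [], []
    for step in range(1, n_steps + 1):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"network integration diverged at t={step * dt} ms for {params}")
        t = step * dt
        if step % stride == 0 and t > burn_in:
            rec_t.append(t)
            rec_V.append(y[0].copy())
    return np.asarray(rec_t), np.asarray(rec_V)


# ---------------------------------------------------------------------------
# BOLD + FC readout
# ---------------------------------------------------------------------------

#: canonical Balloon-Windkessel hemodynamic parameters
BW_PARAMS = {
    "kappa": 0.65,  # 1/s, signal decay
    "gamma": 0.41,  # 1/s, flow-dependent elimination
    "tau": 0.98,    # s, hemodynamic transit time
    "alpha": 0.32,  # Grubb's vessel stiffness exponent
    "rho": 0.34,    # resting oxygen extraction fraction
    "V0": 0.04,     # resting venous blood volume fraction
}


def bold_transform(
    V_series: np.ndarray,
    dt: float,
    TR: float = 0.8,
    bw: dict | None = None,
    standardize: bool = True,
):
    """Convert regional neural series into BOLD signals sampled at TR.

    Parameters
    ----------
    V_series
        (T, n) neural activity; each region is z-scored before driving the
        hemodynamics (making the transform scale-free) unless ``standardize``
        is False.
    dt
        Sampling interval of ``V_series`` in seconds.
    TR
        Output repetition time in seconds.

    Returns (t_s, bold) with bold of shape (T_TR, n).
    """
    if TR <= 0:
        raise ValueError("TR must be positive")
    p = dict(BW_PARAMS, **(bw or {}))
    z = np.asarray(V_series, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if standardize:
        sd = z.std(axis=0)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=0)) / sd
    T, n = z.shape
    kappa, gam, tau, alpha, rho, V0 = (p[k] for k in ("kappa", "gamma", "tau", "alpha", "rho", "V0"))
    k1, k2, k3 = 7.0 * rho, 2.0, 2.0 * rho - 0.2

    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)

    def rhs(state, u):
        s_, f_, v_, q_ = state
        f_ = np.maximum(f_, 1e-6)
        v_ = np.maximum(v_, 1e-6)
        ds = u - kappa * s_ - gam * (f_ - 1.0)
        df = s_
        E = 1.0 - (1.0 - rho) ** (1.0 / f_)
        dv = (f_ - v_ ** (1.0 / alpha)) / tau
        dq = (f_ * E / rho - v_ ** (1.0 / alpha - 1.0) * q_) / tau
        return np.stack([ds, df, dv, dq])

    y = np.stack([s, f, v, q])
    bold = np.empty((T, n))
    for i in range(T):
        u = z[i]
        k1_ = rhs(y, u)
        k2_ = rhs(y + 0.5 * dt * k1_, u)
        k3_ = rhs(y + 0.5 * dt * k2_, u)
        k4_ = rhs(y + dt * k3_, u)
        y = y + (dt / 6.0) * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
        v_, q_ = np.maximum(y[2], 1e-6), y[3]
        bold[i] = V0 * (k1 * (1.0 - q_) + k2 * (1.0 - q_ / v_) + k3 * (1.0 - v_))

    stride = max(1, int(round(TR / dt)))
    idx = np.arange(0, T, stride)
    return idx * dt, bold[idx]


def fc_pipeline(bold: np.ndarray, fs: float, band=(0.01, 0.1)) -> FCMatrix:
    """Zero-phase bandpass filter then all-to-all Pearson correlation.

    ``bold`` is (T, n) sampled at ``fs`` Hz (typically 1/TR).
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[1] < 2:
        raise ValueError("fc_pipeline needs a (T, n>=2) series matrix")
    b, a = butter(2, band, btype="bandpass", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if bold.shape[0] <= padlen:
        raise ValueError(f"series too short for the bandpass filter warm-up ({bold.shape[0]} <= {padlen})")
    filtered = filtfilt(b, a, bold, axis=0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(filtered.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(matrix=np.clip(corr, -1.0, 1.0))


def exclusion_filter(
    V_series: np.ndarray,
    fc: FCMatrix,
    mean_fc_max: float = 0.3,
    amplitude_min: float = 0.01,
):
    """Keep/reject verdict for one simulation.

    Rejects when any region is non-oscillatory (post-burn-in peak-to-peak
    amplitude below ``amplitude_min``) or when the mean upper-triangle FC
    exceeds ``mean_fc_max``.  Returns (keep, reason) with reason None on keep.
    """
    V_series = np.atleast_2d(np.asarray(V_series, dtype=float))
    ptp = V_series.max(axis=0) - V_series.min(axis=0)
    if np.any(ptp < amplitude_min):
        return False, "non-oscillatory"
    if fc.mean_offdiagonal > mean_fc_max:
        return False, f"mean FC {fc.mean_offdiagonal:.3f} > {mean_fc_max}"
    return True, None


# ---------------------------------------------------------------------------
# synthetic connectome
# ---------------------------------------------------------------------------

def synthetic_connectome(n: int, density: float = 0.3, seed: int = 0) -> Connectome:
    """Random symmetric weighted connectome standing in for a DTI matrix.

    Each of the n(n-1)/2 undirected pairs is connected with probability
    ``density``; weights are uniform on (0.5, 1.5).  Any isolated region is
    linked to its ring neighbor so that every row sum is positive.  The result
    is deterministic given the seed.
    """
    if n < 2:
        raise ValueError("synthetic_connectome requires n >= 2")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    weights = rng.uniform(0.5, 1.5, len(iu[0])) * mask
    w = np.zeros((n, n))
    w[iu] = weights
    w = w + w.T
    for i in np.flatnonzero(w.sum(axis=1) == 0):
        j = (i + 1) % n
        w[i, j] = w[j, i] = 1.0
    return Connectome(weights=w)


def write_connectome(path, connectome: Connectome) -> None:
    """Square delimited matrix with a header row of region labels."""
    pd.DataFrame(connectome.weights, columns=connectome.labels).to_csv(path, index=False)


def read_connectome(path) -> Connectome:
    df = pd.read_csv(path)
    return Connectome(weights=df.to_numpy(dtype=float), labels=list(df.columns))
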