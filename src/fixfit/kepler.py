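"""Closed-form Kepler two-body orbit model.

The orbit of a body of mass ``m1`` around a focal mass ``m2`` is an ellipse
fully described by two composite shape parameters, the eccentricity ``e`` and
the semi-latus rectum ``l``::

    r(theta) = l / (1 + e cos theta)
    e = |r0^3 w0^2 / (G m2) - 1|
    l = r0^4 w0^2 / (G m2)

Both composites are independent of ``m1`` (it cancels in the equation of
motion) and depend on ``m2`` and ``w0`` only through ``w0^2 / m2`` — the known
parameter degeneracies that the bottleneck analysis is expected to recover.

Units follow the rescaled convention that keeps all sampled parameters at
comparable magnitude: masses in kg, distances in m, angular velocity in 1/day,
and G = 0.5 m^3 kg^-1 day^-2.

An independent numerical oracle (:func:`eq1_oracle`) integrates the radial
equation of motion directly and is used only for cross-checking the closed
form in tests; the data pipeline always uses the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "KeplerParams",
    "OrbitShape",
    "OrbitTrace",
    "composite_params",
    "apsis_branch",
    "default_theta_grid",
    "orbit_radii",
    "orbit_radii_batch",
    "eq1_oracle",
    "write_trace",
    "read_trace",
]

#: default gravitational constant in the rescaled units (m^3 kg^-1 day^-2)
G_DEFAULT = 0.5

#: default sampling range for m1, m2, r0, omega0
SAMPLING_RANGE = (0.1, 1.0)


@dataclass(frozen=True)
class KeplerParams:
    """Native parameters of the two-body problem.

    m1
        Mass of the orbiting body (kg). Structurally redundant.
    m2
        Mass of the focal body (kg).
    r0
        Apsis distance at theta = 0 (m).
    omega0
        Angular velocity at r0 (1/day).
    G
        Gravitational constant (m^3 kg^-1 day^-2).
    """

    m1: float
    m2: float
    r0: float
    omega0: float
    G: float = G_DEFAULT

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "r0", "omega0", "G"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"Kepler parameter {name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class OrbitShape:
    """Composite orbit parameters: eccentricity and semi-latus rectum."""

    e: float
    l: float

    def __post_init__(self) -> None:
        if self.e < 0:
            raise ValueError(f"eccentricity must be nonnegative, got {self.e}")
        if self.l <= 0:
            raise ValueError(f"semi-latus rectum must be positive, got {self.l}")


@dataclass
class OrbitTrace:
    """Radii sampled on an angular grid, with log radii for the NN output space."""

    theta_grid: np.ndarray
    r: np.ndarray
    log_r: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.theta_grid.shape != self.r.shape:
            raise ValueError("theta_grid and r must have equal length")
        if np.any(self.r <= 0):
            raise ValueError("orbit radii must be strictly positive everywhere")
        if self.log_r is None:
            self.log_r = np.log(self.r)


def composite_params(p: KeplerParams) -> OrbitShape:
    """Map native parameters to the composite orbit shape (independent of m1)."""
    x = p.r0**3 * p.omega0**2 / (p.G * p.m2)
    return OrbitShape(e=abs(x - 1.0), l=x * p.r0)


def apsis_branch(p: KeplerParams) -> str:
    """Which apsis the initial condition r0 sits on.

    For ``r0^3 w0^2 > G m2`` the body starts at periapsis (r0 is the closest
    approach); for the opposite inequality r0 is the apoapsis.  The composite
    formulas apply verbatim on both branches; the branch is recorded so that
    downstream users know which geometry a sample represents.
    """
    x = p.r0**3 * p.omega0**2 / (p.G * p.m2)
    return "periapsis" if x >= 1.0 else "apoapsis"


def default_theta_grid(n: int = 100) -> np.ndarray:
    """Endpoint-inclusive even spacing on [0, 2*pi], in radians."""
    return np.linspace(0.0, 2.0 * np.pi, n)


def orbit_radii(shape: OrbitShape, theta_grid: np.ndarray | None = None) -> OrbitTrace:
    """Evaluate the conic-section radius r(theta) = l / (1 + e cos theta).

    Requires ``e < 1``: on a full angular grid a parabolic or hyperbolic
    trajectory has diverging radius.
    """
    if shape.e >= 1.0:
        raise ValueError(f"orbit_radii requires e < 1 for a closed ellipse, got e={shape.e}")
    if theta_grid is None:
        theta_grid = default_theta_grid()
    theta_grid = np.asarray(theta_grid, dtype=float)
    r = shape.l / (1.0 + shape.e * np.cos(theta_grid))
    return OrbitTrace(theta_grid=theta_grid, r=r)


def orbit_radii_batch(e: np.ndarray, l: np.ndarray, theta_grid: np.ndarray) -> np.ndarray:
    """Vectorized r(theta) for many orbits at once; returns an (N, T) matrix."""
    e = np.asarray(e, dtype=float)[:, None]
    l = np.asarray(l, dtype=float)[:, None]
    if np.any(e >= 1.0):
        raise ValueError("orbit_radii_batch requires e < 1 for every sample")
    return l / (1.0 + e * np.cos(np.asarray(theta_grid, dtype=float)[None, :]))


def eq1_oracle(
    p: KeplerParams,
    theta_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OrbitTrace:
    """Integrate the radial equation of motion and sample r at given angles.

    The second-order radial equation (with m1 cancelled and conserved angular
    momentum L = r0^2 w0, so omega = L / r^2) is integrated as the first-order
    system (r, rdot, theta) with rdot(0) = 0 using an adaptive explicit
    Runge-Kutta scheme.  This is a test oracle, not part of the data pipeline.
    """
    if theta_grid is None:
        theta_grid = default_theta_grid()
    theta_grid = np.asarray(theta_grid, dtype=float)
    shape = composite_params(p)
    if shape.e >= 1.0:
        raise ValueError("eq1_oracle supports bound (elliptical) orbits only (e < 1)")

    L = p.r0**2 * p.omega0
    gm2 = p.G * p.m2

    def rhs(_t, y):
        r, rdot, _theta = y
        return [rdot, L**2 / r**3 - gm2 / r**2, L / r**2]

    # orbital period of the ellipse bounds the integration window
    a = shape.l / (1.0 - shape.e**2)
    period = 2.0 * np.pi * np.sqrt(a**3 / gm2)

    sol = solve_ivp(
        rhs,
        (0.0, 1.05 * period),
        [p.r0, 0.0, 0.0],
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(
            f"eq1_oracle integration failed for {p}: {sol.message}"
        )
    theta_end = sol.y[2, -1]
    if theta_end < theta_grid.max():
        raise RuntimeError(
            f"eq1_oracle swept only {theta_end:.4f} rad < requested {theta_grid.max():.4f}"
        )

    # theta(t) is strictly increasing (omega > 0): invert it per grid angle
    t_grid = sol.t
    theta_of_t = sol.y[2]
    r_out = np.empty_like(theta_grid)
    for i, th in enumerate(theta_grid):
        if th <= 0.0:
            r_out[i] = p.r0
            continue
        j = int(np.searchsorted(theta_of_t, th))
        t_lo, t_hi = t_grid[max(j - 1, 0)], t_grid[min(j, len(t_grid) - 1)]
        if t_hi <= t_lo:
            t_root = t_lo
        else:
            t_root = brentq(lambda t: sol.sol(t)[2] - th, t_lo, t_hi, xtol=1e-12)
        r_out[i] = sol.sol(t_root)[0]
    return OrbitTrace(theta_grid=theta_grid, r=r_out)


def write_trace(path, trace: OrbitTrace, transformed: bool = False) -> None:
    """Write a two-column delimited trace: (theta, r) or (theta, log_r)."""
    col = trace.log_r if transformed else trace.r
    header = "theta,log_r" if transformed else "theta,r"
    np.savetxt(path, np.column_stack([trace.theta_grid, col]), delimiter=",", header=header, comments="")


def read_trace(path, transformed: bool = False) -> OrbitTrace:
    """Read a trace written by :func:`write_trace`."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    theta, col = data[:, 0], data[:, 1]
    r = np.exp(col) if transformed else col
    return OrbitTrace(theta_grid=theta, r=r)
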