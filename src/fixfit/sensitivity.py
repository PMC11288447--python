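"""Global sensitivity of latent parameters to the original model parameters.

After training, the encoder maps each sampled parameter vector to its latent
coordinates.  Structural and Correlative Sensitivity Analysis (SCSA), an
HDMR-based method that tolerates the non-uniform sampling produced by the
admissibility filters, then attributes the variance of each latent coordinate
y_j to the individual inputs x_i.  Only the *uncorrelated* first-order index
is reported::

    S_unc[i, j] = sum_s f_ij(x_i^(s))^2  /  sum_s (y_j^(s) - mean(y_j))^2

where f_ij is the data-driven first-order component function of input i.
The component functions of all inputs are fitted jointly by penalized least
squares on a per-input cubic B-spline basis (8 interior knots by default),
so shared (correlated) variance is partitioned among inputs rather than
double-counted; for independent inputs and an additive model the indices
reduce to the classical first-order variance shares.

Indices below ~0.02 are conventionally reported as "no influence".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "SensitivityMatrix",
    "NEGLIGIBLE_INDEX",
    "encode",
    "scsa_unc",
]

#: indices below this value are labelled negligible in reports
NEGLIGIBLE_INDEX = 0.02


@dataclass
class SensitivityMatrix:
    """I x J matrix of uncorrelated sensitivity indices."""

    values: np.ndarray
    input_names: tuple
    latent_names: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.input_names), len(self.latent_names)):
            raise ValueError("values shape must be (n_inputs, n_latents)")
        if not np.all(np.isfinite(v)):
            raise ValueError("sensitivity indices must be finite")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.input_names),
                            columns=list(self.latent_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def negligible(self) -> pd.DataFrame:
        """Boolean table of entries below the no-influence threshold."""
        return self.to_frame() < NEGLIGIBLE_INDEX


def encode(norm_params: np.ndarray, model) -> np.ndarray:
    """Latent coordinates of normalized parameters under a trained encoder."""
    norm_params = np.asarray(norm_params, dtype=float)
    if norm_params.ndim == 1:
        norm_params = norm_params[None, :]
    if norm_params.shape[1] != model.spec.input_width:
        raise ValueError(
            f"parameter width {norm_params.shape[1]} != encoder input width {model.spec.input_width}"
        )
    return np.asarray(model.encode(norm_params), dtype=float)


def _spline_design(x: np.ndarray, n_knots: int, degree: int) -> np.ndarray:
    """B-spline design matrix for one input, with evenly spaced interior knots."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        span = abs(lo) if lo != 0 else 1.0
        lo, hi = lo - 1e-9 * span, hi + 1e-9 * span
    interior = np.linspace(lo, hi, n_knots + 2)[1:-1]
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    xc = np.clip(x, lo, hi - 1e-12 * (hi - lo))
    return BSpline.design_matrix(xc, t, degree).toarray()


def scsa_unc(
    X: np.ndarray,
    Y: np.ndarray,
    input_names=None,
    latent_names=None,
    n_knots: int = 8,
    degree: int = 3,
    ridge: float = 1e-6,
) -> SensitivityMatrix:
    """Uncorrelated first-order SCSA indices of every latent wrt every input.

    Parameters
    ----------
    X
        (N, I) input samples (any scale; each input gets its own spline basis).
    Y
        (N, J) latent samples, row-aligned with X.
    ridge
        Tikhonov penalty (relative to the design Gram diagonal) stabilizing
        the joint component-function fit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    n, I = X.shape
    J = Y.shape[1]
    if n <= (n_knots + degree + 1) * I:
        raise ValueError("too few samples for the spline basis; increase N")
    if input_names is None:
        input_names = tuple(f"x{i+1}" for i in range(I))
    if latent_names is None:
        latent_names = tuple(f"L{j+1}" for j in range(J))

    # per-input centered spline blocks, fitted jointly
    blocks = []
    for i in range(I):
        B = _spline_design(X[:, i], n_knots, degree)
        blocks.append(B - B.mean(axis=0))
    design = np.hstack(blocks)
    gram = design.T @ design
    lam = ridge * np.trace(gram) / gram.shape[0]
    gram[np.diag_indices_from(gram)] += lam

    values = np.empty((I, J))
    col_slices = []
    start = 0
    for B in blocks:
        col_slices.append(slice(start, start + B.shape[1]))
        start += B.shape[1]
    for j in range(J):
        y = Y[:, j] - Y[:, j].mean()
        denom = float(y @ y)
        if denom <= 0:
            raise ValueError(f"latent column {latent_names[j]!r} has zero variance")
        coef = np.linalg.solve(gram, design.T @ y)
        for i, sl in enumerate(col_slices):
            f_i = blocks[i] @ coef[sl]
            values[i, j] = float(f_i @ f_i) / denom
    return SensitivityMatrix(values=values, input_names=tuple(input_names),
                             latent_names=tuple(latent_names))
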