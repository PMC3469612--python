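"""Ordinary cross-validation (OCV) selection of the regularization parameter.

Leave-one-sensor-out prediction error has a closed form through the
sensor-space resolution matrix A = G W: the deleted-sensor residual equals
the full-fit residual inflated by 1/(1 - A_ii), so no refits are needed:

    cost(lambda) = sum_i ((v_i - (A v)_i) / (1 - A_ii))^2 .

The identity is exact for independent observations.  Correlated noise is
handled by evaluating the cost on whitened data, where the hat matrix
C^-1/2 A C^1/2 is symmetric with eigenvalues in [0, 1); for C
proportional to the identity the whitened cost coincides with the literal
formula.  Multi-sample data (sensors x samples) pools per-sample costs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .inverse import InverseFamily, InverseOperator

__all__ = ["OCVResult", "sensor_resolution", "ocv_cost", "select_lambda"]


@dataclass
class OCVResult:
    """Grid, per-lambda costs, selected lambda and diagnostics."""

    lam_grid: np.ndarray
    costs: np.ndarray
    lam: float
    resolution_diag: np.ndarray
    at_boundary: bool = False
    info: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"lambda": self.lam_grid, "cost": self.costs}).to_csv(path, index=False)


def sensor_resolution(G, W) -> np.ndarray:
    """Sensor-space resolution matrix A = G W (fitted data = A v)."""
    g = G.matrix if hasattr(G, "matrix") else np.asarray(G, dtype=float)
    w = W.W if isinstance(W, InverseOperator) else np.asarray(W, dtype=float)
    return g @ w


def _cost_from_A(v: np.ndarray, a: np.ndarray) -> float:
    diag = np.diag(a)
    denom = 1.0 - diag
    if np.any(np.abs(denom) <= 1e-12):
        raise FloatingPointError(
            "resolution diagonal reaches 1: perfect fit, lambda too small for OCV")
    v = np.asarray(v, dtype=float)
    resid = v - a @ v
    if v.ndim == 1:
        return float(np.sum((resid / denom) ** 2))
    return float(np.sum((resid / denom[:, None]) ** 2))


def ocv_cost(v: np.ndarray, G, W, C: np.ndarray | None = None) -> float:
    """OCV cost for data ``v`` under the operator W (A = G W).

    Without ``C`` this is the literal closed form above and equals the
    explicit leave-one-sensor-out squared prediction error of the
    regularized fit.  With a noise covariance ``C`` the cost is evaluated on
    whitened data (hat matrix C^-1/2 A C^1/2, observations C^-1/2 v).
    """
    a = sensor_resolution(G, W)
    if C is None:
        return _cost_from_A(v, a)
    cmh, cph = _cov_roots(np.asarray(C, dtype=float))
    v = np.asarray(v, dtype=float)
    return _cost_from_A(cmh @ v, cmh @ a @ cph)


def _cov_roots(c: np.ndarray):
    w, vec = np.linalg.eigh(c)
    w = np.clip(w, 1e-15 * w.max(), None)
    cmh = (vec * w**-0.5) @ vec.T
    cph = (vec * w**0.5) @ vec.T
    return cmh, cph


def select_lambda(v: np.ndarray, family: InverseFamily,
                  lam_grid: np.ndarray | None = None, n_grid: int = 25) -> OCVResult:
    """Grid-minimize the whitened OCV cost over lambda for one algorithm.

    The whitened hat matrix diagonalizes once (S~ = C^-1/2 G R G^T C^-1/2 =
    U diag(d) U^T, A~(lambda) = U diag(d/(d+lambda)) U^T), so the whole grid
    costs a single eigendecomposition.  Default grid: ``n_grid`` log-spaced
    points spanning [1e-4, 1e2] times the scale-free anchor
    trace(G R G^T)/trace(C)/n.  Multi-sample ``v`` (sensors x samples) pools
    per-sample costs; warns when the minimum sits on a grid boundary.
    """
    if lam_grid is None:
        anchor = family.default_lambda_scale()
        lam_grid = anchor * np.logspace(-4, 2, n_grid)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if len(lam_grid) < 5:
        raise ValueError("lambda grid must have >= 5 points")

    cmh, _ = _cov_roots(family.c)
    st = cmh @ family.s @ cmh
    d, u = np.linalg.eigh(0.5 * (st + st.T))
    d = np.clip(d, 0.0, None)
    vt = cmh @ (np.asarray(v, dtype=float)[:, None] if np.ndim(v) == 1 else np.asarray(v, dtype=float))
    utv = u.T @ vt

    costs = np.full(len(lam_grid), np.inf)
    diag_at = {}
    for i, lam in enumerate(lam_grid):
        shrink = d / (d + lam)
        a_diag = (u**2) @ shrink
        denom = 1.0 - a_diag
        if np.any(np.abs(denom) <= 1e-12):
            continue  # perfect interpolation: overfit, cost infinite
        resid = vt - u @ (shrink[:, None] * utv)
        costs[i] = float(np.sum((resid / denom[:, None]) ** 2))
        diag_at[i] = a_diag
    if not np.any(np.isfinite(costs)):
        raise RuntimeError("OCV cost infinite on the whole grid; selection failed")
    best = int(np.nanargmin(costs))
    at_boundary = best in (0, len(lam_grid) - 1)
    if at_boundary:
        warnings.warn("OCV minimum at the lambda-grid boundary; widen the grid",
                      RuntimeWarning, stacklevel=2)
    return OCVResult(lam_grid, costs, float(lam_grid[best]), diag_at[best],
                     at_boundary, {"algorithm": family.algorithm})
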