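"""Regularised inversion of the chest-to-pericardium potential problem.

The inverse problem of ECG imaging recovers the pericardial potential u from
noisy chest data y_d by minimising

    1/2 ||A u - y_d||^2_{L2(Gamma)}  +  lambda^2 R(u),

discretised with the trapezoidal mass matrices of the collocation grids.
Four penalties R are supported, all expressed through a symmetric matrix M in
the normal equations ``(A^T S_Gamma A + lambda^2 M) u = A^T S_Gamma y_d``:

``tik0``  L2 norm of the Dirichlet data:        M = S_Sigma
``tik1``  L2 norm of the Neumann data:          M = B^T S_Sigma B
``h12``   H^{1/2} trace norm <B u, u>:          M = (B^T S_Sigma + S_Sigma B)/2
``tv``    smoothed L1 norm of the Neumann data, linearised once around the
          zero-order Tikhonov solution u0 (lagged diffusivity):
          M = B^T W S_Sigma B,  W_ii = 1 / (2 sqrt((B u0)_i^2 + beta))

where B is the discrete Steklov (Dirichlet-to-Neumann) operator.  The
regularisation parameter can be chosen per time step by the L-curve
maximum-curvature criterion, with the maximum over the heartbeat used as a
single conservative parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

from .bem import TransferOperators

__all__ = [
    "RegularisationSpec",
    "TABLE_DEFAULT_LAMBDA",
    "regularisation_matrix",
    "inverse_solve",
    "l_curve_select",
]

RegKind = Literal["tik0", "tik1", "h12", "tv"]

#: study-default regularisation parameters per kind
TABLE_DEFAULT_LAMBDA: dict[str, float] = {
    "tik0": 1e-6, "tik1": 1e-3, "h12": 1e-5, "tv": 1e-5,
}


@dataclass(frozen=True)
class RegularisationSpec:
    kind: RegKind
    lam: float | None = None  #: None selects the study default for the kind
    beta: float = 1e-5  #: TV smoothing constant
    symmetrised_h12: bool = True  #: exact symmetrised gradient (see notes)

    def __post_init__(self) -> None:
        if self.kind not in TABLE_DEFAULT_LAMBDA:
            raise ValueError(f"unknown regularisation kind {self.kind!r}")
        if self.lam is None:
            object.__setattr__(self, "lam", TABLE_DEFAULT_LAMBDA[self.kind])
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.kind == "tv" and self.beta <= 0:
            raise ValueError("beta must be positive for tv")


def regularisation_matrix(spec: RegularisationSpec, ops: TransferOperators,
                          u0: np.ndarray | None = None) -> np.ndarray:
    """Symmetric penalty matrix M for the normal equations.

    ``u0`` (the zero-order Tikhonov solution) is required exactly for the TV
    kind, where it freezes the lagged-diffusivity weight.
    """
    S = ops.S_sigma  # diagonal entries
    if spec.kind == "tik0":
        M = np.diag(S)
    elif spec.kind == "tik1":
        M = ops.B.T @ (S[:, None] * ops.B)
    elif spec.kind == "h12":
        if spec.symmetrised_h12:
            M = 0.5 * (ops.B.T * S[None, :] + S[:, None] * ops.B)
        else:
            # the one-sided form S (B^T + B) / 2, symmetrised a posteriori
            raw = 0.5 * S[:, None] * (ops.B.T + ops.B)
            M = 0.5 * (raw + raw.T)
    elif spec.kind == "tv":
        if u0 is None:
            raise ValueError("tv regularisation requires the tik0 solution u0")
        w = 1.0 / (2.0 * np.sqrt((ops.B @ u0) ** 2 + spec.beta))
        M = ops.B.T @ ((w * S)[:, None] * ops.B)
    else:  # pragma: no cover - guarded in the spec dataclass
        raise ValueError(spec.kind)
    M = 0.5 * (M + M.T)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite entries in regularisation matrix")
    return M


def _normal_solve(ops: TransferOperators, yd: np.ndarray, lam: float,
                  M: np.ndarray) -> np.ndarray:
    AtS = ops.A.T * ops.S_gamma[None, :]
    lhs = AtS @ ops.A + lam ** 2 * M
    rhs = AtS @ yd
    with warnings.catch_warnings():
        # at the weak end of an L-curve sweep the normal matrix is expected
        # to be near-singular; the corner criterion never picks those lambdas
        warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
        return scipy.linalg.solve(lhs, rhs, assume_a="sym")


def inverse_solve(ops: TransferOperators, yd: np.ndarray,
                  spec: RegularisationSpec) -> np.ndarray:
    """Solve the regularised normal equations for one time step.

    For TV the zero-order Tikhonov solution at the same lambda provides the
    frozen weight (a single lagged-diffusivity linearisation, no iteration).
    """
    yd = np.asarray(yd, dtype=float)
    if yd.shape[-1] != ops.A.shape[0]:
        raise ValueError("yd must have length n_Gamma")
    u0 = None
    if spec.kind == "tv":
        tik0 = RegularisationSpec("tik0", lam=spec.lam)
        u0 = _normal_solve(ops, yd, tik0.lam, regularisation_matrix(tik0, ops))
    M = regularisation_matrix(spec, ops, u0=u0)
    return _normal_solve(ops, yd, spec.lam, M)


def _objective_parts(ops: TransferOperators, yd: np.ndarray, u: np.ndarray,
                     M: np.ndarray) -> tuple[float, float]:
    r = ops.A @ u - yd
    residual = float(r @ (ops.S_gamma * r))
    penalty = float(u @ (M @ u))
    return residual, penalty


def l_curve_select(ops: TransferOperators, yd: np.ndarray, kind: RegKind,
                   lam_grid: Sequence[float] | None = None,
                   beta: float = 1e-5) -> float:
    """L-curve choice of lambda, maximal over the supplied time steps.

    ``yd`` may be a single chest vector or a matrix with one column per time
    step.  Per step, the lambda of maximal finite-difference curvature of
    (log residual-norm, log penalty-value) over the log-spaced grid is
    picked (interior points only, ties towards larger lambda); the maximum
    over steps is returned, the conservative policy that limits oscillations
    over the heartbeat.
    """
    if lam_grid is None:
        lam_grid = np.logspace(-8, 0, 33)
    lam_grid = np.asarray(sorted(lam_grid), dtype=float)
    if lam_grid.size < 9:
        raise ValueError("lambda grid needs at least 9 points")
    yd = np.atleast_2d(np.asarray(yd, dtype=float).T).T  # (n_Gamma, n_steps)

    picks = []
    for col in yd.T:
        logr = np.empty(lam_grid.size)
        logp = np.empty(lam_grid.size)
        for i, lam in enumerate(lam_grid):
            spec = RegularisationSpec(kind, lam=lam, beta=beta)
            u = inverse_solve(ops, col, spec)
            M = regularisation_matrix(
                spec, ops,
                u0=inverse_solve(ops, col, RegularisationSpec("tik0", lam=lam))
                if kind == "tv" else None)
            residual, penalty = _objective_parts(ops, col, u, M)
            if residual <= 0 or penalty <= 0:
                residual, penalty = max(residual, 1e-300), max(penalty, 1e-300)
            logr[i] = 0.5 * np.log(residual)
            logp[i] = 0.5 * np.log(penalty)
        if np.ptp(logr) < 1e-12 or np.ptp(logp) < 1e-12:
            raise ValueError("degenerate L-curve: residual or penalty constant")
        picks.append(_max_curvature(lam_grid, logr, logp))
    return float(max(picks))


def _max_curvature(lam_grid: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    """Interior grid point of maximal |curvature| of the curve (x, y)(log lam)."""
    t = np.log(lam_grid)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx ** 2 + dy ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.abs(dx * ddy - dy * ddx) / denom
    kappa[~np.isfinite(kappa)] = -np.inf
    interior = kappa[1:-1]
    # ties broken towards larger lambda for stability
    best = len(interior) - 1 - int(np.argmax(interior[::-1])) + 1
    return float(lam_grid[best])
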