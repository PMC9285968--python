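"""Periodic space-time random deformation field of the pericardium.

The uncertain pericardial contour is modelled as a random deformation of the
reference contour: displaced positions are

    chi(z, xi) = E[chi](z) + sum_k m_k(z) xi_k,      xi in [-1, 1]^K,

where z = (x, t) runs over the space-time collocation points of the reference
pericardium and the weighted modes m_k = sqrt(lambda_k) chi_k come from a
pivoted Cholesky factorisation of the covariance, truncated at a relative
trace tolerance.  The covariance is a tensor product of a periodic sine-power
kernel in time and Matern kernels in space (smoothness 5/2 for the first
spatial component, the Gaussian limit for the second); the two displacement
components are uncorrelated, so each is factorised separately and the mode
lists are merged by pivot magnitude.

The parameters xi are iid uniform on [-1, 1] (variance 1/3 per coordinate);
the expansion is used literally, without variance rescaling, so the per-point
displacement standard deviation is ``sqrt(sum_k m_k^2 / 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import shapely
from shapely.geometry import LinearRing, Polygon

from .geometry import ClosedCurve, SpaceTimeGeometry

__all__ = [
    "CovarianceModel",
    "KLExpansion",
    "AdmissibilityError",
    "spatial_kernel",
    "temporal_kernel",
    "covariance_entry",
    "pivoted_cholesky",
    "build_kl",
    "sample_deformation",
    "deformed_points",
    "shape_std",
]


@dataclass(frozen=True)
class CovarianceModel:
    """Covariance of the deformation field (lengths mm, times ms).

    ``nu_components`` holds the Matern smoothness per displacement component;
    only 5/2 and infinity (the Gaussian limit) are supported.
    """

    rho: float = 50.0  #: spatial correlation length
    sigma2: float = 4.0 / 3.0  #: pointwise variance
    nu_components: tuple[float, float] = (2.5, np.inf)
    period: float = 690.0  #: heartbeat duration T

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.sigma2 <= 0 or self.period <= 0:
            raise ValueError("rho, sigma2 and period must be positive")
        for nu in self.nu_components:
            if nu != 2.5 and not np.isinf(nu):
                raise ValueError("only smoothness 5/2 and infinity are supported")


def spatial_kernel(d, nu: float, rho: float = 50.0, sigma2: float = 4.0 / 3.0):
    """Matern covariance of the spatial distance ``d`` (closed forms only)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if nu == 2.5:
        q = np.sqrt(5.0) * d / rho
        return sigma2 * (1.0 + q + q ** 2 / 3.0) * np.exp(-q)
    if np.isinf(nu):
        return sigma2 * np.exp(-d ** 2 / (2.0 * rho ** 2))
    raise ValueError("only smoothness 5/2 and infinity are supported")


def temporal_kernel(t, t_other, period: float = 690.0):
    """Sine-power kernel of the geodesic phase distance on the heartbeat circle.

    Times are mapped to phases ``eta = 2 pi t / T``; the kernel is
    ``(cos theta + 1) / 2`` with ``theta = arccos(cos(eta - eta'))``, hence
    1 at zero lag, 0 at half a period, and exactly T-periodic.
    """
    eta = 2.0 * np.pi * np.asarray(t, dtype=float) / period
    eta_other = 2.0 * np.pi * np.asarray(t_other, dtype=float) / period
    theta = np.arccos(np.clip(np.cos(eta - eta_other), -1.0, 1.0))
    return 0.5 * (np.cos(theta) + 1.0)


def covariance_entry(z, z_other, model: CovarianceModel = CovarianceModel()) -> np.ndarray:
    """2x2 covariance block between two space-time points ``(x, t)``.

    The components of the deformation are uncorrelated, so the block is
    diagonal: the temporal factor times the per-component spatial kernel of
    the Euclidean distance between the reference positions.
    """
    x, t = np.asarray(z[0], dtype=float), float(z[1])
    x2, t2 = np.asarray(z_other[0], dtype=float), float(z_other[1])
    d = float(np.linalg.norm(x - x2))
    kt = float(temporal_kernel(t, t2, model.period))
    return np.diag([kt * float(spatial_kernel(d, nu, model.rho, model.sigma2))
                    for nu in model.nu_components])


# ---------------------------------------------------------------------------
# pivoted Cholesky
# ---------------------------------------------------------------------------

def pivoted_cholesky(get_column: Callable[[int], np.ndarray], diag: np.ndarray,
                     tol: float, max_rank: int | None = None,
                     absolute: bool = False) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy low-rank factorisation ``C ~= L L^T`` of a PSD matrix.

    Columns of C are evaluated lazily through ``get_column``.  Stops when the
    trace residual drops below ``tol`` (relative to the initial trace unless
    ``absolute``).  Returns ``(L, pivot_values, relative_residual)``; the
    pivot value of a mode is the diagonal residual it removed, a natural
    importance ordering.
    """
    d = np.array(diag, dtype=float)
    n = d.size
    trace0 = d.sum()
    if trace0 <= 0:
        raise ValueError("covariance has non-positive trace")
    target = tol * (1.0 if absolute else trace0)
    max_rank = n if max_rank is None else min(max_rank, n)

    buf = np.empty((n, min(max_rank, 64)))
    pivot_values: list[float] = []
    k = 0
    while d.sum() > target and k < max_rank:
        p = int(np.argmax(d))
        dp = d[p]
        if dp <= 0:
            if dp < -1e-12 * trace0:
                raise np.linalg.LinAlgError(
                    f"covariance is numerically indefinite (pivot {dp:.3e})")
            break
        col = np.array(get_column(p), dtype=float)  # copy: updated in place
        if k:
            col -= buf[:, :k] @ buf[p, :k]
        if k == buf.shape[1]:  # grow by doubling
            buf = np.concatenate([buf, np.empty_like(buf)], axis=1)
        ell = buf[:, k]
        np.divide(col, np.sqrt(dp), out=ell)
        ell[p] = np.sqrt(dp)
        d -= ell ** 2
        d[p] = 0.0
        if d.min() < -1e-12 * trace0:
            raise np.linalg.LinAlgError(
                f"covariance is numerically indefinite (pivot {d.min():.3e})")
        np.maximum(d, 0.0, out=d)  # clip round-off negatives
        pivot_values.append(float(dp))
        k += 1
    return buf[:, :k].copy(), np.asarray(pivot_values), float(d.sum() / trace0)


# ---------------------------------------------------------------------------
# KL expansion on the space-time collocation points
# ---------------------------------------------------------------------------

class AdmissibilityError(RuntimeError):
    """A sampled deformation violates the geometric uniformity conditions."""


@dataclass(frozen=True)
class KLExpansion:
    """Mean positions and weighted modes at the space-time collocation points.

    ``positions`` has shape ``(n_t, n_sigma, 2)``; ``modes`` has shape
    ``(K, n_t, n_sigma, 2)`` where each mode is supported on a single
    displacement component.  ``pivot_values`` gives the importance ordering
    (descending) used to merge the two per-component factorisations.
    """

    positions: np.ndarray
    modes: np.ndarray
    pivot_values: np.ndarray
    trace_residual: float
    model: CovarianceModel
    geometry: SpaceTimeGeometry = field(repr=False)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def n_sigma(self) -> int:
        return self.positions.shape[1]

    def mode_sup_norms(self) -> np.ndarray:
        """Sup-norm of each weighted mode, the anisotropy driver for quadrature."""
        return np.abs(self.modes).reshape(self.n_modes, -1).max(axis=1)


def build_kl(geometry: SpaceTimeGeometry, model: CovarianceModel | None = None,
             tol: float = 1e-4, n_sigma: int = 500,
             max_rank: int | None = None, absolute_tol: bool = False) -> KLExpansion:
    """Low-rank KL expansion of the deformation field by pivoted Cholesky.

    The covariance of each displacement component is factorised separately
    (they are uncorrelated) on the ``n_t x n_sigma`` space-time collocation
    points, each to the requested trace tolerance; the mode lists are merged
    sorted by pivot magnitude.
    """
    model = model or CovarianceModel(period=geometry.period)
    if not 0 < tol < 1 and not absolute_tol:
        raise ValueError("relative tolerance must lie in (0, 1)")
    s = np.arange(n_sigma) / n_sigma
    positions = np.stack([c.point(s) for c in geometry.pericardium])  # (n_t, n_s, 2)
    n_t = positions.shape[0]
    flat = positions.reshape(-1, 2)  # time-major ordering of the dof
    # temporal factor on the distinct stored instants only
    kt = temporal_kernel(geometry.times[:, None], geometry.times[None, :],
                         model.period)
    t_of = np.repeat(np.arange(n_t), n_sigma)

    def make_column(nu: float) -> Callable[[int], np.ndarray]:
        def column(j: int) -> np.ndarray:
            d = np.linalg.norm(flat - flat[j], axis=1)
            return kt[t_of, t_of[j]] * spatial_kernel(d, nu, model.rho, model.sigma2)
        return column

    diag = np.full(flat.shape[0], model.sigma2)
    factors = []
    for nu in model.nu_components:
        L, pv, res = pivoted_cholesky(make_column(nu), diag, tol,
                                      max_rank=max_rank, absolute=absolute_tol)
        factors.append((L, pv, res))

    # merge the per-component mode lists by pivot magnitude
    entries = []
    for comp, (L, pv, _) in enumerate(factors):
        for k in range(L.shape[1]):
            entries.append((pv[k], comp, L[:, k]))
    entries.sort(key=lambda e: -e[0])

    K = len(entries)
    modes = np.zeros((K, n_t, n_sigma, 2))
    pivot_values = np.empty(K)
    for i, (pv, comp, vec) in enumerate(entries):
        modes[i, :, :, comp] = vec.reshape(n_t, n_sigma)
        pivot_values[i] = pv

    total_res = sum(f[2] for f in factors) / len(factors)  # equal traces
    return KLExpansion(positions=positions, modes=modes,
                       pivot_values=pivot_values, trace_residual=total_res,
                       model=model, geometry=geometry)


def deformed_points(kl: KLExpansion, xi: np.ndarray, t_index: int) -> np.ndarray:
    """Deformed collocation points at one instant, shape (n_sigma, 2)."""
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (kl.n_modes,):
        raise ValueError(f"xi must have shape ({kl.n_modes},)")
    if np.any(np.abs(xi) > 1.0 + 1e-12):
        raise ValueError("xi must lie in [-1, 1]^K")
    return kl.positions[t_index] + np.einsum("k,kid->id", xi, kl.modes[:, t_index])


def check_admissible(pts: np.ndarray, speeds: np.ndarray,
                     chest_polygon: Polygon, t_index: int) -> None:
    """Discrete surrogate of the uniformity condition on a deformed contour.

    Requires a non-degenerate parameterisation (minimal nodal speed above
    1e-3 of the mean), a simple polyline, and strict containment in the
    chest; violations raise :class:`AdmissibilityError` naming the instant.
    """
    if speeds.min() <= 1e-3 * speeds.mean():
        raise AdmissibilityError(f"degenerate parameterisation at instant {t_index}")
    if not LinearRing(pts).is_simple:
        raise AdmissibilityError(f"self-intersection at instant {t_index}")
    if not np.all(shapely.contains_xy(chest_polygon, pts[:, 0], pts[:, 1])):
        raise AdmissibilityError(
            f"deformed pericardium leaves the chest at instant {t_index}")


def sample_deformation(kl: KLExpansion, xi: np.ndarray, t_index: int,
                       check: bool = True) -> ClosedCurve:
    """Deformed pericardial contour at one stored instant.

    The curve is the balanced trigonometric interpolant of the deformed
    collocation points; :func:`check_admissible` guards the result unless
    ``check`` is disabled.
    """
    pts = deformed_points(kl, xi, t_index)
    curve = ClosedCurve.from_points(pts, role="pericardium")
    if check:
        n = kl.n_sigma
        check_admissible(pts, curve.speed(np.arange(n) / n),
                         Polygon(kl.geometry.chest.polyline()), t_index)
    return curve


def shape_std(kl: KLExpansion) -> np.ndarray:
    """Per-point, per-component displacement standard deviation.

    With xi uniform on [-1, 1] each coordinate has variance 1/3, so the
    closed form is ``sqrt(sum_k m_k^2 / 3)``; shape ``(n_t, n_sigma, 2)``.
    The conventional 95% shape band is mean +/- 1.96 times this field.
    """
    return np.sqrt(np.sum(kl.modes ** 2, axis=0) / 3.0)
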