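"""Collocation discretisation of the boundary integral operators.

The torso potential satisfies a Laplace problem on the 2D annular domain D
between the pericardium Sigma and the chest Gamma, with Dirichlet data on
Sigma and zero Neumann data on Gamma.  The direct boundary integral
formulation couples the single layer operator V (kernel
``G(x, x') = -log||x - x'|| / (2 pi)``) and the double layer operator K
(kernel ``dG/dn(x')``) on both boundary components.  All normals are exterior
to D: outward on the chest, towards the cardiac cavity on the pericardium.

Discretisation is by Nystrom collocation on equispaced parameter grids.
Blocks coupling distinct curves use the plain trapezoidal rule.  Same-curve
single layer blocks split the kernel into the periodic logarithm
``-log(4 sin^2(pi (s - s'))) / (4 pi)``, integrated with exact spectral
weights, plus a smooth remainder handled by the trapezoidal rule; the
same-curve double layer diagonal is the curvature limit of the kernel.  For
analytic curves the scheme converges exponentially in the grid size.

Matrices act on vectors of physical boundary values; the arc-length measure
``||gamma'(s_j)|| / n`` is folded into the quadrature weights, so e.g.
``V . 1`` equals ``-a log a`` on a circle of radius ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.linalg

from .geometry import ClosedCurve, Role

__all__ = [
    "CurveGrid",
    "BoundaryBlocks",
    "TransferOperators",
    "BVPSolution",
    "log_quadrature_weights",
    "assemble_blocks",
    "mass_matrix",
    "solve_bvp",
    "build_transfer",
]


@lru_cache(maxsize=32)
def log_quadrature_weights(n: int) -> np.ndarray:
    """Circulant weights integrating the periodic log kernel exactly.

    Returns ``w`` of length ``n`` such that for any trigonometric polynomial
    f of order <= n/2,

        int_0^1 log(4 sin^2(pi (s_i - sigma))) f(sigma) dsigma
            ~= sum_j w[(i - j) mod n] f(s_j),

    exactly in exact arithmetic.  Derived from the Fourier expansion
    ``log(4 sin^2(pi tau)) = -2 sum_k cos(2 pi k tau) / k``.
    """
    k = np.arange(n)
    freq = np.minimum(k, n - k)
    coeff = np.zeros(n)
    coeff[1:] = -1.0 / freq[1:]
    return np.fft.ifft(coeff).real


@lru_cache(maxsize=32)
def _circulant_index(n: int) -> np.ndarray:
    return (np.arange(n)[:, None] - np.arange(n)[None, :]) % n


@lru_cache(maxsize=32)
def _sin2_matrix(n: int) -> np.ndarray:
    """4 sin^2(pi (s_i - s_j)) on the equispaced grid, diagonal left at 0."""
    s = np.arange(n) / n
    return 4.0 * np.sin(np.pi * (s[:, None] - s[None, :])) ** 2


@dataclass(frozen=True)
class CurveGrid:
    """A closed curve sampled at the collocation nodes s_i = i/n.

    Holds everything the Nystrom assembly needs: points, first and second
    derivatives, speeds and exterior-to-D unit normals.  Built either from a
    :class:`~ecguq.geometry.ClosedCurve` or directly from deformed node
    positions via FFT spectral differentiation of their balanced
    trigonometric interpolant (the sampling hot path).
    """

    point: np.ndarray  # (n, 2)
    d1: np.ndarray
    d2: np.ndarray
    speed: np.ndarray  # (n,)
    normal: np.ndarray  # (n, 2), exterior to the torso domain

    @property
    def n(self) -> int:
        return self.point.shape[0]

    @classmethod
    def from_curve(cls, curve: ClosedCurve, n: int) -> "CurveGrid":
        p0, p1, p2 = curve.grid_eval(n)
        return cls._finalise(p0, p1, p2, curve.role)

    @classmethod
    def from_points(cls, points: np.ndarray, role: Role) -> "CurveGrid":
        points = np.asarray(points, dtype=float)
        n = points.shape[0]
        c = np.fft.fft(points, axis=0)
        k = np.fft.fftfreq(n, d=1.0 / n)
        k1 = k.copy()
        if n % 2 == 0:
            k1[n // 2] = 0.0  # the balanced Nyquist cosine has zero nodal slope
        d1 = np.fft.ifft(2j * np.pi * k1[:, None] * c, axis=0).real
        d2 = np.fft.ifft(-(2.0 * np.pi * k[:, None]) ** 2 * c, axis=0).real
        return cls._finalise(points, d1, d2, role)

    @classmethod
    def _finalise(cls, p0, p1, p2, role: Role) -> "CurveGrid":
        speed = np.sqrt(p1[:, 0] ** 2 + p1[:, 1] ** 2)
        normal = np.column_stack([p1[:, 1], -p1[:, 0]]) / speed[:, None]
        if role == "pericardium":
            normal = -normal
        return cls(p0, p1, p2, speed, normal)


@dataclass(frozen=True)
class BoundaryBlocks:
    """The eight dense operator blocks on the (Sigma, Gamma) grid pair."""

    V_ss: np.ndarray
    V_sg: np.ndarray
    V_gs: np.ndarray
    V_gg: np.ndarray
    K_ss: np.ndarray
    K_sg: np.ndarray
    K_gs: np.ndarray
    K_gg: np.ndarray
    speed_sigma: np.ndarray
    speed_gamma: np.ndarray
    n_sigma: int
    n_gamma: int


@dataclass(frozen=True)
class TransferOperators:
    """Discrete solution operator A, Steklov operator B and mass matrices."""

    A: np.ndarray  # (n_Gamma, n_Sigma): u on Sigma -> trace on Gamma
    B: np.ndarray  # (n_Sigma, n_Sigma): u on Sigma -> exterior normal derivative
    S_sigma: np.ndarray  # diagonal entries ||gamma'(s_i)|| / n
    S_gamma: np.ndarray
    speed_sigma: np.ndarray
    speed_gamma: np.ndarray


@dataclass(frozen=True)
class BVPSolution:
    """Traces of the forward solution: chest values and pericardial flux."""

    chest_trace: np.ndarray  # rho_{0,Gamma}
    flux_weighted: np.ndarray  # rho~_{1,Sigma} = rho_{1,Sigma} * speed
    flux: np.ndarray  # rho_{1,Sigma}, exterior-normal derivative values


def _cross_single(x: CurveGrid, y: CurveGrid) -> np.ndarray:
    diff = x.point[:, None, :] - y.point[None, :, :]
    r2 = diff[..., 0] ** 2 + diff[..., 1] ** 2
    return (-0.25 / np.pi) * np.log(r2) * (y.speed[None, :] / y.n)


def _cross_double(x: CurveGrid, y: CurveGrid) -> np.ndarray:
    diff = x.point[:, None, :] - y.point[None, :, :]
    r2 = diff[..., 0] ** 2 + diff[..., 1] ** 2
    num = diff[..., 0] * y.normal[None, :, 0] + diff[..., 1] * y.normal[None, :, 1]
    return num / (2.0 * np.pi * r2) * (y.speed[None, :] / y.n)


def _same_curve_single(g: CurveGrid) -> np.ndarray:
    """Single layer on one curve: log-splitting quadrature, spectral accuracy."""
    n = g.n
    diff = g.point[:, None, :] - g.point[None, :, :]
    r2 = diff[..., 0] ** 2 + diff[..., 1] ** 2
    sin2 = _sin2_matrix(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        smooth = (-0.25 / np.pi) * np.log(r2 / sin2)
    np.fill_diagonal(smooth, (-0.5 / np.pi) * np.log(g.speed / (2.0 * np.pi)))
    log_part = (-0.25 / np.pi) * log_quadrature_weights(n)[_circulant_index(n)]
    return (log_part + smooth / n) * g.speed[None, :]


def _same_curve_double(g: CurveGrid) -> np.ndarray:
    """Double layer on one curve; the diagonal is the curvature limit."""
    diff = g.point[:, None, :] - g.point[None, :, :]
    r2 = diff[..., 0] ** 2 + diff[..., 1] ** 2
    num = diff[..., 0] * g.normal[None, :, 0] + diff[..., 1] * g.normal[None, :, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = num / (2.0 * np.pi * r2)
    diag = (g.d2[:, 0] * g.normal[:, 0] + g.d2[:, 1] * g.normal[:, 1]) \
        / (4.0 * np.pi * g.speed ** 2)
    np.fill_diagonal(kernel, diag)
    return kernel * (g.speed[None, :] / g.n)


def assemble_blocks(curve_sigma: ClosedCurve | CurveGrid,
                    curve_gamma: ClosedCurve | CurveGrid,
                    n_sigma: int, n_gamma: int,
                    check_separation: bool = True,
                    gamma_self_blocks: tuple[np.ndarray, np.ndarray] | None = None,
                    ) -> BoundaryBlocks:
    """Assemble all Nystrom blocks for the (pericardium, chest) curve pair.

    ``gamma_self_blocks`` may carry precomputed ``(V_gg, K_gg)`` when the
    chest is fixed across many assemblies.
    """
    gs = curve_sigma if isinstance(curve_sigma, CurveGrid) \
        else CurveGrid.from_curve(curve_sigma, n_sigma)
    gg = curve_gamma if isinstance(curve_gamma, CurveGrid) \
        else CurveGrid.from_curve(curve_gamma, n_gamma)
    if gs.n != n_sigma or gg.n != n_gamma:
        raise ValueError("grid sizes disagree with the requested counts")

    if check_separation:
        diff = gs.point[:, None, :] - gg.point[None, :, :]
        d2 = diff[..., 0] ** 2 + diff[..., 1] ** 2
        if d2.min() < 1e-20:
            raise ValueError("pericardium and chest collocation points collide")

    V_ss = _same_curve_single(gs)
    K_ss = _same_curve_double(gs)
    if gamma_self_blocks is None:
        V_gg = _same_curve_single(gg)
        K_gg = _same_curve_double(gg)
    else:
        V_gg, K_gg = gamma_self_blocks

    return BoundaryBlocks(
        V_ss=V_ss, V_sg=_cross_single(gs, gg), V_gs=_cross_single(gg, gs),
        V_gg=V_gg, K_ss=K_ss, K_sg=_cross_double(gs, gg),
        K_gs=_cross_double(gg, gs), K_gg=K_gg,
        speed_sigma=gs.speed, speed_gamma=gg.speed,
        n_sigma=gs.n, n_gamma=gg.n)


def chest_self_blocks(curve_gamma: ClosedCurve | CurveGrid, n_gamma: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Precompute the chest-chest blocks (V_gg, K_gg) for repeated assembly."""
    gg = curve_gamma if isinstance(curve_gamma, CurveGrid) \
        else CurveGrid.from_curve(curve_gamma, n_gamma)
    return _same_curve_single(gg), _same_curve_double(gg)


def mass_matrix(curve: ClosedCurve, n: int) -> np.ndarray:
    """Diagonal trapezoidal mass matrix, entries ``||gamma'(s_i)|| / n``."""
    if n < 4:
        raise ValueError("need n >= 4")
    return np.diag(curve.speed(np.arange(n) / n) / n)


def _block_system(blocks: BoundaryBlocks) -> tuple[np.ndarray, np.ndarray]:
    """LHS matrix and RHS map (applied to u) of the 2x2 block system.

    Unknowns are stacked as [rho_{1,Sigma}; rho_{0,Gamma}] (physical values;
    the arc-length weights live inside the blocks).
    """
    ns, ng = blocks.n_sigma, blocks.n_gamma
    m = ns + ng
    lhs = np.empty((m, m))
    lhs[:ns, :ns] = blocks.V_ss
    lhs[:ns, ns:] = -blocks.K_sg
    lhs[ns:, :ns] = -blocks.V_gs
    lhs[ns:, ns:] = blocks.K_gg
    lhs[ns + np.arange(ng), ns + np.arange(ng)] += 0.5
    rhs = np.empty((m, ns))
    rhs[:ns] = blocks.K_ss
    rhs[np.arange(ns), np.arange(ns)] += 0.5
    rhs[ns:] = -blocks.K_gs
    return lhs, rhs


_COND_LIMIT = 1e14


def solve_bvp(blocks: BoundaryBlocks, u: np.ndarray) -> BVPSolution:
    """Solve the forward problem for pericardial Dirichlet data ``u``."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != blocks.n_sigma:
        raise ValueError("u must have length n_Sigma")
    lhs, rhs = _block_system(blocks)
    lu, piv = scipy.linalg.lu_factor(lhs, check_finite=False)
    absdiag = np.abs(np.diag(lu))
    if absdiag.max() > _COND_LIMIT * max(absdiag.min(), 1e-300):
        raise np.linalg.LinAlgError("block system is numerically singular")
    sol = scipy.linalg.lu_solve((lu, piv), rhs @ u, check_finite=False)
    flux = sol[: blocks.n_sigma]
    chest = sol[blocks.n_sigma:]
    return BVPSolution(chest_trace=chest, flux_weighted=flux * blocks.speed_sigma,
                       flux=flux)


def build_transfer(blocks: BoundaryBlocks, method: str = "block") -> TransferOperators:
    """Build the discrete solution operator A and Steklov operator B.

    ``method="block"`` solves the full block system for all unit vectors at
    once; ``method="schur"`` forms the Schur complement on the chest
    explicitly.  Both paths agree to round-off (the Schur path requires the
    pericardial single layer to be invertible, which fails on curves of unit
    logarithmic capacity; the block path has no such restriction).
    """
    ns, ng = blocks.n_sigma, blocks.n_gamma
    if method == "block":
        lhs, rhs = _block_system(blocks)
        sol = scipy.linalg.solve(lhs, rhs, check_finite=False)
        B = sol[:ns]
        A = sol[ns:]
    elif method == "schur":
        Vss_inv_Ksg = scipy.linalg.solve(blocks.V_ss, blocks.K_sg)
        Vss_inv_half_Kss = scipy.linalg.solve(blocks.V_ss, 0.5 * np.eye(ns) + blocks.K_ss)
        schur = 0.5 * np.eye(ng) + blocks.K_gg - blocks.V_gs @ Vss_inv_Ksg
        A = scipy.linalg.solve(schur, blocks.V_gs @ Vss_inv_half_Kss - blocks.K_gs)
        B = Vss_inv_half_Kss + Vss_inv_Ksg @ A
    else:
        raise ValueError(f"unknown method {method!r}")
    return TransferOperators(
        A=A, B=B,
        S_sigma=blocks.speed_sigma / ns,
        S_gamma=blocks.speed_gamma / ng,
        speed_sigma=blocks.speed_sigma,
        speed_gamma=blocks.speed_gamma,
    )
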