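"""Shape-uncertainty studies: parameter-to-field evaluators.

These tie the KL deformation model to the boundary-integral solvers: every
parameter point ``xi`` yields a deformed pericardium per time instant, the
forward (or regularised inverse) problem is solved on the deformed geometry,
and the resulting space-time field feeds the moment quadratures.  The
pericardial potential is attached to the material coordinate s, so its
collocation values are unchanged under deformation; the chest data of the
inverse problem are fixed once on the reference geometry.

The chest is fixed, so its grid data and self-interaction blocks are
assembled once and shared across all parameter points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .bem import CurveGrid, assemble_blocks, build_transfer, chest_self_blocks, solve_bvp
from .forward import PericardialPotential, PotentialParams, add_noise
from .inverse import RegularisationSpec, inverse_solve
from .shape_field import KLExpansion, check_admissible, deformed_points

__all__ = ["ForwardUQProblem", "InverseUQProblem", "MultiRegInverseProblem"]


@dataclass
class ForwardUQProblem:
    """Map xi -> chest potential field on the (possibly restricted) time grid.

    ``u_values[j]`` holds the pericardial potential at the collocation nodes
    for the j-th selected instant; the returned field has shape
    ``(n_gamma, n_times_selected)`` (squeezed to a vector for one instant).
    """

    kl: KLExpansion
    n_gamma: int
    potential: PericardialPotential = field(
        default_factory=lambda: PericardialPotential(PotentialParams()))
    time_indices: tuple[int, ...] | None = None
    admissibility_check: bool = True

    def __post_init__(self) -> None:
        geom = self.kl.geometry
        if self.time_indices is None:
            self.time_indices = tuple(range(geom.n_times))
        s = np.arange(self.kl.n_sigma) / self.kl.n_sigma
        self.u_values = np.stack(
            [self.potential(s, geom.times[j]) for j in self.time_indices])
        self._chest_grid = CurveGrid.from_curve(geom.chest, self.n_gamma)
        self._chest_blocks = chest_self_blocks(self._chest_grid, self.n_gamma)
        self._chest_polygon = Polygon(geom.chest.polyline())

    def _sigma_grid(self, xi: np.ndarray, t_index: int) -> CurveGrid:
        pts = deformed_points(self.kl, xi, t_index)
        grid = CurveGrid.from_points(pts, role="pericardium")
        if self.admissibility_check:
            check_admissible(pts, grid.speed, self._chest_polygon, t_index)
        return grid

    def _blocks(self, xi: np.ndarray, t_index: int):
        return assemble_blocks(self._sigma_grid(xi, t_index), self._chest_grid,
                               self.kl.n_sigma, self.n_gamma,
                               check_separation=False,
                               gamma_self_blocks=self._chest_blocks)

    def reference_field(self) -> np.ndarray:
        """Forward solution on the undeformed reference geometry."""
        return self(np.zeros(self.kl.n_modes))

    def __call__(self, xi: np.ndarray) -> np.ndarray:
        out = np.empty((self.n_gamma, len(self.time_indices)))
        for col, j in enumerate(self.time_indices):
            out[:, col] = solve_bvp(self._blocks(xi, j), self.u_values[col]).chest_trace
        return out[:, 0] if out.shape[1] == 1 else out


@dataclass
class InverseUQProblem:
    """Map xi -> regularised pericardial reconstruction from fixed chest data.

    The data ``yd`` are generated once: the forward problem on the reference
    geometry plus Gaussian noise of the configured variance.  Per parameter
    point, the transfer operators are rebuilt on the deformed geometry and
    the inverse problem is solved per selected instant.
    """

    kl: KLExpansion
    n_gamma: int
    spec: RegularisationSpec
    potential: PericardialPotential = field(
        default_factory=lambda: PericardialPotential(PotentialParams()))
    noise_variance: float = 1e-8
    noise_seed: int = 0
    time_indices: tuple[int, ...] | None = None
    admissibility_check: bool = True

    def __post_init__(self) -> None:
        self._forward = ForwardUQProblem(
            self.kl, self.n_gamma, self.potential, self.time_indices,
            self.admissibility_check)
        self.time_indices = self._forward.time_indices
        clean = np.atleast_2d(self._forward.reference_field().T).T
        self.yd = add_noise(clean, self.noise_variance, self.noise_seed).values
        self.u_values = self._forward.u_values

    def reference_field(self) -> np.ndarray:
        return self(np.zeros(self.kl.n_modes))

    def __call__(self, xi: np.ndarray) -> np.ndarray:
        out = np.empty((self.kl.n_sigma, len(self.time_indices)))
        for col, j in enumerate(self.time_indices):
            ops = build_transfer(self._forward._blocks(xi, j))
            out[:, col] = inverse_solve(ops, self.yd[:, col], self.spec)
        return out[:, 0] if out.shape[1] == 1 else out


@dataclass
class MultiRegInverseProblem:
    """Map xi -> reconstructions for several regularisations at once.

    Shares the per-node geometry assembly and transfer-operator build across
    regularisation kinds; the returned array stacks one reconstruction field
    per spec, shape ``(n_specs * n_sigma,)`` for a single instant (or
    ``(n_specs * n_sigma, n_times)``), so it slots directly into the moment
    accumulators.
    """

    kl: KLExpansion
    n_gamma: int
    specs: tuple[RegularisationSpec, ...]
    potential: PericardialPotential = field(
        default_factory=lambda: PericardialPotential(PotentialParams()))
    noise_variance: float = 1e-8
    noise_seed: int = 0
    time_indices: tuple[int, ...] | None = None
    admissibility_check: bool = True

    def __post_init__(self) -> None:
        self._forward = ForwardUQProblem(
            self.kl, self.n_gamma, self.potential, self.time_indices,
            self.admissibility_check)
        self.time_indices = self._forward.time_indices
        clean = np.atleast_2d(self._forward.reference_field().T).T
        self.yd = add_noise(clean, self.noise_variance, self.noise_seed).values
        self.u_values = self._forward.u_values

    def __call__(self, xi: np.ndarray) -> np.ndarray:
        ns = self.kl.n_sigma
        out = np.empty((len(self.specs) * ns, len(self.time_indices)))
        for col, j in enumerate(self.time_indices):
            ops = build_transfer(self._forward._blocks(xi, j))
            for r, spec in enumerate(self.specs):
                out[r * ns:(r + 1) * ns, col] = inverse_solve(
                    ops, self.yd[:, col], spec)
        return out[:, 0] if out.shape[1] == 1 else out

    def split(self, field: np.ndarray) -> dict[str, np.ndarray]:
        """Slice a stacked field back into one block per regularisation kind."""
        ns = self.kl.n_sigma
        return {spec.kind: field[r * ns:(r + 1) * ns]
                for r, spec in enumerate(self.specs)}
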