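"""Pericardial source potential, forward solves and noisy chest recordings.

The pericardial potential emulates a left bundle branch block: two activation
wavefronts leave the right-ventricular free wall (curvilinear coordinate
s = 0) and meet at the left-ventricular free wall (s = 0.5) after 150 ms, a
long-QRS propagation.  The transmembrane-like waveform at each point is a
difference of two logistic ramps (sharp depolarisation upstroke, slow
repolarisation) and is strictly T-periodic in time.  The potential is
attached to the material coordinate s, so it rides along with any deformation
of the pericardium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bem import BoundaryBlocks, solve_bvp
from .geometry import SpaceTimeGeometry

__all__ = [
    "PotentialParams",
    "PericardialPotential",
    "ChestRecording",
    "reference_potential",
    "forward_solve",
    "forward_movie",
    "add_noise",
]


@dataclass(frozen=True)
class PotentialParams:
    """Shape of the prescribed pericardial potential (times in ms)."""

    amplitude: float = 1.0
    propagation_time: float = 150.0  #: s=0 -> s=0.5 activation delay
    depolarisation_width: float = 5.0  #: logistic upstroke width
    apd: float = 250.0  #: action potential duration (plateau)
    repolarisation_width: float = 30.0  #: logistic downstroke width
    period: float = 690.0  #: heartbeat duration T


def _logistic(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def activation_time(s, params: PotentialParams = PotentialParams()) -> np.ndarray:
    """Arrival time tau(s) of the two symmetric wavefronts started at s=0."""
    frac = np.mod(np.asarray(s, dtype=float), 1.0)
    return 2.0 * params.propagation_time * np.minimum(frac, 1.0 - frac)


def reference_potential(s, t, params: PotentialParams = PotentialParams()) -> np.ndarray:
    """Evaluate u(s, t); broadcasting over ``s`` and ``t``.

    ``u(s, t) = A [sigma((t~ - tau)/w_d) - sigma((t~ - tau - APD)/w_r)]``
    with ``t~ = t mod T``, which makes u exactly T-periodic.
    """
    tau = activation_time(s, params)
    t_mod = np.mod(np.asarray(t, dtype=float), params.period)
    up = _logistic((t_mod - tau) / params.depolarisation_width)
    down = _logistic((t_mod - tau - params.apd) / params.repolarisation_width)
    return params.amplitude * (up - down)


@dataclass(frozen=True)
class PericardialPotential:
    """Callable wrapper u(s, t) around :func:`reference_potential`."""

    params: PotentialParams = PotentialParams()

    def __call__(self, s, t) -> np.ndarray:
        return reference_potential(s, t, self.params)

    def on_grid(self, n: int, times: np.ndarray) -> np.ndarray:
        """Sample u at collocation nodes i/n for each time; shape (n, n_t)."""
        s = np.arange(n) / n
        return np.column_stack([self(s, t) for t in np.atleast_1d(times)])


def forward_solve(blocks: BoundaryBlocks, u: np.ndarray) -> np.ndarray:
    """Chest trace A u for one geometry snapshot (unit torso conductivity)."""
    return solve_bvp(blocks, u).chest_trace


def forward_movie(geometry: SpaceTimeGeometry, potential: PericardialPotential,
                  n_sigma: int, n_gamma: int) -> np.ndarray:
    """Chest traces on the stored time grid; shape (n_Gamma, n_t)."""
    from .bem import assemble_blocks

    out = np.empty((n_gamma, geometry.n_times))
    s = np.arange(n_sigma) / n_sigma
    for j, (curve, t) in enumerate(zip(geometry.pericardium, geometry.times)):
        blocks = assemble_blocks(curve, geometry.chest, n_sigma, n_gamma)
        out[:, j] = forward_solve(blocks, potential(s, t))
    return out


@dataclass(frozen=True)
class ChestRecording:
    """Noisy chest data y_d over (s_i, t_j) plus its noise metadata."""

    values: np.ndarray  # (n_Gamma, n_t)
    noise_variance: float
    seed: int
    snr_db: float


def add_noise(y: np.ndarray, variance: float, seed: int = 0) -> ChestRecording:
    """Add iid zero-mean Gaussian noise of the given variance to ``y``.

    The reported SNR is the power ratio ``10 log10(mean(y^2) / variance)``
    over all space-time samples (infinite for zero variance).
    """
    y = np.asarray(y, dtype=float)
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0.0:
        return ChestRecording(y.copy(), 0.0, seed, np.inf)
    rng = np.random.default_rng(seed)
    noisy = y + rng.normal(0.0, np.sqrt(variance), size=y.shape)
    snr = 10.0 * np.log10(np.mean(y ** 2) / variance)
    return ChestRecording(noisy, variance, seed, snr)
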