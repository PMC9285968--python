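"""Shared fixtures: analytic annulus oracles and small synthetic geometries."""

import numpy as np
import pytest

from ecguq.bem import assemble_blocks, build_transfer
from ecguq.geometry import ClosedCurve, SpaceTimeGeometry, synthesize_torso


@pytest.fixture(scope="session")
def annulus_blocks():
    """Concentric circles a=1 (pericardium), b=2 (chest) at n=128.

    Separation of variables gives closed forms for every operator: the
    cos(2*pi*m*s) mode maps to chest amplitude 2 a^m b^m / (a^2m + b^2m).
    """
    sigma = ClosedCurve.circle(1.0, role="pericardium")
    gamma = ClosedCurve.circle(2.0, role="chest")
    return assemble_blocks(sigma, gamma, 128, 128)


@pytest.fixture(scope="session")
def annulus_ops(annulus_blocks):
    return build_transfer(annulus_blocks)


@pytest.fixture(scope="session")
def torso():
    """Default synthetic space-time torso (50 instants, T = 690 ms)."""
    return synthesize_torso()


@pytest.fixture(scope="session")
def torso_single_instant(torso):
    """One mid-depolarisation instant of the default torso (t ~ 193 ms)."""
    j = int(np.argmin(np.abs(torso.times - 189.0)))
    return SpaceTimeGeometry(torso.chest, (torso.pericardium[j],),
                             [torso.times[j]], torso.period)


@pytest.fixture(scope="session")
def small_kl(torso_single_instant):
    """Single-instant KL expansion at modest resolution (n = 64)."""
    from ecguq.shape_field import build_kl

    return build_kl(torso_single_instant, tol=1e-4, n_sigma=64)
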