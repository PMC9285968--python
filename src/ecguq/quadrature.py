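"""Quadrature on the parameter cube [-1, 1]^K and moment estimation.

Moments of the potential under shape uncertainty are integrals against the
uniform product density ``2^{-K}`` on the cube.  Two families of rules are
provided:

* an anisotropic sparse (Smolyak combination) quadrature built from nested
  differences of one-dimensional Gauss-Legendre rules of size ``m(l) = l + 1``
  over the total-degree index set ``{k : sum_j alpha_j k_j <= L}``, with the
  per-dimension weights ``alpha_j`` driven by the decay of the KL modes;
* the unscrambled Halton sequence (radical inverses in the first K primes,
  starting at index 1) mapped to the cube with equal weights.

All weights include the uniform density, so every rule integrates the
constant 1 to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import qmc

__all__ = [
    "QuadratureRule",
    "MomentField",
    "sparse_rule",
    "halton_rule",
    "anisotropy_weights",
    "estimate_moments",
    "convergence_study",
    "MemoizedEvaluator",
    "sparse_index_set",
]


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes in [-1, 1]^K with weights summing to one."""

    nodes: np.ndarray  # (N, K)
    weights: np.ndarray  # (N,)
    provenance: str = ""

    def __post_init__(self) -> None:
        nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape[0] != weights.size:
            raise ValueError("node/weight count mismatch")
        if np.any(np.abs(nodes) > 1.0 + 1e-12):
            raise ValueError("nodes must lie in the closed cube [-1, 1]^K")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError(f"weights sum to {weights.sum()!r}, expected 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def size(self) -> int:
        return self.weights.size


# ---------------------------------------------------------------------------
# anisotropic sparse Gauss-Legendre (combination technique)
# ---------------------------------------------------------------------------

def _gl_probability_rule(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre rule normalised against the density 1/2 on [-1, 1]."""
    x, w = leggauss(size)
    return x, w / 2.0


def _difference_rule(level: int) -> tuple[np.ndarray, np.ndarray]:
    """1-D difference rule Delta_l = Q_{m(l)} - Q_{m(l-1)}, m(l) = l + 1."""
    x1, w1 = _gl_probability_rule(level + 1)
    if level == 0:
        return x1, w1
    x0, w0 = _gl_probability_rule(level)
    return np.concatenate([x1, x0]), np.concatenate([w1, -w0])


class _NodeBudgetExceeded(Exception):
    def __init__(self, count: int):
        self.count = count


def sparse_index_set(alpha: np.ndarray, level: float,
                     node_budget: int | None = None) -> list[tuple[int, ...]]:
    """Multi-indices k >= 0 with ``sum_j alpha_j k_j <= level`` (sparse storage).

    Each index is returned as a tuple of (dimension, level) pairs for its
    non-zero entries.  Dimensions are processed in order of increasing alpha,
    which keeps the recursion shallow.  If ``node_budget`` is given, the
    enumeration aborts as soon as the predicted tensor-node count (the sum of
    ``prod_j (2 k_j + 1)`` over the set) exceeds it, so oversized requests
    fail fast instead of exhausting memory.
    """
    order = np.argsort(alpha, kind="stable")
    out: list[tuple[int, ...]] = []
    nodes_so_far = 0

    def recurse(pos: int, budget: float, current: list[tuple[int, int]],
                node_count: int) -> None:
        nonlocal nodes_so_far
        out.append(tuple(current))
        nodes_so_far += node_count
        if node_budget is not None and nodes_so_far > node_budget:
            raise _NodeBudgetExceeded(nodes_so_far)
        for idx in range(pos, order.size):
            dim = int(order[idx])
            a = alpha[dim]
            if a > budget + 1e-12:
                break  # alphas are sorted: no later dimension fits either
            k = 1
            while k * a <= budget + 1e-12:
                current.append((dim, k))
                recurse(idx + 1, budget - k * a, current, node_count * (2 * k + 1))
                current.pop()
                k += 1

    recurse(0, float(level), [], 1)
    return out


def sparse_rule(n_dims: int, level: float,
                alpha: Sequence[float] | None = None,
                node_budget: int = 2_000_000) -> QuadratureRule:
    """Anisotropic sparse Gauss-Legendre rule on [-1, 1]^n_dims.

    ``alpha`` are the per-dimension anisotropy weights (>= 1 after scaling
    the smallest to 1); ``None`` gives the isotropic rule.  Raises if the
    predicted tensor-node count exceeds ``node_budget``.
    """
    if alpha is None:
        alpha = np.ones(n_dims)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size != n_dims:
        raise ValueError("alpha must have one weight per dimension")
    if np.any(alpha <= 0):
        raise ValueError("anisotropy weights must be positive")
    alpha = alpha / alpha.min()  # smallest weight scaled to 1

    try:
        indices = sparse_index_set(alpha, level, node_budget=node_budget)
    except _NodeBudgetExceeded as exc:
        raise ValueError(
            f"sparse rule would tensorise more than {exc.count} nodes, over "
            f"the budget of {node_budget}") from None

    acc: dict[tuple[tuple[int, float], ...], float] = {}
    for idx in indices:
        if not idx:
            key: tuple[tuple[int, float], ...] = ()
            acc[key] = acc.get(key, 0.0) + 1.0
            continue
        dims = [dim for dim, _ in idx]
        pieces = [_difference_rule(k) for _, k in idx]
        grids = np.meshgrid(*[p[0] for p in pieces], indexing="ij")
        wgrids = np.meshgrid(*[p[1] for p in pieces], indexing="ij")
        coords = np.stack([g.ravel() for g in grids], axis=1)
        wprod = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
        for coord, w in zip(coords, wprod):
            key = tuple((dim, round(float(c), 14)) for dim, c in zip(dims, coord)
                        if round(float(c), 14) != 0.0)
            acc[key] = acc.get(key, 0.0) + float(w)

    # drop nodes whose difference-rule contributions cancelled exactly
    cutoff = 1e-14 * max(abs(w) for w in acc.values())
    keys = sorted(k for k, w in acc.items() if abs(w) > cutoff)
    nodes = np.zeros((len(keys), n_dims))
    weights = np.empty(len(keys))
    for i, key in enumerate(keys):
        for dim, c in key:
            nodes[i, dim] = c
        weights[i] = acc[key]
    return QuadratureRule(nodes, weights,
                          provenance=f"sparse(level={level}, K={n_dims})")


def anisotropy_weights(mode_sup_norms: np.ndarray) -> np.ndarray:
    """Decay-adaptive anisotropy weights from the KL mode magnitudes.

    ``alpha_j = max(1, log2(r_max / r_j))`` with ``r_j`` the sup-norm of the
    j-th weighted mode: slowly decaying (important) modes get weight 1, fast
    decaying ones are visited only at high levels.
    """
    r = np.asarray(mode_sup_norms, dtype=float)
    if np.any(r <= 0):
        raise ValueError("mode magnitudes must be positive")
    return np.maximum(1.0, np.log2(r.max() / r))


# ---------------------------------------------------------------------------
# Halton quasi-Monte Carlo
# ---------------------------------------------------------------------------

def halton_rule(n_dims: int, n_points: int, scramble: bool = False,
                seed: int | None = None) -> QuadratureRule:
    """First ``n_points`` Halton points on [-1, 1]^n_dims, weights 1/N.

    The unscrambled sequence starts at index 1 (radical inverses 1/2, 1/3,
    ... in the first ``n_dims`` primes) for bit-reproducibility; optional
    Owen scrambling is available behind a seed.
    """
    if n_points < 1:
        raise ValueError("need at least one point")
    engine = qmc.Halton(d=n_dims, scramble=scramble, seed=seed)
    if not scramble:
        engine.fast_forward(1)  # skip the all-zeros index-0 point
    pts = 2.0 * engine.random(n_points) - 1.0
    return QuadratureRule(pts, np.full(n_points, 1.0 / n_points),
                          provenance=f"halton(N={n_points}, K={n_dims})")


# ---------------------------------------------------------------------------
# moment estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MomentField:
    """First two moments, variance and std of a field over its grid."""

    m1: np.ndarray
    m2: np.ndarray
    provenance: str = ""

    @property
    def variance(self) -> np.ndarray:
        return np.maximum(self.m2 - self.m1 ** 2, 0.0)

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(self.variance)


class MemoizedEvaluator:
    """Cache field evaluations keyed by the parameter point.

    Nested sparse rules and growing QMC prefixes revisit nodes; caching makes
    convergence studies pay for each distinct geometry solve once.
    """

    def __init__(self, func: Callable[[np.ndarray], np.ndarray]):
        self._func = func
        self._cache: dict[bytes, np.ndarray] = {}
        self.calls = 0

    def __call__(self, xi: np.ndarray) -> np.ndarray:
        key = np.round(np.asarray(xi, dtype=float), 14).tobytes()
        hit = self._cache.get(key)
        if hit is None:
            self.calls += 1
            hit = np.asarray(self._func(xi), dtype=float)
            self._cache[key] = hit
        return hit


def estimate_moments(rule: QuadratureRule,
                     evaluator: Callable[[np.ndarray], np.ndarray],
                     progress: Callable[[int, int], None] | None = None
                     ) -> MomentField:
    """Accumulate the first two moments of ``evaluator(xi)`` under ``rule``.

    The evaluator must be deterministic per node; an inadmissible node is a
    hard error (silently skipping nodes would bias the moments).
    """
    m1 = m2 = None
    n = rule.size
    for i in range(n):
        try:
            y = np.asarray(evaluator(rule.nodes[i]), dtype=float)
        except Exception as exc:
            raise RuntimeError(
                f"evaluator failed at quadrature node {i}: {exc}") from exc
        w = rule.weights[i]
        if m1 is None:
            m1 = w * y
            m2 = w * y ** 2
        else:
            m1 += w * y
            m2 += w * y ** 2
        if progress is not None:
            progress(i + 1, n)
    return MomentField(m1, m2, provenance=rule.provenance)


def _rel_sup_error(m: np.ndarray, ref: np.ndarray) -> float:
    return float(np.abs(m - ref).max() / np.abs(ref).max())


def convergence_study(rules: Sequence[QuadratureRule],
                      evaluator: Callable[[np.ndarray], np.ndarray],
                      reference: MomentField) -> dict:
    """Error table and fitted convergence rate against a reference.

    Per rule the relative sup-norm errors of the first and second moment are
    recorded; the rate is the negative least-squares slope of log10(error)
    versus log10(N), fitted per moment, and ``rate`` is their mean.
    """
    if len(rules) < 3:
        raise ValueError("need at least 3 rule sizes for a rate fit")
    sizes, err1, err2 = [], [], []
    for rule in rules:
        mom = estimate_moments(rule, evaluator)
        sizes.append(rule.size)
        err1.append(_rel_sup_error(mom.m1, reference.m1))
        err2.append(_rel_sup_error(mom.m2, reference.m2))
    log_n = np.log10(sizes)
    rates = []
    for err in (err1, err2):
        slope = np.polyfit(log_n, np.log10(np.maximum(err, 1e-300)), 1)[0]
        rates.append(-slope)
    return {
        "N": sizes,
        "error_M1": err1,
        "error_M2": err2,
        "rate_M1": rates[0],
        "rate_M2": rates[1],
        "rate": float(np.mean(rates)),
    }
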