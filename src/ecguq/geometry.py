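"""Smooth closed boundary curves and the space-time reference torso geometry.

Curves are stored as truncated trigonometric polynomials

    gamma(s) = sum_k a_k cos(2*pi*k*s) + b_k sin(2*pi*k*s),   s in [0, 1),

one coefficient pair per spatial component, so that gamma is 1-periodic by
construction and the collocation method applied on top of it converges
spectrally.  All lengths are in millimetres.

The torso cross-section is a fixed chest contour ``Gamma`` enclosing a
heartbeat-periodic family of pericardial contours ``Sigma(t)``.  Since no
anatomical dataset ships with the package, :func:`synthesize_torso` emulates a
CMR-derived mid-ventricular cross section: a smooth oval chest at torso scale
and a pulsating pericardium whose area is maximal at diastole (t = 0) and
minimal at systole.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import LinearRing, Point, Polygon

__all__ = [
    "ClosedCurve",
    "SpaceTimeGeometry",
    "CollocationGrid",
    "TorsoParams",
    "fit_fourier_curve",
    "synthesize_torso",
    "pericardium_at_time",
    "trig_interp_coefficients",
]

Role = Literal["chest", "pericardium"]

#: number of points of the fine polyline used for validity checks
_CHECK_RESOLUTION = 720


def trig_interp_coefficients(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Balanced trigonometric interpolation coefficients from uniform samples.

    Given ``f_j = f(j/n)``, returns ``(a, b)`` with ``a[k]``/``b[k]`` the
    cosine/sine coefficients of the unique balanced interpolant of order
    ``n//2`` (the Nyquist mode, if present, is assigned to the cosine).
    ``samples`` may be 1-D or of shape ``(n, m)`` (coefficients per column).
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    c = np.fft.rfft(samples, axis=0) / n
    m = c.shape[0]
    a = np.empty_like(c, dtype=float)
    b = np.empty_like(c, dtype=float)
    a[0] = c[0].real
    b[0] = 0.0
    if m > 1:
        a[1:] = 2.0 * c[1:].real
        b[1:] = -2.0 * c[1:].imag
    if n % 2 == 0 and m == n // 2 + 1:
        a[-1] = c[-1].real  # balanced Nyquist term
        b[-1] = 0.0
    return a, b


@dataclass(frozen=True)
class ClosedCurve:
    """A smooth closed planar curve as a truncated trigonometric polynomial.

    Parameters
    ----------
    cos_coef, sin_coef:
        Arrays of shape ``(M + 1, 2)``; row ``k`` holds the order-``k``
        cosine/sine coefficients of the two spatial components (mm).
    role:
        ``"chest"`` or ``"pericardium"``; fixes which side of the curve the
        exterior normal of the torso domain lies on (outward for the chest,
        towards the cardiac cavity for the pericardium).
    """

    cos_coef: np.ndarray
    sin_coef: np.ndarray
    role: Role = "pericardium"
    unit: str = "mm"

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.cos_coef, dtype=float))
        b = np.atleast_2d(np.asarray(self.sin_coef, dtype=float))
        if a.shape != b.shape or a.shape[1] != 2:
            raise ValueError("coefficient arrays must both have shape (M+1, 2)")
        object.__setattr__(self, "cos_coef", a)
        object.__setattr__(self, "sin_coef", b)

    # -- constructors ------------------------------------------------------

    @classmethod
    def circle(cls, radius: float, center: Sequence[float] = (0.0, 0.0),
               role: Role = "pericardium") -> "ClosedCurve":
        a = np.array([[center[0], center[1]], [radius, 0.0]])
        b = np.array([[0.0, 0.0], [0.0, radius]])
        return cls(a, b, role=role)

    @classmethod
    def ellipse(cls, semi_axes: Sequence[float], center: Sequence[float] = (0.0, 0.0),
                angle: float = 0.0, role: Role = "chest") -> "ClosedCurve":
        ca, sa = np.cos(angle), np.sin(angle)
        a = np.array([[center[0], center[1]],
                      [semi_axes[0] * ca, semi_axes[0] * sa]])
        b = np.array([[0.0, 0.0], [-semi_axes[1] * sa, semi_axes[1] * ca]])
        return cls(a, b, role=role)

    @classmethod
    def from_points(cls, points: np.ndarray, role: Role = "pericardium") -> "ClosedCurve":
        """Balanced trigonometric interpolant of uniformly parameterised points."""
        a, b = trig_interp_coefficients(np.asarray(points, dtype=float))
        return cls(a, b, role=role)

    # -- basic properties --------------------------------------------------

    @property
    def order(self) -> int:
        return self.cos_coef.shape[0] - 1

    def _modes(self, s: np.ndarray, derivative: int = 0) -> np.ndarray:
        """Evaluate the curve or an s-derivative at parameters ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        k = np.arange(self.order + 1)
        phase = 2.0 * np.pi * np.outer(s, k)
        w = (2.0 * np.pi * k) ** derivative
        cos_t, sin_t = np.cos(phase), np.sin(phase)
        if derivative % 4 == 0:
            ca, cb = cos_t, sin_t
        elif derivative % 4 == 1:
            ca, cb = -sin_t, cos_t
        elif derivative % 4 == 2:
            ca, cb = -cos_t, -sin_t
        else:
            ca, cb = sin_t, -cos_t
        return (ca * w) @ self.cos_coef + (cb * w) @ self.sin_coef

    def grid_eval(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Point, first and second derivative at the n collocation nodes.

        Shares the phase matrices across the three derivative orders, which
        matters in the sampling hot path of the uncertainty studies.
        """
        s = np.arange(n) / n
        k = np.arange(self.order + 1)
        phase = 2.0 * np.pi * np.outer(s, k)
        cos_t, sin_t = np.cos(phase), np.sin(phase)
        w1 = 2.0 * np.pi * k
        w2 = w1 ** 2
        p0 = cos_t @ self.cos_coef + sin_t @ self.sin_coef
        p1 = (-sin_t * w1) @ self.cos_coef + (cos_t * w1) @ self.sin_coef
        p2 = (-cos_t * w2) @ self.cos_coef + (-sin_t * w2) @ self.sin_coef
        return p0, p1, p2

    def point(self, s) -> np.ndarray:
        return self._modes(s, 0)

    def derivative(self, s, order: int = 1) -> np.ndarray:
        return self._modes(s, order)

    def speed(self, s) -> np.ndarray:
        return np.linalg.norm(self._modes(s, 1), axis=-1)

    def tangent(self, s) -> np.ndarray:
        d = self._modes(s, 1)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def normal(self, s) -> np.ndarray:
        """Unit normal, exterior to the torso domain D.

        For a counterclockwise curve the clockwise rotation of the tangent
        points outward; the pericardium role flips the sign so the normal
        points into the cardiac cavity (still exterior to D).
        """
        t = self.tangent(s)
        n = np.stack([t[..., 1], -t[..., 0]], axis=-1)
        return -n if self.role == "pericardium" else n

    def curvature(self, s) -> np.ndarray:
        """Signed curvature kappa = (x'y'' - y'x'') / |gamma'|^3."""
        d1 = self._modes(s, 1)
        d2 = self._modes(s, 2)
        num = d1[..., 0] * d2[..., 1] - d1[..., 1] * d2[..., 0]
        return num / np.linalg.norm(d1, axis=-1) ** 3

    def evaluate(self, s) -> dict[str, np.ndarray]:
        """Point, tangent, exterior normal, speed and curvature at ``s``."""
        return {
            "point": self.point(s),
            "tangent": self.tangent(s),
            "normal": self.normal(s),
            "speed": self.speed(s),
            "curvature": self.curvature(s),
        }

    # -- geometric predicates ---------------------------------------------

    def polyline(self, n: int = _CHECK_RESOLUTION) -> np.ndarray:
        return self.point(np.arange(n) / n)

    def signed_area(self, n: int = _CHECK_RESOLUTION) -> float:
        p = self.polyline(n)
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def is_counterclockwise(self) -> bool:
        return self.signed_area() > 0

    def is_simple(self, n: int = _CHECK_RESOLUTION) -> bool:
        return bool(LinearRing(self.polyline(n)).is_simple)

    def min_speed(self, n: int = _CHECK_RESOLUTION) -> float:
        return float(self.speed(np.arange(n) / n).min())

    def length(self, n: int = 4096) -> float:
        """Curve length by the trapezoidal rule (spectrally accurate)."""
        return float(self.speed(np.arange(n) / n).mean())

    def validate(self) -> None:
        if self.min_speed() <= 0.0:
            raise ValueError("degenerate parameterisation: vanishing speed")
        if not self.is_simple():
            raise ValueError("curve is not simple (self-intersection detected)")

    def with_role(self, role: Role) -> "ClosedCurve":
        return replace(self, role=role)

    # -- persistence -------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("component,k,cos,sin\n")
            for ci, comp in enumerate("xy"):
                for k in range(self.order + 1):
                    fh.write(f"{comp},{k},{self.cos_coef[k, ci]:.17g},{self.sin_coef[k, ci]:.17g}\n")

    @classmethod
    def from_csv(cls, path: str | Path, role: Role = "pericardium") -> "ClosedCurve":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        expected = {"component", "k", "cos", "sin"}
        if not expected.issubset(df.columns):
            raise ValueError(f"curve file {path}: expected columns {sorted(expected)}")
        order = int(df["k"].max())
        a = np.zeros((order + 1, 2))
        b = np.zeros((order + 1, 2))
        for ci, comp in enumerate("xy"):
            sub = df[df["component"] == comp].sort_values("k")
            a[sub["k"].to_numpy(), ci] = sub["cos"].to_numpy()
            b[sub["k"].to_numpy(), ci] = sub["sin"].to_numpy()
        return cls(a, b, role=role)


@dataclass(frozen=True)
class CollocationGrid:
    """Equispaced collocation nodes s_i = i/n on [0, 1)."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("need at least 4 collocation points")

    @property
    def nodes(self) -> np.ndarray:
        return np.arange(self.n) / self.n


@dataclass(frozen=True)
class SpaceTimeGeometry:
    """Fixed chest contour plus one pericardial contour per stored instant."""

    chest: ClosedCurve
    pericardium: tuple[ClosedCurve, ...]
    times: np.ndarray  # ms, strictly increasing in [0, T)
    period: float  # ms

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pericardium", tuple(self.pericardium))
        if len(self.pericardium) != t.size:
            raise ValueError("one pericardium curve per stored time required")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= self.period):
            raise ValueError("times must satisfy 0 <= t_0 < ... < t_last < T")

    @property
    def n_times(self) -> int:
        return len(self.pericardium)

    def clearance(self) -> float:
        """Minimal distance between any pericardial contour and the chest."""
        chest = LinearRing(self.chest.polyline())
        return min(chest.distance(LinearRing(c.polyline())) for c in self.pericardium)

    def hold_all_box(self) -> np.ndarray:
        """Axis-aligned bounding box [[xmin, ymin], [xmax, ymax]] of the tube."""
        pts = np.vstack([self.chest.polyline()] + [c.polyline() for c in self.pericardium])
        return np.array([pts.min(axis=0), pts.max(axis=0)])

    def validate(self, min_clearance: float = 1e-9) -> None:
        self.chest.validate()
        chest_poly = Polygon(self.chest.polyline())
        chest_ring = LinearRing(self.chest.polyline())
        for curve, t in zip(self.pericardium, self.times):
            curve.validate()
            poly = curve.polyline()
            if not all(chest_poly.contains(Point(*p)) for p in poly[:: max(1, len(poly) // 64)]):
                raise ValueError(f"pericardium at t={t} ms not inside the chest")
            if chest_ring.distance(LinearRing(poly)) <= min_clearance:
                raise ValueError(f"pericardium at t={t} ms touches the chest")

    # -- persistence -------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.chest.to_csv(outdir / "chest.csv")
        entries = []
        for j, (curve, t) in enumerate(zip(self.pericardium, self.times)):
            name = f"pericardium_{j:03d}.csv"
            curve.to_csv(outdir / name)
            entries.append({"file": name, "time_ms": float(t)})
        manifest = {
            "chest": "chest.csv",
            "pericardium": entries,
            "period_ms": float(self.period),
            "unit": "mm",
        }
        (outdir / "geometry.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, indir: str | Path) -> "SpaceTimeGeometry":
        indir = Path(indir)
        manifest = json.loads((indir / "geometry.json").read_text())
        chest = ClosedCurve.from_csv(indir / manifest["chest"], role="chest")
        curves, times = [], []
        for entry in manifest["pericardium"]:
            curves.append(ClosedCurve.from_csv(indir / entry["file"], role="pericardium"))
            times.append(entry["time_ms"])
        return cls(chest, tuple(curves), np.asarray(times), manifest["period_ms"])


# ---------------------------------------------------------------------------
# Fourier contour fitting
# ---------------------------------------------------------------------------

def fit_fourier_curve(points: np.ndarray, threshold: float = 1e-3,
                      role: Role = "pericardium") -> ClosedCurve:
    """Least-squares truncated Fourier fit of an ordered closed contour.

    The truncation order is the smallest ``M`` whose least-squares
    trigonometric fit (uniform parameterisation ``s_j = j/n``) achieves a
    relative root-mean-square error at most ``threshold``; the relative error
    normalises by the RMS distance of the points from their centroid.  The
    input polygon must be simple; its orientation is normalised
    counterclockwise before fitting.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
        raise ValueError("need at least 8 ordered planar points")
    if not LinearRing(pts).is_simple:
        raise ValueError("input polygon is not simple")
    # counterclockwise normalisation (shoelace)
    x, y = pts[:, 0], pts[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        pts = pts[::-1]

    n = pts.shape[0]
    s = np.arange(n) / n
    centroid = pts.mean(axis=0)
    scale = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    if scale == 0.0:
        raise ValueError("degenerate contour: all points coincide")

    max_order = n // 2 - 1
    achieved = np.inf
    for order in range(max_order + 1):
        k = np.arange(order + 1)
        phase = 2.0 * np.pi * np.outer(s, k)
        design = np.hstack([np.cos(phase), np.sin(phase[:, 1:])]) if order else np.cos(phase)
        coef, *_ = np.linalg.lstsq(design, pts, rcond=None)
        resid = pts - design @ coef
        achieved = np.sqrt(np.mean(np.sum(resid ** 2, axis=1))) / scale
        if achieved <= threshold:
            a = coef[: order + 1]
            b = np.zeros_like(a)
            if order:
                b[1:] = coef[order + 1:]
            curve = ClosedCurve(a, b, role=role)
            curve.validate()
            return curve
    raise ValueError(
        f"threshold {threshold:g} unreachable at maximal order {max_order}; "
        f"achieved relative RMSE {achieved:.3e}"
    )


# ---------------------------------------------------------------------------
# Synthetic torso generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsoParams:
    """Parameters of the emulated torso cross-section.

    The defaults reproduce the study conditions: a heartbeat of T = 690 ms
    sampled at 50 instants with systole at 270 ms, a fixed chest oval of
    180 x 120 mm semi-axes and a pericardium of 45 mm mean radius whose area
    pulsates with the heartbeat.
    """

    period: float = 690.0  # ms (RR interval)
    n_times: int = 50
    t_systole: float = 270.0  # ms
    chest_semi_axes: tuple[float, float] = (180.0, 120.0)  # mm
    chest_perturbation: float = 0.02  # relative amplitude of low-order wobble
    pericardium_center: tuple[float, float] = (-40.0, 15.0)  # mm
    pericardium_radius: float = 45.0  # mm, time-mean
    pericardium_shape_amplitude: float = 0.06  # relative radial harmonics
    pulsation_amplitude: float = 0.08  # relative radius modulation over the beat
    seed: int = 0


def _pulsation_profile(params: TorsoParams) -> np.ndarray:
    """Two-harmonic T-periodic profile f with f(0)=1 (max), f(t_sys)=-1 (min)."""
    eta_s = 2.0 * np.pi * params.t_systole / params.period
    system = np.array([
        [1.0, 0.0, 1.0, 0.0],
        [0.0, 1.0, 0.0, 2.0],
        [np.cos(eta_s), np.sin(eta_s), np.cos(2 * eta_s), np.sin(2 * eta_s)],
        [-np.sin(eta_s), np.cos(eta_s), -2 * np.sin(2 * eta_s), 2 * np.cos(2 * eta_s)],
    ])
    return np.linalg.solve(system, np.array([1.0, 0.0, -1.0, 0.0]))


def synthesize_torso(params: TorsoParams | None = None) -> SpaceTimeGeometry:
    """Generate the emulated space-time torso geometry.

    Deterministic for a given seed.  Raises if the requested parameters
    violate the chest/pericardium clearance invariant.
    """
    p = params or TorsoParams()
    rng = np.random.default_rng(p.seed)
    n_dense = 256
    s = np.arange(n_dense) / n_dense
    phi = 2.0 * np.pi * s

    # chest: oval with a small seeded low-order radial perturbation
    wobble = np.zeros(n_dense)
    for k, amp_scale in ((2, 0.5), (3, 1.0)):
        amp = p.chest_perturbation * amp_scale
        ph = rng.uniform(0, 2 * np.pi)
        wobble += amp * np.cos(k * phi + ph)
    ax, ay = p.chest_semi_axes
    chest_pts = np.column_stack([
        ax * (1.0 + wobble) * np.cos(phi),
        ay * (1.0 + wobble) * np.sin(phi),
    ])
    chest = ClosedCurve.from_points(chest_pts, role="chest")

    # pericardium: smooth perturbed circle, radius modulated over the beat
    shape = np.zeros(n_dense)
    for k, amp_scale in ((2, 1.0), (3, 0.6), (4, 0.3)):
        amp = p.pericardium_shape_amplitude * amp_scale
        ph = rng.uniform(0, 2 * np.pi)
        shape += amp * np.cos(k * phi + ph)

    coef = _pulsation_profile(p)
    times = np.arange(p.n_times) * p.period / p.n_times
    eta = 2.0 * np.pi * times / p.period
    profile = (coef[0] * np.cos(eta) + coef[1] * np.sin(eta)
               + coef[2] * np.cos(2 * eta) + coef[3] * np.sin(2 * eta))

    cx, cy = p.pericardium_center
    curves = []
    for f in profile:
        radius = p.pericardium_radius * (1.0 + p.pulsation_amplitude * f)
        pts = np.column_stack([
            cx + radius * (1.0 + shape) * np.cos(phi),
            cy + radius * (1.0 + shape) * np.sin(phi),
        ])
        curves.append(ClosedCurve.from_points(pts, role="pericardium"))

    geom = SpaceTimeGeometry(chest, tuple(curves), times, p.period)
    geom.validate(min_clearance=1.0)
    return geom


def pericardium_at_time(geometry: SpaceTimeGeometry, t: float) -> ClosedCurve:
    """Pericardial contour at an arbitrary time by trigonometric interpolation.

    The stored instants must be uniform in [0, T); the interpolation is
    T-periodic and exact at the stored instants.  Times outside [0, T) are
    reduced modulo T.
    """
    t = float(t) % geometry.period
    times = geometry.times
    n_t = geometry.n_times
    if n_t == 1:
        return geometry.pericardium[0]
    if not np.allclose(times, np.arange(n_t) * geometry.period / n_t):
        raise ValueError("time interpolation requires a uniform time grid")
    j = t / geometry.period * n_t
    j_near = int(round(j)) % n_t
    if abs(j - round(j)) < 1e-12:  # exactly a stored instant
        return geometry.pericardium[j_near]

    orders = [c.order for c in geometry.pericardium]
    order = max(orders)
    stacked = np.zeros((n_t, 2 * (order + 1) * 2))
    for jj, curve in enumerate(geometry.pericardium):
        m = curve.order
        a = np.zeros((order + 1, 2))
        b = np.zeros((order + 1, 2))
        a[: m + 1] = curve.cos_coef
        b[: m + 1] = curve.sin_coef
        stacked[jj] = np.concatenate([a.ravel(), b.ravel()])
    at, bt = trig_interp_coefficients(stacked)
    k = np.arange(at.shape[0])
    tau = t / geometry.period
    vals = (np.cos(2 * np.pi * k * tau) @ at + np.sin(2 * np.pi * k * tau) @ bt)
    half = vals.size // 2
    a = vals[:half].reshape(order + 1, 2)
    b = vals[half:].reshape(order + 1, 2)
    return ClosedCurve(a, b, role="pericardium")
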