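"""Spline curve model: arc-length resampling and signed curvature.

The section chain is fitted with a cubic spline on the chord-length
parameter, resampled at a uniform arc-length step (default 0.01 mm) and
differentiated analytically to obtain signed curvature.

Sign convention: with the chain ordered coronal -> apical and tissue on the
right of the direction of travel, locally convex surface is positive and
locally concave (the landmark features) is negative.  In (y, z) coordinates
this is kappa = (z' y'' - y' z'') / (y'^2 + z'^2)^(3/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep

from .errors import DegenerateInputError
from .mesh import CrossSectionPolyline

DEFAULT_STEP = 0.01  # mm
BOUNDARY_SAMPLES = 5  # samples flagged at each end (spline end effects)

# 5-point Gauss-Legendre nodes/weights on [-1, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(5)


class SplineCurve:
    """A fitted parametric cubic spline with arc-length machinery."""

    def __init__(self, tck, u_end: float):
        self.tck = tck
        self.u_end = float(u_end)
        self._build_arclength_table()

    # -- evaluation ---------------------------------------------------------

    def point(self, u) -> np.ndarray:
        y, z = splev(np.asarray(u, dtype=np.float64), self.tck)
        return np.stack([y, z], axis=-1)

    def derivative(self, u, order: int = 1) -> np.ndarray:
        y, z = splev(np.asarray(u, dtype=np.float64), self.tck, der=order)
        return np.stack([y, z], axis=-1)

    def speed(self, u) -> np.ndarray:
        d = self.derivative(u, 1)
        return np.linalg.norm(np.atleast_2d(d), axis=-1)

    # -- arc length ---------------------------------------------------------

    def _build_arclength_table(self, cells_per_knot_span: int = 8):
        n_cells = max(256, cells_per_knot_span * (len(self.tck[0]) - 7))
        grid = np.linspace(0.0, self.u_end, n_cells + 1)
        a, b = grid[:-1], grid[1:]
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        nodes = mid[:, None] + half[:, None] * _GL_X[None, :]
        sp = self.speed(nodes.ravel()).reshape(nodes.shape)
        cell_len = (sp * _GL_W[None, :]).sum(axis=1) * half
        self._u_grid = grid
        self._s_grid = np.concatenate([[0.0], np.cumsum(cell_len)])

    @property
    def length(self) -> float:
        return float(self._s_grid[-1])

    def arc_length(self, u) -> np.ndarray:
        """Arc length from the curve start to parameter u (vectorized)."""
        u = np.atleast_1d(np.asarray(u, dtype=np.float64))
        idx = np.clip(np.searchsorted(self._u_grid, u, side="right") - 1, 0, len(self._u_grid) - 2)
        a = self._u_grid[idx]
        half = 0.5 * (u - a)
        mid = 0.5 * (u + a)
        nodes = mid[:, None] + half[:, None] * _GL_X[None, :]
        sp = self.speed(nodes.ravel()).reshape(nodes.shape)
        return self._s_grid[idx] + (sp * _GL_W[None, :]).sum(axis=1) * half

    def u_at_arc_length(self, s, tol: float = 1e-9, max_iter: int = 60) -> np.ndarray:
        """Invert arc length by safeguarded Newton iteration (to tol mm)."""
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        s = np.clip(s, 0.0, self.length)
        idx = np.clip(np.searchsorted(self._s_grid, s, side="right") - 1, 0, len(self._s_grid) - 2)
        lo = self._u_grid[idx].copy()
        hi = self._u_grid[idx + 1].copy()
        seg = self._s_grid[idx + 1] - self._s_grid[idx]
        frac = np.divide(s - self._s_grid[idx], seg, out=np.zeros_like(s), where=seg > 0)
        u = lo + frac * (hi - lo)
        for _ in range(max_iter):
            err = self.arc_length(u) - s
            if np.max(np.abs(err)) < tol:
                break
            hi = np.where(err > 0, np.minimum(u, hi), hi)
            lo = np.where(err < 0, np.maximum(u, lo), lo)
            sp = np.maximum(self.speed(u), 1e-12)
            u = u - err / sp
            bad = (u <= lo) | (u >= hi)
            u = np.where(bad, 0.5 * (lo + hi), u)
        return u


@dataclass
class SampledCurve:
    """Arc-length-uniform samples of a section curve."""

    s: np.ndarray  # (n,) arc length, uniform step h, starts at 0
    points: np.ndarray  # (n, 2) columns (y, z) mm
    h: float = DEFAULT_STEP
    u: np.ndarray | None = None  # spline parameters per sample (if fitted)
    source: SplineCurve | None = field(default=None, repr=False)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=np.float64)
        self.points = np.asarray(self.points, dtype=np.float64)
        if len(self.s) != len(self.points):
            raise ValueError("s and points length mismatch")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def index_at(self, s: float) -> int:
        """Nearest sample index for an arc-length position."""
        return int(np.clip(np.round(s / self.h), 0, len(self.s) - 1))


@dataclass
class CurvatureProfile:
    """Signed curvature per sample of a SampledCurve (the comb data)."""

    curve: SampledCurve
    kappa: np.ndarray  # (n,) signed curvature mm^-1
    boundary: np.ndarray | None = None  # bool mask of end samples to skip
    site_id: str = "site"

    def __post_init__(self):
        self.kappa = np.asarray(self.kappa, dtype=np.float64)
        if len(self.kappa) != len(self.curve):
            raise ValueError("kappa length mismatch")
        if not np.all(np.isfinite(self.kappa)):
            raise ValueError("non-finite curvature values")
        if self.boundary is None:
            mask = np.zeros(len(self.kappa), dtype=bool)
            k = min(BOUNDARY_SAMPLES, len(mask))
            mask[:k] = True
            mask[len(mask) - k :] = True
            self.boundary = mask

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("s_mm,y_mm,z_mm,kappa_per_mm,boundary_flag\n")
            for s, (y, z), k, b in zip(self.curve.s, self.curve.points, self.kappa, self.boundary):
                fh.write(f"{s:.17g},{y:.17g},{z:.17g},{k:.17g},{int(b)}\n")


def fit_spline(polyline, smoothing: float = 0.0) -> SplineCurve:
    """Fit a chord-length-parameterized cubic spline to a section chain.

    ``smoothing`` is the allowed RMS point-to-curve deviation in mm;
    0 interpolates the points exactly.
    """
    if isinstance(polyline, CrossSectionPolyline):
        pts = polyline.points
    else:
        pts = np.asarray(polyline, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected (n, 2) points")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    if len(pts) < 4:
        raise DegenerateInputError(f"need >= 4 distinct points, got {len(pts)}")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    s_scipy = len(pts) * smoothing**2
    tck, u = splprep([pts[:, 0], pts[:, 1]], u=chord, s=s_scipy, k=3)
    return SplineCurve(tck, u[-1])


def resample(curve: SplineCurve, h: float = DEFAULT_STEP) -> SampledCurve:
    """Sample the spline at arc lengths 0, h, 2h, ... (Gauss-Legendre inversion)."""
    if h <= 0:
        raise ValueError("h must be positive")
    total = curve.length
    n = int(np.floor(total / h + 1e-9))
    s = np.arange(n + 1) * h
    u = curve.u_at_arc_length(s)
    return SampledCurve(s=s, points=curve.point(u), h=h, u=u, source=curve)


def signed_curvature(curve: SampledCurve, site_id: str = "site") -> CurvatureProfile:
    """Signed curvature from analytic spline derivatives at each sample."""
    if len(curve) < 5:
        raise DegenerateInputError(f"need >= 5 samples, got {len(curve)}")
    if curve.source is None or curve.u is None:
        raise DegenerateInputError("curve carries no spline handle; use fit_spline + resample")
    d1 = curve.source.derivative(curve.u, 1)
    d2 = curve.source.derivative(curve.u, 2)
    yp, zp = d1[:, 0], d1[:, 1]
    ypp, zpp = d2[:, 0], d2[:, 1]
    speed_sq = yp**2 + zp**2
    kappa = (zp * ypp - yp * zpp) / np.power(speed_sq, 1.5)
    return CurvatureProfile(curve=curve, kappa=kappa, site_id=site_id)


def curvature_profile(
    polyline, smoothing: float = 0.0, h: float = DEFAULT_STEP, site_id: str | None = None
) -> CurvatureProfile:
    """Convenience pipeline: fit, resample, differentiate."""
    if site_id is None:
        site_id = getattr(polyline, "site_id", "site")
    spline = fit_spline(polyline, smoothing=smoothing)
    return signed_curvature(resample(spline, h=h), site_id=site_id)


def curvature_comb(profile: CurvatureProfile, scale: float = 1.0) -> dict:
    """Comb geometry: one tooth per sample, drawn toward the centre of curvature.

    Returns base points, tip points and the sign tag per sample
    (+1 convex / "blue", -1 concave / "red", 0 straight).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    curve = profile.curve
    if curve.source is not None and curve.u is not None:
        d1 = curve.source.derivative(curve.u, 1)
    else:
        d1 = np.gradient(curve.points, curve.s, axis=0)
    tangents = d1 / np.maximum(np.linalg.norm(d1, axis=1, keepdims=True), 1e-12)
    # right normal (t_z, -t_y); tooth vector kappa * scale * right-normal points
    # toward the centre of curvature on either side
    right = np.stack([tangents[:, 1], -tangents[:, 0]], axis=1)
    teeth = scale * profile.kappa[:, None] * right
    return {
        "base": curve.points.copy(),
        "tip": curve.points + teeth,
        "sign": np.sign(profile.kappa).astype(int),
        "scale": scale,
    }


def comb_to_csv(comb: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("y_base,z_base,y_tip,z_tip,sign\n")
        for b, t, sg in zip(comb["base"], comb["tip"], comb["sign"]):
            fh.write(f"{b[0]:.17g},{b[1]:.17g},{t[0]:.17g},{t[1]:.17g},{sg}\n")


def comb_to_svg(comb: dict, path, width: int = 800) -> None:
    """Minimal SVG rendering: curve polyline plus colour-coded comb teeth."""
    base, tip = comb["base"], comb["tip"]
    allpts = np.concatenate([base, tip])
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    scale = (width - 20) / span.max()
    height = int(span[1] * scale) + 20

    def xy(p):
        x = 10 + (p[0] - lo[0]) * scale
        y = height - 10 - (p[1] - lo[1]) * scale  # flip: +z up
        return f"{x:.2f},{y:.2f}"

    colors = {1: "#1f77b4", 0: "#888888", -1: "#d62728"}
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        '<polyline fill="none" stroke="black" stroke-width="1.2" points="'
        + " ".join(xy(p) for p in base)
        + '"/>',
    ]
    for b, t, sg in zip(base, tip, comb["sign"]):
        bx, by = xy(b).split(",")
        tx, ty = xy(t).split(",")
        lines.append(
            f'<line x1="{bx}" y1="{by}" x2="{tx}" y2="{ty}" '
            f'stroke="{colors[int(sg)]}" stroke-width="0.5"/>'
        )
    lines.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
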