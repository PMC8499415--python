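"""Synthetic bucco-oral cross-section profiles with known ground truth.

Profiles are G1 chains of circular arcs (piecewise-constant curvature), so
the analytic curvature field is exact and every downstream number can be
checked.  Chain layout, coronal -> apical:

    convex crown arc | concave CEJ arc group | near-straight root |
    concave GM arc group | convex gingiva arc

Each concave "arc group" is three arcs (shoulder / core / shoulder) with the
core at the nominal curvature, so the greatest concavity is attained on a
short core arc centred at the ground-truth landmark.  The root length is
solved so the CEJ-to-GM chord equals the requested recession depth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .curve import DEFAULT_STEP, SampledCurve
from .errors import ConstructionError

Z95 = 1.6448536269514722  # standard normal 95th percentile
Z75 = 0.6744897501960817  # 75th percentile


# ---------------------------------------------------------------------------
# spec and examiner model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileSpec:
    """Parametric description of one synthetic cross-section."""

    crown_kappa: float = 0.3  # mm^-1, convex crown surface
    cej_kappa: float = -1.0  # mm^-1, negative (concave); magnitude ~0.3-2.3
    cej_arc_span: float = 0.3  # mm, total span of the CEJ concave group
    root_kappa: float = 0.05  # mm^-1, near-straight root (slightly convex)
    recession_depth: float = 1.9  # mm, ground-truth CEJ-GM distance
    gm_kappa: float = -4.4  # mm^-1, negative; magnitude ~2-9
    gm_arc_span: float = 0.25  # mm
    gingiva_kappa: float = 0.3  # mm^-1, convex gingiva surface
    noise_sigma: float = 0.0  # mm, Gaussian point noise
    seed: int = 0
    crown_span: float = 3.0  # mm
    gingiva_span: float = 2.0  # mm
    core_span: float = 0.02  # mm, span of the full-curvature core arc
    shoulder_ratio: float = 0.5  # shoulder curvature / core curvature

    def validate(self) -> None:
        if self.crown_kappa <= 0 or self.gingiva_kappa <= 0:
            raise ConstructionError("crown and gingiva curvature must be positive (convex)")
        if self.cej_kappa >= 0 or self.gm_kappa >= 0:
            raise ConstructionError("CEJ and GM curvature must be negative (concave)")
        if self.cej_arc_span <= 0 or self.gm_arc_span <= 0:
            raise ConstructionError("arc spans must be positive")
        if self.recession_depth <= 0:
            raise ConstructionError("recession_depth must be positive")
        if self.core_span <= 0 or not 0 < self.shoulder_ratio <= 1:
            raise ConstructionError("invalid core_span or shoulder_ratio")
        if self.noise_sigma < 0:
            raise ConstructionError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class ExaminerModel:
    """Curvature-dependent pick noise: flatter landmarks are harder to pick."""

    sigma0: float = 0.1  # mm * mm^-1
    kappa_floor: float = 0.1  # mm^-1

    def pick_sd(self, kappa: float) -> float:
        return self.sigma0 / max(abs(kappa), self.kappa_floor)


@dataclass(frozen=True)
class GroundTruthLandmark:
    kind: str
    s: float
    point: tuple
    kappa: float


@dataclass
class SyntheticProfile:
    spec: ProfileSpec
    curve: SampledCurve
    kappa_field: np.ndarray  # analytic signed curvature per sample
    junctions: np.ndarray  # arc-boundary arc lengths
    cej: GroundTruthLandmark
    gm: GroundTruthLandmark
    root_length: float
    pieces: list = field(repr=False, default_factory=list)

    @property
    def site_id(self) -> str:
        return f"synthetic-{self.spec.seed}"


# ---------------------------------------------------------------------------
# arc-chain machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Arc:
    s0: float
    length: float
    kappa: float  # package sign convention (convex +)
    p0: tuple
    phi0: float

    def point(self, s) -> np.ndarray:
        """Position at absolute arc length s (vectorized)."""
        ds = np.asarray(s, dtype=np.float64) - self.s0
        omega = -self.kappa  # heading rate under the sign convention
        y0, z0 = self.p0
        if abs(omega) < 1e-12:
            return np.stack(
                [y0 + ds * np.cos(self.phi0), z0 + ds * np.sin(self.phi0)], axis=-1
            )
        phi = self.phi0 + omega * ds
        return np.stack(
            [
                y0 + (np.sin(phi) - np.sin(self.phi0)) / omega,
                z0 + (np.cos(self.phi0) - np.cos(phi)) / omega,
            ],
            axis=-1,
        )

    def end(self) -> tuple:
        p = self.point(self.s0 + self.length)
        return (float(p[0]), float(p[1])), self.phi0 - self.kappa * self.length


def _build_chain(pieces: list[tuple[float, float]], phi0: float, p0=(0.0, 0.0)) -> list[_Arc]:
    arcs = []
    s0, phi, p = 0.0, phi0, p0
    for length, kappa in pieces:
        arc = _Arc(s0=s0, length=length, kappa=kappa, p0=p, phi0=phi)
        arcs.append(arc)
        p, phi = arc.end()
        s0 += length
    return arcs


def _chain_point(arcs: list[_Arc], s) -> np.ndarray:
    s = np.atleast_1d(np.asarray(s, dtype=np.float64))
    bounds = np.array([a.s0 for a in arcs] + [arcs[-1].s0 + arcs[-1].length])
    idx = np.clip(np.searchsorted(bounds, s, side="right") - 1, 0, len(arcs) - 1)
    out = np.empty((len(s), 2))
    for i, arc in enumerate(arcs):
        mask = idx == i
        if mask.any():
            out[mask] = arc.point(s[mask])
    return out


def _concave_group(total_span: float, kappa: float, core_span: float, shoulder_ratio: float):
    """(length, kappa) pieces for shoulder/core/shoulder; core is centred."""
    core = min(core_span, total_span / 3.0)
    shoulder = (total_span - core) / 2.0
    return [
        (shoulder, shoulder_ratio * kappa),
        (core, kappa),
        (shoulder, shoulder_ratio * kappa),
    ]


def _group_turn(pieces) -> float:
    """Total heading change magnitude across a group of concave arcs."""
    return float(sum(abs(k) * ln for ln, k in pieces))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_profile(spec: ProfileSpec, h: float = DEFAULT_STEP) -> SyntheticProfile:
    """Build one profile; deterministic for a fixed spec (incl. seed)."""
    spec.validate()
    cej_group = _concave_group(spec.cej_arc_span, spec.cej_kappa, spec.core_span, spec.shoulder_ratio)
    gm_group = _concave_group(spec.gm_arc_span, spec.gm_kappa, spec.core_span, spec.shoulder_ratio)
    delta_crown = spec.crown_kappa * spec.crown_span
    delta_cej = _group_turn(cej_group)
    if delta_crown + delta_cej > np.pi:
        raise ConstructionError("crown/CEJ turn angles exceed pi; reduce spans or curvature")
    if _group_turn(gm_group) > 0.45 * np.pi:
        raise ConstructionError("GM turn angle too large; reduce gm_arc_span or gm_kappa")
    phi0 = -np.pi / 2 + delta_crown - delta_cej  # root heading ends up vertical

    s_cej = spec.crown_span + spec.cej_arc_span / 2.0
    pre_root = spec.crown_span + spec.cej_arc_span

    def pieces_for(root_len: float):
        return (
            [(spec.crown_span, spec.crown_kappa)]
            + cej_group
            + [(root_len, spec.root_kappa)]
            + gm_group
            + [(spec.gingiva_span, spec.gingiva_kappa)]
        )

    def depth_of(root_len: float) -> float:
        arcs = _build_chain(pieces_for(root_len), phi0)
        s_gm = pre_root + root_len + spec.gm_arc_span / 2.0
        pts = _chain_point(arcs, [s_cej, s_gm])
        return float(np.linalg.norm(pts[0] - pts[1]))

    t_lo, t_hi = 1e-4, 100.0
    d_lo = depth_of(t_lo)
    if d_lo > spec.recession_depth:
        raise ConstructionError(
            f"recession_depth {spec.recession_depth} mm unreachable: arc spans alone "
            f"give a CEJ-GM distance of {d_lo:.3f} mm"
        )
    if depth_of(t_hi) < spec.recession_depth:
        raise ConstructionError("recession_depth too large for the root-length bound")
    root_length = brentq(
        lambda t: depth_of(t) - spec.recession_depth, t_lo, t_hi, xtol=1e-12, rtol=1e-15
    )

    arcs = _build_chain(pieces_for(root_length), phi0)
    total = arcs[-1].s0 + arcs[-1].length
    n = int(np.floor(total / h + 1e-9))
    s = np.arange(n + 1) * h
    points = _chain_point(arcs, s)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        points = points + rng.normal(0.0, spec.noise_sigma, points.shape)

    bounds = np.array([a.s0 for a in arcs] + [total])
    idx = np.clip(np.searchsorted(bounds, s, side="right") - 1, 0, len(arcs) - 1)
    kappa_field = np.array([arcs[i].kappa for i in idx])

    s_gm = pre_root + root_length + spec.gm_arc_span / 2.0
    cej_pt = _chain_point(arcs, s_cej)[0]
    gm_pt = _chain_point(arcs, s_gm)[0]
    return SyntheticProfile(
        spec=spec,
        curve=SampledCurve(s=s, points=points, h=h),
        kappa_field=kappa_field,
        junctions=bounds[1:-1].copy(),
        cej=GroundTruthLandmark("CEJ", float(s_cej), tuple(cej_pt), spec.cej_kappa),
        gm=GroundTruthLandmark("GM", float(s_gm), tuple(gm_pt), spec.gm_kappa),
        root_length=float(root_length),
        pieces=arcs,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def lognormal_params(median: float, q_low: float, q_high: float, z: float = Z95):
    """(mu, sigma) of a LogNormal matched to a median and symmetric quantiles."""
    if not 0 < q_low < median < q_high:
        raise ValueError("need 0 < q_low < median < q_high")
    return np.log(median), (np.log(q_high) - np.log(q_low)) / (2.0 * z)


#: default parameter distributions: medians and quantile ranges of CEJ / GM
#: curvature magnitude (5th-95th) and recession depth (quartiles)
DEFAULT_COHORT_DISTRIBUTIONS = {
    "cej_kappa": {"median": 0.99, "q_low": 0.32, "q_high": 2.30, "z": Z95, "clip": (0.15, 4.0)},
    "gm_kappa": {"median": 4.39, "q_low": 1.98, "q_high": 9.14, "z": Z95, "clip": (1.2, 12.0)},
    "recession_depth": {"median": 1.90, "q_low": 1.25, "q_high": 2.62, "z": Z75, "clip": (0.5, 8.0)},
}


def _adaptive_spans(cej_kappa: float, gm_kappa: float, depth: float) -> tuple[float, float]:
    """Arc spans keeping group turn angles moderate across the kappa range
    and small enough that the requested depth stays reachable."""
    cej_span = float(np.clip(0.5 / abs(cej_kappa), 0.15, min(0.5, 0.45 * depth)))
    gm_span = float(np.clip(1.0 / abs(gm_kappa), 0.1, min(0.4, 0.35 * depth)))
    return cej_span, gm_span


def draw_cohort_specs(
    n: int,
    seed: int = 0,
    distributions: dict | None = None,
    noise_sigma: float = 0.0,
) -> list[ProfileSpec]:
    """Draw per-site ProfileSpecs from moment-matched LogNormal distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = dict(DEFAULT_COHORT_DISTRIBUTIONS)
    if distributions:
        dists.update(distributions)
    rng = np.random.default_rng(seed)
    site_seeds = np.random.SeedSequence(seed).generate_state(n)

    def draw(name):
        d = dists[name]
        mu, sigma = lognormal_params(d["median"], d["q_low"], d["q_high"], d.get("z", Z95))
        values = rng.lognormal(mu, sigma, size=n)
        lo, hi = d.get("clip", (None, None))
        return np.clip(values, lo, hi)

    cej = draw("cej_kappa")
    gm = draw("gm_kappa")
    # the GM fold is sharper than the CEJ groove at every site (Fig. 4-style
    # ranges barely overlap); enforce the per-site ordering explicitly
    gm = np.maximum(gm, 1.1 * cej + 0.1)
    depth = draw("recession_depth")
    specs = []
    for i in range(n):
        cej_span, gm_span = _adaptive_spans(cej[i], gm[i], depth[i])
        specs.append(
            ProfileSpec(
                cej_kappa=-float(cej[i]),
                gm_kappa=-float(gm[i]),
                recession_depth=float(depth[i]),
                cej_arc_span=cej_span,
                gm_arc_span=gm_span,
                noise_sigma=noise_sigma,
                seed=int(site_seeds[i]),
            )
        )
    return specs


def generate_cohort(
    n: int,
    seed: int = 0,
    distributions: dict | None = None,
    noise_sigma: float = 0.0,
    h: float = DEFAULT_STEP,
) -> list[SyntheticProfile]:
    """Draw specs and build all profiles (reproducible by seed)."""
    specs = draw_cohort_specs(n, seed=seed, distributions=distributions, noise_sigma=noise_sigma)
    profiles = []
    for spec in specs:
        try:
            profiles.append(generate_profile(spec, h=h))
        except ConstructionError:
            # depth incompatible with drawn spans: retry with a deeper-site layout
            profiles.append(generate_profile(replace(spec, crown_span=2.0, gingiva_span=1.5), h=h))
    return profiles


def truth_table(profiles: list[SyntheticProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "site_id": p.site_id,
                "cej_s_mm": p.cej.s,
                "gm_s_mm": p.gm.s,
                "cej_kappa_per_mm": p.cej.kappa,
                "gm_kappa_per_mm": p.gm.kappa,
                "depth_mm": p.spec.recession_depth,
            }
        )
    return pd.DataFrame(rows)


def simulate_examiner(
    profiles: list[SyntheticProfile],
    model: ExaminerModel = ExaminerModel(),
    n_examiners: int = 3,
    rounds: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate manual picks: ground-truth s plus curvature-dependent noise.

    Returns a long pick table with columns site_id, examiner, round,
    landmark, s_mm, y_mm, z_mm, true_kappa_per_mm.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in profiles:
        for landmark in (p.cej, p.gm):
            sd = model.pick_sd(landmark.kappa)
            for e in range(1, n_examiners + 1):
                for r in range(1, rounds + 1):
                    s_pick = landmark.s + rng.normal(0.0, sd)
                    s_pick = float(np.clip(s_pick, 0.0, p.curve.length))
                    i = p.curve.index_at(s_pick)
                    rows.append(
                        {
                            "site_id": p.site_id,
                            "examiner": f"examiner{e}",
                            "round": r,
                            "landmark": landmark.kind,
                            "s_mm": s_pick,
                            "y_mm": float(p.curve.points[i, 0]),
                            "z_mm": float(p.curve.points[i, 1]),
                            "true_kappa_per_mm": landmark.kappa,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_deviations(
    specs: list[ProfileSpec],
    model: ExaminerModel = ExaminerModel(),
    n_examiners: int = 3,
    rounds: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw signed pick deviations directly from the examiner model.

    Lightweight counterpart of simulate_examiner for mechanism studies:
    no profile geometry is built, only the curvature-dependent deviations.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, spec in enumerate(specs):
        for landmark, kappa in (("CEJ", spec.cej_kappa), ("GM", spec.gm_kappa)):
            sd = model.pick_sd(kappa)
            for e in range(1, n_examiners + 1):
                for r in range(1, rounds + 1):
                    rows.append(
                        {
                            "site_id": f"site{i}",
                            "examiner": f"examiner{e}",
                            "round": r,
                            "landmark": landmark,
                            "deviation_mm": rng.normal(0.0, sd),
                            "reference_kappa_per_mm": kappa,
                        }
                    )
    return pd.DataFrame(rows)


def extrude_profile(profile: SyntheticProfile, width: float = 2.0, every: int = 5):
    """Extrude the (y, z) profile along x into a triangle ribbon mesh.

    Lets the mesh-slicing stage be integration-tested against ground truth:
    slicing the ribbon at x=0 recovers the profile polyline.
    """
    from .mesh import TriangleMesh

    pts = profile.curve.points[::every]
    n = len(pts)
    half = width / 2.0
    left = np.column_stack([np.full(n, -half), pts])
    right = np.column_stack([np.full(n, half), pts])
    vertices = np.concatenate([left, right])
    faces = []
    for i in range(n - 1):
        a, b = i, i + 1
        c, d = n + i, n + i + 1
        faces += [(a, c, b), (b, c, d)]
    return TriangleMesh(vertices, np.array(faces))
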