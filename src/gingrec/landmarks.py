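"""CEJ and GM landmark detection from curvature sign transitions.

The cemento-enamel junction (CEJ) is the first qualifying convex->concave
transition scanning coronal -> apical; the gingival margin (GM) is the first
qualifying convex->concave transition scanning in the opposite direction
(apico-coronal).  Each landmark is the sample of greatest concavity (minimum
signed curvature) within the concave run of its transition.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .curve import CurvatureProfile
from .errors import LandmarkNotFoundError, OrientationError

DEFAULT_MIN_PROMINENCE = 0.1  # mm^-1
DEFAULT_MIN_RUN = 0.05  # mm

CORONO_APICAL = "corono-apical"
APICO_CORONAL = "apico-coronal"


@dataclass(frozen=True)
class TransitionSegment:
    kind: str  # "convex_to_concave" (only kind produced)
    scan_direction: str  # CORONO_APICAL or APICO_CORONAL
    s_start: float
    s_end: float
    extremum_s: float
    extremum_kappa: float

    def __post_init__(self):
        if not self.s_start < self.s_end:
            raise ValueError("s_start must be < s_end")
        if not (self.s_start <= self.extremum_s <= self.s_end):
            raise ValueError("extremum outside segment bounds")
        if self.extremum_kappa >= 0:
            raise ValueError("concave extremum must have negative curvature")


@dataclass(frozen=True)
class Landmark:
    kind: str  # "CEJ" or "GM"
    s: float
    point: tuple  # (y, z) mm
    kappa: float
    segment: TransitionSegment

    def __post_init__(self):
        if self.kappa >= 0:
            raise ValueError("landmark curvature must be negative (concavity)")


def _sign_runs(kappa: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of curvature sign as (start, stop_exclusive, sign)."""
    signs = np.where(kappa >= 0, 1, -1)
    runs = []
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            runs.append((start, i, int(signs[start])))
            start = i
    return runs


def _merge_short_runs(runs, min_samples: int):
    """Absorb runs shorter than min_samples into their neighbours.

    Shortest runs go first so isolated sign-flip blips vanish without
    disturbing the surrounding long runs.
    """
    runs = list(runs)
    while True:
        lengths = [stop - start for start, stop, _ in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_samples or len(runs) == 1:
            return runs
        start, stop, sign = runs.pop(shortest)
        if shortest > 0:
            ps, _, psign = runs[shortest - 1]
            runs[shortest - 1] = (ps, stop, psign)
            # possibly merge with the following run of the same sign
            if shortest < len(runs):
                ns, nstop, nsign = runs[shortest]
                if nsign == psign:
                    runs[shortest - 1] = (ps, nstop, psign)
                    runs.pop(shortest)
        else:
            ns, nstop, nsign = runs[0]
            runs[0] = (start, nstop, nsign)


def find_transitions(
    profile: CurvatureProfile,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_run: float = DEFAULT_MIN_RUN,
) -> list[TransitionSegment]:
    """Locate qualifying convex->concave transitions in both scan directions.

    A transition qualifies when the adjoining convex and concave runs each
    span at least min_run of arc length and the concave run's extremum
    magnitude reaches min_prominence.  Boundary samples are excluded.
    Returned in coronal->apical order of the concave run.
    """
    interior = ~profile.boundary
    idx = np.flatnonzero(interior)
    if len(idx) < 3:
        return []
    kappa = profile.kappa[idx]
    s = profile.curve.s[idx]
    h = profile.curve.h
    min_samples = max(1, int(np.ceil(min_run / h)))

    runs = _merge_short_runs(_sign_runs(kappa), min_samples)
    segments = []
    for a, b in zip(runs[:-1], runs[1:]):
        if a[1] - a[0] < min_samples or b[1] - b[0] < min_samples:
            continue
        pair = None
        if a[2] > 0 and b[2] < 0:  # convex then concave: corono-apical transition
            pair = (a, b, CORONO_APICAL)
        elif a[2] < 0 and b[2] > 0:  # concave then convex: apico-coronal transition
            pair = (b, a, APICO_CORONAL)
        if pair is None:
            continue
        _, concave, direction = pair
        c0, c1, _ = concave
        local = kappa[c0:c1]
        j = int(np.argmin(local))  # first (most coronal) index on exact ties
        if -local[j] < min_prominence:
            continue
        segments.append(
            TransitionSegment(
                kind="convex_to_concave",
                scan_direction=direction,
                s_start=float(s[a[0]]),
                s_end=float(s[b[1] - 1]),
                extremum_s=float(s[c0 + j]),
                extremum_kappa=float(local[j]),
            )
        )
    return segments


def _landmark_from_segment(profile: CurvatureProfile, segment: TransitionSegment, kind: str) -> Landmark:
    i = profile.curve.index_at(segment.extremum_s)
    return Landmark(
        kind=kind,
        s=float(profile.curve.s[i]),
        point=tuple(profile.curve.points[i]),
        kappa=float(profile.kappa[i]),
        segment=segment,
    )


def detect_cej(profile: CurvatureProfile, segments: list[TransitionSegment]) -> Landmark:
    """First qualifying convex->concave transition scanning coronal -> apical."""
    candidates = [seg for seg in segments if seg.scan_direction == CORONO_APICAL]
    if not candidates:
        raise LandmarkNotFoundError(
            f"{profile.site_id}: no convex->concave transition in corono-apical scan",
            candidates=[asdict(seg) for seg in segments],
        )
    chosen = min(candidates, key=lambda seg: seg.s_start)
    return _landmark_from_segment(profile, chosen, "CEJ")


def detect_gm(
    profile: CurvatureProfile,
    segments: list[TransitionSegment],
    cej: Landmark | None = None,
) -> Landmark:
    """First qualifying convex->concave transition scanning apical -> coronal.

    If the CEJ landmark is supplied, only segments apical to it (larger s)
    are eligible and the GM must lie apical to the CEJ (smaller z).
    """
    candidates = [seg for seg in segments if seg.scan_direction == APICO_CORONAL]
    if cej is not None:
        candidates = [seg for seg in candidates if seg.extremum_s > cej.segment.extremum_s]
    if not candidates:
        raise LandmarkNotFoundError(
            f"{profile.site_id}: no convex->concave transition in apico-coronal scan"
            + (" apical to the CEJ" if cej is not None else ""),
            candidates=[asdict(seg) for seg in segments],
        )
    chosen = max(candidates, key=lambda seg: seg.s_end)  # first seen from the apical end
    gm = _landmark_from_segment(profile, chosen, "GM")
    if cej is not None and gm.point[1] >= cej.point[1]:
        raise OrientationError(
            f"{profile.site_id}: GM (z={gm.point[1]:.3f}) is coronal to CEJ (z={cej.point[1]:.3f})"
        )
    return gm


def detect_landmarks(
    profile: CurvatureProfile,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_run: float = DEFAULT_MIN_RUN,
) -> tuple[Landmark, Landmark, dict]:
    """Run both detections; returns (cej, gm, report)."""
    segments = find_transitions(profile, min_prominence=min_prominence, min_run=min_run)
    cej = detect_cej(profile, segments)
    gm = detect_gm(profile, segments, cej=cej)
    report = detection_report(profile, cej, gm, segments, min_prominence, min_run)
    return cej, gm, report


def detection_report(profile, cej, gm, segments, min_prominence, min_run) -> dict:
    def lm(landmark):
        return {
            "kind": landmark.kind,
            "s_mm": landmark.s,
            "y_mm": landmark.point[0],
            "z_mm": landmark.point[1],
            "kappa_per_mm": landmark.kappa,
        }

    return {
        "site_id": profile.site_id,
        "landmarks": {"CEJ": lm(cej), "GM": lm(gm)},
        "candidates": [asdict(seg) for seg in segments],
        "gates": {"min_prominence_per_mm": min_prominence, "min_run_mm": min_run},
    }
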