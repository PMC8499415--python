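"""Recession depth and manual-pick deviation measurements.

Depth is the in-plane Euclidean distance between the CEJ and GM points.
Manual-pick deviation is the signed along-curve distance from the automated
reference landmark: positive = manual pick coronal to the reference,
negative = apical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve import CurvatureProfile, SampledCurve
from .errors import GingrecError, InputError, OffCurveError
from .landmarks import Landmark, detect_landmarks

SNAP_WARN_DIST = 0.05  # mm: picks farther than this are snapped and flagged
SNAP_MAX_DIST = 0.5  # mm: picks farther than this are rejected


@dataclass(frozen=True)
class RecessionRecord:
    site_id: str
    method: str  # "automated", "examiner<k>" or "clinical"
    round: int
    cej_s: float | None
    gm_s: float | None
    depth: float
    status: str = "ok"

    def __post_init__(self):
        if self.status == "ok" and self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class DeviationRecord:
    site_id: str
    examiner: str
    round: int
    landmark: str  # "CEJ" or "GM"
    deviation: float  # signed mm, + coronal
    reference_kappa: float
    snapped: bool = False


def recession_depth(cej_point, gm_point) -> float:
    """Euclidean in-plane distance between the two measurement points."""
    a = np.asarray(cej_point, dtype=np.float64)
    b = np.asarray(gm_point, dtype=np.float64)
    return float(np.linalg.norm(a - b))


def snap_to_curve(point, curve: SampledCurve) -> tuple[int, float]:
    """Nearest sample index and its distance for an off-curve pick."""
    d = np.linalg.norm(curve.points - np.asarray(point, dtype=np.float64), axis=1)
    i = int(np.argmin(d))
    return i, float(d[i])


def arc_length_deviation(
    manual_point,
    reference: Landmark,
    curve: SampledCurve,
    site_id: str = "site",
    examiner: str = "examiner1",
    round: int = 1,
) -> DeviationRecord:
    """Signed along-curve deviation of a manual 2D pick from the reference."""
    i, dist = snap_to_curve(manual_point, curve)
    if dist > SNAP_MAX_DIST:
        raise OffCurveError(
            f"{site_id}: pick {tuple(manual_point)} is {dist:.3f} mm from the curve"
        )
    return DeviationRecord(
        site_id=site_id,
        examiner=examiner,
        round=round,
        landmark=reference.kind,
        deviation=float(reference.s - curve.s[i]),
        reference_kappa=reference.kappa,
        snapped=dist > SNAP_WARN_DIST,
    )


def deviation_from_s(
    s_manual: float,
    reference: Landmark,
    site_id: str = "site",
    examiner: str = "examiner1",
    round: int = 1,
) -> DeviationRecord:
    """Deviation for a pick given directly as an arc-length position."""
    return DeviationRecord(
        site_id=site_id,
        examiner=examiner,
        round=round,
        landmark=reference.kind,
        deviation=float(reference.s - s_manual),
        reference_kappa=reference.kappa,
    )


def batch_measure(
    profiles: dict[str, CurvatureProfile],
    picks: pd.DataFrame | None = None,
    min_prominence: float | None = None,
    min_run: float | None = None,
    return_reports: bool = False,
):
    """Measure every site; returns (measurements, deviations) long tables.

    ``profiles`` maps site_id -> CurvatureProfile.  ``picks`` (optional) has
    columns site_id, examiner, round, landmark and either s_mm or y_mm/z_mm.
    Detection failures are carried as flagged rows, never dropped.
    With return_reports=True a third element maps site_id -> detection report.
    """
    gates = {}
    if min_prominence is not None:
        gates["min_prominence"] = min_prominence
    if min_run is not None:
        gates["min_run"] = min_run

    if picks is not None and len(picks):
        dup_keys = ["site_id", "examiner", "round", "landmark"]
        if picks.duplicated(subset=dup_keys).any():
            dups = picks[picks.duplicated(subset=dup_keys, keep=False)]
            raise InputError(f"duplicate pick rows:\n{dups[dup_keys]}")

    meas_rows, dev_rows = [], []
    reports: dict[str, dict] = {}
    references: dict[str, tuple[Landmark, Landmark]] = {}
    for site_id, profile in profiles.items():
        try:
            cej, gm, report = detect_landmarks(profile, **gates)
            report["n_samples"] = len(profile.kappa)
            reports[site_id] = report
        except GingrecError as exc:
            meas_rows.append(
                {
                    "site_id": site_id,
                    "method": "automated",
                    "round": 0,
                    "cej_s": np.nan,
                    "gm_s": np.nan,
                    "depth_mm": np.nan,
                    "status": f"{type(exc).__name__}: {exc}",
                }
            )
            continue
        references[site_id] = (cej, gm)
        meas_rows.append(
            {
                "site_id": site_id,
                "method": "automated",
                "round": 0,
                "cej_s": cej.s,
                "gm_s": gm.s,
                "depth_mm": recession_depth(cej.point, gm.point),
                "status": "ok",
            }
        )

    if picks is not None and len(picks):
        for (site_id, examiner, rnd), group in picks.groupby(["site_id", "examiner", "round"]):
            if site_id not in references:
                continue
            cej_ref, gm_ref = references[site_id]
            curve = profiles[site_id].curve
            points = {}
            for _, row in group.iterrows():
                ref = cej_ref if row["landmark"] == "CEJ" else gm_ref
                if "s_mm" in row.index and not pd.isna(row.get("s_mm")):
                    rec = deviation_from_s(
                        float(row["s_mm"]), ref, site_id=site_id,
                        examiner=str(examiner), round=int(rnd),
                    )
                    points[row["landmark"]] = curve.points[curve.index_at(float(row["s_mm"]))]
                else:
                    pt = (float(row["y_mm"]), float(row["z_mm"]))
                    rec = arc_length_deviation(
                        pt, ref, curve, site_id=site_id,
                        examiner=str(examiner), round=int(rnd),
                    )
                    points[row["landmark"]] = np.asarray(pt)
                dev_rows.append(rec.__dict__)
            if "CEJ" in points and "GM" in points:
                meas_rows.append(
                    {
                        "site_id": site_id,
                        "method": str(examiner),
                        "round": int(rnd),
                        "cej_s": np.nan,
                        "gm_s": np.nan,
                        "depth_mm": recession_depth(points["CEJ"], points["GM"]),
                        "status": "ok",
                    }
                )

    measurements = pd.DataFrame(
        meas_rows,
        columns=["site_id", "method", "round", "cej_s", "gm_s", "depth_mm", "status"],
    )
    deviations = pd.DataFrame(
        dev_rows,
        columns=["site_id", "examiner", "round", "landmark", "deviation", "reference_kappa", "snapped"],
    ).rename(columns={"deviation": "deviation_mm", "reference_kappa": "reference_kappa_per_mm"})
    if return_reports:
        return measurements, deviations, reports
    return measurements, deviations
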