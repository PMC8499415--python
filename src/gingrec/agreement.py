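"""Observer-agreement statistics: ICC, Bland-Altman, multiplicity, strata.

ICC is the two-way random-effects, absolute-agreement, single-measures
coefficient (ICC(A,1) in McGraw & Wong notation) computed from ANOVA mean
squares with the F-based 95% confidence interval.  Bland-Altman limits of
agreement use the sample SD of paired differences with t-based confidence
intervals (the classical sqrt(3/n) approximation for the limits).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    bias_ci: tuple
    loa_low: float
    loa_high: float
    loa_low_ci: tuple
    loa_high_ci: tuple
    n: int
    t_stat: float
    p_value: float
    p_adjusted: float | None = None
    degenerate: bool = False  # all differences identical: p undefined

    def to_dict(self) -> dict:
        return asdict(self)


def icc(ratings, alpha: float = 0.05) -> ICCResult:
    """Two-way random, absolute agreement, single measures ICC with 95% CI.

    ``ratings`` is an (n_subjects, k_raters) array or DataFrame with no
    missing cells.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise InputError("ratings must be 2-D (subjects x raters)")
    n, k = x.shape
    if k < 2:
        raise InputError("need at least 2 raters")
    if n < 3:
        raise InputError("need at least 3 subjects")
    if np.isnan(x).any():
        raise InputError("missing cells are not allowed (no imputation)")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msb = ss_rows / (n - 1)  # between subjects
    msj = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msb + (k - 1) * mse + k * (msj - mse) / n
    estimate = (msb - mse) / denom if denom > 0 else np.nan

    if mse <= 0:  # perfect agreement: degenerate F distributions
        lo = hi = estimate
    else:
        # McGraw & Wong (1996) F-based CI for ICC(A,1)
        fj = msj / mse
        a = (k * estimate) / (n * (1 - estimate)) if estimate < 1 else np.inf
        b = 1 + (k * estimate * (n - 1)) / (n * (1 - estimate)) if estimate < 1 else np.inf
        v = (a * fj + b) ** 2 / (a**2 * fj**2 / (k - 1) + b**2 / ((n - 1) * (k - 1)))
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msb - f_u * mse) / (f_u * (k * msj + (k * n - k - n) * mse) + n * msb)
        hi = n * (f_l * msb - mse) / (k * msj + (k * n - k - n) * mse + n * f_l * msb)
    return ICCResult(
        estimate=float(estimate),
        ci_low=float(lo),
        ci_high=float(hi),
        model="two-way random, absolute agreement, single measures (ICC(A,1))",
        n_subjects=n,
        n_raters=k,
    )


def bland_altman(a, b, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman agreement of method a against reference method b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("a and b must be 1-D and the same length")
    n = len(a)
    if n < 3:
        raise InputError("need at least 3 paired measurements")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = float(stats.t.ppf(1 - alpha / 2, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    if sd == 0.0:
        t_stat, p_value, degenerate = np.nan, np.nan, True
    else:
        t_stat, p_value = stats.ttest_1samp(d, 0.0)
        degenerate = False
    return BlandAltmanResult(
        bias=bias,
        bias_ci=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa_low=loa_low,
        loa_high=loa_high,
        loa_low_ci=(loa_low - tcrit * se_loa, loa_low + tcrit * se_loa),
        loa_high_ci=(loa_high - tcrit * se_loa, loa_high + tcrit * se_loa),
        n=n,
        t_stat=float(t_stat),
        p_value=float(p_value),
        degenerate=degenerate,
    )


def bland_altman_plot_data(a, b) -> pd.DataFrame:
    """Per-site (mean, difference) pairs for regenerating the plots."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return pd.DataFrame({"mean_mm": 0.5 * (a + b), "difference_mm": a - b})


def adjust_p(p_values, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity adjustment (Bonferroni by default); monotone, capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method=method)[1]


def agreement_report(
    measurements: pd.DataFrame,
    deviations: pd.DataFrame | None = None,
    adjust_method: str = "bonferroni",
    kappa_threshold: float = 1.0,
) -> dict:
    """Full study-style analysis from a long measurements table.

    Expects columns site_id, method ("automated" or examiner ids), round,
    depth_mm, status.  Produces per examiner x round Bland-Altman blocks
    against the automated reference (with adjusted p-values), inter- and
    intra-examiner ICCs, and optional curvature stratification of deviations.
    """
    ok = measurements[measurements["status"] == "ok"]
    auto = ok[ok["method"] == "automated"].set_index("site_id")["depth_mm"]
    manual = ok[ok["method"] != "automated"]
    report: dict = {"n_sites_automated": int(len(auto)), "bland_altman": {}}

    blocks = []
    for (method, rnd), grp in manual.groupby(["method", "round"]):
        grp = grp.set_index("site_id")
        common = grp.index.intersection(auto.index)
        if len(common) < 3:
            continue
        blocks.append(((str(method), int(rnd)), grp.loc[common, "depth_mm"], auto.loc[common]))
    results = [bland_altman(a.to_numpy(), b.to_numpy()) for _, a, b in blocks]
    raw_p = [r.p_value for r in results]
    finite = np.isfinite(raw_p)
    adj = np.full(len(raw_p), np.nan)
    if finite.any():
        adj[finite] = adjust_p(np.asarray(raw_p)[finite], method=adjust_method)
    for ((method, rnd), _, _), res, p_adj in zip(blocks, results, adj):
        block = res.to_dict()
        block["p_adjusted"] = None if np.isnan(p_adj) else float(p_adj)
        report["bland_altman"][f"{method}|round{rnd}"] = block
    report["p_adjust_method"] = adjust_method

    # inter-examiner ICC per round, intra-examiner ICC per method
    report["icc"] = {"inter_examiner": {}, "intra_examiner": {}}
    wide = manual.pivot_table(index="site_id", columns=["method", "round"], values="depth_mm")
    for rnd in sorted(manual["round"].unique()):
        cols = [c for c in wide.columns if c[1] == rnd]
        table = wide[cols].dropna()
        if len(cols) >= 2 and len(table) >= 3:
            report["icc"]["inter_examiner"][f"round{rnd}"] = icc(table).to_dict()
    for method in sorted(manual["method"].unique()):
        cols = [c for c in wide.columns if c[0] == method]
        table = wide[cols].dropna()
        if len(cols) >= 2 and len(table) >= 3:
            report["icc"]["intra_examiner"][str(method)] = icc(table).to_dict()

    if deviations is not None and len(deviations):
        strat = threshold_stratify(deviations, kappa_threshold=kappa_threshold)
        strat.pop("scatter")
        report["curvature_stratification"] = strat
    return report


def threshold_stratify(deviations: pd.DataFrame, kappa_threshold: float = 1.0) -> dict:
    """Split deviation records at a curvature-magnitude threshold.

    Expects columns deviation_mm and reference_kappa_per_mm.  Returns per
    stratum n, median |deviation|, IQR and 95th percentile, plus the
    (|kappa|, deviation) scatter table.
    """
    if "deviation_mm" not in deviations or "reference_kappa_per_mm" not in deviations:
        raise InputError("need deviation_mm and reference_kappa_per_mm columns")
    abs_kappa = deviations["reference_kappa_per_mm"].abs()
    out = {"kappa_threshold_per_mm": float(kappa_threshold), "strata": {}}
    for name, mask in (
        ("below", abs_kappa < kappa_threshold),
        ("above", abs_kappa >= kappa_threshold),
    ):
        sub = deviations.loc[mask, "deviation_mm"].abs()
        if len(sub) == 0:
            out["strata"][name] = {"n": 0}
            continue
        q1, q3 = np.percentile(sub, [25, 75])
        out["strata"][name] = {
            "n": int(len(sub)),
            "median_abs_deviation_mm": float(sub.median()),
            "iqr_mm": (float(q1), float(q3)),
            "p95_abs_deviation_mm": float(np.percentile(sub, 95)),
        }
    out["scatter"] = pd.DataFrame(
        {
            "abs_kappa_per_mm": abs_kappa.to_numpy(),
            "deviation_mm": deviations["deviation_mm"].to_numpy(),
        }
    )
    return out
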