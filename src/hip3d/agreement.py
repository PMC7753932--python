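"""Method-comparison statistics: Pearson r, paired differences,
Bland–Altman limits of agreement, and the intraclass correlation
coefficient (two-way random effects, absolute agreement, single
measurement — ICC(2,1)), with its F-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import PARAMETERS


@dataclass
class AgreementReport:
    parameter: str
    n: int
    r: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff: float
    sd_diff: float
    abs_mean_diff: float
    abs_sd_diff: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (-1 - 1e-9 <= self.r <= 1 + 1e-9):
            raise ValueError("Pearson r outside [-1, 1]")
        if not (self.ba_loa_low - 1e-9 <= self.ba_bias <= self.ba_loa_high + 1e-9):
            raise ValueError("Bland-Altman bias outside its limits of agreement")


def _as_pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("paired series must have equal length")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-test p-value."""
    x, y = _as_pair(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paired_differences(x, y) -> dict:
    """Signed and absolute summaries of the elementwise differences x - y."""
    x, y = _as_pair(x, y)
    d = x - y
    ad = np.abs(d)
    ddof = 1 if len(d) > 1 else 0
    return {
        "mean_diff": float(d.mean()),
        "sd_diff": float(d.std(ddof=ddof)),
        "range_diff": (float(d.min()), float(d.max())),
        "abs_mean_diff": float(ad.mean()),
        "abs_sd_diff": float(ad.std(ddof=ddof)),
        "range_abs_diff": (float(ad.min()), float(ad.max())),
    }


def bland_altman(x, y) -> dict:
    """Bias and 1.96-SD limits of agreement, plus the plotting table."""
    x, y = _as_pair(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "table": pd.DataFrame({"mean": (x + y) / 2.0, "diff": d}),
    }


def icc_absolute_agreement(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float], dict]:
    """ICC(2,1) for two fixed methods with its F-based 95% CI.

    Two-way random-effects ANOVA decomposition (subjects x methods),
    absolute agreement, single measurement.  Negative point estimates
    are clamped to 0 and flagged; an all-identical degenerate input
    returns ICC 1 with a degenerate-CI flag.
    """
    x, y = _as_pair(x, y)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 pairs for the ICC")
    data = np.column_stack([x, y])
    k = 2
    gm = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - gm) ** 2).sum()
    ss_rows = k * ((row_means - gm) ** 2).sum()
    ss_cols = n * ((col_means - gm) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    flags: dict = {}
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(ss_total, 0.0):
        flags["degenerate"] = "no variance in the data"
        return 1.0, (float("nan"), float("nan")), flags
    icc = (msr - mse) / denom
    if icc < 0:
        flags["negative_estimate_clamped"] = float(icc)
        icc = 0.0
    if mse <= 0:
        flags["degenerate_ci"] = "zero residual variance"
        return float(icc), (float(icc), float(icc)), flags
    # F-based CI (McGraw & Wong, case 2-1 absolute agreement)
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper)), flags


def agreement_report(x, y, parameter: str = "") -> AgreementReport:
    """All agreement statistics for one paired series."""
    x, y = _as_pair(x, y)
    flags: dict = {}
    try:
        r, p = pearson(x, y)
    except ValueError as exc:
        flags["pearson_error"] = str(exc)
        r, p = (1.0, float("nan")) if np.allclose(x, y) else (float("nan"),) * 2
    d = paired_differences(x, y)
    ba = bland_altman(x, y)
    icc, (lo, hi), icc_flags = icc_absolute_agreement(x, y)
    flags.update(icc_flags)
    return AgreementReport(
        parameter=parameter, n=len(x), r=r, p_value=p,
        mean_a=float(np.mean(x)), sd_a=float(np.std(x, ddof=1)),
        mean_b=float(np.mean(y)), sd_b=float(np.std(y, ddof=1)),
        mean_diff=d["mean_diff"], sd_diff=d["sd_diff"],
        abs_mean_diff=d["abs_mean_diff"], abs_sd_diff=d["abs_sd_diff"],
        ba_bias=ba["bias"], ba_loa_low=ba["loa_low"], ba_loa_high=ba["loa_high"],
        icc=icc, icc_ci_low=lo, icc_ci_high=hi, flags=flags,
    )


def compare_reports(reports_a: dict, reports_b: dict,
                    parameters=PARAMETERS) -> pd.DataFrame:
    """Per-parameter agreement table between two report sets.

    ``reports_a`` / ``reports_b`` map hip id to a
    :class:`~hip3d.morphometry.MorphometryReport` (or any object with
    the parameter attributes).  Hips are matched by id; a hip missing
    from one set raises with the offending id.
    """
    ids = sorted(reports_a)
    missing = [i for i in ids if i not in reports_b] + \
        [i for i in sorted(reports_b) if i not in reports_a]
    if missing:
        raise ValueError(f"hip id(s) missing from one report set: {missing}")
    rows = []
    for p in parameters:
        a = [getattr(reports_a[i], p) for i in ids]
        b = [getattr(reports_b[i], p) for i in ids]
        rows.append(agreement_report(a, b, parameter=p).__dict__)
    df = pd.DataFrame(rows).drop(columns="flags")
    return df
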