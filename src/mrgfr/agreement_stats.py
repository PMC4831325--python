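"""Cohort-level agreement between MR-GFR estimates and a reference GFR.

Ordinary least-squares regression of MR-GFR on the reference values,
Bland-Altman bias and limits of agreement, and a per-method summary table
(range, mean +/- SD, agreement statistics) mirroring the usual reporting
layout of method-comparison studies.

The limits of agreement are ``bias +/- 2 SD`` of the differences (sample
SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_fitting import FitResult, HctMode, Method

__all__ = ["AgreementStats", "linear_regression", "bland_altman", "summarize_cohort", "format_summary"]


class StatsError(ValueError):
    """Invalid input to an agreement-statistics computation."""


@dataclass(frozen=True)
class AgreementStats:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def _paired(ref, mr) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    mr = np.asarray(mr, dtype=float)
    if ref.shape != mr.shape or ref.ndim != 1:
        raise StatsError("ref and mr must be 1-D arrays of equal length")
    if ref.size < 3:
        raise StatsError("need at least 3 paired measurements")
    return ref, mr


def linear_regression(ref, mr) -> tuple[float, float, float, float]:
    """OLS of MR-GFR on reference GFR.

    Returns ``(slope, intercept, r_squared, p_value)`` with a two-sided p
    for the slope differing from zero.
    """
    ref, mr = _paired(ref, mr)
    if np.ptp(ref) == 0:
        raise StatsError("reference values have zero variance")
    res = stats.linregress(ref, mr)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def bland_altman(ref, mr) -> tuple[float, float, float]:
    """Mean difference (MR - ref) and bias +/- 2 SD limits of agreement."""
    ref, mr = _paired(ref, mr)
    d = mr - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 2.0 * sd, bias + 2.0 * sd


def agreement(ref, mr) -> AgreementStats:
    """Regression plus Bland-Altman statistics for one method."""
    slope, intercept, r2, p = linear_regression(ref, mr)
    bias, lo, hi = bland_altman(ref, mr)
    return AgreementStats(slope, intercept, r2, p, bias, lo, hi, n=len(np.asarray(ref)))


def summarize_cohort(results: list[FitResult], ref) -> pd.DataFrame:
    """Per-method x Hct-mode summary table with agreement statistics.

    ``results`` holds one kidney ``FitResult`` per subject for each
    (method, hct_mode) cell, carrying ``subject_id`` in its provenance;
    ``ref`` maps to subjects in sorted subject-id order. Every observed
    method x hct_mode combination must be complete.
    """
    ref = np.asarray(ref, dtype=float)
    rows = []
    for r in results:
        if r.gfr_ml_min is None or r.method is None or r.hct_mode is None:
            raise StatsError("summarize_cohort needs kidney fits with method and hct_mode")
        rows.append(
            {
                "subject_id": r.provenance.get("subject_id"),
                "method": Method(r.method).value,
                "hct_mode": HctMode(r.hct_mode).value,
                "gfr_ml_min": r.gfr_ml_min,
                "fit_r_squared": r.r_squared,
            }
        )
    df = pd.DataFrame(rows)
    methods = sorted(df["method"].unique())
    modes = sorted(df["hct_mode"].unique())
    missing = [
        (mo, me)
        for mo in modes
        for me in methods
        if df[(df.method == me) & (df.hct_mode == mo)].empty
    ]
    if missing:
        raise StatsError(f"empty summary cells: {missing}")

    out = []
    for mo in modes:
        for me in methods:
            cell = df[(df.method == me) & (df.hct_mode == mo)].sort_values("subject_id")
            g = cell["gfr_ml_min"].to_numpy()
            if g.size != ref.size:
                raise StatsError(
                    f"cell ({mo}, {me}) has {g.size} subjects but {ref.size} reference values"
                )
            if ref.size >= 3:
                ag = agreement(ref, g)
            else:  # too few subjects for regression; report ranges only
                nan = float("nan")
                ag = AgreementStats(nan, nan, nan, nan, nan, nan, nan, n=int(ref.size))
            out.append(
                {
                    "hct_mode": mo,
                    "method": me,
                    "n": ag.n,
                    "gfr_min": float(g.min()),
                    "gfr_max": float(g.max()),
                    "gfr_mean": float(g.mean()),
                    "gfr_sd": float(g.std(ddof=1)) if g.size > 1 else 0.0,
                    "slope": ag.slope,
                    "intercept": ag.intercept,
                    "r_squared": ag.r_squared,
                    "p_value": ag.p_value,
                    "bias": ag.bias,
                    "loa_low": ag.loa_low,
                    "loa_high": ag.loa_high,
                    "min_fit_r_squared": float(cell["fit_r_squared"].min()),
                }
            )
    return pd.DataFrame(out)


def format_summary(summary: pd.DataFrame, ref=None) -> str:
    """Plain-text report of the summary table, one row per model variant."""
    lines = ["GFR method comparison (mL/min)", "=" * 64]
    if ref is not None:
        ref = np.asarray(ref, dtype=float)
        lines.append(
            f"{'reference':>22}: range {ref.min():6.1f}-{ref.max():6.1f}  "
            f"mean {ref.mean():6.1f} +/- {ref.std(ddof=1):5.1f}"
        )
    for _, row in summary.iterrows():
        lines.append(
            f"{row.method:>12}/{row.hct_mode:<9}: range {row.gfr_min:6.1f}-{row.gfr_max:6.1f}  "
            f"mean {row.gfr_mean:6.1f} +/- {row.gfr_sd:5.1f}  "
            f"R2 {row.r_squared:5.3f}  bias {row.bias:6.1f} "
            f"[{row.loa_low:6.1f}, {row.loa_high:6.1f}]"
        )
    return "\n".join(lines)
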