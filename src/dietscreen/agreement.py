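"""Method-comparison statistics between paired FFQ and SDQ outputs.

The agreement analysis treats the long FFQ as one measurement method and the
short questionnaire as the other, on the same respondents:

* Bland–Altman: per-pair difference d_i = FFQ_i − SDQ_i against the per-pair
  mean m_i = (FFQ_i + SDQ_i)/2; limits of agreement are the mean difference
  ± 2·SD (sample SD, n−1 denominator; the multiplier is exactly 2 by
  convention here, not 1.96, and is configurable).
* Proportional bias: ordinary least squares of d on m with classical
  normal-theory two-sided t inference on the slope and a 95% CI.
* Pearson correlations per food group, stratified by age (<80 vs ≥80 years),
  with p from t = r·sqrt((n−2)/(1−r²)) on n−2 df and a "negligible" flag for
  r below the reporting threshold (0.30).

All formulas are evaluated directly; tests cross-check them against
scipy/statsmodels as independent oracles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ffq_pipeline import DailyServesProfile
from .instruments import FoodGroup, ReportingThresholds
from .scoring import DietScore

logger = logging.getLogger("dietscreen")

__all__ = [
    "AgreementResult",
    "CorrelationResult",
    "paired_scores",
    "bland_altman",
    "pearson",
    "stratified_correlations",
    "correlations_to_frame",
    "bland_altman_plot",
]

STRATA = ("under_80", "80_plus", "all")


@dataclass
class AgreementResult:
    """Bland–Altman summary with bias regression (difference = FFQ − SDQ)."""

    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    multiplier: float
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    slope_p: float
    slope_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "multiplier": self.multiplier,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci_low": self.slope_ci_low,
            "slope_ci_high": self.slope_ci_high,
            "slope_p": self.slope_p,
            "slope_defined": self.slope_defined,
        }


@dataclass
class CorrelationResult:
    group: str
    stratum: str
    n: int
    r: float
    p: float
    negligible: bool


def paired_scores(
    scores_ffq: Sequence[DietScore], scores_sdq: Sequence[DietScore]
) -> pd.DataFrame:
    """Inner-join totals on respondent_id; log how many were excluded."""
    a = {s.respondent_id: s.total for s in scores_ffq}
    b = {s.respondent_id: s.total for s in scores_sdq}
    shared = [rid for rid in a if rid in b]  # preserves FFQ order
    excluded = (len(a) - len(shared)) + (len(b) - len(shared))
    if excluded:
        logger.warning("paired_scores: %d respondents lacked a pair and were excluded", excluded)
    if not shared:
        raise ValueError("no overlapping respondents between the two score sets")
    return pd.DataFrame(
        {
            "respondent_id": shared,
            "ffq_total": [a[r] for r in shared],
            "sdq_total": [b[r] for r in shared],
        }
    )


def bland_altman(
    ffq: Sequence[float],
    sdq: Sequence[float],
    multiplier: float = 2.0,
    alpha: float = 0.05,
) -> AgreementResult:
    """Bland–Altman agreement of two paired measurement series.

    Differences are FFQ − SDQ.  Limits of agreement are
    mean ± multiplier × SD (n−1).  The bias regression fits
    difference = slope × pair-mean + intercept by ordinary least squares;
    if the pair means have zero variance the slope is undefined and the
    result is flagged degenerate.
    """
    x = np.asarray(ffq, dtype=float)
    y = np.asarray(sdq, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("at least 3 pairs required")
    d = x - y
    m = (x + y) / 2.0
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    loa_lower = mean_diff - multiplier * sd_diff
    loa_upper = mean_diff + multiplier * sd_diff

    sxx = float(np.sum((m - m.mean()) ** 2))
    if sxx == 0.0:
        logger.warning("bland_altman: zero variance of pair means; slope undefined")
        return AgreementResult(
            n_pairs=n, mean_diff=mean_diff, sd_diff=sd_diff,
            loa_lower=loa_lower, loa_upper=loa_upper, multiplier=multiplier,
            slope=float("nan"), intercept=float("nan"),
            slope_ci_low=float("nan"), slope_ci_high=float("nan"),
            slope_p=float("nan"), slope_defined=False,
        )
    sxy = float(np.sum((m - m.mean()) * (d - d.mean())))
    slope = sxy / sxx
    intercept = float(d.mean() - slope * m.mean())
    resid = d - (intercept + slope * m)
    dof = n - 2
    s2 = float(np.sum(resid**2)) / dof if dof > 0 else float("nan")
    se = math.sqrt(s2 / sxx)
    tcrit = float(stats.t.ppf(1 - alpha / 2, dof))
    if se > 0:
        tstat = slope / se
        p = 2.0 * float(stats.t.sf(abs(tstat), dof))
    else:
        p = 0.0 if slope != 0 else 1.0
    return AgreementResult(
        n_pairs=n, mean_diff=mean_diff, sd_diff=sd_diff,
        loa_lower=loa_lower, loa_upper=loa_upper, multiplier=multiplier,
        slope=float(slope), intercept=intercept,
        slope_ci_low=float(slope - tcrit * se), slope_ci_high=float(slope + tcrit * se),
        slope_p=p, slope_defined=True,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t distribution.

    Returns (nan, nan) when either input is constant (r undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("inputs must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("at least 3 observations required")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = math.sqrt(float(np.sum(xc**2)))
    sy = math.sqrt(float(np.sum(yc**2)))
    if sx == 0.0 or sy == 0.0:
        logger.warning("pearson: constant input, correlation undefined")
        return float("nan"), float("nan")
    r = float(np.sum(xc * yc)) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


def _pairwise(
    ffq: dict[str, float], sdq: dict[str, float], ids: Sequence[str]
) -> tuple[list[float], list[float]]:
    xs, ys = [], []
    for rid in ids:
        a, b = ffq.get(rid), sdq.get(rid)
        if a is None or b is None or math.isnan(a) or math.isnan(b):
            continue
        xs.append(a)
        ys.append(b)
    return xs, ys


def stratified_correlations(
    profiles_ffq: Sequence[DailyServesProfile],
    profiles_sdq: Sequence[DailyServesProfile],
    thresholds: Optional[ReportingThresholds] = None,
) -> list[CorrelationResult]:
    """Per-group Pearson correlations, stratified by age.

    Ages come from the FFQ profiles.  Strata are <cut, ≥cut (default 80
    years) and the pooled cohort.  Within each group × stratum only
    pairwise-complete respondents enter; strata with fewer than 3 complete
    pairs are emitted with undefined r and flagged negligible=False.
    """
    th = thresholds or ReportingThresholds()
    ages = {p.respondent_id: p.age_years for p in profiles_ffq}
    shared = [p.respondent_id for p in profiles_ffq
              if p.respondent_id in {q.respondent_id for q in profiles_sdq}]
    if not shared:
        raise ValueError("no overlapping respondents")
    strata_ids = {
        "under_80": [r for r in shared if ages[r] is not None and ages[r] < th.age_cut_years],
        "80_plus": [r for r in shared if ages[r] is not None and ages[r] >= th.age_cut_years],
        "all": shared,
    }
    groups = [g for g in FoodGroup
              if any(g in p.serves for p in profiles_ffq)
              and any(g in p.serves for p in profiles_sdq)]
    ffq_by = {g: {p.respondent_id: p.serves.get(g, float("nan")) for p in profiles_ffq}
              for g in groups}
    sdq_by = {g: {p.respondent_id: p.serves.get(g, float("nan")) for p in profiles_sdq}
              for g in groups}
    out: list[CorrelationResult] = []
    for g in groups:
        for stratum in STRATA:
            xs, ys = _pairwise(ffq_by[g], sdq_by[g], strata_ids[stratum])
            if len(xs) < 3:
                logger.warning(
                    "stratified_correlations: %s/%s has %d complete pairs (<3)",
                    g.value, stratum, len(xs),
                )
                out.append(CorrelationResult(g.value, stratum, len(xs),
                                             float("nan"), float("nan"), False))
                continue
            r, p = pearson(xs, ys)
            negligible = (not math.isnan(r)) and abs(r) < th.negligible_r
            out.append(CorrelationResult(g.value, stratum, len(xs), r, p, negligible))
    return out


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in results])


def bland_altman_plot(
    ffq: Sequence[float],
    sdq: Sequence[float],
    result: AgreementResult,
    path,
    title: str = "Bland–Altman: FFQ vs SDQ total scores",
) -> None:
    """Scatter of difference vs pair mean with mean line, LOA and the bias
    regression line, written to ``path`` (format from the extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(ffq, dtype=float)
    y = np.asarray(sdq, dtype=float)
    m = (x + y) / 2.0
    d = x - y
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(m, d, s=18, alpha=0.6, edgecolor="none")
    ax.axhline(result.mean_diff, color="k",
               label=f"mean diff = {result.mean_diff:.2f}")
    ax.axhline(result.loa_upper, color="k", linestyle=":",
               label=f"LOA = ({result.loa_lower:.2f}, {result.loa_upper:.2f})")
    ax.axhline(result.loa_lower, color="k", linestyle=":")
    if result.slope_defined:
        grid = np.linspace(m.min(), m.max(), 50)
        ax.plot(grid, result.intercept + result.slope * grid, color="C3",
                label=f"y = {result.slope:.2f}x {result.intercept:+.2f}")
    ax.set_xlabel("Mean of FFQ and SDQ total scores")
    ax.set_ylabel("Difference (FFQ − SDQ)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
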