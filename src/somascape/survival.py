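"""Kaplan-Meier curves, median OS, and log-rank group comparison.

Times are follow-up months; an event is death (Alive = right-censored).
KM curves and KM medians come from lifelines; the log-rank statistic is
computed here in the standard observed-vs-expected form so the
Mantel-Haenszel-style hazard ratio HR = (O_A/E_A)/(O_B/E_B) — which
lifelines does not expose — shares the same event tables. At a tied time,
deaths are processed before censorings (the usual convention).

Two "median OS" conventions circulate in clinical reports: the KM median
(first time the survival estimate drops to <= 0.5, undefined if it never
does) and the plain median of observed follow-up times, which ignores
censoring. Group comparisons report both rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import chi2

from .landscape import GeneSampleMatrix


@dataclass
class KMCurve:
    times: np.ndarray          # step times (event times)
    survival: np.ndarray       # S(t) after each step, non-increasing from 1
    median: float              # KM median; NaN when S never reaches 0.5
    n: int


@dataclass
class SurvivalComparison:
    n_a: int
    n_b: int
    observed: tuple[float, float]    # (O_A, O_B)
    expected: tuple[float, float]    # (E_A, E_B)
    chi_square: float
    p_value: float
    hazard_ratio: float              # (O_A/E_A)/(O_B/E_B)
    defined: bool                    # False when there are no events at all
    curve_a: KMCurve | None = None
    curve_b: KMCurve | None = None
    km_medians: tuple[float, float] | None = None
    plain_medians: tuple[float, float] | None = None


def km_curve(times, events) -> KMCurve:
    """Product-limit survival estimate with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("need at least one record")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.sort(np.unique(times[events]))
    surv = kmf.survival_function_at_times(event_times).to_numpy() if len(event_times) else np.array([])
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return KMCurve(event_times, surv, median, n=len(times))


def _logrank_oe(times_a, events_a, times_b, events_b):
    """O, E and hypergeometric variance for group A over pooled event times."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    # at-risk counts: everyone with time >= t (deaths at t counted at risk at t)
    n_a = (ta[None, :] >= event_times[:, None]).sum(axis=1).astype(float)
    n_b = (tb[None, :] >= event_times[:, None]).sum(axis=1).astype(float)
    d_a = ((ta[None, :] == event_times[:, None]) & ea[None, :]).sum(axis=1).astype(float)
    d_b = ((tb[None, :] == event_times[:, None]) & eb[None, :]).sum(axis=1).astype(float)
    n_tot = n_a + n_b
    d_tot = d_a + d_b
    e_a = d_tot * n_a / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n_tot > 1,
            d_tot * (n_a / n_tot) * (n_b / n_tot) * (n_tot - d_tot) / (n_tot - 1),
            0.0,
        )
    return float(d_a.sum()), float(e_a.sum()), float(var.sum()), float(d_b.sum()), float(d_tot.sum() - e_a.sum())


def logrank_compare(times_a, events_a, times_b, events_b, curves: bool = True) -> SurvivalComparison:
    """Two-group log-rank test with O/E-ratio hazard ratio.

    chi-square = (O_A - E_A)^2 / V with V the summed hypergeometric
    variance; p is two-sided from the 1-df chi-square distribution.
    With zero events overall the comparison is flagged undefined.
    """
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    o_a, e_a, var, o_b, e_b = _logrank_oe(times_a, events_a, times_b, events_b)
    if o_a + o_b == 0:
        return SurvivalComparison(len(times_a), len(times_b), (0.0, 0.0), (0.0, 0.0),
                                  float("nan"), float("nan"), float("nan"), defined=False)
    if var > 0:
        stat = (o_a - e_a) ** 2 / var
        p = float(chi2.sf(stat, df=1))
    else:  # identical groups or a single shared event pattern
        stat, p = 0.0, 1.0
    if e_a > 0 and e_b > 0 and o_b > 0:
        hr = (o_a / e_a) / (o_b / e_b)
    else:
        hr = float("inf") if o_a > 0 and o_b == 0 else float("nan")
    cmp = SurvivalComparison(len(times_a), len(times_b), (o_a, o_b), (e_a, e_b),
                             float(stat), p, float(hr), defined=True)
    if curves:
        cmp.curve_a = km_curve(times_a, events_a)
        cmp.curve_b = km_curve(times_b, events_b)
        cmp.km_medians = (cmp.curve_a.median, cmp.curve_b.median)
    return cmp


def compare_by_feature(
    clinical: pd.DataFrame,
    matrix: GeneSampleMatrix | pd.DataFrame,
    feature: str,
) -> SurvivalComparison:
    """Compare OS between feature-positive and feature-negative samples.

    ``matrix`` is a gene x sample indicator (mutation or CNV status);
    group A = carriers of ``feature``, group B = non-carriers. Both KM
    medians and plain medians of observed times are reported.
    """
    mat = matrix.matrix if isinstance(matrix, GeneSampleMatrix) else matrix
    if feature not in mat.index:
        raise ValueError(f"feature {feature!r} absent from matrix")
    clin = clinical.set_index("sample_id")
    missing = [s for s in mat.columns if s not in clin.index]
    if missing:
        raise ValueError(f"samples without clinical records: {missing[:5]}")
    carrier = mat.loc[feature] > 0
    pos = [s for s in mat.columns if carrier[s]]
    neg = [s for s in mat.columns if not carrier[s]]
    if not pos or not neg:
        raise ValueError(f"feature {feature!r} does not split the cohort into two groups")
    ta = clin.loc[pos, "months"].to_numpy(float)
    tb = clin.loc[neg, "months"].to_numpy(float)
    ea = (clin.loc[pos, "status"] == "Dead").to_numpy()
    eb = (clin.loc[neg, "status"] == "Dead").to_numpy()
    cmp = logrank_compare(ta, ea, tb, eb)
    cmp.plain_medians = (float(np.median(ta)), float(np.median(tb)))
    return cmp
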