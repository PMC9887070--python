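"""Average annual percent change (AAPC) with joinpoint-style segment selection.

A rate series is modelled as piecewise log-linear in calendar year, fit as
a Poisson regression on counts with a log person-years offset and
continuity at the breakpoints. Breakpoint placement is an exhaustive grid
search over interior integer years; the number of joinpoints is chosen by
BIC. The AAPC over an interval is the segment-length-weighted combination

    AAPC = 100 * (exp(sum_j w_j beta_j) - 1),

where beta_j is segment j's slope on the log-rate scale and w_j the
fraction of the interval it covers. Confidence intervals are large-sample
normal on the log scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_tables import ValidationError

__all__ = [
    "SegmentedFit",
    "TrendEstimate",
    "fit_segmented_loglinear",
    "aapc",
    "area_aapc",
    "national_aapc",
]

MIN_SEGMENT_SPAN = 2  # year-intervals per segment, i.e. >= 3 calendar years


@dataclass
class SegmentedFit:
    """A fitted continuous piecewise log-linear trend."""

    years: np.ndarray          # observed years, strictly increasing
    breakpoints: list[int]     # interior breakpoint years (may be empty)
    slopes: np.ndarray         # per-segment log-rate slope per year
    slope_cov: np.ndarray      # covariance of the per-segment slopes
    deviance: float
    bic: float
    n_params: int

    @property
    def segment_bounds(self) -> list[tuple[int, int]]:
        edges = [int(self.years[0])] + list(self.breakpoints) + [int(self.years[-1])]
        return list(zip(edges[:-1], edges[1:]))


@dataclass
class TrendEstimate:
    """AAPC over an interval with CI and segment bookkeeping."""

    aapc: float
    ci_low: float
    ci_high: float
    interval: tuple[int, int]
    breakpoints: list[int]
    slopes: np.ndarray
    weights: np.ndarray
    se_log: float = float("nan")  # SE of the interval-weighted log slope
    estimable: bool = True
    area_id: str | None = None
    stratum: dict = field(default_factory=dict)


def _design(t: np.ndarray, t0: float, breaks: list[int]) -> np.ndarray:
    cols = [np.ones_like(t, dtype=float), t - t0]
    for k in breaks:
        cols.append(np.clip(t - k, 0.0, None))
    return np.column_stack(cols)


def _fit_one(years, counts, offset_log, breaks):
    X = _design(years, years[0], breaks)
    model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset_log)
    res = model.fit()
    bic = -2.0 * res.llf + X.shape[1] * np.log(len(years))
    return res, bic


def _candidate_breaksets(years: np.ndarray, m: int) -> list[tuple[int, ...]]:
    y0, y1 = int(years[0]), int(years[-1])
    interior = range(y0 + MIN_SEGMENT_SPAN, y1 - MIN_SEGMENT_SPAN + 1)
    out = []
    for combo in itertools.combinations(interior, m):
        if all(b - a >= MIN_SEGMENT_SPAN for a, b in zip(combo[:-1], combo[1:])):
            out.append(combo)
    return out


def fit_segmented_loglinear(years, counts, person_years,
                            max_joinpoints: int = 2) -> SegmentedFit:
    """Fit the best piecewise Poisson log-linear trend by BIC.

    For each candidate number of joinpoints 0..max, every admissible
    placement of integer-year breakpoints (segments at least 3 calendar
    years long) is fit; the placement with the lowest deviance wins for
    that size, and BIC arbitrates across sizes.
    """
    years = np.asarray(years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    py = np.asarray(person_years, dtype=float)
    if not (np.diff(years) > 0).all():
        raise ValidationError("years must be strictly increasing")
    if (counts < 0).any() or (py <= 0).any():
        raise ValidationError("counts must be >= 0 and person-years > 0")
    n_min = 2 * (max_joinpoints + 1) + 1
    if len(years) < n_min:
        raise ValidationError(
            f"series too short: need >= {n_min} years for {max_joinpoints} joinpoints"
        )
    offset_log = np.log(py)

    best = None
    for m in range(max_joinpoints + 1):
        best_m = None
        for breaks in _candidate_breaksets(years, m):
            res, bic = _fit_one(years, counts, offset_log, list(breaks))
            if best_m is None or res.deviance < best_m[1].deviance:
                best_m = (list(breaks), res, bic)
        if best_m is None:
            continue
        if best is None or best_m[2] < best[2]:
            best = best_m
    breaks, res, bic = best

    # Segment slopes are cumulative sums of the hinge coefficients.
    p = len(res.params)
    L = np.zeros((len(breaks) + 1, p))
    for j in range(len(breaks) + 1):
        L[j, 1] = 1.0
        L[j, 2: 2 + j] = 1.0
    slopes = L @ res.params
    slope_cov = L @ res.cov_params() @ L.T
    return SegmentedFit(
        years=years, breakpoints=breaks, slopes=np.asarray(slopes),
        slope_cov=np.asarray(slope_cov), deviance=float(res.deviance),
        bic=float(bic), n_params=p,
    )


def aapc(fit: SegmentedFit, interval: tuple[int, int] | None = None,
         alpha: float = 0.05) -> TrendEstimate:
    """Length-weighted AAPC over ``interval`` from a segmented fit."""
    if interval is None:
        interval = (int(fit.years[0]), int(fit.years[-1]))
    y0, y1 = interval
    if y1 <= y0:
        raise ValidationError(f"empty interval {interval}")
    if y0 < fit.years[0] or y1 > fit.years[-1]:
        raise ValidationError(f"interval {interval} outside fitted range")
    total = float(y1 - y0)
    weights = np.array([
        max(0.0, min(e, y1) - max(s, y0)) / total for s, e in fit.segment_bounds
    ])
    log_aapc = float(weights @ fit.slopes)
    se = float(np.sqrt(weights @ fit.slope_cov @ weights))
    from scipy.stats import norm
    z = norm.ppf(1 - alpha / 2)
    return TrendEstimate(
        aapc=100.0 * (np.exp(log_aapc) - 1.0),
        ci_low=100.0 * (np.exp(log_aapc - z * se) - 1.0),
        ci_high=100.0 * (np.exp(log_aapc + z * se) - 1.0),
        interval=interval, breakpoints=list(fit.breakpoints),
        slopes=fit.slopes.copy(), weights=weights, se_log=se,
    )


def _series_from_tables(incidence: pd.DataFrame, person_years: pd.DataFrame,
                        stratum: dict, area_id: str | None,
                        interval: tuple[int, int] | None):
    inc = incidence
    for k, v in stratum.items():
        if k in inc.columns:
            inc = inc[inc[k] == v]
    pyt = person_years[person_years["sex"] == stratum["sex"]] \
        if "sex" in stratum else person_years
    if area_id is not None:
        inc = inc[inc["area_id"] == area_id]
        pyt = pyt[pyt["area_id"] == area_id]
    if interval is not None:
        inc = inc[(inc["year"] >= interval[0]) & (inc["year"] <= interval[1])]
        pyt = pyt[(pyt["year"] >= interval[0]) & (pyt["year"] <= interval[1])]
    O = inc.groupby("year")["count"].sum()
    P = pyt.groupby("year")["person_years"].sum()
    years = np.array(sorted(P.index))
    counts = np.array([O.get(y, 0) for y in years], dtype=float)
    py = np.array([P[y] for y in years], dtype=float)
    return years, counts, py


def area_aapc(incidence: pd.DataFrame, person_years: pd.DataFrame,
              stratum: dict, area_id: str,
              interval: tuple[int, int] | None = None,
              max_joinpoints: int = 1) -> TrendEstimate:
    """Per-area AAPC; areas with no cases over the interval are flagged
    unestimable rather than fit."""
    years, counts, py = _series_from_tables(
        incidence, person_years, stratum, area_id, interval)
    if counts.sum() < 1:
        return TrendEstimate(
            aapc=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            interval=(int(years[0]), int(years[-1])) if len(years) else (0, 0),
            breakpoints=[], slopes=np.array([]), weights=np.array([]),
            estimable=False, area_id=area_id, stratum=dict(stratum),
        )
    fit = fit_segmented_loglinear(years, counts, py, max_joinpoints=max_joinpoints)
    est = aapc(fit, interval=(int(years[0]), int(years[-1])))
    est.area_id = area_id
    est.stratum = dict(stratum)
    return est


def national_aapc(incidence: pd.DataFrame, person_years: pd.DataFrame,
                  stratum: dict, interval: tuple[int, int] | None = None,
                  max_joinpoints: int = 2) -> TrendEstimate:
    """AAPC of the whole-registry series for one stratum."""
    years, counts, py = _series_from_tables(
        incidence, person_years, stratum, None, interval)
    fit = fit_segmented_loglinear(years, counts, py, max_joinpoints=max_joinpoints)
    est = aapc(fit, interval=(int(years[0]), int(years[-1])))
    est.stratum = dict(stratum)
    return est
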