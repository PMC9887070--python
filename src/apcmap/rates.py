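"""Age-specific rates, direct (WHO 2000) standardization, expected counts and SIRs.

Two standardizations coexist in registry work and both live here:

* **direct** — the age-standardized rate ASR = sum_a w_a r_a with fixed
  standard-population weights w_a; comparable across populations and time
  but noisy when counts are small;
* **indirect** — the standardized incidence ratio SIR_i = O_i / E_i, where
  E_i applies reference age-specific rates to area i's person-years; stable
  enough for small areas, and the quantity the disease maps smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_tables import AgeGroup, ConfigError, ValidationError, make_age_groups

__all__ = [
    "StandardPopulation",
    "who_2000_standard",
    "age_specific_rates",
    "direct_asr",
    "asr_series",
    "standard_rates",
    "expected_counts",
    "sir",
    "sir_by_area",
    "histology_proportions",
]

PER = 100_000.0

# WHO World Standard population (2000), proportions per 5-year band 0-4 ... 85+.
_WHO2000_BANDS = list(range(0, 86, 5))
_WHO2000_WEIGHTS = [
    8.86, 8.69, 8.60, 8.47, 8.22, 7.93, 7.61, 7.15, 6.59,
    6.04, 5.37, 4.55, 3.72, 2.96, 2.21, 1.52, 0.91, 0.63,
]


@dataclass(frozen=True)
class StandardPopulation:
    """Per-age-group standard weights, normalized to sum to one."""

    age_groups: tuple[AgeGroup, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ConfigError("standard weights must be nonnegative")
        if len(w) != len(self.age_groups):
            raise ConfigError("weights and age groups differ in length")
        object.__setattr__(self, "weights", tuple(w / w.sum()))

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def who_2000_standard(age_groups: list[AgeGroup] | None = None) -> StandardPopulation:
    """WHO 2000 world-standard weights, re-normalized to the bands in use.

    With no argument, the full 18-band 0-4 ... 85+ standard is returned.
    Passing a restricted banding (e.g. the eleven 30-84 bands) re-normalizes
    the matching weights over that range.
    """
    if age_groups is None:
        age_groups = [
            AgeGroup(index=i, lower=lo, upper=(lo + 4) if lo < 85 else 99)
            for i, lo in enumerate(_WHO2000_BANDS)
        ]
        return StandardPopulation(tuple(age_groups), tuple(_WHO2000_WEIGHTS))
    by_lower = dict(zip(_WHO2000_BANDS, _WHO2000_WEIGHTS))
    weights = []
    for g in age_groups:
        if g.lower not in by_lower:
            raise ConfigError(f"age band {g} does not align with WHO 2000 5-year bands")
        weights.append(by_lower[g.lower])
    return StandardPopulation(tuple(age_groups), tuple(weights))


def age_specific_rates(counts, person_years, per: float = PER) -> np.ndarray:
    """Incidence rates per ``per`` person-years, age group by age group.

    A band with zero person-years and zero cases yields NaN (flagged
    missing); zero person-years with positive cases is a data error.
    """
    O = np.asarray(counts, dtype=float)
    P = np.asarray(person_years, dtype=float)
    if O.shape != P.shape:
        raise ValidationError("counts and person-years shapes differ")
    bad = (P <= 0) & (O > 0)
    if bad.any():
        raise ValidationError(
            f"positive counts with zero person-years in age group(s) {np.flatnonzero(bad).tolist()}"
        )
    rates = np.full(O.shape, np.nan)
    ok = P > 0
    rates[ok] = per * O[ok] / P[ok]
    return rates


def direct_asr(rates, std: StandardPopulation, person_years=None,
               alpha: float = 0.05, per: float = PER):
    """Directly standardized rate, variance, and gamma confidence interval.

    ASR = sum_a w_a r_a. The variance is the usual Poisson form
    sum_a w_a^2 r_a per / P_a (requires ``person_years``); the CI uses the
    gamma approximation on the standardized count scale.

    Returns ``(asr, variance, ci_low, ci_high)``; variance/CI are NaN when
    person-years are not supplied.
    """
    r = np.asarray(rates, dtype=float)
    w = std.weight_array
    if r.shape != w.shape:
        raise ValidationError("rates and standard weights differ in length")
    missing = np.isnan(r) & (w > 0)
    if missing.any():
        raise ValidationError(
            f"missing rates for weighted age group(s) {np.flatnonzero(missing).tolist()}"
        )
    r = np.where(np.isnan(r), 0.0, r)
    asr = float(np.sum(w * r))
    if person_years is None:
        return asr, float("nan"), float("nan"), float("nan")
    P = np.asarray(person_years, dtype=float)
    ok = P > 0
    var = float(np.sum(w[ok] ** 2 * r[ok] * per / P[ok]))
    if asr == 0.0 or var == 0.0:
        return asr, var, 0.0, 0.0 if asr == 0.0 else asr
    # Gamma interval (Fay-Feuer style) on the weighted-count scale.
    shape = asr ** 2 / var
    scale = var / asr
    lo = float(stats.gamma.ppf(alpha / 2, a=shape, scale=scale))
    wmax = float(np.max(w[ok] ** 2 * per / P[ok]))
    shape_hi = (asr + wmax) ** 2 / (var + wmax ** 2)
    scale_hi = (var + wmax ** 2) / (asr + wmax)
    hi = float(stats.gamma.ppf(1 - alpha / 2, a=shape_hi, scale=scale_hi))
    return asr, var, lo, hi


def asr_series(incidence: pd.DataFrame, person_years: pd.DataFrame,
               std: StandardPopulation, by=("sex", "histology")) -> pd.DataFrame:
    """Tidy per-year ASR table for each stratum in ``by``.

    Output columns: *by*, year, asr, ci_low, ci_high.
    """
    by = list(by)
    n_ages = len(std.age_groups)
    py = (person_years.groupby(["sex", "year", "age_group"], as_index=False)
          ["person_years"].sum())
    rows = []
    for key, grp in incidence.groupby(by + ["year"]):
        key = key if isinstance(key, tuple) else (key,)
        stratum = dict(zip(by + ["year"], key))
        O = np.zeros(n_ages)
        for _, r in grp.groupby("age_group", as_index=False)["count"].sum().iterrows():
            O[int(r["age_group"])] = r["count"]
        sel = (py["sex"] == stratum["sex"]) & (py["year"] == stratum["year"])
        P = np.zeros(n_ages)
        for _, r in py[sel].iterrows():
            if int(r["age_group"]) < n_ages:
                P[int(r["age_group"])] = r["person_years"]
        rates = age_specific_rates(O[: n_ages], P)
        asr, _, lo, hi = direct_asr(rates, std, person_years=P)
        rows.append({**stratum, "asr": asr, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows).sort_values(by + ["year"]).reset_index(drop=True)


def standard_rates(incidence: pd.DataFrame, person_years: pd.DataFrame,
                   years: tuple[int, int], by=("sex", "histology")) -> pd.DataFrame:
    """Reference age-specific rates pooled over a calendar window.

    These are the standard rates of the indirect method: the average
    age-specific incidence over ``years`` (inclusive), stratified by ``by``.
    Output columns: *by*, age_group, rate (cases per person-year).
    """
    by = list(by)
    y0, y1 = years
    inc = incidence[(incidence["year"] >= y0) & (incidence["year"] <= y1)]
    pyt = person_years[(person_years["year"] >= y0) & (person_years["year"] <= y1)]
    O = inc.groupby(by + ["age_group"], as_index=False)["count"].sum()
    P = (pyt.groupby(["sex", "age_group"], as_index=False)["person_years"].sum())
    merged = O.merge(P, on=["sex", "age_group"], how="left")
    if merged["person_years"].isna().any() or (merged["person_years"] <= 0).any():
        raise ValidationError("reference window lacks person-years for some strata")
    merged["rate"] = merged["count"] / merged["person_years"]
    return merged[by + ["age_group", "rate"]]


def expected_counts(person_years: pd.DataFrame, std_rates: pd.DataFrame,
                    stratum: dict, years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Expected cases per area: E_i = sum_a P_ia R_a for one stratum.

    ``std_rates`` must cover every age group present in the person-years.
    """
    pyt = person_years[person_years["sex"] == stratum["sex"]]
    if years is not None:
        pyt = pyt[(pyt["year"] >= years[0]) & (pyt["year"] <= years[1])]
    sr = std_rates
    for k, v in stratum.items():
        if k in sr.columns:
            sr = sr[sr[k] == v]
    rates = sr.set_index("age_group")["rate"]
    P = pyt.groupby(["area_id", "age_group"], as_index=False)["person_years"].sum()
    missing = set(P["age_group"]) - set(rates.index)
    if missing:
        raise ValidationError(f"standard rates missing for age group(s) {sorted(missing)}")
    P["expected"] = P["person_years"] * P["age_group"].map(rates)
    return P.groupby("area_id", as_index=False)["expected"].sum()


def sir(observed: float, expected: float):
    """SIR and its sampling variance for one area.

    Variance is the delta-method Poisson form with a one-case floor,
    sigma^2 = max(O, 1) / E^2, so zero-count areas carry finite, large
    variance and can still be shrunk toward the null.
    """
    if expected <= 0:
        raise ValidationError(f"expected count must be positive, got {expected}")
    if observed < 0:
        raise ValidationError("observed count must be nonnegative")
    ratio = observed / expected
    variance = max(observed, 1.0) / expected ** 2
    return ratio, variance


def sir_by_area(incidence: pd.DataFrame, person_years: pd.DataFrame,
                std_rates: pd.DataFrame, stratum: dict,
                years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Observed, expected, SIR and variance per area for one stratum.

    Output columns: area_id, observed, expected, sir, variance. Areas with
    zero expected counts are excluded (they cannot enter mapping).
    """
    inc = incidence
    for k, v in stratum.items():
        if k in inc.columns:
            inc = inc[inc[k] == v]
    if years is not None:
        inc = inc[(inc["year"] >= years[0]) & (inc["year"] <= years[1])]
    O = inc.groupby("area_id", as_index=False)["count"].sum().rename(columns={"count": "observed"})
    E = expected_counts(person_years, std_rates, stratum, years=years)
    df = E.merge(O, on="area_id", how="left").fillna({"observed": 0})
    df = df[df["expected"] > 0].reset_index(drop=True)
    vals = [sir(o, e) for o, e in zip(df["observed"], df["expected"])]
    df["sir"] = [v[0] for v in vals]
    df["variance"] = [v[1] for v in vals]
    return df[["area_id", "observed", "expected", "sir", "variance"]]


def histology_proportions(incidence: pd.DataFrame) -> pd.DataFrame:
    """Per-(sex, year) share of each histology label among all cases.

    Years with zero cases in a stratum are omitted (flagged missing rather
    than reported as 0/0).
    """
    totals = incidence.groupby(["sex", "year"], as_index=False)["count"].sum()
    totals = totals[totals["count"] > 0].rename(columns={"count": "total"})
    by_hist = incidence.groupby(["sex", "year", "histology"], as_index=False)["count"].sum()
    df = by_hist.merge(totals, on=["sex", "year"], how="inner")
    df["proportion"] = df["count"] / df["total"]
    return df[["sex", "year", "histology", "proportion"]]
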