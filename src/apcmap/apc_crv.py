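"""Age-period-cohort decomposition under the constant-relative-variation rule.

The APC model writes the log incidence rate of age group ``a`` in period
``p`` (birth cohort ``c = p - a + A - 1``) as

    log r_ap = mu + alpha_a + pi_p + gamma_c .

Because cohort = period - age, the model has a flat likelihood direction:
a linear trend ("drift") can be moved freely between the period and cohort
effects (with a compensating tilt of the age curve) without changing any
fitted rate. The constant-relative-variation (CRV) rule restores
identifiability by treating the age curve as deterministic and choosing
the drift allocation at which the period effects and the cohort effects
have equal relative variation - the coefficient of variation of the
exponentiated (rate-ratio scale) effects.

Estimation is in two steps: a Poisson log-linear reference fit with all
drift assigned to cohort (period constrained to zero linear trend), then a
one-dimensional root search along the exact invariance direction for the
allocation delta* at which the two relative variations agree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_tables import ValidationError, make_age_groups

__all__ = [
    "APCGrid",
    "APCEffects",
    "CRVResult",
    "build_apc_grid",
    "fit_apc_reference",
    "poisson_deviance",
    "curvatures",
    "net_drift",
    "drift_reallocate",
    "relative_variation",
    "solve_crv",
    "bootstrap_bands",
]


@dataclass
class APCGrid:
    """Cross-classified age x period counts and person-years.

    ``counts`` and ``person_years`` are (A, P) arrays; cohort index
    ``c = p - a + (A - 1)`` runs over the A + P - 1 diagonals, oldest
    cohort first.
    """

    counts: np.ndarray
    person_years: np.ndarray
    age_midpoints: np.ndarray      # years
    period_midpoints: np.ndarray   # middle calendar year of each band

    @property
    def n_ages(self) -> int:
        return self.counts.shape[0]

    @property
    def n_periods(self) -> int:
        return self.counts.shape[1]

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    def cohort_index(self, a: int, p: int) -> int:
        return p - a + (self.n_ages - 1)

    @property
    def cohort_median_years(self) -> np.ndarray:
        """Median birth year per cohort: period midpoint minus age midpoint."""
        A, P = self.n_ages, self.n_periods
        years = np.full(self.n_cohorts, np.nan)
        for a in range(A):
            for p in range(P):
                years[self.cohort_index(a, p)] = (
                    self.period_midpoints[p] - self.age_midpoints[a]
                )
        return years


@dataclass
class APCEffects:
    """Intercept plus age/period/cohort effect vectors on the log scale.

    ``delta`` records the drift allocation applied relative to the
    reference fit (log-rate per band moved from cohort to period).
    Period and cohort effects are zero-sum.
    """

    mu: float
    alpha: np.ndarray
    pi: np.ndarray
    gamma: np.ndarray
    delta: float = 0.0
    deviance: float = float("nan")

    def fitted_log_rates(self) -> np.ndarray:
        """(A, P) array of fitted cell log rates."""
        A, P = len(self.alpha), len(self.pi)
        out = np.empty((A, P))
        for a in range(A):
            for p in range(P):
                c = p - a + (A - 1)
                out[a, p] = self.mu + self.alpha[a] + self.pi[p] + self.gamma[c]
        return out


@dataclass
class CRVResult:
    """CRV-balanced effects plus the delta-profile diagnostic."""

    effects: APCEffects
    delta_star: float
    net_drift: float                  # log-rate per band, reference allocation
    profile: pd.DataFrame             # columns delta, rv_period, rv_cohort
    reference: APCEffects


def build_apc_grid(incidence: pd.DataFrame, person_years: pd.DataFrame,
                   age_range: tuple[int, int] = (30, 84),
                   period_range: tuple[int, int] = (1997, 2016),
                   band_width: int = 5,
                   stratum: dict | None = None) -> APCGrid:
    """Aggregate banded tables into an A x P grid with cohort bookkeeping.

    Records outside the age or period range are excluded. With the default
    arguments this is the 11 x 4 design (44 cells, 14 cohorts).
    """
    groups = make_age_groups(*age_range, band_width)
    y0, y1 = period_range
    if (y1 - y0 + 1) % band_width != 0:
        raise ValidationError("period range not divisible into bands")
    period_starts = list(range(y0, y1 + 1, band_width))
    A, P = len(groups), len(period_starts)

    inc = incidence
    pyt = person_years
    if stratum:
        for k, v in stratum.items():
            if k in inc.columns:
                inc = inc[inc[k] == v]
            if k in pyt.columns:
                pyt = pyt[pyt[k] == v]

    by_lower = {g.lower: g.index for g in groups}

    def _accumulate(df, value):
        out = np.zeros((A, P))
        df = df[(df["year"] >= y0) & (df["year"] <= y1)]
        for (ag, yr), v in df.groupby(["age_group", "year"])[value].sum().items():
            lower = age_range[0] + int(ag) * band_width
            if lower not in by_lower:
                continue
            p = (int(yr) - y0) // band_width
            out[by_lower[lower], p] += v
        return out

    O = _accumulate(inc, "count")
    N = _accumulate(pyt, "person_years")
    if O.sum() == 0 and N.sum() == 0:
        raise ValidationError("empty APC grid: no records in range")
    return APCGrid(
        counts=O, person_years=N,
        age_midpoints=np.array([g.midpoint for g in groups]),
        period_midpoints=np.array(
            [ps + (band_width - 1) / 2.0 for ps in period_starts]),
    )


def _zero_sum_basis(n: int, also_orthogonal_to: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal basis of vectors summing to zero (optionally also
    orthogonal to an extra direction, used to strip the period linear trend)."""
    constraints = [np.ones(n)]
    if also_orthogonal_to is not None:
        constraints.append(np.asarray(also_orthogonal_to, dtype=float))
    C = np.column_stack(constraints)
    # Null space of C^T via SVD.
    _, s, Vt = np.linalg.svd(C.T)
    rank = int(np.sum(s > 1e-12))
    return Vt[rank:].T


def fit_apc_reference(grid: APCGrid) -> APCEffects:
    """Poisson log-linear APC fit under the reference constraint.

    All drift is assigned to cohort: period effects are constrained to
    zero sum *and* zero linear trend, cohort and age to zero sum. The
    curvatures (second differences) of the period and cohort effects and
    the net drift are identifiable; the returned point allocation is the
    arbitrary anchor that ``solve_crv`` moves along.
    """
    A, P, C = grid.n_ages, grid.n_periods, grid.n_cohorts
    if (grid.person_years <= 0).any():
        raise ValidationError("every APC cell needs positive person-years")
    O = grid.counts.ravel()
    N = grid.person_years.ravel()
    a_idx, p_idx = np.divmod(np.arange(A * P), P)
    c_idx = p_idx - a_idx + (A - 1)

    Xa = np.eye(A)[a_idx]
    Xp = np.eye(P)[p_idx]
    Xc = np.eye(C)[c_idx]
    Za = _zero_sum_basis(A)
    Zp = _zero_sum_basis(P, also_orthogonal_to=np.arange(P) - (P - 1) / 2.0)
    Zc = _zero_sum_basis(C)
    X = np.column_stack([np.ones(A * P), Xa @ Za, Xp @ Zp, Xc @ Zc])

    model = sm.GLM(O, X, family=sm.families.Poisson(), offset=np.log(N))
    res = model.fit(maxiter=200, tol=1e-12)
    if not res.converged:
        raise RuntimeError(f"APC reference fit did not converge: {res.mle_retvals}")
    theta = np.asarray(res.params)
    k = 1
    alpha = Za @ theta[k: k + Za.shape[1]]; k += Za.shape[1]
    pi = Zp @ theta[k: k + Zp.shape[1]]; k += Zp.shape[1]
    gamma = Zc @ theta[k: k + Zc.shape[1]]
    return APCEffects(mu=float(theta[0]), alpha=alpha, pi=pi, gamma=gamma,
                      delta=0.0, deviance=float(res.deviance))


def poisson_deviance(grid: APCGrid, effects: APCEffects) -> float:
    """Poisson deviance of an effect set against a grid's observed counts."""
    mu = grid.person_years * np.exp(effects.fitted_log_rates())
    O = grid.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(O > 0, O * np.log(O / mu), 0.0)
    return float(2.0 * np.sum(term - (O - mu)))


def curvatures(effects: np.ndarray) -> np.ndarray:
    """Second differences of an effect vector - invariant to drift."""
    return np.diff(effects, n=2)


def net_drift(effects: APCEffects) -> float:
    """Least-squares linear slope of the cohort effects per band index.

    Under the reference constraint all drift sits in cohort, so this is
    the model's net drift.
    """
    c = np.arange(len(effects.gamma), dtype=float)
    c -= c.mean()
    return float(effects.gamma @ c / (c @ c))


def drift_reallocate(effects: APCEffects, delta: float) -> APCEffects:
    """Move linear drift ``delta`` (log-rate per band) from cohort to period.

    The transformation follows the model's exact invariance direction:
    period gains a linear term, cohort loses one, and the age curve tilts
    to compensate (cohort = period - age makes the three shifts cancel
    cell-by-cell). Fitted log rates and the Poisson deviance are unchanged
    to machine precision; zero-sum coding is preserved because all shifts
    use centred indices.
    """
    A, P, C = len(effects.alpha), len(effects.pi), len(effects.gamma)
    a = np.arange(A) - (A - 1) / 2.0
    p = np.arange(P) - (P - 1) / 2.0
    c = np.arange(C) - (C - 1) / 2.0
    return replace(
        effects,
        alpha=effects.alpha - delta * a,
        pi=effects.pi + delta * p,
        gamma=effects.gamma - delta * c,
        delta=effects.delta + delta,
    )


def relative_variation(effects: np.ndarray) -> float:
    """Coefficient of variation of the exponentiated effects.

    Effects live on the log rate-ratio scale; their relative variation is
    SD(exp(effects)) / mean(exp(effects)) with population (1/n) variance.
    Invariant to adding a constant to all effects.
    """
    v = np.asarray(effects, dtype=float)
    if v.size < 2:
        raise ValidationError("relative variation needs at least 2 effects")
    r = np.exp(v)
    return float(r.std() / r.mean())


def _rv_gap(reference: APCEffects, delta: float) -> float:
    eff = drift_reallocate(reference, delta)
    return relative_variation(eff.pi) - relative_variation(eff.gamma)


def solve_crv(grid: APCGrid, n_profile: int = 101,
              gtol: float = 1e-8) -> CRVResult:
    """Find the drift allocation at which period and cohort effects have
    equal relative variation.

    The search runs along the invariance direction between the two
    extreme allocations (all drift in cohort - the reference - and all
    drift in period). If the gap g(delta) = RV(period) - RV(cohort) does
    not change sign across that bracket, candidate minima of |g| are
    reported and the solve fails loudly.
    """
    from scipy.optimize import brentq

    reference = fit_apc_reference(grid)
    nu = net_drift(reference)

    lo, hi = sorted((0.0, nu))
    grid_deltas = np.linspace(lo, hi, n_profile) if hi > lo else np.array([0.0])
    profile = pd.DataFrame({
        "delta": grid_deltas,
        "rv_period": [relative_variation(drift_reallocate(reference, d).pi)
                      for d in grid_deltas],
        "rv_cohort": [relative_variation(drift_reallocate(reference, d).gamma)
                      for d in grid_deltas],
    })

    g = lambda d: _rv_gap(reference, d)
    if abs(g(0.0)) <= gtol:
        # Degenerate null (e.g. pure age model): reference already balanced.
        return CRVResult(drift_reallocate(reference, 0.0), 0.0, nu, profile, reference)
    if hi == lo:
        raise RuntimeError(
            "CRV balancing failed: no drift to reallocate but "
            f"RV(period) - RV(cohort) = {g(0.0):.3g} != 0"
        )

    g_lo, g_hi = g(lo), g(hi)
    if g_lo == 0.0:
        delta_star = lo
    elif g_hi == 0.0:
        delta_star = hi
    elif g_lo * g_hi < 0:
        delta_star = brentq(g, lo, hi, xtol=1e-13)
    else:
        gap = np.abs(profile["rv_period"] - profile["rv_cohort"]).to_numpy()
        local_min = [i for i in range(1, len(gap) - 1)
                     if gap[i] <= gap[i - 1] and gap[i] <= gap[i + 1]]
        if not local_min:
            local_min = [int(np.argmin(gap))]
        candidates = [(float(grid_deltas[i]), float(gap[i])) for i in local_min]
        raise RuntimeError(
            "CRV balancing failed: RV(period) - RV(cohort) does not change "
            f"sign over the drift bracket [{lo:.6g}, {hi:.6g}]; candidate "
            f"|gap| minima (delta, gap): {candidates}"
        )
    if abs(g(delta_star)) > gtol:
        raise RuntimeError(
            f"CRV root search did not reach tolerance: |g({delta_star})| = "
            f"{abs(g(delta_star)):.3g} > {gtol}"
        )
    eff = drift_reallocate(reference, delta_star)
    return CRVResult(eff, float(delta_star), nu, profile, reference)


def plot_effects(grid: APCGrid, result: CRVResult, path,
                 bands: dict | None = None, title: str | None = None) -> None:
    """Three-panel age/period/cohort rate-ratio plot on a log scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    eff = result.effects
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=False)
    panels = [
        ("age", grid.age_midpoints, eff.alpha, "alpha"),
        ("period", grid.period_midpoints, eff.pi, "pi"),
        ("cohort", grid.cohort_median_years, eff.gamma, "gamma"),
    ]
    for ax, (term, x, v, key) in zip(axes, panels):
        ax.plot(x, np.exp(v), "o-", color="tab:blue", ms=4)
        if bands is not None:
            ax.fill_between(x, np.exp(bands[f"{key}_low"]),
                            np.exp(bands[f"{key}_high"]), alpha=0.25,
                            color="tab:blue")
        ax.set_yscale("log")
        ax.axhline(1.0, color="grey", lw=0.6)
        ax.set_xlabel(term)
    axes[0].set_ylabel("rate ratio")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "apcmap"})
    plt.close(fig)


def bootstrap_bands(grid: APCGrid, result: CRVResult, n_boot: int = 200,
                    seed: int = 0, alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Parametric-bootstrap percentile bands for the CRV effect curves.

    Cell counts are resampled Poisson around the fitted means, the whole
    reference-fit-plus-balancing procedure is re-run, and pointwise
    percentile bands are taken for each effect curve.
    """
    rng = np.random.default_rng(seed)
    mean = np.exp(result.effects.fitted_log_rates()) * grid.person_years
    draws = {"alpha": [], "pi": [], "gamma": []}
    for _ in range(n_boot):
        boot = APCGrid(
            counts=rng.poisson(mean).astype(float),
            person_years=grid.person_years,
            age_midpoints=grid.age_midpoints,
            period_midpoints=grid.period_midpoints,
        )
        try:
            res_b = solve_crv(boot)
        except RuntimeError:
            continue
        draws["alpha"].append(res_b.effects.alpha)
        draws["pi"].append(res_b.effects.pi)
        draws["gamma"].append(res_b.effects.gamma)
    out = {}
    for key, arrs in draws.items():
        stack = np.vstack(arrs)
        out[f"{key}_low"] = np.quantile(stack, alpha / 2, axis=0)
        out[f"{key}_high"] = np.quantile(stack, 1 - alpha / 2, axis=0)
    out["n_used"] = np.array([len(draws["alpha"])])
    return out
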