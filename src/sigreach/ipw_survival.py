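"""IPW-adjusted Kaplan-Meier curves, RMST, and bootstrap contrasts.

Overall survival is compared between the two tumor-location groups
(sigmoidoscopy-visualizable vs colonoscopy-required) within age-group x
stage strata.  Because location is not randomized, curves are adjusted by
inverse probability weighting (IPW): a logistic model of group membership
on sex and race/ethnicity yields each patient's propensity for their own
group, and patients are weighted by (marginal group probability)/(fitted
propensity) — stabilized weights, which have mean ~1 per group and leave
the point estimates unchanged in expectation while bounding variance.

The weighted product-limit estimator uses weighted event and at-risk sums
over the distinct event times; ties between events and censorings at the
same month are resolved events-first (the standard convention).  The
restricted mean survival time (RMST) at horizon tau is the exact area
under the step curve on [0, tau]; contrasts are

- DRMST: RMST(visualizable) - RMST(requires colonoscopy) within a
  stratum, and
- DDRMST: the localized-vs-distant RMST gap of the visualizable group
  minus the same gap in the colonoscopy group, within an age group,

with bootstrap standard errors (patients resampled with replacement
within the stratum, weights re-estimated in every replicate so that
weight-estimation uncertainty propagates), two-sided normal Z-tests, and
Bonferroni multiplicity control over the declared test family.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sigreach.association import (
    SeparationError,
    ConvergenceError,
    fit_logistic_irls,
)
from sigreach.subsites import ReachCategory

__all__ = [
    "PropensityWeights",
    "WeightedSurvivalCurve",
    "RmstEstimate",
    "ContrastResult",
    "estimate_weights",
    "weighted_km",
    "rmst",
    "drmst",
    "ddrmst",
    "make_drmst_statistic",
    "make_ddrmst_statistic",
    "bootstrap_inference",
    "bonferroni_adjust",
    "DEFAULT_TAUS",
]

_VIS = ReachCategory.VISUALIZABLE.value
_COL = ReachCategory.REQUIRES_COLONOSCOPY.value

#: Follow-up horizons in months (2, 5 and 10 years).
DEFAULT_TAUS = (24, 60, 120)


@dataclasses.dataclass
class PropensityWeights:
    """Per-patient IPW weights aligned with the cohort's row order."""

    weights: np.ndarray
    stabilized: bool
    covariates: tuple[str, ...]
    n_extreme: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be finite and positive")
        self.weights = w


@dataclasses.dataclass
class WeightedSurvivalCurve:
    """IPW product-limit estimate over the distinct event-time grid.

    ``times`` holds the distinct event times (months) and ``survival`` the
    estimate just after each; S(0) = 1 and the curve is a right-continuous
    step function.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk_w: np.ndarray
    events_w: np.ndarray
    n_subjects: int
    max_observed_time: float
    last_observation_event: bool
    no_events: bool = False

    def evaluate(self, t: np.ndarray | float) -> np.ndarray | float:
        """S(t) with the curve carried flat beyond the last event time."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return s if np.ndim(t) else float(s[0])


@dataclasses.dataclass
class RmstEstimate:
    """RMST at horizon tau, optionally with bootstrap uncertainty."""

    tau: float
    value: float
    estimable: bool = True
    extrapolated: bool = False
    se: float | None = None
    ci_level: float = 0.99
    ci_low: float | None = None
    ci_high: float | None = None


@dataclasses.dataclass
class ContrastResult:
    """DRMST or DDRMST contrast, with bootstrap inference when attached."""

    kind: str
    tau: float
    value: float
    stratum: dict | None = None
    estimable: bool = True
    se: float | None = None
    z: float | None = None
    p: float | None = None
    ci_level: float = 0.99
    ci_low: float | None = None
    ci_high: float | None = None
    n_reps: int | None = None
    n_failed_reps: int | None = None
    alpha_adjusted: float | None = None
    significant: bool | None = None


def estimate_weights(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "race_ethnicity"),
    stabilize: bool = True,
    *,
    extreme_threshold: float = 1e-6,
) -> PropensityWeights:
    """Estimate IPW weights for reach-group membership from covariates.

    Fits a logistic propensity model of visualizable-group membership on
    the (categorical) covariates with the package's IRLS engine, then
    weights each patient by 1/p-hat of their *own* group; with
    ``stabilize`` the numerator is the marginal group share instead of 1,
    so weights average ~1 per group.

    Propensities below ``extreme_threshold`` are counted and reported via
    a warning (``n_extreme`` on the result), not clipped.
    """
    reach = cohort["reach"].astype(str).to_numpy()
    in_model = np.isin(reach, (_VIS, _COL))
    if not in_model.all():
        raise ValueError("cohort contains EXCLUDED reach records; filter first")
    y = (reach == _VIS).astype(float)

    # Aggregate to covariate cells: the fit cost is bounded by the number
    # of distinct covariate patterns, not the number of patients.
    codes_list, n_levels = [], []
    for cov in covariates:
        codes, uniques = pd.factorize(cohort[cov].astype(str), sort=True)
        codes_list.append(codes)
        n_levels.append(len(uniques))
    cell = np.zeros(len(cohort), dtype=np.int64)
    for codes, k in zip(codes_list, n_levels):
        cell = cell * k + codes
    cell_ids, first_rows, cell_inv = np.unique(
        cell, return_index=True, return_inverse=True
    )
    n_cells = len(cell_ids)

    cell_tot = np.bincount(cell_inv, minlength=n_cells).astype(float)
    cell_vis = np.bincount(cell_inv, weights=y, minlength=n_cells)

    # One dummy column per non-reference level of each covariate.
    design_cols = [np.ones(n_cells)]
    for codes, k in zip(codes_list, n_levels):
        cell_code = codes[first_rows]
        for lvl in range(1, k):
            design_cols.append((cell_code == lvl).astype(float))
    X = np.column_stack(design_cols)

    beta, _, _, _, _ = fit_logistic_irls(X, cell_vis / cell_tot, cell_tot)
    p_cell = 1.0 / (1.0 + np.exp(-(X @ beta)))
    p_vis = p_cell[cell_inv]
    p_own = np.where(y == 1, p_vis, 1.0 - p_vis)

    n_extreme = int(np.sum(p_own < extreme_threshold))
    if n_extreme:
        warnings.warn(
            f"{n_extreme} patients have propensity < {extreme_threshold:g}; "
            "their weights are extreme",
            RuntimeWarning,
            stacklevel=2,
        )
    p_own = np.maximum(p_own, np.finfo(float).tiny)
    if stabilize:
        marg_vis = y.mean()
        numerator = np.where(y == 1, marg_vis, 1.0 - marg_vis)
    else:
        numerator = 1.0
    return PropensityWeights(
        weights=numerator / p_own,
        stabilized=stabilize,
        covariates=tuple(covariates),
        n_extreme=n_extreme,
    )


def weighted_km(
    times: np.ndarray,
    events: np.ndarray,
    weights: np.ndarray | None = None,
) -> WeightedSurvivalCurve:
    """Weighted Kaplan-Meier product-limit estimate.

    S(t) = prod over distinct event times t_i <= t of (1 - d_i/n_i) with
    weighted event sums d_i and weighted at-risk sums n_i (everyone whose
    observed time is >= t_i, so censorings tied with events are still at
    risk: events-first tie handling).  Unit weights recover the classical
    Kaplan-Meier estimator exactly.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and positive")

    uniq_t, inv = np.unique(t, return_inverse=True)
    w_leaving = np.bincount(inv, weights=w)
    w_events = np.bincount(inv, weights=w * e)
    at_risk = w.sum() - np.concatenate([[0.0], np.cumsum(w_leaving)[:-1]])

    has_event = w_events > 0
    if not has_event.any():
        return WeightedSurvivalCurve(
            times=np.array([]),
            survival=np.array([]),
            at_risk_w=np.array([]),
            events_w=np.array([]),
            n_subjects=len(t),
            max_observed_time=float(uniq_t[-1]),
            last_observation_event=False,
            no_events=True,
        )
    ev_t = uniq_t[has_event]
    d = w_events[has_event]
    n_at = at_risk[has_event]
    surv = np.cumprod(1.0 - d / n_at)
    last_is_event = bool(e[t == t.max()].any())
    return WeightedSurvivalCurve(
        times=ev_t,
        survival=surv,
        at_risk_w=n_at,
        events_w=d,
        n_subjects=len(t),
        max_observed_time=float(uniq_t[-1]),
        last_observation_event=last_is_event,
    )


def rmst(
    curve: WeightedSurvivalCurve,
    tau: float,
    *,
    min_stratum_n: int = 10,
) -> RmstEstimate:
    """RMST at tau: the exact area under the step curve on [0, tau].

    If follow-up in the stratum ends (all weight leaves) before ``tau``
    with a censored last observation, the curve value past the end is
    unidentified; carrying it flat would extrapolate, so the estimate is
    flagged not estimable.  Strata smaller than ``min_stratum_n`` subjects
    are likewise not estimable.  An estimate whose final step is carried
    flat past the last *event* to ``tau`` is flagged ``extrapolated``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if curve.n_subjects == 0:
        return RmstEstimate(tau=tau, value=float("nan"), estimable=False)
    insufficient = curve.n_subjects < min_stratum_n
    follow_up_short = curve.max_observed_time < tau
    if insufficient or (follow_up_short and not curve.last_observation_event):
        return RmstEstimate(tau=tau, value=float("nan"), estimable=False)

    knots = np.concatenate([[0.0], curve.times, [np.inf]])
    s_vals = np.concatenate([[1.0], curve.survival])
    area = 0.0
    for i in range(len(s_vals)):
        left = min(knots[i], tau)
        right = min(knots[i + 1], tau)
        if right > left:
            area += s_vals[i] * (right - left)
    return RmstEstimate(tau=tau, value=float(area), extrapolated=bool(follow_up_short))


def drmst(
    curve_visualizable: WeightedSurvivalCurve,
    curve_colonoscopy: WeightedSurvivalCurve,
    tau: float,
    *,
    min_stratum_n: int = 10,
    stratum: dict | None = None,
) -> ContrastResult:
    """Point DRMST: RMST(visualizable) - RMST(requires colonoscopy)."""
    r_vis = rmst(curve_visualizable, tau, min_stratum_n=min_stratum_n)
    r_col = rmst(curve_colonoscopy, tau, min_stratum_n=min_stratum_n)
    ok = r_vis.estimable and r_col.estimable
    value = r_vis.value - r_col.value if ok else float("nan")
    return ContrastResult(
        kind="DRMST", tau=tau, value=value, estimable=ok, stratum=stratum
    )


def ddrmst(
    rmst_components: Mapping[tuple[str, str], RmstEstimate | float],
    tau: float,
    *,
    stratum: dict | None = None,
) -> ContrastResult:
    """Point DDRMST from four stage x reach RMST components.

    Keys are (reach, stage) for reach in {VISUALIZABLE,
    REQUIRES_COLONOSCOPY} and stage in {localized, distant}:

    (RMST_vis,loc - RMST_vis,dist) - (RMST_col,loc - RMST_col,dist)
    """
    vals = {}
    estimable = True
    for reach in (_VIS, _COL):
        for stage in ("localized", "distant"):
            comp = rmst_components[(reach, stage)]
            if isinstance(comp, RmstEstimate):
                estimable &= comp.estimable
                vals[(reach, stage)] = comp.value
            else:
                vals[(reach, stage)] = float(comp)
                estimable &= np.isfinite(comp)
    value = (
        (vals[(_VIS, "localized")] - vals[(_VIS, "distant")])
        - (vals[(_COL, "localized")] - vals[(_COL, "distant")])
        if estimable
        else float("nan")
    )
    return ContrastResult(
        kind="DDRMST", tau=tau, value=value, estimable=estimable, stratum=stratum
    )


def _group_curve(
    sub: pd.DataFrame, weights: np.ndarray, group: str
) -> WeightedSurvivalCurve | None:
    mask = (sub["reach"].astype(str) == group).to_numpy()
    if not mask.any():
        return None
    return weighted_km(
        sub.loc[mask, "survival_months"].to_numpy(float),
        (sub.loc[mask, "vital_status"].astype(str) == "dead").to_numpy(),
        weights[mask],
    )


def make_drmst_statistic(
    tau: float,
    covariates: Sequence[str] = ("sex", "race_ethnicity"),
    stabilize: bool = True,
    min_stratum_n: int = 10,
) -> Callable[[pd.DataFrame], float]:
    """Build the DRMST statistic for :func:`bootstrap_inference`.

    The returned callable re-estimates IPW weights on the (resampled)
    stratum, computes both group curves and returns the DRMST point value
    (NaN when not estimable, e.g. one group absent or propensity model
    separated).
    """

    def statistic(sub: pd.DataFrame) -> float:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                w = estimate_weights(sub, covariates, stabilize).weights
        except (SeparationError, ConvergenceError):
            return float("nan")
        cv = _group_curve(sub, w, _VIS)
        cc = _group_curve(sub, w, _COL)
        if cv is None or cc is None:
            return float("nan")
        return drmst(cv, cc, tau, min_stratum_n=min_stratum_n).value

    statistic.kind = "DRMST"  # type: ignore[attr-defined]
    statistic.tau = tau  # type: ignore[attr-defined]
    return statistic


def make_ddrmst_statistic(
    tau: float,
    covariates: Sequence[str] = ("sex", "race_ethnicity"),
    stabilize: bool = True,
    min_stratum_n: int = 10,
) -> Callable[[pd.DataFrame], float]:
    """Build the DDRMST statistic over an age-group stratum.

    The input frame must contain localized and distant records of both
    reach groups; weights are re-estimated per stage substratum (matching
    the stratified analysis) in every evaluation.
    """

    def statistic(sub: pd.DataFrame) -> float:
        comps: dict[tuple[str, str], float] = {}
        for stage in ("localized", "distant"):
            ss = sub[sub["stage"].astype(str) == stage]
            if len(ss) == 0:
                return float("nan")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    w = estimate_weights(ss, covariates, stabilize).weights
            except (SeparationError, ConvergenceError):
                return float("nan")
            for group in (_VIS, _COL):
                curve = _group_curve(ss, w, group)
                if curve is None:
                    return float("nan")
                est = rmst(curve, tau, min_stratum_n=min_stratum_n)
                if not est.estimable:
                    return float("nan")
                comps[(group, stage)] = est.value
        return ddrmst(comps, tau).value

    statistic.kind = "DDRMST"  # type: ignore[attr-defined]
    statistic.tau = tau  # type: ignore[attr-defined]
    return statistic


def bootstrap_inference(
    cohort: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    n_reps: int = 2000,
    seed: int | None = None,
    ci_level: float = 0.99,
    *,
    max_failed_frac: float = 0.10,
    stratum: dict | None = None,
) -> ContrastResult:
    """Bootstrap SE, Z-test and percentile CI for a stratum contrast.

    Patients are resampled with replacement within the stratum; the
    statistic (which re-estimates IPW weights internally) is evaluated on
    each replicate.  SE is the standard deviation across replicates,
    Z = point/SE with a two-sided normal p-value, and the CI is the
    percentile interval at ``ci_level``.  Replicate RNG streams derive
    deterministically from ``seed`` (same seed, same results, regardless
    of evaluation order).

    Raises
    ------
    RuntimeError
        If more than ``max_failed_frac`` of replicates are not estimable,
        or the statistic is degenerate (zero bootstrap variance).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    point = float(statistic(cohort))
    kind = getattr(statistic, "kind", "contrast")
    tau = float(getattr(statistic, "tau", float("nan")))
    if not np.isfinite(point):
        return ContrastResult(
            kind=kind, tau=tau, value=point, estimable=False, stratum=stratum
        )

    n = len(cohort)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    values = np.empty(n_reps)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, n)
        values[r] = statistic(cohort.iloc[idx].reset_index(drop=True))

    ok = np.isfinite(values)
    n_failed = int(n_reps - ok.sum())
    if n_failed > max_failed_frac * n_reps:
        raise RuntimeError(
            f"bootstrap inference refused: {n_failed}/{n_reps} replicates "
            "not estimable (sparse stratum?)"
        )
    good = values[ok]
    se = float(np.std(good, ddof=1))
    # float-roundoff spread (~1e-15 months) counts as zero
    if se <= 1e-9 * max(1.0, abs(point)):
        raise RuntimeError(
            "bootstrap inference refused: statistic is constant under "
            "resampling (degenerate stratum)"
        )
    z = point / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(good, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ContrastResult(
        kind=kind,
        tau=tau,
        value=point,
        stratum=stratum,
        estimable=True,
        se=se,
        z=float(z),
        p=p,
        ci_level=ci_level,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_reps=n_reps,
        n_failed_reps=n_failed,
    )


def bonferroni_adjust(
    p_values: Sequence[float], m: int, alpha: float = 0.05
) -> np.ndarray:
    """Bonferroni significance flags: p_i < alpha/m.

    ``m`` is the declared size of the test family (27 for the DRMST grid
    of 3 ages x 3 stages x 3 horizons; 18 for the DDRMST family), fixed by
    the analysis plan rather than inferred from however many tests were
    estimable.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < (alpha / m)
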