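"""Synthetic SEER-like colorectal cohorts with known ground truth.

The generator emulates the structure of a 2000-2020 registry case listing
so every pipeline stage is testable without registry access: a 9-subsite
ICD-O-3 topography distribution per age group (defaulting to the
published cohort's empirical proportions), categorical demographics, a
configurable location-covariate association (confounding on the log-odds
scale), a stage mixture per location group, and stage x location
exponential survival with administrative right-censoring tied to the year
of diagnosis (later diagnoses have shorter potential follow-up, as in a
real registry).  Survival months are floored to whole months, matching
registry recode granularity.

Every stochastic choice flows from one seed; the same seed yields a
bit-identical cohort.  Alongside the cohort, :func:`generate` returns a
ground-truth record (true log-odds, true hazard rates, closed-form RMSTs)
for parameter-recovery tests.

What this does *not* emulate: screening behavior, lead-time bias,
incidence trends, or covariate-dependent survival — survival depends on
stage and location group only, so the IPW-adjusted and crude survival
targets coincide by construction (the weights correct composition, not
outcome, noise).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from sigreach import reference
from sigreach.data_model import AGE_GROUPS, RACE_LEVELS, SEX_LEVELS, add_derived_columns
from sigreach.subsites import COLONOSCOPY_CODES, VISUALIZABLE_CODES, ReachCategory

__all__ = [
    "GeneratorConfig",
    "generate",
    "inject_exclusions",
    "closed_form_rmst",
    "exponential_rate_for_rmst",
    "default_subsite_probs",
    "write_case_listing",
]

_VIS = ReachCategory.VISUALIZABLE.value
_COL = ReachCategory.REQUIRES_COLONOSCOPY.value

#: Months in the 2000-2020 accrual window (administrative cutoff).
WINDOW_MONTHS = 21 * 12

STAGES = ("localized", "regional", "distant")


def closed_form_rmst(rate: float, tau: float) -> float:
    """RMST of an exponential(rate) survival time: (1 - e^(-rate*tau))/rate."""
    return (1.0 - np.exp(-rate * tau)) / rate


def exponential_rate_for_rmst(target: float, tau: float) -> float:
    """Invert the exponential RMST formula for the monthly hazard rate."""
    if not 0 < target < tau:
        raise ValueError(f"target RMST must lie in (0, tau); got {target} at tau={tau}")
    return brentq(lambda lam: closed_form_rmst(lam, tau) - target, 1e-8, 10.0)


def default_subsite_probs() -> dict[str, dict[str, float]]:
    """Per-age-group subsite probabilities from the published count grid."""
    out: dict[str, dict[str, float]] = {}
    for j, age in enumerate(reference.AGE_GROUP_ORDER):
        col = {code: counts[j] for code, counts in reference.SUBSITE_AGE_COUNTS.items()}
        tot = sum(col.values())
        out[age] = {code: c / tot for code, c in col.items()}
    return out


def _mix_from_reference(factor: str) -> dict[str, float]:
    levels = reference.TABLE1_FACTORS[factor]
    total = sum(n for _, n in levels.values())
    return {lvl: n / total for lvl, (_, n) in levels.items()}


def _default_stage_mix_by_reach() -> dict[str, dict[str, float]]:
    stage = reference.TABLE1_FACTORS["stage"]
    vis_tot = sum(a for a, _ in stage.values())
    col_tot = sum(n - a for a, n in stage.values())
    return {
        _VIS: {s: a / vis_tot for s, (a, _) in stage.items()},
        _COL: {s: (n - a) / col_tot for s, (a, n) in stage.items()},
    }


def _default_confounding() -> dict[tuple[str, str], float]:
    # Location-covariate association strengths typical of this cohort:
    # male sex and Asian/Pacific-Islander race shift toward distal
    # (visualizable) tumors, non-Hispanic Black toward proximal.
    return {
        ("sex", "male"): float(np.log(1.52)),
        ("race_ethnicity", "Hispanic"): float(np.log(1.18)),
        ("race_ethnicity", "NH-AIAN"): float(np.log(1.17)),
        ("race_ethnicity", "NH-API"): float(np.log(1.56)),
        ("race_ethnicity", "NH-Black"): float(np.log(0.76)),
        ("race_ethnicity", "NH-Unknown"): float(np.log(1.35)),
    }


def _default_rmst120_targets() -> dict[tuple[str, str], float]:
    # Months of RMST at the 120-month horizon per (stage, reach) cell:
    # localized comparable between location groups; regional ~75 vs ~66
    # (distal advantage); distant markedly worse with a larger
    # localized-distant gap for proximal tumors.
    return {
        ("localized", _VIS): 101.0,
        ("localized", _COL): 99.0,
        ("regional", _VIS): 75.0,
        ("regional", _COL): 66.0,
        ("distant", _VIS): 30.0,
        ("distant", _COL): 22.0,
    }


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for a synthetic registry cohort.

    Defaults reproduce the published cohort's marginal structure: age-group
    and subsite-within-age mixtures from the subsite-by-age count grid,
    sex/race mixtures from the cohort characteristics table, stage mixture
    per location group, and exponential stage x location survival with
    monthly hazards set from RMST-at-120-months targets.

    ``confounding_log_odds`` maps (covariate, level) to an additive shift
    on the logit probability of a visualizable location; an empty mapping
    means location is independent of demographics (all stabilized IPW
    weights ~1).  ``reach_logit_shift`` adds a global offset on the same
    scale (0 keeps the age-group empirical mixtures).
    """

    n_patients: int = 10_000
    seed: int | None = None
    age_group_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _mix_from_reference("age_group")
    )
    subsite_probs_by_age: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=default_subsite_probs
    )
    sex_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _mix_from_reference("sex")
    )
    race_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _mix_from_reference("race_ethnicity")
    )
    confounding_log_odds: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=_default_confounding
    )
    reach_logit_shift: float = 0.0
    stage_mix_by_reach: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=_default_stage_mix_by_reach
    )
    rmst120_targets: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=_default_rmst120_targets
    )
    survival_rates: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, mix in [
            ("age_group_mix", self.age_group_mix),
            ("sex_mix", self.sex_mix),
            ("race_mix", self.race_mix),
        ]:
            _check_mixture(name, mix)
        for age, probs in self.subsite_probs_by_age.items():
            _check_mixture(f"subsite_probs_by_age[{age}]", probs)
        for reach, mix in self.stage_mix_by_reach.items():
            _check_mixture(f"stage_mix_by_reach[{reach}]", mix)
        if self.survival_rates is None:
            self.survival_rates = {
                cell: exponential_rate_for_rmst(target, 120.0)
                for cell, target in self.rmst120_targets.items()
            }
        for cell, rate in self.survival_rates.items():
            if rate <= 0:
                raise ValueError(f"nonpositive hazard rate for {cell}")

    def true_rmst(self, stage: str, reach: str, tau: float) -> float:
        """Closed-form RMST implied by the configured exponential hazards."""
        return closed_form_rmst(self.survival_rates[(stage, reach)], tau)

    def true_drmst(self, stage: str, tau: float) -> float:
        return self.true_rmst(stage, _VIS, tau) - self.true_rmst(stage, _COL, tau)

    def ground_truth(self, taus: tuple[float, ...] = (24.0, 60.0, 120.0)) -> dict:
        """Closed-form targets for recovery tests, JSON-serializable."""
        return {
            "survival_rates": {f"{s}|{r}": v for (s, r), v in self.survival_rates.items()},
            "rmst": {
                f"{s}|{r}|{int(tau)}": self.true_rmst(s, r, tau)
                for s in STAGES
                for r in (_VIS, _COL)
                for tau in taus
            },
            "drmst": {
                f"{s}|{int(tau)}": self.true_drmst(s, tau)
                for s in STAGES
                for tau in taus
            },
            "confounding_log_odds": {
                f"{cov}[{lvl}]": v for (cov, lvl), v in self.confounding_log_odds.items()
            },
            "reach_logit_shift": self.reach_logit_shift,
        }


def _check_mixture(name: str, mix: Mapping) -> None:
    probs = np.array(list(mix.values()), dtype=float)
    if np.any(probs < 0):
        raise ValueError(f"{name} has a negative probability")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} does not sum to 1 (sum={probs.sum():.12f})")


def _sample_categorical(rng: np.random.Generator, mix: Mapping[str, float], n: int) -> np.ndarray:
    levels = np.array(list(mix.keys()), dtype=object)
    p = np.array(list(mix.values()), dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def _sample_ages(rng: np.random.Generator, groups: np.ndarray) -> np.ndarray:
    """Integer ages consistent with each group; 50+ centered near the
    registry's median (~66, IQR 56-77)."""
    n = len(groups)
    ages = np.empty(n, dtype=np.int64)
    m = groups == "under45"
    ages[m] = rng.integers(20, 45, m.sum())
    m = groups == "45to49"
    ages[m] = rng.integers(45, 50, m.sum())
    m = groups == "50plus"
    draw = rng.normal(67.0, 13.0, m.sum())
    ages[m] = np.clip(np.round(draw), 50, 99).astype(np.int64)
    return ages


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic case-listing cohort plus its ground truth.

    Returns the cohort as a canonical-column DataFrame (round-trippable
    through :func:`sigreach.data_model.read_case_listing` via
    :func:`write_case_listing`) and the closed-form ground-truth record.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    age_group = _sample_categorical(rng, config.age_group_mix, n)
    age_years = _sample_ages(rng, age_group)
    sex = _sample_categorical(rng, config.sex_mix, n)
    race = _sample_categorical(rng, config.race_mix, n)

    # Location group: logit(P(visualizable | age group)) shifted by the
    # covariate confounding terms, then subsite sampled within the group.
    p_vis_base = np.array(
        [
            sum(
                p
                for code, p in config.subsite_probs_by_age[g].items()
                if code in VISUALIZABLE_CODES
            )
            for g in age_group
        ]
    )
    logit = np.log(p_vis_base / (1.0 - p_vis_base)) + config.reach_logit_shift
    # Confounding shifts are centered on the covariate mixture so the
    # marginal visualizable share per age group stays (to first order) at
    # the configured subsite mixture; level-vs-level log-odds contrasts
    # are unaffected by the centering.
    mixes = {"sex": config.sex_mix, "race_ethnicity": config.race_mix}
    for (cov, lvl), shift in config.confounding_log_odds.items():
        if cov not in mixes:
            raise ValueError(f"confounding covariate must be sex or race_ethnicity: {cov}")
        values = sex if cov == "sex" else race
        logit = logit + shift * ((values == lvl) - mixes[cov].get(lvl, 0.0))
    p_vis = 1.0 / (1.0 + np.exp(-logit))
    is_vis = rng.random(n) < p_vis

    topography = np.empty(n, dtype=object)
    for g in set(age_group):
        probs = config.subsite_probs_by_age[g]
        for vis_flag, codeset in ((True, VISUALIZABLE_CODES), (False, COLONOSCOPY_CODES)):
            mask = (age_group == g) & (is_vis == vis_flag)
            if not mask.any():
                continue
            codes = [c for c in sorted(codeset) if probs.get(c, 0) > 0]
            p = np.array([probs[c] for c in codes])
            topography[mask] = rng.choice(np.array(codes, object), mask.sum(), p=p / p.sum())

    reach = np.where(is_vis, _VIS, _COL)
    stage = np.empty(n, dtype=object)
    for r in (_VIS, _COL):
        mask = reach == r
        mix = {s: p for s, p in config.stage_mix_by_reach[r].items() if s in STAGES}
        stage[mask] = _sample_categorical(rng, mix, mask.sum())

    # Administrative censoring: uniform entry over the accrual window,
    # follow-up truncated at the window end.
    entry_month = rng.integers(0, WINDOW_MONTHS, n)
    censor_months = (WINDOW_MONTHS - entry_month).astype(float)
    rates = np.array([config.survival_rates[(s, r)] for s, r in zip(stage, reach)])
    event_time = rng.exponential(1.0 / rates)
    dead = event_time <= censor_months
    survival_months = np.floor(np.where(dead, event_time, censor_months)).astype(np.int64)
    year_dx = 2000 + (entry_month // 12)

    cohort = pd.DataFrame(
        {
            "topography_code": topography,
            "age_years": age_years,
            "sex": sex,
            "race_ethnicity": race,
            "stage": stage,
            "year_dx": year_dx,
            "survival_months": pd.array(survival_months, dtype="Int64"),
            "vital_status": np.where(dead, "dead", "alive"),
            "autopsy_only": np.zeros(n, dtype=bool),
        }
    )
    return cohort, config.ground_truth()


def inject_exclusions(
    cohort: pd.DataFrame,
    rules: Mapping[str, int | float],
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Append rows violating specific exclusion rules, with a manifest.

    ``rules`` maps rule name (see
    :data:`sigreach.data_model.EXCLUSION_RULES`) to either an exact row
    count (int) or a rate in [0, 1) applied binomially to the cohort size
    (float).  Each injected row violates exactly its own rule, so the
    expected exclusion log is the returned manifest exactly.  The rows are
    shuffled into the cohort deterministically under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if len(cohort) == 0:
        raise ValueError("cannot inject into an empty cohort")
    manifest: dict[str, int] = {}
    new_rows = []
    for rule, amount in rules.items():
        if isinstance(amount, float) and not float(amount).is_integer():
            if not 0 <= amount < 1:
                raise ValueError(f"rate for {rule} must be in [0, 1)")
            count = int(rng.binomial(len(cohort), amount))
        else:
            count = int(amount)
            if count < 0:
                raise ValueError(f"negative injection count for {rule}")
        manifest[rule] = count
        for _ in range(count):
            row = cohort.iloc[int(rng.integers(0, len(cohort)))].to_dict()
            # Start from a rule-clean template so the row violates only its
            # own rule.
            row["survival_months"] = (
                1 if pd.isna(row["survival_months"]) else max(int(row["survival_months"]), 1)
            )
            row["autopsy_only"] = False
            row["stage"] = row["stage"] if row["stage"] != "unknown" else "localized"
            if rule == "stage_unknown":
                row["stage"] = "unknown"
            elif rule == "nonspecific_or_unlisted_subsite":
                row["topography_code"] = str(
                    rng.choice(np.array(["C188", "C189", "C260", "C181"], object))
                )
            elif rule == "autopsy_only":
                row["autopsy_only"] = True
            elif rule == "missing_survival":
                row["survival_months"] = pd.NA
            elif rule == "zero_survival":
                row["survival_months"] = 0
            else:
                raise ValueError(f"unknown exclusion rule: {rule}")
            new_rows.append(row)

    if not new_rows:
        return cohort.copy(), manifest
    combined = pd.concat([cohort, pd.DataFrame(new_rows)], ignore_index=True)
    combined["survival_months"] = combined["survival_months"].astype("Int64")
    order = rng.permutation(len(combined))
    return combined.iloc[order].reset_index(drop=True), manifest


def write_case_listing(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort in the delimited case-listing format the reader expects."""
    cohort.to_csv(path, sep="\t" if str(path).endswith((".tsv", ".txt")) else ",", index=False)


def derived_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Convenience: generate and attach derived (age/year group, reach) columns."""
    cohort, truth = generate(config)
    return add_derived_columns(cohort), truth
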