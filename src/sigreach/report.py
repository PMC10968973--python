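"""Pipeline orchestration: from a case listing (or synthetic config) to
the analysis bundle.

The bundle mirrors the deliverables of the registry analysis: the
exclusion log; a cohort-characteristics table with visualizable counts,
percentages, univariable and multivariable odds ratios; a subsite-by-age
count grid; the age x stage visualizable-proportion grid; IPW-adjusted
Kaplan-Meier curve coordinates per stratum; and the RMST / DRMST / DDRMST
grid with bootstrap CIs, Z-tests and Bonferroni significance flags.
Everything is deterministic given the seed.  The two analysis arms are
isolated: a failure in the survival arm still yields association results,
with the failure recorded in the bundle status.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sigreach import __version__ as _version
from sigreach import reference
from sigreach.association import (
    ContingencyTable,
    crosstab,
    fit_logistic,
    odds_ratio_univariable,
    proportion_by_stratum,
    round_half_up,
)
from sigreach.data_model import (
    AGE_GROUPS,
    ExclusionLog,
    apply_exclusions,
    read_case_listing,
)
from sigreach.ipw_survival import (
    DEFAULT_TAUS,
    ContrastResult,
    bonferroni_adjust,
    bootstrap_inference,
    estimate_weights,
    make_ddrmst_statistic,
    make_drmst_statistic,
    weighted_km,
)
from sigreach.subsites import SUBSITE_LABELS, ReachCategory
from sigreach.synthetic import GeneratorConfig, generate

__all__ = ["RunConfig", "run", "replicate_tables", "write_bundle"]

_VIS = ReachCategory.VISUALIZABLE.value
_COL = ReachCategory.REQUIRES_COLONOSCOPY.value

TABLE1_FACTOR_ORDER = ("age_group", "sex", "stage", "race_ethnicity", "year_group")

#: Reference levels of the demographic logistic model.
TABLE1_REFERENCES = {
    "age_group": "50plus",
    "sex": "female",
    "stage": "localized",
    "race_ethnicity": "NH-White",
    "year_group": "2000-2004",
}


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` (a case-listing file) or
    ``synthetic`` (a :class:`~sigreach.synthetic.GeneratorConfig`) must be
    given.
    """

    input_path: str | Path | None = None
    schema: Mapping | str | None = None
    synthetic: GeneratorConfig | None = None
    output_dir: str | Path | None = None
    run_association: bool = True
    run_survival: bool = True
    taus: Sequence[float] = DEFAULT_TAUS
    n_reps: int = 2000
    ci_level: float = 0.99
    alpha_m_drmst: int = 27
    alpha_m_ddrmst: int = 18
    seed: int | None = None
    stabilize_weights: bool = True
    min_stratum_n: int = 10
    covariates: Sequence[str] = ("sex", "race_ethnicity")

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("specify exactly one of input_path or synthetic")


def _table1(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort-characteristics replica: counts, percents, uni/multi ORs."""
    rows = [
        {
            "factor": "overall",
            "level": "overall",
            "n_visualizable": int((cohort["reach"] == _VIS).sum()),
            "n_total": int(cohort["reach"].isin([_VIS, _COL]).sum()),
        }
    ]
    tables: dict[str, ContingencyTable] = {}
    for factor in TABLE1_FACTOR_ORDER:
        tables[factor] = crosstab(cohort, factor, TABLE1_REFERENCES[factor])
        for level, (a, n) in tables[factor].levels.items():
            rows.append(
                {"factor": factor, "level": level, "n_visualizable": a, "n_total": n}
            )
    df = pd.DataFrame(rows)
    df["percent"] = [
        round_half_up(100.0 * a / n, 1) if n else float("nan")
        for a, n in zip(df["n_visualizable"], df["n_total"])
    ]
    for col in ("uni_or", "uni_ci_low", "uni_ci_high"):
        df[col] = np.nan
    for factor, table in tables.items():
        for level in table.levels:
            if level == table.reference:
                continue
            est = odds_ratio_univariable(table, level)
            sel = (df["factor"] == factor) & (df["level"] == level)
            df.loc[sel, ["uni_or", "uni_ci_low", "uni_ci_high"]] = (
                est.odds_ratio,
                est.ci_low,
                est.ci_high,
            )

    factors = {
        f: [TABLE1_REFERENCES[f]]
        + [l for l in tables[f].levels if l != TABLE1_REFERENCES[f]]
        for f in TABLE1_FACTOR_ORDER
        if len(tables[f].levels) > 1
    }
    fit = fit_logistic(cohort, factors)
    ors = fit.odds_ratios().set_index("term")
    for col in ("multi_or", "multi_ci_low", "multi_ci_high"):
        df[col] = np.nan
    for factor in factors:
        for level in factors[factor][1:]:
            term = f"{factor}[{level}]"
            if term in ors.index:
                sel = (df["factor"] == factor) & (df["level"] == level)
                df.loc[sel, ["multi_or", "multi_ci_low", "multi_ci_high"]] = (
                    ors.loc[term, ["odds_ratio", "ci_low", "ci_high"]].to_numpy()
                )
    return df


def _table2(cohort: pd.DataFrame) -> pd.DataFrame:
    """Subsite x age-group count grid with totals and percentages."""
    sub = cohort[cohort["reach"].isin([_VIS, _COL])]
    rows = []
    total = len(sub)
    for code in reference.SUBSITE_AGE_COUNTS:  # display order: distal first
        site = sub[sub["topography_code"] == code]
        row = {"topography_code": code, "site": SUBSITE_LABELS[code]}
        for age in AGE_GROUPS:
            row[age] = int((site["age_group"] == age).sum())
        row["all_ages"] = len(site)
        row["percent"] = 100.0 * len(site) / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _survival_grid(cohort: pd.DataFrame, cfg: RunConfig) -> dict:
    """DRMST per age x stage x tau and DDRMST per age x tau, with
    bootstrap inference and multiplicity flags; plus KM coordinates."""
    stages = [s for s in ("localized", "regional", "distant") if (cohort["stage"] == s).any()]
    ages = [a for a in AGE_GROUPS if (cohort["age_group"] == a).any()]
    master = np.random.SeedSequence(cfg.seed)
    drmst_results, ddrmst_results, curves = [], [], []
    for age in ages:
        age_sub = cohort[cohort["age_group"] == age]
        for stage in stages:
            sub = age_sub[age_sub["stage"] == stage].reset_index(drop=True)
            if len(sub):
                try:
                    w = estimate_weights(sub, cfg.covariates, cfg.stabilize_weights).weights
                    for group in (_VIS, _COL):
                        m = (sub["reach"] == group).to_numpy()
                        if m.any():
                            curve = weighted_km(
                                sub.loc[m, "survival_months"].to_numpy(float),
                                (sub.loc[m, "vital_status"] == "dead").to_numpy(),
                                w[m],
                            )
                            curves.append(
                                pd.DataFrame(
                                    {
                                        "age_group": age,
                                        "stage": stage,
                                        "reach": group,
                                        "time": np.concatenate([[0.0], curve.times]),
                                        "survival": np.concatenate([[1.0], curve.survival]),
                                    }
                                )
                            )
                except Exception:
                    pass
            for tau in cfg.taus:
                stat = make_drmst_statistic(
                    tau, cfg.covariates, cfg.stabilize_weights, cfg.min_stratum_n
                )
                seed_r = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
                try:
                    res = bootstrap_inference(
                        sub,
                        stat,
                        n_reps=cfg.n_reps,
                        seed=seed_r,
                        ci_level=cfg.ci_level,
                        stratum={"age_group": age, "stage": stage},
                    )
                except (RuntimeError, ValueError):
                    res = ContrastResult(
                        kind="DRMST",
                        tau=tau,
                        value=float("nan"),
                        estimable=False,
                        stratum={"age_group": age, "stage": stage},
                    )
                drmst_results.append(res)
        if {"localized", "distant"} <= set(stages):
            dd_sub = age_sub[age_sub["stage"].isin(["localized", "distant"])].reset_index(
                drop=True
            )
            for tau in cfg.taus:
                stat = make_ddrmst_statistic(
                    tau, cfg.covariates, cfg.stabilize_weights, cfg.min_stratum_n
                )
                seed_r = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
                try:
                    res = bootstrap_inference(
                        dd_sub,
                        stat,
                        n_reps=cfg.n_reps,
                        seed=seed_r,
                        ci_level=cfg.ci_level,
                        stratum={"age_group": age},
                    )
                except (RuntimeError, ValueError):
                    res = ContrastResult(
                        kind="DDRMST",
                        tau=tau,
                        value=float("nan"),
                        estimable=False,
                        stratum={"age_group": age},
                    )
                ddrmst_results.append(res)

    for results, m in ((drmst_results, cfg.alpha_m_drmst), (ddrmst_results, cfg.alpha_m_ddrmst)):
        ps = [r.p for r in results if r.p is not None]
        if ps:
            flags = bonferroni_adjust(ps, m)
            i = 0
            for r in results:
                if r.p is not None:
                    r.alpha_adjusted = 0.05 / m
                    r.significant = bool(flags[i])
                    i += 1

    def _frame(results):
        return pd.DataFrame(
            [
                {
                    **(r.stratum or {}),
                    "kind": r.kind,
                    "tau": r.tau,
                    "value": r.value,
                    "se": r.se,
                    "z": r.z,
                    "p": r.p,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "ci_level": r.ci_level,
                    "alpha_adjusted": r.alpha_adjusted,
                    "significant": r.significant,
                    "estimable": r.estimable,
                }
                for r in results
            ]
        )

    km = (
        pd.concat(curves, ignore_index=True)
        if curves
        else pd.DataFrame(columns=["age_group", "stage", "reach", "time", "survival"])
    )
    return {
        "drmst": _frame(drmst_results),
        "ddrmst": _frame(ddrmst_results),
        "km_curves": km,
    }


def run(config: RunConfig) -> dict:
    """Execute the pipeline and return (and optionally write) the bundle."""
    bundle: dict = {"status": {}, "manifest": _manifest(config)}
    if config.synthetic is not None:
        raw, truth = generate(config.synthetic)
        bundle["ground_truth"] = truth
    else:
        raw = read_case_listing(config.input_path, config.schema)
    cohort, log = apply_exclusions(raw)
    bundle["exclusion_log"] = log
    bundle["cohort_n"] = len(cohort)

    if config.run_association:
        try:
            bundle["table1"] = _table1(cohort)
            bundle["table2"] = _table2(cohort)
            bundle["proportions_age_stage"] = proportion_by_stratum(cohort)
            bundle["status"]["association"] = "ok"
        except Exception as exc:  # isolate arms
            bundle["status"]["association"] = f"failed: {exc}"
            bundle["status"]["association_traceback"] = traceback.format_exc()
    if config.run_survival:
        try:
            bundle.update(_survival_grid(cohort, config))
            bundle["status"]["survival"] = "ok"
        except Exception as exc:
            bundle["status"]["survival"] = f"failed: {exc}"
            bundle["status"]["survival_traceback"] = traceback.format_exc()

    if config.output_dir is not None:
        write_bundle(bundle, config.output_dir)
    return bundle


def _manifest(config: RunConfig) -> dict:
    payload = {
        f.name: str(getattr(config, f.name))
        for f in dataclasses.fields(config)
        if f.name not in ("output_dir",)
    }
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
    return {"package_version": _version, "config": payload, "config_sha256": digest,
            "seed": config.seed}


def write_bundle(bundle: dict, output_dir: str | Path) -> None:
    """Write every bundle component as TSV (tables) or JSON (records)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{key}.tsv", sep="\t", index=False)
            value.to_json(out / f"{key}.json", orient="records", indent=2)
        elif isinstance(value, ExclusionLog):
            value.to_json(out / f"{key}.json")
        else:
            (out / f"{key}.json").write_text(json.dumps(value, indent=2, default=str) + "\n")


def replicate_tables() -> dict[str, pd.DataFrame]:
    """Recompute the published cohort tables from their raw printed counts.

    Works entirely from :mod:`sigreach.reference` count data: percentages,
    univariable Wald odds ratios per factor level, the subsite count grid
    with column percentages, and the headline proportions (overall,
    per age group, under-50 combined).  Nothing derived is stored; every
    statistic is recomputed here at call time.
    """
    rows = []
    for factor, levels in reference.TABLE1_FACTORS.items():
        ref_level = next(iter(levels))
        table = ContingencyTable(factor=factor, levels=dict(levels), reference=ref_level)
        for level, (a, n) in levels.items():
            row = {
                "factor": factor,
                "level": level,
                "n_visualizable": a,
                "n_total": n,
                "percent": table.percent(level),
            }
            if level != ref_level:
                est = odds_ratio_univariable(table, level)
                row.update(
                    uni_or=est.odds_ratio, uni_ci_low=est.ci_low, uni_ci_high=est.ci_high
                )
            rows.append(row)
    table1 = pd.DataFrame(rows)

    t2_rows = []
    for code, counts in reference.SUBSITE_AGE_COUNTS.items():
        total = sum(counts)
        t2_rows.append(
            {
                "topography_code": code,
                "site": SUBSITE_LABELS[code],
                **dict(zip(reference.AGE_GROUP_ORDER, counts)),
                "all_ages": total,
                "percent": 100.0 * total / reference.COHORT_N,
            }
        )
    table2 = pd.DataFrame(t2_rows)

    age = reference.TABLE1_FACTORS["age_group"]
    vis_u50 = age["under45"][0] + age["45to49"][0]
    n_u50 = age["under45"][1] + age["45to49"][1]
    overall_vis = sum(a for a, _ in age.values())
    headline = pd.DataFrame(
        [
            {"quantity": "overall", "percent_visualizable": 100.0 * overall_vis / reference.COHORT_N},
            {"quantity": "under45", "percent_visualizable": 100.0 * age["under45"][0] / age["under45"][1]},
            {"quantity": "45to49", "percent_visualizable": 100.0 * age["45to49"][0] / age["45to49"][1]},
            {"quantity": "50plus", "percent_visualizable": 100.0 * age["50plus"][0] / age["50plus"][1]},
            {"quantity": "under50", "percent_visualizable": 100.0 * vis_u50 / n_u50},
        ]
    )
    return {"table1": table1, "table2": table2, "headline_proportions": headline}
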