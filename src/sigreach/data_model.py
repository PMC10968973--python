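"""Cohort data structures, case-listing ingestion, and exclusion rules.

A cohort is held as a :class:`pandas.DataFrame` with one row per patient
and the canonical columns

``topography_code, age_years, sex, race_ethnicity, stage, year_dx,
survival_months, vital_status, autopsy_only``

plus, after :func:`apply_exclusions`, the derived columns ``age_group``,
``year_group`` and ``reach``.  ``survival_months`` is a nullable integer
(missing means incomplete follow-up, which is an exclusion).

Exclusion rules mirror registry practice for this analysis: unknown
summary stage, non-specific or unanalyzed subsites, autopsy-only
diagnoses, incomplete survival data, and zero survival are removed, in a
fixed documented order, with per-rule counts kept in an
:class:`ExclusionLog` (the order matters for the per-rule counts because a
record may violate several rules; the first matching rule claims it).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from sigreach.subsites import (
    ANALYZED_CODES,
    ReachCategory,
    classify_subsite,
    normalize_topography,
)

__all__ = [
    "COHORT_COLUMNS",
    "AGE_GROUPS",
    "YEAR_GROUPS",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "STAGE_LEVELS",
    "EXCLUSION_RULES",
    "CaseListingError",
    "ExclusionLog",
    "read_case_listing",
    "load_schema",
    "apply_exclusions",
    "add_derived_columns",
    "assign_age_group",
    "assign_year_group",
    "write_cohort",
]

COHORT_COLUMNS = (
    "topography_code",
    "age_years",
    "sex",
    "race_ethnicity",
    "stage",
    "year_dx",
    "survival_months",
    "vital_status",
    "autopsy_only",
)

AGE_GROUPS = ("under45", "45to49", "50plus")
YEAR_GROUPS = ("2000-2004", "2005-2009", "2010-2014", "2015-2020")
SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("NH-White", "Hispanic", "NH-AIAN", "NH-API", "NH-Black", "NH-Unknown")
STAGE_LEVELS = ("localized", "regional", "distant", "unknown")

#: Exclusion rules in application order.
EXCLUSION_RULES = (
    "stage_unknown",
    "nonspecific_or_unlisted_subsite",
    "autopsy_only",
    "missing_survival",
    "zero_survival",
)


class CaseListingError(ValueError):
    """Configuration-level problem with a case-listing file or schema."""


@dataclasses.dataclass
class ExclusionLog:
    """Per-rule removal counts, in application order.

    Satisfies the conservation identity
    ``n_input == n_output + sum(counts.values())``.
    """

    n_input: int
    counts: dict[str, int]
    n_output: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_output + sum(self.counts.values()):
            raise ValueError("exclusion log does not conserve record counts")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def assign_age_group(age_years: int) -> str:
    """Age-group partition: <45, 45-49 inclusive, 50 and over."""
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    if age_years < 45:
        return "under45"
    if age_years <= 49:
        return "45to49"
    return "50plus"


def assign_year_group(year_dx: int) -> str:
    """Diagnosis-year grouping over 2000-2020 (last bin spans six years)."""
    if not 2000 <= year_dx <= 2020:
        raise ValueError(f"year of diagnosis out of range 2000-2020: {year_dx}")
    if year_dx <= 2004:
        return "2000-2004"
    if year_dx <= 2009:
        return "2005-2009"
    if year_dx <= 2014:
        return "2010-2014"
    return "2015-2020"


def load_schema(path: str | Path) -> dict:
    """Load a YAML column-mapping config.

    The file maps source column names to canonical field names under
    ``columns:``, and may list ``missing_survival_values`` (strings that
    encode incomplete survival follow-up in the given export).
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, Mapping) or "columns" not in cfg:
        raise CaseListingError(f"schema file {path} must contain a 'columns' mapping")
    return dict(cfg)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n", ""}:
        return False
    raise ValueError(f"unparseable boolean: {value!r}")


def read_case_listing(
    path: str | Path,
    schema: Mapping | str | Path | None = None,
    *,
    missing_survival_values: Iterable[str] = ("", "unknown", "na", "nan"),
) -> pd.DataFrame:
    """Read a delimited SEER-style case listing into a validated cohort table.

    Parameters
    ----------
    path
        CSV or TSV file with a header row; the delimiter is taken from the
        extension (``.tsv``/``.txt`` tab, otherwise comma).
    schema
        Either a mapping ``{source column: canonical field}``, a path to a
        YAML config with a ``columns`` mapping (see :func:`load_schema`),
        or ``None`` when the file already uses canonical column names.  A
        ``histology`` field may be mapped; if present, only ICD-O-3
        histology 8140 (adenocarcinoma NOS) rows are retained.
    missing_survival_values
        Strings (case-insensitive) that encode incomplete survival data;
        how a given export flags it varies, so it is configurable.

    Returns
    -------
    pandas.DataFrame
        Validated cohort table.  Rows that fail field-level validation are
        dropped from the table but collected (with their 1-based data line
        numbers) in ``result.attrs["row_errors"]`` — never silently.

    Raises
    ------
    CaseListingError
        If a mapped column is absent from the file.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    if schema is None:
        colmap: dict[str, str] = {c: c for c in raw.columns if c in COHORT_COLUMNS + ("histology",)}
    else:
        if isinstance(schema, (str, Path)):
            schema = load_schema(schema)
        colmap = dict(schema.get("columns", schema))
        missing_survival_values = tuple(
            schema.get("missing_survival_values", missing_survival_values)
        ) if isinstance(schema, Mapping) and "columns" in schema else tuple(missing_survival_values)

    missing_cols = [src for src in colmap if src not in raw.columns]
    if missing_cols:
        raise CaseListingError(f"mapped columns absent from {path.name}: {missing_cols}")
    unmapped = set(COHORT_COLUMNS) - set(colmap.values())
    # autopsy_only is frequently absent from exports; default to False.
    if unmapped - {"autopsy_only"}:
        raise CaseListingError(f"schema does not cover required fields: {sorted(unmapped)}")

    df = raw[list(colmap)].rename(columns=colmap)
    if "autopsy_only" not in df.columns:
        df["autopsy_only"] = "false"

    missing_surv = {str(v).strip().lower() for v in missing_survival_values}
    records: list[dict] = []
    row_errors: list[tuple[int, str]] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            records.append(_validate_row(rec, missing_surv))
        except ValueError as exc:
            row_errors.append((line_no, str(exc)))

    cohort = pd.DataFrame(records, columns=COHORT_COLUMNS + (("histology",) if "histology" in colmap.values() else ()))
    if "histology" in cohort.columns:
        cohort = cohort[cohort["histology"] == "8140"].drop(columns="histology")
        cohort = cohort.reset_index(drop=True)
    cohort = _finalize_dtypes(cohort)
    cohort.attrs["row_errors"] = row_errors
    return cohort


def _validate_row(rec: dict, missing_surv: set[str]) -> dict:
    out: dict = {}
    out["topography_code"] = normalize_topography(rec["topography_code"])
    try:
        age = int(str(rec["age_years"]).strip())
    except ValueError:
        raise ValueError(f"unparseable age: {rec['age_years']!r}") from None
    if age < 0:
        raise ValueError(f"negative age: {age}")
    out["age_years"] = age

    sex = str(rec["sex"]).strip().lower()
    if sex not in SEX_LEVELS:
        raise ValueError(f"unknown sex category: {rec['sex']!r}")
    out["sex"] = sex

    race = str(rec["race_ethnicity"]).strip()
    if race not in RACE_LEVELS:
        raise ValueError(f"unknown race/ethnicity category: {race!r}")
    out["race_ethnicity"] = race

    stage = str(rec["stage"]).strip().lower()
    if stage not in STAGE_LEVELS:
        raise ValueError(f"unknown stage category: {rec['stage']!r}")
    out["stage"] = stage

    try:
        year = int(str(rec["year_dx"]).strip())
    except ValueError:
        raise ValueError(f"unparseable year of diagnosis: {rec['year_dx']!r}") from None
    if not 2000 <= year <= 2020:
        raise ValueError(f"year of diagnosis out of range: {year}")
    out["year_dx"] = year

    surv_raw = str(rec["survival_months"]).strip()
    if surv_raw.lower() in missing_surv:
        out["survival_months"] = None
    else:
        try:
            surv = int(surv_raw)
        except ValueError:
            raise ValueError(f"unparseable survival months: {surv_raw!r}") from None
        if surv < 0:
            raise ValueError(f"negative survival months: {surv}")
        out["survival_months"] = surv

    vital = str(rec["vital_status"]).strip().lower()
    if vital not in {"alive", "dead"}:
        raise ValueError(f"unknown vital status: {rec['vital_status']!r}")
    out["vital_status"] = vital
    out["autopsy_only"] = _parse_bool(rec["autopsy_only"])
    if "histology" in rec:
        out["histology"] = str(rec["histology"]).strip()
    return out


def _finalize_dtypes(cohort: pd.DataFrame) -> pd.DataFrame:
    cohort = cohort.copy()
    if len(cohort) == 0:
        for c in COHORT_COLUMNS:
            if c not in cohort.columns:
                cohort[c] = pd.Series(dtype=object)
    cohort["age_years"] = cohort["age_years"].astype("int64") if len(cohort) else cohort["age_years"]
    cohort["year_dx"] = cohort["year_dx"].astype("int64") if len(cohort) else cohort["year_dx"]
    cohort["survival_months"] = cohort["survival_months"].astype("Int64")
    cohort["autopsy_only"] = cohort["autopsy_only"].astype(bool) if len(cohort) else cohort["autopsy_only"]
    return cohort


def add_derived_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach ``age_group``, ``year_group`` and ``reach`` columns."""
    out = cohort.copy()
    out["age_group"] = pd.Categorical(
        [assign_age_group(a) for a in out["age_years"]], categories=AGE_GROUPS
    )
    out["year_group"] = pd.Categorical(
        [assign_year_group(y) for y in out["year_dx"]], categories=YEAR_GROUPS
    )
    out["reach"] = pd.Categorical(
        [classify_subsite(c).value for c in out["topography_code"]],
        categories=[c.value for c in ReachCategory],
    )
    return out


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the cohort exclusion rules and log per-rule counts.

    Rules, in order: unknown stage; topography outside the nine analyzed
    subsites (including the non-specific codes C188, C189, C260);
    autopsy-only diagnosis; missing survival months; zero survival months.
    A record violating several rules is counted once, under the first rule
    that matches.  Idempotent: re-applying to the output removes nothing.

    Returns the retained cohort with derived columns attached, plus the
    :class:`ExclusionLog`.
    """
    n_in = len(cohort)
    masks = {
        "stage_unknown": cohort["stage"].astype(str).eq("unknown"),
        "nonspecific_or_unlisted_subsite": ~cohort["topography_code"].isin(ANALYZED_CODES),
        "autopsy_only": cohort["autopsy_only"].astype(bool),
        "missing_survival": cohort["survival_months"].isna(),
        "zero_survival": cohort["survival_months"].eq(0).fillna(False),
    }
    claimed = pd.Series(False, index=cohort.index)
    counts: dict[str, int] = {}
    for rule in EXCLUSION_RULES:
        hit = masks[rule] & ~claimed
        counts[rule] = int(hit.sum())
        claimed |= hit

    retained = cohort.loc[~claimed].reset_index(drop=True)
    retained = add_derived_columns(retained)
    log = ExclusionLog(n_input=n_in, counts=counts, n_output=len(retained))
    return retained, log


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical cohort file (TSV, derived columns included)."""
    cohort.to_csv(path, sep="\t", index=False)
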