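"""Contingency tables, odds ratios, and logistic regression for reach.

The outcome throughout is binary: tumor subsite visualizable on flexible
sigmoidoscopy (1) versus requiring full colonoscopy (0); records with
``reach == EXCLUDED`` never enter these analyses.

Univariable odds ratios come from the closed-form 2x2 cross-product with
Wald intervals on the log scale, OR = (a/b)/(c/d) and
SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d).  The multivariable model is a
main-effects logistic regression fit by iteratively reweighted least
squares (IRLS), written here rather than delegated so that the fitting
procedure (start at zero, relative log-likelihood tolerance 1e-10, max 50
iterations, explicit separation detection) is fully pinned down; tests
cross-check it against an independent GLM implementation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sigreach.subsites import ReachCategory

__all__ = [
    "ContingencyTable",
    "OddsRatioEstimate",
    "LogisticFit",
    "SeparationError",
    "ConvergenceError",
    "crosstab",
    "odds_ratio_univariable",
    "fit_logistic",
    "fit_logistic_irls",
    "proportion_by_stratum",
    "round_half_up",
]

_VIS = ReachCategory.VISUALIZABLE.value
_COL = ReachCategory.REQUIRES_COLONOSCOPY.value


class SeparationError(RuntimeError):
    """The outcome is perfectly (or degenerately) predicted; MLE diverges."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (report convention), e.g. 73.15 -> 73.2."""
    factor = 10.0**decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


@dataclasses.dataclass
class ContingencyTable:
    """Per-level (visualizable, total) counts for one factor.

    ``levels`` maps level name -> (n_visualizable, n_total); insertion
    order is the display order.  ``reference`` is the baseline level for
    odds ratios.
    """

    factor: str
    levels: dict[str, tuple[int, int]]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError(
                f"reference level {self.reference!r} not present for factor {self.factor!r}"
            )
        for level, (a, n) in self.levels.items():
            if a < 0 or n < 0 or a > n:
                raise ValueError(f"invalid counts for {self.factor}={level}: ({a}, {n})")

    def percent(self, level: str, decimals: int = 1) -> float:
        a, n = self.levels[level]
        if n == 0:
            return float("nan")
        return round_half_up(100.0 * a / n, decimals)


@dataclasses.dataclass
class OddsRatioEstimate:
    """Wald odds-ratio estimate for one factor level versus the reference."""

    level: str
    odds_ratio: float
    log_or: float
    se_log_or: float
    ci_level: float
    ci_low: float
    ci_high: float


@dataclasses.dataclass
class LogisticFit:
    """Converged IRLS maximum-likelihood logistic fit."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_obs: float

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def odds_ratios(self, ci_level: float = 0.95) -> pd.DataFrame:
        """OR = exp(coef) with Wald intervals, one row per non-intercept term."""
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        rows = []
        for i, term in enumerate(self.terms):
            if term == "intercept":
                continue
            b, se = self.params[i], self.bse[i]
            rows.append(
                {
                    "term": term,
                    "odds_ratio": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se)),
                    "ci_high": float(np.exp(b + z * se)),
                }
            )
        return pd.DataFrame(rows)


def _binary_outcome(cohort: pd.DataFrame) -> pd.DataFrame:
    if "reach" not in cohort.columns:
        raise ValueError("cohort lacks a 'reach' column; run apply_exclusions first")
    sub = cohort[cohort["reach"].isin([_VIS, _COL])]
    return sub


def crosstab(
    cohort: pd.DataFrame, factor: str, reference: str | None = None
) -> ContingencyTable:
    """Count (visualizable, total) per level of ``factor``.

    ``reference`` defaults to the first category of the column (categorical
    ordering) or the first level in sorted order otherwise.
    """
    sub = _binary_outcome(cohort)
    col = sub[factor]
    if isinstance(col.dtype, pd.CategoricalDtype):
        level_order = list(col.cat.categories)
    else:
        level_order = sorted(col.dropna().unique())
    levels: dict[str, tuple[int, int]] = {}
    for level in level_order:
        mask = col == level
        n = int(mask.sum())
        if n == 0:
            continue
        a = int((sub.loc[mask, "reach"] == _VIS).sum())
        levels[level] = (a, n)
    ref = reference if reference is not None else next(iter(levels))
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} unseen in cohort for factor {factor!r}")
    return ContingencyTable(factor=factor, levels=levels, reference=ref)


def odds_ratio_univariable(
    table: ContingencyTable,
    level: str,
    ci_level: float = 0.95,
    continuity_correction: bool = False,
) -> OddsRatioEstimate:
    """Closed-form 2x2 odds ratio of ``level`` versus the table's reference.

    With cells a = visualizable at level, b = not visualizable at level,
    and c, d likewise at the reference: OR = (a/b)/(c/d), with the Wald
    interval exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    ``continuity_correction`` adds 0.5 to every cell (Haldane-Anscombe),
    needed only when a cell is zero.
    """
    if level == table.reference:
        raise ValueError("level must differ from the reference level")
    a, n1 = table.levels[level]
    c, n0 = table.levels[table.reference]
    b, d = n1 - a, n0 - c
    cells = np.array([a, b, c, d], dtype=float)
    if continuity_correction:
        cells = cells + 0.5
    if np.any(cells == 0):
        raise ZeroDivisionError(
            "zero cell in 2x2 table; pass continuity_correction=True to use "
            "the Haldane-Anscombe 0.5 correction"
        )
    a_, b_, c_, d_ = cells
    log_or = float(np.log((a_ / b_) / (c_ / d_)))
    se = float(np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return OddsRatioEstimate(
        level=level,
        odds_ratio=float(np.exp(log_or)),
        log_or=log_or,
        se_log_or=se,
        ci_level=ci_level,
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
    )


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Newton/IRLS core for binomial logistic regression.

    ``y`` may be 0/1 indicators or cell proportions; ``weights`` are
    binomial denominators (cell totals) or prior weights, default 1.
    Convergence: relative log-likelihood change < ``tol``.  Returns
    ``(beta, cov, loglik, n_iter, converged)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.all(y * w == 0) or np.all((1 - y) * w == 0):
        raise SeparationError("outcome is constant; the model is degenerate")

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    ll_old = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + tol):
            converged = True
            break
        ll_old = ll
        irls_w = w * p * (1 - p)
        z_work = eta + (y - p) / (p * (1 - p))
        XtW = X.T * irls_w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z_work)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (separation or collinear design)"
            ) from None
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "diverging coefficients; data are (quasi-)separated"
            )
        eta = X @ beta
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    info = (X.T * (w * p * (1 - p))) @ X
    cov = np.linalg.inv(info)
    return beta, cov, ll, n_iter, converged


def _build_design(
    cohort: pd.DataFrame, factors: Mapping[str, Sequence[str]]
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix; each factor's first listed level is the
    reference and gets no column."""
    n = len(cohort)
    cols = [np.ones(n)]
    names = ["intercept"]
    for factor, level_order in factors.items():
        observed = set(cohort[factor].astype(str).unique())
        unknown = observed - set(map(str, level_order))
        if unknown:
            raise ValueError(f"unlisted levels for factor {factor!r}: {sorted(unknown)}")
        for level in list(level_order)[1:]:
            cols.append((cohort[factor].astype(str) == str(level)).to_numpy(float))
            names.append(f"{factor}[{level}]")
    return np.column_stack(cols), names


def fit_logistic(
    cohort: pd.DataFrame,
    factors: Mapping[str, Sequence[str]],
    *,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> LogisticFit:
    """Multivariable logistic regression of reach on categorical factors.

    ``factors`` maps column name -> ordered level list, reference first
    (e.g. 50plus, female, localized, NH-White, 2000-2004 for the full
    demographic model).  Main effects only.  Identical factor-level rows
    are aggregated into binomial cells before fitting, so the fit cost is
    bounded by the number of distinct covariate patterns, not patients.
    """
    sub = _binary_outcome(cohort)
    if len(sub) == 0:
        raise ValueError("no records with a binary reach outcome")
    y_ind = (sub["reach"] == _VIS).astype(int)
    keys = [sub[f].astype(str) for f in factors]
    grouped = (
        pd.DataFrame({"_y": y_ind, **{f: k for f, k in zip(factors, keys)}})
        .groupby(list(factors), observed=True)["_y"]
        .agg(["sum", "count"])
        .reset_index()
    )
    X, names = _build_design(grouped, factors)
    y = grouped["sum"].to_numpy(float) / grouped["count"].to_numpy(float)
    w = grouped["count"].to_numpy(float)
    beta, cov, ll, n_iter, converged = fit_logistic_irls(
        X, y, w, tol=tol, max_iter=max_iter
    )
    return LogisticFit(
        terms=names,
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        cov=cov,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        n_obs=float(w.sum()),
    )


def proportion_by_stratum(
    cohort: pd.DataFrame, rows: str = "age_group", cols: str = "stage"
) -> pd.DataFrame:
    """Visualizable proportion per (row, column) stratum with marginals.

    Returns a tidy table with one record per cell (including ``all`` row
    and column marginals): visualizable count, total, and percent rounded
    half-up to one decimal; empty strata report percent as NaN
    (not estimable).
    """
    sub = _binary_outcome(cohort)
    row_levels = _observed_levels(sub[rows])
    col_levels = _observed_levels(sub[cols])
    records = []
    for r in row_levels + ["all"]:
        rmask = np.ones(len(sub), bool) if r == "all" else (sub[rows] == r).to_numpy()
        for c in col_levels + ["all"]:
            cmask = np.ones(len(sub), bool) if c == "all" else (sub[cols] == c).to_numpy()
            cell = sub[rmask & cmask]
            n = len(cell)
            a = int((cell["reach"] == _VIS).sum())
            records.append(
                {
                    rows: r,
                    cols: c,
                    "n_visualizable": a,
                    "n_total": n,
                    "percent": round_half_up(100.0 * a / n, 1) if n else float("nan"),
                }
            )
    return pd.DataFrame(records)


def _observed_levels(col: pd.Series) -> list:
    if isinstance(col.dtype, pd.CategoricalDtype):
        present = set(col.dropna().unique())
        return [l for l in col.cat.categories if l in present]
    return sorted(col.dropna().unique())
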