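"""Model-building recipe: stepwise refinement, forward check, VIF screen,
added-last importance, temporal models, within-year nesting, and the
observer-type sensitivity check."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import term_is_categorical
from .errors import InvalidArgumentError
from .glmm import (
    FitResult,
    LRTResult,
    ModelSpec,
    fit_glmm,
    likelihood_ratio_test,
    pseudo_r2_adjusted,
    tukey_posthoc,
)
from .synth import factor_group

DEFAULT_ALPHA = 0.05


@dataclass
class RefinementStep:
    step: int
    action: str          # "drop" | "add" | "stop" | "non-estimable"
    term: str | None
    lrt: LRTResult | None

    def as_line(self) -> str:
        if self.lrt is None:
            return f"{self.step}\t{self.action}\t{self.term or ''}\t\t\t"
        return (f"{self.step}\t{self.action}\t{self.term}\t"
                f"{self.lrt.chi_square:.4f}\t{self.lrt.df}\t{self.lrt.p_value:.6g}")


@dataclass
class RefinementTrace:
    steps: list[RefinementStep]
    final_spec: ModelSpec
    final_fit: FitResult | None
    non_estimable: bool = False
    forward_agreement: bool | None = None
    observer_sensitivity: bool | None = None

    def log_lines(self) -> list[str]:
        return [s.as_line() for s in self.steps]


def _term_pvalues(spec: ModelSpec, data: pd.DataFrame, fit: FitResult,
                  droppable, mode: str) -> dict[str, LRTResult | None]:
    out = {}
    for term in droppable:
        reduced = fit_glmm(spec.drop_term(term), data, mode=mode)
        if not reduced.converged:
            out[term] = None
            continue
        out[term] = likelihood_ratio_test(fit, reduced)
    return out


def backward_stepwise(spec: ModelSpec, data: pd.DataFrame,
                      alpha: float = DEFAULT_ALPHA, protected=(),
                      mode: str = "agq0") -> RefinementTrace:
    """Iteratively drop the least-significant term until all remaining terms
    test below *alpha*.

    Ties among candidate deletions break by larger LRT p, then smaller
    absolute coefficient, then specification order.  Random effects and
    *protected* terms are never dropped.  Every step is logged.
    """
    protected = set(protected)
    current = spec
    steps: list[RefinementStep] = []
    step_no = 0
    fit = fit_glmm(current, data, mode=mode)
    while True:
        if not fit.converged:
            steps.append(RefinementStep(step_no, "non-estimable", None, None))
            return RefinementTrace(steps, current, fit, non_estimable=True)
        droppable = [t for t in current.fixed_terms if t not in protected]
        if not droppable:
            break
        lrts = _term_pvalues(current, data, fit, droppable, mode)
        candidates = []
        for order, term in enumerate(droppable):
            res = lrts[term]
            if res is None:
                continue
            if res.p_value >= alpha:
                candidates.append((-res.p_value, abs(fit.term_beta(term)), order, term, res))
        if not candidates:
            break
        candidates.sort()
        _, _, _, worst, res = candidates[0]
        step_no += 1
        steps.append(RefinementStep(step_no, "drop", worst, res))
        current = current.drop_term(worst)
        fit = fit_glmm(current, data, mode=mode)
    steps.append(RefinementStep(step_no + 1, "stop", None, None))
    return RefinementTrace(steps, current, fit)


def forward_check(trace: RefinementTrace, spec: ModelSpec, data: pd.DataFrame,
                  alpha: float = DEFAULT_ALPHA, protected=(),
                  mode: str = "agq0") -> bool:
    """Greedy forward selection from the intercept(+protected) model; the
    returned flag is True iff it reaches the same final term set as the
    backward trace.  Disagreement is a reported outcome, never an error."""
    protected = [t for t in spec.fixed_terms if t in set(protected)]
    remaining = [t for t in spec.fixed_terms if t not in protected]
    chosen: list[str] = []
    current = spec.with_terms(tuple(protected))
    fit = fit_glmm(current, data, mode=mode)
    while remaining and fit.converged:
        best = None
        for order, term in enumerate(remaining):
            cand = fit_glmm(current.add_term(term), data, mode=mode)
            if not cand.converged:
                continue
            res = likelihood_ratio_test(cand, fit)
            if res.p_value < alpha and (best is None or res.p_value < best[0]):
                best = (res.p_value, order, term, cand)
        if best is None:
            break
        _, _, term, fit = best
        chosen.append(term)
        current = current.add_term(term)
        remaining.remove(term)
    forward_set = set(chosen) | set(protected)
    backward_set = set(trace.final_spec.fixed_terms)
    agreement = forward_set == backward_set
    trace.forward_agreement = agreement
    return agreement


def vif_screen(data: pd.DataFrame, terms, threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors 1/(1-R^2) for continuous predictors.

    Perfectly collinear terms are reported as infinite and flagged."""
    terms = list(terms)
    if len(terms) < 2:
        raise InvalidArgumentError("VIF needs at least 2 continuous terms")
    X = np.column_stack([np.asarray(data[t], dtype=float) for t in terms])
    X = X - X.mean(axis=0)
    rows = []
    n = X.shape[0]
    for j, term in enumerate(terms):
        xj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        tss = float(xj @ xj)
        if tss == 0:
            raise InvalidArgumentError(f"term {term!r} has zero variance")
        r2 = 1.0 - float(resid @ resid) / tss
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append((term, float(r2), vif, bool(vif > threshold)))
    return pd.DataFrame(rows, columns=["term", "r_squared", "vif", "flagged"])


@dataclass
class ImportanceTable:
    """Per-predictor added-last adjusted-R2 changes for one final model."""

    table: pd.DataFrame           # term, group, delta_r2, delta_r2_relative
    group_means: pd.Series        # mean delta_r2 per PI/PA/TP group
    final_r2: float
    most_important: str | None

    def ranking(self) -> list[str]:
        return list(self.table.sort_values("delta_r2", ascending=False)["term"])


def importance_added_last(final_spec: ModelSpec, data: pd.DataFrame,
                          mode: str = "agq0") -> ImportanceTable:
    """Added-last importance: for each retained predictor, the change in
    adjusted pseudo-R2 between the final model and the final model without
    that predictor, plus group means over the PI/PA/TP factor partition."""
    fit = fit_glmm(final_spec, data, mode=mode)
    if not fit.converged:
        raise InvalidArgumentError("final model did not converge")
    null_fit = fit_glmm(final_spec.with_terms(()), data, mode=mode)
    r2_full = pseudo_r2_adjusted(fit, null_fit)
    rows = []
    for term in final_spec.fixed_terms:
        sub = fit_glmm(final_spec.drop_term(term), data, mode=mode)
        if not sub.converged:
            rows.append((term, _group_or_none(term), np.nan, np.nan, False))
            continue
        r2_sub = pseudo_r2_adjusted(sub, null_fit)
        delta = r2_full - r2_sub
        rel = delta / r2_full if r2_full != 0 else np.nan
        rows.append((term, _group_or_none(term), delta, rel, True))
    table = pd.DataFrame(rows, columns=["term", "group", "delta_r2",
                                        "delta_r2_relative", "estimable"])
    grouped = table.dropna(subset=["group"]).groupby("group")["delta_r2"].mean()
    est = table[table["estimable"] & table["delta_r2"].notna()]
    most = est.loc[est["delta_r2"].idxmax(), "term"] if len(est) else None
    return ImportanceTable(table=table, group_means=grouped,
                           final_r2=r2_full, most_important=most)


def _group_or_none(term: str):
    try:
        return factor_group(term)
    except InvalidArgumentError:
        return None


@dataclass
class TemporalResult:
    response: str
    fit: FitResult
    year_lrt: LRTResult | None
    time_of_day_lrt: LRTResult | None
    nested_time_z: pd.DataFrame | None   # per-year slope, z, p (NaN rows = NA)
    year_tukey: pd.DataFrame | None
    notes: list[str] = field(default_factory=list)


def temporal_models(spec: ModelSpec, data: pd.DataFrame,
                    alpha: float = DEFAULT_ALPHA, mode: str = "agq0",
                    year_col: str = "year", time_col: str = "time_of_day") -> TemporalResult:
    """Fit the year + time-of-day model for one response, with time-of-day
    additionally nested within year, and Tukey year contrasts.

    *spec* supplies the response/family/random structure; its fixed terms
    beyond year and time-of-day (e.g. observer type) are kept as-is."""
    notes: list[str] = []
    years = sorted(data[year_col].astype(str).unique())
    base_terms = [t for t in spec.fixed_terms if t not in (year_col, time_col)]
    full = spec.with_terms(tuple([year_col, time_col] + base_terms))
    fit = fit_glmm(full, data, mode=mode)
    year_lrt = tod_lrt = None
    tukey = None
    nested = None
    if len(years) < 2:
        notes.append("single year in data: temporal contrasts skipped")
        return TemporalResult(spec.response, fit, None, None, None, None, notes)
    if fit.converged:
        red_y = fit_glmm(full.drop_term(year_col), data, mode=mode)
        if red_y.converged:
            year_lrt = likelihood_ratio_test(fit, red_y)
        red_t = fit_glmm(full.drop_term(time_col), data, mode=mode)
        if red_t.converged:
            tod_lrt = likelihood_ratio_test(fit, red_t)
        if len(years) >= 3:
            tukey = tukey_posthoc(fit, year_col)
        else:
            notes.append("fewer than 3 years: Tukey contrasts skipped")
    nested_spec = full.drop_term(time_col).add_term(f"{time_col}:{year_col}")
    nfit = fit_glmm(nested_spec, data, mode=mode)
    if nfit.converged:
        nested = _nested_term_table(nfit, f"{time_col}:{year_col}", years)
    return TemporalResult(spec.response, fit, year_lrt, tod_lrt, nested, tukey, notes)


def _nested_term_table(fit: FitResult, term: str, levels) -> pd.DataFrame:
    info = fit.design_info
    present = info.categorical_levels.get(term, [])
    rows = []
    cols = info.columns_for(term)
    by_level = dict(zip(present, cols))
    for level in levels:
        if level not in by_level:
            rows.append((level, np.nan, np.nan, np.nan))
            continue
        j = by_level[level]
        slope = fit.coefficients.iloc[j]
        z = fit.z.iloc[j]
        p = 2 * stats.norm.sf(abs(z))
        rows.append((level, slope, z, p))
    return pd.DataFrame(rows, columns=["year", "slope", "z", "p"])


def within_year_nested(predictor: str, final_spec: ModelSpec, data: pd.DataFrame,
                       alpha: float = DEFAULT_ALPHA, mode: str = "agq0",
                       year_col: str = "year") -> pd.DataFrame:
    """Per-year significance of one retained predictor.

    Continuous predictors are nested within year (per-year slopes, Wald z);
    categorical predictors are tested by per-year subset LRTs.  Years in
    which the predictor does not vary are reported as NA rows."""
    if predictor not in final_spec.fixed_terms:
        raise InvalidArgumentError(f"{predictor!r} is not in the final model")
    if year_col not in data.columns:
        raise InvalidArgumentError(f"year column {year_col!r} missing")
    years = sorted(data[year_col].astype(str).unique())
    if term_is_categorical(data, predictor):
        rows = []
        for year in years:
            sub = data[data[year_col].astype(str) == year]
            if sub[predictor].nunique() < 2:
                rows.append((year, np.nan, np.nan, np.nan))
                continue
            terms = tuple(t for t in final_spec.fixed_terms if t != year_col)
            full = fit_glmm(final_spec.with_terms(terms), sub, mode=mode)
            red = fit_glmm(final_spec.with_terms(
                tuple(t for t in terms if t != predictor)), sub, mode=mode)
            if not (full.converged and red.converged):
                rows.append((year, np.nan, np.nan, np.nan))
                continue
            res = likelihood_ratio_test(full, red)
            rows.append((year, res.chi_square, np.nan, res.p_value))
        out = pd.DataFrame(rows, columns=["year", "chi_square", "z", "p"])
    else:
        terms = tuple(t if t != predictor else f"{predictor}:{year_col}"
                      for t in final_spec.fixed_terms)
        nfit = fit_glmm(final_spec.with_terms(terms), data, mode=mode)
        out = _nested_term_table(nfit, f"{predictor}:{year_col}", years)
        out = out.rename(columns={"slope": "estimate"})
        out.insert(1, "chi_square", np.nan)
        out = out[["year", "chi_square", "z", "p"]]
    sig = pd.array(out["p"] < alpha, dtype="boolean")
    sig[out["p"].isna().to_numpy()] = pd.NA
    out["significant"] = sig
    out.attrs["n_significant"] = int((out["p"] < alpha).sum())
    out.attrs["n_years"] = len(years)
    return out


def observer_sensitivity(final_spec: ModelSpec, data: pd.DataFrame,
                         alpha: float = DEFAULT_ALPHA, mode: str = "agq0",
                         observer_col: str = "observer_type") -> tuple[bool | None, pd.DataFrame]:
    """Refit with and without observer type; the flag is True iff the set of
    significant terms is unchanged.  Returns (flag, comparison table); the
    flag is None when no observer column is available (skipped, noticed)."""
    if observer_col not in data.columns or observer_col not in final_spec.fixed_terms:
        return None, pd.DataFrame()
    with_obs = fit_glmm(final_spec, data, mode=mode)
    without_spec = final_spec.drop_term(observer_col)
    other_terms = [t for t in final_spec.fixed_terms if t != observer_col]
    rows = []
    agree = True
    for term in other_terms:
        p_with = _single_term_p(final_spec, data, with_obs, term, mode)
        p_without = _single_term_p(without_spec, data, None, term, mode)
        sig_w = p_with < alpha if p_with is not None else None
        sig_wo = p_without < alpha if p_without is not None else None
        if sig_w != sig_wo:
            agree = False
        rows.append((term, p_with, p_without, sig_w, sig_wo))
    table = pd.DataFrame(rows, columns=["term", "p_with_observer",
                                        "p_without_observer",
                                        "significant_with", "significant_without"])
    return agree, table


def _single_term_p(spec: ModelSpec, data: pd.DataFrame, fit, term, mode):
    if fit is None:
        fit = fit_glmm(spec, data, mode=mode)
    if not fit.converged:
        return None
    red = fit_glmm(spec.drop_term(term), data, mode=mode)
    if not red.converged:
        return None
    return likelihood_ratio_test(fit, red).p_value
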