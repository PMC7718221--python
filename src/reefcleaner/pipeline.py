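"""End-to-end orchestration of the analysis stages for one dataset:
temporal models, contextual-factor model refinement and importance,
subsample consistency classification, and spatial summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consistency import (
    beta_interval,
    classify_consistency,
    rank_importance,
    run_subsample_simulations,
)
from .design import standardize_predictors
from .errors import NonEstimableError, ValidationError
from .glmm import (
    BINOMIAL_PROBIT,
    fit_glmm,
    likelihood_ratio_test,
    overdispersion_ratio,
)
from .spatial import (
    aggregation_correlation,
    aggregation_pc1,
    mantel_test,
    station_distance_matrix,
    station_predicted_summary,
    station_random_effect_test,
)
from .synth import CONTINUOUS_FACTORS
from .tables import RESPONSES, build_response_table, temporal_spec
from .workflow import (
    backward_stepwise,
    forward_check,
    importance_added_last,
    observer_sensitivity,
    temporal_models,
    vif_screen,
    within_year_nested,
)


@dataclass
class ResponseAnalysis:
    response: str
    trace: object
    final_fit: object
    vif: pd.DataFrame
    importance: object | None
    consistency: object | None
    rank_table: pd.DataFrame | None
    beta_intervals: dict[str, tuple[float, float]]
    within_year: dict[str, pd.DataFrame]
    observer_flag: bool | None
    overdispersion: float | None
    full_p: dict[str, float]
    notes: list[str] = field(default_factory=list)


@dataclass
class SpatialAnalysis:
    response: str
    summary: object
    mantel_mean: object
    mantel_rse: object
    correlation: tuple[float, float] | None
    station_lrt: object | None


def analyze_response(records, events, traits, survey, response: str,
                     alpha: float = 0.05, n_sim: int = 1000,
                     subsample_size: int = 192, threshold: float = 0.95,
                     master_seed: int = 0, mode: str = "agq0",
                     run_consistency: bool = True, **table_kw) -> ResponseAnalysis:
    """Full contextual-factor analysis for one behaviour."""
    data, spec, _ = build_response_table(records, events, traits, survey,
                                         response, **table_kw)
    vif = vif_screen(data, CONTINUOUS_FACTORS)
    trace = backward_stepwise(spec, data, alpha=alpha,
                              protected=("observer_type",), mode=mode)
    notes = []
    if trace.non_estimable:
        notes.append("backward stepwise hit a non-estimable step")
        return ResponseAnalysis(response, trace, trace.final_fit, vif, None, None,
                                None, {}, {}, None, None, {}, notes)
    forward_check(trace, spec, data, alpha=alpha,
                  protected=("observer_type",), mode=mode)
    final_spec = trace.final_spec
    final_fit = trace.final_fit
    obs_flag, _ = observer_sensitivity(final_spec, data, alpha=alpha, mode=mode)

    overdisp = None
    if spec.family == BINOMIAL_PROBIT:
        overdisp = overdispersion_ratio(final_fit)

    full_p: dict[str, float] = {}
    for term in final_spec.fixed_terms:
        red = fit_glmm(final_spec.drop_term(term), data, mode=mode)
        if red.converged:
            full_p[term] = likelihood_ratio_test(final_fit, red).p_value

    importance = importance_added_last(final_spec, data, mode=mode)

    within = {}
    for term in final_spec.fixed_terms:
        if term == "observer_type":
            continue
        if full_p.get(term, 1.0) < alpha:
            within[term] = within_year_nested(term, final_spec, data,
                                              alpha=alpha, mode=mode)

    report = None
    rank_table = None
    intervals: dict[str, tuple[float, float]] = {}
    if run_consistency and len([t for t in final_spec.fixed_terms
                                if t != "observer_type"]):
        sim_spec = final_spec
        runs = run_subsample_simulations(sim_spec, data, n_sim=n_sim,
                                         subsample_size=subsample_size,
                                         master_seed=master_seed, mode=mode)
        report = classify_consistency(runs, full_p, alpha=alpha, threshold=threshold)
        # the observer covariate is plumbing, not a contextual factor
        report.table = report.table[
            report.table["predictor"] != "observer_type"].reset_index(drop=True)
        consistent = report.consistent_predictors()
        if consistent:
            try:
                rank_table = rank_importance(runs, consistent, alpha=alpha)
            except (ValidationError, NonEstimableError) as exc:
                notes.append(f"rank importance unavailable: {exc}")
            for t in consistent:
                try:
                    intervals[t] = beta_interval(runs, t)
                except (ValidationError, NonEstimableError):
                    pass
    return ResponseAnalysis(response, trace, final_fit, vif, importance, report,
                            rank_table, intervals, within, obs_flag, overdisp,
                            full_p, notes)


def analyze_spatial(records, events, traits, survey, stations, response: str,
                    alpha: float = 0.05, n_perm: int = 9999, master_seed: int = 0,
                    mode: str = "agq0", **table_kw) -> SpatialAnalysis:
    """Temporal-model predictions per station, Mantel tests of spatial
    autocorrelation for means and relative standard errors, and the
    aggregation-PC1 correlation, for one behaviour."""
    data, spec, _ = build_response_table(records, events, traits, survey,
                                         response, **table_kw)
    data, _ = standardize_predictors(data, ["time_of_day"])
    tspec = temporal_spec(spec)
    tres = temporal_models(tspec, data, alpha=alpha, mode=mode)
    # keep only significant temporal terms for prediction, per the recipe
    keep = []
    if tres.year_lrt is not None and tres.year_lrt.p_value < alpha:
        keep.append("year")
    if tres.time_of_day_lrt is not None and tres.time_of_day_lrt.p_value < alpha:
        keep.append("time_of_day")
    pred_spec = tspec.with_terms(tuple(keep))
    pred_fit = fit_glmm(pred_spec, data, mode=mode)
    summary = station_predicted_summary(pred_fit, data)
    dmat, ids = station_distance_matrix(stations)
    idx = {s: i for i, s in enumerate(ids)}
    present = [s for s in summary.table["station_id"] if s in idx]
    sel = np.array([idx[s] for s in present])
    dsub = dmat[np.ix_(sel, sel)]
    tab = summary.table.set_index("station_id").loc[present]

    def value_dist(values: np.ndarray) -> np.ndarray:
        return np.abs(values[:, None] - values[None, :])

    mantel_mean = mantel_rse = None
    if len(present) >= 3:
        mantel_mean = mantel_test(dsub, value_dist(tab["predicted_mean"].to_numpy()),
                                  n_perm=n_perm, seed=master_seed)
        rse = tab["rse_percent"].to_numpy()
        ok = np.isfinite(rse)
        if ok.sum() >= 3:
            mantel_rse = mantel_test(dsub[np.ix_(ok, ok)], value_dist(rse[ok]),
                                     n_perm=n_perm, seed=master_seed + 1)
    corr = None
    pc1 = aggregation_pc1([s for s in stations] if not isinstance(stations, pd.DataFrame)
                          else stations)
    try:
        corr = aggregation_correlation(summary.means(), pc1)
    except ValidationError:
        pass
    try:
        st_lrt = station_random_effect_test(pred_spec, data, mode=mode)
    except (ValidationError, NonEstimableError):
        st_lrt = None
    return SpatialAnalysis(response, summary, mantel_mean, mantel_rse, corr, st_lrt)


def analyze_dataset(records, events, traits, survey, stations,
                    responses=RESPONSES, **kw) -> dict[str, ResponseAnalysis]:
    return {r: analyze_response(records, events, traits, survey, r, **kw)
            for r in responses}
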