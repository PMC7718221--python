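"""Consistency classification of predictors by subsample refitting.

The final model for a behaviour is refit many times on random subsamples
of the observations (without replacement, the subsample size matching the
mean number of observations per year).  Each refit records, per predictor,
a likelihood-ratio p-value and the standardized coefficient; predictors
significant in at least a threshold share of refits are *consistent*,
predictors significant on the full data but below the threshold are
*dynamic*.  Consistent predictors are further ranked by the share of
refits in which their |beta| was the largest.

Standardization is expected to have been applied once on the full dataset
before calling into this module, so coefficients are comparable across
refits; non-converged refits are excluded from both numerator and
denominator, with the converged count reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, NonEstimableError
from .glmm import GlmmProblem, ModelSpec
from .synth import factor_group
from .errors import ValidationError

DEFAULT_N_SIM = 1000
DEFAULT_SUBSAMPLE = 192
DEFAULT_THRESHOLD = 0.95


@dataclass
class SimulationRun:
    run_index: int
    seed: int
    observation_ids: np.ndarray
    p_values: dict[str, float]
    betas: dict[str, float]
    converged: bool


def run_subsample_simulations(final_spec: ModelSpec, data: pd.DataFrame,
                              n_sim: int = DEFAULT_N_SIM,
                              subsample_size: int = DEFAULT_SUBSAMPLE,
                              master_seed: int = 0,
                              obs_col: str = "observation_id",
                              mode: str = "agq0") -> list[SimulationRun]:
    """Refit the final model on ``n_sim`` random observation subsamples.

    Run *i* is seeded ``master_seed + i`` (i = 1..n_sim) and draws
    ``subsample_size`` distinct observation IDs; every data row belonging
    to a selected observation enters the refit (so duration models keep
    all events of selected observations).  Non-converged runs are recorded
    as such, never retried.
    """
    if obs_col not in data.columns:
        raise InvalidArgumentError(f"observation column {obs_col!r} missing")
    obs_ids = pd.unique(data[obs_col])
    if len(obs_ids) < subsample_size:
        raise InvalidArgumentError(
            f"data has {len(obs_ids)} distinct observations, "
            f"fewer than subsample_size={subsample_size}"
        )
    full = GlmmProblem.from_spec(final_spec, data)
    terms = list(final_spec.fixed_terms)
    reduced = {t: GlmmProblem.from_spec(final_spec.drop_term(t), data) for t in terms}
    term_df = {t: len(full.design_info.columns_for(t)) for t in terms}
    # map observation id -> row indices once
    codes, uniq = pd.factorize(data[obs_col])
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(len(uniq) + 1))
    rows_for = {uniq[i]: order[bounds[i]:bounds[i + 1]] for i in range(len(uniq))}

    theta0 = full.fit(mode=mode).theta  # warm-start bracket for every refit
    runs: list[SimulationRun] = []
    for i in range(1, n_sim + 1):
        seed = master_seed + i
        rng = np.random.default_rng(seed)
        chosen = rng.choice(obs_ids, size=subsample_size, replace=False)
        rows = np.sort(np.concatenate([rows_for[o] for o in chosen]))
        fit_f = full.subset(rows).fit(mode=mode, theta0=theta0)
        ok = fit_f.converged
        ps: dict[str, float] = {}
        bs: dict[str, float] = {}
        for t in terms:
            bs[t] = fit_f.term_beta(t) if term_df[t] == 1 else np.nan
            fit_r = reduced[t].subset(rows).fit(mode=mode, theta0=theta0)
            if not fit_r.converged:
                ok = False
                ps[t] = np.nan
                continue
            chi2 = max(2.0 * (fit_f.loglik - fit_r.loglik), 0.0)
            ps[t] = float(stats.chi2.sf(chi2, term_df[t]))
        runs.append(SimulationRun(i, seed, np.asarray(chosen), ps, bs, ok))
    n_conv = sum(r.converged for r in runs)
    if n_sim and n_conv / n_sim < 0.95:
        warnings.warn(f"only {n_conv}/{n_sim} subsample refits converged")
    return runs


@dataclass
class ConsistencyReport:
    table: pd.DataFrame
    n_runs: int
    n_converged: int
    alpha: float
    threshold: float

    def label_of(self, predictor: str) -> str:
        return self.table.set_index("predictor").loc[predictor, "label"]

    def consistent_predictors(self) -> list[str]:
        return list(self.table.loc[self.table["label"] == "consistent", "predictor"])


def classify_consistency(runs: list[SimulationRun],
                         full_p: dict[str, float],
                         alpha: float = 0.05,
                         threshold: float = DEFAULT_THRESHOLD) -> ConsistencyReport:
    """Label each predictor consistent / dynamic / non-predictor.

    ``proportion_significant`` is computed over converged runs only (the
    denominator convention is recorded on the report).  A predictor is
    *consistent* when that proportion reaches *threshold*, *dynamic* when
    it is significant in the full-data model (``full_p``) but below the
    threshold, and a *non-predictor* otherwise.  Effect direction is the
    sign of the median coefficient (NA for categorical predictors)."""
    conv = [r for r in runs if r.converged]
    if not conv:
        raise NonEstimableError("no converged subsample runs")
    terms = list(conv[0].p_values)
    rows = []
    for t in terms:
        ps = np.array([r.p_values[t] for r in conv])
        bs = np.array([r.betas[t] for r in conv])
        prop = float(np.mean(ps < alpha))
        if prop >= threshold:
            label = "consistent"
        elif full_p.get(t, 1.0) < alpha:
            label = "dynamic"
        else:
            label = "non-predictor"
        direction = np.nan
        if np.isfinite(bs).any():
            med = float(np.median(bs[np.isfinite(bs)]))
            direction = float(np.sign(med))
        try:
            group = factor_group(t)
        except ValidationError:
            group = ""
        rows.append((t, group, prop, float(ps.min()), float(ps.max()),
                     direction, label, len(conv)))
    table = pd.DataFrame(rows, columns=[
        "predictor", "group", "proportion_significant", "p_min", "p_max",
        "direction", "label", "n_converged"])
    return ConsistencyReport(table=table, n_runs=len(runs), n_converged=len(conv),
                             alpha=alpha, threshold=threshold)


def rank_importance(runs: list[SimulationRun], consistent_set,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Share of converged runs in which each consistent predictor had the
    largest |beta| (its rank-importance p).

    Predictors with p < alpha were effectively never the most important
    one; a singleton consistent set is trivially most important (p = 1,
    with a notice in the table attrs)."""
    consistent = list(consistent_set)
    if not consistent:
        raise InvalidArgumentError("consistent set is empty")
    conv = [r for r in runs if r.converged]
    if not conv:
        raise NonEstimableError("no converged subsample runs")
    if len(consistent) == 1:
        out = pd.DataFrame({"predictor": consistent, "rank_importance_p": [1.0],
                            "never_most_important": [False]})
        out.attrs["notice"] = "singleton consistent set: trivially most important"
        return out
    wins = {t: 0 for t in consistent}
    n_used = 0
    for r in conv:
        vals = {t: abs(r.betas.get(t, np.nan)) for t in consistent}
        if not all(np.isfinite(v) for v in vals.values()):
            continue
        n_used += 1
        wins[max(vals, key=vals.get)] += 1
    if n_used == 0:
        raise NonEstimableError("no runs with coefficients for all consistent predictors")
    out = pd.DataFrame({
        "predictor": consistent,
        "rank_importance_p": [wins[t] / n_used for t in consistent],
    })
    out["never_most_important"] = out["rank_importance_p"] < alpha
    out.attrs["n_runs_used"] = n_used
    return out


def beta_interval(runs: list[SimulationRun], predictor: str,
                  level: float = 0.95, signed: bool = False) -> tuple[float, float]:
    """Empirical percentile interval of the predictor's coefficient
    magnitude (or signed coefficient) across converged runs."""
    if not (0 < level <= 1):
        raise InvalidArgumentError("level must be in (0, 1]")
    conv = [r for r in runs if r.converged]
    vals = np.array([r.betas.get(predictor, np.nan) for r in conv])
    vals = vals[np.isfinite(vals)]
    if len(vals) < 40:
        raise NonEstimableError(
            f"only {len(vals)} converged coefficient values for {predictor!r}; need >= 40"
        )
    if not signed:
        vals = np.abs(vals)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [tail, 1.0 - tail])
    return float(lo), float(hi)
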