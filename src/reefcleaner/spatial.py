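"""Station-level spatial characterization: predicted means with relative
standard errors, Mantel permutation tests on station distances,
aggregation PC1 scores, and aggregation-behaviour correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import (
    InvalidArgumentError,
    NonEstimableError,
    UndefinedStatisticError,
)
from .glmm import FitResult, LRTResult, ModelSpec, fit_glmm, likelihood_ratio_test


@dataclass
class SpatialSummary:
    """Per-station predicted behaviour summary (response scale)."""

    table: pd.DataFrame  # station_id, n, predicted_mean, se, rse_percent

    def means(self) -> pd.Series:
        return self.table.set_index("station_id")["predicted_mean"]


def station_predicted_summary(fit: FitResult, data: pd.DataFrame,
                              station_col: str = "station_id") -> SpatialSummary:
    """Per-station mean of model predictions (response scale, including
    station-level random intercepts) and the relative standard error
    100 * SE / |mean|.

    Stations contributing fewer than 2 predictions, or with mean 0, get an
    NA relative standard error."""
    if not fit.converged:
        raise NonEstimableError("predictions require a converged fit")
    if station_col not in data.columns:
        raise InvalidArgumentError(f"station column {station_col!r} missing")
    if len(data) != fit.n_obs:
        raise InvalidArgumentError("data does not match the fitted rows")
    df = pd.DataFrame({station_col: data[station_col].to_numpy(),
                       "pred": fit.fitted})
    rows = []
    for st, grp in df.groupby(station_col, sort=True):
        n = len(grp)
        mean = float(grp["pred"].mean())
        se = float(grp["pred"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rse = np.nan
        if n >= 2 and mean != 0 and np.isfinite(se):
            rse = 100.0 * se / abs(mean)
        rows.append((st, n, mean, se, rse))
    return SpatialSummary(pd.DataFrame(
        rows, columns=["station_id", "n", "predicted_mean", "se", "rse_percent"]))


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidArgumentError(f"{name} is not square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise InvalidArgumentError(f"{name} is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise InvalidArgumentError(f"{name} has a nonzero diagonal")
    return d


def mantel_test(dist_a, dist_b, n_perm: int = 9999, seed: int = 0,
                exhaustive: bool = False) -> MantelResult:
    """One-sided (upper tail) Mantel permutation test.

    The statistic is the Pearson correlation of the upper-triangle entries;
    rows and columns of the second matrix are permuted jointly and the
    add-one p-value ``(1 + #[r_perm >= r_obs]) / (1 + n_perm)`` is
    reported.  With ``exhaustive=True`` all n! relabellings are enumerated
    instead (tiny instances only) and the p-value is the exact proportion."""
    a = _check_distance_matrix(dist_a, "dist_a")
    b = _check_distance_matrix(dist_b, "dist_b")
    if a.shape != b.shape:
        raise InvalidArgumentError("distance matrices differ in dimension")
    n = a.shape[0]
    if n < 3:
        raise InvalidArgumentError("Mantel test needs at least 3 stations")
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    if np.std(va) == 0 or np.std(b[iu]) == 0:
        raise UndefinedStatisticError("constant distance matrix: correlation undefined")
    r_obs = float(np.corrcoef(va, b[iu])[0, 1])
    if exhaustive:
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(range(n)):
            p = np.asarray(perm)
            r = float(np.corrcoef(va, b[np.ix_(p, p)][iu])[0, 1])
            total += 1
            if r >= r_obs - 1e-12:
                count += 1
        return MantelResult(r_obs, count / total, total)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = float(np.corrcoef(va, b[np.ix_(p, p)][iu])[0, 1])
        if r >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm)


def station_distance_matrix(stations) -> tuple[np.ndarray, list[str]]:
    """Euclidean distance matrix from Station objects or an x/y table."""
    if isinstance(stations, pd.DataFrame):
        ids = list(stations["station_id"])
        xy = stations[["x", "y"]].to_numpy(float)
    else:
        ids = [s.station_id for s in stations]
        xy = np.array([[s.x, s.y] for s in stations], dtype=float)
    return squareform(pdist(xy)), ids


def aggregation_pc1(stations, radius_small: float = 3.0,
                    radius_large: float = 5.0) -> pd.Series:
    """First principal-component score of (nearest-neighbour distance,
    #stations within the small radius, #stations within the large radius).

    Columns are standardized first; zero-variance features are dropped with
    a warning.  The sign is oriented so that larger scores mean more
    aggregated stations (positive loadings on the neighbour counts)."""
    d, ids = station_distance_matrix(stations)
    n = len(ids)
    if n < 3:
        raise InvalidArgumentError("aggregation PC1 needs at least 3 stations")
    if radius_small > radius_large:
        raise InvalidArgumentError("radius_small must not exceed radius_large")
    off = d + np.diag([np.inf] * n)
    nn = off.min(axis=1)
    c_small = (off <= radius_small).sum(axis=1).astype(float)
    c_large = (off <= radius_large).sum(axis=1).astype(float)
    feats = np.column_stack([nn, c_small, c_large])
    signs = np.array([-1.0, 1.0, 1.0])  # aggregation orientation per feature
    sds = feats.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        return pd.Series(np.zeros(n), index=ids, name="pc1_score")
    if not keep.all():
        import warnings

        warnings.warn("zero-variance aggregation feature(s) dropped")
    Fz = (feats[:, keep] - feats[:, keep].mean(axis=0)) / sds[keep]
    _, _, vt = np.linalg.svd(Fz, full_matrices=False)
    load = vt[0]
    if float(load @ signs[keep]) < 0:
        load = -load
    scores = Fz @ load
    return pd.Series(scores, index=ids, name="pc1_score")


def aggregation_correlation(predicted_means: pd.Series,
                            pc1_scores: pd.Series) -> tuple[float, float]:
    """Two-sided Pearson correlation between station predicted means and
    aggregation PC1 scores (aligned on station id)."""
    joined = pd.concat([predicted_means.rename("mean"),
                        pc1_scores.rename("pc1")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise InvalidArgumentError("need at least 3 stations with both values")
    if joined["mean"].std() == 0 or joined["pc1"].std() == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r, p = stats.pearsonr(joined["mean"], joined["pc1"])
    return float(r), float(p)


def station_random_effect_test(spec: ModelSpec, data: pd.DataFrame,
                               mode: str = "agq0",
                               station_col: str = "station_id") -> LRTResult:
    """LRT of the model with vs. without the station random intercept,
    reported at df = 1 with no boundary correction."""
    if station_col not in spec.random_terms:
        raise InvalidArgumentError(
            f"model spec has no {station_col!r} random intercept to test"
        )
    full = fit_glmm(spec, data, mode=mode)
    reduced = fit_glmm(spec.without_random(station_col), data, mode=mode)
    if not (full.converged and reduced.converged):
        raise NonEstimableError("random-effect LRT requires converged fits")
    return likelihood_ratio_test(full, reduced)
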