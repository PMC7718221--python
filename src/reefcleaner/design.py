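"""Design-matrix construction and predictor standardization.

Terms are named by data columns.  A term is *categorical* when its column
has object/category/bool dtype (treatment contrasts, reference level first
alphabetically) and *continuous* otherwise.  The nested syntax ``"x:g"``
expands a continuous column ``x`` into one slope column per level of the
categorical column ``g``; levels in which ``x`` does not vary are skipped
and recorded so callers can report them as NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegeneratePredictorError, InvalidArgumentError, SchemaError

INTERCEPT = "(Intercept)"


def is_categorical(series: pd.Series) -> bool:
    return (
        isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == object
        or series.dtype == bool
    )


@dataclass
class DesignInfo:
    """Column bookkeeping for a built fixed-effects matrix."""

    terms: tuple[str, ...]
    column_names: list[str]
    term_columns: dict[str, list[int]]
    categorical_levels: dict[str, list] = field(default_factory=dict)
    nested_skipped: dict[str, list] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def columns_for(self, term: str) -> list[int]:
        return self.term_columns[term]


def term_is_categorical(data: pd.DataFrame, term: str) -> bool:
    """Whether *term* enters the model as a (whole) categorical factor."""
    if ":" in term:
        return False
    return is_categorical(data[term])


def build_design(data: pd.DataFrame, terms) -> tuple[np.ndarray, DesignInfo]:
    """Build a fixed-effects matrix with an explicit leading intercept.

    Returns the dense matrix and a :class:`DesignInfo` mapping each term to
    its column indices (the intercept is column 0 and carries no term).
    """
    n = len(data)
    if n == 0:
        raise InvalidArgumentError("cannot build a design matrix from an empty table")
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = [INTERCEPT]
    term_columns: dict[str, list[int]] = {}
    cat_levels: dict[str, list] = {}
    nested_skipped: dict[str, list] = {}

    for term in terms:
        idx: list[int] = []
        if ":" not in term:
            _require(data, term)
        if ":" in term:
            xname, gname = term.split(":", 1)
            _require(data, xname)
            _require(data, gname)
            x = np.asarray(data[xname], dtype=float)
            g = data[gname]
            levels = _levels(g)
            skipped = []
            for level in levels:
                mask = np.asarray(g == level)
                if x[mask].std() == 0.0:
                    skipped.append(level)
                    continue
                idx.append(len(cols))
                cols.append(np.where(mask, x, 0.0))
                names.append(f"{xname}:{gname}[{level}]")
            nested_skipped[term] = skipped
            cat_levels[term] = [l for l in levels if l not in skipped]
        elif is_categorical(data[term]):
            levels = _levels(data[term])
            cat_levels[term] = levels
            for level in levels[1:]:  # first level is the reference
                idx.append(len(cols))
                cols.append(np.asarray(data[term] == level, dtype=float))
                names.append(f"{term}[{level}]")
        else:
            _require(data, term)
            idx.append(len(cols))
            cols.append(np.asarray(data[term], dtype=float))
            names.append(term)
        term_columns[term] = idx

    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        bad = [names[j] for j in np.where(~np.isfinite(X).all(axis=0))[0]]
        raise SchemaError(f"non-finite values in design columns: {bad}")
    info = DesignInfo(
        terms=tuple(terms),
        column_names=names,
        term_columns=term_columns,
        categorical_levels=cat_levels,
        nested_skipped=nested_skipped,
    )
    return X, info


def _levels(series: pd.Series) -> list:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [l for l in series.cat.categories if (series == l).any()]
    return sorted(pd.unique(series.dropna()))


def _require(data: pd.DataFrame, col: str) -> None:
    if col not in data.columns:
        raise SchemaError(f"column {col!r} not found in data")


def standardize_predictors(
    data: pd.DataFrame, continuous_terms
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Scale and centre continuous predictor columns to mean 0, sd 1.

    Uses the sample standard deviation (ddof=1).  Returns the transformed
    copy of *data* plus ``{term: (mean, sd)}`` metadata sufficient to map
    coefficients back to the raw scale.  Constant columns raise
    :class:`DegeneratePredictorError` naming the offending term.
    """
    out = data.copy()
    meta: dict[str, tuple[float, float]] = {}
    for term in continuous_terms:
        _require(data, term)
        x = np.asarray(data[term], dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0.0:
            raise DegeneratePredictorError(
                f"predictor {term!r} has zero variance and cannot be standardized"
            )
        out[term] = (x - mu) / sd
        meta[term] = (mu, sd)
    return out, meta
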