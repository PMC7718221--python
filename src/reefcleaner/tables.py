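"""Builders turning raw observation/event tables into model-ready tables
and :class:`~reefcleaner.glmm.ModelSpec` objects for the four behaviours
(cleaning/posing frequency and duration)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import standardize_predictors
from .errors import InvalidArgumentError, SchemaError
from .glmm import BINOMIAL_PROBIT, GAUSSIAN_LOG, ModelSpec, transform_duration
from .synth import ALL_FACTORS, CONTINUOUS_FACTORS, derive_contextual_factors

RESPONSES = ("clean_frequency", "pose_frequency", "clean_duration", "pose_duration")

_REQUIRED_RECORD_COLS = (
    "observation_id", "station_id", "year", "time_of_day", "observer_type",
    "observed_minutes", "species_id", "clean_count", "pose_count", "swimby_count",
)


def validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_RECORD_COLS if c not in records.columns]
    if missing:
        raise SchemaError(f"observation table is missing columns: {missing}")
    if len(records) == 0:
        raise SchemaError("observation table is empty")
    for i, (col, ok) in enumerate([
        ("observed_minutes", (records["observed_minutes"] > 0)
         & (records["observed_minutes"] <= 10)),
        ("clean_count", records["clean_count"] >= 0),
        ("pose_count", records["pose_count"] >= 0),
        ("swimby_count", records["swimby_count"] >= 0),
    ]):
        if not ok.all():
            row = int(np.where(~ok.to_numpy())[0][0])
            raise SchemaError(f"invalid value in column {col!r} at row {row}")


def ensure_trials(records: pd.DataFrame, trials_per_minute: float = 6.0) -> pd.DataFrame:
    """Attach the binomial denominator column when absent: one opportunity
    per 1/k minutes of observation, at least one trial per row."""
    if "trials" in records.columns:
        return records
    out = records.copy()
    out["trials"] = np.maximum(
        np.round(out["observed_minutes"] * trials_per_minute).astype(int), 1)
    return out


def _mode_for(response: str) -> str:
    return "cleaning" if response.startswith("clean") else "posing"


def build_frequency_table(records, traits, survey, response: str,
                          trials_per_minute: float = 6.0,
                          include_observer: bool = True,
                          standardize: bool = True,
                          species_cleaned: str = "events"):
    """Model table + spec for a frequency response with the 12 contextual
    factors as fixed terms and a station random intercept."""
    if response not in ("clean_frequency", "pose_frequency"):
        raise InvalidArgumentError(f"not a frequency response: {response!r}")
    validate_records(records)
    data = ensure_trials(records, trials_per_minute)
    data = derive_contextual_factors(data, traits, survey, _mode_for(response),
                                     species_cleaned=species_cleaned)
    count_col = "clean_count" if response == "clean_frequency" else "pose_count"
    data[count_col] = np.minimum(data[count_col], data["trials"])
    meta = {}
    if standardize:
        data, meta = standardize_predictors(data, CONTINUOUS_FACTORS)
    terms = list(ALL_FACTORS) + (["observer_type"] if include_observer else [])
    spec = ModelSpec(response=count_col, family=BINOMIAL_PROBIT,
                     fixed_terms=tuple(terms), random_terms=("station_id",),
                     trials="trials")
    return data, spec, meta


def build_duration_table(records, events, traits, survey, response: str,
                         epsilon: float = 1e-4, floor: float = 1e-6,
                         weight_by_minutes: bool = True,
                         include_observer: bool = True,
                         standardize: bool = True,
                         species_cleaned: str = "events"):
    """Model table + spec for a duration response.

    One row per cleaning/posing event; the response is the absolute logit
    of the event's share of the observed time, modelled Gaussian with a
    log link, random intercepts for station and observation, and (by
    default) weights proportional to observation length."""
    if response not in ("clean_duration", "pose_duration"):
        raise InvalidArgumentError(f"not a duration response: {response!r}")
    validate_records(records)
    etype = "clean" if response == "clean_duration" else "pose"
    ev = events[events["event_type"] == etype]
    if len(ev) == 0:
        raise InvalidArgumentError(f"no {etype!r} events in the event table")
    data = derive_contextual_factors(records, traits, survey, _mode_for(response),
                                     species_cleaned=species_cleaned)
    data = ev.merge(data, on=["observation_id", "species_id"], how="left",
                    validate="many_to_one")
    if data["station_id"].isna().any():
        raise SchemaError("event rows reference unknown observation/species pairs")
    total_s = data["observed_minutes"].to_numpy(float) * 60.0
    prop = np.clip(data["duration_s"].to_numpy(float) / total_s, 0.0, 1.0)
    data["abs_logit_duration"] = transform_duration(prop, epsilon=epsilon, floor=floor)
    if weight_by_minutes:
        data["duration_weight"] = data["observed_minutes"].to_numpy(float) / 10.0
    meta = {}
    if standardize:
        data, meta = standardize_predictors(data, CONTINUOUS_FACTORS)
    terms = list(ALL_FACTORS) + (["observer_type"] if include_observer else [])
    spec = ModelSpec(response="abs_logit_duration", family=GAUSSIAN_LOG,
                     fixed_terms=tuple(terms),
                     random_terms=("station_id", "observation_id"),
                     weights="duration_weight" if weight_by_minutes else None)
    return data, spec, meta


def build_response_table(records, events, traits, survey, response: str, **kw):
    if response in ("clean_frequency", "pose_frequency"):
        kw.pop("epsilon", None), kw.pop("floor", None), kw.pop("weight_by_minutes", None)
        return build_frequency_table(records, traits, survey, response, **kw)
    kw.pop("trials_per_minute", None)
    return build_duration_table(records, events, traits, survey, response, **kw)


def temporal_spec(spec: ModelSpec, include_observer: bool = True) -> ModelSpec:
    """Replace the contextual-factor terms by the temporal ones."""
    terms = ["year", "time_of_day"] + (["observer_type"] if include_observer else [])
    return spec.with_terms(tuple(terms))
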