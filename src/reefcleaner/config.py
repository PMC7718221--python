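"""Run configuration: defaults, validation, YAML loading, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import InvalidArgumentError


@dataclass
class RunConfig:
    """All analysis parameters with defaults reproducing the study settings
    (alpha 0.05, 1000 subsample refits of 192 observations, 95% consistency
    threshold)."""

    # paths
    output_dir: str = "out"
    observations: str | None = None
    events: str | None = None
    traits: str | None = None
    survey: str | None = None
    stations: str | None = None
    # analysis parameters
    alpha: float = 0.05
    n_sim: int = 1000
    subsample_size: int = 192
    consistency_threshold: float = 0.95
    n_perm: int = 9999
    trials_per_minute: float = 6.0
    epsilon: float = 1e-4
    duration_floor: float = 1e-6
    weight_durations: bool = True
    mode: str = "agq0"
    responses: tuple[str, ...] = ("clean_frequency", "pose_frequency",
                                  "clean_duration", "pose_duration")
    # generator parameters
    seed: int = 1
    years: int = 8
    n_per_year: int = 192
    n_species: int = 12
    n_stations: int = 82
    area: tuple[float, float] = (70.0, 60.0)
    min_sep: float = 1.0
    station_sd: float = 0.5

    def __post_init__(self):
        checks = [
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.n_sim >= 1, "n_sim must be >= 1"),
            (self.subsample_size >= 1, "subsample_size must be >= 1"),
            (0 < self.consistency_threshold <= 1,
             "consistency_threshold must be in (0, 1]"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (self.trials_per_minute > 0, "trials_per_minute must be positive"),
            (0 < self.epsilon < 0.5, "epsilon must be in (0, 0.5)"),
            (self.mode in ("agq0", "laplace"), "mode must be agq0 or laplace"),
            (self.years >= 1, "years must be >= 1"),
            (self.n_per_year >= 1, "n_per_year must be >= 1"),
            (self.n_species >= 2, "n_species must be >= 2"),
            (self.n_stations >= 1, "n_stations must be >= 1"),
            (self.station_sd >= 0, "station_sd must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidArgumentError(msg)
        bad = set(self.responses) - {"clean_frequency", "pose_frequency",
                                     "clean_duration", "pose_duration"}
        if bad:
            raise InvalidArgumentError(f"unknown responses: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InvalidArgumentError("config file must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        for key in ("responses",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "area" in raw and isinstance(raw["area"], list):
            raw["area"] = tuple(raw["area"])
        return cls(**raw)

    _PATH_FIELDS = ("output_dir", "observations", "events", "traits",
                    "survey", "stations")

    def hash(self) -> str:
        """Hash of the analysis-relevant parameters (paths excluded, so the
        same run written to a different directory hashes identically)."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in self._PATH_FIELDS}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
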