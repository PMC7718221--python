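"""Seeded synthetic cleaner-client observation data.

The generator inverts the analysis models: per-row event counts are drawn
binomially on a probit linear predictor built from standardized contextual
factors (with per-year coefficient trajectories and station random
intercepts), and per-event durations are drawn so that the
absolute-logit-transformed interaction proportions follow the log-link
Gaussian model.  Draw order is swim-bys, then posing, then cleaning, so
every factor that is arithmetically derived from earlier draws enters the
linear predictors with its exactly-consistent value; the one factor
derived from later draws (number of species cleaned) enters through an
exogenous per-observation latent instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .errors import InvalidArgumentError, MissingDataError, PlacementError

# the 3/4/5 partner-identity / partner-abundance / third-party partition
FACTOR_GROUPS: dict[str, tuple[str, ...]] = {
    "PI": ("client_functional_group", "client_trophic_level", "client_body_size"),
    "PA": ("client_local_abundance", "client_wider_abundance",
           "cleaner_local_abundance", "cleaner_wider_abundance"),
    "TP": ("number_species_cleaned", "number_species_locally_available",
           "number_species_wider", "client_local_relative_abundance",
           "abundance_other_cleaners"),
}
ALL_FACTORS: tuple[str, ...] = tuple(f for g in FACTOR_GROUPS.values() for f in g)
CATEGORICAL_FACTORS: tuple[str, ...] = ("client_functional_group",)
CONTINUOUS_FACTORS: tuple[str, ...] = tuple(
    f for f in ALL_FACTORS if f not in CATEGORICAL_FACTORS
)


def factor_group(name: str) -> str:
    for g, members in FACTOR_GROUPS.items():
        if name in members:
            return g
    raise InvalidArgumentError(f"unknown contextual factor {name!r}")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ClientSpecies:
    species_id: str
    trophic_level: float  # within [2, 4.4]
    body_size: float      # cm, within [9, 150]
    sociality: str        # solitary | gregarious
    mobility: str         # sedentary | free-ranging

    @property
    def functional_group(self) -> str:
        return f"{self.sociality}/{self.mobility}"


@dataclass
class Station:
    station_id: str
    x: float
    y: float
    occupied_years: set = field(default_factory=set)


@dataclass
class TrueEffectConfig:
    """True per-factor coefficient trajectories for every response.

    Each mapping sends a contextual-factor name to a length-``years``
    coefficient trajectory on the standardized-predictor scale: a constant
    trajectory models a consistent predictor, a year-varying one a dynamic
    predictor, and omitted factors are null.  The remaining fields control
    the random-effect and noise architecture; together with a seed the
    configuration fully determines the generated tables.
    """

    years: int
    clean_freq: dict[str, tuple] = field(default_factory=dict)
    pose_freq: dict[str, tuple] = field(default_factory=dict)
    clean_dur: dict[str, tuple] = field(default_factory=dict)
    pose_dur: dict[str, tuple] = field(default_factory=dict)
    station_sd: float = 0.5
    obs_sd: float = 0.3          # per-observation intercept sd in duration models
    residual_sd: float = 0.5     # duration residual sd on the |logit| scale
    eta_noise_sd: float = 0.0    # row-level overdispersion in count predictors
    trials_per_minute: float = 6.0
    clean_intercept: float = -2.0
    pose_intercept: float = -1.8
    clean_dur_intercept: float = 0.8
    pose_dur_intercept: float = 0.8
    observer_effect: float = 0.0

    def __post_init__(self):
        for name in ("clean_freq", "pose_freq", "clean_dur", "pose_dur"):
            traj = getattr(self, name)
            for factor, values in traj.items():
                if factor not in ALL_FACTORS:
                    raise InvalidArgumentError(f"unknown factor {factor!r} in {name}")
                values = tuple(float(v) for v in np.atleast_1d(values))
                if len(values) == 1:
                    values = values * self.years
                if len(values) != self.years:
                    raise InvalidArgumentError(
                        f"trajectory for {factor!r} in {name} has length "
                        f"{len(values)}, expected {self.years}"
                    )
                traj[factor] = values

    @classmethod
    def null(cls, years: int, **kw) -> "TrueEffectConfig":
        return cls(years=years, **kw)

    def set_constant(self, response: str, factor: str, beta: float) -> "TrueEffectConfig":
        getattr(self, response)[factor] = (float(beta),) * self.years
        self.__post_init__()
        return self

    def set_varying(self, response: str, factor: str, values) -> "TrueEffectConfig":
        getattr(self, response)[factor] = tuple(float(v) for v in values)
        self.__post_init__()
        return self


# ---------------------------------------------------------------------------
# community and stations


_TROPHIC_RANGE = (2.0, 4.4)
_SIZE_RANGE = (9.0, 150.0)
_FUNCTIONAL_CROSS = [("solitary", "sedentary"), ("solitary", "free-ranging"),
                     ("gregarious", "sedentary"), ("gregarious", "free-ranging")]


def generate_community(n_species: int, seed: int) -> list[ClientSpecies]:
    """Draw a client community with traits inside the documented ranges.

    The first four species cycle through the sociality x mobility cross so
    all four functional groups are represented whenever ``n_species >= 4``.
    """
    if n_species < 2:
        raise InvalidArgumentError("a community needs at least 2 client species")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_species):
        if i < 4:
            soc, mob = _FUNCTIONAL_CROSS[i]
        else:
            soc, mob = _FUNCTIONAL_CROSS[rng.integers(4)]
        lo, hi = _SIZE_RANGE
        size = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        out.append(ClientSpecies(
            species_id=f"sp{i + 1:02d}",
            trophic_level=float(rng.uniform(*_TROPHIC_RANGE)),
            body_size=size,
            sociality=soc,
            mobility=mob,
        ))
    return out


def generate_stations(n_stations: int, area=(70.0, 60.0), min_sep: float = 1.0,
                      seed: int = 0, max_tries_per_station: int = 200) -> list[Station]:
    """Place stations uniformly in a rectangle with a minimum separation.

    Rejection sampling with a retry cap; infeasible packings raise
    :class:`PlacementError` with a diagnostic.
    """
    if n_stations < 1:
        raise InvalidArgumentError("n_stations must be >= 1")
    width, height = float(area[0]), float(area[1])
    rng = np.random.default_rng(seed)
    xs = np.empty(0)
    ys = np.empty(0)
    tries_left = max_tries_per_station * n_stations
    while len(xs) < n_stations:
        if tries_left <= 0:
            raise PlacementError(
                f"placed only {len(xs)}/{n_stations} stations at min_sep="
                f"{min_sep} in a {width}x{height} area before hitting the retry cap"
            )
        x, y = rng.uniform(0, width), rng.uniform(0, height)
        tries_left -= 1
        if len(xs) and np.min((xs - x) ** 2 + (ys - y) ** 2) < min_sep ** 2:
            continue
        xs = np.append(xs, x)
        ys = np.append(ys, y)
    return [Station(station_id=f"st{i + 1:03d}", x=float(x), y=float(y))
            for i, (x, y) in enumerate(zip(xs, ys))]


# ---------------------------------------------------------------------------
# observation generator


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - np.mean(x)) / sd


def _fg_effect(levels: pd.Series, traj_value: float) -> np.ndarray:
    """Categorical functional-group contribution: the year coefficient is
    applied to the solitary/free-ranging level, half to solitary/sedentary."""
    lv = levels.to_numpy()
    out = np.zeros(len(lv))
    out[lv == "solitary/free-ranging"] = traj_value
    out[lv == "solitary/sedentary"] = 0.5 * traj_value
    return out


def generate_observations(community, stations, effects: TrueEffectConfig,
                          n_per_year: int = 192, years: int = 8, seed: int = 0,
                          occupancy_range=(15, 60), max_species_per_obs: int = 5,
                          start_year: int = 2010):
    """Generate one synthetic dataset.

    Returns ``(records, events, traits, survey)``: the observation x client
    table (exactly ``years * n_per_year`` distinct observations), the
    per-event duration table, the species trait table and the
    wider-environment survey table.
    """
    if effects.years != years:
        raise InvalidArgumentError(
            f"effect trajectories cover {effects.years} years, requested {years}"
        )
    if n_per_year < 1 or years < 1:
        raise InvalidArgumentError("n_per_year and years must be positive")
    rng = np.random.default_rng(seed)
    n_stations = len(stations)
    year_labels = [str(start_year + t) for t in range(years)]

    # -- station / year level structure -------------------------------------
    lo = min(occupancy_range[0], n_stations)
    hi = min(occupancy_range[1], n_stations)
    occupied: dict[str, list[int]] = {}
    for yl in year_labels:
        n_occ = int(rng.integers(lo, hi + 1))
        occupied[yl] = sorted(rng.choice(n_stations, size=n_occ, replace=False))
    for yl in year_labels:
        for si in occupied[yl]:
            stations[si].occupied_years.add(yl)

    station_b = {r: rng.normal(0.0, effects.station_sd, n_stations)
                 for r in ("clean_freq", "pose_freq", "clean_dur", "pose_dur")}
    station_gobies = np.clip(np.round(rng.normal(2.0, 1.2, (years, n_stations))), 1, 9)

    year_env = pd.DataFrame({
        "year": year_labels,
        "cleaner_wider_abundance": rng.uniform(0.6, 1.28, years),
        "number_species_wider": rng.integers(45, 79, years).astype(float),
        "abundance_other_cleaners": rng.uniform(0.72, 3.19, years),
    })

    traits = pd.DataFrame({
        "species_id": [s.species_id for s in community],
        "trophic_level": [s.trophic_level for s in community],
        "body_size": [s.body_size for s in community],
        "sociality": [s.sociality for s in community],
        "mobility": [s.mobility for s in community],
    })
    n_species = len(community)
    swim_propensity = np.exp(rng.normal(0.8, 0.5, n_species))  # species visit rates
    wider = []
    for t, yl in enumerate(year_labels):
        base = swim_propensity * np.exp(rng.normal(-1.5, 0.4, n_species))
        for s, sp in enumerate(community):
            wider.append((yl, sp.species_id, float(base[s])))
    survey = pd.DataFrame(wider, columns=["year", "species_id", "wider_abundance"])
    survey = survey.merge(year_env, on="year")

    # -- observation rows ---------------------------------------------------
    rows = []
    obs_meta = []
    obs_counter = 0
    for t, yl in enumerate(year_labels):
        occ = occupied[yl]
        for _ in range(n_per_year):
            obs_counter += 1
            oid = f"obs{obs_counter:05d}"
            si = int(occ[rng.integers(len(occ))])
            minutes = float(np.round(rng.uniform(8.0, 10.0), 2))
            trials = max(1, int(round(minutes * effects.trials_per_minute)))
            tod = float(np.round(rng.uniform(7.5, 17.0), 2))
            observer = "multi-year" if rng.random() < 0.6 else "single-year"
            k_species = int(min(1 + rng.poisson(1.2), max_species_per_obs, n_species))
            sp_idx = rng.choice(n_species, size=k_species, replace=False)
            n_cleaned_latent = int(min(rng.poisson(2.0), 7))
            gobies = float(station_gobies[t, si])
            for s in sp_idx:
                swim = int(rng.poisson(swim_propensity[s] * minutes / 10.0))
                rows.append((oid, f"st{si + 1:03d}", yl, tod, observer, minutes,
                             trials, community[s].species_id, swim, gobies,
                             n_cleaned_latent, t, si))
            obs_meta.append((oid, k_species))

    rec = pd.DataFrame(rows, columns=[
        "observation_id", "station_id", "year", "time_of_day", "observer_type",
        "observed_minutes", "trials", "species_id", "swimby_count",
        "cleaner_local_abundance", "_n_cleaned_latent", "_year_idx", "_station_idx",
    ])
    rec = rec.merge(traits, on="species_id").merge(
        survey, on=["year", "species_id"]).sort_values(
        ["observation_id", "species_id"], kind="mergesort").reset_index(drop=True)
    rec["client_functional_group"] = rec["sociality"] + "/" + rec["mobility"]
    yr_idx = rec["_year_idx"].to_numpy()
    st_idx = rec["_station_idx"].to_numpy()
    n_rows = len(rec)
    observer_x = (rec["observer_type"] == "multi-year").to_numpy(float)

    def _year_centered(x: np.ndarray) -> np.ndarray:
        out = x.astype(float).copy()
        for t in range(years):
            mask = yr_idx == t
            out[mask] -= out[mask].mean()
        return out

    def eta_for(response: str, factors: pd.DataFrame, intercept: float,
                station_effects: np.ndarray) -> np.ndarray:
        eta = np.full(n_rows, intercept)
        traj = getattr(effects, response)
        for factor, values in traj.items():
            coefs = np.asarray(values)[yr_idx]
            if factor == "client_functional_group":
                base = _fg_effect(factors[factor], 1.0)
            else:
                base = _zscore(factors[factor].to_numpy(float))
            if len(set(values)) > 1:
                # year-varying coefficients act on the within-year centred
                # signal, so a dynamic effect does not masquerade as a
                # between-year intercept shift
                base = _year_centered(base)
            eta = eta + base * coefs
        eta = eta + station_effects[st_idx]
        eta = eta + effects.observer_effect * observer_x
        if effects.eta_noise_sd > 0:
            eta = eta + rng.normal(0.0, effects.eta_noise_sd, n_rows)
        return eta

    # -- posing (factors in posing mode: swim-by based) ---------------------
    pose_factors = _assemble_factors(rec, mode="posing",
                                     pose=np.zeros(n_rows, int),
                                     clean=None)
    eta_pose = eta_for("pose_freq", pose_factors, effects.pose_intercept,
                       station_b["pose_freq"])
    trials_arr = rec["trials"].to_numpy(int)
    pose = rng.binomial(trials_arr, special.ndtr(eta_pose))
    rec["pose_count"] = pose

    # -- cleaning (factors in cleaning mode: pose + swim-by based) ----------
    clean_factors = _assemble_factors(rec, mode="cleaning", pose=pose, clean=None)
    eta_clean = eta_for("clean_freq", clean_factors, effects.clean_intercept,
                        station_b["clean_freq"])
    clean = rng.binomial(trials_arr, special.ndtr(eta_clean))
    rec["clean_count"] = clean

    # -- per-event durations ------------------------------------------------
    obs_b_clean: dict[str, float] = {}
    obs_b_pose: dict[str, float] = {}
    events = []
    for resp, counts, factors, icept, bkey, store in (
        ("clean_dur", clean, clean_factors, effects.clean_dur_intercept,
         "clean_dur", obs_b_clean),
        ("pose_dur", pose, pose_factors, effects.pose_dur_intercept,
         "pose_dur", obs_b_pose),
    ):
        eta = np.full(n_rows, icept)
        traj = getattr(effects, resp)
        for factor, values in traj.items():
            coefs = np.asarray(values)[yr_idx]
            if factor == "client_functional_group":
                base = _fg_effect(factors[factor], 1.0)
            else:
                base = _zscore(factors[factor].to_numpy(float))
            if len(set(values)) > 1:
                base = _year_centered(base)
            eta = eta + base * coefs
        eta = eta + station_b[bkey][st_idx]
        etype = "clean" if resp == "clean_dur" else "pose"
        for i in np.where(counts > 0)[0]:
            oid = rec.at[i, "observation_id"]
            if oid not in store:
                store[oid] = rng.normal(0.0, effects.obs_sd)
            mu = np.exp(eta[i] + store[oid])
            total_s = rec.at[i, "observed_minutes"] * 60.0
            for _ in range(int(counts[i])):
                tval = max(mu + rng.normal(0.0, effects.residual_sd), 1e-3)
                prop = special.expit(-tval)  # short events: p below 0.5
                events.append((oid, rec.at[i, "species_id"], etype,
                               float(prop * total_s)))
    events = pd.DataFrame(events, columns=["observation_id", "species_id",
                                           "event_type", "duration_s"])

    rec = rec.drop(columns=["sociality", "mobility", "client_functional_group",
                            "wider_abundance", "cleaner_wider_abundance",
                            "number_species_wider", "abundance_other_cleaners",
                            "_year_idx", "_station_idx"])
    rec = rec.rename(columns={"_n_cleaned_latent": "number_species_cleaned_recorded"})
    return rec, events, traits, survey


def _assemble_factors(rec: pd.DataFrame, mode: str, pose, clean) -> pd.DataFrame:
    """Build the 12 contextual-factor columns for one response mode.

    ``pose``/``clean`` may be passed explicitly (generator path, where the
    columns are not on *rec* yet) or read from *rec* (analysis path).
    ``clean=None`` substitutes the exogenous per-observation latent for the
    number of species cleaned (generator path only).
    """
    pose = np.asarray(rec["pose_count"] if pose is None else pose, int)
    swim = rec["swimby_count"].to_numpy(int)
    if mode == "cleaning":
        local = pose + swim
    elif mode == "posing":
        local = swim.copy()
    else:
        raise InvalidArgumentError(f"unknown response_mode {mode!r}")
    obs = rec["observation_id"].to_numpy()
    df = pd.DataFrame({
        "client_functional_group": rec["client_functional_group"],
        "client_trophic_level": rec["trophic_level"].to_numpy(float),
        "client_body_size": rec["body_size"].to_numpy(float),
        "client_local_abundance": local.astype(float),
        "client_wider_abundance": rec["wider_abundance"].to_numpy(float),
        "cleaner_local_abundance": rec["cleaner_local_abundance"].to_numpy(float),
        "cleaner_wider_abundance": rec["cleaner_wider_abundance"].to_numpy(float),
        "number_species_wider": rec["number_species_wider"].to_numpy(float),
        "abundance_other_cleaners": rec["abundance_other_cleaners"].to_numpy(float),
    }, index=rec.index)
    grp = pd.Series(local.astype(float)).groupby(obs)
    totals = grp.transform("sum").to_numpy()
    nrows = grp.transform("size").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, local / np.maximum(totals, 1e-12), 1.0 / nrows)
    df["client_local_relative_abundance"] = rel
    active = (local > 0).astype(float)
    df["number_species_locally_available"] = (
        pd.Series(active).groupby(obs).transform("sum").to_numpy()
    )
    if clean is None:
        col = ("_n_cleaned_latent" if "_n_cleaned_latent" in rec.columns
               else "number_species_cleaned_recorded")
        df["number_species_cleaned"] = rec[col].to_numpy(float)
    else:
        cleaned = (np.asarray(clean, int) > 0).astype(float)
        df["number_species_cleaned"] = (
            pd.Series(cleaned).groupby(obs).transform("sum").to_numpy()
        )
    return df[list(ALL_FACTORS)]


def derive_contextual_factors(records: pd.DataFrame, traits: pd.DataFrame,
                              survey: pd.DataFrame, response_mode: str,
                              species_cleaned: str = "events") -> pd.DataFrame:
    """Attach the 12 contextual-factor columns to an observation table.

    ``response_mode`` selects how client local abundance and availability
    are computed: for ``"cleaning"`` posing and swim-by frequencies are
    combined, for ``"posing"`` only swim-bys count.  The number of species
    cleaned is counted from the observation's cleaning outcomes by default
    (``species_cleaned="events"``); ``"recorded"`` instead uses an
    observation-level ``number_species_cleaned_recorded`` column, which
    avoids the mechanical feedback of an outcome-derived predictor when
    one is available.  Missing trait or survey entries raise
    :class:`MissingDataError` naming the gap.
    """
    if species_cleaned not in ("events", "recorded"):
        raise InvalidArgumentError("species_cleaned must be 'events' or 'recorded'")
    if species_cleaned == "recorded" and \
            "number_species_cleaned_recorded" not in records.columns:
        raise MissingDataError(
            "species_cleaned='recorded' needs a number_species_cleaned_recorded column")
    if response_mode not in ("cleaning", "posing"):
        raise InvalidArgumentError(f"response_mode must be cleaning|posing, got {response_mode!r}")
    rec = records.copy()
    missing_sp = set(rec["species_id"]) - set(traits["species_id"])
    if missing_sp:
        raise MissingDataError(f"no trait entries for species: {sorted(missing_sp)}")
    tr = traits.set_index("species_id")
    rec["trophic_level"] = rec["species_id"].map(tr["trophic_level"])
    rec["body_size"] = rec["species_id"].map(tr["body_size"])
    rec["client_functional_group"] = (
        rec["species_id"].map(tr["sociality"]) + "/" + rec["species_id"].map(tr["mobility"])
    )
    missing_yr = set(rec["year"].astype(str)) - set(survey["year"].astype(str))
    if missing_yr:
        raise MissingDataError(f"no survey entries for years: {sorted(missing_yr)}")
    sv = survey.copy()
    sv["year"] = sv["year"].astype(str)
    rec["year"] = rec["year"].astype(str)
    merged = rec.merge(sv, on=["year", "species_id"], how="left",
                       validate="many_to_one")
    if merged["wider_abundance"].isna().any():
        bad = merged.loc[merged["wider_abundance"].isna(),
                         ["species_id", "year"]].drop_duplicates()
        raise MissingDataError(
            "no survey abundance for species/year pairs: "
            + ", ".join(f"{r.species_id}/{r.year}" for r in bad.itertuples())
        )
    merged.index = rec.index
    clean_arg = (None if species_cleaned == "recorded"
                 else merged["clean_count"].to_numpy())
    factors = _assemble_factors(merged, mode=response_mode, pose=None,
                                clean=clean_arg)
    out = records.copy()
    for col in factors.columns:
        out[col] = factors[col].to_numpy()
    return out


# ---------------------------------------------------------------------------
# summaries


def summarize_dataset(records: pd.DataFrame) -> dict:
    """Table-1-style dataset summary.

    Returns per-year rows (occupied stations, total observations, mean and
    SE of observations per station) plus grand totals: total observations,
    mean observations per year, and total observation time in minutes
    (10 minutes per focal observation).
    """
    if records is None or len(records) == 0:
        raise InvalidArgumentError("cannot summarize an empty observation table")
    obs = records.drop_duplicates("observation_id")
    per_year = []
    for year, grp in obs.groupby(obs["year"].astype(str), sort=True):
        counts = grp.groupby("station_id")["observation_id"].nunique()
        n_st = len(counts)
        total = int(grp["observation_id"].nunique())
        mean = total / n_st
        se = float(counts.std(ddof=1) / math.sqrt(n_st)) if n_st > 1 else 0.0
        per_year.append((year, n_st, total, mean, se))
    table = pd.DataFrame(per_year, columns=[
        "year", "stations_occupied", "total_observations",
        "mean_obs_per_station", "se_obs_per_station"])
    grand_total = int(table["total_observations"].sum())
    n_years = len(table)
    return {
        "per_year": table,
        "grand_total_observations": grand_total,
        "mean_observations_per_year": grand_total / n_years,
        "total_observation_minutes": grand_total * 10.0,
    }
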