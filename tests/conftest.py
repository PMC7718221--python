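import pandas as pd
import pytest

from reefcleaner import synth


@pytest.fixture(scope="session")
def community():
    return synth.generate_community(10, seed=101)


@pytest.fixture(scope="session")
def stations():
    return synth.generate_stations(40, seed=202)


@pytest.fixture(scope="session")
def null_dataset(community, stations):
    """Small all-null dataset: 3 years x 80 observations, station sd 0.3."""
    cfg = synth.TrueEffectConfig(years=3, station_sd=0.3, trials_per_minute=1.0,
                                 clean_intercept=-1.2, pose_intercept=-1.0)
    rec, ev, traits, survey = synth.generate_observations(
        community, stations, cfg, n_per_year=80, years=3, seed=303,
        occupancy_range=(12, 40))
    return rec, ev, traits, survey


@pytest.fixture(scope="session")
def effect_dataset(community, stations):
    """4 years x 120 observations with two strong constant effects on
    cleaning frequency and one on cleaning duration."""
    cfg = synth.TrueEffectConfig(
        years=4, station_sd=0.4, trials_per_minute=1.0, clean_intercept=-1.2,
        clean_freq={"client_trophic_level": (-0.5,), "client_body_size": (0.5,)},
        clean_dur={"client_trophic_level": (0.3,)},
    )
    rec, ev, traits, survey = synth.generate_observations(
        community, stations, cfg, n_per_year=120, years=4, seed=404,
        occupancy_range=(12, 40))
    return rec, ev, traits, survey


@pytest.fixture(scope="session")
def freq_model(effect_dataset):
    """Standardized cleaning-frequency table + spec on the effect dataset."""
    from reefcleaner.tables import build_frequency_table

    rec, ev, traits, survey = effect_dataset
    data, spec, meta = build_frequency_table(
        rec, traits, survey, "clean_frequency", trials_per_minute=1.0,
        species_cleaned="recorded")
    return data, spec


def table1_records():
    """Observation table encoding the published per-year sampling effort:
    station counts and total observation counts for the 8 study years."""
    years = ["2010", "2011", "2012", "2013", "2014", "2015", "2016", "2017"]
    n_stations = [15, 32, 31, 21, 24, 22, 60, 59]
    n_obs = [61, 271, 233, 108, 143, 166, 290, 267]
    rows = []
    oid = 0
    for year, ns, no in zip(years, n_stations, n_obs):
        for i in range(no):
            oid += 1
            rows.append((f"obs{oid:05d}", f"st{(i % ns) + 1:03d}", year))
    return pd.DataFrame(rows, columns=["observation_id", "station_id", "year"])


@pytest.fixture(scope="session")
def table1_fixture():
    return table1_records()
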