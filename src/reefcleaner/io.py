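"""Delimited-text readers/writers and the provenance manifest.

All tables are UTF-8 CSV with a header row; every file written by the
pipeline starts with a comment line carrying the schema version, the
config hash and the master seed, so two runs with equal hashes produce
byte-identical files.
"""

from __future__ import annotations

import json
import os

import pandas as pd

from .errors import SchemaError

SCHEMA_VERSION = "1"


def write_table(df: pd.DataFrame, path: str, config_hash: str = "",
                seed: int | None = None) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# reefcleaner schema={SCHEMA_VERSION} "
                 f"config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise SchemaError(f"input table not found: {path}")
    return pd.read_csv(path, comment="#")


def write_manifest(path: str, config, extra: dict | None = None) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    from dataclasses import asdict

    payload = {
        "schema": SCHEMA_VERSION,
        "config": asdict(config),
        "config_hash": config.hash(),
        "master_seed": config.seed,
    }
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def stations_frame(stations) -> pd.DataFrame:
    return pd.DataFrame({
        "station_id": [s.station_id for s in stations],
        "x": [s.x for s in stations],
        "y": [s.y for s in stations],
        "occupied_years": [";".join(sorted(s.occupied_years)) for s in stations],
    })


def fit_summary_frame(fit, full_p=None, importance=None) -> pd.DataFrame:
    """Fixed column order export of one fit: term, beta, se, z, p, r2_change."""
    rows = []
    imp = {}
    if importance is not None:
        imp = dict(zip(importance.table["term"], importance.table["delta_r2"]))
    for term in fit.spec.fixed_terms if fit.spec else []:
        beta = fit.term_beta(term)
        cols = fit.design_info.columns_for(term)
        se = fit.se.iloc[cols[0]] if len(cols) == 1 else float("nan")
        z = fit.z.iloc[cols[0]] if len(cols) == 1 else float("nan")
        p = (full_p or {}).get(term, float("nan"))
        rows.append((term, beta, se, z, p, imp.get(term, float("nan"))))
    return pd.DataFrame(rows, columns=["term", "beta", "se", "z", "p", "r2_change"])
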