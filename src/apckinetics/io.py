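"""Config handling and tidy CSV / JSON readers-writers.

All artifact files carry a provenance header: package version, a hash of
the generating configuration, and the seed (when randomness was involved).
CSV provenance lives in ``#``-prefixed comment lines so the files stay
directly loadable by any CSV reader that skips comments.

Column schemas
--------------
time course : time_s, species, concentration_nM        (tidy/long)
trace       : cell_id, time_s, intensity
onset calls : cell_id, onset_s, argmin_s, flags
scan        : k_a, k_c, k_d, metric, value, censored   (tidy/long)
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import TimeCourse
from .onset import FluorescenceTrace, OnsetCall
from .parameters import RateParameters, TwoSubstrateParameters
from .scan import ScanResult


class SchemaError(ValueError):
    """An input file is missing a required column."""


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance_lines(config=None, seed=None) -> list[str]:
    lines = [f"# apckinetics version: {__version__}"]
    if config is not None:
        lines.append(f"# config hash: {config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def _write_csv(df: pd.DataFrame, path, config=None, seed=None) -> None:
    path = Path(path)
    header = "\n".join(_provenance_lines(config, seed))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        # pandas' default float repr is shortest-round-trip: exact re-read
        df.to_csv(fh, index=False)


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def load_config(path) -> dict:
    """Load a JSON or YAML parameter configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def params_from_config(config: dict) -> RateParameters | TwoSubstrateParameters:
    """Build parameters from a config mapping; two-substrate if it has k_d_S."""
    if "k_d_S" in config or "scenario" in config:
        return TwoSubstrateParameters.from_dict(config)
    return RateParameters.from_dict(config)


# ---------------------------------------------------------------- time courses

def write_timecourse_csv(tc: TimeCourse, path, config=None) -> None:
    n = tc.times.size
    df = pd.DataFrame({
        "time_s": np.repeat(tc.times, len(tc.species)),
        "species": np.tile(tc.species, n),
        "concentration_nM": tc.states.ravel(),
    })
    cfg = config if config is not None else getattr(tc.params, "to_dict", lambda: None)()
    _write_csv(df, path, config=cfg)


def read_timecourse_csv(path) -> TimeCourse:
    df = _read_csv(path, ("time_s", "species", "concentration_nM"))
    wide = df.pivot(index="time_s", columns="species", values="concentration_nM")
    species = tuple(dict.fromkeys(df["species"]))  # preserve file order
    wide = wide[list(species)]
    return TimeCourse(times=wide.index.to_numpy(dtype=float),
                      states=wide.to_numpy(dtype=float),
                      species=species, params=None)


# --------------------------------------------------------------------- traces

def write_trace_csv(traces, path, config=None, seed=None) -> None:
    frames = [pd.DataFrame({"cell_id": tr.cell_id, "time_s": tr.times,
                            "intensity": tr.intensities}) for tr in traces]
    _write_csv(pd.concat(frames, ignore_index=True), path, config=config, seed=seed)


def read_trace_csv(path) -> list[FluorescenceTrace]:
    df = _read_csv(path, ("cell_id", "time_s", "intensity"))
    return [
        FluorescenceTrace(cell_id=str(cid), times=g["time_s"].to_numpy(),
                          intensities=g["intensity"].to_numpy())
        for cid, g in df.groupby("cell_id", sort=False)
    ]


def write_onset_csv(calls: list[OnsetCall], path, config=None) -> None:
    df = pd.DataFrame({
        "cell_id": [c.cell_id for c in calls],
        "onset_s": [np.nan if c.onset_time is None else c.onset_time for c in calls],
        "argmin_s": [np.nan if c.argmin_time is None else c.argmin_time for c in calls],
        "flags": [";".join(c.flags) for c in calls],
    })
    _write_csv(df, path, config=config)


# ---------------------------------------------------------------------- scans

_SCAN_VALUE_COLUMNS = ("T95", "T50", "Td", "max_occupancy", "T95_S", "Td_S",
                       "T95_C", "Td_C", "rel_onset_difference", "td_ratio",
                       "competition_effect", "max_occupancy_S", "max_occupancy_C")


def write_scan_csv(result: ScanResult, path) -> None:
    """Tidy scan table: one row per grid cell per metric."""
    t = result.table
    metrics = [c for c in _SCAN_VALUE_COLUMNS if c in t.columns]
    long = t.melt(id_vars=["k_a", "k_c", "k_d", "censored"],
                  value_vars=metrics, var_name="metric", value_name="value")
    long = long[["k_a", "k_c", "k_d", "metric", "value", "censored"]]
    _write_csv(long, path, config=result.provenance)


def read_scan_csv(path) -> pd.DataFrame:
    return _read_csv(path, ("k_a", "k_c", "k_d", "metric", "value", "censored"))


# ----------------------------------------------------------------------- JSON

def write_metrics_json(metrics: dict, path, config=None, seed=None) -> None:
    payload = {
        "provenance": {
            "version": __version__,
            "config_hash": None if config is None else config_hash(config),
            "seed": seed,
        },
        "metrics": metrics,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)
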