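"""Plain-text I/O: per-channel signal CSVs, cohort tables, model JSON.

Raw recordings are written one two-column CSV (time_s, value) per channel
plus a ``stages.csv`` annotation file; cohort tables use a single CSV with
metadata then parameter columns, with provenance recorded in leading
``#`` comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import FEATURE_NAMES, FEATURE_UNITS, Channel, RawSignalSet

CHANNEL_FILES = {
    "ECG": "ecg.csv", "PPG": "ppg.csv", "RESP": "resp.csv",
    "EDA": "eda.csv", "TFACE": "tface.csv", "TFINGER": "tfinger.csv",
}


def write_signals_csv(signals: RawSignalSet, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, ch in signals.channels.items():
        fname = CHANNEL_FILES.get(name, f"{name.lower()}.csv")
        pd.DataFrame({"time_s": ch.times, "value": ch.data}).to_csv(
            directory / fname, index=False, float_format="%.6f")
        (directory / (fname + ".meta")).write_text(
            f"fs_hz={ch.fs}\nunit={ch.unit}\n")
    pd.DataFrame(signals.stages,
                 columns=["label", "start_s", "end_s"]).to_csv(
        directory / "stages.csv", index=False)
    return directory


def read_signals_csv(directory) -> RawSignalSet:
    directory = Path(directory)
    channels = {}
    for name, fname in CHANNEL_FILES.items():
        path = directory / fname
        if not path.exists():
            continue
        meta = dict(line.split("=", 1) for line in
                    (directory / (fname + ".meta")).read_text().split())
        data = pd.read_csv(path)["value"].to_numpy()
        channels[name] = Channel(data, float(meta["fs_hz"]), meta["unit"])
    stages = [(r.label, float(r.start_s), float(r.end_s)) for r in
              pd.read_csv(directory / "stages.csv").itertuples()]
    return RawSignalSet(channels=channels, stages=stages)


def write_cohort_csv(cohort: pd.DataFrame, path,
                     provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        cohort.to_csv(fh, index=False)
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_units_sidecar(path) -> Path:
    """Document the unit of every parameter column next to a cohort CSV."""
    path = Path(path)
    lines = [f"{name}\t{FEATURE_UNITS[name]}" for name in FEATURE_NAMES]
    path.write_text("parameter\tunit\n" + "\n".join(lines) + "\n")
    return path


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
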