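"""Stage-level extraction of all 27 parameters from a raw recording.

Every extractor operates on non-overlapping 1-minute windows aligned to
the stage start and valid windows are averaged; a feature with no valid
window is reported missing, never zero-filled.  Channels that are absent
simply leave their features missing, mirroring per-parameter availability
in real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..types import RawSignalSet, empty_feature_vector
from .beats import correct_ectopics, detect_beats
from .eda import eda_decompose, eda_features
from .hrv import hrv_spectral_features, hrv_time_features
from .pulses import detect_pulses, pulse_arrival_time
from .resp import respiratory_features, respiratory_window
from .temperature import temperature_features


@dataclass
class ExtractionResult:
    features: pd.Series
    window_counts: dict[str, int] = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def extract_all(signals: RawSignalSet, stage: str,
                window_s: float = 60.0) -> ExtractionResult:
    """Extract the full feature vector for one annotated stage."""
    start, end = signals.stage_span(stage)
    fv = empty_feature_vector()
    counts: dict[str, int] = {}
    flags: list[str] = []
    n_windows = int((end - start) // window_s)
    windows = [(start + i * window_s, start + (i + 1) * window_s)
               for i in range(n_windows)]

    beats = None
    if "ECG" in signals.channels:
        beats = correct_ectopics(detect_beats(signals.channels["ECG"]))
        if beats.n_beats == 0:
            flags.append("no_beats")
            beats = None
    if beats is not None:
        tvals = {"HR": [], "SDNN": [], "RMSSD": []}
        svals = {"PLF": [], "PHF": [], "LF_HF": [], "PHFn": []}
        evals = {"PHFex": [], "PHFexn": [], "LF_HFex": []}
        for w in windows:
            t = hrv_time_features(beats, w, window_s)
            if np.isfinite(t["HR"]):
                for k in tvals:
                    tvals[k].append(t[k])
            s = hrv_spectral_features(beats, w, "standard")
            if np.isfinite(s["PLF"]):
                for k in svals:
                    svals[k].append(s[k])
            e = hrv_spectral_features(beats, w, "extended")
            if np.isfinite(e["PHFex"]):
                for k in evals:
                    evals[k].append(e[k])
        for d in (tvals, svals, evals):
            for k, v in d.items():
                vv = [x for x in v if np.isfinite(x)]
                if vv:
                    fv[k] = float(np.mean(vv))
                counts[k] = len(vv)

    if beats is not None and "PPG" in signals.channels:
        pulses = detect_pulses(signals.channels["PPG"])
        if pulses.n_pulses:
            pats, stds = [], []
            for w in windows:
                p = pulse_arrival_time(beats, pulses, w)
                if np.isfinite(p["PAT"]):
                    pats.append(p["PAT"])
                    stds.append(p["stdPAT"])
            if pats:
                fv["PAT"] = float(np.mean(pats))
                fv["stdPAT"] = float(np.mean(stds))
            counts["PAT"] = len(pats)

    if "RESP" in signals.channels:
        resp = signals.channels["RESP"]
        rrs, pks = [], []
        for w in windows:
            rate, pk, valid = respiratory_window(
                resp.segment(w[0], w[1]))
            if valid:
                rrs.append(rate)
                pks.append(pk)
        if rrs:
            fv["RR"] = float(np.mean(rrs))
            fv["Pk"] = float(np.mean(pks))
        counts["RR"] = len(rrs)

    if "EDA" in signals.channels:
        raw = signals.channels["EDA"].segment(start, end)
        dec = eda_decompose(raw)
        e = eda_features(dec.tonic, dec.phasic, (0.0, end - start),
                         raw=raw, window_s=window_s)
        for k, v in e.items():
            fv[k] = v
        counts["EDA"] = n_windows

    face = signals.channels.get("TFACE")
    finger = signals.channels.get("TFINGER")
    if face is not None or finger is not None:
        tacc: dict[str, list[float]] = {}
        for w in windows:
            tf = temperature_features(
                face.segment(w[0], w[1]) if face is not None else None,
                finger.segment(w[0], w[1]) if finger is not None else None)
            for k, v in tf.items():
                if np.isfinite(v):
                    tacc.setdefault(k, []).append(v)
        for k, v in tacc.items():
            fv[k] = float(np.mean(v))
            counts[k] = len(v)

    return ExtractionResult(features=fv, window_counts=counts,
                            flags=tuple(flags))
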