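"""Core containers shared by the simulator, feature extractors and statistics.

Units follow the conventions of autonomic psychophysiology: interbeat
intervals in seconds, pulse arrival time in milliseconds, skin conductance
in microsiemens, temperature in degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

GROUPS = ("TD", "ADHD")
GENDERS = ("male", "female")
STAGES = ("baseline", "stress")

#: Canonical order of the extracted parameters (CSV column order).
FEATURE_NAMES = (
    "HR", "SDNN", "RMSSD", "PLF", "PHF", "LF_HF", "PHFn",
    "PHFex", "PHFexn", "LF_HFex",
    "PAT", "stdPAT",
    "RR", "Pk",
    "mTonic", "stdTonic", "mPhasic", "stdPhasic", "aucPhasic", "EDASymp",
    "TFace", "TFinger", "TGradFace", "TGradFinger",
    "TPowFace", "TPowFinger", "TRatio",
)

#: Units per parameter, for the sidecar documentation file.
FEATURE_UNITS = {
    "HR": "bpm", "SDNN": "s", "RMSSD": "s",
    "PLF": "s^-2", "PHF": "s^-2", "LF_HF": "AD", "PHFn": "nu",
    "PHFex": "s^-2", "PHFexn": "nu", "LF_HFex": "AD",
    "PAT": "ms", "stdPAT": "ms", "RR": "Hz", "Pk": "%",
    "mTonic": "uS", "stdTonic": "uS", "mPhasic": "uS", "stdPhasic": "uS",
    "aucPhasic": "uS*s", "EDASymp": "AD",
    "TFace": "degC", "TFinger": "degC",
    "TGradFace": "degC", "TGradFinger": "degC",
    "TPowFace": "degC^2", "TPowFinger": "degC^2", "TRatio": "AD",
}

METADATA_COLUMNS = ("subject_id", "group", "gender", "age", "stage")


class SignalError(ValueError):
    """Raised on invalid signal inputs (too short, zero rate, ...)."""


@dataclass(frozen=True)
class SubjectSpec:
    """Identity and randomness source for one simulated subject."""

    subject_id: str
    group: str
    gender: str
    age: int
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not 7 <= int(self.age) <= 12:
            raise ValueError(f"age must be within 7-12 years, got {self.age}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class Channel:
    """One uniformly sampled signal channel."""

    data: np.ndarray
    fs: float
    unit: str = "a.u."

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SignalError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))

    @property
    def duration(self) -> float:
        return self.data.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.fs

    def segment(self, start_s: float, end_s: float) -> "Channel":
        """Return the sub-channel covering [start_s, end_s)."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        return Channel(self.data[i0:i1], self.fs, self.unit)


@dataclass
class RawSignalSet:
    """One subject's multichannel recording with stage annotations.

    ``channels`` maps labels (ECG, PPG, RESP, EDA, TFACE, TFINGER) to
    :class:`Channel`; ``stages`` is a list of (label, start_s, end_s).
    """

    channels: dict[str, Channel]
    stages: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        spans = sorted((s, e) for _, s, e in self.stages)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("stage annotations overlap")
        for name, ch in self.channels.items():
            for label, _, end in self.stages:
                if ch.duration + 1e-9 < end:
                    raise ValueError(
                        f"channel {name} ({ch.duration:.1f} s) does not cover "
                        f"stage {label} ending at {end:.1f} s"
                    )

    def stage_span(self, label: str) -> tuple[float, float]:
        for name, start, end in self.stages:
            if name == label:
                return start, end
        raise KeyError(f"stage {label!r} not annotated")

    def stage_channel(self, channel: str, stage: str) -> Channel:
        start, end = self.stage_span(stage)
        return self.channels[channel].segment(start, end)


@dataclass
class BeatSeries:
    """Heartbeat event times and the derived interbeat-interval series."""

    times: np.ndarray
    valid: Optional[np.ndarray] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.times.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def ibis(self) -> np.ndarray:
        """Successive interbeat intervals (seconds)."""
        return np.diff(self.times)

    @property
    def n_beats(self) -> int:
        return int(self.times.size)

    def in_window(self, start_s: float, end_s: float) -> "BeatSeries":
        mask = (self.times >= start_s) & (self.times < end_s)
        return BeatSeries(self.times[mask], self.valid[mask], self.flags)


@dataclass
class PulseSeries:
    """PPG pulse fiducials (50%-rise points) inside artifact-free windows."""

    times: np.ndarray
    clean_windows: list[tuple[float, float]] = field(default_factory=list)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("pulse times must be strictly increasing")

    @property
    def n_pulses(self) -> int:
        return int(self.times.size)


def empty_feature_vector() -> pd.Series:
    """All-missing feature vector in canonical order."""
    return pd.Series(np.nan, index=list(FEATURE_NAMES), dtype=float)


__all__ = [
    "GROUPS", "GENDERS", "STAGES", "FEATURE_NAMES", "FEATURE_UNITS",
    "METADATA_COLUMNS", "SignalError", "SubjectSpec", "Channel",
    "RawSignalSet", "BeatSeries", "PulseSeries", "empty_feature_vector",
    "replace",
]
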