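"""PPG pulse detection with Hjorth-parameter artifact masking, and PAT.

Pulse quality is screened per window through the Hjorth descriptors
(activity, mobility, complexity): windows falling outside calibration
bounds around the recording's median descriptor values are masked.  Inside
clean windows each pulse fiducial is the instant the upstroke crosses 50%
of the foot-to-peak amplitude.  The pulse arrival time (PAT) is the delay
from each ECG R peak to the first such fiducial within 600 ms.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..types import BeatSeries, Channel, PulseSeries, SignalError

HJORTH_WINDOW_S = 5.0
#: multiplicative bounds on activity and mobility relative to the median
HJORTH_ACTIVITY_BOUNDS = (0.05, 20.0)
HJORTH_MOBILITY_BOUNDS = (0.25, 4.0)
PAT_MATCH_MS = 600.0


def _hjorth(x: np.ndarray) -> tuple[float, float, float]:
    activity = np.var(x)
    if activity < 1e-24:
        return activity, 0.0, 0.0
    dx = np.diff(x)
    mobility = np.sqrt(np.var(dx) / activity)
    ddx = np.diff(dx)
    mob_dx = np.sqrt(np.var(ddx) / np.var(dx)) if np.var(dx) > 0 else 0.0
    complexity = mob_dx / mobility if mobility > 0 else 0.0
    return activity, mobility, complexity


def detect_pulses(ppg: Channel) -> PulseSeries:
    """Pulse fiducials (50%-rise points) in artifact-free windows."""
    if ppg.fs < 100:
        raise SignalError(f"PPG sampling rate {ppg.fs} Hz below 100 Hz")
    x = ppg.data - np.mean(ppg.data)
    if np.max(np.abs(x)) < 1e-12:
        return PulseSeries(np.empty(0), flags=("no_pulses",))

    # Hjorth screening per window against recording-median calibration
    wlen = int(HJORTH_WINDOW_S * ppg.fs)
    n_win = max(x.size // wlen, 1)
    stats = np.array([_hjorth(x[i * wlen:(i + 1) * wlen])
                      for i in range(n_win)])
    med = np.median(stats, axis=0)
    good = np.ones(n_win, dtype=bool)
    if med[0] > 0:
        good &= (stats[:, 0] > HJORTH_ACTIVITY_BOUNDS[0] * med[0]) \
            & (stats[:, 0] < HJORTH_ACTIVITY_BOUNDS[1] * med[0])
    if med[1] > 0:
        good &= (stats[:, 1] > HJORTH_MOBILITY_BOUNDS[0] * med[1]) \
            & (stats[:, 1] < HJORTH_MOBILITY_BOUNDS[1] * med[1])
    clean_windows = [(i * wlen / ppg.fs, min((i + 1) * wlen, x.size) / ppg.fs)
                     for i in range(n_win) if good[i]]
    if not clean_windows:
        return PulseSeries(np.empty(0), flags=("all_masked",))

    peaks, _ = sps.find_peaks(x, distance=int(0.3 * ppg.fs),
                              prominence=0.3 * np.percentile(np.abs(x), 95))
    fiducials = []
    for p in peaks:
        t_peak = p / ppg.fs
        if not any(lo <= t_peak < hi for lo, hi in clean_windows):
            continue
        lo = max(p - int(0.4 * ppg.fs), 0)
        foot = lo + int(np.argmin(x[lo:p + 1]))
        half = x[foot] + 0.5 * (x[p] - x[foot])
        seg = x[foot:p + 1]
        above = np.nonzero(seg >= half)[0]
        if above.size == 0:
            continue
        i1 = foot + above[0]
        if i1 == foot:
            t50 = foot / ppg.fs
        else:
            y0, y1 = x[i1 - 1], x[i1]
            frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.0
            t50 = (i1 - 1 + frac) / ppg.fs
        fiducials.append(t50)
    fiducials = np.unique(fiducials)
    if fiducials.size == 0:
        return PulseSeries(np.empty(0), clean_windows, flags=("no_pulses",))
    return PulseSeries(fiducials, clean_windows)


def pulse_arrival_time(beats: BeatSeries, pulses: PulseSeries,
                       window: tuple[float, float]) -> dict[str, float]:
    """Mean and SD (ms) of the R-peak-to-pulse delay over the window."""
    start, end = window
    bt = beats.times[(beats.times >= start) & (beats.times < end)]
    delays = []
    for tb in bt:
        after = pulses.times[(pulses.times > tb)
                             & (pulses.times <= tb + PAT_MATCH_MS / 1000.0)]
        if after.size:
            delays.append((after[0] - tb) * 1000.0)
    if len(delays) < 2:
        return {"PAT": np.nan, "stdPAT": np.nan}
    delays = np.asarray(delays)
    return {"PAT": float(np.mean(delays)),
            "stdPAT": float(np.std(delays, ddof=1))}
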