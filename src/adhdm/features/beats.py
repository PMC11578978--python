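"""QRS detection and ectopic / false-detection correction.

The detector band-passes the ECG around the QRS energy (5-25 Hz), squares
the derivative, smooths, and peak-picks with a physiological refractory
period.  Interval-level correction then repairs false detections (interval
pairs merged) and missed beats (long gaps split) against a running median.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..types import BeatSeries, Channel, SignalError

REFRACTORY_S = 0.25
#: relative deviation from the running median that flags an interval
ECTOPIC_TOLERANCE = 0.30


def detect_beats(ecg: Channel) -> BeatSeries:
    """Locate one fiducial per QRS-like complex.

    Returns an empty, flagged series when the signal carries no energy.
    """
    if ecg.fs < 250:
        raise SignalError(f"ECG sampling rate {ecg.fs} Hz below 250 Hz")
    if ecg.duration < 10:
        raise SignalError(f"need >= 10 s of ECG, got {ecg.duration:.1f} s")
    x = ecg.data - np.mean(ecg.data)
    if np.max(np.abs(x)) < 1e-12:
        return BeatSeries(np.empty(0), flags=("no_beats",))

    sos = sps.butter(3, [5, 25], btype="bandpass", fs=ecg.fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(int(0.05 * ecg.fs), 1)
    energy = sps.convolve(energy, np.ones(win) / win, mode="same")

    height = 0.2 * np.percentile(energy, 99)
    peaks, _ = sps.find_peaks(
        energy, height=height, distance=int(REFRACTORY_S * ecg.fs))
    if peaks.size == 0:
        return BeatSeries(np.empty(0), flags=("no_beats",))

    # refine each fiducial to the local extremum of the band-passed signal
    half = int(0.05 * ecg.fs)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, bp.size)
        refined.append(lo + np.argmax(np.abs(bp[lo:hi])))
    refined = np.unique(refined)
    return BeatSeries(refined / ecg.fs)


def correct_ectopics(beats: BeatSeries,
                     tolerance: float = ECTOPIC_TOLERANCE) -> BeatSeries:
    """Repair false detections and missed beats in the interval series.

    Intervals deviating more than ``tolerance`` from the running median of
    five are treated either as false detections (the offending beat is
    removed, merging the interval pair) or as missed beats (the long gap
    is split into the nearest multiple of the local median).
    """
    if beats.n_beats < 3:
        return BeatSeries(beats.times, flags=beats.flags + ("too_few_beats",))
    times = list(beats.times)
    for _ in range(10):  # passes until stable
        ibis = np.diff(times)
        med = _running_median(ibis, 5)
        changed = False
        i = 0
        new_times = [times[0]]
        while i < len(ibis):
            dev = abs(ibis[i] - med[i]) / med[i]
            if dev <= tolerance:
                new_times.append(times[i + 1])
                i += 1
                continue
            if (ibis[i] < med[i] and i + 1 < len(ibis)
                    and abs(ibis[i] + ibis[i + 1] - med[i]) / med[i]
                    <= tolerance):
                # false detection: drop the middle beat
                new_times.append(times[i + 2])
                i += 2
                changed = True
            elif ibis[i] > med[i]:
                # missed beat(s): split gap into k equal intervals
                k = max(int(round(ibis[i] / med[i])), 1)
                step = ibis[i] / k
                for j in range(1, k + 1):
                    new_times.append(times[i] + j * step)
                i += 1
                changed = k > 1
            else:
                new_times.append(times[i + 1])
                i += 1
        times = new_times
        if not changed:
            break
    return BeatSeries(np.asarray(times), flags=beats.flags)


def _running_median(x: np.ndarray, width: int) -> np.ndarray:
    """Centered running median with shrinking edges."""
    half = width // 2
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        lo, hi = max(i - half, 0), min(i + half + 1, x.size)
        out[i] = np.median(x[lo:hi])
    return out
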