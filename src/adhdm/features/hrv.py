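"""Time- and frequency-domain heart-rate-variability indices.

Time-domain indices (HR, SDNN, RMSSD) are computed per 1-minute window and
averaged over the stage.  Spectral indices are computed from the
instantaneous heart-rate series, resampled uniformly at 4 Hz by cubic
interpolation, with Welch's estimator (60 s Hann segments, 50% overlap).
The standard high-frequency band is 0.15-0.4 Hz; in extended mode its
upper edge is raised to half the mean heart rate (in Hz) so parasympathetic
power is not truncated at the high heart rates typical of children.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from ..types import BeatSeries

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RESAMPLE_HZ = 4.0


def _window_ibis(beats: BeatSeries, start: float, end: float) -> np.ndarray:
    """IBIs whose terminating beat falls inside [start, end)."""
    t = beats.times
    ib = beats.ibis
    mask = (t[1:] >= start) & (t[1:] < end) & (t[:-1] >= start)
    return ib[mask]


def hrv_time_features(beats: BeatSeries, window: tuple[float, float],
                      window_s: float = 60.0) -> dict[str, float]:
    """HR (bpm), SDNN (s), RMSSD (s), averaged over 1-minute windows."""
    start, end = window
    hrs, sdnns, rmssds = [], [], []
    w0 = start
    while w0 + window_s <= end + 1e-9:
        ibis = _window_ibis(beats, w0, w0 + window_s)
        if ibis.size >= 2:
            hrs.append(60.0 / np.mean(ibis))
            sdnns.append(np.std(ibis, ddof=1))
            diffs = np.diff(ibis)
            rmssds.append(np.sqrt(np.mean(diffs ** 2)) if diffs.size else 0.0)
        w0 += window_s
    if not hrs:
        return {"HR": np.nan, "SDNN": np.nan, "RMSSD": np.nan}
    return {"HR": float(np.mean(hrs)),
            "SDNN": float(np.mean(sdnns)),
            "RMSSD": float(np.mean(rmssds))}


def instantaneous_hr(beats: BeatSeries, start: float, end: float,
                     fs: float = RESAMPLE_HZ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform instantaneous-HR series (Hz) by cubic interpolation."""
    t = beats.times
    if t.size < 4:
        raise ValueError("need at least 4 beats for interpolation")
    hr_inst = 1.0 / beats.ibis  # Hz, indexed at the terminating beat
    spline = CubicSpline(t[1:], hr_inst)
    grid = np.arange(start, end, 1.0 / fs)
    grid = grid[(grid >= t[1]) & (grid <= t[-1])]
    return grid, spline(grid)


def extended_hf_edge(mean_hr_bpm: float) -> float:
    """Upper HF edge in extended mode: half the mean heart rate in Hz."""
    return (mean_hr_bpm / 60.0) / 2.0


def _band_power(f: np.ndarray, psd: np.ndarray,
                band: tuple[float, float]) -> float:
    mask = (f >= band[0]) & (f <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def hrv_spectral_features(beats: BeatSeries, window: tuple[float, float],
                          band_mode: str = "standard") -> dict[str, float]:
    """Band powers of the instantaneous-HR spectrum.

    Returns PLF, PHF, LF_HF, PHFn for ``standard`` mode and PHFex, PHFexn,
    LF_HFex for ``extended`` mode (LF limits are unchanged in either mode).
    """
    if band_mode not in ("standard", "extended"):
        raise ValueError(f"unknown band_mode {band_mode!r}")
    missing = {"PLF": np.nan, "PHF": np.nan, "LF_HF": np.nan, "PHFn": np.nan} \
        if band_mode == "standard" else \
        {"PHFex": np.nan, "PHFexn": np.nan, "LF_HFex": np.nan}

    start, end = window
    ibis = _window_ibis(beats, start, end)
    if ibis.size < 2 or (end - start) < 60.0:
        return missing
    mean_hr_bpm = 60.0 / np.mean(ibis)
    hf_hi = HF_BAND[1]
    if band_mode == "extended":
        hf_hi = extended_hf_edge(mean_hr_bpm)
        if hf_hi <= HF_BAND[0]:
            return missing  # degenerate band: mean HR below 18 bpm

    try:
        _, hr = instantaneous_hr(beats, start, end)
    except ValueError:
        return missing
    if hr.size < 32:
        return missing
    if np.var(hr) < 1e-18:
        out = dict.fromkeys(missing, np.nan)
        for key in ("PLF", "PHF", "PHFex"):
            if key in out:
                out[key] = 0.0
        return out

    nperseg = min(int(60 * RESAMPLE_HZ), hr.size)
    f, psd = sps.welch(hr, fs=RESAMPLE_HZ, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant")
    plf = _band_power(f, psd, LF_BAND)
    phf = _band_power(f, psd, (HF_BAND[0], hf_hi))
    total = plf + phf
    lf_hf = plf / phf if phf > 0 else np.nan
    phfn = 100.0 * phf / total if total > 0 else np.nan
    if band_mode == "standard":
        return {"PLF": plf, "PHF": phf, "LF_HF": lf_hf, "PHFn": phfn}
    return {"PHFex": phf, "PHFexn": phfn, "LF_HFex": lf_hf}
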