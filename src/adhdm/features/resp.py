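"""Respiratory rate and spectral-peak stability.

The respiratory rate is the frequency of the dominant peak of the power
spectrum within 0.1-0.6 Hz.  Pk expresses, in percent, how much of the
in-band power is concentrated within +/- 0.015 Hz of that peak; windows
with Pk at or below 65% are considered unstable and excluded from stage
averages.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..types import Channel

RESP_BAND = (0.1, 0.6)
PEAK_HALF_WIDTH_HZ = 0.015
PK_VALID_THRESHOLD = 65.0


def respiratory_window(resp: Channel) -> tuple[float, float, bool]:
    """(rate_hz, pk_percent, valid) for one >= 60 s window."""
    x = resp.data - np.mean(resp.data)
    n = x.size
    if n < 2 or np.max(np.abs(x)) < 1e-12:
        return np.nan, np.nan, False
    # unpadded boxcar periodogram: a tone with an integer number of cycles
    # concentrates in a single bin, so Pk cleanly separates stable breathing
    # from mixtures; the peak slab is floored at 1.5 bins to tolerate
    # off-bin leakage
    f, psd = sps.periodogram(x, fs=resp.fs, window="boxcar")
    band = (f >= RESP_BAND[0]) & (f <= RESP_BAND[1])
    if not band.any() or psd[band].max() <= 0:
        return np.nan, np.nan, False
    fb, pb = f[band], psd[band]
    peak = fb[np.argmax(pb)]
    half_width = max(PEAK_HALF_WIDTH_HZ, 1.5 * (f[1] - f[0]))
    near = np.abs(fb - peak) <= half_width
    pk = 100.0 * pb[near].sum() / pb.sum()
    return float(peak), float(pk), bool(pk > PK_VALID_THRESHOLD)


def respiratory_features(resp: Channel, window: tuple[float, float],
                         window_s: float = 60.0,
                         t0: float = 0.0) -> dict[str, float]:
    """Stage-level RR (Hz) and Pk (%) averaged over valid 1-minute windows.

    ``t0`` is the channel's absolute start time, so stage windows given in
    recording time can be mapped onto the channel samples.
    """
    start, end = window
    rrs, pks = [], []
    w0 = start
    while w0 + window_s <= end + 1e-9:
        seg = resp.segment(w0 - t0, w0 - t0 + window_s)
        rate, pk, valid = respiratory_window(seg)
        if valid:
            rrs.append(rate)
            pks.append(pk)
        w0 += window_s
    if not rrs:
        return {"RR": np.nan, "Pk": np.nan}
    return {"RR": float(np.mean(rrs)), "Pk": float(np.mean(pks))}
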