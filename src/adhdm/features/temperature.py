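"""Skin-temperature indices from face and finger thermistors.

Artifact spikes (successive-sample jumps above 1 degC) are removed by
linear interpolation before computation — the automated counterpart of
manual segment inspection.
"""

from __future__ import annotations

import numpy as np

from ..types import Channel

SPIKE_JUMP_C = 1.0
DECIMATE_S = 10.0


def clean_temperature(ch: Channel, jump_c: float = SPIKE_JUMP_C) -> Channel:
    """Interpolate across samples that jump more than ``jump_c`` degC."""
    x = ch.data.copy()
    bad = np.zeros(x.size, dtype=bool)
    jumps = np.abs(np.diff(x)) > jump_c
    bad[1:] |= jumps
    if bad.any() and not bad.all():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return Channel(x, ch.fs, ch.unit)


def _site_features(ch: Channel) -> dict[str, float]:
    x = clean_temperature(ch).data
    block = int(DECIMATE_S * ch.fs)
    n_blocks = x.size // block
    if n_blocks >= 2:
        decimated = x[:n_blocks * block].reshape(n_blocks, block).mean(axis=1)
        tgrad = float(np.mean(np.diff(decimated)))
    else:
        tgrad = np.nan
    return {"T": float(np.mean(x)),
            "TGrad": tgrad,
            "TPow": float(np.mean(x ** 2))}


def temperature_features(face: Channel | None, finger: Channel | None,
                         window: tuple[float, float] | None = None,
                         ) -> dict[str, float]:
    """Mean, 10-s gradient and mean power per site, plus the finger/face
    ratio of window means."""
    out = {"TFace": np.nan, "TGradFace": np.nan, "TPowFace": np.nan,
           "TFinger": np.nan, "TGradFinger": np.nan, "TPowFinger": np.nan,
           "TRatio": np.nan}
    if face is not None and face.data.size:
        site = _site_features(face)
        out.update(TFace=site["T"], TGradFace=site["TGrad"],
                   TPowFace=site["TPow"])
    if finger is not None and finger.data.size:
        site = _site_features(finger)
        out.update(TFinger=site["T"], TGradFinger=site["TGrad"],
                   TPowFinger=site["TPow"])
    if np.isfinite(out["TFace"]) and np.isfinite(out["TFinger"]) \
            and out["TFace"] != 0:
        out["TRatio"] = out["TFinger"] / out["TFace"]
    return out
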