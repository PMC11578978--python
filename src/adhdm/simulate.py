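"""Synthetic cohort generation: raw biosignals and feature-level tables.

Two levels of simulation are provided.  ``simulate_subject_signals``
renders one subject's six-channel recording (ECG, PPG, respiration, EDA,
face and finger temperature) from an explicit generative model with
controllable autonomic modulations, so the signal-processing chain can be
tested against known ground truth.  ``simulate_feature_cohort`` draws
feature vectors directly from published per-group moments, so the
statistical pipeline can be exercised at cohort scale.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .moments import (PUBLISHED_MALE_FRACTION, TargetMoments,
                      lognormal_params, published_moments)
from .types import (FEATURE_NAMES, GROUPS, Channel, RawSignalSet, SignalError,
                    SubjectSpec)

MIN_STAGE_S = 120.0  # at least two 1-minute analysis windows per stage

#: biexponential sudomotor impulse response time constants (seconds)
SCR_RISE_S = 0.75
SCR_DECAY_S = 2.0


@dataclass(frozen=True)
class SignalGenConfig:
    """Parameter carrier for the raw-signal generator.

    IBI modulation amplitudes are in seconds; the PPG transit delay is the
    time from the R peak to the pulse's 50%-rise fiducial.
    """

    baseline_s: float = 300.0
    stress_s: float = 300.0
    fs_ecg: float = 1000.0
    fs_ppg: float = 1000.0
    fs_low: float = 256.0          # respiration, EDA, temperatures
    mean_hr_bpm: float = 90.0
    lf_amp_s: float = 0.015        # 0.1 Hz Mayer-wave IBI modulation
    hf_amp_s: float = 0.020        # respiratory sinus arrhythmia
    resp_freq_hz: float = 0.30
    ibi_jitter_s: float = 0.0
    pat_ms: float = 200.0
    eda_tonic_us: float = 2.0
    eda_drift_us_per_s: float = 0.0005
    scr_rate_per_min: float = 4.0
    scr_amp_us: float = 0.3
    temp_face_c: float = 31.0
    temp_finger_c: float = 29.0
    noise_sd: dict = field(default_factory=lambda: {
        "ECG": 0.0, "PPG": 0.0, "RESP": 0.0, "EDA": 0.0,
        "TFACE": 0.0, "TFINGER": 0.0,
    })
    # additive changes applied to the scalar fields during the stress stage
    stress_shift: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fs in (self.fs_ecg, self.fs_ppg, self.fs_low):
            if fs <= 0:
                raise SignalError(f"sampling rate must be positive, got {fs}")
        for d in (self.baseline_s, self.stress_s):
            if d < MIN_STAGE_S:
                raise SignalError(
                    f"stage duration {d} s below minimum {MIN_STAGE_S} s")
        if not (0.1 < self.resp_freq_hz < 0.5):
            raise SignalError(
                f"respiratory frequency must lie in (0.1, 0.5) Hz, "
                f"got {self.resp_freq_hz}")
        for name in ("mean_hr_bpm", "lf_amp_s", "hf_amp_s", "ibi_jitter_s",
                     "scr_rate_per_min", "scr_amp_us"):
            if getattr(self, name) < 0:
                raise SignalError(f"{name} must be non-negative")

    def for_stage(self, stage: str) -> "SignalGenConfig":
        if stage != "stress" or not self.stress_shift:
            return self
        changes = {k: getattr(self, k) + v for k, v in self.stress_shift.items()}
        return replace(self, stress_shift={}, **changes)


def _beat_times(cfg: SignalGenConfig, duration: float, t0: float,
                rng: np.random.Generator) -> np.ndarray:
    """Integrate the IBI model: constant mean + LF/HF sinusoids + jitter."""
    mean_ibi = 60.0 / cfg.mean_hr_bpm
    times = []
    t = t0
    while t < t0 + duration:
        times.append(t)
        ibi = (mean_ibi
               + cfg.lf_amp_s * np.sin(2 * np.pi * 0.1 * t)
               + cfg.hf_amp_s * np.sin(2 * np.pi * cfg.resp_freq_hz * t))
        if cfg.ibi_jitter_s > 0:
            ibi += cfg.ibi_jitter_s * rng.standard_normal()
        ibi = max(ibi, 0.25)  # refractory floor
        t += ibi
    return np.asarray(times)


def _render_ecg(beats: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Gaussian-template R waves (sigma 10 ms) at each beat time."""
    x = np.zeros(n)
    sigma = 0.010
    half = int(round(4 * sigma * fs))
    tpl_t = np.arange(-half, half + 1) / fs
    for tb in beats:
        c = int(round(tb * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        x[lo:hi] += np.exp(-((np.arange(lo, hi) / fs - tb) ** 2)
                           / (2 * sigma ** 2))
    del tpl_t
    return x


def _render_ppg(beats: np.ndarray, n: int, fs: float, pat_ms: float) -> np.ndarray:
    """Raised-cosine pulses whose 50%-rise point sits at beat + PAT."""
    x = np.zeros(n)
    width = 0.30
    # upstroke of 0.5*(1 - cos(2*pi*s/W)) crosses 50% amplitude at s = W/4
    for tb in beats:
        onset = tb + pat_ms / 1000.0 - width / 4.0
        i0 = int(np.ceil(onset * fs))
        i1 = int(np.floor((onset + width) * fs))
        i0c, i1c = max(i0, 0), min(i1 + 1, n)
        if i0c >= i1c:
            continue
        s = np.arange(i0c, i1c) / fs - onset
        x[i0c:i1c] += 0.5 * (1 - np.cos(2 * np.pi * s / width))
    return x


def _scr_kernel(fs: float) -> np.ndarray:
    """Biexponential sudomotor response, peak-normalized to 1."""
    t = np.arange(0, 10 * SCR_DECAY_S, 1 / fs)
    h = np.exp(-t / SCR_DECAY_S) - np.exp(-t / SCR_RISE_S)
    return h / h.max()


def _render_eda(cfg: SignalGenConfig, duration: float, fs: float,
                rng: np.random.Generator,
                events: np.ndarray | None = None) -> np.ndarray:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    tonic = cfg.eda_tonic_us + cfg.eda_drift_us_per_s * t
    phasic = np.zeros(n)
    if events is None:
        events = scr_event_times(cfg.scr_rate_per_min, duration, rng)
    kernel = _scr_kernel(fs)
    for te in events:
        i0 = int(round(te * fs))
        if i0 >= n:
            continue
        seg = min(kernel.size, n - i0)
        phasic[i0:i0 + seg] += cfg.scr_amp_us * kernel[:seg]
    return tonic + phasic


def scr_event_times(rate_per_min: float, duration: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Poisson sudomotor event times over [0, duration)."""
    if rate_per_min <= 0:
        return np.empty(0)
    rate = rate_per_min / 60.0
    times, t = [], 0.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        times.append(t)
    return np.asarray(times)


def simulate_subject_signals(spec: SubjectSpec,
                             cfg: SignalGenConfig) -> RawSignalSet:
    """Render one subject's six-channel recording with stage annotations.

    The same (spec, cfg) pair always yields bit-identical channels.
    """
    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(8)]
    (rng_beats, rng_scr, rng_n_ecg, rng_n_ppg,
     rng_n_resp, rng_n_eda, rng_n_tf, rng_n_tg) = rngs

    stage_spans = [("baseline", 0.0, cfg.baseline_s),
                   ("stress", cfg.baseline_s, cfg.baseline_s + cfg.stress_s)]
    total = cfg.baseline_s + cfg.stress_s

    beats = np.concatenate([
        _beat_times(cfg.for_stage(label), end - start, start, rng_beats)
        for label, start, end in stage_spans])

    n_hi = int(round(total * cfg.fs_ecg))
    ecg = _render_ecg(beats, n_hi, cfg.fs_ecg)
    n_ppg = int(round(total * cfg.fs_ppg))
    pats = [cfg.for_stage(label).pat_ms for label, _, _ in stage_spans]
    ppg = np.zeros(n_ppg)
    for (label, start, end), pat in zip(stage_spans, pats):
        sel = beats[(beats >= start) & (beats < end)]
        ppg += _render_ppg(sel, n_ppg, cfg.fs_ppg, pat)

    n_lo = int(round(total * cfg.fs_low))
    t_lo = np.arange(n_lo) / cfg.fs_low
    resp = np.zeros(n_lo)
    eda = np.zeros(n_lo)
    tface = np.zeros(n_lo)
    tfinger = np.zeros(n_lo)
    for label, start, end in stage_spans:
        c = cfg.for_stage(label)
        m = (t_lo >= start) & (t_lo < end)
        resp[m] = np.sin(2 * np.pi * c.resp_freq_hz * t_lo[m])
        seg = _render_eda(c, end - start, cfg.fs_low, rng_scr)
        k = min(int(m.sum()), seg.size)
        eda[np.nonzero(m)[0][:k]] = seg[:k]
        tface[m] = c.temp_face_c
        tfinger[m] = c.temp_finger_c

    def noisy(x, key, rng):
        sd = cfg.noise_sd.get(key, 0.0)
        return x + sd * rng.standard_normal(x.size) if sd > 0 else x

    channels = {
        "ECG": Channel(noisy(ecg, "ECG", rng_n_ecg), cfg.fs_ecg, "mV"),
        "PPG": Channel(noisy(ppg, "PPG", rng_n_ppg), cfg.fs_ppg, "a.u."),
        "RESP": Channel(noisy(resp, "RESP", rng_n_resp), cfg.fs_low, "a.u."),
        "EDA": Channel(noisy(eda, "EDA", rng_n_eda), cfg.fs_low, "uS"),
        "TFACE": Channel(noisy(tface, "TFACE", rng_n_tf), cfg.fs_low, "degC"),
        "TFINGER": Channel(noisy(tfinger, "TFINGER", rng_n_tg),
                           cfg.fs_low, "degC"),
    }
    return RawSignalSet(channels=channels, stages=stage_spans)


# ---------------------------------------------------------------------------
# feature-level cohort simulation


def _draw_group(n: int, group: str, moments: TargetMoments,
                correlation: np.ndarray | None, stage: str,
                rng: np.random.Generator) -> pd.DataFrame:
    """Draw n feature vectors for one group via a Gaussian copula."""
    params = moments.parameters
    p = len(params)
    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (p, p):
            raise ValueError(
                f"correlation must be {p}x{p} for {p} parameters")
        eig = np.linalg.eigvalsh((correlation + correlation.T) / 2)
        if eig.min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")
        z = rng.multivariate_normal(
            np.zeros(p), correlation, size=n, method="eigh")
    else:
        z = rng.standard_normal((n, p))
    out = {}
    for j, name in enumerate(params):
        mean, sd = moments.mean_sd(name, group, stage)
        if sd == 0:
            out[name] = np.full(n, mean)
        elif moments.is_lognormal(name) and mean > 0:
            mu, sigma = lognormal_params(mean, sd)
            out[name] = np.exp(mu + sigma * z[:, j])
        else:
            out[name] = mean + sd * z[:, j]
    return pd.DataFrame(out)


def simulate_feature_cohort(n_td: int, n_adhd: int,
                            moments: TargetMoments | None = None,
                            correlation: np.ndarray | None = None,
                            seed: int = 0,
                            stages: tuple[str, ...] = ("baseline",),
                            ) -> pd.DataFrame:
    """Draw a subjects x features cohort table from per-group target moments.

    Features are drawn per group from independent (or copula-correlated)
    normals, log-normally for right-skewed parameters, with per-group
    means/SDs from ``moments``.  Gender follows the published per-group
    male fractions; age is uniform on 7-12 years.  A ``stress`` stage, if
    requested, adds the group-specific reactivity shift plus within-subject
    noise to the baseline values.
    """
    if n_td < 1 or n_adhd < 1:
        raise ValueError("both groups need at least one subject")
    moments = moments or published_moments()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames = []
    for group, n in (("TD", n_td), ("ADHD", n_adhd)):
        base = _draw_group(n, group, moments, correlation, "baseline", rng)
        ids = [f"{group}{i + 1:04d}" for i in range(n)]
        gender = np.where(
            rng.random(n) < PUBLISHED_MALE_FRACTION[group], "male", "female")
        age = rng.integers(7, 13, size=n)
        meta = pd.DataFrame({
            "subject_id": ids, "group": group, "gender": gender, "age": age})
        if "baseline" in stages:
            frames.append(pd.concat(
                [meta.assign(stage="baseline"), base], axis=1))
        if "stress" in stages:
            stress = base.copy()
            for name in moments.parameters:
                b_mean, b_sd = moments.mean_sd(name, group, "baseline")
                s_mean, _ = moments.mean_sd(name, group, "stress")
                delta = s_mean - b_mean
                noise = 0.3 * b_sd * rng.standard_normal(n)
                stress[name] = base[name] + delta + noise
            frames.append(pd.concat(
                [meta.assign(stage="stress"), stress], axis=1))
    cohort = pd.concat(frames, ignore_index=True)
    order = ["subject_id", "group", "gender", "age", "stage"] + list(
        moments.parameters)
    return cohort[order]


def apply_missingness(cohort: pd.DataFrame,
                      moments: TargetMoments | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Mask feature entries to mirror the published per-parameter n values.

    For each parameter and group the available-n is scaled from the
    published cohort size to the simulated group size and the complement is
    set missing uniformly at random.  Metadata columns are never masked.
    """
    moments = moments or published_moments()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = cohort.copy()
    for group in GROUPS:
        pub_size = moments.group_sizes[group]
        for stage in out.loc[out["group"] == group, "stage"].unique():
            idx = out.index[(out["group"] == group) & (out["stage"] == stage)]
            size = len(idx)
            if size == 0:
                continue
            for name in moments.parameters:
                if name not in out.columns:
                    continue
                avail = moments.available_n(name, group)
                if avail > pub_size:
                    raise ValueError(
                        f"available-n {avail} exceeds published {group} "
                        f"group size {pub_size} for {name}")
                scaled = int(round(avail * size / pub_size))
                n_miss = size - scaled
                if n_miss <= 0:
                    continue
                mask = rng.choice(idx, size=n_miss, replace=False)
                out.loc[mask, name] = np.nan
    return out


def simulate_labelled_cohort(n_per_group: int, model=None,
                             seed: int = 0) -> pd.DataFrame:
    """Cohort whose class labels are drawn from the logistic scorer itself.

    Features are drawn from the per-group target moments; each subject's
    label is then a Bernoulli draw of their model probability, so the
    label-feature relationship follows the generative logistic model
    exactly.  The ``group`` column is overwritten with the drawn label;
    the generating probability is kept in ``true_score``.
    """
    from .model import published_model, score_cohort  # deferred: no cycle

    model = model or published_model()
    cohort = simulate_feature_cohort(n_per_group, n_per_group, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    scores = score_cohort(cohort, model)
    labels = rng.random(len(cohort)) < scores.to_numpy()
    out = cohort.copy()
    out["true_score"] = scores.to_numpy()
    out["group"] = np.where(labels, "ADHD", "TD")
    out["subject_id"] = [f"S{i + 1:05d}" for i in range(len(out))]
    return out


__all__ = [
    "SignalGenConfig", "simulate_subject_signals", "simulate_feature_cohort",
    "simulate_labelled_cohort", "apply_missingness", "scr_event_times",
    "MIN_STAGE_S",
]
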