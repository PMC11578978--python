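"""Published per-group baseline moments of the 27 autonomic parameters.

These are the group means, SDs and per-parameter available sample sizes of
the original 29 TD / 69 ADHD child cohort, used by the simulator as target
moments and by the scorer to reconstruct standardization constants.

The printed tonic-EDA means are negative in microsiemens, which is
impossible for a raw skin conductance level; the published values were
evidently detrended or re-referenced before averaging. They are treated
here as given numeric targets (the simulator reproduces them as numbers,
not as physical conductances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Original-study cohort sizes the per-parameter available-n values refer to.
PUBLISHED_GROUP_SIZES = {"TD": 29, "ADHD": 69}

# parameter: (td_n, td_mean, td_sd, adhd_n, adhd_mean, adhd_sd)
_BASELINE_TABLE = {
    "HR":          (28, 91.19, 8.88,   53, 86.93, 11.23),
    "SDNN":        (28, 0.053, 0.02,   53, 0.072, 0.04),
    "RMSSD":       (28, 0.022, 0.01,   53, 0.030, 0.02),
    "PLF":         (28, 0.488, 0.30,   53, 0.611, 0.34),
    "PHF":         (28, 0.462, 0.35,   53, 0.663, 0.63),
    "LF_HF":       (28, 158.28, 128.76, 53, 163.66, 109.99),
    "PHFn":        (28, 47.06, 12.39,  53, 47.77, 14.91),
    "PHFex":       (28, 0.581, 0.41,   53, 0.850, 0.83),
    "PHFexn":      (28, 54.36, 11.64,  53, 54.43, 14.04),
    "LF_HFex":     (28, 98.72, 46.24,  53, 107.76, 59.97),
    "PAT":         (18, 203.68, 17.18, 10, 211.44, 12.78),
    "stdPAT":      (18, 7.12, 3.16,    10, 8.43, 3.48),
    "RR":          (19, 0.36, 0.08,    26, 0.32, 0.09),
    "Pk":          (19, 70.06, 3.65,   26, 69.95, 2.47),
    "mTonic":      (29, -0.139, 0.64,  51, -0.530, 0.59),
    "stdTonic":    (29, 0.155, 0.10,   51, 0.240, 0.11),
    "mPhasic":     (29, 0.115, 0.13,   51, 0.074, 0.08),
    "stdPhasic":   (29, 0.084, 0.06,   51, 0.067, 0.06),
    "aucPhasic":   (29, 6.89, 7.57,    51, 4.46, 4.79),
    "EDASymp":     (29, 0.534, 0.80,   51, 0.316, 0.45),
    "TFace":       (29, 30.77, 1.05,   65, 33.07, 1.12),
    "TGradFace":   (29, 0.009, 0.01,   65, 0.004, 0.02),
    "TPowFace":    (29, 948.05, 65.58, 65, 1095.12, 72.86),
    "TFinger":     (29, 28.67, 5.09,   31, 30.66, 5.28),
    "TGradFinger": (29, 0.023, 0.06,   31, 0.029, 0.10),
    "TPowFinger":  (29, 847.25, 282.23, 31, 967.37, 310.33),
    "TRatio":      (29, 0.933, 0.17,   27, 0.919, 0.16),
}

#: Parameters simulated log-normally: strictly positive and right-skewed
#: (includes every parameter the classification model log-transforms).
LOGNORMAL_PARAMETERS = frozenset({
    "SDNN", "RMSSD", "PLF", "PHF", "LF_HF", "PHFex", "LF_HFex",
    "stdPAT", "stdTonic", "mPhasic", "stdPhasic", "aucPhasic", "EDASymp",
})

# Stress-minus-baseline mean shifts per group.  Magnitudes are not published
# (only directions and significances); signs reproduce the reported
# reactivity pattern: similar HR/RMSSD response in both groups, larger
# vagal (PHF) response in TD, larger tonic-EDA / respiratory-rate / finger
# temperature response in ADHD, lower respiratory stability (Pk) in ADHD.
DEFAULT_STRESS_DELTAS = {
    #               TD      ADHD
    "HR":          (3.0,    3.0),
    "RMSSD":       (-0.002, -0.002),
    "PHF":         (0.25,   0.05),
    "LF_HF":       (-40.0,  -5.0),
    "PHFex":       (0.30,   0.05),
    "LF_HFex":     (-25.0,  -5.0),
    "PAT":         (-3.0,   -8.0),
    "RR":          (0.01,   0.03),
    "Pk":          (-1.0,   -3.0),
    "mTonic":      (0.20,   0.50),
    "stdTonic":    (0.03,   0.10),
    "mPhasic":     (0.02,   0.04),
    "TFinger":     (-0.5,   0.5),
    "TRatio":      (-0.03,  0.01),
}


@dataclass
class TargetMoments:
    """Per-parameter, per-group target mean/SD plus available-n.

    ``table`` is indexed by parameter with columns
    ``td_n, td_mean, td_sd, adhd_n, adhd_mean, adhd_sd, lognormal``;
    ``group_sizes`` are the cohort sizes the available-n columns refer to;
    ``stress_deltas`` maps parameter -> (td_delta, adhd_delta) mean shifts.
    """

    table: pd.DataFrame
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(PUBLISHED_GROUP_SIZES))
    stress_deltas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STRESS_DELTAS))

    def __post_init__(self) -> None:
        t = self.table
        if (t["td_sd"] < 0).any() or (t["adhd_sd"] < 0).any():
            raise ValueError("target SDs must be non-negative")
        for g, n_col in (("TD", "td_n"), ("ADHD", "adhd_n")):
            if (t[n_col] > self.group_sizes[g]).any():
                bad = t.index[t[n_col] > self.group_sizes[g]].tolist()
                raise ValueError(
                    f"available-n exceeds {g} group size for {bad}")

    @property
    def parameters(self) -> list[str]:
        return list(self.table.index)

    def mean_sd(self, parameter: str, group: str,
                stage: str = "baseline") -> tuple[float, float]:
        row = self.table.loc[parameter]
        pre = "td" if group == "TD" else "adhd"
        mean = float(row[f"{pre}_mean"])
        if stage == "stress" and parameter in self.stress_deltas:
            mean += self.stress_deltas[parameter][0 if group == "TD" else 1]
        return mean, float(row[f"{pre}_sd"])

    def available_n(self, parameter: str, group: str) -> int:
        pre = "td" if group == "TD" else "adhd"
        return int(self.table.loc[parameter, f"{pre}_n"])

    def is_lognormal(self, parameter: str) -> bool:
        return bool(self.table.loc[parameter, "lognormal"])


def published_moments() -> TargetMoments:
    """The published baseline table as simulator target moments."""
    rows = []
    for name, (tn, tm, ts, an, am, asd) in _BASELINE_TABLE.items():
        rows.append((name, tn, tm, ts, an, am, asd, name in LOGNORMAL_PARAMETERS))
    table = pd.DataFrame(
        rows,
        columns=["parameter", "td_n", "td_mean", "td_sd",
                 "adhd_n", "adhd_mean", "adhd_sd", "lognormal"],
    ).set_index("parameter")
    return TargetMoments(table=table)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given raw mean and SD."""
    if mean <= 0:
        raise ValueError("log-normal target mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


#: Gender composition of the original cohort (male counts / group size).
PUBLISHED_MALE_FRACTION = {"TD": 11 / 29, "ADHD": 51 / 69}

#: Published gender contingency table, rows = (male, female), cols = (TD, ADHD).
PUBLISHED_GENDER_TABLE = np.array([[11, 51], [18, 18]])

#: Published mean (SD) of age per group, years.
PUBLISHED_AGE = {"TD": (9.14, 0.92), "ADHD": (8.95, 1.51)}
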