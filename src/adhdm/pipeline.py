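"""End-to-end reproducible run: simulate -> describe -> impute -> match ->
VIF -> stepwise fit -> ROC/Youden -> report.

A single global seed is fanned out to fixed per-stage child seeds, so
toggling one stage never shifts another stage's randomness.  Every output
file carries provenance (config hash + seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .model import (LOG_FEATURES, confusion_at_cutoff, fit_stepwise_logit,
                    prepare_design, roc_and_youden)
from .moments import published_moments
from .simulate import apply_missingness, simulate_feature_cohort
from .stats import (check_balance, compare_groups, impute_missing,
                    match_cohort, vif_reduce)
from .types import FEATURE_NAMES

log = logging.getLogger("adhdm.pipeline")

#: PAT and temperature parameters are excluded from the default candidate
#: set (few real observations / basal group differences); extended-band
#: duplicates of the standard HRV indices are likewise excluded.
DEFAULT_CANDIDATES = [
    "HR", "SDNN", "RMSSD", "PLF", "PHF", "LF_HF", "PHFn",
    "RR", "Pk", "mTonic", "stdTonic", "mPhasic", "stdPhasic",
    "aucPhasic", "EDASymp",
]

# fixed stage indices for child-seed derivation
_STAGE_SEEDS = {"simulate": 0, "missingness": 1, "impute": 2, "extract": 3}


@dataclass
class RunConfig:
    seed: int = 0
    n_td: int = 200
    n_adhd: int = 200
    simulate: bool = True
    feature_csv: str | None = None   # used when simulate is False
    with_missingness: bool = False
    outdir: str = "adhdm_run"
    window_s: float = 60.0
    caliper: float = 0.2
    max_ratio: int = 2
    vif_threshold: float = 5.0
    alpha: float = 0.05
    cutoff: float | None = None      # None -> Youden-selected
    candidates: list[str] = field(
        default_factory=lambda: list(DEFAULT_CANDIDATES))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        doc = asdict(self)
        doc.pop("outdir", None)  # output location is not analytic state
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Fixed per-stage child seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    provenance = {"seed": config.seed, "config_sha256": config.digest(),
                  "python": sys.version.split()[0],
                  "numpy": np.__version__, "pandas": pd.__version__}
    try:
        return _run(config, outdir, provenance)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, provenance: dict) -> Path:
    moments = published_moments()
    if config.simulate:
        cohort = simulate_feature_cohort(
            config.n_td, config.n_adhd, moments,
            seed=stage_seed(config.seed, "simulate"))
        if config.with_missingness:
            cohort = apply_missingness(
                cohort, moments, seed=stage_seed(config.seed, "missingness"))
        log.info("simulated %d TD + %d ADHD subjects",
                 config.n_td, config.n_adhd)
    else:
        if not config.feature_csv:
            raise ValueError("feature_csv required when simulate is off")
        cohort = aio.read_cohort_csv(config.feature_csv)
        log.info("loaded %d rows from %s", len(cohort), config.feature_csv)
    aio.write_cohort_csv(cohort, outdir / "cohort.csv", provenance)
    aio.write_units_sidecar(outdir / "cohort_units.tsv")

    baseline = cohort[cohort["stage"] == "baseline"].reset_index(drop=True)

    # descriptive group comparisons
    rows = []
    for name in FEATURE_NAMES:
        if name not in baseline.columns:
            continue
        try:
            c = compare_groups(baseline, name, alpha=config.alpha)
        except ValueError:
            continue
        rows.append({"parameter": name, "n_td": c.n_td, "n_adhd": c.n_adhd,
                     "mean_td": c.mean_td, "sd_td": c.sd_td,
                     "mean_adhd": c.mean_adhd, "sd_adhd": c.sd_adhd,
                     "test": c.test, "transform": c.transform,
                     "p": c.p_value})
    pd.DataFrame(rows).to_csv(outdir / "comparisons.csv", index=False)

    # impute -> match -> VIF -> stepwise fit; columns too sparse for the
    # imputation model (under 50% observed) are excluded with a log entry
    features = []
    for c in config.candidates:
        if c not in baseline.columns:
            continue
        frac = float(baseline[c].notna().mean())
        if frac < 0.5:
            log.info("dropping %s: only %.0f%% observed", c, 100 * frac)
        else:
            features.append(c)
    imputed = impute_missing(baseline, feature_cols=features,
                             seed=stage_seed(config.seed, "impute"))
    match = match_cohort(imputed, caliper=config.caliper,
                         max_ratio=config.max_ratio)
    log.info("matched %d TD anchors to %d ADHD subjects",
             len(match.pairs), sum(len(v) for v in match.pairs.values()))
    balance = check_balance(match, imputed)
    design_rows = imputed[imputed["subject_id"].isin(match.matched_ids)]

    kept = vif_reduce(design_rows, features,
                      threshold=config.vif_threshold)
    log.info("VIF kept %d of %d candidates", len(kept), len(features))
    design = prepare_design(design_rows, kept)
    y = (design_rows["group"] == "ADHD").astype(float).to_numpy()
    cand_cols = [f"log_{c}" if c in LOG_FEATURES else c for c in kept]
    fit = fit_stepwise_logit(design, y, cand_cols, alpha=config.alpha)
    fit.table.to_csv(outdir / "model_coefficients.csv")

    scores = np.asarray(
        fit.result.predict(), dtype=float)
    roc = roc_and_youden(scores, y)
    cutoff = config.cutoff if config.cutoff is not None else roc["cutoff"]
    report = confusion_at_cutoff(scores, y, cutoff)

    model_doc = {
        "provenance": provenance,
        "retained": fit.retained, "forced": fit.forced,
        "coefficients": fit.table["coef"].to_dict(),
        "cutoff": cutoff,
    }
    aio.write_json(model_doc, outdir / "model.json")
    aio.write_json({"provenance": provenance, "balance_post_match": balance,
                    "pre_post_balance": match.balance,
                    "roc": roc, **report.as_dict()},
                   outdir / "report.json")
    (outdir / "report.txt").write_text(report.to_text() + "\n")
    aio.write_json({"provenance": provenance, **asdict(config)},
                   outdir / "provenance.json")
    log.info("AUC %.3f at cutoff %.3f", roc["AUC"], cutoff)
    return outdir
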