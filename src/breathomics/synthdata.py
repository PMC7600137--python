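"""Synthetic untargeted LC-MS study generator.

Emulates the data structure of a two-group exhaled-breath-condensate
(EBC) metabolomics study: a case group measured at two timepoints (T0,
T1), an independent control group measured once, and replicate
injections of a pooled quality-control (QC) sample.  Intensities are
log-normal per feature with a subject random intercept on the log scale
so that paired (multilevel) analyses have within-subject correlation to
exploit.  A configurable subset of features carries a standardized
between-group shift, and optionally a T0->T1 shift in the case group,
providing ground truth for parameter-recovery tests.

Feature identifiers follow the ``time@mass`` convention of untargeted
LC-MS feature tables (retention time in minutes @ m/z in Da).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "GroundTruth", "generate_study", "pooled_qc_profile"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated two-group EBC study.

    Defaults mirror the clinical design this generator emulates:
    26 cases (sampled at T0 and T1), 16 controls, 108 features per
    ionization mode, and a small planted panel of group-discriminating
    features with a standardized log-scale effect.
    """

    n_case: int = 26
    n_control: int = 16
    n_features: int = 108
    n_discriminating: int = 10
    effect_size: float = 1.5      # standardized mean shift, log-intensity units
    paired_effect: float = 0.0    # mean T0->T1 shift (case group), sd units
    n_qc: int = 8
    missing_rate: float = 0.10
    qc_cv_high_fraction: float = 0.10
    qc_cv_low: float = 0.10       # raw-scale CV of well-behaved features in QC
    qc_cv_high: float = 0.40      # raw-scale CV of noisy features in QC
    icc: float = 0.5              # subject random-intercept share of log variance
    sigma_log: float = 0.5        # total within-group log-scale sd
    missing_mechanism: str = "censor"  # censor (below-detection) | mcar
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_features": self.n_features,
            "n_discriminating": self.n_discriminating,
            "n_qc": self.n_qc,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
        if self.n_discriminating > self.n_features:
            raise ValueError(
                "n_discriminating must not exceed n_features "
                f"({self.n_discriminating} > {self.n_features})"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate!r}")
        if not 0.0 <= self.qc_cv_high_fraction <= 1.0:
            raise ValueError(
                f"qc_cv_high_fraction must be in [0, 1], got {self.qc_cv_high_fraction!r}"
            )
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError(f"icc must be in [0, 1], got {self.icc!r}")
        if self.sigma_log <= 0:
            raise ValueError(f"sigma_log must be positive, got {self.sigma_log!r}")
        for name in ("qc_cv_low", "qc_cv_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)!r}")
        if self.missing_mechanism not in ("censor", "mcar"):
            raise ValueError(
                f"missing_mechanism must be 'censor' or 'mcar', got {self.missing_mechanism!r}"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulated study, for recovery tests."""

    discriminating_feature_ids: set = field(default_factory=set)
    paired_shift_feature_ids: set = field(default_factory=set)
    true_group: dict = field(default_factory=dict)  # sample_id -> case/control/QC

    def to_json(self, path: str | Path) -> None:
        payload = {
            "discriminating_feature_ids": sorted(self.discriminating_feature_ids),
            "paired_shift_feature_ids": sorted(self.paired_shift_feature_ids),
            "true_group": self.true_group,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _feature_ids(rng: np.random.Generator, n: int) -> list[str]:
    # retention times 0.5-12 min, m/z 100-600 Da, formatted time@mass
    rt = np.sort(rng.uniform(0.5, 12.0, size=n))
    mz = rng.uniform(100.0, 600.0, size=n)
    return [f"{t:.2f}@{m:.4f}" for t, m in zip(rt, mz)]


def _qc_log_sd(cv: np.ndarray) -> np.ndarray:
    # log-normal: CV = sqrt(exp(s^2) - 1)  =>  s = sqrt(log(1 + CV^2))
    return np.sqrt(np.log1p(np.asarray(cv, dtype=float) ** 2))


def generate_study(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a feature table, sample metadata and ground truth.

    Returns
    -------
    table : DataFrame, samples x features, ``time@mass`` columns; NaN marks
        missing values.
    meta : DataFrame with columns sample_id, group, subject_id, timepoint,
        is_qc (group in {case, control, QC}; timepoint in {T0, T1, none}).
    truth : GroundTruth with the planted discriminating feature ids.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    feats = _feature_ids(rng, p)

    # per-feature baseline log-intensity (typical dynamic range ~3 decades)
    base = rng.normal(loc=11.0, scale=1.5, size=p)
    shift = config.effect_size * config.sigma_log
    disc_idx = rng.choice(p, size=config.n_discriminating, replace=False)
    disc_mask = np.zeros(p, dtype=bool)
    disc_mask[disc_idx] = True
    paired_shift = config.paired_effect * config.sigma_log

    sd_subj = np.sqrt(config.icc) * config.sigma_log
    sd_resid = np.sqrt(1.0 - config.icc) * config.sigma_log

    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []

    def add_sample(sample_id, group, subject, timepoint, mean_log, subj_intercept):
        logx = mean_log + subj_intercept + rng.normal(0.0, sd_resid, size=p)
        rows.append(np.exp(logx))
        meta_rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "subject_id": subject,
                "timepoint": timepoint,
                "is_qc": group == "QC",
            }
        )

    case_mean = base + shift * disc_mask
    for i in range(config.n_case):
        subj = f"case{i + 1:02d}"
        b = rng.normal(0.0, sd_subj, size=p)
        add_sample(f"{subj}_T0", "case", subj, "T0", case_mean, b)
        add_sample(
            f"{subj}_T1", "case", subj, "T1", case_mean + paired_shift * disc_mask, b
        )
    for i in range(config.n_control):
        subj = f"ctrl{i + 1:02d}"
        b = rng.normal(0.0, sd_subj, size=p)
        add_sample(f"{subj}", "control", subj, "none", base, b)

    # pooled QC: fixed pooled profile, replicate injections with per-feature
    # technical CV; a configured fraction of features is given high CV so the
    # QC filter has something to remove
    n_high = int(round(config.qc_cv_high_fraction * p))
    cv = np.full(p, config.qc_cv_low)
    if n_high:
        high_idx = rng.choice(p, size=n_high, replace=False)
        cv[high_idx] = config.qc_cv_high
    qc_sd = _qc_log_sd(cv)
    pooled = base + 0.5 * shift * disc_mask  # pooled sample mixes both groups
    for i in range(config.n_qc):
        logx = pooled - 0.5 * qc_sd**2 + rng.normal(0.0, qc_sd, size=p)
        rows.append(np.exp(logx))
        meta_rows.append(
            {
                "sample_id": f"QC{i + 1:02d}",
                "group": "QC",
                "subject_id": "pooled",
                "timepoint": "none",
                "is_qc": True,
            }
        )

    meta = pd.DataFrame(meta_rows)
    table = pd.DataFrame(rows, index=meta["sample_id"].tolist(), columns=feats)
    table.index.name = "sample_id"

    # missing values in study samples only (QC injections stay complete so
    # the CV filter is well defined); default mechanism is left-censoring —
    # intensities below a global detection threshold are lost, which is the
    # structure the below-minimum imputation downstream assumes — with MCAR
    # deletion available as a stress-test alternative
    if config.missing_rate > 0:
        study = ~meta["is_qc"].to_numpy()
        n_study = int(study.sum())
        block = table.values[:n_study]
        if config.missing_mechanism == "censor":
            threshold = np.quantile(block, config.missing_rate)
            miss = block < threshold
        else:
            miss = rng.random((n_study, p)) < config.missing_rate
        # keep at least one observed value per feature among study samples
        all_gone = miss.all(axis=0)
        if all_gone.any():
            for j in np.flatnonzero(all_gone):
                miss[np.argmax(block[:, j]), j] = False
        block[miss] = np.nan
        table.iloc[:n_study] = block

    truth = GroundTruth(
        discriminating_feature_ids={feats[j] for j in disc_idx},
        paired_shift_feature_ids=(
            {feats[j] for j in disc_idx} if config.paired_effect != 0 else set()
        ),
        true_group=dict(zip(meta["sample_id"], meta["group"])),
    )
    return table, meta, truth


def pooled_qc_profile(
    table: pd.DataFrame,
    cv_target: float | np.ndarray,
    n_replicates: int = 8,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Replicate injections of the pooled profile of ``table``.

    The pooled profile is the per-feature mean of the observed values;
    replicates are log-normal around it with per-feature raw-scale CV
    converging to ``cv_target`` as the replicate count grows.
    """
    if n_replicates < 2:
        raise ValueError("at least 2 QC replicates are required (CV undefined below 2)")
    cv = np.broadcast_to(np.asarray(cv_target, dtype=float), (table.shape[1],)).copy()
    if (cv < 0).any():
        raise ValueError("cv_target must be nonnegative per feature")
    rng = np.random.default_rng(seed)
    pooled = table.mean(axis=0, skipna=True).to_numpy()
    s = _qc_log_sd(cv)
    logs = np.log(pooled)[None, :] - 0.5 * s[None, :] ** 2 + rng.normal(
        0.0, 1.0, size=(n_replicates, table.shape[1])
    ) * s[None, :]
    out = pd.DataFrame(
        np.exp(logs),
        index=[f"QC{i + 1:02d}" for i in range(n_replicates)],
        columns=table.columns,
    )
    out.index.name = "sample_id"
    return out


def write_study(
    table: pd.DataFrame, meta: pd.DataFrame, truth: GroundTruth, outdir: str | Path
) -> None:
    """Write table/meta as CSV and ground truth as JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "features.csv")
    meta.to_csv(outdir / "samples.csv", index=False)
    truth.to_json(outdir / "truth.json")


def config_from_dict(d: dict) -> SimConfig:
    allowed = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**d)
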