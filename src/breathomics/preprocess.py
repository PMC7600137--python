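"""Feature-table preprocessing for untargeted and targeted metabolomics.

Untargeted branch, in the order the pipeline enforces:

1. ``qc_cv_filter`` — drop features whose coefficient of variation across
   pooled-QC replicate injections exceeds a threshold (default 25%).
2. ``impute_missing`` — replace each missing entry by a uniform draw in
   (0, feature minimum), the standard left-censored imputation for
   below-detection LC-MS intensities.
3. ``pqn_normalize`` — probabilistic quotient normalization: divide each
   sample by the median of its feature-wise quotients to a reference
   spectrum, correcting sample-wide dilution.
4. ``log_center`` — natural log, then per-feature mean centering.

Targeted branch: ``impute_below_loq`` (uniform in (0, LOQ)) followed by
``autoscale`` (unit variance per analyte).

Each operation returns a new table and stamps a processing history into
``DataFrame.attrs`` so that out-of-order calls on pipeline tables raise
instead of silently producing nonsense; fresh tables with no history can
be fed to any single operation directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessReport",
    "PipelineOrderError",
    "qc_cv_filter",
    "impute_missing",
    "pqn_normalize",
    "log_center",
    "autoscale",
    "impute_below_loq",
    "preprocess_untargeted",
]

_STAGES = ("qc_cv_filter", "impute_missing", "pqn_normalize", "log_center")


class PipelineOrderError(RuntimeError):
    """Raised when preprocessing steps are applied out of order."""


@dataclass
class PreprocessReport:
    removed_feature_ids: dict = field(default_factory=dict)  # id -> (cv, reason)
    imputation_count: int = 0
    pqn_quotients: dict = field(default_factory=dict)        # sample id -> median quotient
    transform: str | None = None                             # log-center | autoscale

    def to_dict(self) -> dict:
        return {
            "removed_feature_ids": {
                k: {"cv": None if v[0] is None else float(v[0]), "reason": v[1]}
                for k, v in self.removed_feature_ids.items()
            },
            "imputation_count": int(self.imputation_count),
            "pqn_quotients": {k: float(v) for k, v in self.pqn_quotients.items()},
            "transform": self.transform,
        }


def _history(table: pd.DataFrame) -> list[str]:
    return list(table.attrs.get("preprocess_history", []))


def _check_order(table: pd.DataFrame, step: str) -> list[str]:
    """Reject a step if any later-stage step already ran on this table."""
    hist = _history(table)
    rank = _STAGES.index(step)
    later = [h for h in hist if h in _STAGES and _STAGES.index(h) > rank]
    if later:
        raise PipelineOrderError(
            f"{step} cannot run after {later[-1]}; required order is "
            + " -> ".join(_STAGES)
        )
    return hist


def _stamp(table: pd.DataFrame, hist: list[str], step: str) -> pd.DataFrame:
    table.attrs["preprocess_history"] = hist + [step]
    return table


def qc_cv_filter(
    table: pd.DataFrame,
    qc_sample_ids: set | list,
    threshold: float = 0.25,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop features with QC coefficient of variation above ``threshold``.

    CV is sd/mean over the observed QC intensities of each feature, with
    the sample (n-1) standard deviation.  Features with no QC signal or a
    zero QC mean cannot be assessed and are excluded with a reason.
    """
    hist = _check_order(table, "qc_cv_filter")
    qc_ids = [s for s in table.index if s in set(qc_sample_ids)]
    if len(qc_ids) < 2:
        raise ValueError(f"need >=2 QC samples to estimate CV, found {len(qc_ids)}")
    qc = table.loc[qc_ids]

    report = PreprocessReport()
    keep: list[str] = []
    for feat in table.columns:
        vals = qc[feat].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            report.removed_feature_ids[feat] = (None, "no QC signal")
            continue
        mean = vals.mean()
        if mean == 0:
            report.removed_feature_ids[feat] = (None, "zero mean")
            continue
        cv = vals.std(ddof=1) / mean
        if cv > threshold:
            report.removed_feature_ids[feat] = (cv, f"CV {cv:.3f} > {threshold:g}")
        else:
            keep.append(feat)
    out = table[keep].copy()
    return _stamp(out, hist, "qc_cv_filter"), report


def impute_missing(
    table: pd.DataFrame, seed: int | None = 0
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Replace missing entries by uniform draws in (0, feature minimum).

    Observed values are untouched; a feature that is entirely missing
    cannot be imputed and raises.
    """
    hist = _check_order(table, "impute_missing")
    out = table.copy()
    report = PreprocessReport()
    rng = np.random.default_rng(seed)
    for feat in out.columns:
        col = out[feat]
        mask = col.isna()
        if not mask.any():
            continue
        observed = col.dropna().to_numpy(dtype=float)
        if observed.size == 0:
            raise ValueError(f"feature {feat!r} has no observed values to impute from")
        lo, hi = 0.0, float(observed.min())
        draws = rng.uniform(lo, hi, size=int(mask.sum()))
        # open interval: uniform(0, hi) hits the endpoints with prob. 0 but
        # guard against an exact 0 draw anyway
        draws = np.where(draws == 0.0, hi * 0.5, draws)
        out.loc[mask, feat] = draws
        report.imputation_count += int(mask.sum())
    return _stamp(out, hist, "impute_missing"), report


def pqn_normalize(
    table: pd.DataFrame, reference: str | pd.Series | np.ndarray = "median"
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Probabilistic quotient normalization.

    For each sample, quotients q_j = x_j / ref_j are formed over features
    with positive reference value, and the sample is divided by
    median(q).  ``reference="median"`` uses the median spectrum of the
    table itself (callers should pass study samples only).
    """
    hist = _check_order(table, "pqn_normalize")
    x = table.to_numpy(dtype=float)
    if np.isnan(x).any() or (x <= 0).any():
        raise ValueError(
            "PQN requires a complete, strictly positive table; impute missing "
            "values first"
        )
    if isinstance(reference, str):
        if reference != "median":
            raise ValueError(f"unknown reference {reference!r}")
        ref = np.median(x, axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (x.shape[1],):
            raise ValueError("reference spectrum length does not match feature count")
    usable = ref > 0
    if not usable.any():
        raise ValueError("reference spectrum has no positive entries")
    quotients = x[:, usable] / ref[usable][None, :]
    med = np.median(quotients, axis=1)
    out = pd.DataFrame(x / med[:, None], index=table.index, columns=table.columns)
    report = PreprocessReport(pqn_quotients=dict(zip(table.index, med)))
    return _stamp(out, hist, "pqn_normalize"), report


def log_center(table: pd.DataFrame) -> pd.DataFrame:
    """Natural log then per-feature mean centering (untargeted transform)."""
    hist = _check_order(table, "log_center")
    x = table.to_numpy(dtype=float)
    bad = ~(x > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive entry at sample {table.index[i]!r}, "
            f"feature {table.columns[j]!r}; log transform requires positive values"
        )
    logged = np.log(x)
    centered = logged - logged.mean(axis=0, keepdims=True)
    out = pd.DataFrame(centered, index=table.index, columns=table.columns)
    return _stamp(out, hist, "log_center")


def autoscale(table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Center to mean 0 and scale to unit sd per feature (targeted transform).

    Constant features have no scale and are dropped with a warning.
    """
    x = table.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("autoscale requires a complete table; impute first")
    sd = x.std(axis=0, ddof=ddof)
    constant = sd == 0
    if constant.any():
        dropped = [c for c, flag in zip(table.columns, constant) if flag]
        warnings.warn(f"dropping constant features with zero variance: {dropped}")
    keep = ~constant
    scaled = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    out = pd.DataFrame(
        scaled, index=table.index, columns=table.columns[keep]
    )
    out.attrs["preprocess_history"] = _history(table) + ["autoscale"]
    return out


def impute_below_loq(
    values: pd.DataFrame,
    loq: pd.Series | dict,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Replace below-LOQ measurements by uniform draws in (0, LOQ).

    A censored entry is one that is missing (NaN) or strictly below its
    analyte's limit of quantification.  Quantified entries are untouched.
    """
    loq = pd.Series(loq)
    out = values.copy()
    rng = np.random.default_rng(seed)
    for analyte in out.columns:
        col = out[analyte].to_numpy(dtype=float)
        if analyte not in loq.index:
            if np.isnan(col).any():
                raise ValueError(f"no LOQ provided for analyte {analyte!r} with censored entries")
            continue
        limit = float(loq[analyte])
        if limit <= 0:
            raise ValueError(f"LOQ must be positive for analyte {analyte!r}, got {limit}")
        censored = np.isnan(col) | (col < limit)
        if censored.any():
            draws = rng.uniform(0.0, limit, size=int(censored.sum()))
            draws = np.where(draws == 0.0, limit * 0.5, draws)
            col[censored] = draws
            out[analyte] = col
    out.attrs["preprocess_history"] = _history(values) + ["impute_below_loq"]
    return out


def preprocess_untargeted(
    table: pd.DataFrame,
    qc_sample_ids: set | list,
    cv_threshold: float = 0.25,
    seed: int | None = 0,
    drop_qc: bool = True,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full untargeted chain: CV filter -> impute -> PQN -> log + center.

    QC samples are used for the CV filter and then dropped (default)
    before normalization, so PQN's median-spectrum reference reflects
    study samples only.
    """
    filtered, rep_filter = qc_cv_filter(table, qc_sample_ids, threshold=cv_threshold)
    if drop_qc:
        filtered = filtered.drop(index=[s for s in filtered.index if s in set(qc_sample_ids)])
        filtered.attrs["preprocess_history"] = ["qc_cv_filter"]
    imputed, rep_impute = impute_missing(filtered, seed=seed)
    normalized, rep_pqn = pqn_normalize(imputed, reference="median")
    out = log_center(normalized)
    report = PreprocessReport(
        removed_feature_ids=rep_filter.removed_feature_ids,
        imputation_count=rep_impute.imputation_count,
        pqn_quotients=rep_pqn.pqn_quotients,
        transform="log-center",
    )
    return out, report
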