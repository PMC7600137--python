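"""Orchestration of the pair-wise contrasts of a two-group EBC study.

Three contrasts are supported, each run per ionization mode on its own
preprocessed feature table:

* ``T0-vs-control`` and ``T1-vs-control`` — unpaired: Mann–Whitney +
  BH-FDR screening and PLS-DA stability selection.
* ``T0-vs-T1-paired`` — paired: Wilcoxon signed-rank screening and
  multilevel PLS-DA (stability selection on signed within-subject
  differences).

Each contrast starts with a per-group PCA outlier screen (flagged
samples are dropped and logged), ends by merging the univariate and
multivariate relevant sets, and optionally annotates the merged set
against a local metabolite mass table.  A targeted branch applies
below-LOQ imputation + autoscaling before the same statistical engine.
All parameters and seeds are recorded in the result for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import chemometrics as chem
from . import preprocess as prep
from . import univariate as uni

__all__ = [
    "AnalysisConfig",
    "ComparisonResult",
    "run_contrast",
    "targeted_contrast",
    "overlap",
    "CONTRASTS",
]

log = logging.getLogger(__name__)

CONTRASTS = ("T0-vs-control", "T1-vs-control", "T0-vs-T1-paired")


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis parameters, defaulting to the pipeline's standard values."""

    cv_threshold: float = 0.25   # QC CV filter
    delta: float = 0.10          # BH-FDR level
    alpha: float = 0.05          # relevance / outlier significance level
    pca_alpha: float = 0.05
    A: int | None = 2            # latent variables; None -> pick by MCCcv over 1..5
    B: int = 200                 # bootstrap subsamples
    folds: int = 5
    n_perm: int = 1000           # label permutations (0 skips the test)
    vip_cut: float = 1.0
    n_null: int = 20             # permuted re-runs calibrating selection frequency
    b_null: int | None = None    # subsamples per null run (default B)
    tol_ppm: float = 20.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ComparisonResult:
    contrast: str
    mode: str
    univariate_significant: set
    multivariate_relevant: set
    merged: set
    mcc_cv: float | None
    mcc_oob: float
    permutation_p: float | None
    outliers_dropped: list
    annotation_hits: list
    unannotated: list
    multivariate_subset_of_univariate: bool
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "mode": self.mode,
            "univariate_significant": sorted(self.univariate_significant),
            "multivariate_relevant": sorted(self.multivariate_relevant),
            "merged": sorted(self.merged),
            "n_univariate_significant": len(self.univariate_significant),
            "n_multivariate_relevant": len(self.multivariate_relevant),
            "n_merged": len(self.merged),
            "mcc_cv": None if self.mcc_cv is None else round(float(self.mcc_cv), 6),
            "mcc_oob": round(float(self.mcc_oob), 6),
            "permutation_p": (
                None if self.permutation_p is None else round(float(self.permutation_p), 6)
            ),
            "outliers_dropped": list(self.outliers_dropped),
            "annotation_hits": [h.to_dict() for h in self.annotation_hits],
            "unannotated": list(self.unannotated),
            "multivariate_subset_of_univariate": self.multivariate_subset_of_univariate,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _contrast_samples(meta: pd.DataFrame, contrast: str) -> pd.DataFrame:
    m = meta[~meta["is_qc"]]
    if contrast == "T0-vs-control":
        sel = m[(m["group"] == "control") | ((m["group"] == "case") & (m["timepoint"] == "T0"))]
    elif contrast == "T1-vs-control":
        sel = m[(m["group"] == "control") | ((m["group"] == "case") & (m["timepoint"] == "T1"))]
    elif contrast == "T0-vs-T1-paired":
        sel = m[(m["group"] == "case") & (m["timepoint"].isin(["T0", "T1"]))]
    else:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {CONTRASTS}")
    return sel


def _screen_outliers(
    table: pd.DataFrame, meta_sel: pd.DataFrame, contrast: str, alpha: float
) -> list:
    """Per-group PCA T²/Q screen; returns flagged sample ids."""
    if contrast == "T0-vs-T1-paired":
        grouping = meta_sel["timepoint"]
    else:
        grouping = meta_sel["group"]
    flagged: list = []
    for _, ids in meta_sel.groupby(grouping.to_numpy())["sample_id"]:
        sub = table.loc[[s for s in ids if s in table.index]]
        if len(sub) < 3:
            continue
        _, bad = chem.pca_outlier_screen(sub, alpha=alpha)
        if bad:
            log.info("PCA outlier screen flagged %s", bad)
        flagged.extend(bad)
    return flagged


def _choose_A(table, labels, config: AnalysisConfig, groups=None) -> int:
    if config.A is not None:
        return config.A
    n = len(table)
    best_a, best = 1, -np.inf
    for a in range(1, min(5, n - 2, table.shape[1]) + 1):
        m = chem.cross_validate_mcc(
            table, labels, A=a, folds=config.folds, seed=config.seed, groups=groups
        )
        if m > best:
            best_a, best = a, m
    return best_a


def _annotate_merged(
    merged: set, mode: str, db: pd.DataFrame | None, tol_ppm: float
) -> tuple[list, list]:
    if db is None or not merged:
        return [], sorted(merged)
    triples = []
    for fid in sorted(merged):
        _, mz = _annotate.parse_feature_id(fid)
        triples.append((fid, mz, mode))
    return _annotate.match_features(triples, db, tol_ppm=tol_ppm)


def run_contrast(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: str,
    config: AnalysisConfig = AnalysisConfig(),
    mode: str = "negative",
    annotation_db: pd.DataFrame | None = None,
    preprocessed: bool = False,
) -> ComparisonResult:
    """Run one pair-wise contrast end to end on one ionization mode.

    ``table`` is a raw feature table (QC rows included) unless
    ``preprocessed=True``, in which case it must already be filtered,
    imputed, normalized and log-centered and contain study samples only.
    """
    missing = set(meta["sample_id"]) - set(table.index)
    if missing:
        raise ValueError(f"metadata names samples absent from the table: {sorted(missing)}")

    if not preprocessed:
        qc_ids = set(meta.loc[meta["is_qc"], "sample_id"])
        table, report = prep.preprocess_untargeted(
            table, qc_ids, cv_threshold=config.cv_threshold, seed=config.seed
        )
    else:
        report = None

    sel = _contrast_samples(meta, contrast)
    sel = sel[sel["sample_id"].isin(table.index)]
    sub = table.loc[sel["sample_id"].tolist()]

    dropped = _screen_outliers(sub, sel, contrast, config.pca_alpha)
    if dropped:
        sel = sel[~sel["sample_id"].isin(dropped)]
        sub = sub.drop(index=dropped)

    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in ("cv", "perm", "stability")}

    if contrast == "T0-vs-T1-paired":
        screen = uni.wilcoxon_paired_screen(sub, sel, delta=config.delta)
        diffs, labels, groups = chem.multilevel_transform(sub, sel)
        A = _choose_A(diffs, labels, config, groups=groups)
        stab = chem.stability_selection(
            diffs, labels, A=A, B=config.B, alpha=config.alpha,
            vip_cut=config.vip_cut, n_null=config.n_null, b_null=config.b_null,
            groups=groups, seed=seeds["stability"],
        )
        mcc_cv = chem.cross_validate_mcc(
            diffs, labels, A=A, folds=config.folds, seed=seeds["cv"], groups=groups
        )
        perm_p = None
        if config.n_perm > 0:
            perm_p = chem.permutation_test(
                diffs, labels, A=A, n_perm=config.n_perm, folds=config.folds,
                seed=seeds["perm"], observed=mcc_cv, groups=groups,
            )["p_value"]
    else:
        labels = pd.Series(sel["group"].to_numpy(), index=sel["sample_id"])
        screen = uni.mann_whitney_screen(sub, labels, delta=config.delta)
        A = _choose_A(sub, labels.loc[sub.index], config)
        stab = chem.stability_selection(
            sub, labels.loc[sub.index], A=A, B=config.B, alpha=config.alpha,
            vip_cut=config.vip_cut, n_null=config.n_null, b_null=config.b_null,
            seed=seeds["stability"],
        )
        mcc_cv = chem.cross_validate_mcc(
            sub, labels.loc[sub.index], A=A, folds=config.folds, seed=seeds["cv"]
        )
        perm_p = None
        if config.n_perm > 0:
            perm_p = chem.permutation_test(
                sub, labels.loc[sub.index], A=A, n_perm=config.n_perm,
                folds=config.folds, seed=seeds["perm"], observed=mcc_cv,
            )["p_value"]

    uni_set = screen.significant_features
    multi_set = stab.relevant_features
    merged = uni_set | multi_set
    hits, unann = _annotate_merged(merged, mode, annotation_db, config.tol_ppm)

    provenance = {
        "config": config.to_dict(),
        "n_latent_variables": A,
        "operation_seeds": seeds,
        "n_samples": int(len(sub)),
        "n_features": int(sub.shape[1]),
        "preprocess": None if report is None else report.to_dict(),
        "operations": [
            "pca_outlier_screen",
            screen.test,
            "bh_fdr",
            "multilevel_transform" if contrast == "T0-vs-T1-paired" else "fit_plsda",
            "stability_selection",
            "cross_validate_mcc",
            "permutation_test" if config.n_perm > 0 else None,
            "match_features" if annotation_db is not None else None,
        ],
    }
    return ComparisonResult(
        contrast=contrast,
        mode=mode,
        univariate_significant=uni_set,
        multivariate_relevant=multi_set,
        merged=merged,
        mcc_cv=mcc_cv,
        mcc_oob=stab.mcc_oob,
        permutation_p=perm_p,
        outliers_dropped=dropped,
        annotation_hits=hits,
        unannotated=unann,
        multivariate_subset_of_univariate=multi_set <= uni_set,
        provenance=provenance,
    )


def overlap(a: set, b: set, name_a: str = "A", name_b: str = "B") -> dict:
    """Shared / unique counts between two relevant-feature sets."""
    a, b = set(a), set(b)
    shared = a & b
    return {
        "shared": len(shared),
        f"unique_{name_a}": len(a - b),
        f"unique_{name_b}": len(b - a),
        "shared_ids": sorted(shared),
        f"unique_{name_a}_ids": sorted(a - b),
        f"unique_{name_b}_ids": sorted(b - a),
    }


def targeted_contrast(
    values: pd.DataFrame,
    loq: pd.Series | dict,
    labels: pd.Series | dict,
    config: AnalysisConfig = AnalysisConfig(),
) -> ComparisonResult:
    """Targeted panel contrast: below-LOQ imputation, autoscale, same engine.

    ``values`` is samples x analytes (concentrations; NaN or values
    below the analyte's LOQ are treated as censored), ``labels`` maps
    sample id to one of two groups.
    """
    labels = pd.Series(labels)
    labels = labels.loc[[s for s in values.index if s in labels.index]]
    vals = values.loc[labels.index]
    loq_s = pd.Series(loq)
    censored = vals.isna() | vals.lt(loq_s.reindex(vals.columns), axis=1)
    if censored.all(axis=None):
        log.warning("all targeted values are below LOQ; analysis runs on imputed noise")
    imputed = prep.impute_below_loq(vals, loq, seed=config.seed)
    scaled = prep.autoscale(imputed)

    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in ("cv", "perm", "stability")}
    screen = uni.mann_whitney_screen(scaled, labels, delta=config.delta)
    A = _choose_A(scaled, labels, config)
    stab = chem.stability_selection(
        scaled, labels, A=A, B=config.B, alpha=config.alpha,
        vip_cut=config.vip_cut, n_null=config.n_null, b_null=config.b_null,
        seed=seeds["stability"],
    )
    mcc_cv = chem.cross_validate_mcc(
        scaled, labels, A=A, folds=config.folds, seed=seeds["cv"]
    )
    perm_p = None
    if config.n_perm > 0:
        perm_p = chem.permutation_test(
            scaled, labels, A=A, n_perm=config.n_perm, folds=config.folds,
            seed=seeds["perm"], observed=mcc_cv,
        )["p_value"]

    uni_set = screen.significant_features
    multi_set = stab.relevant_features
    merged = uni_set | multi_set
    provenance = {
        "config": config.to_dict(),
        "n_latent_variables": A,
        "operation_seeds": seeds,
        "n_samples": int(len(scaled)),
        "n_features": int(scaled.shape[1]),
        "operations": [
            "impute_below_loq", "autoscale", "mann-whitney", "bh_fdr",
            "stability_selection", "cross_validate_mcc",
            "permutation_test" if config.n_perm > 0 else None,
        ],
    }
    return ComparisonResult(
        contrast="targeted",
        mode="targeted",
        univariate_significant=uni_set,
        multivariate_relevant=multi_set,
        merged=merged,
        mcc_cv=mcc_cv,
        mcc_oob=stab.mcc_oob,
        permutation_p=perm_p,
        outliers_dropped=[],
        annotation_hits=[],
        unannotated=sorted(merged),
        multivariate_subset_of_univariate=multi_set <= uni_set,
        provenance=provenance,
    )
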