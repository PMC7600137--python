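"""Putative annotation of LC-MS features by adduct-corrected mass lookup.

An observed m/z is converted to a candidate neutral monoisotopic mass
under each polarity-consistent adduct rule (deprotonation in negative
mode; protonation, water loss and ammonia loss in positive mode) and
matched against a local metabolite table within a ppm tolerance.
Matches are accurate-mass only — annotation Level 3, no MS/MS evidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AdductRule",
    "AnnotationHit",
    "ADDUCT_RULES",
    "neutral_mass",
    "observed_mz",
    "match_features",
    "parse_feature_id",
    "load_marker_db",
]

log = logging.getLogger(__name__)

PROTON = 1.007276   # Da
H2O = 18.010565     # Da
NH3 = 17.026549     # Da


@dataclass(frozen=True)
class AdductRule:
    """Maps observed m/z to neutral monoisotopic mass: M = mz + offset."""

    name: str
    offset: float
    polarity: str  # negative | positive


ADDUCT_RULES: dict[str, AdductRule] = {
    "M-H": AdductRule("M-H", +PROTON, "negative"),
    "M+H": AdductRule("M+H", -PROTON, "positive"),
    "M+H-H2O": AdductRule("M+H-H2O", -PROTON + H2O, "positive"),
    "M+H-NH3": AdductRule("M+H-NH3", -PROTON + NH3, "positive"),
}


def neutral_mass(mz: float, rule: str | AdductRule) -> float:
    """Neutral monoisotopic mass implied by an observed m/z under a rule."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if isinstance(rule, str):
        try:
            rule = ADDUCT_RULES[rule]
        except KeyError:
            raise ValueError(
                f"unknown adduct rule {rule!r}; known: {sorted(ADDUCT_RULES)}"
            ) from None
    return mz + rule.offset


def observed_mz(neutral: float, rule: str | AdductRule) -> float:
    """Inverse of :func:`neutral_mass` (adduct re-application)."""
    if isinstance(rule, str):
        rule = ADDUCT_RULES[rule]
    return neutral - rule.offset


@dataclass
class AnnotationHit:
    feature_id: str
    candidate: str
    candidate_class: str
    adduct: str
    neutral_mass: float
    error_ppm: float
    error_mda: float
    level: str = "3"

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "candidate": self.candidate,
            "candidate_class": self.candidate_class,
            "adduct": self.adduct,
            "neutral_mass": round(self.neutral_mass, 6),
            "error_ppm": round(self.error_ppm, 3),
            "error_mda": round(self.error_mda, 3),
            "level": self.level,
        }


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    """Split a ``time@mass`` id into (retention time min, m/z Da)."""
    try:
        rt, mz = feature_id.split("@")
        return float(rt), float(mz)
    except ValueError:
        raise ValueError(
            f"feature id {feature_id!r} is not of the form 'time@mass'"
        ) from None


def match_features(
    features,
    db: pd.DataFrame,
    tol_ppm: float = 20.0,
    polarity: str | None = None,
) -> tuple[list[AnnotationHit], list[str]]:
    """Match features against a metabolite mass table under all adducts.

    Parameters
    ----------
    features : iterable of (feature_id, mz, polarity) triples, or a
        DataFrame with those columns; ``polarity`` overrides per-feature
        polarity if given.
    db : DataFrame with columns name, class, monoisotopic_mass_da.
    tol_ppm : ppm tolerance on the neutral mass.

    Returns the hits (sorted by |ppm error| within each feature) and the
    ids of features with no hit.
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be nonnegative")
    if isinstance(features, pd.DataFrame):
        triples = [
            (r["feature_id"], float(r["mz"]), polarity or r.get("polarity"))
            for _, r in features.iterrows()
        ]
    else:
        triples = [
            (fid, float(mz), polarity or pol) for fid, mz, pol in features
        ]

    candidates = []
    for _, row in db.iterrows():
        try:
            mass = float(row["monoisotopic_mass_da"])
            name = str(row["name"])
            klass = str(row.get("class", ""))
            if not np.isfinite(mass) or mass <= 0:
                raise ValueError
        except (ValueError, KeyError, TypeError):
            warnings.warn(f"skipping malformed metabolite db row: {dict(row)}")
            log.warning("malformed db row skipped: %s", dict(row))
            continue
        candidates.append((name, klass, mass))

    hits: list[AnnotationHit] = []
    unannotated: list[str] = []
    for fid, mz, pol in triples:
        if pol not in ("negative", "positive"):
            raise ValueError(f"feature {fid!r} has unknown polarity {pol!r}")
        feature_hits = []
        for rule in ADDUCT_RULES.values():
            if rule.polarity != pol:
                continue
            m = neutral_mass(mz, rule)
            for name, klass, mass in candidates:
                err_ppm = (m - mass) / mass * 1e6
                if abs(err_ppm) <= tol_ppm:
                    feature_hits.append(
                        AnnotationHit(
                            feature_id=fid,
                            candidate=name,
                            candidate_class=klass,
                            adduct=rule.name,
                            neutral_mass=m,
                            error_ppm=err_ppm,
                            error_mda=(m - mass) * 1e3,
                        )
                    )
        feature_hits.sort(key=lambda h: abs(h.error_ppm))
        if feature_hits:
            hits.extend(feature_hits)
        else:
            unannotated.append(fid)
    return hits, unannotated


def load_marker_db() -> pd.DataFrame:
    """Bundled local metabolite table of six EBC asthma marker candidates.

    Synthetic stand-in for a metabolite database extract: the neutral
    monoisotopic masses are back-calculated from reported feature m/z
    values under their adduct rules, not taken from HMDB/METLIN records.
    """
    with resources.files("breathomics").joinpath(
        "data/ebc_asthma_markers_synthetic.csv"
    ).open() as fh:
        return pd.read_csv(fh)
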