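"""Per-feature nonparametric screening with Benjamini–Hochberg FDR control.

Unpaired contrasts use the two-sided Mann–Whitney U test; paired
contrasts (one sample per subject at each of two timepoints) use the
Wilcoxon signed-rank test on within-subject differences.  P-values are
exact for small, tie-free samples and tie-corrected normal
approximations otherwise.  Features are declared significant when their
BH-adjusted q-value is at or below the FDR level delta (default 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnivariateResult",
    "mann_whitney_screen",
    "wilcoxon_paired_screen",
    "bh_fdr",
]

# exact null enumeration is cheap and tie-free below this combined n
_EXACT_N_MAX = 20


@dataclass
class UnivariateResult:
    table: pd.DataFrame  # index: feature id; columns: statistic, p, q, significant
    test: str            # mann-whitney | wilcoxon-paired
    delta: float

    @property
    def significant_features(self) -> set:
        return set(self.table.index[self.table["significant"]])

    def to_csv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "feature_id"})
        out.to_csv(path, index=False)


def bh_fdr(pvalues, delta: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: q-values and the reject set.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; a feature is
    rejected when q <= delta.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= delta


def _exact_ok(values: np.ndarray) -> bool:
    return np.unique(values).size == values.size


def mann_whitney_screen(
    table: pd.DataFrame,
    groups: pd.Series | dict,
    delta: float = 0.10,
    method: str = "auto",
) -> UnivariateResult:
    """Two-sided Mann–Whitney U per feature, BH-corrected at ``delta``.

    ``groups`` maps sample id to one of exactly two labels.  With
    ``method="auto"`` the exact null distribution is used when the
    combined sample size is at most 20 and the feature has no ties;
    otherwise the tie-corrected normal approximation (with continuity
    correction) applies — the regime of the n=26 vs 16 study design.
    """
    groups = pd.Series(groups)
    groups = groups.loc[[s for s in table.index if s in groups.index]]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    ids_a = groups.index[groups == levels[0]]
    ids_b = groups.index[groups == levels[1]]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {len(ids_a)} {levels[0]!r}, "
            f"{len(ids_b)} {levels[1]!r})"
        )
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")

    stats_, ps = [], []
    a_all = table.loc[ids_a].to_numpy(dtype=float)
    b_all = table.loc[ids_b].to_numpy(dtype=float)
    n = a_all.shape[0] + b_all.shape[0]
    for j in range(table.shape[1]):
        a, b = a_all[:, j], b_all[:, j]
        if method == "auto":
            use = (
                "exact"
                if n <= _EXACT_N_MAX and _exact_ok(np.concatenate([a, b]))
                else "asymptotic"
            )
        else:
            use = method
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=use)
        stats_.append(res.statistic)
        ps.append(min(1.0, res.pvalue))
    q, rej = bh_fdr(ps, delta=delta)
    out = pd.DataFrame(
        {"statistic": stats_, "p": ps, "q": q, "significant": rej},
        index=table.columns,
    )
    return UnivariateResult(table=out, test="mann-whitney", delta=delta)


def wilcoxon_paired_screen(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    delta: float = 0.10,
    method: str = "auto",
) -> UnivariateResult:
    """Wilcoxon signed-rank on T1-T0 differences per feature, BH at ``delta``.

    ``meta`` must pair every subject's T0 sample with its T1 sample.
    Zero differences are dropped (Wilcoxon's convention); a feature whose
    differences are all zero gets p = 1.
    """
    pairs = _pair_map(table, meta)
    if len(pairs) < 5:
        import warnings

        warnings.warn(
            f"only {len(pairs)} pairs: the exact signed-rank p-value cannot fall "
            "below 2^-(n-1), so FDR-significant calls are unlikely"
        )
    t0 = table.loc[[p[0] for p in pairs.values()]].to_numpy(dtype=float)
    t1 = table.loc[[p[1] for p in pairs.values()]].to_numpy(dtype=float)
    diffs = t1 - t0

    stats_, ps = [], []
    for j in range(diffs.shape[1]):
        d = diffs[:, j]
        nz = d[d != 0]
        if nz.size == 0:
            stats_.append(0.0)
            ps.append(1.0)
            continue
        if method == "auto":
            use = (
                "exact"
                if nz.size <= _EXACT_N_MAX and _exact_ok(np.abs(nz))
                else "approx"
            )
        else:
            use = {"exact": "exact", "asymptotic": "approx"}[method]
        # zeros already dropped (Wilcoxon's convention), so the exact path
        # never sees them
        res = stats.wilcoxon(nz, alternative="two-sided", method=use)
        stats_.append(res.statistic)
        ps.append(min(1.0, res.pvalue))
    q, rej = bh_fdr(ps, delta=delta)
    out = pd.DataFrame(
        {"statistic": stats_, "p": ps, "q": q, "significant": rej},
        index=table.columns,
    )
    return UnivariateResult(table=out, test="wilcoxon-paired", delta=delta)


def _pair_map(table: pd.DataFrame, meta: pd.DataFrame) -> dict:
    """subject -> (T0 sample id, T1 sample id), validated against the table."""
    m = meta[meta["sample_id"].isin(table.index)]
    pairs: dict = {}
    for subj, grp in m.groupby("subject_id"):
        tps = dict(zip(grp["timepoint"], grp["sample_id"]))
        if "T0" not in tps and "T1" not in tps:
            continue  # e.g. controls, not part of the paired contrast
        if "T0" not in tps or "T1" not in tps:
            raise ValueError(f"subject {subj!r} lacks a matched T0/T1 pair")
        if (grp["timepoint"].isin(["T0", "T1"])).sum() != 2:
            raise ValueError(f"subject {subj!r} has duplicated timepoint samples")
        pairs[subj] = (tps["T0"], tps["T1"])
    if not pairs:
        raise ValueError("no T0/T1 pairs found in metadata")
    return pairs
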