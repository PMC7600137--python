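"""PCA outlier screening and PLS-DA machinery for two-group metabolomics.

This module implements the multivariate engine of the analysis:

* :func:`pca_outlier_screen` — per-group PCA with Hotelling T² and Q
  (squared prediction error) control limits at level alpha.
* :func:`fit_plsda` — NIPALS partial least squares with a {-1, +1}
  coded class response (PLS1-DA); prediction is the sign of the fitted
  response.
* :func:`vip` — variable influence on projection, the per-feature
  importance whose squared values average 1.
* :func:`post_transform` — rotation of the fitted score space into one
  predictive direction (maximal covariance with the coded response) and
  A-1 response-orthogonal directions, leaving fitted values untouched.
* :func:`cross_validate_mcc` / :func:`permutation_test` — stratified
  K-fold Matthews-correlation estimate and its label-permutation null.
* :func:`stability_selection` — bootstrap ensemble of PLS-DA fits; a
  feature is relevant when its VIP>1 selection frequency exceeds the
  (1-alpha) quantile of frequencies obtained under class permutation;
  out-of-bag majority votes give MCCoob.
* :func:`multilevel_transform` — signed within-subject differences for
  paired (multilevel) PLS-DA.

Everything operates on plain numpy arrays / pandas objects; centering is
always re-estimated on the training portion of a split so resampled
performance estimates do not leak information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCAModel",
    "PLSDAModel",
    "PostTransformedModel",
    "StabilityModel",
    "pca_outlier_screen",
    "fit_plsda",
    "vip",
    "post_transform",
    "mcc",
    "mcc_from_labels",
    "cross_validate_mcc",
    "permutation_test",
    "stability_selection",
    "multilevel_transform",
    "structured_noise_diagnostic",
]


# ---------------------------------------------------------------------------
# PCA outlier screening
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: np.ndarray          # p x A, orthonormal columns
    scores: np.ndarray            # n x A
    explained_variance: np.ndarray
    residual_variance: np.ndarray  # eigenvalues beyond A
    n_components: int
    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    alpha: float
    sample_ids: list


def _t2_limit(n: int, A: int, alpha: float) -> float:
    if n <= A:
        return np.inf
    f = stats.f.ppf(1.0 - alpha, A, n - A)
    return A * (n - 1) * (n + 1) / (n * (n - A)) * f


def _q_limit_jackson_mudholkar(resid_eig: np.ndarray, alpha: float) -> float:
    lam = resid_eig[resid_eig > 1e-12]
    if lam.size == 0:
        return np.inf
    th1, th2, th3 = (np.sum(lam**k) for k in (1, 2, 3))
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 < 1e-3:
        h0 = 1e-3
    z = stats.norm.ppf(1.0 - alpha)
    inner = (
        z * np.sqrt(2.0 * th2 * h0**2) / th1
        + 1.0
        + th2 * h0 * (h0 - 1.0) / th1**2
    )
    if inner <= 0:
        return 0.0
    return th1 * inner ** (1.0 / h0)


def pca_outlier_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_components: int | None = None,
    variance_explained: float = 0.80,
) -> tuple[PCAModel, list]:
    """PCA of one group of samples with T² and Q outlier limits.

    The component count is the smallest number of principal components
    explaining ``variance_explained`` of the variance (capped so a
    residual subspace remains), unless fixed via ``n_components``.  A
    sample is flagged when its Hotelling T² exceeds the F-distribution
    control limit or its squared residual Q exceeds the
    Jackson–Mudholkar limit, both at level ``alpha``.
    """
    x = np.asarray(table, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples per modeled group")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0

    if n_components is not None:
        if n_components < 1 or n_components > rank:
            raise ValueError(f"n_components must be in [1, rank={rank}]")
        A = int(n_components)
    else:
        frac = np.cumsum(eig) / eig.sum()
        A = int(np.searchsorted(frac, variance_explained) + 1)
        A = max(1, min(A, rank - 1 if rank > 1 else 1, n - 2 if n > 2 else 1, 10))

    scores = u[:, :A] * s[:A]
    loadings = vt[:A].T
    t2 = np.sum(scores**2 / eig[:A][None, :], axis=1)
    resid = xc - scores @ loadings.T
    q = np.sum(resid**2, axis=1)

    if alpha >= 1.0:
        t2_lim, q_lim = 0.0, 0.0
        flagged_mask = np.ones(n, dtype=bool)
    elif alpha <= 0.0:
        t2_lim, q_lim = np.inf, np.inf
        flagged_mask = np.zeros(n, dtype=bool)
    else:
        t2_lim = _t2_limit(n, A, alpha)
        q_lim = _q_limit_jackson_mudholkar(eig[A:], alpha)
        flagged_mask = (t2 > t2_lim) | (q > q_lim)

    ids = list(table.index)
    model = PCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance=eig[:A],
        residual_variance=eig[A:],
        n_components=A,
        t2=t2,
        q=q,
        t2_limit=t2_lim,
        q_limit=q_lim,
        alpha=alpha,
        sample_ids=ids,
    )
    return model, [ids[i] for i in np.flatnonzero(flagged_mask)]


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    """NIPALS PLS1 fit with {-1, +1} coded response.

    ``levels`` maps the two class labels to the coding: levels[0] -> -1,
    levels[1] -> +1.  ``weights`` columns are unit norm; ``scores``
    columns are mutually orthogonal.  Prediction threshold is 0 on the
    fitted response.
    """

    levels: tuple
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # p x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray     # n x A
    coef: np.ndarray       # p
    feature_ids: list
    y_coded: np.ndarray    # n, in {-1, +1}

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def decision_function(self, x) -> np.ndarray:
        xc = np.asarray(x, dtype=float) - self.x_mean
        return xc @ self.coef + self.y_mean

    def predict_coded(self, x) -> np.ndarray:
        f = self.decision_function(x)
        return np.where(f >= 0, 1, -1)

    def predict(self, x) -> np.ndarray:
        coded = self.predict_coded(x)
        return np.asarray([self.levels[1] if c > 0 else self.levels[0] for c in coded])

    def fitted(self) -> np.ndarray:
        return self.scores @ self.y_loadings + self.y_mean


def _encode(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    levels = tuple(sorted(pd.unique(labels), key=str))
    if len(levels) != 2:
        raise ValueError(f"exactly two classes required, got {levels}")
    y = np.where(labels == levels[1], 1.0, -1.0)
    return y, levels


def fit_plsda(table, labels, A: int = 2) -> PLSDAModel:
    """Fit PLS-DA by sequential NIPALS extraction on centered data.

    Components whose weight vector vanishes (no covariance left to
    model) end the extraction early.
    """
    x = np.asarray(table, dtype=float)
    y, levels = _encode(labels)
    n, p = x.shape
    if y.size != n:
        raise ValueError("labels length does not match sample count")
    if min((y < 0).sum(), (y > 0).sum()) < 2:
        raise ValueError("each class needs at least 2 samples")
    if A < 1 or A > min(n - 1, p):
        raise ValueError(f"A must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if not np.any(x.std(axis=0) > 0):
        raise ValueError("X has zero variance")

    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xd = x - x_mean
    yd = y - y_mean
    scale = np.abs(xd).max()
    if scale == 0:
        raise ValueError("X has zero variance")

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros(A)
    T = np.zeros((n, A))
    a_used = 0
    for a in range(A):
        w = xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale * np.abs(yd).sum() + 1e-300:
            break
        w /= nw
        t = xd @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        pl = xd.T @ t / tt
        ql = float(yd @ t / tt)
        W[:, a], P[:, a], Q[a], T[:, a] = w, pl, ql, t
        xd = xd - np.outer(t, pl)
        yd = yd - ql * t
        a_used += 1
    if a_used == 0:
        raise ValueError("no predictive component could be extracted (constant response?)")
    W, P, Q, T = W[:, :a_used], P[:, :a_used], Q[:a_used], T[:, :a_used]
    coef = W @ np.linalg.solve(P.T @ W, Q)
    feats = list(table.columns) if isinstance(table, pd.DataFrame) else list(range(p))
    return PLSDAModel(
        levels=levels,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coef=coef,
        feature_ids=feats,
        y_coded=y.astype(int),
    )


def vip(model: PLSDAModel) -> pd.Series:
    """Variable influence on projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )
    with SSY_a the response sum of squares explained by component a;
    the mean of squared VIPs over features is 1 by construction.
    """
    W, Q, T = model.weights, model.y_loadings, model.scores
    p = W.shape[0]
    ssy = Q**2 * np.einsum("ia,ia->a", T, T)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    v = np.sqrt(p * (wn**2 @ ssy) / total)
    return pd.Series(v, index=model.feature_ids, name="VIP")


# ---------------------------------------------------------------------------
# Post-transformation
# ---------------------------------------------------------------------------


@dataclass
class PostTransformedModel:
    model: PLSDAModel
    rotation: np.ndarray            # A x A orthogonal
    predictive_scores: np.ndarray   # n
    orthogonal_scores: np.ndarray   # n x (A-1)
    predictive_loading: np.ndarray  # p
    orthogonal_loadings: np.ndarray  # p x (A-1)

    def fitted(self) -> np.ndarray:
        # fitted response is invariant under rotation of the score space
        T = np.column_stack([self.predictive_scores, self.orthogonal_scores])
        yc = self.model.y_coded - self.model.y_mean
        coefs, *_ = np.linalg.lstsq(T, yc, rcond=None)
        return T @ coefs + self.model.y_mean


def post_transform(model: PLSDAModel) -> PostTransformedModel:
    """Rotate the score space into predictive + response-orthogonal parts.

    The predictive direction maximizes covariance with the coded
    response among all rotations of the fitted score space; remaining
    directions have zero covariance with it.  Fitted responses and class
    predictions are unchanged (the rotation is orthogonal).
    """
    A = model.n_components
    T = model.scores
    yc = model.y_coded - model.y_mean
    if A == 1:
        warnings.warn("post-transformation of a 1-component model is the identity")
        return PostTransformedModel(
            model=model,
            rotation=np.eye(1),
            predictive_scores=T[:, 0].copy(),
            orthogonal_scores=np.empty((T.shape[0], 0)),
            predictive_loading=model.x_loadings[:, 0].copy(),
            orthogonal_loadings=np.empty((model.x_loadings.shape[0], 0)),
        )
    c = T.T @ yc
    nc = np.linalg.norm(c)
    if nc <= 0:
        raise ValueError("scores carry no covariance with the response")
    # orthonormal basis whose first vector is c/||c||
    basis, _ = np.linalg.qr(np.column_stack([c / nc, np.eye(A)[:, : A - 1]]))
    # qr may flip signs; align first basis vector with c
    if basis[:, 0] @ c < 0:
        basis[:, 0] *= -1
    R = basis
    T_rot = T @ R
    P_rot = model.x_loadings @ R
    return PostTransformedModel(
        model=model,
        rotation=R,
        predictive_scores=T_rot[:, 0],
        orthogonal_scores=T_rot[:, 1:],
        predictive_loading=P_rot[:, 0],
        orthogonal_loadings=P_rot[:, 1:],
    )


def structured_noise_diagnostic(
    table, labels, A: int = 2, n_perm: int = 50, seed: int | None = 0
) -> dict:
    """Advisory check for structured (systematic) orthogonal variation.

    Measures the share of total X variance captured by the
    response-orthogonal directions of the post-transformed model and
    compares it against a null in which each feature column is
    independently permuted (destroying between-feature correlation but
    preserving marginals).  A large observed share relative to that
    isotropized null indicates a systematic orthogonal factor —
    structured noise — in which case VIP ranking should be interpreted
    with care.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(table, dtype=float)
    y = np.asarray(labels)

    def ortho_xvar_share(xmat) -> float:
        m = fit_plsda(xmat, y, A=A)
        if m.n_components < 2:
            return 0.0
        pt = post_transform(m)
        # SSX of a rotated component k is ||t_k||^2 * ||p_k||^2
        ssx_orth = sum(
            (pt.orthogonal_scores[:, k] ** 2).sum()
            * (pt.orthogonal_loadings[:, k] ** 2).sum()
            for k in range(pt.orthogonal_scores.shape[1])
        )
        xc = xmat - xmat.mean(axis=0)
        return float(ssx_orth / (xc**2).sum())

    observed = ortho_xvar_share(x)
    null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = np.column_stack(
            [rng.permutation(x[:, j]) for j in range(x.shape[1])]
        )
        null[b] = ortho_xvar_share(shuffled)
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return {
        "orthogonal_variance_share": observed,
        "null_median": float(np.median(null)),
        "p_value": float(p),
        "structured_noise_suspected": bool(p <= 0.05),
    }


# ---------------------------------------------------------------------------
# MCC, cross-validation, permutation test
# ---------------------------------------------------------------------------


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation from 2x2 counts; 0 when a marginal is empty."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + tn + fp + fn == 0:
        raise ValueError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def mcc_from_labels(true, predicted, positive) -> float:
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    tp = int(np.sum((true == positive) & (predicted == positive)))
    tn = int(np.sum((true != positive) & (predicted != positive)))
    fp = int(np.sum((true != positive) & (predicted == positive)))
    fn = int(np.sum((true == positive) & (predicted != positive)))
    return mcc(tp, tn, fp, fn)


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per sample, balanced within each class."""
    assign = np.empty(y.size, dtype=int)
    for level in np.unique(y):
        idx = np.flatnonzero(y == level)
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def cross_validate_mcc(
    table,
    labels,
    A: int = 2,
    folds: int = 5,
    seed: int | None = 0,
    groups=None,
) -> float:
    """Stratified K-fold MCC of PLS-DA with in-fold centering.

    Held-out predictions from all folds are pooled into one confusion
    matrix; its MCC is returned.  With ``groups`` (paired multilevel
    rows), whole subjects are assigned to folds so a difference row and
    its mirror never straddle a train/test split.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x = np.asarray(table, dtype=float)
    y, levels = _encode(labels)
    rng = np.random.default_rng(seed)
    if groups is not None:
        g = np.asarray(groups)
        uniq = np.unique(g)
        order = rng.permutation(uniq.size)
        gfold = dict(zip(uniq[order], np.arange(uniq.size) % folds))
        assign = np.array([gfold[v] for v in g])
    else:
        if min((y < 0).sum(), (y > 0).sum()) < folds:
            warnings.warn(
                "a class has fewer members than folds; some folds lack that "
                "class in training or test"
            )
        assign = _stratified_folds(y, folds, rng)
    pred = np.zeros_like(y)
    for k in range(folds):
        test = assign == k
        if not test.any():
            continue
        a_eff = min(A, int((~test).sum()) - 1, x.shape[1])
        model = fit_plsda(x[~test], y[~test], A=a_eff)
        pred[test] = model.predict_coded(x[test])
    return mcc_from_labels(y, pred, positive=1)


def permutation_test(
    table,
    labels,
    A: int = 2,
    n_perm: int = 1000,
    folds: int = 5,
    seed: int | None = 0,
    observed: float | None = None,
    groups=None,
) -> dict:
    """Label-permutation null of the cross-validated MCC.

    p = (1 + #{null >= observed}) / (1 + n_perm).  With ``groups`` the
    permutation flips whole signed pairs (the paired exchangeable null).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels_arr = np.asarray(labels)
    y, levels = _encode(labels_arr)
    groups_arr = None if groups is None else np.asarray(groups)
    if observed is None:
        observed = cross_validate_mcc(
            table, labels_arr, A=A, folds=folds,
            seed=int(rng.integers(2**31)), groups=groups_arr,
        )
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_null = _null_labels(y, groups_arr, rng)
        null[b] = cross_validate_mcc(
            table,
            y_null,
            A=A,
            folds=folds,
            seed=int(rng.integers(2**31)),
            groups=groups_arr,
        )
    p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return {"p_value": p, "observed_mcc_cv": float(observed), "null_mcc_cv": null}


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------


@dataclass
class StabilityModel:
    B: int
    selection_frequency: pd.Series
    relevant_features: set
    frequency_threshold: float
    oob_votes: pd.DataFrame     # index sample id: n_oob, vote_fraction, predicted
    mcc_oob: float
    vip_cut: float
    alpha: float
    seed: int | None
    mcc_cv: float | None = None
    permutation_p: float | None = None
    null_frequencies: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "vip_cut": self.vip_cut,
            "alpha": self.alpha,
            "seed": self.seed,
            "frequency_threshold": float(self.frequency_threshold),
            "selection_frequency": {
                k: float(v) for k, v in self.selection_frequency.items()
            },
            "relevant_features": sorted(self.relevant_features),
            "mcc_oob": float(self.mcc_oob),
            "mcc_cv": None if self.mcc_cv is None else float(self.mcc_cv),
            "permutation_p": (
                None if self.permutation_p is None else float(self.permutation_p)
            ),
        }


def _bootstrap_indices(
    y: np.ndarray,
    groups: np.ndarray | None,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """In-bag row indices (with repeats) and out-of-bag row indices.

    Ungrouped data: stratified bootstrap within each class.  Grouped
    (paired) data: subjects are resampled whole, so a difference row and
    its mirrored twin are never split across in-bag and out-of-bag.
    """
    n = y.size
    if groups is None:
        for _ in range(max_retries):
            parts = []
            for level in np.unique(y):
                idx = np.flatnonzero(y == level)
                parts.append(rng.choice(idx, size=idx.size, replace=True))
            inbag = np.concatenate(parts)
            oob = np.setdiff1d(np.arange(n), inbag)
            if np.unique(y[inbag]).size == 2 and oob.size > 0:
                return inbag, oob
        raise RuntimeError("could not draw a bootstrap subsample containing both classes")
    uniq = np.unique(groups)
    for _ in range(max_retries):
        drawn = rng.choice(uniq, size=uniq.size, replace=True)
        inbag = np.concatenate([np.flatnonzero(groups == g) for g in drawn])
        oob_groups = np.setdiff1d(uniq, drawn)
        oob = np.concatenate(
            [np.flatnonzero(groups == g) for g in oob_groups]
        ) if oob_groups.size else np.array([], dtype=int)
        if np.unique(y[inbag]).size == 2 and oob.size > 0:
            return inbag, oob
    raise RuntimeError("could not draw a bootstrap subsample with out-of-bag subjects")


def _null_labels(
    y: np.ndarray, groups: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    if groups is None:
        return rng.permutation(y)
    # paired data: the exchangeable null flips each subject's signed pair
    out = y.copy()
    for g in np.unique(groups):
        if rng.random() < 0.5:
            out[groups == g] = -out[groups == g]
    return out


def _selection_run(
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None,
    A: int,
    B: int,
    vip_cut: float,
    rng: np.random.Generator,
    collect_oob: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One stability-selection pass: frequencies + OOB vote tallies."""
    n, p = x.shape
    sel_counts = np.zeros(p)
    vote_pos = np.zeros(n)
    vote_n = np.zeros(n)
    score_sum = np.zeros(n)
    for _ in range(B):
        inbag, oob = _bootstrap_indices(y, groups, rng)
        a_eff = min(A, inbag.size - 1, p)
        model = fit_plsda(x[inbag], y[inbag], A=a_eff)
        sel_counts += (vip(model).to_numpy() > vip_cut)
        if collect_oob and oob.size:
            f = model.decision_function(x[oob])
            vote_pos[oob] += f >= 0
            vote_n[oob] += 1
            score_sum[oob] += f
    return sel_counts / B, vote_pos, vote_n, score_sum


def stability_selection(
    table,
    labels,
    A: int = 2,
    B: int = 200,
    alpha: float = 0.05,
    vip_cut: float = 1.0,
    n_null: int = 20,
    b_null: int | None = None,
    groups=None,
    seed: int | None = 0,
) -> StabilityModel:
    """Bootstrap stability selection of PLS-DA features with OOB MCC.

    For each of ``B`` stratified bootstrap subsamples a PLS-DA model is
    fitted in-bag and features with VIP above ``vip_cut`` are marked
    selected; the per-feature selection frequency is compared against
    the (1-alpha) quantile of frequencies from ``n_null`` re-runs on
    class-permuted labels (``b_null`` subsamples each, default ``B``).
    Out-of-bag samples are classified by majority vote across
    subsamples; MCCoob is the Matthews correlation of those votes.

    ``groups`` (one id per row) switches to whole-subject resampling for
    paired multilevel data.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    x = np.asarray(table, dtype=float)
    y, levels = _encode(labels)
    groups_arr = None if groups is None else np.asarray(groups)
    feats = list(table.columns) if isinstance(table, pd.DataFrame) else list(range(x.shape[1]))
    rng = np.random.default_rng(seed)

    freq, vote_pos, vote_n, score_sum = _selection_run(
        x, y, groups_arr, A, B, vip_cut, rng, collect_oob=True
    )

    b_null = B if b_null is None else b_null
    null_freqs = []
    for _ in range(max(1, n_null)):
        y_null = _null_labels(y, groups_arr, rng)
        f_null, _, _, _ = _selection_run(
            x, y_null, groups_arr, A, b_null, vip_cut, rng, collect_oob=False
        )
        null_freqs.append(f_null)
    null_pool = np.concatenate(null_freqs)
    threshold = float(np.quantile(null_pool, 1.0 - alpha))
    relevant = {f for f, fr in zip(feats, freq) if fr > threshold}

    # majority vote; exact ties go to the class with larger mean fitted response
    seen = vote_n > 0
    vote_frac = np.divide(vote_pos, vote_n, out=np.full_like(vote_pos, np.nan), where=seen)
    pred = np.where(vote_frac > 0.5, 1, -1)
    tie = seen & (vote_frac == 0.5)
    pred[tie] = np.where(score_sum[tie] >= 0, 1, -1)
    mcc_oob = mcc_from_labels(y[seen], pred[seen], positive=1)

    ids = list(table.index) if isinstance(table, pd.DataFrame) else list(range(x.shape[0]))
    votes = pd.DataFrame(
        {
            "n_oob": vote_n.astype(int),
            "vote_fraction": vote_frac,
            "predicted": np.where(
                seen, np.where(pred > 0, str(levels[1]), str(levels[0])), None
            ),
        },
        index=ids,
    )
    return StabilityModel(
        B=B,
        selection_frequency=pd.Series(freq, index=feats, name="selection_frequency"),
        relevant_features=relevant,
        frequency_threshold=threshold,
        oob_votes=votes,
        mcc_oob=mcc_oob,
        vip_cut=vip_cut,
        alpha=alpha,
        seed=seed,
        null_frequencies=null_pool,
    )


# ---------------------------------------------------------------------------
# Multilevel (paired) transform
# ---------------------------------------------------------------------------


def multilevel_transform(
    table: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Signed within-subject differences for multilevel PLS-DA.

    Each paired subject contributes two rows: T1-T0 labeled "+" and
    T0-T1 labeled "-"; classifying the sign of the difference profile
    isolates the within-subject (treatment) effect.  Returns the
    difference table, the labels, and the subject id of each row (for
    subject-level resampling downstream).
    """
    from .univariate import _pair_map

    pairs = _pair_map(table, meta)
    rows, labels, groups, ids = [], [], [], []
    for subj, (s0, s1) in pairs.items():
        d = table.loc[s1].to_numpy(dtype=float) - table.loc[s0].to_numpy(dtype=float)
        rows.extend([d, -d])
        labels.extend(["+", "-"])
        groups.extend([subj, subj])
        ids.extend([f"{subj}_plus", f"{subj}_minus"])
    out = pd.DataFrame(rows, index=ids, columns=table.columns)
    return out, pd.Series(labels, index=ids), pd.Series(groups, index=ids)
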