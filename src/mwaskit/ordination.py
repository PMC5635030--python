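"""Ecological distances and ordination: Bray–Curtis / Jensen–Shannon,
PERMANOVA, PCA, and distance-based redundancy analysis (dbRDA / CAP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

__all__ = [
    "distance_matrix",
    "permanova",
    "PermanovaResult",
    "pca_ordination",
    "PcaResult",
    "dbrda",
    "DbrdaResult",
]


@dataclass
class PermanovaResult:
    factor_id: str
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray

    def top_loading_features(self, component: str, k: int = 5) -> list[str]:
        """Features with the largest absolute weight on one component."""
        w = self.loadings[component].abs().sort_values(ascending=False)
        return w.index[:k].to_list()


@dataclass
class DbrdaResult:
    sample_scores: pd.DataFrame  # samples x constrained axes (CAP1, CAP2, ...)
    centroids: pd.DataFrame  # group level x constrained axes
    constrained_inertia: float
    total_inertia: float
    discarded_negative_inertia: float
    feature_weights: pd.DataFrame | None = None  # post-hoc correlations


def distance_matrix(
    m: pd.DataFrame,
    metric: str = "bray_curtis",
    pseudocount: float = 1e-9,
    sqrt_jsd: bool = False,
) -> pd.DataFrame:
    """Pairwise sample-by-sample dissimilarity of abundance profiles.

    ``bray_curtis`` works on the profiles as given (no internal
    renormalization).  ``jensen_shannon`` adds ``pseudocount``, renormalizes
    each sample to a probability vector, and returns the Jensen–Shannon
    divergence in nats (the square-root metric form with ``sqrt_jsd=True``).
    """
    vals = m.to_numpy(dtype=float).T  # samples x features
    if (vals < 0).any():
        raise ValueError("abundance matrix has negative entries")
    totals = vals.sum(axis=1)
    if (totals == 0).any():
        bad = list(m.columns[np.flatnonzero(totals == 0)])
        raise ValueError(f"sample(s) with zero total abundance: {bad}")
    if metric == "bray_curtis":
        d = pdist(vals, metric="braycurtis")
    elif metric == "jensen_shannon":
        p = vals + pseudocount
        p /= p.sum(axis=1, keepdims=True)
        d = pdist(p, metric="jensenshannon")  # sqrt of JS divergence, base e
        if not sqrt_jsd:
            d = d**2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    dm = squareform(d)
    return pd.DataFrame(dm, index=m.columns, columns=m.columns)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for lev in levels:
        mask = labels == lev
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss_total, ss_within


def permanova(
    d: pd.DataFrame,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    factor_id: str = "factor",
) -> PermanovaResult:
    """One-way permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic compares among-group to within-group sums of
    squared distances; the p-value counts label permutations with an equal
    or larger F under the plus-one rule, so ``p >= 1/(n_perm+1)`` always.
    """
    dm = np.asarray(d, dtype=float)
    if dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    labels = np.asarray(labels)
    if labels.shape[0] != dm.shape[0]:
        raise ValueError("labels must align with the distance matrix")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("factor needs at least two levels")
    if (counts < 2).any():
        raise ValueError("every factor level needs at least 2 samples")

    n, g = dm.shape[0], len(levels)
    d2 = dm**2
    ss_total, ss_within = _permanova_ss(d2, labels, levels)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (g - 1)) / (ss_within / (n - g))

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, ssw = _permanova_ss(d2, perm, levels)
        ssa = ss_total - ssw
        f_perm = (ssa / (g - 1)) / (ssw / (n - g))
        if f_perm >= f_obs - 1e-12:
            count_ge += 1
    p = (1.0 + count_ge) / (1.0 + n_perm)
    return PermanovaResult(
        factor_id=factor_id,
        pseudo_F=float(f_obs),
        r_squared=float(ss_among / ss_total),
        p_value=float(p),
        n_permutations=n_perm,
    )


def pca_ordination(m: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Principal component analysis of samples over (centered) features.

    Components are ordered by explained variance; each component's sign is
    fixed so its largest-magnitude feature loading is positive, making the
    orientation reproducible.  Loadings expose which features carry the most
    weight on each axis (e.g., the dominant genera of a cohort).
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 features and 2 samples")
    x = m.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("matrix is constant: zero variance, PCA undefined")
    k = n_components or min(x.shape)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(k, s.size)
    var = s**2 / (x.shape[0] - 1)
    ratio = var / var.sum()
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    coords = pd.DataFrame(u[:, :k] * s[:k], index=m.columns, columns=comp_names)
    loadings = pd.DataFrame(vt[:k].T, index=m.index, columns=comp_names)
    return PcaResult(coordinates=coords, loadings=loadings,
                     explained_variance_ratio=ratio[:k])


def _pcoa(dm: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Principal coordinates of a distance matrix.

    Returns (coordinates, eigenvalues kept, total positive inertia,
    discarded negative inertia).  Negative eigenvalues (from non-Euclidean
    dissimilarities) are dropped and their magnitude reported.
    """
    n = dm.shape[0]
    a = -0.5 * dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg = float(-evals[evals < -tol].sum())
    keep = evals > tol
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    return coords, evals[keep], float(evals[keep].sum()), neg


def dbrda(
    d: pd.DataFrame,
    labels,
    features: pd.DataFrame | None = None,
    n_axes: int | None = None,
) -> DbrdaResult:
    """Distance-based redundancy analysis (CAP) on a grouping factor.

    Embeds the distance matrix by principal coordinates (negative eigenvalues
    dropped, their inertia reported), regresses the coordinates on the
    centered group indicator matrix, and extracts constrained axes from the
    fitted values by SVD.  With a feature-by-sample matrix supplied, each
    feature's weight on an axis is its Pearson correlation with the axis
    scores (post-hoc), which is how the driving taxa of a separation are
    conventionally read off.
    """
    sample_ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(len(labels)))
    dm = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("factor needs at least two levels")
    coords, evals, total_inertia, neg_inertia = _pcoa(dm)

    # centered one-hot design; rank g-1
    x = np.stack([(labels == lev).astype(float) for lev in levels], axis=1)
    x = x - x.mean(axis=0, keepdims=True)
    beta, *_ = np.linalg.lstsq(x, coords, rcond=None)
    fitted = x @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * max(s[0], 1.0)))
    k = min(rank, n_axes or rank)
    scores = u[:, :k] * s[:k]
    # orientation: first level's centroid negative on axis 1 -> flip for reproducibility
    for jax in range(k):
        lead = scores[labels == levels[0], jax].mean()
        if lead < 0:
            scores[:, jax] *= -1
    axis_names = [f"CAP{j + 1}" for j in range(k)]
    score_df = pd.DataFrame(scores, index=sample_ids, columns=axis_names)
    centroids = score_df.groupby(pd.Series(labels, index=score_df.index)).mean()

    weights = None
    if features is not None:
        rows = {}
        fv = features.to_numpy(dtype=float)
        for i, feat in enumerate(features.index):
            rows[feat] = [
                pearsonr(fv[i], scores[:, jax])[0] if np.std(fv[i]) > 0 else np.nan
                for jax in range(k)
            ]
        weights = pd.DataFrame.from_dict(rows, orient="index", columns=axis_names)

    constrained = float((s[:k] ** 2).sum())
    return DbrdaResult(
        sample_scores=score_df,
        centroids=centroids,
        constrained_inertia=constrained,
        total_inertia=total_inertia,
        discarded_negative_inertia=neg_inertia,
        feature_weights=weights,
    )
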