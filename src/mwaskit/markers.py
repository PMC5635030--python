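"""Marker discovery and evaluation.

The centre-piece is *RFCV*: repeated stratified k-fold cross-validation of a
random forest, where features are ranked by importance inside every training
fold, nested top-k panels are scored on the held-out fold, the error curves
are averaged, and the panel is chosen by the "minimum error plus one standard
deviation" rule — the smallest panel (capped at ``max_panel`` features) whose
mean error beats the cutoff.  The same machinery drives the disease
classifier, the TMA-lyase-only classifier, clinical-index association
pre-selection (regression forests), and the medication-stratified classifier
comparisons.  ROC summaries use the rank-statistic AUC with a DeLong
asymptotic confidence interval and Youden's index for the operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold, KFold

from .ordination import distance_matrix, permanova
from .stats import spearman_permutation, two_group_masks

__all__ = [
    "MarkerSelection",
    "ROCResult",
    "GroupLassoResult",
    "rfcv_select",
    "roc_analysis",
    "enzyme_classifier",
    "group_lasso",
    "clinical_association",
    "medication_analysis",
]


@dataclass
class MarkerSelection:
    ranked_features: list[str]
    error_curve: pd.Series  # mean CV error per panel size
    error_sd_at_min: float
    cutoff: float
    candidate_panels: list[int]
    chosen_panel: list[str]
    probabilities: pd.Series | None  # out-of-fold disease probability (binary)
    task: str = "classify"
    importances: pd.Series | None = None

    @property
    def chosen_size(self) -> int:
        return len(self.chosen_panel)


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    roc_points: pd.DataFrame  # columns: cutoff, fpr, tpr
    youden_cutoff: float
    youden_index: float


@dataclass
class GroupLassoResult:
    group_ids: list[str]
    coefficient_norms: pd.Series
    selected_groups: list[str]
    regularization_path: pd.DataFrame  # penalty x group -> norm
    bootstrap_selection_frequency: pd.Series
    penalty: float
    objective_history: list[float] = field(default_factory=list)


def _rank_features(importances: np.ndarray) -> np.ndarray:
    """Descending importance, stable tie-break by original feature order."""
    return np.lexsort((np.arange(importances.size), -importances))


def _downsample_balanced(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample (size of the smallest class)."""
    levels, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for lev in levels:
        idx = np.flatnonzero(y == lev)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


def rfcv_select(
    m: pd.DataFrame,
    labels,
    folds: int = 5,
    repeats: int = 5,
    max_panel: int = 25,
    balance: bool = False,
    seed: int = 0,
    n_trees: int = 500,
    task: str = "classify",
) -> MarkerSelection:
    """Cross-validated random-forest marker selection.

    ``m`` is feature-by-sample; ``labels`` a per-sample factor (two or more
    levels for classification) or numeric response (``task="regress"``).
    Within each training fold features are ranked by forest importance and
    the top-k panels (k = 1..``max_panel``) are scored on the held-out fold;
    curves are averaged over ``folds``×``repeats``.  The cutoff is the curve
    minimum plus the standard deviation of the per-fold errors at that point;
    the chosen panel is the smallest size whose mean error is below the
    cutoff, realized on the cross-fold aggregate importance ranking.

    For classification the error is the held-out misclassification rate and
    out-of-fold case probabilities are returned (binary problems).  With
    ``balance=True`` each training fold is downsampled to its smallest class
    before fitting, which is how unequal multi-disease cohorts are handled.
    """
    x_all = m.to_numpy(dtype=float).T  # samples x features
    feature_ids = m.index.to_list()
    n_samples, n_features = x_all.shape
    max_panel = min(max_panel, n_features)
    rng = np.random.default_rng(seed)

    if task == "classify":
        y_all = np.asarray(pd.Series(np.asarray(labels)).astype(str))
        classes, class_counts = np.unique(y_all, return_counts=True)
        if class_counts.min() < folds:
            raise ValueError(
                f"smallest class has {class_counts.min()} samples; "
                f"use fewer than {folds} folds"
            )
        binary = len(classes) == 2
        case_level = sorted(classes)[0]
    elif task == "regress":
        y_all = np.asarray(labels, dtype=float)
        if n_samples < folds:
            raise ValueError("fewer samples than folds")
        binary = False
        case_level = None
    else:
        raise ValueError("task must be 'classify' or 'regress'")

    sizes = np.arange(1, max_panel + 1)
    fold_errors: list[np.ndarray] = []  # one error-per-size vector per fold
    agg_importance = np.zeros(n_features)
    prob_sum = np.zeros(n_samples)
    prob_n = np.zeros(n_samples)

    def make_forest(rs: int):
        if task == "classify":
            return RandomForestClassifier(n_estimators=n_trees, random_state=rs, n_jobs=1)
        return RandomForestRegressor(
            n_estimators=n_trees, random_state=rs, max_features=1.0 / 3.0, n_jobs=1
        )

    for rep in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        if task == "classify":
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(x_all, y_all)
        else:
            splitter = KFold(n_splits=folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(x_all)
        for train, test in split_iter:
            if balance and task == "classify":
                train = train[_downsample_balanced(y_all[train], rng)]
            x_tr, y_tr = x_all[train], y_all[train]
            x_te, y_te = x_all[test], y_all[test]

            ranker = make_forest(int(rng.integers(0, 2**31 - 1)))
            ranker.fit(x_tr, y_tr)
            order = _rank_features(ranker.feature_importances_)
            agg_importance += ranker.feature_importances_

            errs = np.empty(sizes.size)
            for si, k in enumerate(sizes):
                cols = order[:k]
                sub = make_forest(int(rng.integers(0, 2**31 - 1)))
                sub.fit(x_tr[:, cols], y_tr)
                if task == "classify":
                    pred = sub.predict(x_te[:, cols])
                    errs[si] = float(np.mean(pred != y_te))
                else:
                    pred = sub.predict(x_te[:, cols])
                    errs[si] = float(np.mean((pred - y_te) ** 2))
            fold_errors.append(errs)

    err_mat = np.stack(fold_errors)  # (folds*repeats) x sizes
    mean_curve = err_mat.mean(axis=0)
    i_min = int(np.argmin(mean_curve))
    sd_at_min = float(err_mat[:, i_min].std(ddof=1))
    cutoff = float(mean_curve[i_min] + sd_at_min)
    candidates = [int(k) for k, e in zip(sizes, mean_curve) if e < cutoff]
    chosen_k = min(candidates) if candidates else int(sizes[i_min])

    ranked_idx = _rank_features(agg_importance)
    ranked_features = [feature_ids[i] for i in ranked_idx]
    chosen_panel = ranked_features[:chosen_k]

    probabilities = None
    if task == "classify" and binary:
        # out-of-fold probabilities: fully nested — each fold re-ranks
        # features on its own training data and keeps its own top chosen_k,
        # so neither the panel identity nor the fit sees the held-out samples
        rng2 = np.random.default_rng(seed + 1)
        for rep in range(repeats):
            rs = int(rng2.integers(0, 2**31 - 1))
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            for train, test in splitter.split(x_all, y_all):
                if balance:
                    train = train[_downsample_balanced(y_all[train], rng2)]
                ranker = make_forest(int(rng2.integers(0, 2**31 - 1)))
                ranker.fit(x_all[train], y_all[train])
                cols = _rank_features(ranker.feature_importances_)[:chosen_k]
                clf = make_forest(int(rng2.integers(0, 2**31 - 1)))
                clf.fit(x_all[np.ix_(train, cols)], y_all[train])
                ci = list(clf.classes_).index(case_level)
                p = clf.predict_proba(x_all[np.ix_(test, cols)])[:, ci]
                prob_sum[test] += p
                prob_n[test] += 1
        probabilities = pd.Series(prob_sum / np.maximum(prob_n, 1), index=m.columns,
                                  name=f"p_{case_level}")

    return MarkerSelection(
        ranked_features=ranked_features,
        error_curve=pd.Series(mean_curve, index=sizes, name="cv_error"),
        error_sd_at_min=sd_at_min,
        cutoff=cutoff,
        candidate_panels=candidates,
        chosen_panel=chosen_panel,
        probabilities=probabilities,
        task=task,
        importances=pd.Series(agg_importance / err_mat.shape[0], index=feature_ids),
    )


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong asymptotic variance of the rank-statistic AUC."""
    m, n = pos.size, neg.size
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


def roc_analysis(
    probabilities,
    labels,
    case_label: str | None = None,
    ci_method: str = "delong",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ROCResult:
    """ROC summary of per-sample scores against two-level labels.

    AUC is the concordant-pair fraction (ties credit 1/2); the 95 % CI comes
    from the DeLong variance of that rank statistic, or from a stratified
    percentile bootstrap with ``ci_method="bootstrap"``.  Youden's index is
    the maximum of sensitivity + specificity − 1 over cutoffs, with ties
    broken toward the lower cutoff (favouring sensitivity).
    """
    scores = np.asarray(probabilities, dtype=float)
    case, ctrl, _, _ = two_group_masks(labels, case_label)
    pos, neg = scores[case], scores[ctrl]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    auc = _auc_rank(pos, neg)
    if ci_method == "delong":
        se = np.sqrt(_delong_variance(pos, neg, auc))
        ci_low = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
        ci_high = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = [
            _auc_rank(pos[rng.integers(0, pos.size, pos.size)],
                      neg[rng.integers(0, neg.size, neg.size)])
            for _ in range(n_bootstrap)
        ]
        ci_low, ci_high = (float(q) for q in np.quantile(reps, [0.025, 0.975]))
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")

    # ROC curve over the observed score cutoffs (predict positive when
    # score >= cutoff), plus the degenerate endpoints
    cutoffs = np.unique(scores)[::-1]
    fpr = [(neg >= c).mean() for c in cutoffs]
    tpr = [(pos >= c).mean() for c in cutoffs]
    points = pd.DataFrame({"cutoff": cutoffs, "fpr": fpr, "tpr": tpr})
    j = points["tpr"] - points["fpr"]
    j_max = j.max()
    best = points.loc[np.isclose(j, j_max), "cutoff"].min()  # lowest cutoff on ties
    return ROCResult(
        auc=float(auc),
        ci_low=ci_low,
        ci_high=ci_high,
        roc_points=points,
        youden_cutoff=float(best),
        youden_index=float(j_max),
    )


def enzyme_classifier(
    enzyme_matrix: pd.DataFrame,
    labels,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    n_trees: int = 500,
    case_label: str | None = None,
) -> tuple[MarkerSelection, ROCResult]:
    """RFCV classifier on a small enzyme-family profile (e.g., the four
    TMA-lyase families CutC/CutD/YeaW/YeaX).

    Same selection machinery as :func:`rfcv_select`; with at most a handful
    of features the panel search is trivially bounded.  A matrix with no
    variation yields chance-level probabilities (AUC ≈ 0.5).
    """
    sel = rfcv_select(
        enzyme_matrix, labels, folds=folds, repeats=repeats,
        max_panel=len(enzyme_matrix.index), seed=seed, n_trees=n_trees,
    )
    roc = roc_analysis(sel.probabilities, labels, case_label)
    return sel, roc


# ---------------------------------------------------------------------------
# group LASSO (proximal gradient)


def _logistic_loss_grad(beta, b0, x, y):
    eta = x @ beta + b0
    # y in {0,1}
    p = 1.0 / (1.0 + np.exp(-eta))
    loss = np.mean(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta)
    resid = (p - y) / x.shape[0]
    return loss, x.T @ resid, resid.sum()


def _linear_loss_grad(beta, b0, x, y):
    r = x @ beta + b0 - y
    loss = 0.5 * np.mean(r**2)
    return loss, x.T @ r / x.shape[0], r.mean()


def _group_prox(beta, groups_idx, weights, thresh):
    for gi, idx in enumerate(groups_idx):
        norm = np.linalg.norm(beta[idx])
        if norm <= thresh * weights[gi]:
            beta[idx] = 0.0
        else:
            beta[idx] *= 1.0 - thresh * weights[gi] / norm
    return beta


def _fit_group_lasso_path(x, y, groups_idx, weights, lambdas, family, max_iter=2000, tol=1e-8):
    """ISTA with step 1/L; warm starts along the path.  Returns coefficient
    matrix per lambda and the objective history of the last fit."""
    n, p = x.shape
    spectral2 = np.linalg.norm(x, 2) ** 2
    lips = spectral2 / (4.0 * n) if family == "logistic" else spectral2 / n
    lips = max(lips, 1e-12)
    step = 1.0 / lips
    loss_grad = _logistic_loss_grad if family == "logistic" else _linear_loss_grad

    beta = np.zeros(p)
    b0 = 0.0
    coefs = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    history: list[float] = []
    for li, lam in enumerate(lambdas):
        history = []
        for _ in range(max_iter):
            loss, grad, grad0 = loss_grad(beta, b0, x, y)
            penalty = lam * sum(
                w * np.linalg.norm(beta[idx]) for w, idx in zip(weights, groups_idx)
            )
            history.append(loss + penalty)
            if len(history) > 1 and abs(history[-2] - history[-1]) < tol * max(1.0, abs(history[-2])):
                break
            beta = _group_prox(beta - step * grad, groups_idx, weights, lam * step)
            b0 -= step * grad0
        coefs[li] = beta
        intercepts[li] = b0
    return coefs, intercepts, history


def group_lasso(
    features: pd.DataFrame,
    y,
    group_map: dict[str, list[str]],
    penalty_path=None,
    bootstraps: int = 10,
    seed: int = 0,
    family: str = "logistic",
    cv_folds: int = 5,
) -> GroupLassoResult:
    """Group-penalized regression over feature groups (e.g., KO modules).

    Solves  min  loss(β) + λ Σ_g √p_g ‖β_g‖₂  by proximal gradient with
    warm-started penalty path (logistic loss for a binary response, squared
    loss otherwise).  λ is chosen by ``cv_folds``-fold cross-validated loss
    over the path, the model refit on all samples, and group selection
    stability estimated by refitting on ``bootstraps`` resamples of the
    samples.  Groups must partition the feature rows.
    """
    feats = features.index.to_list()
    claimed = [f for g in sorted(group_map) for f in group_map[g]]
    if sorted(claimed) != sorted(feats) or len(claimed) != len(set(claimed)):
        raise ValueError("group_map must partition the feature set exactly")
    group_ids = sorted(group_map)
    pos = {f: i for i, f in enumerate(feats)}
    groups_idx = [np.array([pos[f] for f in group_map[g]]) for g in group_ids]
    weights = np.array([np.sqrt(len(idx)) for idx in groups_idx])

    x = features.to_numpy(dtype=float).T  # samples x features
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    if family == "logistic":
        y_arr = np.asarray(pd.Series(np.asarray(y)).astype("category").cat.codes, dtype=float)
        if len(np.unique(y_arr)) != 2:
            raise ValueError("logistic family needs a binary response")
    else:
        y_arr = np.asarray(y, dtype=float)
    n = x.shape[0]

    if penalty_path is None:
        resid0 = (y_arr - y_arr.mean()) / n
        lam_max = max(
            np.linalg.norm(x[:, idx].T @ resid0) / w for idx, w in zip(groups_idx, weights)
        )
        lam_max = max(lam_max, 1e-8)
        penalty_path = np.geomspace(lam_max, lam_max * 1e-2, 20)
    penalty_path = np.asarray(penalty_path, dtype=float)

    rng = np.random.default_rng(seed)
    # lambda by cross-validated loss
    order = rng.permutation(n)
    folds_idx = np.array_split(order, cv_folds)
    cv_loss = np.zeros(len(penalty_path))
    loss_fn = _logistic_loss_grad if family == "logistic" else _linear_loss_grad
    for hold in folds_idx:
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        coefs, b0s, _ = _fit_group_lasso_path(x[mask], y_arr[mask], groups_idx, weights,
                                              penalty_path, family)
        for li in range(len(penalty_path)):
            loss, *_ = loss_fn(coefs[li], b0s[li], x[hold], y_arr[hold])
            cv_loss[li] += loss * hold.size
    best_li = int(np.argmin(cv_loss))
    lam = float(penalty_path[best_li])

    coefs, _, history = _fit_group_lasso_path(x, y_arr, groups_idx, weights, penalty_path, family)
    beta = coefs[best_li]
    norms = pd.Series(
        [float(np.linalg.norm(beta[idx])) for idx in groups_idx], index=group_ids, name="norm"
    )
    selected = [g for g in group_ids if norms[g] > 1e-10]

    path_df = pd.DataFrame(
        {g: [float(np.linalg.norm(coefs[li][idx])) for li in range(len(penalty_path))]
         for g, idx in zip(group_ids, groups_idx)},
        index=pd.Index(penalty_path, name="penalty"),
    )

    sel_count = pd.Series(0.0, index=group_ids)
    for _ in range(bootstraps):
        bs = rng.integers(0, n, size=n)
        if family == "logistic" and len(np.unique(y_arr[bs])) < 2:
            bs = rng.permutation(n)  # degenerate resample: fall back to a shuffle
        c_bs, _, _ = _fit_group_lasso_path(x[bs], y_arr[bs], groups_idx, weights,
                                           np.array([lam]), family)
        for g, idx in zip(group_ids, groups_idx):
            if np.linalg.norm(c_bs[0][idx]) > 1e-10:
                sel_count[g] += 1
    freq = sel_count / bootstraps

    return GroupLassoResult(
        group_ids=group_ids,
        coefficient_norms=norms,
        selected_groups=selected,
        regularization_path=path_df,
        bootstrap_selection_frequency=freq,
        penalty=lam,
        objective_history=history,
    )


def clinical_association(
    mlg_matrix: pd.DataFrame,
    indices: pd.DataFrame,
    n_perm: int = 999,
    cc_min: float = 0.2,
    p_max: float = 0.05,
    seed: int = 0,
    folds: int = 5,
    repeats: int = 2,
    n_trees: int = 200,
    strong_cc: float = 0.25,
) -> pd.DataFrame:
    """Associate MLG abundances with clinical indices.

    Per index: a regression-forest RFCV pre-selects a small MLG panel
    (many-to-one), then each selected (MLG, index) pair is retained only if
    the permutational Spearman test gives p < ``p_max`` and |cc| >=
    ``cc_min``.  Pairs with |cc| > ``strong_cc`` are flagged ``strong``
    (drawn as thicker association lines).  Indices with too few complete
    observations are skipped with a note in the returned attrs.

    Returns columns ``index``, ``mlg``, ``cc``, ``p_value``, ``strength``.
    """
    rng = np.random.default_rng(seed)
    records = []
    skipped = []
    for idx_name in indices.columns:
        y = pd.to_numeric(indices[idx_name], errors="coerce")
        ok = y.notna()
        if ok.sum() < max(8, folds):
            skipped.append(idx_name)
            continue
        samples = indices.index[ok]
        sub = mlg_matrix.loc[:, samples]
        sel = rfcv_select(
            sub, y[ok].to_numpy(), folds=folds, repeats=repeats,
            max_panel=min(25, len(sub.index)), seed=int(rng.integers(0, 2**31 - 1)),
            n_trees=n_trees, task="regress",
        )
        for mlg_id in sel.chosen_panel:
            vec = sub.loc[mlg_id].to_numpy(dtype=float)
            if np.all(vec == vec[0]):
                continue
            cc, p = spearman_permutation(
                vec, y[ok].to_numpy(), n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
            )
            if p < p_max and abs(cc) >= cc_min:
                strength = "strong" if abs(cc) > strong_cc else "moderate"
                records.append((idx_name, mlg_id, float(cc), float(p), strength))
    out = pd.DataFrame(records, columns=["index", "mlg", "cc", "p_value", "strength"])
    out.attrs["skipped_indices"] = skipped
    return out


def medication_analysis(
    m: pd.DataFrame,
    labels,
    drug_flags: pd.DataFrame,
    folds: int = 5,
    repeats: int = 2,
    seed: int = 0,
    n_trees: int = 200,
    max_panel: int = 25,
    n_perm: int = 999,
    case_label: str = "case",
    min_stratum: int | None = None,
) -> pd.DataFrame:
    """Medication-confounder assessment by stratified classifiers + PERMANOVA.

    For each drug column (boolean per sample; defined for cases — controls
    are untreated) three two-way RFCV classifiers are run: treated cases vs
    controls, untreated cases vs controls, and treated vs untreated cases;
    each reports AUC and Youden's index.  Comparisons with a stratum smaller
    than ``min_stratum`` (default: ``folds``) are marked not computed (NaN).
    A Jensen–Shannon-divergence PERMANOVA (among cases, treated vs untreated,
    ``n_perm`` permutations) quantifies each drug's overall compositional
    effect.  The disease signal dominates a drug's effect when the
    case-vs-control AUCs exceed the treated-vs-untreated AUC.
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series(np.asarray(labels), index=m.columns)
    case_mask = labels == case_label
    min_stratum = min_stratum if min_stratum is not None else folds

    rows = []
    for drug in drug_flags.columns:
        flags = drug_flags[drug].reindex(m.columns).fillna(0).astype(bool)
        strata = {
            "case_drug": m.columns[case_mask & flags],
            "case_nodrug": m.columns[case_mask & ~flags],
            "control": m.columns[~case_mask],
        }
        comparisons = [
            ("case_drug_vs_control", strata["case_drug"], strata["control"]),
            ("case_nodrug_vs_control", strata["case_nodrug"], strata["control"]),
            ("case_drug_vs_case_nodrug", strata["case_drug"], strata["case_nodrug"]),
        ]
        result = {"drug": drug,
                  "n_case_drug": len(strata["case_drug"]),
                  "n_case_nodrug": len(strata["case_nodrug"]),
                  "n_control": len(strata["control"])}
        for name, a, b in comparisons:
            if len(a) < min_stratum or len(b) < min_stratum:
                result[f"{name}_auc"] = np.nan
                result[f"{name}_youden"] = np.nan
                continue
            cols = list(a) + list(b)
            lab = ["grp_a"] * len(a) + ["grp_b"] * len(b)
            sel = rfcv_select(
                m.loc[:, cols], lab, folds=folds, repeats=repeats,
                max_panel=max_panel, seed=int(rng.integers(0, 2**31 - 1)),
                n_trees=n_trees,
            )
            roc = roc_analysis(sel.probabilities, lab, case_label="grp_a")
            result[f"{name}_auc"] = roc.auc
            result[f"{name}_youden"] = roc.youden_index

        # compositional drug effect among cases
        n_t, n_u = len(strata["case_drug"]), len(strata["case_nodrug"])
        if n_t >= 2 and n_u >= 2:
            cols = list(strata["case_drug"]) + list(strata["case_nodrug"])
            d = distance_matrix(m.loc[:, cols], metric="jensen_shannon")
            pr = permanova(
                d, ["treated"] * n_t + ["untreated"] * n_u, n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)), factor_id=drug,
            )
            result["permanova_p"] = pr.p_value
            result["permanova_F"] = pr.pseudo_F
        else:
            result["permanova_p"] = np.nan
            result["permanova_F"] = np.nan
        rows.append(result)
    return pd.DataFrame(rows).set_index("drug")
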