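"""Case/control statistics: differential abundance, FDR, networks,
reporter scores, permutational correlations, gene-content tests.

Conventions shared across the module:

* abundance matrices are feature-by-sample DataFrames (see ``profiles``);
* group labels are a pandas Series or array aligned with the sample columns,
  with exactly two levels for the two-group tests; the *case* level is taken
  to be the lexicographically smaller label unless given explicitly;
* permutation p-values follow the plus-one rule
  ``p = (1 + #extreme) / (1 + n_perm)`` and are therefore never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialRecord",
    "NetworkEdge",
    "ReporterRecord",
    "benjamini_hochberg",
    "differential_abundance",
    "cooccurrence_network",
    "network_to_graph",
    "reporter_scores",
    "spearman_permutation",
    "fisher_gene_content",
    "two_group_masks",
]

logger = logging.getLogger(__name__)

#: |reporter score| flagging threshold: one-sided 95 % normal quantile,
#: printed to one decimal.
REPORTER_DETECTION = 1.6
#: two-sided 95 % normal quantile, drawn as the confidence band on plots.
REPORTER_BAND = 1.96

Z_CLAMP = 8.0  # caps |Z| so p ~ 0 cannot inject infinities


@dataclass
class DifferentialRecord:
    feature_id: str
    p_value: float
    q_value: float
    direction: str  # "case-enriched" | "control-enriched" | "none"
    median_case: float
    median_control: float


@dataclass
class NetworkEdge:
    feature_a: str
    feature_b: str
    cc: float
    sign: str  # "positive" | "negative"
    weight_class: str  # "thin" | "medium" | "thick"


@dataclass
class ReporterRecord:
    module_id: str
    reporter_score: float
    n_kos: int
    direction: str  # "case" | "control" | "none"


def two_group_masks(groups, case_label: str | None = None) -> tuple[np.ndarray, np.ndarray, str, str]:
    """Split a two-level label vector into (case_mask, control_mask)."""
    g = pd.Series(np.asarray(groups))
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if case_label is None:
        case_label = levels[0]
    elif case_label not in levels:
        raise ValueError(f"case label {case_label!r} not among {levels}")
    other = [l for l in levels if l != case_label][0]
    return (g == case_label).to_numpy(), (g == other).to_numpy(), case_label, other


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p and enrichment direction of x vs y."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0, "none"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    # direction from the rank sums: U1 > n1*n2/2 means x ranks higher
    u1 = res.statistic
    mid = len(x) * len(y) / 2.0
    if u1 > mid:
        direction = "case-enriched"
    elif u1 < mid:
        direction = "control-enriched"
    else:
        direction = "none"
    return float(res.pvalue), direction


def differential_abundance(
    m: pd.DataFrame,
    groups,
    q_cut: float = 0.05,
    case_label: str | None = None,
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test with BH correction.

    Returns a DataFrame indexed by feature with columns ``median_case``,
    ``median_control``, ``direction``, ``p_value``, ``q_value`` and
    ``significant`` (q < ``q_cut``).  Direction reflects which group holds
    the larger rank sum regardless of significance.
    """
    case, ctrl, _, _ = two_group_masks(groups, case_label)
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    vals = m.to_numpy(dtype=float)
    records = []
    for i, feat in enumerate(m.index):
        x, y = vals[i, case], vals[i, ctrl]
        p, direction = _rank_sum_test(x, y)
        records.append((feat, float(np.median(x)), float(np.median(y)), direction, p))
    out = pd.DataFrame(
        records, columns=["feature", "median_case", "median_control", "direction", "p_value"]
    ).set_index("feature")
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_cut
    return out


def _weight_class(abs_cc: float) -> str:
    if abs_cc > 0.7:
        return "thick"
    if abs_cc > 0.5:
        return "medium"
    return "thin"


def cooccurrence_network(
    m: pd.DataFrame,
    sample_subset=None,
    cc_min: float = 0.3,
) -> pd.DataFrame:
    """Spearman co-occurrence edges among features at |cc| >= ``cc_min``.

    Computed on the given sample subset (case and control networks are built
    separately by passing each group's samples).  Edge weight classes follow
    the conventional band display: thick |cc| > 0.7, medium 0.5–0.7, thin
    0.3–0.5.  Returns an edge table with columns ``feature_a``, ``feature_b``,
    ``cc``, ``sign``, ``weight_class``; pairs ordered a < b.
    """
    sub = m if sample_subset is None else m.loc[:, list(sample_subset)]
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    feats = sub.index.to_list()
    cc, _ = sps.spearmanr(sub.to_numpy(dtype=float), axis=1)
    if np.ndim(cc) == 0:  # scipy collapses the 2-feature case to a scalar
        cc = np.array([[1.0, float(cc)], [float(cc), 1.0]])
    rows = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            c = float(cc[i, j])
            if np.isnan(c) or abs(c) < cc_min:
                continue
            rows.append(
                (feats[i], feats[j], c, "positive" if c > 0 else "negative", _weight_class(abs(c)))
            )
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "cc", "sign", "weight_class"])


def network_to_graph(edges: pd.DataFrame):
    """Edge table -> networkx Graph (for GraphML export)."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.feature_a, row.feature_b, cc=row.cc, sign=row.sign,
                   weight_class=row.weight_class)
    return g


def _ko_z_scores(
    ko_matrix: pd.DataFrame, case: np.ndarray, ctrl: np.ndarray, use_adjusted_p: bool
) -> pd.Series:
    """Signed Z per KO from the smaller one-sided rank-sum p.

    The sign is positive for case-enrichment.  Z = Phi^-1(1 - p), clamped to
    |Z| <= 8 for numerical safety.
    """
    vals = ko_matrix.to_numpy(dtype=float)
    p_one = np.empty(len(ko_matrix))
    signs = np.empty(len(ko_matrix))
    for i in range(len(ko_matrix)):
        x, y = vals[i, case], vals[i, ctrl]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p_one[i], signs[i] = 0.5, 1.0
            continue
        p_greater = sps.mannwhitneyu(x, y, alternative="greater", method="auto").pvalue
        p_less = sps.mannwhitneyu(x, y, alternative="less", method="auto").pvalue
        if p_greater <= p_less:
            p_one[i], signs[i] = p_greater, 1.0
        else:
            p_one[i], signs[i] = p_less, -1.0
    if use_adjusted_p:
        p_one = benjamini_hochberg(p_one)
    z = sps.norm.isf(p_one)  # Phi^-1(1 - p)
    z = np.clip(z, -Z_CLAMP, Z_CLAMP) * signs
    return pd.Series(z, index=ko_matrix.index)


def reporter_scores(
    ko_matrix: pd.DataFrame,
    groups,
    module_map: dict[str, set[str]],
    min_samples: int = 5,
    n_background: int = 1000,
    seed: int = 0,
    case_label: str | None = None,
    use_adjusted_p: bool = False,
) -> pd.DataFrame:
    """Module-level reporter scores from per-KO rank-sum Z-scores.

    KOs present (abundance > 0) in strictly more than ``min_samples`` samples
    receive a signed Z from their one-sided Wilcoxon p (direction chosen as
    the smaller one-sided p; positive = case-enriched).  A module of k scored
    KOs aggregates ``Z_raw = sum(Z)/sqrt(k)`` and is corrected against
    ``n_background`` random same-size KO sets:
    ``score = (Z_raw - mean_bg) / sd_bg``.  |score| >= 1.6 flags a module as
    differentiating (one-sided 95 %); the 1.96 two-sided band is what plots
    conventionally draw.

    Modules whose KOs are all absent from the matrix (after the occurrence
    filter) are excluded with a logged warning.
    """
    case, ctrl, _, _ = two_group_masks(groups, case_label)
    rng = np.random.default_rng(seed)

    occurrence = (ko_matrix.to_numpy() > 0).sum(axis=1)
    scored = ko_matrix.loc[occurrence > min_samples]
    if scored.empty:
        raise ValueError("no KO passes the occurrence filter")
    z = _ko_z_scores(scored, case, ctrl, use_adjusted_p)
    z_values = z.to_numpy()

    records = []
    for module_id in sorted(module_map):
        kos = module_map[module_id]
        present = sorted(kos & set(z.index))
        k = len(present)
        if k == 0:
            logger.warning("reporter_scores: module %s has no scored KOs; excluded", module_id)
            continue
        z_raw = z.loc[present].sum() / np.sqrt(k)
        # background: k-sized random draws from all scored KOs
        draws = rng.choice(z_values.size, size=(n_background, k), replace=True)
        bg = z_values[draws].sum(axis=1) / np.sqrt(k)
        sd = bg.std(ddof=0)
        score = (z_raw - bg.mean()) / sd if sd > 0 else 0.0
        if score >= REPORTER_DETECTION:
            direction = "case"
        elif score <= -REPORTER_DETECTION:
            direction = "control"
        else:
            direction = "none"
        records.append((module_id, float(score), k, direction))
    out = pd.DataFrame(records, columns=["module", "reporter_score", "n_kos", "direction"])
    return out.set_index("module")


def spearman_permutation(
    x, y, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Spearman correlation with a label-permutation p-value.

    ``p = (1 + #{|cc_perm| >= |cc_obs|}) / (1 + n_perm)`` where permutations
    shuffle ``y`` against ``x``.  Pairs with a missing value in either vector
    are dropped first.  Constant vectors make the correlation undefined and
    raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    cc_obs = float(rx @ ry / n)
    rng = np.random.default_rng(seed)
    perms = np.array([rx @ rng.permutation(ry) / n for _ in range(n_perm)])
    p = (1.0 + np.sum(np.abs(perms) >= abs(cc_obs) - 1e-12)) / (1.0 + n_perm)
    return cc_obs, float(p)


def fisher_gene_content(presence: pd.DataFrame, groups, case_label: str | None = None) -> pd.DataFrame:
    """Fisher exact test of gene occurrence between two sample groups.

    ``presence`` is a gene-by-sample boolean (or 0/1) matrix, as produced by
    pangenome presence/absence callers.  Each gene's 2x2 table (present /
    absent x case / control) gets a two-sided Fisher exact p; BH q across
    genes.  Returns columns ``n_case_present``, ``n_control_present``,
    ``p_value``, ``q_value``.
    """
    case, ctrl, _, _ = two_group_masks(groups, case_label)
    vals = presence.to_numpy()
    if not np.isin(vals, [0, 1, True, False]).all():
        raise ValueError("presence matrix must be boolean / 0-1")
    vals = vals.astype(bool)
    n_case, n_ctrl = int(case.sum()), int(ctrl.sum())
    records = []
    for i, gene in enumerate(presence.index):
        a = int(vals[i, case].sum())
        b = int(vals[i, ctrl].sum())
        table = [[a, n_case - a], [b, n_ctrl - b]]
        p = sps.fisher_exact(table, alternative="two-sided")[1]
        records.append((gene, a, b, float(p)))
    out = pd.DataFrame(records, columns=["gene", "n_case_present", "n_control_present", "p_value"])
    out = out.set_index("gene")
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out
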