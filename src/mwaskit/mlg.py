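"""Metagenomic linkage groups (MLGs): co-abundance gene binning.

Genes on one microbial chromosome rise and fall together across samples, so
clusters of co-varying catalog genes act as proxies for genomes or strains.
The binning procedure here is deliberately simple and reproducible:

1. rank-transform each gene's abundance profile (midranks for ties) and
   compute all pairwise Spearman correlations;
2. connect genes whose correlation reaches ``cc_threshold`` and take
   connected components of the resulting graph;
3. refine each component by average-linkage agglomeration on the distance
   ``1 - cc``, cutting the dendrogram at ``1 - cc_threshold``;
4. keep clusters with strictly more than ``min_genes`` members.

All ordering is canonicalized (genes sorted lexicographically before
clustering), so the result does not depend on input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .profiles import as_annotation_frame

__all__ = ["MLG", "TaxonomyAssignment", "build_mlgs", "mlg_abundance", "assign_taxonomy"]


@dataclass
class TaxonomyAssignment:
    """Reference-genome vote over an MLG's constituent genes.

    ``top_genomes`` lists up to three ``(genome, fraction_of_genes,
    mean_identity_percent)`` records sorted by fraction; ``assigned_taxon``
    is set only when the leading genome covers strictly more than half of
    the MLG's genes.
    """

    assigned_taxon: str | None
    top_genomes: list[tuple[str, float, float]] = field(default_factory=list)


@dataclass
class MLG:
    mlg_id: str
    gene_ids: frozenset[str]
    abundance: pd.Series | None = None
    taxonomy: TaxonomyAssignment | None = None

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation between rows (midranks, float32)."""
    ranks = rankdata(values, axis=1).astype(np.float32)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    norms[norms == 0] = np.inf  # constant rows correlate with nothing
    ranks /= norms[:, None]
    cc = ranks @ ranks.T
    np.clip(cc, -1.0, 1.0, out=cc)
    return cc


def build_mlgs(
    m: pd.DataFrame,
    cc_threshold: float = 0.6,
    min_genes: int = 100,
    seed: int = 0,
) -> list[MLG]:
    """Cluster genes of a prevalence-filtered abundance matrix into MLGs.

    Returns clusters with strictly more than ``min_genes`` members, ordered
    by decreasing size (ties by smallest member gene id).  ``seed`` is
    accepted for interface uniformity; the procedure itself is deterministic.
    """
    if not 0.0 < cc_threshold < 1.0:
        raise ValueError("cc_threshold must lie in (0, 1)")
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate abundances")

    # canonical order: lexicographic gene ids; drop all-zero samples
    m = m.sort_index()
    totals = m.to_numpy().sum(axis=0)
    m = m.loc[:, totals > 0]
    genes = m.index.to_numpy()
    n = len(genes)
    if n < 2:
        return []

    cc = _spearman_matrix(m.to_numpy(dtype=np.float32))
    adj = cc >= cc_threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    clusters: list[np.ndarray] = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if members.size <= min_genes:
            continue  # refinement cannot grow a component
        if members.size == 1:
            clusters.append(members)
            continue
        sub = cc[np.ix_(members, members)].astype(np.float64)
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        z = linkage(squareform(dist, checks=False), method="average")
        assign = fcluster(z, t=1.0 - cc_threshold, criterion="distance")
        for cl in np.unique(assign):
            clusters.append(members[assign == cl])

    kept = [c for c in clusters if c.size > min_genes]
    kept.sort(key=lambda c: (-c.size, genes[c].min()))
    return [
        MLG(mlg_id=f"MLG{k:04d}", gene_ids=frozenset(genes[c])) for k, c in enumerate(kept)
    ]


def mlg_abundance(mlgs: list[MLG], m: pd.DataFrame) -> pd.DataFrame:
    """Sum member-gene relative abundances into an MLG-by-sample matrix.

    Every member gene must be present in ``m``; a missing gene raises an
    error naming the gene and its MLG.  The returned abundances are also
    attached to each MLG's ``abundance`` field.
    """
    index = m.index
    rows = []
    for mlg in mlgs:
        missing = mlg.gene_ids - set(index)
        if missing:
            gene = sorted(missing)[0]
            raise KeyError(f"gene {gene!r} of {mlg.mlg_id} absent from abundance matrix")
        row = m.loc[sorted(mlg.gene_ids)].sum(axis=0)
        mlg.abundance = row
        rows.append(row.rename(mlg.mlg_id))
    if not rows:
        return pd.DataFrame(columns=m.columns, index=pd.Index([], name="mlg"))
    out = pd.DataFrame(rows)
    out.index.name = "mlg"
    return out


def assign_taxonomy(
    mlg: MLG, gene_taxa, species_identity_floor: float | None = None
) -> TaxonomyAssignment:
    """Assign an MLG to a reference genome by majority vote of its genes.

    ``gene_taxa`` maps gene -> genome (annotation frame or mapping; an
    ``identity`` column, when present, feeds the mean-identity report).  The
    fraction for each candidate genome is computed over *all* genes of the
    MLG, annotated or not.  A genome is assigned only when its fraction
    strictly exceeds 0.5; the top three genomes are always reported.  With
    ``species_identity_floor`` set (e.g. 95.0), assignment additionally
    requires the leading genome's mean percent identity to reach the floor —
    off by default since the vote rule alone is the standard criterion.
    """
    frame = as_annotation_frame(gene_taxa)
    members = sorted(mlg.gene_ids)
    sub = frame.loc[frame.index.intersection(members)]
    if sub.empty:
        ta = TaxonomyAssignment(assigned_taxon=None, top_genomes=[])
        mlg.taxonomy = ta
        return ta
    counts = sub.groupby("feature").size()
    if "identity" in sub.columns:
        mean_ident = sub.groupby("feature")["identity"].mean()
    else:
        mean_ident = pd.Series(np.nan, index=counts.index)
    frac = counts / mlg.size
    order = sorted(frac.index, key=lambda g: (-frac[g], g))
    top = [(g, float(frac[g]), float(mean_ident[g])) for g in order[:3]]
    assigned = order[0] if frac[order[0]] > 0.5 else None
    if assigned is not None and species_identity_floor is not None:
        lead_ident = mean_ident[assigned]
        if np.isnan(lead_ident) or lead_ident < species_identity_floor:
            assigned = None
    ta = TaxonomyAssignment(assigned_taxon=assigned, top_genomes=top)
    mlg.taxonomy = ta
    return ta
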