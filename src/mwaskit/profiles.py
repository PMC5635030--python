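"""Gene profiles: normalization, prevalence filtering, feature summarization.

The common currency of the pipeline is an *abundance matrix*: a pandas
DataFrame with feature ids on the rows and sample ids on the columns, holding
non-negative relative abundances (per-sample gene-level columns sum to 1
before any filtering).  Annotation maps carry one best assignment per gene
per annotation space (genus, KO, enzyme family, virus), optionally with the
percent identity and bit score of the underlying alignment hit.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "relative_abundance",
    "filter_low_occurrence",
    "aggregate_features",
    "filter_best_hits",
    "as_annotation_frame",
    "validate_abundance_matrix",
    "PROTEIN_HIT_THRESHOLDS",
    "NUCLEOTIDE_HIT_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: BlastP-style thresholds for functional annotation: identity > 35 %,
#: bit score > 60, E-value < 1e-3 (all strict).
PROTEIN_HIT_THRESHOLDS = {"min_identity": 35.0, "min_score": 60.0, "max_evalue": 1e-3}

#: BlastN-style thresholds for virus annotation: identity > 65 %, score > 60.
NUCLEOTIDE_HIT_THRESHOLDS = {"min_identity": 65.0, "min_score": 60.0, "max_evalue": None}


def validate_abundance_matrix(m: pd.DataFrame, normalized: bool = False) -> None:
    """Raise on negative entries or duplicate ids; optionally require columns
    to sum to 1 (gene-level profiles before filtering)."""
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups[:5]}")
    if m.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    vals = m.to_numpy()
    if (vals < 0).any():
        raise ValueError("abundance matrix has negative entries")
    if normalized:
        sums = vals.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
        if bad.size:
            raise ValueError(f"columns not normalized: {list(m.columns[bad[:5]])}")


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a gene-by-sample count matrix to relative abundances.

    Each column is divided by its sum; zeros are preserved.  An all-zero
    sample column is an error (a sample with no mapped reads carries no
    compositional information).
    """
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts matrix has negative entries")
    sums = vals.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"all-zero sample column(s): {list(counts.columns[zero])}")
    out = pd.DataFrame(vals / sums, index=counts.index, columns=counts.columns)
    return out


def filter_low_occurrence(m: pd.DataFrame, min_samples: int = 10) -> pd.DataFrame:
    """Drop features detected (abundance > 0) in fewer than ``min_samples``
    samples.

    Mirrors the binning-stage gene prevalence filter (genes seen in fewer
    than 10 samples are removed before clustering).  Columns are *not*
    renormalized afterwards, so the retained genes keep the relative
    abundances they had on the full profile; summed cluster abundances stay
    comparable across filter settings.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    occurrence = (m.to_numpy() > 0).sum(axis=1)
    return m.loc[occurrence >= min_samples]


def as_annotation_frame(ann: Mapping[str, str] | pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Normalize an annotation map to a DataFrame indexed by gene with
    columns ``feature`` and (optionally) ``identity`` and ``score``."""
    if isinstance(ann, pd.DataFrame):
        if "feature" not in ann.columns:
            raise ValueError("annotation frame needs a 'feature' column")
        out = ann.copy()
    elif isinstance(ann, pd.Series):
        out = ann.rename("feature").to_frame()
    else:
        out = pd.Series(dict(ann), name="feature").to_frame()
    out.index.name = "gene"
    if out.index.has_duplicates:
        raise ValueError("annotation map assigns a gene more than once")
    return out


def aggregate_features(m: pd.DataFrame, ann: Mapping[str, str] | pd.DataFrame) -> pd.DataFrame:
    """Sum gene abundances into annotated features (genus, KO, virus, ...).

    Each output feature's abundance per sample is the sum of its member
    genes' abundances; genes without an annotation are dropped (the output
    does not renormalize, so unannotated mass simply disappears from the
    column totals).
    """
    frame = as_annotation_frame(ann)
    if frame.empty:
        return pd.DataFrame(index=pd.Index([], name="feature"), columns=m.columns, dtype=float)
    mapping = frame["feature"]
    common = m.index.intersection(mapping.index)
    sub = m.loc[common]
    grouped = sub.groupby(mapping.loc[common].to_numpy()).sum()
    grouped.index.name = "feature"
    return grouped.sort_index()


def filter_best_hits(
    hits: pd.DataFrame,
    min_identity: float = 35.0,
    min_score: float = 60.0,
    max_evalue: float | None = 1e-3,
) -> pd.DataFrame:
    """Reduce an alignment hit table to one best assignment per gene.

    ``hits`` carries BLAST outfmt-6-style columns ``gene``, ``target``,
    ``identity`` (percent), ``score`` (bit score) and optionally ``evalue``.
    A hit passes when identity > ``min_identity``, score > ``min_score`` and,
    if ``max_evalue`` is given, E-value < ``max_evalue`` (all strict, as the
    thresholds are conventionally printed).  Among passing hits the
    highest-scoring one wins; ties on score break by higher identity, then
    lexicographically smaller target id.  Malformed rows (non-numeric or
    out-of-range fields) are skipped with a logged warning count.

    Returns an annotation frame indexed by gene with columns ``feature``,
    ``identity``, ``score``.
    """
    required = {"gene", "target", "identity", "score"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    h = hits.copy()
    for col in ("identity", "score", "evalue"):
        if col in h.columns:
            h[col] = pd.to_numeric(h[col], errors="coerce")
    bad = h["identity"].isna() | h["score"].isna() | (h["identity"] < 0) | (h["identity"] > 100)
    if "evalue" in h.columns:
        bad |= h["evalue"].notna() & (h["evalue"] < 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("filter_best_hits: skipped %d malformed hit row(s)", n_bad)
        h = h.loc[~bad]

    keep = (h["identity"] > min_identity) & (h["score"] > min_score)
    if max_evalue is not None:
        if not math.isfinite(max_evalue):
            raise ValueError("max_evalue must be finite when given")
        if "evalue" not in h.columns:
            raise ValueError("max_evalue given but hit table has no 'evalue' column")
        keep &= h["evalue"] < max_evalue
    h = h.loc[keep]
    if h.empty:
        return pd.DataFrame(columns=["feature", "identity", "score"],
                            index=pd.Index([], name="gene"))

    # best hit: max score, then max identity, then lexicographic target
    h = h.sort_values(["gene", "score", "identity", "target"],
                      ascending=[True, False, False, True], kind="mergesort")
    best = h.drop_duplicates("gene", keep="first").set_index("gene")
    out = best[["target", "identity", "score"]].rename(columns={"target": "feature"})
    return out
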