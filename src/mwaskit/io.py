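"""TSV/JSON adapters for pipeline inputs and outputs.

All matrices travel as tab-separated files with the feature ids in the first
column and sample ids in the header; annotation maps are two-column
(gene, feature) TSVs with optional ``identity`` / ``score`` columns; module
maps are long-form (module, ko) TSVs.  Column orders are fixed so outputs
are bit-stable across runs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_module_map",
    "read_metadata",
    "read_hit_table",
    "write_edges",
    "write_graphml",
]

#: default column order of a BLAST outfmt-6-style hit table
HIT_COLUMNS = ("gene", "target", "identity", "score", "evalue")


def read_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    return m


def write_matrix(m: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    frame.index = frame.index.astype(str)
    frame.index.name = "gene"
    if "feature" not in frame.columns:
        # two-column file: second column is the feature
        frame = frame.rename(columns={frame.columns[0]: "feature"})
    return frame


def read_module_map(path: str | Path) -> dict[str, set[str]]:
    frame = pd.read_csv(path, sep="\t")
    if not {"module", "ko"} <= set(frame.columns):
        raise ValueError(f"{path}: module map needs columns 'module' and 'ko'")
    out: dict[str, set[str]] = {}
    for mod, ko in zip(frame["module"], frame["ko"]):
        out.setdefault(str(mod), set()).add(str(ko))
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def read_hit_table(path: str | Path, columns=HIT_COLUMNS, header: bool = False) -> pd.DataFrame:
    """Read an alignment hit table; ``columns`` states the column ordering
    (BLAST outfmt 6 ordering is configurable by permuting this tuple)."""
    frame = pd.read_csv(path, sep="\t", header=0 if header else None)
    if not header:
        if frame.shape[1] < len(columns):
            frame.columns = list(columns[: frame.shape[1]])
        else:
            frame.columns = list(columns) + [
                f"extra{i}" for i in range(frame.shape[1] - len(columns))
            ]
    return frame


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    edges.to_csv(path, sep="\t", index=False)


def write_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    import networkx as nx

    from .stats import network_to_graph

    nx.write_graphml(network_to_graph(edges), path)
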