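"""Plain-text readers and writers for the pipeline's file formats.

All tabular formats are TSV; lines starting with ``#`` are treated as
comments.  Expression matrices have the gene ID in the first column and
sample IDs in the header; PPI edge lists are two-column TSV with an
optional STRING-export-style header (``protein1  protein2
combined_score``); gene sets use the GMT dialect (set name, description,
then tab-separated member IDs).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .expression import ExpressionMatrix


def read_expression_tsv(path: str | Path, scale: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(df, scale=scale)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# expression matrix, scale={expr.scale}\n")
        expr.data.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    required = {"animal", "tissue", "library", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_gene_lengths_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.iloc[:, 0]


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_id_list(ids, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_ppi_tsv(path: str | Path, min_score: float | None = None) -> nx.Graph:
    """Two-column PPI edge list, optionally STRING-style with a
    ``combined_score`` column filtered at ``min_score``."""
    df = pd.read_csv(path, sep=r"\s+|\t", engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError("PPI file needs at least two columns")
    cols = list(df.columns)
    if min_score is not None:
        if "combined_score" not in cols:
            raise ValueError("min_score given but no combined_score column")
        df = df[df["combined_score"].astype(float) >= min_score]
    g = nx.Graph()
    g.add_edges_from(
        (str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]) if a != b
    )
    return g


def write_ppi_tsv(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\n")
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{v}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
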