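"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV with the gene identifier in the first
column and one column per sample (log2 scale).  Gene sets use GMT or
one-gene-per-line text; networks are exported as edge-list TSV, GraphML
and SIF.  All readers return pandas/networkx objects; no binary formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ["sample", "study", "stress", "condition", "genotype"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (first column = gene ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    values = df.to_numpy()
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dup}")
    if not np.isfinite(values).all():
        raise ValueError(f"non-finite values in expression matrix {path}")
    return df.astype(float)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path, gene_column: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=gene_column, float_format="%.6g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {missing}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (probe, locus); repeated probe rows denote ambiguity."""
    table = pd.read_csv(path, sep="\t", header=None, names=["probe", "locus"], dtype=str)
    mapping: dict[str, list[str]] = {}
    for probe, locus in zip(table["probe"], table["locus"]):
        mapping.setdefault(probe, [])
        if locus is not None and not pd.isna(locus) and locus not in mapping[probe]:
            mapping[probe].append(locus)
    return mapping


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "nutrinet") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_prior_matrix(path: str | Path) -> pd.DataFrame:
    """TF x gene nonnegative weight table (rows = TFs)."""
    priors = pd.read_csv(path, sep="\t", index_col=0)
    if (priors.to_numpy() < 0).any():
        raise ValueError(f"negative prior weights in {path}")
    return priors.astype(float)


def write_prior_matrix(priors: pd.DataFrame, path: str | Path) -> None:
    priors.to_csv(path, sep="\t", index_label="tf", float_format="%.6g")


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = []
    for u, v, data in graph.edges(data=True):
        rows.append(
            {
                "u": u,
                "v": v,
                "weight": data.get("weight", np.nan),
                "p": data.get("p", np.nan),
                "fdr": data.get("fdr", np.nan),
            }
        )
    pd.DataFrame(rows, columns=["u", "v", "weight", "p", "fdr"]).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def write_sif(graph: nx.Graph, path: str | Path, relation: str | None = None) -> None:
    """Simple interaction format for Cytoscape interchange."""
    if relation is None:
        relation = "regulates" if graph.is_directed() else "coexp"
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in graph.nodes():
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
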