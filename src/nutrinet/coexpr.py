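"""Undirected co-expression network with a correlation-significance filter.

All gene pairs are scored by Pearson correlation across samples; each
edge p-value comes from the exact t transform t = r sqrt((n-2)/(1-r^2))
on n-2 degrees of freedom (two-sided), the whole pair family is adjusted
by Benjamini-Hochberg (Bonferroni available), and only edges with an
adjusted p below the threshold (default 0.0005) are retained.  Edge
weights are the signed correlations.  Hubs are nodes ranked by degree.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["correlation_edges", "hub_nodes", "correlation_pvalues"]

logger = logging.getLogger(__name__)


def correlation_pvalues(r: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t transform on n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n_samples - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, np.clip(p, 0, 1))


def correlation_edges(
    matrix: pd.DataFrame,
    fdr_threshold: float = 0.0005,
    method: str = "bh",
    node_attrs: dict[str, dict] | None = None,
) -> nx.Graph:
    """Build the significance-filtered Pearson co-expression network.

    Parameters
    ----------
    matrix : genes x samples log2 expression; needs >=4 samples.
    fdr_threshold : adjusted-p cut-off for retaining an edge.
    method : "bh" (default) or "bonferroni" adjustment across all pairs.
    node_attrs : optional per-gene attribute dicts (e.g. is_tf, origin).

    Zero-variance genes cannot be correlated and are excluded with a
    logged warning.  Undirected edges are stored once with u < v.
    """
    n_samples = matrix.shape[1]
    if n_samples < 4:
        raise ValueError("correlation test needs >=4 samples (n-2 >= 2)")
    variances = matrix.to_numpy(dtype=float).var(axis=1)
    flat = matrix.index[variances == 0].tolist()
    if flat:
        logger.warning("excluding %d zero-variance genes from the network: %s",
                       len(flat), flat[:5])
    data = matrix.loc[variances > 0]
    genes = data.index.to_numpy()
    g = nx.Graph()
    for gene in genes:
        g.add_node(gene, **(node_attrs.get(gene, {}) if node_attrs else {}))
    if len(genes) < 2:
        return g

    r = np.corrcoef(data.to_numpy(dtype=float))
    iu, ju = np.triu_indices(len(genes), k=1)
    r_pairs = r[iu, ju]
    p_pairs = correlation_pvalues(r_pairs, n_samples)
    if method == "bh":
        adj = bh_adjust(p_pairs)
    elif method == "bonferroni":
        adj = np.minimum(p_pairs * p_pairs.size, 1.0)
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    keep = adj < fdr_threshold
    for a, b, w, p, q in zip(iu[keep], ju[keep], r_pairs[keep], p_pairs[keep], adj[keep]):
        u, v = sorted((genes[a], genes[b]))
        g.add_edge(u, v, weight=float(w), p=float(p), fdr=float(q))
    return g


def hub_nodes(net: nx.Graph, top_k: int | None = None) -> list[tuple[str, int]]:
    """Nodes ranked by degree (descending), ties broken by gene ID.

    ``top_k`` larger than the node count (or None) returns the full
    ranking.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    ranked = sorted(net.degree(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ranked = ranked[: max(0, top_k)]
    return ranked
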