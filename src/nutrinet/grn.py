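"""Directed TF→target network inference by random-forest importances.

For every target gene an ensemble of regression trees (default 1000)
predicts its expression from the expression of the candidate regulators
(the TF list minus the target itself).  At each split a candidate subset
of size ceil(sqrt(#regulators)) is drawn — uniformly by default, or with
probability proportional to a nonnegative prior weight per (TF, target)
when a prior matrix is supplied; uniform priors therefore recover the
plain ensemble-of-trees behaviour, and informative priors bias the
regulator sampling toward supported edges.  Edge importance is the total
variance (impurity) reduction credited to each regulator, summed over
trees and normalized per target to sum to 1.  Everything is
deterministic given the seed and the input ordering.

Tree defaults: unlimited depth, min 2 samples per leaf, bootstrap
resampling per tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DirectedEdgeScores",
    "rf_importance_network",
    "threshold_directed",
    "edge_recovery_auroc",
]

logger = logging.getLogger(__name__)


@dataclass
class DirectedEdgeScores:
    """(TF, target) importance table: rows = TFs, columns = targets."""

    scores: pd.DataFrame
    n_trees: int
    seed: int
    normalized_per_target: bool = True
    tf_list: list[str] = field(default_factory=list)

    def ranked_edges(self) -> pd.DataFrame:
        """Long-format edges sorted by importance (desc), ties by name."""
        long = (
            self.scores.stack()
            .rename_axis(["tf", "target"])
            .reset_index(name="score")
        )
        long = long[long["tf"] != long["target"]]
        return long.sort_values(
            ["score", "tf", "target"], ascending=[False, True, True]
        ).reset_index(drop=True)


@njit(cache=True)
def _fit_forest(X, y, logw, n_trees, mtry, min_leaf, seeds):  # pragma: no cover
    """Fit an ensemble for one target; return summed variance reductions.

    X: (n_samples, n_reg) regulator expression; y: target expression;
    logw: log prior weight per regulator (-inf excludes a regulator);
    candidate subsets per split are drawn without replacement with
    probability proportional to exp(logw) via the Gumbel top-k trick.
    """
    n, p = X.shape
    imp = np.zeros(p)
    idx = np.empty(n, np.int64)
    cap = 4 * n + 8
    stack_lo = np.empty(cap, np.int64)
    stack_hi = np.empty(cap, np.int64)
    keys = np.empty(p)
    cand = np.empty(mtry, np.int64)
    tmp = np.empty(n, np.int64)
    vals = np.empty(n)
    for t in range(n_trees):
        np.random.seed(seeds[t])
        for i in range(n):  # bootstrap sample
            idx[i] = int(np.random.random() * n)
        top = 0
        stack_lo[top] = 0
        stack_hi[top] = n
        top += 1
        while top > 0:
            top -= 1
            lo = stack_lo[top]
            hi = stack_hi[top]
            m = hi - lo
            if m < 2 * min_leaf:
                continue
            s = 0.0
            ss = 0.0
            for i in range(lo, hi):
                v = y[idx[i]]
                s += v
                ss += v * v
            sse = ss - s * s / m
            if sse <= 1e-12:
                continue
            # Gumbel top-k: weighted sampling without replacement
            for j in range(p):
                u = np.random.random()
                keys[j] = logw[j] - np.log(-np.log(u + 1e-300) + 1e-300)
            for c in range(mtry):
                best_j = 0
                best_k = -1e308
                for j in range(p):
                    if keys[j] > best_k:
                        best_k = keys[j]
                        best_j = j
                cand[c] = best_j
                keys[best_j] = -1e308
            best_gain = 0.0
            best_f = -1
            best_thr = 0.0
            for c in range(mtry):
                f = cand[c]
                if logw[f] == -np.inf:
                    continue
                for i in range(m):
                    vals[i] = X[idx[lo + i], f]
                order = np.argsort(vals[:m], kind="mergesort")
                ls = 0.0
                lss = 0.0
                for pos in range(m - 1):
                    v = y[idx[lo + order[pos]]]
                    ls += v
                    lss += v * v
                    nl = pos + 1
                    nr = m - nl
                    if nl < min_leaf or nr < min_leaf:
                        continue
                    if vals[order[pos]] == vals[order[pos + 1]]:
                        continue
                    rs = s - ls
                    rss = ss - lss
                    gain = sse - (lss - ls * ls / nl) - (rss - rs * rs / nr)
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (vals[order[pos]] + vals[order[pos + 1]])
            if best_f < 0:
                continue
            imp[best_f] += best_gain
            nl = 0
            for i in range(lo, hi):
                if X[idx[i], best_f] <= best_thr:
                    tmp[nl] = idx[i]
                    nl += 1
            nr = nl
            for i in range(lo, hi):
                if X[idx[i], best_f] > best_thr:
                    tmp[nr] = idx[i]
                    nr += 1
            for i in range(m):
                idx[lo + i] = tmp[i]
            stack_lo[top] = lo
            stack_hi[top] = lo + nl
            top += 1
            stack_lo[top] = lo + nl
            stack_hi[top] = hi
            top += 1
    return imp


def rf_importance_network(
    matrix: pd.DataFrame,
    tfs,
    n_trees: int = 1000,
    priors: pd.DataFrame | None = None,
    seed: int = 0,
    min_samples_leaf: int = 2,
    targets=None,
) -> DirectedEdgeScores:
    """Score every TF→target edge by random-forest variance reduction.

    Parameters
    ----------
    matrix : genes x samples log2 expression matrix.
    tfs : iterable of regulator gene IDs (must be rows of the matrix).
    priors : optional TF x gene nonnegative weight table; a target whose
        prior column is all zero over its candidate regulators is an
        error.  ``None`` means uniform candidate sampling.
    targets : genes to score (default: every gene in the matrix).

    Determinism contract: identical seed + identical row/column ordering
    of the inputs gives bit-identical scores (the per-tree random streams
    are derived from the master seed in input order).
    """
    tf_list = list(dict.fromkeys(tfs))
    missing = [t for t in tf_list if t not in matrix.index]
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {missing}")
    if len(tf_list) < 2:
        raise ValueError("need >=2 TFs to build a regulator ensemble")
    if matrix.shape[1] < 10:
        logger.warning("only %d samples; importances will be unstable", matrix.shape[1])
    if targets is None:
        targets = list(matrix.index)
    else:
        targets = list(targets)
        absent = [g for g in targets if g not in matrix.index]
        if absent:
            raise ValueError(f"targets absent from matrix: {absent}")
    if priors is not None:
        if (priors.to_numpy() < 0).any():
            raise ValueError("prior weights must be nonnegative")
        bad_tf = [t for t in tf_list if t not in priors.index]
        if bad_tf:
            raise ValueError(f"TFs missing from prior matrix: {bad_tf}")

    X_all = matrix.T.to_numpy(dtype=float)  # samples x genes
    col_of = {g: i for i, g in enumerate(matrix.index)}
    tf_cols = np.array([col_of[t] for t in tf_list])

    ss = np.random.SeedSequence(seed)
    target_seeds = {g: child for g, child in zip(targets, ss.spawn(len(targets)))}

    scores = pd.DataFrame(0.0, index=pd.Index(tf_list, name="tf"),
                          columns=pd.Index(targets, name="target"))
    for gene in targets:
        reg_mask = np.array([t != gene for t in tf_list])
        regs = [t for t in tf_list if t != gene]
        if not regs:
            continue
        Xr = np.ascontiguousarray(X_all[:, tf_cols[reg_mask]])
        y = np.ascontiguousarray(X_all[:, col_of[gene]])
        if priors is not None:
            if gene not in priors.columns:
                raise ValueError(f"target {gene} missing from the prior matrix columns")
            w = priors.reindex(index=regs)[gene].to_numpy(dtype=float)
            if not np.isfinite(w).all():
                raise ValueError(f"non-finite prior weights for target {gene}")
            if w.sum() <= 0:
                raise ValueError(f"prior weights for target {gene} are all zero")
            with np.errstate(divide="ignore"):
                logw = np.log(w / w.sum())
        else:
            logw = np.zeros(len(regs))
        mtry = max(1, math.ceil(math.sqrt(len(regs))))
        seeds = target_seeds[gene].generate_state(n_trees, dtype=np.uint32).astype(np.int64)
        imp = _fit_forest(Xr, y, logw, n_trees, mtry, int(min_samples_leaf), seeds)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        scores.loc[regs, gene] = imp
    return DirectedEdgeScores(
        scores=scores, n_trees=n_trees, seed=seed, tf_list=tf_list
    )


def threshold_directed(
    scores: DirectedEdgeScores,
    top_n: int | None = None,
    score_cutoff: float | None = None,
) -> nx.DiGraph:
    """Keep the highest-scoring directed edges; exactly one selector."""
    if (top_n is None) == (score_cutoff is None):
        raise ValueError("give exactly one of top_n or score_cutoff")
    edges = scores.ranked_edges()
    if top_n is not None:
        edges = edges.iloc[: max(0, top_n)]
    else:
        edges = edges[edges["score"] >= score_cutoff]
    g = nx.DiGraph()
    tf_set = set(scores.tf_list)
    for node in set(edges["tf"]) | set(edges["target"]):
        g.add_node(node, is_tf=node in tf_set)
    for _, row in edges.iterrows():
        g.add_edge(row["tf"], row["target"], weight=float(row["score"]))
    return g


def edge_recovery_auroc(scores: DirectedEdgeScores, true_edges: set[tuple[str, str]]) -> float:
    """AUROC of the importance ranking against a planted edge set.

    Candidates are all (TF, target) pairs in the score table with
    TF != target.
    """
    from sklearn.metrics import roc_auc_score

    long = scores.scores.stack().rename_axis(["tf", "target"]).reset_index(name="score")
    long = long[long["tf"] != long["target"]]
    labels = [
        1 if (tf, tg) in true_edges else 0 for tf, tg in zip(long["tf"], long["target"])
    ]
    return float(roc_auc_score(labels, long["score"].to_numpy()))
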