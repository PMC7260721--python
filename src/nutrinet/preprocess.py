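"""Across-sample quantile normalization and probe-to-gene collapsing.

Input matrices are assumed to be background-corrected log2 intensities
(RMA-style upstream processing); this module forces every sample onto a
common value distribution and resolves probe identifiers to gene loci,
discarding probes with no match or an ambiguous (multi-locus) match.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["quantile_normalize", "collapse_probes"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share the rank-wise mean distribution.

    Every value is replaced by the across-sample mean of the values at its
    rank; after normalization every column has the identical sorted value
    vector.  Ties within a column receive the mean of the reference values
    of the ranks they occupy (midrank convention), which keeps the
    operation deterministic and symmetric in tied entries.

    Parameters
    ----------
    matrix : DataFrame, genes x samples, no missing values, >=2 columns.

    Returns
    -------
    DataFrame with identical labels and the normalized values.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains missing or non-finite values; imputation is out of scope")
    n = values.shape[0]
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        col_order = order[:, j]
        # boundaries of tie groups in the sorted column
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        if len(starts) == n:  # all distinct: fast path
            out[col_order, j] = reference
        else:
            for s, e in zip(starts, ends):
                out[col_order[s:e], j] = reference[s:e].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(
    matrix: pd.DataFrame,
    probe_map: dict[str, list[str]],
    how: str = "mean",
) -> pd.DataFrame:
    """Map probe rows to gene loci, discarding unmapped/ambiguous probes.

    Probes absent from the map or mapping to zero loci are dropped; probes
    matching more than one locus are discarded as ambiguous.  When several
    probes resolve to the same single locus they are collapsed to one row:
    ``how="mean"`` takes the per-sample arithmetic mean of their log2
    values (default), ``how="max_mean"`` keeps the probe with the highest
    average intensity.

    Raises
    ------
    ValueError if no probe survives the filter.
    """
    if how not in ("mean", "max_mean"):
        raise ValueError(f"unknown collapse rule {how!r}")
    locus_of: dict[str, str] = {}
    for probe in matrix.index:
        loci = probe_map.get(probe, [])
        if len(loci) == 1:
            locus_of[probe] = loci[0]
    if not locus_of:
        raise ValueError("no probes map unambiguously to a locus; empty matrix after filtering")
    kept = matrix.loc[list(locus_of)]
    loci = pd.Index([locus_of[p] for p in kept.index], name=matrix.index.name)
    if how == "mean":
        collapsed = kept.groupby(loci, sort=True).mean()
    else:
        avg = kept.mean(axis=1).to_numpy()
        best = (
            pd.DataFrame({"locus": loci, "avg": avg, "probe": kept.index})
            .sort_values(["locus", "avg", "probe"], ascending=[True, False, True])
            .drop_duplicates("locus")
        )
        collapsed = kept.loc[best["probe"]]
        collapsed.index = pd.Index(best["locus"].to_numpy(), name=matrix.index.name)
        collapsed = collapsed.sort_index()
    return collapsed
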