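"""Cross-study evidence combination and the common-responsive gene call.

Within each stress type, per-study two-sided p-values are combined by the
weighted inverse-normal (Stouffer) method on directional one-sided
p-values: p_one = p_two / 2 on the observed direction,
z_i = sign_i * Phi^{-1}(1 - p_one_i), and

    z_combined = sum(w_i z_i) / sqrt(sum(w_i^2)),   w_i = sqrt(n_i)

with a two-sided normal tail for the combined p.  A gene is "common
nutrient-responsive" when its combined p falls below the cut-off in at
least ``min_stress_types`` stress types.  Fixed-effect inverse-variance
pooling of log2FC effects is available as an alternative combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "StudyResult",
    "MetaResult",
    "combine_inverse_normal",
    "combine_effect_sizes",
    "meta_analyze",
    "call_common_responsive",
]

logger = logging.getLogger(__name__)

#: two-sided p-values of exactly 0 or 1 are clamped to this distance from
#: the boundary before the normal-quantile transform (documented epsilon).
P_EPSILON = 1e-15


@dataclass
class StudyResult:
    """Per-study, per-gene evidence entering the meta step."""

    study: str
    stress: str
    table: pd.DataFrame  # index gene; columns log2fc, p_value, n_samples

    def __post_init__(self):
        required = {"log2fc", "p_value", "n_samples"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"study table lacks columns {sorted(missing)}")
        p = self.table["p_value"].to_numpy()
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p-values outside [0, 1]")


@dataclass
class MetaResult:
    """Combined per-stress tables plus the derived common-responsive set."""

    per_stress: dict[str, pd.DataFrame]  # stress -> (gene: combined_z, combined_p, n_studies)
    p_threshold: float
    min_stress_types: int
    common_responsive: set[str] = field(default_factory=set)
    n_stress_passing: pd.Series | None = None


def combine_inverse_normal(
    p_values: np.ndarray, directions: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Stouffer combination of directional one-sided p-values.

    Parameters are arrays of shape (n_studies,) or (n_studies, n_genes):
    two-sided p, direction in {-1, 0, +1}, positive weight per study.
    Returns (combined_z, combined_p two-sided).
    """
    p_in = np.asarray(p_values, dtype=float)
    was_1d = p_in.ndim == 1
    # per-study axis is axis 0; a 1-D input is one gene across studies
    p = p_in.reshape(-1, 1) if was_1d else p_in
    sgn = np.asarray(directions, dtype=float).reshape(p.shape)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values outside [0, 1]")
    n_bad = int(np.sum((p <= 0) | (p >= 1)))
    if n_bad:
        logger.warning("clamping %d boundary p-values to epsilon %.1e", n_bad, P_EPSILON)
    p = np.clip(p, P_EPSILON, 1.0 - P_EPSILON)
    p_one = p / 2.0
    z = stats.norm.isf(p_one) * np.where(sgn == 0, 0.0, np.sign(sgn))
    w = w.reshape(-1, *([1] * (z.ndim - 1)))
    combined_z = (w * z).sum(axis=0) / np.sqrt((w**2).sum())
    combined_p = np.clip(2.0 * stats.norm.sf(np.abs(combined_z)), 0, 1)
    if was_1d:
        return float(np.squeeze(combined_z)), float(np.squeeze(combined_p))
    return combined_z, combined_p


def combine_effect_sizes(
    effects: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect inverse-variance pooling of per-study effects.

    ``effects``/``variances``: shape (n_studies,) or (n_studies, n_genes).
    Returns (pooled_effect, two-sided p of pooled effect / SE).
    """
    d = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if d.ndim == 1:
        d = d.reshape(-1, 1)
        v = v.reshape(-1, 1)
    if d.shape[0] < 2:
        raise ValueError("effect-size pooling needs >=2 studies")
    if np.any(v <= 0):
        raise ValueError("effect variances must be positive")
    w = 1.0 / v
    pooled = (w * d).sum(axis=0) / w.sum(axis=0)
    pooled_var = 1.0 / w.sum(axis=0)
    z = pooled / np.sqrt(pooled_var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.squeeze(pooled), np.squeeze(np.clip(p, 0, 1))


def meta_analyze(
    studies: list[StudyResult],
    p_threshold: float = 0.05,
    min_stress_types: int = 2,
    adjust: bool = False,
) -> MetaResult:
    """Combine studies within each stress type, then call the common set.

    Weights are sqrt(n_samples) per study.  ``adjust=True`` applies BH to
    the combined p-values within each stress before thresholding
    (default off: the cut-off applies to the unadjusted combined p).
    Genes absent from a study are combined over the studies that measured
    them; a per-gene direction-consistency score (fraction of studies
    agreeing with the majority sign) is reported for diagnostics.

    When the study tables carry an ``is_deg`` column, a stress type only
    counts toward the common call for genes with fold-change-gated DEG
    support in at least one of its studies (the candidate genes whose
    evidence the combination "once more determines"); without the column
    the combined p-gate alone decides.  This mirrors re-testing the
    per-dataset DEG lists rather than every measured gene, and keeps
    stress-specific responders from leaking into the common set through
    a second stress's 5% type-I error.
    """
    by_stress: dict[str, list[StudyResult]] = {}
    for sr in studies:
        by_stress.setdefault(sr.stress, []).append(sr)
    if len(by_stress) < 2:
        raise ValueError("common-responsive calling needs >=2 stress types")

    per_stress: dict[str, pd.DataFrame] = {}
    for stress, group in sorted(by_stress.items()):
        genes = sorted(set().union(*(set(sr.table.index) for sr in group)))
        k = len(group)
        p = np.ones((k, len(genes)))
        sgn = np.zeros((k, len(genes)))
        w = np.empty(k)
        present = np.zeros((k, len(genes)), dtype=bool)
        for i, sr in enumerate(group):
            tab = sr.table.reindex(genes)
            mask = tab["p_value"].notna().to_numpy()
            present[i] = mask
            p[i, mask] = tab["p_value"].to_numpy()[mask]
            sgn[i, mask] = np.sign(tab["log2fc"].to_numpy()[mask])
            w[i] = np.sqrt(float(tab["n_samples"].dropna().iloc[0]) if mask.any() else 1.0)
        # a missing study contributes z=0 at its weight; renormalize by the
        # weights of the studies actually present per gene instead
        p_clamped = np.clip(p, P_EPSILON, 1 - P_EPSILON)
        z = stats.norm.isf(p_clamped / 2.0) * sgn
        z[~present] = 0.0
        wcol = w[:, None] * present
        denom = np.sqrt((wcol**2).sum(axis=0))
        combined_z = (wcol * z).sum(axis=0) / np.where(denom > 0, denom, 1.0)
        combined_p = np.clip(2.0 * stats.norm.sf(np.abs(combined_z)), 0, 1)
        maj = np.sign(np.where(sgn * present != 0, sgn, 0).sum(axis=0))
        agree = ((sgn == maj[None, :]) & present).sum(axis=0)
        consistency = np.where(present.sum(axis=0) > 0, agree / present.sum(axis=0).clip(1), 0.0)
        table = pd.DataFrame(
            {
                "combined_z": combined_z,
                "combined_p": combined_p,
                "n_studies_used": present.sum(axis=0),
                "direction_consistency": consistency,
            },
            index=pd.Index(genes, name="gene"),
        )
        if any("is_deg" in sr.table.columns for sr in group):
            support = set()
            for sr in group:
                if "is_deg" in sr.table.columns:
                    support |= set(sr.table.index[sr.table["is_deg"].astype(bool)])
            table["deg_support"] = table.index.isin(support)
        per_stress[stress] = table

    result = MetaResult(per_stress, p_threshold, min_stress_types)
    result.common_responsive, result.n_stress_passing = call_common_responsive(
        per_stress, p_threshold, min_stress_types, adjust=adjust, return_counts=True
    )
    return result


def call_common_responsive(
    per_stress: dict[str, pd.DataFrame],
    p_threshold: float = 0.05,
    min_stress_types: int = 2,
    adjust: bool = False,
    return_counts: bool = False,
):
    """Genes whose combined p passes the cut-off in >= min_stress_types stresses.

    Tables carrying a ``deg_support`` column additionally require the
    gene to have fold-change-gated DEG support in that stress.
    """
    if len(per_stress) < 2:
        raise ValueError("need >=2 stress types")
    genes = sorted(set().union(*(set(t.index) for t in per_stress.values())))
    counts = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    for table in per_stress.values():
        p = table["combined_p"]
        if adjust:
            p = pd.Series(bh_adjust(p.to_numpy()), index=p.index)
        mask = p < p_threshold
        if "deg_support" in table.columns:
            mask &= table["deg_support"].astype(bool)
        passing = p.index[mask]
        counts.loc[passing] += 1
    common = set(counts.index[counts >= min_stress_types])
    if return_counts:
        return common, counts
    return common
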