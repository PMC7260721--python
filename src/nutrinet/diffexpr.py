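"""Per-study differential expression with empirical-Bayes variance moderation.

The model is the standard two-group linear contrast on log2 intensities:
per gene g, log2FC_g = mean(treatment) - mean(control) with a pooled
within-group variance s_g^2 on d = n_t + n_c - 2 residual degrees of
freedom.  Gene-wise variances are shrunk toward a global prior variance
s0^2 with d0 prior degrees of freedom, estimated by moment matching on
the log sample variances (digamma/trigamma method).  The moderated
statistic

    t_g = log2FC_g / sqrt(s~_g^2 (1/n_t + 1/n_c)),
    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

is referred to a t distribution on d0 + d degrees of freedom (standard
normal when d0 is infinite).  Multiple testing is controlled by the
Benjamini-Hochberg step-up, and a gene is called differentially expressed
when |log2FC| > 1 (strict) and FDR < 0.05, both thresholds configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignInfo",
    "ModerationParams",
    "fit_contrasts",
    "estimate_moderation",
    "moderated_statistics",
    "bh_adjust",
    "call_degs",
    "deg_table",
]


@dataclass(frozen=True)
class DesignInfo:
    """Sample-to-group labels plus the (treatment, control) contrast."""

    groups: dict[str, str]  # sample id -> group label
    contrast: tuple[str, str]  # (treatment, control)

    def __post_init__(self):
        treat, ctrl = self.contrast
        labels = set(self.groups.values())
        for grp in (treat, ctrl):
            if grp not in labels:
                raise ValueError(f"contrast group {grp!r} has no samples")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes hyperparameters: prior df d0 and prior variance s0^2."""

    prior_df: float
    prior_var: float

    def __post_init__(self):
        if not (self.prior_df > 0):
            raise ValueError("prior_df must be positive (may be inf)")
        if not (self.prior_var > 0 and np.isfinite(self.prior_var)):
            raise ValueError("prior_var must be positive and finite")


def fit_contrasts(matrix: pd.DataFrame, design: DesignInfo) -> pd.DataFrame:
    """Gene-wise two-group contrast: effect, pooled variance, residual df.

    Returns a DataFrame indexed by gene with columns ``log2fc``,
    ``residual_var``, ``residual_df``, ``n_treat``, ``n_ctrl``.
    """
    treat, ctrl = design.contrast
    t_samples = [s for s in design.samples(treat) if s in matrix.columns]
    c_samples = [s for s in design.samples(ctrl) if s in matrix.columns]
    missing = [s for s in design.groups if s not in matrix.columns]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing}")
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("each contrast group needs >=2 samples for a defined variance")
    xt = matrix[t_samples].to_numpy(dtype=float)
    xc = matrix[c_samples].to_numpy(dtype=float)
    nt, nc = xt.shape[1], xc.shape[1]
    log2fc = xt.mean(axis=1) - xc.mean(axis=1)
    ss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xc - xc.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = nt + nc - 2
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "residual_var": ss / df,
            "residual_df": float(df),
            "n_treat": nt,
            "n_ctrl": nc,
        },
        index=matrix.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(residual_vars: np.ndarray, residual_df: float) -> ModerationParams:
    """Moment-match the scaled-inverse-chi-square prior on gene variances.

    Under the hierarchical model s_g^2 ~ s0^2 * chi2_d / d scaled by a
    gene variance drawn from s0^2 * d0 / chi2_{d0}, the log sample
    variances satisfy

        E[log s_g^2] = log s0^2 + digamma(d/2) - log(d/2)
                                - digamma(d0/2) + log(d0/2)
        Var[log s_g^2] = trigamma(d/2) + trigamma(d0/2)

    so d0 follows from inverting the trigamma function on the excess
    spread of the observed log variances, and s0^2 from the mean.  When
    the observed spread does not exceed the chi-square-only spread, the
    prior is effectively a point mass: d0 = inf with s0^2 the
    geometric-mean-based estimate.

    Zero/negative variances are excluded from estimation (shrinkage still
    covers them downstream).
    """
    s2 = np.asarray(residual_vars, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size == 0:
        raise ValueError("all residual variances are zero; moderation undefined")
    if s2.size < 30:
        raise ValueError(f"need >=30 genes with positive variance, got {s2.size}")
    d = float(residual_df)
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    excess = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if excess <= 0:
        return ModerationParams(prior_df=np.inf, prior_var=float(np.exp(e.mean())))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return ModerationParams(prior_df=float(d0), prior_var=float(s0))


def moderated_statistics(
    log2fc: np.ndarray,
    residual_vars: np.ndarray,
    residual_df: float,
    params: ModerationParams,
    n_treat: int,
    n_ctrl: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p for each gene.

    ``prior_df = 0`` is accepted as the unmoderated limit (ordinary pooled
    t); ``prior_df = inf`` pins the variance at ``prior_var`` and refers
    the statistic to the standard normal.
    """
    lfc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(residual_vars, dtype=float)
    d0 = params.prior_df
    s0 = params.prior_var
    d = float(residual_df)
    if np.isinf(d0):
        post_var = np.full_like(s2, s0)
        df_total = np.inf
    else:
        post_var = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(post_var * (1.0 / n_treat + 1.0 / n_ctrl))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
        t = np.where((se == 0) & (lfc != 0), np.sign(lfc) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, np.clip(p, 0.0, 1.0)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame, lfc_threshold: float = 1.0, fdr_threshold: float = 0.05
) -> set[str]:
    """Genes with |log2FC| strictly above the fold gate and FDR below the gate."""
    mask = (table["log2fc"].abs() > lfc_threshold) & (table["fdr"] < fdr_threshold)
    return set(table.index[mask])


def deg_table(
    matrix: pd.DataFrame,
    design: DesignInfo,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full per-study DEG table: contrast fit, moderation, BH, call flag."""
    fit = fit_contrasts(matrix, design)
    params = estimate_moderation(fit["residual_var"].to_numpy(), fit["residual_df"].iloc[0])
    t, p = moderated_statistics(
        fit["log2fc"].to_numpy(),
        fit["residual_var"].to_numpy(),
        fit["residual_df"].iloc[0],
        params,
        int(fit["n_treat"].iloc[0]),
        int(fit["n_ctrl"].iloc[0]),
    )
    out = fit.copy()
    out["moderated_t"] = t
    out["p_value"] = p
    out["fdr"] = bh_adjust(p)
    degs = call_degs(out.assign(fdr=out["fdr"]), lfc_threshold, fdr_threshold)
    out["is_deg"] = out.index.isin(degs)
    out.attrs["moderation"] = params
    return out
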