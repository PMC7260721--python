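"""Small phenotype and qRT-PCR measurement formulas.

wavy root index = primary root path length / vertical root depth (>= 1,
1 for a perfectly straight vertical root); growth-arrest fraction =
arrested / germinated with a Wilson 95% binomial interval; qRT-PCR
relative expression follows the 2^-ddCt model with amplification
efficiency fixed at 2 (one cycle = one doubling), normalizing the target
gene to a reference gene (e.g. ACTIN 2) and to the control condition.
Replicate fold changes are summarized by their geometric mean
(symmetric on the log scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RootMeasurement",
    "QpcrRecord",
    "wavy_root_index",
    "growth_arrest_fraction",
    "qpcr_relative_expression",
    "summarize_fold_changes",
]


@dataclass(frozen=True)
class RootMeasurement:
    root_length: float
    root_depth: float

    def __post_init__(self):
        if not (self.root_depth > 0):
            raise ValueError("root depth must be positive")
        if not (self.root_length > 0):
            raise ValueError("root length must be positive")
        if self.root_length < self.root_depth:
            raise ValueError("root length cannot be shorter than its vertical depth")


@dataclass(frozen=True)
class QpcrRecord:
    """Cycle thresholds for target and reference genes, treatment and control."""

    ct_target_treatment: float
    ct_reference_treatment: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")


def wavy_root_index(m: RootMeasurement) -> float:
    """Path length over vertical depth; 1.0 means a straight root."""
    return m.root_length / m.root_depth


def growth_arrest_fraction(n_arrested: int, n_germinated: int) -> tuple[float, tuple[float, float]]:
    """Fraction of germinated plants showing sustained growth arrest.

    Returns the point estimate and the Wilson 95% confidence interval.
    """
    if n_germinated <= 0:
        raise ValueError("number of germinated plants must be positive")
    if not (0 <= n_arrested <= n_germinated):
        raise ValueError("arrested count must lie in [0, germinated]")
    lo, hi = proportion_confint(n_arrested, n_germinated, alpha=0.05, method="wilson")
    return n_arrested / n_germinated, (float(lo), float(hi))


def qpcr_relative_expression(rec: QpcrRecord) -> float:
    """Fold change 2^-ddCt of the target over control, reference-normalized.

    dCt = Ct_target - Ct_reference per condition;
    ddCt = dCt_treatment - dCt_control; log2(result) = -ddCt exactly.
    """
    dct_t = rec.ct_target_treatment - rec.ct_reference_treatment
    dct_c = rec.ct_target_control - rec.ct_reference_control
    return float(2.0 ** (-(dct_t - dct_c)))


def summarize_fold_changes(fold_changes) -> float:
    """Geometric mean of per-replicate fold changes (mean of log2 values)."""
    fc = np.asarray(list(fold_changes), dtype=float)
    if fc.size == 0 or np.any(fc <= 0):
        raise ValueError("fold changes must be positive and non-empty")
    return float(2.0 ** np.mean(np.log2(fc)))
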