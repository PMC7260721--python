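"""Synthetic multi-study expression data with planted ground truth.

Emulates the structure of a public-microarray compendium: several
independent studies per stress type, each a small two-group (control vs
stress) experiment on log2-scale intensities with independent Gaussian
noise.  A configurable fraction of genes responds to each stress; a
shared pool responds to exactly two stress types, defining the true
"common nutrient-responsive" set.  Two genotype-effect gene sets
(gpa1-like / agb1-like) are planted with fixed intersection sizes
against that pool.  A separate generator plants a linear TF→target
regulatory layer with a prior-weight table whose accuracy is
controllable, for exercising the network-inference stage.

Per-gene baselines are drawn once per stress and shared across that
stress's studies so studies of the same stress are correlated, and a
true responder keeps one direction per (gene, stress) across studies so
directional one-sided combination is coherent.  All randomness derives
from a single master seed through per-study substreams; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .diffexpr import DesignInfo

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_multistudy",
    "simulate_grn",
    "write_multistudy",
    "write_grn",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _default_mutant_sizes() -> dict[str, int]:
    return {"gpa1": 180, "agb1": 130}


def _default_intersections() -> dict[str, int]:
    return {"gpa1": 20, "agb1": 40}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic compendium.

    Defaults describe the standard conditions: 3 stress types x 4
    studies, 3 replicates per group, responders at mean log2FC 2 (sd
    0.5) over Gaussian noise of sd 0.25 on the log2 scale, with 60% of
    each stress's responders drawn from a pool shared by two stresses.
    """

    n_genes: int = 2000
    stress_types: tuple[str, ...] = ("Fe-def", "Zn-def", "Zn-excess")
    studies_per_stress: int = 4
    samples_per_group: int = 3
    frac_responsive_per_stress: float = 0.2
    frac_common_responsive: float = 0.6
    effect_lfc_mean: float = 2.0
    effect_lfc_sd: float = 0.5
    noise_sd: float = 0.25
    n_mutant_specific: dict[str, int] = field(default_factory=_default_mutant_sizes)
    planted_intersection: dict[str, int] = field(default_factory=_default_intersections)
    n_tfs: int = 20
    targets_per_tf: int = 5
    grn_samples: int = 60
    grn_signal_sd: float = 1.0
    grn_noise_sd: float = 1.0
    prior_accuracy: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "studies_per_stress", "n_tfs", "targets_per_tf", "grn_samples"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if self.samples_per_group < 2:
            raise ConfigError("samples_per_group must be >=2 (variance needs replicates)")
        if len(self.stress_types) < 2:
            raise ConfigError("stress_types needs >=2 labels for a common-responsive set")
        for name in ("frac_responsive_per_stress", "frac_common_responsive"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1)")
        if not (0.0 <= self.prior_accuracy <= 1.0):
            raise ConfigError("prior_accuracy must lie in [0, 1]")
        for name in ("effect_lfc_sd", "noise_sd", "grn_signal_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.grn_noise_sd < 0:
            raise ConfigError("grn_noise_sd must be nonnegative")
        if set(self.n_mutant_specific) != set(self.planted_intersection):
            raise ConfigError("n_mutant_specific and planted_intersection must share genotypes")
        n_common = self.n_common_responsive
        for geno, size in self.n_mutant_specific.items():
            if size < 0:
                raise ConfigError(f"n_mutant_specific[{geno!r}] must be nonnegative")
            planted = self.planted_intersection[geno]
            if planted > min(size, n_common):
                raise ConfigError(
                    f"planted_intersection[{geno!r}]={planted} exceeds "
                    f"min(mutant size {size}, common pool {n_common})"
                )
        if sum(self.n_mutant_specific.values()) > self.n_genes:
            raise ConfigError("n_mutant_specific totals exceed n_genes")

    @property
    def n_responsive_per_stress(self) -> int:
        return int(round(self.frac_responsive_per_stress * self.n_genes))

    @property
    def n_common_responsive(self) -> int:
        return int(round(self.frac_common_responsive * self.n_responsive_per_stress))


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring downstream stages."""

    responsive_sets: dict[str, set[str]]
    common_responsive: set[str]
    mutant_sets: dict[str, set[str]]
    planted_intersections: dict[str, int]
    true_edges: set[tuple[str, str]]
    cluster_labels: dict[str, str]

    def check(self) -> None:
        """Internal set-algebra consistency (common = pairwise unions)."""
        stresses = list(self.responsive_sets)
        pairwise = set()
        for i, a in enumerate(stresses):
            for b in stresses[i + 1 :]:
                pairwise |= self.responsive_sets[a] & self.responsive_sets[b]
        if pairwise != self.common_responsive:
            raise AssertionError("common_responsive != union of pairwise intersections")
        for tf, _target in self.true_edges:
            if not tf.startswith("TF"):
                raise AssertionError(f"true edge source {tf} is not a declared TF")

    def as_dict(self) -> dict:
        return {
            "responsive_sets": {k: sorted(v) for k, v in self.responsive_sets.items()},
            "common_responsive": sorted(self.common_responsive),
            "mutant_sets": {k: sorted(v) for k, v in self.mutant_sets.items()},
            "planted_intersections": self.planted_intersections,
            "true_edges": sorted(list(e) for e in self.true_edges),
            "cluster_labels": self.cluster_labels,
        }


@dataclass
class SimulatedStudy:
    stress: str
    study: str
    matrix: pd.DataFrame  # genes x samples, log2 scale
    design: DesignInfo


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_multistudy(config: SimulationConfig) -> tuple[list[SimulatedStudy], GroundTruth]:
    """Generate one control/treatment matrix per (stress, study) plus truth."""
    ss = np.random.SeedSequence(config.seed)
    truth_rng = np.random.default_rng(ss.spawn(1)[0])
    genes = _gene_ids(config.n_genes)
    gene_arr = np.array(genes)
    stresses = list(config.stress_types)

    # --- plant responsive sets -------------------------------------------
    m = config.n_common_responsive
    r = config.n_responsive_per_stress
    perm = truth_rng.permutation(config.n_genes)
    pool_idx = perm[:m]
    # each common gene responds in exactly two stress types
    pair_choices = [
        tuple(truth_rng.choice(len(stresses), size=2, replace=False)) for _ in range(m)
    ]
    responsive_idx: dict[str, list[int]] = {s: [] for s in stresses}
    for gi, pair in zip(pool_idx, pair_choices):
        for si in pair:
            responsive_idx[stresses[si]].append(int(gi))
    cursor = m
    for s in stresses:
        n_unique = max(0, r - len(responsive_idx[s]))
        uniq = perm[cursor : cursor + n_unique]
        cursor += n_unique
        responsive_idx[s].extend(int(i) for i in uniq)

    # consistent per-(gene, stress) effect: one sign, one magnitude
    effects: dict[str, np.ndarray] = {}
    for s in stresses:
        eff = np.zeros(config.n_genes)
        idx = np.array(responsive_idx[s], dtype=int)
        if idx.size:
            mag = np.abs(
                truth_rng.normal(config.effect_lfc_mean, config.effect_lfc_sd, idx.size)
            )
            sign = truth_rng.choice([-1.0, 1.0], size=idx.size)
            eff[idx] = sign * mag
        effects[s] = eff

    # --- mutant-specific sets with planted intersections ------------------
    pool_set = [int(i) for i in pool_idx]
    non_common = [int(i) for i in perm[m:]]
    mutant_sets: dict[str, set[str]] = {}
    pool_cursor = 0
    rest_cursor = 0
    pool_shuffled = truth_rng.permutation(pool_set) if pool_set else np.array([], dtype=int)
    rest_shuffled = truth_rng.permutation(non_common)
    for geno in sorted(config.n_mutant_specific):
        size = config.n_mutant_specific[geno]
        planted = config.planted_intersection[geno]
        inside = pool_shuffled[pool_cursor : pool_cursor + planted]
        pool_cursor += planted
        outside = rest_shuffled[rest_cursor : rest_cursor + (size - planted)]
        rest_cursor += size - planted
        mutant_sets[geno] = set(gene_arr[np.concatenate([inside, outside]).astype(int)])

    # --- shared baselines ------------------------------------------------
    base = truth_rng.normal(8.0, 1.5, config.n_genes)
    stress_jitter = {s: truth_rng.normal(0.0, 0.25, config.n_genes) for s in stresses}

    # --- per-study matrices ----------------------------------------------
    n_studies = len(stresses) * config.studies_per_stress
    study_streams = ss.spawn(n_studies)
    studies: list[SimulatedStudy] = []
    spg = config.samples_per_group
    k = 0
    for s in stresses:
        baseline = base + stress_jitter[s]
        for j in range(config.studies_per_stress):
            rng = np.random.default_rng(study_streams[k])
            k += 1
            noise = rng.normal(0.0, config.noise_sd, (config.n_genes, 2 * spg))
            ctrl = baseline[:, None] + noise[:, :spg]
            trt = baseline[:, None] + effects[s][:, None] + noise[:, spg:]
            cols = [f"{s}.st{j + 1}.ctrl{i + 1}" for i in range(spg)] + [
                f"{s}.st{j + 1}.trt{i + 1}" for i in range(spg)
            ]
            matrix = pd.DataFrame(
                np.hstack([ctrl, trt]), index=pd.Index(genes, name="gene"), columns=cols
            )
            groups = {c: ("control" if ".ctrl" in c else "treatment") for c in cols}
            studies.append(
                SimulatedStudy(
                    stress=s,
                    study=f"{s}.st{j + 1}",
                    matrix=matrix,
                    design=DesignInfo(groups=groups, contrast=("treatment", "control")),
                )
            )

    # --- ground truth -----------------------------------------------------
    responsive_sets = {s: set(gene_arr[np.array(sorted(set(responsive_idx[s])), dtype=int)])
                       if responsive_idx[s] else set() for s in stresses}
    common = set(gene_arr[pool_idx.astype(int)]) if m else set()
    cluster_labels: dict[str, str] = {}
    pattern_ids: dict[tuple, str] = {}
    for gi, pair in zip(pool_idx, pair_choices):
        gene = gene_arr[int(gi)]
        signs = tuple(
            (stresses[si], int(np.sign(effects[stresses[si]][int(gi)]))) for si in sorted(pair)
        )
        if signs not in pattern_ids:
            pattern_ids[signs] = f"P{len(pattern_ids) + 1}"
        cluster_labels[gene] = pattern_ids[signs]
    truth = GroundTruth(
        responsive_sets=responsive_sets,
        common_responsive=common,
        mutant_sets=mutant_sets,
        planted_intersections=dict(config.planted_intersection),
        true_edges=set(),
        cluster_labels=cluster_labels,
    )
    truth.check()
    return studies, truth


def simulate_grn(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Planted linear TF→target layer plus a prior-weight table.

    TF expression is iid standard normal; each target is a weighted sum
    of 1-3 TF parents (weights of magnitude ~grn_signal_sd, random sign)
    plus Gaussian noise of sd grn_noise_sd.  The prior matrix (TF x
    target) places ``prior_accuracy`` of each target's mass on its true
    parents, the remainder uniformly on non-parents.
    """
    # separate stream family from simulate_multistudy for the same seed
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7919)))
    n_tfs = config.n_tfs
    n_targets = config.n_tfs * config.targets_per_tf
    tfs = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    targets = [f"TG{i + 1:03d}" for i in range(n_targets)]

    X_tf = rng.normal(0.0, 1.0, (n_tfs, config.grn_samples))
    X_tg = np.empty((n_targets, config.grn_samples))
    true_edges: set[tuple[str, str]] = set()
    priors = pd.DataFrame(
        0.0, index=pd.Index(tfs, name="tf"), columns=pd.Index(targets, name="target")
    )
    for ti, target in enumerate(targets):
        n_parents = int(rng.integers(1, min(3, n_tfs) + 1))
        parents = rng.choice(n_tfs, size=n_parents, replace=False)
        w = (
            rng.choice([-1.0, 1.0], size=n_parents)
            * config.grn_signal_sd
            * rng.uniform(0.75, 1.25, n_parents)
        )
        signal = w @ X_tf[parents]
        X_tg[ti] = signal + rng.normal(0.0, config.grn_noise_sd, config.grn_samples)
        for p in parents:
            true_edges.add((tfs[int(p)], target))
        non_parents = [i for i in range(n_tfs) if i not in set(int(p) for p in parents)]
        if non_parents:
            priors.iloc[parents, ti] = config.prior_accuracy / n_parents
            priors.iloc[non_parents, ti] = (1.0 - config.prior_accuracy) / len(non_parents)
        else:
            priors.iloc[parents, ti] = 1.0 / n_parents

    samples = [f"grn.s{i + 1}" for i in range(config.grn_samples)]
    matrix = pd.DataFrame(
        np.vstack([X_tf, X_tg]), index=pd.Index(tfs + targets, name="gene"), columns=samples
    )
    truth = GroundTruth(
        responsive_sets={},
        common_responsive=set(),
        mutant_sets={},
        planted_intersections={},
        true_edges=true_edges,
        cluster_labels={},
    )
    return matrix, truth, priors


def write_multistudy(
    studies: list[SimulatedStudy], truth: GroundTruth, outdir: str | Path
) -> dict[str, str]:
    """Write matrices, sample sheet, ground truth JSON and gene-set GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    sheet_rows = []
    for st in studies:
        path = outdir / f"expr_{st.study}.tsv"
        nio.write_expression_tsv(st.matrix, path)
        paths[st.study] = str(path)
        for sample, group in st.design.groups.items():
            sheet_rows.append(
                {
                    "sample": sample,
                    "study": st.study,
                    "stress": st.stress,
                    "condition": "stress" if group == "treatment" else "control",
                    "genotype": "Col-0",
                }
            )
    sheet = pd.DataFrame(sheet_rows, columns=nio.SAMPLE_SHEET_COLUMNS)
    nio.write_sample_sheet(sheet, outdir / "samples.tsv")
    nio.write_json(truth.as_dict(), outdir / "ground_truth.json")
    gene_sets = {f"responsive_{s}": g for s, g in truth.responsive_sets.items()}
    gene_sets["common_responsive"] = truth.common_responsive
    gene_sets.update({f"mutant_{g}": s for g, s in truth.mutant_sets.items()})
    nio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    paths["sample_sheet"] = str(outdir / "samples.tsv")
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    paths["gene_sets"] = str(outdir / "gene_sets.gmt")
    return paths


def write_grn(
    matrix: pd.DataFrame, truth: GroundTruth, priors: pd.DataFrame, outdir: str | Path
) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nio.write_expression_tsv(matrix, outdir / "grn_expression.tsv")
    nio.write_prior_matrix(priors, outdir / "grn_priors.tsv")
    nio.write_gene_list([g for g in matrix.index if g.startswith("TF")], outdir / "tf_list.txt")
    nio.write_json(truth.as_dict(), outdir / "grn_truth.json")
    return {
        "expression": str(outdir / "grn_expression.tsv"),
        "priors": str(outdir / "grn_priors.tsv"),
        "tf_list": str(outdir / "tf_list.txt"),
        "truth": str(outdir / "grn_truth.json"),
    }
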