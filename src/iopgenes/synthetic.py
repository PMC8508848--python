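"""Synthetic inputs for exercising the pipeline without any download.

The study this package models compared microarray expression in trabecular
meshwork tissue from 13 control and 14 glaucomatous donors over a universe
of roughly 157 focus (IOP-associated) genes plus 480 background
differentially expressed genes. No matrix is publicly deposited, so the
generator emulates those conditions: two groups of samples drawn from
multivariate normals whose correlation matrices embed planted
differentially correlated gene pairs as 2x2 blocks (block-diagonal
construction, hence positive semidefinite by construction when the
background correlation is zero).

Expression values default to exponentiated normals (log-normal) to mimic
intensity-scale positivity; ``gaussian=True`` yields raw normals, under
which the planted Pearson correlations hold exactly in expectation
(exponentiation preserves them only approximately, so calibration work
uses the Gaussian mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    ClusterExpressionRecord,
    DifferentialExpressionRecord,
    ExpressionEvidenceRecord,
    GeneSet,
    GroupedExpressionMatrix,
    VariantAnnotationRecord,
)

#: study-scale defaults: group sizes and gene universe of the emulated data
N_CONTROL = 13
N_CASE = 14
N_FOCUS_GENES = 157
N_BACKGROUND_GENES = 480


@dataclass
class SimulationSpec:
    """Parameters of a two-group expression simulation.

    planted_pairs: (gene_i, gene_j, r_group1, r_group2) index/symbol tuples;
        a gene may appear in at most one planted pair.
    background_r: correlation for all non-planted pairs; only 0 (block
        model) or an equicorrelated value within the closed-form PSD bound
        is accepted.
    """

    n_genes: int = N_FOCUS_GENES + N_BACKGROUND_GENES
    n_group1: int = N_CONTROL
    n_group2: int = N_CASE
    planted_pairs: list = field(default_factory=list)
    background_r: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    gaussian: bool = False
    group_labels: tuple[str, str] = ("control", "case")

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least two genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for i, j, r1, r2 in self.planted_pairs:
            if not (abs(r1) < 1 and abs(r2) < 1):
                raise ValueError(f"planted |r| must be < 1 for pair ({i}, {j})")
        used = [g for i, j, *_ in self.planted_pairs for g in (i, j)]
        if len(used) != len(set(used)):
            raise ValueError("planted pairs must be disjoint (no gene in two pairs)")
        # equicorrelated background: PSD iff -1/(p-1) < rho < 1; planted
        # blocks conflict with a nonzero background, so forbid the mix
        if self.background_r != 0.0:
            if self.planted_pairs:
                raise ValueError("nonzero background_r is only supported without planted pairs")
            lo = -1.0 / (self.n_genes - 1)
            if not (lo < self.background_r < 1):
                raise ValueError(f"equicorrelated background_r must lie in ({lo:.4f}, 1)")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _correlation_matrix(spec: SimulationSpec, group: int) -> np.ndarray:
    p = spec.n_genes
    if spec.background_r != 0.0:
        corr = np.full((p, p), spec.background_r)
        np.fill_diagonal(corr, 1.0)
        return corr
    corr = np.eye(p)
    names = _gene_names(p)
    index = {g: k for k, g in enumerate(names)}
    for gi, gj, r1, r2 in spec.planted_pairs:
        i = gi if isinstance(gi, int) else index[gi]
        j = gj if isinstance(gj, int) else index[gj]
        r = (r1, r2)[group]
        corr[i, j] = corr[j, i] = r
    return corr


def simulate_grouped_expression(spec: SimulationSpec) -> GroupedExpressionMatrix:
    """Draw the two-group matrix specified by ``spec``; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    names = _gene_names(spec.n_genes)
    blocks = []
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for group, (label, n) in enumerate(zip(spec.group_labels, (spec.n_group1, spec.n_group2))):
        corr = _correlation_matrix(spec, group)
        cov = corr * spec.noise_sd**2
        draws = rng.multivariate_normal(np.zeros(spec.n_genes), cov, size=n, method="cholesky").T
        if not spec.gaussian:
            draws = np.exp(draws)
        blocks.append(draws)
        ids = [f"{label}_{k + 1:02d}" for k in range(n)]
        sample_ids.extend(ids)
        groups.update({s: label for s in ids})
    values = pd.DataFrame(np.hstack(blocks), index=names, columns=sample_ids)
    return GroupedExpressionMatrix(values=values, groups=groups)


def simulate_null(
    n_genes: int,
    n1: int = N_CONTROL,
    n2: int = N_CASE,
    seed: int = 0,
    gaussian: bool = True,
) -> GroupedExpressionMatrix:
    """Null model: identical (identity) correlation structure in both groups."""
    spec = SimulationSpec(n_genes=n_genes, n_group1=n1, n_group2=n2, seed=seed, gaussian=gaussian)
    return simulate_grouped_expression(spec)


@dataclass
class EvidenceTruth:
    """Ground-truth pass/fail bookkeeping for a simulated evidence bundle."""

    genes: list[str]
    passes: dict[str, GeneSet]


def simulate_evidence_tables(
    n_genes: int,
    fractions: Optional[dict[str, float]] = None,
    seed: int = 0,
):
    """Randomized evidence tables with known per-filter ground truth.

    ``fractions`` maps filter name (``de_tm``, ``de_sc``, ``high_expr``,
    ``ocular_db``, ``variant_enhancer``, ``variant_eqtl``, ``cluster``) to
    the fraction of genes planted to pass it. Returns (bundle-of-tables
    dict, :class:`EvidenceTruth`). Tables are schema-identical to the
    packaged fixtures, so every funnel count is verifiable by construction.
    """
    defaults = {
        "de_tm": 0.2,
        "de_sc": 0.2,
        "high_expr": 0.5,
        "ocular_db": 0.3,
        "variant_enhancer": 0.5,
        "variant_eqtl": 0.5,
        "cluster": 0.3,
    }
    fractions = {**defaults, **(fractions or {})}
    for name, f in fractions.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"fraction {name} outside [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"SIM{i:04d}" for i in range(n_genes)]
    passes = {
        name: GeneSet(rng.choice(genes, size=round(f * n_genes), replace=False), name)
        for name, f in fractions.items()
    }

    def de_table(key: str) -> list[DifferentialExpressionRecord]:
        recs = []
        for g in genes:
            passing = g in passes[key]
            mag = rng.uniform(1.6, 4.0) if passing else rng.uniform(1.0, 1.45)
            sign = rng.choice([-1.0, 1.0])
            recs.append(DifferentialExpressionRecord(g, sign * mag, float(rng.uniform(1e-6, 1))))
        return recs

    tables = {
        "de_tm": de_table("de_tm"),
        "de_sc": de_table("de_sc"),
        "cells_expr": [
            ExpressionEvidenceRecord(
                g, "TM", fpkm=float(rng.uniform(10, 200)) if g in passes["high_expr"] else float(rng.uniform(0, 9.9))
            )
            for g in genes
        ],
        "ocular_db": [
            ExpressionEvidenceRecord(
                g,
                "TM",
                plier=float(rng.uniform(20, 300)),
                dabg_avg=float(rng.uniform(0, 0.05)) if g in passes["ocular_db"] else float(rng.uniform(0.06, 0.5)),
            )
            for g in genes
        ],
        "variants": [
            VariantAnnotationRecord(
                snp=f"rs{1000 + i}",
                gene=g,
                histone_modification=True,
                enhancer_or_promoter=g in passes["variant_enhancer"],
                eqtl_tissues=("Whole blood",) if g in passes["variant_eqtl"] else (),
            )
            for i, g in enumerate(genes)
        ],
        "clusters": [
            ClusterExpressionRecord(
                g, "Beam Cell A", float(rng.uniform(0.1, 3)) if g in passes["cluster"] else 0.0
            )
            for g in genes
        ],
    }
    return tables, EvidenceTruth(genes=genes, passes=passes)
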