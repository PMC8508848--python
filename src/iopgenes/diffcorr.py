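"""Two-group differential gene-gene correlation analysis.

For every unordered gene pair, Pearson correlations are computed separately
within each sample group (e.g. control and POAG trabecular meshwork). The
two correlations are compared with the classic Fisher z test for two
independent correlations,

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1 - 3) + 1/(n2 - 3)),

with a two-sided p-value from the standard normal tail. Benjamini-Hochberg
adjustment is applied over all enumerated pairs, and pairs with adjusted
FDR at or below the chosen threshold are called differentially correlated.

The normal approximation is used without a small-sample t correction; it is
adequate for group sizes of about a dozen and is the field's standard
treatment of correlation differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import GeneSet, GroupedExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.1
MIN_GROUP_SIZE = 4  # n - 3 must be positive for the Fisher z standard error


@dataclass(frozen=True)
class CorrelationPairResult:
    """One unordered gene pair's per-group correlations and test results."""

    gene_a: str
    gene_b: str
    r_group1: float
    r_group2: float
    n_group1: int
    n_group2: int
    z_stat: float
    p_value: float
    fdr: float
    n_focus_members: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError(f"pair must be stored with gene_a < gene_b: {self.gene_a}, {self.gene_b}")


def preprocess(matrix: GroupedExpressionMatrix) -> GroupedExpressionMatrix:
    """Drop unusable gene rows before correlation.

    Removes, in order: duplicate gene symbols (first occurrence kept),
    genes with any missing value, genes with no expression (all zeros),
    and genes with zero variance within either group (their correlation is
    undefined). Raises if either group retains fewer than four samples or
    no genes survive.
    """
    df = matrix.values
    dup = df.index.duplicated(keep="first")
    if dup.any():
        logger.warning("removed %d duplicated gene rows", int(dup.sum()))
        df = df[~dup]

    has_missing = df.isna().any(axis=1)
    if has_missing.any():
        logger.warning("removed %d genes with missing values", int(has_missing.sum()))
        df = df[~has_missing]

    all_zero = (df == 0).all(axis=1)
    if all_zero.any():
        logger.warning("removed %d genes with no expression", int(all_zero.sum()))
        df = df[~all_zero]

    out = GroupedExpressionMatrix(values=df, groups=matrix.groups)
    for level in out.levels:
        n = len(out.samples_in(level))
        if n < MIN_GROUP_SIZE:
            raise ValueError(f"group {level!r} has {n} samples; need >= {MIN_GROUP_SIZE}")
    zero_var = pd.Series(False, index=df.index)
    for level in out.levels:
        zero_var |= out.submatrix(level).std(axis=1, ddof=1) == 0
    if zero_var.any():
        logger.warning("removed %d genes with zero variance within a group", int(zero_var.sum()))
        df = df[~zero_var]
    if df.empty:
        raise ValueError("no genes left after preprocessing")
    return GroupedExpressionMatrix(values=df, groups=matrix.groups)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 4)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < MIN_GROUP_SIZE:
        raise ValueError(f"need at least {MIN_GROUP_SIZE} observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def z_difference_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z test for the difference of two independent correlations.

    Returns (z statistic, two-sided p). Swapping the two groups negates z
    and leaves p unchanged.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both groups need n > 3 (degenerate standard error otherwise)")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (fisher_z(r1) - fisher_z(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def all_pairs_diffcorr(
    matrix: GroupedExpressionMatrix,
    focus_set: Optional[GeneSet] = None,
    fdr_threshold: float = DEFAULT_FDR,
    pairs: str = "all",
) -> list[CorrelationPairResult]:
    """Enumerate unordered gene pairs, test correlation differences, and
    return the pairs significant at ``fdr_threshold``.

    BH adjustment is computed over ALL enumerated pairs (m = number of
    tests), not just the returned ones. ``pairs="focus-only"`` restricts the
    enumeration to pairs with at least one focus-set member; the default
    tests the full universe. Results are sorted by fdr, then |z| descending,
    then lexicographic pair.
    """
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must be in (0, 1]")
    if pairs not in {"all", "focus-only"}:
        raise ValueError(f"unknown pair universe {pairs!r}")
    matrix = preprocess(matrix)
    genes = list(matrix.values.index)
    if len(genes) < 2:
        raise ValueError("need at least two genes after preprocessing")
    level1, level2 = matrix.levels
    sub1 = matrix.submatrix(level1).to_numpy(dtype=float)
    sub2 = matrix.submatrix(level2).to_numpy(dtype=float)
    n1, n2 = sub1.shape[1], sub2.shape[1]

    corr1 = np.corrcoef(sub1)
    corr2 = np.corrcoef(sub2)
    iu, ju = np.triu_indices(len(genes), k=1)
    if pairs == "focus-only":
        if focus_set is None:
            raise ValueError("focus-only enumeration requires a focus set")
        in_focus = np.array([g in focus_set for g in genes])
        keep = in_focus[iu] | in_focus[ju]
        iu, ju = iu[keep], ju[keep]
    r1 = np.clip(corr1[iu, ju], -1 + 1e-15, 1 - 1e-15)
    r2 = np.clip(corr2[iu, ju], -1 + 1e-15, 1 - 1e-15)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    fdr = bh_fdr(p)

    results: list[CorrelationPairResult] = []
    for k in np.flatnonzero(fdr <= fdr_threshold):
        a, b = sorted((genes[iu[k]], genes[ju[k]]))
        n_focus = None
        if focus_set is not None:
            n_focus = int(a in focus_set) + int(b in focus_set)
        results.append(
            CorrelationPairResult(
                gene_a=a,
                gene_b=b,
                r_group1=float(corr1[iu[k], ju[k]]),
                r_group2=float(corr2[iu[k], ju[k]]),
                n_group1=n1,
                n_group2=n2,
                z_stat=float(z[k]),
                p_value=float(p[k]),
                fdr=float(fdr[k]),
                n_focus_members=n_focus,
            )
        )
    results.sort(key=lambda r: (r.fdr, -abs(r.z_stat), r.gene_a, r.gene_b))
    return results


def unique_gene_count(
    pairs: Sequence[CorrelationPairResult],
    focus_set: Optional[GeneSet] = None,
) -> tuple[int, int, int]:
    """(number of pairs, distinct genes among them, distinct focus genes)."""
    genes: set[str] = set()
    for pr in pairs:
        genes.add(pr.gene_a)
        genes.add(pr.gene_b)
    n_focus = sum(1 for g in genes if focus_set is not None and g in focus_set)
    return len(pairs), len(genes), n_focus


def pairs_to_frame(pairs: Sequence[CorrelationPairResult]) -> pd.DataFrame:
    """Flatten pair results to the on-disk TSV layout."""
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "r_group1": p.r_group1,
                "r_group2": p.r_group2,
                "n_group1": p.n_group1,
                "n_group2": p.n_group2,
                "z": p.z_stat,
                "p": p.p_value,
                "fdr": p.fdr,
                "n_focus_members": p.n_focus_members,
            }
            for p in pairs
        ]
    )


def frame_to_pairs(df: pd.DataFrame) -> list[CorrelationPairResult]:
    out = []
    for row in df.itertuples(index=False):
        nf = getattr(row, "n_focus_members", None)
        out.append(
            CorrelationPairResult(
                gene_a=row.gene_a,
                gene_b=row.gene_b,
                r_group1=float(row.r_group1),
                r_group2=float(row.r_group2),
                n_group1=int(row.n_group1),
                n_group2=int(row.n_group2),
                z_stat=float(row.z),
                p_value=float(row.p),
                fdr=float(row.fdr),
                n_focus_members=None if nf is None or (isinstance(nf, float) and math.isnan(nf)) else int(nf),
            )
        )
    return out
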