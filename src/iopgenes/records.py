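"""Domain record types shared across the pipeline.

All records carry normalized gene symbols (uppercase, stripped of the
asterisk footnote markers that journals print next to symbols). Missing
measurements are represented as ``None`` and always fail downstream
filters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

_ITALIC_MARKERS = re.compile(r"^[\s*_]+|[\s*_]+$")


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol: strip whitespace/asterisk/underscore markers, uppercase.

    Aliases are deliberately NOT remapped (e.g. RPLP2 and RPLP2P1 stay
    distinct symbols); callers may supply their own alias map.
    """
    sym = _ITALIC_MARKERS.sub("", raw)
    if not sym:
        raise ValueError(f"empty gene symbol after normalization: {raw!r}")
    return sym.upper()


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """One gene's signed fold change and p-value in a case/control comparison.

    ``fold_change`` is a signed ratio: negative means downregulated, the
    magnitude is the expression ratio (so |fold_change| >= 1 by convention).
    """

    gene: str
    fold_change: Optional[float]
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.gene}: p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ExpressionEvidenceRecord:
    """One gene's abundance in a named tissue or cell context.

    Either an RNA-Seq abundance (``fpkm``) or a microarray summary
    (``plier`` signal with detection-above-background probabilities) may be
    present; rows printed as all-NA yield records whose every measurement is
    missing.
    """

    gene: str
    context: str
    fpkm: Optional[float] = None
    plier: Optional[float] = None
    dabg_avg: Optional[float] = None
    dabg_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.fpkm is not None and self.fpkm < 0:
            raise ValueError(f"{self.gene}@{self.context}: negative FPKM")
        if self.dabg_avg is not None and not (0.0 <= self.dabg_avg <= 1.0):
            raise ValueError(f"{self.gene}@{self.context}: DABG outside [0, 1]")


@dataclass(frozen=True)
class VariantAnnotationRecord:
    """Regulatory-region flags and eQTL tissue list for one SNP/gene pair."""

    snp: str
    gene: str
    histone_modification: bool
    enhancer_or_promoter: bool
    eqtl_tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not re.fullmatch(r"rs[0-9]+", self.snp):
            raise ValueError(f"malformed rsID: {self.snp!r}")
        if len(set(self.eqtl_tissues)) != len(self.eqtl_tissues):
            raise ValueError(f"{self.snp}: duplicate eQTL tissues")

    @property
    def has_eqtl(self) -> bool:
        return len(self.eqtl_tissues) > 0


@dataclass(frozen=True)
class ClusterExpressionRecord:
    """Median expression of a gene within one scRNA-Seq cell cluster."""

    gene: str
    cluster: str
    median_expression: float

    def __post_init__(self) -> None:
        if self.median_expression < 0:
            raise ValueError(f"{self.gene}@{self.cluster}: negative median expression")


@dataclass(frozen=True)
class ConcentrationRecord:
    """A mean +/- SD mass concentration (pg/mL) for one donor group."""

    label: str
    value_pg_per_ml: float
    sd_pg_per_ml: float
    n: int
    # printed molar-scale values, when the source table carries both units
    value_nm: Optional[float] = None
    sd_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value_pg_per_ml < 0 or self.sd_pg_per_ml < 0:
            raise ValueError(f"{self.label}: negative concentration")
        if self.n < 1:
            raise ValueError(f"{self.label}: n must be >= 1")


class GeneSet:
    """An ordered, duplicate-free collection of gene symbols.

    Order is the input order of first occurrence, which keeps every
    downstream set operation deterministic. Symbols are normalized on entry.
    """

    def __init__(self, genes: Iterable[str] = (), provenance: str = "") -> None:
        self.provenance = provenance
        self._genes: list[str] = []
        self._index: set[str] = set()
        for g in genes:
            self.add(g)

    def add(self, gene: str) -> None:
        sym = normalize_symbol(gene)
        if sym not in self._index:
            self._index.add(sym)
            self._genes.append(sym)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSet):
            return NotImplemented
        return self._genes == other._genes

    def __repr__(self) -> str:
        label = f" {self.provenance!r}" if self.provenance else ""
        return f"GeneSet({len(self)} genes{label})"

    def to_list(self) -> list[str]:
        return list(self._genes)


@dataclass
class GroupedExpressionMatrix:
    """Genes x samples expression matrix with a two-level group label per sample.

    ``values`` is a pandas DataFrame (index = gene symbols, columns = sample
    ids); ``groups`` maps each sample id to one of exactly two group labels.
    """

    values: "object"  # pandas.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        # lexicographic level order keeps the group1/group2 roles a pure
        # function of the labels, so relabelling the groups swaps the roles
        levels = sorted(set(self.groups[s] for s in self.values.columns))
        if len(levels) != 2:
            raise ValueError(f"expected exactly two group levels, got {levels}")
        self.levels: tuple[str, str] = (levels[0], levels[1])

    def samples_in(self, level: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == level]

    def submatrix(self, level: str):
        return self.values[self.samples_in(level)]
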