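"""The gene-prioritization funnel.

Candidate genes near IOP-associated GWAS loci are run through a series of
evidence filters: differential expression in glaucomatous trabecular
meshwork (TM) tissue and Schlemm's canal (SC) cells, high expression
(FPKM) in healthy outflow cells and tissue, significant detection above
background (DABG) in an ocular tissue database, SNP location in regulatory
regions, eQTL support, response to cyclic mechanical stretch, and
specific expression in outflow-pathway scRNA-Seq clusters. Genes passing
more filters accumulate a higher evidence score.

Conventions: fold-change and FPKM thresholds are inclusive (|FC| >= 1.5,
FPKM >= 10, DABG <= 0.05); the stretch-response criterion is strict
(|FC| > 2 and p < 0.05). Missing measurements always fail a filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

from .records import (
    ClusterExpressionRecord,
    DifferentialExpressionRecord,
    ExpressionEvidenceRecord,
    GeneSet,
    VariantAnnotationRecord,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

#: scRNA-Seq clusters of the aqueous-humor production/outflow pathway used
#: by the cluster-specificity filter by default.
OUTFLOW_CLUSTERS = (
    "Beam Cell A",
    "Beam Cell B",
    "Cribiform JCT",
    "SC Endothelium",
    "Collector Channel/Aqueous Vein",
    "Ciliary Muscle",
)


@dataclass
class FilterConfig:
    """Thresholds for every funnel filter.

    fc_threshold: minimum |fold change| for ordinary differential
        expression (inclusive).
    stretch_fc_threshold / stretch_p_threshold: strict bounds for the
        cyclic-stretch dataset (|FC| > 2, p < 0.05).
    fpkm_threshold: minimum RNA-Seq abundance to call a gene highly
        expressed (inclusive).
    dabg_threshold: maximum detection-above-background probability to call
        a microarray signal significant (inclusive).
    """

    fc_threshold: float = 1.5
    stretch_fc_threshold: float = 2.0
    stretch_p_threshold: float = 0.05
    fpkm_threshold: float = 10.0
    dabg_threshold: float = 0.05
    cluster_whitelist: tuple[str, ...] = OUTFLOW_CLUSTERS
    strict_fc: bool = False  # > instead of >= for fc_threshold

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "stretch_fc_threshold", "fpkm_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("stretch_p_threshold", "dabg_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def filter_differential_expression(
    records: Sequence[DifferentialExpressionRecord],
    threshold: float = 1.5,
    p_threshold: Optional[float] = None,
    strict: bool = False,
    provenance: str = "",
) -> GeneSet:
    """Genes whose |fold change| passes ``threshold``.

    The ordinary criterion is inclusive (|FC| >= threshold) regardless of
    p-value; with ``strict=True`` and a ``p_threshold`` it becomes the
    stretch-style criterion |FC| > threshold and p < p_threshold. Missing
    fold changes (and missing p when a p cut is requested) fail.
    """
    out = GeneSet(provenance=provenance)
    for rec in records:
        if rec.fold_change is None:
            continue
        mag = abs(rec.fold_change)
        if (mag > threshold) if strict else (mag >= threshold):
            if p_threshold is not None:
                if rec.p_value is None or not rec.p_value < p_threshold:
                    continue
            out.add(rec.gene)
    return out


def partition_by_direction(
    records: Sequence[DifferentialExpressionRecord],
) -> tuple[GeneSet, GeneSet]:
    """Split DE records into (upregulated, downregulated) gene sets by sign."""
    up, down = GeneSet(provenance="up"), GeneSet(provenance="down")
    for rec in records:
        if rec.fold_change is None:
            continue
        (up if rec.fold_change > 0 else down).add(rec.gene)
    return up, down


def union_nonredundant(sets: Sequence[GeneSet], provenance: str = "union") -> GeneSet:
    """Deduplicated union preserving first-occurrence order."""
    if not sets:
        raise ValueError("union of zero sets")
    out = GeneSet(provenance=provenance)
    for s in sets:
        for g in s:
            out.add(g)
    return out


def intersect(sets: Sequence[GeneSet], provenance: str = "intersection") -> GeneSet:
    """Genes present in every input set, in first-set order."""
    if len(sets) < 2:
        raise ValueError("intersection needs at least two sets")
    out = GeneSet(provenance=provenance)
    rest = sets[1:]
    for g in sets[0]:
        if all(g in s for s in rest):
            out.add(g)
    return out


def filter_high_expression(
    records: Sequence[ExpressionEvidenceRecord],
    threshold: float = 10.0,
    genes: Optional[GeneSet] = None,
    contexts: Optional[Iterable[str]] = None,
    provenance: str = "high-expression",
) -> GeneSet:
    """Genes with FPKM >= threshold in at least one (optionally restricted)
    context; a gene listed in several contexts passes if any value passes."""
    ctx_filter = set(contexts) if contexts is not None else None
    out = GeneSet(provenance=provenance)
    for rec in records:
        if genes is not None and rec.gene not in genes:
            continue
        if ctx_filter is not None and rec.context not in ctx_filter:
            continue
        if rec.fpkm is not None and rec.fpkm >= threshold:
            out.add(rec.gene)
    return out


def combined_tissue_filter(
    db: Sequence[ExpressionEvidenceRecord],
    profile: Sequence[ExpressionEvidenceRecord],
    dabg_threshold: float = 0.05,
    fpkm_threshold: float = 10.0,
    context: str = "TM",
) -> GeneSet:
    """Genes significantly detected (DABG <= cut) in the ocular database AND
    highly expressed (FPKM >= cut) in the tissue profile, both in ``context``.

    Missing values fail; both bounds are inclusive.
    """
    detected = GeneSet(provenance=f"dabg<={dabg_threshold}@{context}")
    for rec in db:
        if rec.context == context and rec.dabg_avg is not None and rec.dabg_avg <= dabg_threshold:
            detected.add(rec.gene)
    high = filter_high_expression(profile, fpkm_threshold, contexts=[context])
    return intersect([detected, high], provenance=f"tissue-confirmed@{context}")


def regulatory_summary(records: Sequence[VariantAnnotationRecord]) -> dict:
    """Count regulatory-region and eQTL support across SNP/gene pairs."""
    per_gene = {
        rec.gene: {
            "snp": rec.snp,
            "histone_modification": rec.histone_modification,
            "enhancer_or_promoter": rec.enhancer_or_promoter,
            "has_eqtl": rec.has_eqtl,
        }
        for rec in records
    }
    return {
        "n_histone": sum(r.histone_modification for r in records),
        "n_enhancer_promoter": sum(r.enhancer_or_promoter for r in records),
        "n_with_eqtl": sum(r.has_eqtl for r in records),
        "per_gene": per_gene,
    }


def filter_cluster_specific(
    records: Sequence[ClusterExpressionRecord],
    whitelist: Iterable[str] = OUTFLOW_CLUSTERS,
    genes: Optional[GeneSet] = None,
) -> GeneSet:
    """Genes with median expression > 0 in at least one whitelisted cluster.

    No abundance cutoff beyond detection: single-cell coverage is shallow
    enough that any detected transcript implies high native expression.
    """
    wl = set(whitelist)
    if not wl:
        raise ValueError("cluster whitelist must be non-empty")
    out = GeneSet(provenance="cluster-specific")
    for rec in records:
        if genes is not None and rec.gene not in genes:
            continue
        if rec.cluster in wl and rec.median_expression > 0:
            out.add(rec.gene)
    return out


#: flag names of the evidence tally, in report order
TALLY_FLAGS = (
    "de_tm",
    "de_sc",
    "high_expr_cells",
    "ocular_db_tm",
    "tissue_fpkm_tm",
    "enhancer_promoter",
    "eqtl",
    "stretch_de",
    "cluster_specific",
    "diffcorr_member",
)


@dataclass
class EvidenceTally:
    """Per-gene boolean evidence flags plus their count.

    ``not_evaluated`` lists flags whose evidence table was not supplied;
    such flags are False and never contribute to the score.
    """

    gene: str
    flags: dict = field(default_factory=dict)
    not_evaluated: tuple[str, ...] = ()

    @property
    def score(self) -> int:
        return sum(bool(v) for v in self.flags.values())


@dataclass
class EvidenceBundle:
    """All loaded evidence tables; any table may be absent (None)."""

    de_tm: Optional[Sequence[DifferentialExpressionRecord]] = None
    de_sc: Optional[Sequence[DifferentialExpressionRecord]] = None
    cells_expr: Optional[Sequence[ExpressionEvidenceRecord]] = None
    ocular_db: Optional[Sequence[ExpressionEvidenceRecord]] = None
    tissue_expr: Optional[Sequence[ExpressionEvidenceRecord]] = None
    variants: Optional[Sequence[VariantAnnotationRecord]] = None
    stretch_de: Optional[Sequence[DifferentialExpressionRecord]] = None
    clusters: Optional[Sequence[ClusterExpressionRecord]] = None
    diffcorr_genes: Optional[GeneSet] = None

    def universe(self) -> GeneSet:
        """All genes mentioned in any loaded table, first-occurrence order."""
        out = GeneSet(provenance="universe")
        for f in fields(self):
            table = getattr(self, f.name)
            if table is None:
                continue
            if isinstance(table, GeneSet):
                for g in table:
                    out.add(g)
            else:
                for rec in table:
                    out.add(rec.gene)
        return out


def _flag_sets(evidence: EvidenceBundle, config: FilterConfig) -> dict[str, Optional[GeneSet]]:
    """Evaluate every filter once, returning a passing GeneSet per flag
    (None where the evidence table is absent)."""
    e, c = evidence, config
    sets: dict[str, Optional[GeneSet]] = dict.fromkeys(TALLY_FLAGS)
    if e.de_tm is not None:
        sets["de_tm"] = filter_differential_expression(e.de_tm, c.fc_threshold, strict=c.strict_fc)
    if e.de_sc is not None:
        sets["de_sc"] = filter_differential_expression(e.de_sc, c.fc_threshold, strict=c.strict_fc)
    if e.cells_expr is not None:
        sets["high_expr_cells"] = filter_high_expression(e.cells_expr, c.fpkm_threshold)
    if e.ocular_db is not None:
        dabg = GeneSet(provenance="ocular-db-tm")
        for rec in e.ocular_db:
            if rec.context == "TM" and rec.dabg_avg is not None and rec.dabg_avg <= c.dabg_threshold:
                dabg.add(rec.gene)
        sets["ocular_db_tm"] = dabg
    if e.tissue_expr is not None:
        sets["tissue_fpkm_tm"] = filter_high_expression(e.tissue_expr, c.fpkm_threshold, contexts=["TM"])
    if e.variants is not None:
        sets["enhancer_promoter"] = GeneSet(
            (r.gene for r in e.variants if r.enhancer_or_promoter), "enhancer-promoter"
        )
        sets["eqtl"] = GeneSet((r.gene for r in e.variants if r.has_eqtl), "eqtl")
    if e.stretch_de is not None:
        sets["stretch_de"] = filter_differential_expression(
            e.stretch_de, c.stretch_fc_threshold, c.stretch_p_threshold, strict=True
        )
    if e.clusters is not None:
        sets["cluster_specific"] = filter_cluster_specific(e.clusters, c.cluster_whitelist)
    if e.diffcorr_genes is not None:
        sets["diffcorr_member"] = e.diffcorr_genes
    return sets


def evidence_tally(
    gene: str,
    evidence: EvidenceBundle,
    config: Optional[FilterConfig] = None,
) -> EvidenceTally:
    """Tally which filters ``gene`` passes across all loaded tables.

    The flag list and equal weighting are this package's explicit
    operationalization of "passed multiple levels of filtering criteria";
    alternative weightings are a caller choice.
    """
    config = config or FilterConfig()
    sym = normalize_symbol(gene)
    sets = _flag_sets(evidence, config)
    if all(s is None for s in sets.values()):
        raise ValueError("at least one evidence table must be loaded")
    if sym not in evidence.universe():
        logger.warning("gene %s absent from every loaded evidence table", sym)
    flags = {name: (s is not None and sym in s) for name, s in sets.items()}
    not_evaluated = tuple(name for name, s in sets.items() if s is None)
    return EvidenceTally(gene=sym, flags=flags, not_evaluated=not_evaluated)


def rank_by_tally(
    genes: Iterable[str],
    evidence: EvidenceBundle,
    config: Optional[FilterConfig] = None,
) -> list[EvidenceTally]:
    """Tally every gene and sort by descending score, ties lexicographic."""
    tallies = [evidence_tally(g, evidence, config) for g in genes]
    return sorted(tallies, key=lambda t: (-t.score, t.gene))
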