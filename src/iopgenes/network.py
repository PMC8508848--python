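"""Differential-correlation network construction and Cytoscape export.

Each significant pair becomes an edge in a simple undirected graph; the
edge weight is -log10(fdr), capped, so more significant pairs are heavier.
Nodes carry their degree and whether they belong to the focus gene set.
Supported interchange formats: SIF, GraphML, and a plain edge TSV, each
re-importable to an identical graph.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .diffcorr import CorrelationPairResult, frame_to_pairs, pairs_to_frame
from .records import GeneSet

DEFAULT_WEIGHT_CAP = 16.0
SIF_INTERACTION = "diffcorr"


def edge_weight(fdr: float, cap: float = DEFAULT_WEIGHT_CAP) -> float:
    """-log10(fdr), capped (fdr of exactly 0 maps to the cap)."""
    if fdr <= 0:
        return cap
    return min(-math.log10(fdr), cap)


def build_network(
    pairs: Sequence[CorrelationPairResult],
    focus_set: Optional[GeneSet] = None,
    weight_cap: float = DEFAULT_WEIGHT_CAP,
) -> nx.Graph:
    """Build the differential-correlation graph from deduplicated pairs."""
    g = nx.Graph()
    for p in pairs:
        if p.gene_a == p.gene_b:
            raise ValueError(f"self-loop pair {p.gene_a}")
        g.add_edge(
            p.gene_a,
            p.gene_b,
            weight=edge_weight(p.fdr, weight_cap),
            z_stat=p.z_stat,
            p=p.p_value,
            fdr=p.fdr,
        )
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
        g.nodes[node]["is_focus"] = bool(focus_set is not None and node in focus_set)
    return g


def top_hubs(g: nx.Graph, k: int) -> list[tuple[str, int]]:
    """The k highest-degree genes, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(g.degree, key=lambda item: (-item[1], item[0]))
    return [(gene, int(deg)) for gene, deg in ranked[:k]]


def annotate_regulator_targets(g: nx.Graph, regulator_table: pd.DataFrame) -> dict[str, int]:
    """Overlap counts between network nodes and a user-supplied
    regulator -> target table (columns: regulator, target)."""
    counts: dict[str, int] = {}
    nodes = set(g.nodes)
    for reg, sub in regulator_table.groupby("regulator"):
        hit = sorted(set(sub["target"]) & nodes)
        counts[str(reg)] = len(hit)
        for gene in hit:
            targets = set(g.nodes[gene].get("regulators", ()))
            targets.add(str(reg))
            g.nodes[gene]["regulators"] = tuple(sorted(targets))
    return counts


def export(g: nx.Graph, fmt: str, path: Union[str, Path]) -> None:
    """Write the network as ``sif``, ``graphml`` or ``edge_tsv``."""
    path = Path(path)
    if fmt == "sif":
        with path.open("w") as fh:
            for a, b in sorted(g.edges):
                fh.write(f"{a}\t{SIF_INTERACTION}\t{b}\n")
            for node in sorted(nx.isolates(g)):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        rows = [
            {"gene_a": a, "gene_b": b, **{k: v for k, v in data.items()}}
            for a, b, data in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_network(fmt: str, path: Union[str, Path]) -> nx.Graph:
    """Re-import a file written by :func:`export`."""
    path = Path(path)
    if fmt == "sif":
        g = nx.Graph()
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) == 3:
                g.add_edge(parts[0], parts[2])
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        attr_cols = [c for c in df.columns if c not in ("gene_a", "gene_b")]
        for row in df.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, **{c: getattr(row, c) for c in attr_cols})
        return g
    raise ValueError(f"unknown import format {fmt!r}")


def pairs_tsv_roundtrip(pairs: Sequence[CorrelationPairResult], path: Union[str, Path]) -> list[CorrelationPairResult]:
    """Convenience: write a pairs TSV and read it back."""
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
    return frame_to_pairs(pd.read_csv(path, sep="\t"))
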