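#!/usr/bin/env python
"""Build the differential-correlation network from the significant pairs
written by 03_diffcorr_simulation.py, report hub genes, and export
Cytoscape-ready SIF/GraphML files."""

import sys
from pathlib import Path

import pandas as pd

from iopgenes import diffcorr as dc, network as net
from iopgenes.records import GeneSet

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pairs_path = RESULTS / "diffcorr_pairs.tsv"
    if not pairs_path.exists():
        sys.exit("run analysis/03_diffcorr_simulation.py first")
    pairs = dc.frame_to_pairs(pd.read_csv(pairs_path, sep="\t"))
    focus = GeneSet((RESULTS / "focus_genes.txt").read_text().split(), "focus")

    g = net.build_network(pairs, focus)
    net.export(g, "graphml", RESULTS / "network.graphml")
    net.export(g, "sif", RESULTS / "network.sif")
    net.export(g, "edge_tsv", RESULTS / "network_edges.tsv")

    print(f"{g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
    print("top hubs (gene, degree):", net.top_hubs(g, 5))
    focus_nodes = sum(1 for n in g.nodes if g.nodes[n]["is_focus"])
    print(f"{focus_nodes} focus genes in the network")


if __name__ == "__main__":
    main()
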