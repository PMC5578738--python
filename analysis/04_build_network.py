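#!/usr/bin/env python
"""Merge the screen's calls with the prior network and classify edges.

Takes the calls table from 02 and the prior plate-screen (ECIA) edge
list, builds the annotated bipartite Beat-Side network, and partitions
edges into new / confirmed / prior_only.  A truly interacting pair whose
bait failed (Beat-Ia::Side in the simulation) is uncallable in the bead
screen and survives only through the prior network — exactly how a
failed orientation should be handled: missing, not fabricated.

Outputs: results/network.tsv, results/network.graphml.
"""

from pathlib import Path

from plexscreen.network_report import (build_network, export_network,
                                       read_calls, read_edge_list,
                                       read_families)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    calls = read_calls(OUT / "screen" / "calls.tsv")
    prior = read_edge_list(ROOT / "data" / "ecia_edges.tsv")
    families = read_families(ROOT / "data" / "families.tsv")
    net = build_network(calls, prior, families)
    export_network(net, OUT / "network.tsv", "tsv")
    export_network(net, OUT / "network.graphml", "graphml")

    groups: dict[str, list] = {"new": [], "confirmed": [], "prior_only": []}
    for a, b, attrs in sorted(net.edges(data=True)):
        groups[attrs["provenance"]].append((a, b))
    print(f"network: {net.number_of_nodes()} proteins, {net.number_of_edges()} edges")
    for prov, edges in groups.items():
        print(f"  {prov} ({len(edges)}):")
        for a, b in edges:
            print(f"    {a}::{b}")
    print(f"wrote {OUT}/network.tsv and network.graphml")


if __name__ == "__main__":
    main()
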