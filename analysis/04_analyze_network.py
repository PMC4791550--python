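#!/usr/bin/env python
"""Stage 4 — read the learned network as regulatory hierarchy.

Ranks hubs by out-degree (the top hub is the candidate master
regulator), classifies nodes as root / intermediate / leaf / isolated,
scores the learned arcs against the simulation's ground truth, and
extracts the radius-1 neighbourhood of the top hub.  Writes node
attributes, GraphML and the hub subnetwork under results/analysis/.
"""

from pathlib import Path

from ctbnet.io import read_sif, write_graphml, write_node_attributes, write_sif
from ctbnet.network import (
    build_graph,
    classify_hierarchy,
    evaluate_structure,
    extract_subnetwork,
    rank_hubs,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "analysis"


def graph_from_sif(path, nodes):
    arcs = read_sif(path)
    return build_graph({v: tuple(sorted(p for p, c in arcs if c == v)) for v in nodes})


def main():
    arcs = read_sif(ROOT / "network" / "network.sif")
    truth_arcs = read_sif(ROOT / "simulated" / "truth_network.sif")
    import pandas as pd

    learned_nodes = set(
        pd.read_csv(ROOT / "network" / "adjacency.tsv", sep="\t")["child"]
    )
    g = build_graph({v: tuple(sorted(p for p, c in arcs if c == v)) for v in learned_nodes})

    OUT.mkdir(parents=True, exist_ok=True)
    write_node_attributes(g, OUT / "node_attributes.tsv")
    write_graphml(g, OUT / "network.graphml")

    hubs = rank_hubs(g)
    classes = classify_hierarchy(g)
    print(f"nodes: {g.number_of_nodes()}  arcs: {g.number_of_edges()}")
    print("hub ranking (gene, out-degree, class):")
    for n in hubs[:5]:
        print(f"  {n}  {g.out_degree(n)}  {classes[n]}")
    by_class = {c: sum(1 for x in classes.values() if x == c) for c in
                ("root", "intermediate", "leaf", "isolated")}
    print(f"hierarchy: {by_class}")

    truth_restricted = {(p, c) for p, c in truth_arcs if p in g and c in g}
    tg = build_graph({v: tuple(sorted(p for p, c in truth_restricted if c == v)) for v in g.nodes})
    ev = evaluate_structure(g, tg)
    print(f"vs ground truth: precision={ev['precision']:.3f} "
          f"recall={ev['recall']:.3f} f1={ev['f1']:.3f}")

    sub = extract_subnetwork(g, [hubs[0]], radius=1)
    write_sif(set(sub.edges), OUT / "top_hub_subnetwork.sif")
    print(f"top-hub neighbourhood: {sub.number_of_nodes()} nodes, "
          f"{sub.number_of_edges()} arcs -> {OUT / 'top_hub_subnetwork.sif'}")


if __name__ == "__main__":
    main()
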