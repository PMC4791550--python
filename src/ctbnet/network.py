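"""Interpretive layer over learned parent sets: the directed regulatory
graph, hub ranking by out-degree, root/intermediate/leaf hierarchy, and
neighbourhood subnetwork extraction.

The hierarchy reading: a regulator that must act throughout the process
sits at the top (root: outgoing arcs only), later or transient
regulators sit in the middle (both incoming and outgoing arcs), and
pure outputs such as cytokines appear as leaves (incoming arcs only).
"""

from __future__ import annotations

import logging

import networkx as nx

from .errors import DataError

__all__ = [
    "build_graph",
    "rank_hubs",
    "classify_hierarchy",
    "extract_subnetwork",
    "evaluate_structure",
    "annotate",
]

log = logging.getLogger(__name__)


def build_graph(parent_sets: dict[str, tuple[str, ...]]) -> nx.DiGraph:
    """Directed graph with one arc per (parent, child) pair.

    The node set covers every variable, including isolated ones.
    Self-loops are rejected (a variable is never its own parent);
    duplicate arcs collapse with a warning.
    """
    g = nx.DiGraph()
    g.add_nodes_from(parent_sets)
    for child, parents in parent_sets.items():
        seen = set()
        for p in parents:
            if p == child:
                raise DataError(f"self-loop on {child}")
            if p in seen:
                log.warning("duplicate arc %s -> %s collapsed", p, child)
                continue
            seen.add(p)
            g.add_edge(p, child)
    return annotate(g)


def annotate(g: nx.DiGraph) -> nx.DiGraph:
    """Recompute node attributes: out_degree, in_degree, hierarchy_class, hub_rank."""
    classes = classify_hierarchy(g)
    ranking = rank_hubs(g)
    rank_of = {n: i + 1 for i, n in enumerate(ranking)}
    for n in g.nodes:
        g.nodes[n]["out_degree"] = g.out_degree(n)
        g.nodes[n]["in_degree"] = g.in_degree(n)
        g.nodes[n]["hierarchy_class"] = classes[n]
        g.nodes[n]["hub_rank"] = rank_of[n]
    return g


def rank_hubs(g: nx.DiGraph) -> list[str]:
    """Nodes ordered by descending out-degree, ties by node id.

    The first element is the network's major hub.
    """
    return sorted(g.nodes, key=lambda n: (-g.out_degree(n), str(n)))


def classify_hierarchy(g: nx.DiGraph) -> dict[str, str]:
    """root: outgoing only; leaf: incoming only; intermediate: both;
    isolated: neither."""
    out = {}
    for n in g.nodes:
        i, o = g.in_degree(n), g.out_degree(n)
        if o >= 1 and i == 0:
            out[n] = "root"
        elif i >= 1 and o == 0:
            out[n] = "leaf"
        elif i >= 1 and o >= 1:
            out[n] = "intermediate"
        else:
            out[n] = "isolated"
    return out


def extract_subnetwork(g: nx.DiGraph, genes, radius: int = 0) -> nx.DiGraph:
    """Induced subgraph on the listed genes plus all neighbours within
    ``radius`` arcs (either direction); attributes are recomputed on the
    subgraph.  Missing gene ids are reported, not fatal."""
    present = [x for x in genes if x in g]
    missing = [x for x in genes if x not in g]
    if missing:
        log.warning("extract_subnetwork: ids not in network: %s", missing)
    if not present:
        return annotate(nx.DiGraph())
    nodes = set(present)
    frontier = set(present)
    undirected = g.to_undirected(as_view=True)
    for _ in range(radius):
        frontier = {m for n in frontier for m in undirected.neighbors(n)} - nodes
        nodes |= frontier
    sub = g.subgraph(nodes).copy()
    return annotate(sub)


def evaluate_structure(inferred: nx.DiGraph, truth: nx.DiGraph) -> dict[str, float]:
    """Direction-sensitive arc precision/recall/F1.

    Conventions: with no true arcs recall = 1; with no inferred arcs
    precision = 1; F1 = 0 only when both precision and recall are 0.
    """
    if set(inferred.nodes) != set(truth.nodes):
        only_i = sorted(set(inferred.nodes) - set(truth.nodes))
        only_t = sorted(set(truth.nodes) - set(inferred.nodes))
        raise DataError(
            f"node universes differ: only-inferred {only_i[:5]}, only-truth {only_t[:5]}"
        )
    inf_arcs = set(inferred.edges)
    true_arcs = set(truth.edges)
    tp = len(inf_arcs & true_arcs)
    fp = len(inf_arcs - true_arcs)
    fn = len(true_arcs - inf_arcs)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }
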