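#!/usr/bin/env python
"""Stage 3 — learn the regulatory network by CTBN structure search.

Converts each replicate's discretized state series into a
piecewise-constant trajectory, pools sufficient statistics, and runs
greedy hill-climbing over parent sets with the Bayesian marginal-
likelihood score (alpha=0.01, tau=5 h, max 5 parents).  Writes the
learned arc list (SIF) and per-family scores under results/network/.
"""

from pathlib import Path

from ctbnet.io import read_states, write_adjacency, write_sif, write_trajectories
from ctbnet.learn import LearnConfig, TrajectoryData, greedy_structure_search, trajectory_from_observations

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "network"


def main():
    states = read_states(ROOT / "preprocess" / "states.tsv")
    trajectories = [
        trajectory_from_observations(states.replicate_matrix(r).to_numpy(), states.times, states.genes)
        for r in states.replicates
    ]
    config = LearnConfig()  # alpha=0.01, tau=5, max_parents=5
    data = TrajectoryData(trajectories, {g: 3 for g in states.genes})
    result = greedy_structure_search(data, config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_sif(result.arcs(), OUT / "network.sif")
    write_adjacency(result, OUT / "adjacency.tsv")
    write_trajectories(dict(enumerate(trajectories, 1)), OUT / "trajectories.tsv")
    print(f"learned network: {len(states.genes)} nodes, {len(result.arcs())} arcs")
    print(f"total log score: {result.score:.3f}")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
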