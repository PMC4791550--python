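#!/usr/bin/env python
"""Stage 1 — generate the synthetic differentiation study.

Emulates the study design the pipeline targets: a case (polarised) and
control (unstimulated) condition measured at 10 unevenly spaced time
points over 72 h in three biological replicates, with 10 signal genes
driven by a known ground-truth CTBN, 5 unregulated null genes and 5
undetected background probes.  Writes the expression bundle, the
ground-truth network and the ground-truth discretized states under
results/simulated/.
"""

from pathlib import Path

from ctbnet import GeneratorConfig, simulate_study
from ctbnet.io import write_bundle, write_sif, write_states
from ctbnet.preprocessing import DiscreteStateMatrix

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"

CONFIG = GeneratorConfig(
    n_genes=10,
    max_true_parents=2,
    noise_sd=0.1,
    n_null_genes=5,
    n_undetected_probes=5,
    seed=2016,
)


def main():
    study = simulate_study(CONFIG)
    write_bundle(study["bundle"], OUT)
    write_sif(study["model"].arcs(), OUT / "truth_network.sif")
    write_states(DiscreteStateMatrix(study["truth_states"]), OUT / "truth_states.tsv")
    n_arcs = len(study["model"].arcs())
    print(f"simulated {len(study['bundle'].values)} probes "
          f"({CONFIG.n_genes} signal, {CONFIG.n_null_genes} null, "
          f"{CONFIG.n_undetected_probes} undetected)")
    print(f"ground-truth network: {CONFIG.n_genes} nodes, {n_arcs} arcs")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
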