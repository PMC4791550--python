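#!/usr/bin/env python
"""Stage 2 — filter, test and discretize the simulated expression.

Applies the preprocessing chain: detection and SD filters, per-time
Welch t-tests with BH correction, selection of genes with q < 0.05 and
|log2 FC| > 1 at some time point, three-bin discretization at +/-1, and
removal of constant genes.  Prints the probe/gene accounting at each
step and writes the discrete state matrix under results/preprocess/.
"""

from pathlib import Path

from ctbnet.io import read_bundle, write_matrix, write_states
from ctbnet.preprocessing import preprocess

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = ROOT / "simulated", ROOT / "preprocess"


def main():
    bundle = read_bundle(SIM / "expression.tsv", SIM / "samples.tsv", SIM / "detection_p.tsv")
    pp = preprocess(bundle)
    OUT.mkdir(parents=True, exist_ok=True)
    write_states(pp["states"], OUT / "states.tsv")
    write_matrix(pp["fc"].loc[pp["states"].genes], OUT / "fold_change.tsv")
    write_matrix(pp["q"].loc[pp["states"].genes], OUT / "qvalues.tsv")
    rep = pp["filter_report"]
    print(f"input probes:            {rep['input']}")
    print(f"removed (not detected):  {rep['removed_detection']}")
    print(f"removed (SD < 0.15):     {rep['removed_sd']}")
    print(f"retained after filters:  {rep['retained']}")
    print(f"selected (DE & |FC|>1):  {len(pp['selected'])}")
    print(f"dropped (constant bin):  {len(pp['dropped_constant'])}")
    print(f"final genes:             {len(pp['states'].genes)}")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
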