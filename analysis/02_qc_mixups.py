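#!/usr/bin/env python
"""Detect mislabeled mice by comparing the two haplotype reconstructions.

Computes the per-mouse mean Euclidean distance dbar between array-based and
expression-based founder probabilities, flags dbar > 0.8, and cross-matches
flagged mice to identify swapped ID pairs. Writes results/qc/mixups.tsv.
"""

import pandas as pd

from agingomics import io
from agingomics.mixups import qc_mixups

COHORT = "results/cohort"
OUT = "results/qc"


def main():
    array = io.read_probs(f"{COHORT}/probs.h5", f"{COHORT}/markers.tsv")
    expr = io.read_probs(f"{COHORT}/probs_expr.h5", f"{COHORT}/markers.tsv")
    report = qc_mixups(array, expr, threshold=0.8)
    io.ensure_dir(OUT)
    report.to_csv(f"{OUT}/mixups.tsv", sep="\t", index=False)
    flagged = report[report["flagged"]]
    print(f"{len(flagged)} of {len(report)} mice flagged (dbar > 0.8):")
    if len(flagged):
        print(flagged.to_string(index=False))
    swaps = flagged[flagged["resolution"] == "swap_candidate"]
    print(f"{len(swaps) // 2} mutual swap pair(s) identified")


if __name__ == "__main__":
    main()
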