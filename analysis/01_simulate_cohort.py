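#!/usr/bin/env python
"""Generate the synthetic DO-like aging cohort used by all later steps.

Writes the full cohort — sample table, founder-probability genomes,
expression-derived (noisy, swap-planted) genomes, transcript counts, peptide
intensities, complex catalog and ground truth — under results/cohort/.
"""

import sys

from agingomics import io
from agingomics.config import SimConfig
from agingomics.simulate import simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = "results/cohort"


def main():
    cfg = SimConfig.default_planted()
    s = simulate_cohort(cfg, SEED)
    io.ensure_dir(OUT)
    io.write_samples(s["samples"], f"{OUT}/samples.tsv")
    io.write_matrix(s["counts"], f"{OUT}/counts.tsv.gz")
    s["peptides"].to_csv(f"{OUT}/peptides.tsv.gz", sep="\t", index=False)
    io.write_probs(s["genomes"], f"{OUT}/probs.h5", f"{OUT}/markers.tsv")
    io.write_probs(s["expression_probs"], f"{OUT}/probs_expr.h5")
    s["complexes"].to_csv(f"{OUT}/complexes.tsv", sep="\t", index=False)
    s["gene_map"].to_csv(f"{OUT}/gene_map.tsv", sep="\t", index=False)
    tr = s["truth"]
    io.write_json({"age_log2fc": tr.age_log2fc, "sex_log2fc": tr.sex_log2fc,
                   "complex_decay": tr.complex_decay,
                   "interactions": [list(i) for i in tr.interactions],
                   "swapped_pairs": [list(p) for p in tr.swapped_pairs]},
                  f"{OUT}/truth.json")
    print(f"cohort: {len(s['samples'])} mice, {len(s['counts'])} genes, "
          f"{len(s['peptides'])} peptides, "
          f"{s['genomes'].n_markers} markers -> {OUT}/")
    print(f"planted: {len(tr.age_log2fc)} age slopes, "
          f"{len(tr.complex_decay)} decaying complexes, "
          f"{len(tr.interactions)} age-QTL, {len(tr.swapped_pairs)} ID swaps")


if __name__ == "__main__":
    main()
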