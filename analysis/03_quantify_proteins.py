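#!/usr/bin/env python
"""Peptide-to-protein quantification.

Filters polymorphic peptides (allele-effect correlation >= 0.7 with the
reference-sharing pattern), rolls peptides up to log2 protein abundance with
within-batch sample scaling, drops proteins missing in more than half the
mice, removes batch BLUPs, and writes both raw and rank-normalized matrices.
"""

import pandas as pd

from agingomics import io
from agingomics.proteomics import quantify

COHORT = "results/cohort"
OUT = "results/proteins"


def main():
    peptides = io.read_peptides(f"{COHORT}/peptides.tsv.gz")
    samples = io.read_samples(f"{COHORT}/samples.tsv")
    genomes = io.read_probs(f"{COHORT}/probs.h5", f"{COHORT}/markers.tsv")
    gene_map = pd.read_csv(f"{COHORT}/gene_map.tsv", sep="\t")
    q = quantify(peptides, samples, genomes=genomes, gene_map=gene_map,
                 r_cut=0.7)
    io.ensure_dir(OUT)
    io.write_matrix(q["abundance"], f"{OUT}/proteins.tsv.gz", "protein_id")
    io.write_matrix(q["rank_normal"], f"{OUT}/proteins_rankz.tsv.gz", "protein_id")
    q["polymorphic_report"].to_csv(f"{OUT}/polymorphic_peptides.tsv",
                                   sep="\t", index=False)
    rep = q["polymorphic_report"]
    print(f"peptides in: {len(peptides)}; polymorphic candidates: {len(rep)}; "
          f"dropped: {int(rep['dropped'].sum())}")
    print(f"proteins quantified after missingness filter: {len(q['abundance'])}")


if __name__ == "__main__":
    main()
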