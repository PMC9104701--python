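#!/usr/bin/env python
"""Per-gene age effects on transcripts (NB GLM + LRT) and proteins (OLS + F).

Age is continuous in years (6/12/18 mo -> 0.5/1/1.5), so every slope is a
log2 fold change per year. Writes results/age_effects/age_effects.tsv and the
transcript-protein concordance by age group.
"""

import pandas as pd

from agingomics import io
from agingomics.age_effects import (filter_transcripts, fit_transcript_age,
                                    fit_protein_age, normalize_counts,
                                    concordance_by_age)

COHORT = "results/cohort"
OUT = "results/age_effects"


def main():
    counts = io.read_matrix(f"{COHORT}/counts.tsv.gz")
    samples = io.read_samples(f"{COHORT}/samples.tsv")
    proteins = io.read_matrix("results/proteins/proteins.tsv.gz")

    counts = filter_transcripts(counts)
    print(f"transcripts passing the >= half-of-samples filter: {len(counts)}")
    de_t = fit_transcript_age(counts, samples, test="age", fdr=0.01)
    de_p = fit_protein_age(proteins, samples, test="age", fdr=0.01)
    io.ensure_dir(OUT)
    res = pd.concat([de_t, de_p], ignore_index=True)
    res.to_csv(f"{OUT}/age_effects.tsv", sep="\t", index=False)
    print(f"transcripts with age effect at FDR<0.01: {int(de_t['significant'].sum())}"
          f" of {len(de_t)}")
    print(f"proteins with age effect at FDR<0.01: {int(de_p['significant'].sum())}"
          f" of {len(de_p)}")

    norm, _ = normalize_counts(counts)
    table, medians = concordance_by_age(norm, proteins, samples)
    table.to_csv(f"{OUT}/concordance_by_age.tsv", sep="\t", index=False)
    print("median transcript-protein r by age group:")
    print(medians.round(3).to_string())


if __name__ == "__main__":
    main()
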