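#!/usr/bin/env python
"""Age-interactive QTL scans with residual-permutation thresholds.

Rank-normalizes expression, runs kinship-aware (LOCO) interactive genome
scans for the planted-interaction genes plus a background panel, derives the
genome-wide LOD_int threshold from residual permutations, calls peaks
(local/distal), and screens 4-Mb windows for distal hotspots.
"""

import json

import numpy as np
import pandas as pd

from agingomics import io
from agingomics.age_effects import filter_transcripts, normalize_counts
from agingomics.proteomics import rank_normal
from agingomics.qtl import (compute_kinship, GenomeScanner,
                            pooled_permutation_threshold, call_age_qtl_peaks,
                            find_hotspots, refine_hotspot_members)

COHORT = "results/cohort"
OUT = "results/age_qtl"
SEED = 11
N_PERM = 200
SUGGESTIVE = 6.0


def main():
    counts = filter_transcripts(io.read_matrix(f"{COHORT}/counts.tsv.gz"))
    samples = io.read_samples(f"{COHORT}/samples.tsv")
    genomes = io.read_probs(f"{COHORT}/probs.h5", f"{COHORT}/markers.tsv")
    gene_map = pd.read_csv(f"{COHORT}/gene_map.tsv", sep="\t")
    truth = json.load(open(f"{COHORT}/truth.json"))

    norm, _ = normalize_counts(counts)
    phen = rank_normal(norm)
    kin = compute_kinship(genomes, mode="loco")
    male = (samples["sex"] == "M").to_numpy(float)
    age = samples["age_years"].to_numpy()
    X = np.column_stack([np.ones(len(samples)), male, age])
    scanner = GenomeScanner(genomes, kin, X, age)

    planted = [g for g, *_ in truth["interactions"]]
    background = [g for g in phen.index[:20] if g not in planted]
    ids = planted + background
    scans = {pid: scanner.scan(phen.loc[pid].to_numpy(), interactive=True)
             for pid in ids}
    thr, _ = pooled_permutation_threshold(phen.loc[ids], genomes, kin, X, age,
                                          B=N_PERM, seed=SEED)
    print(f"genome-wide LOD_int threshold (GWER 0.05, {N_PERM} residual "
          f"permutations, pooled): {thr:.2f}")

    peaks = call_age_qtl_peaks(scans, thr, SUGGESTIVE, gene_map)
    hotspots = find_hotspots(peaks)
    if len(hotspots):
        hotspots["refined_members"] = [
            ",".join(refine_hotspot_members(m.split(","), phen))
            for m in hotspots["members"]]
    io.ensure_dir(OUT)
    peaks.to_csv(f"{OUT}/peaks.tsv", sep="\t", index=False)
    hotspots.to_csv(f"{OUT}/hotspots.tsv", sep="\t", index=False)
    io.write_json({"lod_int_threshold": thr, "suggestive": SUGGESTIVE},
                  f"{OUT}/thresholds.json")
    print(f"{len(peaks)} peaks above the suggestive level "
          f"({int(peaks['significant'].sum())} significant):")
    if len(peaks):
        print(peaks[["phenotype_id", "marker_id", "lod_int", "class",
                     "significant"]].round(2).to_string(index=False))
    print(f"hotspots (> 30 distal age-QTL in a 4-Mb window): {len(hotspots)}")


if __name__ == "__main__":
    main()
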