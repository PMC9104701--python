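"""End-to-end pipeline orchestration: stage sequencing, manifest, validation.

Runs simulate -> qc-mixups -> quantify -> age-effects -> stoichiometry ->
scans over a synthetic cohort, writing every intermediate table plus a
manifest with seeds, input hashes and per-stage row counts. Re-runs skip
stages whose outputs already exist unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .simulate import simulate_cohort
from .mixups import qc_mixups
from .proteomics import quantify, rank_normal
from .age_effects import filter_transcripts, normalize_counts, fit_transcript_age, fit_protein_age
from .stoichiometry import analyze_stoichiometry
from .qtl import (compute_kinship, GenomeScanner, pooled_permutation_threshold,
                  call_age_qtl_peaks, find_hotspots, refine_hotspot_members)

log = logging.getLogger(__name__)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest."""
    config.validate()
    out = io.ensure_dir(config.out_dir)
    manifest_path = os.path.join(out, "manifest.json")
    manifest = {"seed": config.seed, "stages": {}, "thresholds": config.thresholds}
    if os.path.exists(manifest_path) and not config.force:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        manifest.setdefault("stages", {})

    def done(stage, outputs):
        rec = manifest["stages"].get(stage)
        return (not config.force and rec is not None
                and all(os.path.exists(os.path.join(out, p)) for p in outputs))

    def record(stage, outputs, counts, t0):
        manifest["stages"][stage] = {
            "outputs": outputs,
            "hashes": {p: _hash_file(os.path.join(out, p)) for p in outputs},
            "counts": counts,
            "seconds": round(time.time() - t0, 2),
        }
        io.write_json(manifest, manifest_path)

    th = config.thresholds
    sim = None

    def get_sim():
        nonlocal sim
        if sim is None:
            sim = simulate_cohort(config.sim, config.seed)
        return sim

    # --- simulate ------------------------------------------------------
    stage = "simulate"
    outputs = ["samples.tsv", "counts.tsv.gz", "peptides.tsv.gz", "probs.h5",
               "markers.tsv", "complexes.tsv", "gene_map.tsv", "truth.json"]
    if stage in config.stages and not done(stage, outputs):
        t0 = time.time()
        s = get_sim()
        io.write_samples(s["samples"], f"{out}/samples.tsv")
        io.write_matrix(s["counts"], f"{out}/counts.tsv.gz")
        s["peptides"].to_csv(f"{out}/peptides.tsv.gz", sep="\t", index=False)
        io.write_probs(s["genomes"], f"{out}/probs.h5", f"{out}/markers.tsv")
        io.write_probs(s["expression_probs"], f"{out}/probs_expr.h5")
        s["complexes"].to_csv(f"{out}/complexes.tsv", sep="\t", index=False)
        s["gene_map"].to_csv(f"{out}/gene_map.tsv", sep="\t", index=False)
        tr = s["truth"]
        io.write_json({"age_log2fc": tr.age_log2fc, "sex_log2fc": tr.sex_log2fc,
                       "complex_decay": tr.complex_decay,
                       "interactions": [list(i) for i in tr.interactions],
                       "swapped_pairs": [list(p) for p in tr.swapped_pairs]},
                      f"{out}/truth.json")
        record(stage, outputs, {"n_samples": len(s["samples"]),
                                "n_genes": len(s["counts"]),
                                "n_peptides": len(s["peptides"])}, t0)

    # --- qc mixups -----------------------------------------------------
    stage = "qc_mixups"
    if stage in config.stages and not done(stage, ["mixups.tsv"]):
        t0 = time.time()
        s = get_sim()
        report = qc_mixups(s["genomes"], s["expression_probs"],
                           threshold=th["dbar_cut"])
        report.to_csv(f"{out}/mixups.tsv", sep="\t", index=False)
        record(stage, ["mixups.tsv"],
               {"n_flagged": int(report["flagged"].sum())}, t0)

    # --- quantify ------------------------------------------------------
    stage = "quantify"
    if stage in config.stages and not done(stage, ["proteins.tsv.gz"]):
        t0 = time.time()
        s = get_sim()
        try:
            q = quantify(s["peptides"], s["samples"], genomes=s["genomes"],
                         gene_map=s["gene_map"], r_cut=th["r_cut"])
        except Exception as exc:
            raise PipelineError(stage, str(exc))
        io.write_matrix(q["abundance"], f"{out}/proteins.tsv.gz", "protein_id")
        io.write_matrix(q["rank_normal"], f"{out}/proteins_rankz.tsv.gz", "protein_id")
        record(stage, ["proteins.tsv.gz"],
               {"n_proteins": len(q["abundance"])}, t0)

    # --- age effects ---------------------------------------------------
    stage = "age_effects"
    if stage in config.stages and not done(stage, ["age_effects.tsv"]):
        t0 = time.time()
        try:
            counts = io.read_matrix(f"{out}/counts.tsv.gz")
            samples = io.read_samples(f"{out}/samples.tsv")
            proteins = io.read_matrix(f"{out}/proteins.tsv.gz")
        except Exception as exc:
            raise PipelineError(stage, f"cannot read stage inputs: {exc}")
        counts = filter_transcripts(counts)
        de_t = fit_transcript_age(counts, samples, test="age", fdr=th["fdr_de"])
        de_p = fit_protein_age(proteins, samples, test="age", fdr=th["fdr_de"])
        res = pd.concat([de_t, de_p], ignore_index=True)
        res.to_csv(f"{out}/age_effects.tsv", sep="\t", index=False)
        record(stage, ["age_effects.tsv"],
               {"transcripts_tested": len(de_t), "proteins_tested": len(de_p),
                "transcripts_fdr": int(de_t["significant"].sum()),
                "proteins_fdr": int(de_p["significant"].sum())}, t0)

    # --- stoichiometry -------------------------------------------------
    stage = "stoichiometry"
    if stage in config.stages and not done(stage, ["stoich_complexes.tsv"]):
        t0 = time.time()
        proteins = io.read_matrix(f"{out}/proteins.tsv.gz")
        samples = io.read_samples(f"{out}/samples.tsv")
        catalog = pd.read_csv(f"{out}/complexes.tsv", sep="\t")
        res = analyze_stoichiometry(proteins, catalog, samples,
                                    B=config.stoich_permutations,
                                    seed=config.seed,
                                    fdr_pairs=th["fdr_pairs"],
                                    complex_p=th["complex_p"])
        res["pairs"].to_csv(f"{out}/stoich_pairs.tsv", sep="\t", index=False)
        res["perm_pairs"].to_csv(f"{out}/stoich_pair_pvalues.tsv", sep="\t", index=False)
        res["complexes"].to_csv(f"{out}/stoich_complexes.tsv", sep="\t", index=False)
        record(stage, ["stoich_complexes.tsv"],
               {"n_complexes": len(res["complexes"])}, t0)

    # --- scans ---------------------------------------------------------
    stage = "scan"
    if stage in config.stages and not done(stage, ["age_qtl_peaks.tsv"]):
        t0 = time.time()
        s = get_sim()
        samples = s["samples"]
        counts = filter_transcripts(s["counts_clean"])
        norm, _ = normalize_counts(counts)
        phen = rank_normal(norm)
        # scan the planted-interaction genes plus a background set
        planted = [g for g, *_ in s["truth"].interactions]
        background = [g for g in phen.index[:20] if g not in planted]
        ids = planted + background
        kin = compute_kinship(s["genomes"], mode="loco")
        male = (samples["sex"] == "M").to_numpy(float)
        age = samples["age_years"].to_numpy(float)
        X = np.column_stack([np.ones(len(samples)), male, age])
        scanner = GenomeScanner(s["genomes"], kin, X, age)
        scans = {}
        for pid in ids:
            y = phen.loc[pid].to_numpy(float)
            scans[pid] = scanner.scan(y, interactive=True)
        threshold, _ = pooled_permutation_threshold(
            phen.loc[ids], s["genomes"], kin, X, age,
            B=config.n_permutations, seed=config.seed)
        peaks = call_age_qtl_peaks(scans, threshold, th["lod_suggestive"],
                                   s["gene_map"], th["local_window_bp"])
        hotspots = find_hotspots(peaks, th["window_bp"], th["step_bp"],
                                 int(th["hotspot_min"]))
        if len(hotspots):
            hotspots["refined_members"] = [
                ",".join(refine_hotspot_members(m.split(","), phen))
                for m in hotspots["members"]]
        peaks.to_csv(f"{out}/age_qtl_peaks.tsv", sep="\t", index=False)
        hotspots.to_csv(f"{out}/hotspots.tsv", sep="\t", index=False)
        io.write_json({"lod_int_threshold": threshold,
                       "suggestive": th["lod_suggestive"]}, f"{out}/thresholds.json")
        record(stage, ["age_qtl_peaks.tsv"],
               {"n_scanned": len(ids), "n_peaks": len(peaks),
                "threshold": threshold}, t0)

    io.write_json(manifest, manifest_path)
    return manifest


def validate_inputs(paths: dict) -> list:
    """Cross-check format dialects and ID consistency; returns violations."""
    violations = []
    samples = None
    if "samples" in paths:
        try:
            samples = io.read_samples(paths["samples"])
            for col in ("sample_id", "sex", "age_months", "generation", "batch"):
                if col not in samples.columns:
                    violations.append(f"samples: missing column {col!r}")
        except Exception as exc:
            violations.append(f"samples: unreadable ({exc})")
    for key in ("counts", "proteins"):
        if key not in paths:
            continue
        try:
            mat = io.read_matrix(paths[key])
        except Exception as exc:
            violations.append(f"{key}: unreadable ({exc})")
            continue
        if samples is not None:
            extra = set(mat.columns) - set(samples["sample_id"])
            for s in sorted(extra):
                violations.append(f"{key}: sample {s!r} absent from samples table")
    if "probs" in paths and "markers" in paths:
        try:
            probs = io.read_probs(paths["probs"], paths["markers"])
            sums = probs.probs.sum(axis=2)
            bad = np.argwhere(np.abs(sums - 1.0) > 1e-6)
            for m, s in bad[:20]:
                violations.append(
                    f"probs: row (marker={probs.markers['marker_id'].iloc[m]}, "
                    f"sample={probs.sample_ids[s]}) sums to {sums[m, s]:.4f}")
            for c, sub in probs.markers.groupby("chromosome", sort=False):
                if not (np.diff(sub["position_bp"].to_numpy()) > 0).all():
                    violations.append(f"markers: positions not increasing on {c}")
        except Exception as exc:
            violations.append(f"probs: unreadable ({exc})")
    return violations
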