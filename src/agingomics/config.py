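"""Configuration objects for the synthetic cohort generator and the pipeline.

The synthetic cohort emulates a cross-sectional Diversity Outbred (DO) mouse
aging study: three age groups (6, 12, 18 months), both sexes, five breeding
generations, 8-founder mosaic genomes, TMT-style batched proteomics, and
planted ground-truth effects (age slopes, sex effects, complex-correlation
decay, age-by-genotype interactions, sample swaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

#: DO founder strain letters in conventional order.
FOUNDERS = ("A", "B", "C", "D", "E", "F", "G", "H")
FOUNDER_NAMES = ("AJ", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")
#: Index of the reference strain (B6) in the founder order.
REFERENCE_FOUNDER = 1

AGE_MONTHS = (6, 12, 18)


def subseed(seed: int, name: str) -> np.random.Generator:
    """Return an RNG stream derived from ``seed`` and a stable operation name.

    Each generator operation draws from its own named stream so that adding
    or reordering operations never perturbs the randomness of the others.
    """
    h = np.frombuffer(name.encode("utf8"), dtype=np.uint8)
    key = int(np.uint32(np.sum(h.astype(np.uint64) * 1000003 ** np.arange(h.size, dtype=np.uint64) % (2**32))))
    return np.random.default_rng(np.random.SeedSequence((int(seed) % (2**31), key)))


@dataclass
class SimConfig:
    """Parameters of the synthetic DO-like cohort.

    Defaults mirror the design of the emulated study: 185 mice in three age
    groups (33F/29M at 6 mo, 31F/31M at 12 mo, 27F/34M at 18 mo), five
    generations, and 19 proteomics batches of up to 10 mice.
    """

    # cohort
    age_group_counts: dict = field(
        default_factory=lambda: {6: (33, 29), 12: (31, 31), 18: (27, 34)}
    )  # age_months -> (n_female, n_male)
    n_generations: int = 5

    # genome
    n_chromosomes: int = 10
    markers_per_chromosome: int = 40
    chromosome_length: float = 100e6  # bp
    recomb_prob: float = 0.05  # per adjacent-marker interval, per haplotype
    prob_noise: float = 0.0  # symmetric blur on probability rows

    # transcripts
    n_genes: int = 300
    base_mean: float = 100.0
    dispersion_range: tuple = (0.05, 0.3)
    size_factor_log_sd: float = 0.25
    generation_log2_sd: float = 0.05

    # proteomics
    n_complexes: int = 12
    complex_size_range: tuple = (4, 20)
    n_peptides_per_protein: tuple = (2, 8)
    n_batches: int = 19
    batch_size: int = 10
    polymorphic_peptide_fraction: float = 0.1
    base_complex_r: float = 0.8  # within-complex correlation at 6 mo
    protein_transcript_rho: float = 0.0  # within-age-group coupling of protein
    # residual noise to the gene's transcript level (0 = independent layers)
    protein_noise_sd: float = 0.2  # log2 units, per (protein, sample)
    peptide_noise_sd: float = 0.2  # log2 units, per (peptide, sample)
    batch_log2_sd: float = 0.5  # batch shifts on peptide intensities
    loading_log2_sd: float = 0.3  # per-sample loading heterogeneity
    peptide_missing_rate: float = 0.05

    # planted effects (ground truth)
    age_effects: Sequence = ()  # (gene_id, log2fc_per_year)
    sex_effects: Sequence = ()  # (gene_id, log2fc_male_vs_female)
    complex_decays: Sequence = ()  # (complex_id, delta_r_per_year)
    interactions: Sequence = ()  # (gene_id, marker_id, log2_effect_per_year)
    n_sample_swaps: int = 2
    expression_prob_noise: float = 0.05  # blur on expression-derived haplotypes

    seed: int = 0

    @property
    def n_mice(self) -> int:
        return sum(f + m for f, m in self.age_group_counts.values())

    def validate(self) -> None:
        if self.markers_per_chromosome <= 0 or self.n_chromosomes <= 0:
            raise ValueError("marker and chromosome counts must be positive")
        for p in (self.recomb_prob, self.prob_noise, self.polymorphic_peptide_fraction,
                  self.peptide_missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        for c in (self.n_generations, self.n_genes, self.n_batches, self.batch_size):
            if c <= 0:
                raise ValueError("all counts must be positive")
        if 2 * self.n_sample_swaps > self.n_mice:
            raise ValueError("more swapped samples than mice")

    @classmethod
    def default_planted(cls, **kwargs) -> "SimConfig":
        """Config with a standard set of planted effects for end-to-end runs.

        Plants age slopes on 15 genes, sex effects on 10, correlation decay of
        -0.2/yr on three complexes, and two age-by-genotype interactions.
        Planted gene indices are disjoint from complex members (complexes are
        assigned from gene_000 upward) so each signal is read out cleanly.
        """
        cfg = cls(**kwargs)
        lo = 200  # leave low indices for complex membership
        cfg.age_effects = tuple(
            (f"gene_{lo + i:03d}", fc)
            for i, fc in enumerate([1.0, -1.0, 0.5, -0.5, 0.75] * 3)
        )
        cfg.sex_effects = tuple(
            (f"gene_{lo + 20 + i:03d}", fc) for i, fc in enumerate([0.8, -0.8] * 5)
        )
        cfg.complex_decays = (("complex_00", -0.2), ("complex_01", -0.2), ("complex_02", -0.1))
        # strong interactions: after partialling out the additive dosage and
        # age main effects, var(dosage x age) is small, so a slope contrast of
        # ~3 log2/yr between allele groups is what makes an age-QTL stand
        # clear of the genome-wide LOD_int noise floor at n = 185
        cfg.interactions = (
            (f"gene_{lo + 40:03d}", "chr3_m19", 3.0),
            (f"gene_{lo + 41:03d}", "chr7_m09", 3.0),
        )
        return cfg


DEFAULT_THRESHOLDS = {
    "fdr_de": 0.01,
    "fdr_pairs": 0.1,
    "complex_p": 0.05,
    "r_cut": 0.7,
    "dbar_cut": 0.8,
    "lod_suggestive": 6.0,
    "hotspot_min": 30,
    "window_bp": 4e6,
    "step_bp": 1e6,
    "local_window_bp": 1e7,
}


@dataclass
class PipelineConfig:
    """End-to-end run configuration: paths, stage toggles, thresholds, seed."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: Sequence[str] = ("simulate", "qc_mixups", "quantify", "age_effects",
                             "stoichiometry", "scan")
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    n_permutations: int = 200
    stoich_permutations: int = 200
    force: bool = False
    sim: SimConfig = field(default_factory=SimConfig.default_planted)

    def validate(self) -> None:
        for k, v in self.thresholds.items():
            if k not in DEFAULT_THRESHOLDS:
                raise ValueError(f"unknown threshold name: {k!r}")
            if v <= 0:
                raise ValueError(f"threshold {k} must be positive")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            sim_known = set(SimConfig.__dataclass_fields__)
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            if "age_group_counts" in sim_raw:
                sim_raw["age_group_counts"] = {
                    int(k): tuple(v) for k, v in sim_raw["age_group_counts"].items()
                }
            cfg.sim = SimConfig(**sim_raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        import json
        d = json.loads(json.dumps(asdict(self)))  # tuples -> lists for YAML
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
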