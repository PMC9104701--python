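"""Synthetic DO-like cohort generator with known ground truth.

Generates every input the pipeline consumes: 8-founder mosaic genomes as
founder-allele probability arrays, a sample table with age/sex/generation/
batch structure, negative-binomial transcript counts with linear-in-age
log2 fold changes, batch-structured peptide intensity tables with
founder-polymorphic dropout, protein-complex co-abundance whose within-complex
correlation declines linearly with age, and planted sample-ID swaps.

Every operation is a pure function of (config, seed); each draws from its own
named RNG stream so adding one operation never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimConfig, AGE_MONTHS, REFERENCE_FOUNDER, subseed

N_FOUNDERS = 8


@dataclass
class GenotypeProbs:
    """Founder-allele probabilities per marker per sample.

    probs has shape (n_markers, n_samples, 8); each (marker, sample) row is a
    probability vector over the eight founders. ``truth`` holds the underlying
    diplotype (two founder indices) when the object comes from the simulator.
    """

    markers: pd.DataFrame  # marker_id, chromosome, position_bp (ordered)
    sample_ids: list
    probs: np.ndarray  # (M, N, 8)
    truth: Optional[np.ndarray] = None  # (M, N, 2) founder indices

    def __post_init__(self):
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return self.probs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.probs.shape[1]

    def chromosome_index(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(self.markers["chromosome"].to_numpy() == chromosome)

    def dosages(self, marker_id: str) -> np.ndarray:
        """(N, 8) founder dosage (probability) rows at one marker."""
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return self.probs[idx[0]]

    def validate(self, atol: float = 1e-8) -> None:
        rows = self.probs.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=atol):
            raise ValueError("founder probability rows do not sum to 1")
        if (self.probs < -atol).any():
            raise ValueError("negative founder probabilities")
        for _, sub in self.markers.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("marker positions not strictly increasing")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream recovery checks."""

    gene_ids: list
    age_log2fc: dict = field(default_factory=dict)  # gene -> log2fc / year
    sex_log2fc: dict = field(default_factory=dict)  # gene -> log2fc (M vs F)
    generation_log2: Optional[pd.DataFrame] = None  # gene x generation offsets
    interactions: list = field(default_factory=list)  # (gene, marker, effect, alt founder set)
    complex_decay: dict = field(default_factory=dict)  # complex -> delta r / year
    complex_base_r: dict = field(default_factory=dict)
    variant_masks: Optional[pd.Series] = None  # peptide_id -> 8-char 0/1 string
    swapped_pairs: list = field(default_factory=list)  # (sample_a, sample_b)
    sample_loading_log2: Optional[pd.Series] = None
    batch_shift_log2: Optional[pd.Series] = None
    latent_protein_log2: Optional[pd.DataFrame] = None  # genes x samples

    def check_references(self, genes, complexes, markers) -> None:
        for g in list(self.age_log2fc) + list(self.sex_log2fc):
            if g not in genes:
                raise ValueError(f"planted effect on unknown gene {g!r}")
        for c in self.complex_decay:
            if c not in complexes:
                raise ValueError(f"planted decay on unknown complex {c!r}")
        for g, m, *_ in self.interactions:
            if g not in genes or m not in markers:
                raise ValueError(f"planted interaction refers to unknown gene/marker ({g}, {m})")


def simulate_samples(config: SimConfig, seed: int) -> pd.DataFrame:
    """Sample table: sample_id, sex, age_months, age_years, generation, batch.

    Batch assignment is randomized (as in TMT designs that avoid confounding
    batch with age or sex) into ``n_batches`` chunks of up to ``batch_size``.
    """
    config.validate()
    rng = subseed(seed, "samples")
    rows = []
    i = 0
    for age in sorted(config.age_group_counts):
        n_f, n_m = config.age_group_counts[age]
        for sex, n in (("F", n_f), ("M", n_m)):
            for _ in range(n):
                rows.append((f"DO_{i:03d}", sex, age))
                i += 1
    df = pd.DataFrame(rows, columns=["sample_id", "sex", "age_months"])
    df["age_years"] = df["age_months"] / 12.0
    df["generation"] = [f"G{g % config.n_generations}" for g in range(len(df))]
    order = rng.permutation(len(df))
    batch = np.empty(len(df), dtype=object)
    for j, idx in enumerate(order):
        batch[idx] = f"batch_{j // config.batch_size:02d}"
    if len(df) > config.n_batches * config.batch_size:
        raise ValueError("n_batches * batch_size smaller than cohort")
    df["batch"] = batch
    return df


def _marker_map(config: SimConfig) -> pd.DataFrame:
    rows = []
    step = config.chromosome_length / config.markers_per_chromosome
    for c in range(1, config.n_chromosomes + 1):
        for m in range(config.markers_per_chromosome):
            rows.append((f"chr{c}_m{m:02d}", f"chr{c}", int(round((m + 0.5) * step))))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])


def simulate_genomes(config: SimConfig, seed: int) -> GenotypeProbs:
    """8-state Markov-chain founder mosaics, two haplotypes per chromosome.

    Each haplotype starts in a uniformly random founder state and switches to
    a uniformly chosen *different* founder with probability ``recomb_prob``
    per adjacent-marker interval. Probabilities are the one-hot diplotype
    averaged over the two haplotypes (entries in {0, 0.5, 1}), optionally
    blurred with symmetric noise and renormalized.
    """
    config.validate()
    rng = subseed(seed, "genomes")
    markers = _marker_map(config)
    n = config.n_mice
    m_per = config.markers_per_chromosome
    hap_blocks = []
    for _c in range(config.n_chromosomes):
        hap = np.empty((m_per, n, 2), dtype=np.int8)
        hap[0] = rng.integers(0, N_FOUNDERS, size=(n, 2))
        if m_per > 1:
            switch = rng.random(size=(m_per - 1, n, 2)) < config.recomb_prob
            jump = rng.integers(1, N_FOUNDERS, size=(m_per - 1, n, 2))
            for k in range(1, m_per):
                prev = hap[k - 1]
                nxt = np.where(switch[k - 1], (prev + jump[k - 1]) % N_FOUNDERS, prev)
                hap[k] = nxt
        hap_blocks.append(hap)
    haplotypes = np.concatenate(hap_blocks, axis=0)  # (M, N, 2)

    m_total = haplotypes.shape[0]
    probs = np.zeros((m_total, n, N_FOUNDERS), dtype=float)
    mm, nn = np.meshgrid(np.arange(m_total), np.arange(n), indexing="ij")
    np.add.at(probs, (mm, nn, haplotypes[:, :, 0]), 0.5)
    np.add.at(probs, (mm, nn, haplotypes[:, :, 1]), 0.5)
    if config.prob_noise > 0:
        probs = blur_probs(probs, config.prob_noise, subseed(seed, "genome_noise"))
    sample_ids = [f"DO_{i:03d}" for i in range(n)]
    return GenotypeProbs(markers=markers, sample_ids=sample_ids, probs=probs,
                         truth=haplotypes)


def blur_probs(probs: np.ndarray, eps: float, rng: np.random.Generator) -> np.ndarray:
    """Add symmetric nonnegative noise to probability rows and renormalize."""
    noisy = probs + eps * rng.random(probs.shape)
    return noisy / noisy.sum(axis=-1, keepdims=True)


def reconstruction_noise(probs: np.ndarray, eps: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Emulate haplotype-reconstruction error: misassign a fraction eps of
    probability mass to a random point of the founder simplex.

    q = (1 - eps) * p + eps * r with r ~ Dirichlet(1,...,1), so eps is
    directly the expected misassigned mass and rows stay on the simplex.
    """
    r = rng.dirichlet(np.ones(probs.shape[-1]), size=probs.shape[:-1])
    return (1.0 - eps) * probs + eps * r


def _gene_map(config: SimConfig) -> pd.DataFrame:
    """Assign genes uniformly along the genome (chromosome + position)."""
    genome = config.n_chromosomes * config.chromosome_length
    rows = []
    for g in range(config.n_genes):
        pos = (g + 0.5) * genome / config.n_genes
        c = min(int(pos // config.chromosome_length), config.n_chromosomes - 1)
        rows.append((f"gene_{g:03d}", f"chr{c + 1}",
                     int(pos - c * config.chromosome_length)))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "position_bp"])


def make_truth(config: SimConfig, genomes: GenotypeProbs, seed: int) -> SyntheticTruth:
    """Assemble the planted ground truth from the config's effect lists."""
    gene_ids = [f"gene_{g:03d}" for g in range(config.n_genes)]
    rng = subseed(seed, "truth")
    gens = [f"G{g}" for g in range(config.n_generations)]
    gen_off = pd.DataFrame(
        rng.normal(0.0, config.generation_log2_sd, size=(config.n_genes, len(gens))),
        index=gene_ids, columns=gens)
    gen_off = gen_off.sub(gen_off.mean(axis=1), axis=0)  # identifiable: zero-mean
    interactions = []
    for g, m, eff in config.interactions:
        alt = tuple(sorted(rng.choice(N_FOUNDERS, size=4, replace=False).tolist()))
        interactions.append((g, m, float(eff), alt))
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        age_log2fc=dict(config.age_effects),
        sex_log2fc=dict(config.sex_effects),
        generation_log2=gen_off,
        interactions=interactions,
        complex_decay=dict(config.complex_decays),
    )
    complexes = make_complex_catalog(config)
    truth.check_references(set(gene_ids), set(complexes["complex_id"]),
                           set(genomes.markers["marker_id"]))
    for c, d in truth.complex_decay.items():
        size = (complexes["complex_id"] == c).sum()
        if size < 4:
            raise ValueError(f"planted decay on complex {c!r} with <4 members")
        # keep r within [0,1] over the age span
        truth.complex_base_r[c] = min(config.base_complex_r, 1.0 + d * 0.5) if d > 0 \
            else config.base_complex_r
    return truth


def make_complex_catalog(config: SimConfig) -> pd.DataFrame:
    """Deterministic catalog: consecutive genes partitioned into complexes.

    Sizes cycle through the configured range so the catalog is reproducible
    without a dedicated RNG stream.
    """
    lo, hi = config.complex_size_range
    sizes = [(lo + (7 * k) % (hi - lo + 1)) for k in range(config.n_complexes)]
    rows, g = [], 0
    for k, size in enumerate(sizes):
        size = min(size, config.n_genes - g)
        if size < lo:
            break
        for _ in range(size):
            rows.append((f"complex_{k:02d}", f"synthetic complex {k}", f"gene_{g:03d}"))
            g += 1
    return pd.DataFrame(rows, columns=["complex_id", "name", "gene_id"])


def _interaction_dosage(genomes: GenotypeProbs, marker_id: str, alt: tuple) -> np.ndarray:
    """Additive dosage of the alternative-founder allele group in [0, 1]."""
    return genomes.dosages(marker_id)[:, list(alt)].sum(axis=1)


def simulate_transcripts(genomes: GenotypeProbs, samples: pd.DataFrame,
                         truth: SyntheticTruth, seed: int,
                         config: SimConfig) -> pd.DataFrame:
    """Negative-binomial counts (genes x samples) with planted effects.

    log2 of the expected count is linear in age (years), sex, generation and
    any planted genotype-by-age interaction; per-sample size factors add
    sequencing-depth heterogeneity. Counts are Gamma-Poisson draws with
    per-gene dispersion alpha in ``config.dispersion_range``.
    """
    rng = subseed(seed, "transcripts")
    genes = truth.gene_ids
    n_g, n_s = len(genes), len(samples)
    base = config.base_mean * np.exp(rng.normal(0.0, 0.5, size=n_g))
    lo, hi = config.dispersion_range
    alpha = rng.uniform(lo, hi, size=n_g)

    log2_mu = np.tile(np.log2(base)[:, None], (1, n_s))
    age = samples["age_years"].to_numpy()
    male = (samples["sex"] == "M").to_numpy().astype(float)
    gen = samples["generation"].to_numpy()
    gidx = {g: i for i, g in enumerate(genes)}
    for g, fc in truth.age_log2fc.items():
        log2_mu[gidx[g]] += fc * age
    for g, fc in truth.sex_log2fc.items():
        log2_mu[gidx[g]] += fc * male
    if truth.generation_log2 is not None:
        log2_mu += truth.generation_log2.loc[genes, gen].to_numpy()
    for g, m, eff, alt in truth.interactions:
        if g in gidx:
            log2_mu[gidx[g]] += eff * _interaction_dosage(genomes, m, alt) * age

    size_factor = np.exp(rng.normal(0.0, config.size_factor_log_sd, size=n_s))
    mu = (2.0 ** log2_mu) * size_factor[None, :]
    # Gamma-Poisson mixture: Var = mu + alpha * mu^2
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape[:, None], mu * alpha[:, None]) if np.any(alpha > 0) else mu
    lam = np.where(alpha[:, None] > 1e-12, lam, mu)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=samples["sample_id"].tolist())


def _standardize_within_age(values: np.ndarray, age: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values, dtype=float)
    for a in np.unique(age):
        sel = age == a
        block = values[:, sel]
        sd = block.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out[:, sel] = (block - block.mean(axis=1, keepdims=True)) / sd
    return out


def _latent_protein_signal(samples: pd.DataFrame, truth: SyntheticTruth,
                           catalog: pd.DataFrame, config: SimConfig,
                           rng: np.random.Generator,
                           counts: pd.DataFrame = None) -> pd.DataFrame:
    """Latent log2 protein abundance (genes x samples).

    Within-complex co-abundance follows an age-group-specific one-factor
    model: member signal = sqrt(r_k) * F + sqrt(1 - r_k) * e with F shared per
    (complex, sample), so the pairwise correlation among members at age k is
    exactly r_k = base_r + delta_r_per_year * (age_years - 0.5).
    """
    genes = truth.gene_ids
    n_g, n_s = len(genes), len(samples)
    gidx = {g: i for i, g in enumerate(genes)}
    age = samples["age_years"].to_numpy()
    male = (samples["sex"] == "M").to_numpy().astype(float)

    signal = np.tile(rng.normal(10.0, 1.0, size=n_g)[:, None], (1, n_s))
    for g, fc in truth.age_log2fc.items():
        signal[gidx[g]] += fc * age
    for g, fc in truth.sex_log2fc.items():
        signal[gidx[g]] += fc * male

    eps = rng.normal(0.0, 1.0, size=(n_g, n_s))
    rho = config.protein_transcript_rho
    if rho > 0 and counts is not None:
        # couple the protein residual to the gene's (standardized, within-age)
        # transcript level so within-group transcript-protein Pearson r ~= rho
        # for genes whose within-group variation is residual-dominated
        z_t = _standardize_within_age(
            np.log2(counts.loc[genes].to_numpy(float) + 1.0),
            samples["age_months"].to_numpy())
        eps = rho * z_t + np.sqrt(1.0 - rho**2) * eps
    resid = config.protein_noise_sd * eps
    in_complex = np.zeros(n_g, dtype=bool)
    for cid, sub in catalog.groupby("complex_id", sort=False):
        members = [gidx[g] for g in sub["gene_id"] if g in gidx]
        in_complex[members] = True
        base_r = truth.complex_base_r.get(cid, config.base_complex_r)
        decay = truth.complex_decay.get(cid, 0.0)
        factor = rng.normal(0.0, 1.0, size=n_s)
        eps = rng.normal(0.0, 1.0, size=(len(members), n_s))
        r_k = np.clip(base_r + decay * (age - 0.5), 0.0, 1.0)
        comp = np.sqrt(r_k)[None, :] * factor[None, :] + np.sqrt(1.0 - r_k)[None, :] * eps
        signal[members] += comp
    signal += resid
    return pd.DataFrame(signal, index=genes, columns=samples["sample_id"].tolist())


def simulate_peptides(genomes: GenotypeProbs, samples: pd.DataFrame,
                      truth: SyntheticTruth, seed: int,
                      config: SimConfig, counts: pd.DataFrame = None) -> pd.DataFrame:
    """Peptide intensity table with batch structure and polymorphic dropout.

    Returns a long-format-free wide table: peptide_id, protein_id, gene_id,
    variant_mask (8-char 0/1 string, 1 = founder shares the reference allele)
    and one intensity column per sample. Polymorphic peptides are zeroed in
    samples whose true diplotype at the gene's nearest marker carries at least
    one non-reference founder; additional values go missing at random.
    """
    rng = subseed(seed, "peptides")
    catalog = make_complex_catalog(config)
    latent = _latent_protein_signal(samples, truth, catalog, config,
                                    subseed(seed, "latent_protein"),
                                    counts=counts)
    truth.latent_protein_log2 = latent
    genes = truth.gene_ids
    n_s = len(samples)

    lo, hi = config.n_peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=len(genes))
    batch_shift = pd.Series(
        rng.normal(0.0, config.batch_log2_sd, size=config.n_batches),
        index=[f"batch_{b:02d}" for b in range(config.n_batches)])
    loading = pd.Series(rng.normal(0.0, config.loading_log2_sd, size=n_s),
                        index=samples["sample_id"].tolist())
    truth.batch_shift_log2 = batch_shift
    truth.sample_loading_log2 = loading
    shift_per_sample = batch_shift.reindex(samples["batch"]).to_numpy()
    load = loading.to_numpy()

    gene_map = _gene_map(config)
    nearest = nearest_marker_index(gene_map, genomes.markers)

    rows, masks = [], {}
    intensities = []
    for gi, g in enumerate(genes):
        sig = latent.iloc[gi].to_numpy()
        for k in range(n_pep[gi]):
            pid = f"{g}_pep{k}"
            offset = rng.normal(0.0, 1.0)
            noise = rng.normal(0.0, config.peptide_noise_sd, size=n_s)
            inten = 2.0 ** (sig + offset + shift_per_sample + load + noise)
            polymorphic = rng.random() < config.polymorphic_peptide_fraction
            mask = np.ones(N_FOUNDERS, dtype=bool)
            if polymorphic:
                n_alt = int(rng.integers(1, 5))
                alt = rng.choice([a for a in range(N_FOUNDERS) if a != REFERENCE_FOUNDER],
                                 size=n_alt, replace=False)
                mask[alt] = False
                dip = genomes.truth[nearest[gi]]  # (N, 2) founder indices
                carries_alt = ~mask[dip].all(axis=1)
                inten = np.where(carries_alt, 0.0, inten)
            miss = rng.random(n_s) < config.peptide_missing_rate
            inten = np.where(miss, np.nan, inten)
            rows.append((pid, g, g))
            masks[pid] = "".join("1" if b else "0" for b in mask)
            intensities.append(inten)

    table = pd.DataFrame(rows, columns=["peptide_id", "protein_id", "gene_id"])
    table["variant_mask"] = table["peptide_id"].map(masks)
    inten_df = pd.DataFrame(np.vstack(intensities), columns=samples["sample_id"].tolist())
    truth.variant_masks = table.set_index("peptide_id")["variant_mask"]
    return pd.concat([table, inten_df], axis=1)


def plant_sample_swaps(genomes: GenotypeProbs, transcripts: pd.DataFrame,
                       n_swaps: int, seed: int,
                       noise: float = 0.05) -> tuple[GenotypeProbs, pd.DataFrame, list]:
    """Expression-derived haplotypes (a blurred copy) with swapped sample IDs.

    Returns (expression_probs, relabeled transcript matrix, swap truth). The
    swap exchanges the labels of ``n_swaps`` disjoint sample pairs in the
    expression-derived data only, emulating mislabeling in one source.
    """
    if 2 * n_swaps > genomes.n_samples:
        raise ValueError("not enough samples for the requested swaps")
    rng = subseed(seed, "swaps")
    probs = (reconstruction_noise(genomes.probs, noise, rng) if noise > 0
             else genomes.probs.copy())
    order = list(range(genomes.n_samples))
    chosen = rng.choice(genomes.n_samples, size=2 * n_swaps, replace=False)
    pairs = []
    for k in range(n_swaps):
        a, b = int(chosen[2 * k]), int(chosen[2 * k + 1])
        order[a], order[b] = order[b], order[a]
        pairs.append((genomes.sample_ids[a], genomes.sample_ids[b]))
    probs = probs[:, order, :]
    cols = np.array(transcripts.columns)[order]
    swapped_counts = transcripts.copy()
    swapped_counts.columns = transcripts.columns  # labels keep original order
    swapped_counts.loc[:, :] = transcripts[cols].to_numpy()
    expr = GenotypeProbs(markers=genomes.markers.copy(),
                         sample_ids=list(genomes.sample_ids), probs=probs)
    return expr, swapped_counts, pairs


def nearest_marker_index(features: pd.DataFrame, markers: pd.DataFrame) -> np.ndarray:
    """Index of the nearest marker (same chromosome, min |delta pos|) per feature.

    Ties break toward the lower coordinate. Features on chromosomes with no
    markers get -1.
    """
    out = np.full(len(features), -1, dtype=int)
    mk_chrom = markers["chromosome"].to_numpy()
    mk_pos = markers["position_bp"].to_numpy()
    for c in np.unique(features["chromosome"]):
        fsel = np.flatnonzero(features["chromosome"].to_numpy() == c)
        msel = np.flatnonzero(mk_chrom == c)
        if len(msel) == 0:
            continue
        pos = mk_pos[msel]
        for fi in fsel:
            d = np.abs(pos - features["position_bp"].iloc[fi])
            out[fi] = msel[int(np.argmin(d))]  # argmin takes first (lower coord) on ties
    return out


def simulate_cohort(config: SimConfig, seed: int) -> dict:
    """Run every generator stage; returns a dict of all tables plus truth."""
    samples = simulate_samples(config, seed)
    genomes = simulate_genomes(config, seed)
    truth = make_truth(config, genomes, seed)
    counts = simulate_transcripts(genomes, samples, truth, seed, config)
    peptides = simulate_peptides(genomes, samples, truth, seed, config,
                                 counts=counts)
    expr_probs, counts_swapped, pairs = plant_sample_swaps(
        genomes, counts, config.n_sample_swaps, seed,
        noise=config.expression_prob_noise)
    truth.swapped_pairs = pairs
    return {
        "config": config,
        "samples": samples,
        "genomes": genomes,
        "expression_probs": expr_probs,
        "counts": counts_swapped,
        "counts_clean": counts,
        "peptides": peptides,
        "complexes": make_complex_catalog(config),
        "gene_map": _gene_map(config),
        "truth": truth,
    }
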