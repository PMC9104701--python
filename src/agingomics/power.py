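"""Study-design power computations.

Two calculations: the analytic two-sample power to detect a mean difference
between the youngest and oldest age groups (effect in within-group SD units,
noncentral-t), and a simulation estimate of the power to detect an additive
QTL explaining a given fraction of phenotypic variance after genome-wide
error-rate control in a DO-like mosaic genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .config import SimConfig, subseed
from .simulate import simulate_genomes
from .proteomics import rank_normal
from .qtl import compute_kinship, GenomeScanner

import pandas as pd


@dataclass
class PowerResult:
    power: float
    method: str
    n: int
    effect: float
    alpha: float
    mc_se: Optional[float] = None
    threshold: Optional[float] = None


def power_age_effect(n_per_group: int, effect_sd: float, alpha: float,
                     approx: str = "nct") -> PowerResult:
    """Two-sample two-sided t-test power at a given per-group n.

    Noncentrality = effect * sqrt(n/2), df = 2n - 2. ``approx='normal'``
    uses the normal approximation instead of the noncentral t.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_per_group < 2 or effect_sd < 0:
        raise ValueError("need n_per_group >= 2 and effect_sd >= 0")
    df = 2 * n_per_group - 2
    nc = effect_sd * np.sqrt(n_per_group / 2.0)
    if approx == "normal":
        z = stats.norm.isf(alpha / 2)
        power = stats.norm.sf(z - nc) + stats.norm.cdf(-z - nc)
    else:
        tcrit = stats.t.isf(alpha / 2, df)
        power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        if not np.isfinite(power):  # nct overflows at very large df
            return power_age_effect(n_per_group, effect_sd, alpha, approx="normal")
    return PowerResult(power=float(power), method=f"analytic_t/{approx}",
                       n=n_per_group, effect=effect_sd, alpha=alpha)


def power_qtl(n: int = 185, qtl_var_frac: float = 0.20, gwer: float = 0.05,
              n_sim: int = 200, n_perm: int = 200,
              genome_config: SimConfig = None, seed: int = 0) -> PowerResult:
    """Simulation power for an additive QTL after genome-wide correction.

    Simulates a DO-like genome, derives the genome-wide LOD threshold at the
    stated error rate from ``n_perm`` null phenotypes, then plants a
    bi-allelic QTL (founders split 4/4) explaining ``qtl_var_frac`` of the
    phenotype variance at a random marker in each of ``n_sim`` replicates.
    Phenotypes are rank-normalized before scanning, as in the mapping stage.
    """
    if not 0 <= qtl_var_frac < 1:
        raise ValueError("qtl_var_frac must lie in [0, 1)")
    if n_sim < 50:
        import logging
        logging.getLogger(__name__).warning(
            "n_sim=%d gives a wide power confidence interval", n_sim)
    if genome_config is None:
        genome_config = SimConfig()
    genome_config.validate()
    genomes = simulate_genomes(genome_config, seed)
    if genomes.n_samples != n:
        raise ValueError("genome_config cohort size does not match n")
    kinship = compute_kinship(genomes, mode="loco")
    covar = np.ones((n, 1))
    scanner = GenomeScanner(genomes, kinship, covar)
    rng = subseed(seed, "qtl_power")

    def _rn(y):
        return rank_normal(pd.DataFrame(y[None, :])).to_numpy()[0]

    null_max = np.empty(n_perm)
    for b in range(n_perm):
        y = _rn(rng.normal(size=n))
        null_max[b] = scanner.scan(y)["lod"].max()
    threshold = float(np.quantile(null_max, 1.0 - gwer))

    hits = 0
    markers = genomes.markers
    for s in range(n_sim):
        m = int(rng.integers(len(markers)))
        alt = rng.choice(8, size=4, replace=False)
        dosage = genomes.probs[m][:, alt].sum(axis=1)
        dosage = dosage - dosage.mean()
        sd = dosage.std()
        if sd == 0:
            continue
        if qtl_var_frac > 0:
            beta = np.sqrt(qtl_var_frac / (1.0 - qtl_var_frac)) / sd
        else:
            beta = 0.0
        y = _rn(beta * dosage + rng.normal(size=n))
        if scanner.scan(y)["lod"].max() > threshold:
            hits += 1
    power = hits / n_sim
    return PowerResult(power=float(power), method="simulation", n=n,
                       effect=qtl_var_frac, alpha=gwer,
                       mc_se=float(np.sqrt(power * (1 - power) / n_sim)),
                       threshold=threshold)
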