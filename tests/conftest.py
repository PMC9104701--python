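import numpy as np
import pandas as pd
import pytest

from agingomics.config import SimConfig
from agingomics.simulate import simulate_cohort, GenotypeProbs

#: one standard seed for the whole suite, so fixtures are shared and cached
SEED = 1


@pytest.fixture(scope="session")
def cohort():
    """Default planted synthetic cohort (185 mice, planted effects, 2 swaps)."""
    return simulate_cohort(SimConfig.default_planted(), SEED)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects: the null generator for calibration."""
    return simulate_cohort(SimConfig(), SEED + 1)


@pytest.fixture(scope="session")
def quantified(cohort):
    from agingomics.proteomics import quantify
    return quantify(cohort["peptides"], cohort["samples"],
                    genomes=cohort["genomes"], gene_map=cohort["gene_map"])


@pytest.fixture(scope="session")
def small_genomes():
    cfg = SimConfig(age_group_counts={6: (4, 3), 12: (3, 3), 18: (3, 4)},
                    n_chromosomes=3, markers_per_chromosome=10, n_genes=20,
                    n_batches=4, batch_size=5, n_sample_swaps=0)
    from agingomics.simulate import simulate_genomes
    return simulate_genomes(cfg, SEED)


def toy_probs(rows, markers=None, sample_ids=None):
    """GenotypeProbs from an explicit (M, N, 8) array for hand arithmetic."""
    probs = np.asarray(rows, dtype=float)
    m, n, _ = probs.shape
    if markers is None:
        markers = pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(m)],
            "chromosome": ["chr1"] * m,
            "position_bp": (np.arange(m) + 1) * 10,
        })
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return GenotypeProbs(markers=markers, sample_ids=sample_ids, probs=probs)
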