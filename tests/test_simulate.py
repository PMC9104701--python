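"""Generator contracts: determinism, probability conservation, planted truth."""

import numpy as np
import pandas as pd
import pytest

from agingomics.config import SimConfig
from agingomics.simulate import (simulate_genomes, simulate_samples,
                                 simulate_transcripts, simulate_peptides,
                                 plant_sample_swaps, make_truth,
                                 make_complex_catalog, simulate_cohort,
                                 nearest_marker_index, _latent_protein_signal)

from conftest import SEED


def small_cfg(**kw):
    base = dict(age_group_counts={6: (10, 10), 12: (10, 10), 18: (10, 10)},
                n_chromosomes=4, markers_per_chromosome=12, n_genes=30,
                n_batches=6, batch_size=10, n_sample_swaps=1)
    base.update(kw)
    return SimConfig(**base)


class TestGenomes:
    def test_determinism_bit_identical(self):
        cfg = small_cfg()
        g1 = simulate_genomes(cfg, 7)
        g2 = simulate_genomes(cfg, 7)
        assert np.array_equal(g1.probs, g2.probs)
        assert np.array_equal(g1.truth, g2.truth)

    def test_different_seed_differs(self):
        cfg = small_cfg()
        assert not np.array_equal(simulate_genomes(cfg, 1).probs,
                                  simulate_genomes(cfg, 2).probs)

    def test_rows_on_simplex_and_positions_increasing(self):
        g = simulate_genomes(small_cfg(prob_noise=0.05), 3)
        g.validate()

    def test_no_recombination_means_single_founder_per_chromosome(self):
        g = simulate_genomes(small_cfg(recomb_prob=0.0), 5)
        for c in g.markers["chromosome"].unique():
            sel = g.chromosome_index(c)
            hap = g.truth[sel]
            assert (hap == hap[0]).all()

    def test_founder_frequency_uniform(self):
        # law of large numbers: each founder's mean probability ~= 1/8
        cfg = small_cfg(age_group_counts={6: (40, 40), 12: (40, 40), 18: (40, 40)})
        g = simulate_genomes(cfg, 11)
        mean_p = g.probs.mean(axis=(0, 1))
        n_draws = g.n_markers * g.n_samples * 2
        mc_se = np.sqrt((1 / 8) * (7 / 8) / n_draws) * 2  # hom/het correlation margin
        assert np.all(np.abs(mean_p - 1 / 8) < 3 * mc_se * 10)
        assert abs(mean_p.sum() - 1.0) < 1e-12

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_genomes(small_cfg(markers_per_chromosome=0), 1)


class TestSamples:
    def test_cohort_composition(self):
        s = simulate_samples(SimConfig(), 1)
        assert len(s) == 185
        grp = s.groupby(["age_months", "sex"]).size()
        assert grp[(6, "F")] == 33 and grp[(6, "M")] == 29
        assert grp[(12, "F")] == 31 and grp[(12, "M")] == 31
        assert grp[(18, "F")] == 27 and grp[(18, "M")] == 34

    def test_age_years_exact_and_batches_disjoint(self):
        s = simulate_samples(small_cfg(), 2)
        assert (s["age_years"] == s["age_months"] / 12).all()
        assert s.groupby("batch").size().max() <= 10
        assert s["sample_id"].is_unique


class TestTranscripts:
    def test_null_generator_age_independent(self):
        cfg = small_cfg(n_genes=60)
        s = simulate_samples(cfg, 3)
        g = simulate_genomes(cfg, 3)
        truth = make_truth(cfg, g, 3)
        counts = simulate_transcripts(g, s, truth, 3, cfg)
        by_age = counts.T.groupby(s.set_index("sample_id")["age_months"]
                                  .reindex(counts.columns)).mean()
        rel = np.log2(by_age.loc[18] + 1) - np.log2(by_age.loc[6] + 1)
        assert abs(rel.mean()) < 0.15  # no systematic age trend

    def test_planted_log2fc_doubles_mean_over_one_year(self):
        cfg = small_cfg(n_genes=40,
                        age_group_counts={6: (60, 60), 12: (10, 10), 18: (60, 60)},
                        n_batches=26, batch_size=10,
                        age_effects=(("gene_005", 1.0),))
        s = simulate_samples(cfg, 4)
        g = simulate_genomes(cfg, 4)
        truth = make_truth(cfg, g, 4)
        counts = simulate_transcripts(g, s, truth, 4, cfg)
        age = s.set_index("sample_id")["age_months"].reindex(counts.columns)
        m6 = counts.loc["gene_005", (age == 6).to_numpy()].mean()
        m18 = counts.loc["gene_005", (age == 18).to_numpy()].mean()
        assert m18 / m6 == pytest.approx(2.0, rel=0.25)

    def test_poisson_limit_variance_matches_mean(self):
        cfg = small_cfg(n_genes=200, dispersion_range=(1e-8, 1e-8),
                        size_factor_log_sd=0.0, generation_log2_sd=0.0)
        s = simulate_samples(cfg, 5)
        g = simulate_genomes(cfg, 5)
        truth = make_truth(cfg, g, 5)
        counts = simulate_transcripts(g, s, truth, 5, cfg)
        mu = counts.mean(axis=1)
        var = counts.var(axis=1)
        # Poisson: var/mean ~= 1 on average across genes
        assert (var / mu).mean() == pytest.approx(1.0, abs=0.1)

    def test_nb_variance_inflation(self):
        alpha = 0.2
        cfg = small_cfg(n_genes=300, dispersion_range=(alpha, alpha),
                        size_factor_log_sd=0.0, generation_log2_sd=0.0)
        s = simulate_samples(cfg, 6)
        g = simulate_genomes(cfg, 6)
        truth = make_truth(cfg, g, 6)
        counts = simulate_transcripts(g, s, truth, 6, cfg)
        mu = counts.mean(axis=1)
        var = counts.var(axis=1)
        expected = mu + alpha * mu**2
        assert (var / expected).mean() == pytest.approx(1.0, abs=0.15)

    def test_planted_gene_must_exist(self):
        cfg = small_cfg(age_effects=(("no_such_gene", 1.0),))
        g = simulate_genomes(cfg, 1)
        with pytest.raises(ValueError, match="unknown gene"):
            make_truth(cfg, g, 1)


class TestPeptides:
    def test_monomorphic_masks_induce_no_zeros(self):
        cfg = small_cfg(polymorphic_peptide_fraction=0.0,
                        peptide_missing_rate=0.0)
        s = simulate_cohort(cfg, 8)
        cols = s["samples"]["sample_id"]
        vals = s["peptides"][cols].to_numpy()
        assert (s["peptides"]["variant_mask"] == "1" * 8).all()
        assert (vals > 0).all()

    def test_polymorphic_dropout_follows_diplotype(self):
        cfg = small_cfg(polymorphic_peptide_fraction=1.0,
                        peptide_missing_rate=0.0)
        s = simulate_cohort(cfg, 9)
        pep = s["peptides"]
        genomes = s["genomes"]
        gm = s["gene_map"]
        nearest = nearest_marker_index(gm, genomes.markers)
        gene_to_marker = dict(zip(gm["gene_id"], nearest))
        cols = s["samples"]["sample_id"].tolist()
        poly = pep[pep["variant_mask"].str.contains("0")]
        row = poly.iloc[0]
        mask = np.array([c == "1" for c in row["variant_mask"]])
        dip = genomes.truth[gene_to_marker[row["gene_id"]]]
        carries_alt = ~mask[dip].all(axis=1)
        vals = row[cols].to_numpy(float)
        assert (vals[carries_alt] == 0).all()
        assert (vals[~carries_alt] > 0).all()

    def test_null_complex_correlation_flat_in_age(self):
        cfg = small_cfg(age_group_counts={6: (30, 30), 12: (30, 30), 18: (30, 30)},
                        n_batches=18, batch_size=10)
        s = simulate_samples(cfg, 10)
        g = simulate_genomes(cfg, 10)
        truth = make_truth(cfg, g, 10)
        catalog = make_complex_catalog(cfg)
        latent = _latent_protein_signal(s, truth, catalog, cfg,
                                        np.random.default_rng(0))
        slopes = _mean_complex_r_slope(latent, catalog, s)
        assert abs(np.mean(slopes)) < 0.05

    def test_planted_decay_recovered_on_latent_signal(self):
        cfg = small_cfg(age_group_counts={6: (30, 30), 12: (30, 30), 18: (30, 30)},
                        n_batches=18, batch_size=10, n_genes=40,
                        complex_decays=(("complex_01", -0.2),))
        s = simulate_samples(cfg, 11)
        g = simulate_genomes(cfg, 11)
        truth = make_truth(cfg, g, 11)
        catalog = make_complex_catalog(cfg)
        latent = _latent_protein_signal(s, truth, catalog, cfg,
                                        np.random.default_rng(1))
        slopes = _mean_complex_r_slope(latent, catalog, s, only="complex_01")
        assert np.mean(slopes) == pytest.approx(-0.2, abs=0.05)

    def test_planted_decay_requires_four_members(self):
        cfg = small_cfg(complex_size_range=(4, 6), n_complexes=3,
                        complex_decays=(("complex_99", -0.2),))
        g = simulate_genomes(cfg, 1)
        with pytest.raises(ValueError, match="unknown complex"):
            make_truth(cfg, g, 1)


def _mean_complex_r_slope(latent, catalog, samples, only=None):
    """Oracle: mean within-complex pairwise r per age group, then OLS slope."""
    age = samples.set_index("sample_id")["age_months"].reindex(latent.columns)
    slopes = []
    for cid, sub in catalog.groupby("complex_id"):
        if only and cid != only:
            continue
        X = latent.loc[[g for g in sub["gene_id"] if g in latent.index]]
        if len(X) < 4:
            continue
        means = []
        for a in (6, 12, 18):
            r = np.corrcoef(X.loc[:, (age == a).to_numpy()])
            means.append(r[np.triu_indices(len(X), 1)].mean())
        x = np.array([0.5, 1.0, 1.5])
        y = np.array(means)
        slopes.append(np.sum((x - 1.0) * (y - y.mean())) / 0.5)
    return slopes


class TestSampleSwaps:
    def test_no_swaps_probs_match_up_to_noise(self, small_genomes):
        counts = pd.DataFrame(np.arange(20 * 20).reshape(20, 20),
                              columns=small_genomes.sample_ids)
        expr, counts2, pairs = plant_sample_swaps(small_genomes, counts, 0, 12,
                                                  noise=0.02)
        assert pairs == []
        assert np.abs(expr.probs - small_genomes.probs).max() < 0.2
        pd.testing.assert_frame_equal(counts, counts2)

    def test_two_swaps_exactly_four_columns_moved(self, small_genomes):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (30, 20)),
                              columns=small_genomes.sample_ids)
        expr, counts2, pairs = plant_sample_swaps(small_genomes, counts, 2, 13,
                                                  noise=0.0)
        assert len(pairs) == 2
        swapped = {x for p in pairs for x in p}
        assert len(swapped) == 4
        moved = [c for c in counts.columns
                 if not (counts[c] == counts2[c]).all()]
        assert set(moved) == swapped

    def test_too_many_swaps_rejected(self, small_genomes):
        counts = pd.DataFrame(np.zeros((5, 20)), columns=small_genomes.sample_ids)
        with pytest.raises(ValueError):
            plant_sample_swaps(small_genomes, counts, 11, 1)


def test_cohort_determinism_end_to_end():
    cfg = small_cfg()
    a = simulate_cohort(cfg, SEED)
    b = simulate_cohort(cfg, SEED)
    assert np.array_equal(a["genomes"].probs, b["genomes"].probs)
    pd.testing.assert_frame_equal(a["counts"], b["counts"])
    pd.testing.assert_frame_equal(a["peptides"], b["peptides"])
    assert a["truth"].swapped_pairs == b["truth"].swapped_pairs
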