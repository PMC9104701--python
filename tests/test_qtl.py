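"""Kinship, mixed-model scans, permutation thresholds, peaks, hotspots."""

import numpy as np
import pandas as pd
import pytest

from agingomics.config import SimConfig, subseed
from agingomics.simulate import simulate_genomes
from agingomics.qtl import (compute_kinship, fit_null_lmm, GenomeScanner,
                            scan_additive, scan_interactive, gls_scan_bruteforce,
                            residual_permutation_threshold, call_age_qtl_peaks,
                            find_hotspots, refine_hotspot_members, Kinship)

from conftest import toy_probs


def tiny_genomes(n_samples=20, n_chrom=3, markers=8, seed=0, recomb=0.1):
    counts = {6: (n_samples // 4, n_samples // 4),
              12: (n_samples // 4, 0),
              18: (n_samples - 3 * (n_samples // 4), 0)}
    cfg = SimConfig(age_group_counts=counts, n_chromosomes=n_chrom,
                    markers_per_chromosome=markers, recomb_prob=recomb,
                    n_batches=max(2, n_samples // 10 + 1), batch_size=10,
                    n_genes=10)
    return simulate_genomes(cfg, seed)


class TestKinship:
    def test_hand_worked_two_sample_two_marker(self):
        rows = np.zeros((2, 2, 8))
        rows[0, 0, 0] = 1.0            # sample 1 hom founder A at marker 1
        rows[0, 1, :2] = 0.5           # sample 2 het A/B
        rows[1, 0, 1] = 1.0            # sample 1 hom B at marker 2
        rows[1, 1, :2] = 0.5
        markers = pd.DataFrame({"marker_id": ["m1", "m2"],
                                "chromosome": ["chr1", "chr2"],
                                "position_bp": [10, 10]})
        g = toy_probs(rows, markers=markers)
        k = compute_kinship(g, mode="all")
        # K[0,1] = mean over markers of sum_a p q = ((1*0.5) + (1*0.5)) / 2
        assert k.overall[0, 1] == pytest.approx(0.5)
        assert k.overall[0, 0] == pytest.approx(1.0)
        assert k.overall[1, 1] == pytest.approx(0.5)  # het rows: 0.25 + 0.25

    def test_identical_samples_share_diagonal_value(self):
        g = tiny_genomes(seed=3)
        probs = g.probs.copy()
        probs[:, 1, :] = probs[:, 0, :]
        g2 = toy_probs(probs, markers=g.markers, sample_ids=g.sample_ids)
        k = compute_kinship(g2, mode="all")
        assert k.overall[0, 1] == pytest.approx(k.overall[0, 0], abs=1e-12)

    def test_disjoint_founders_zero(self):
        rows = np.zeros((4, 2, 8))
        rows[:, 0, 0] = 1.0
        rows[:, 1, 5] = 1.0
        markers = pd.DataFrame({"marker_id": [f"m{i}" for i in range(4)],
                                "chromosome": ["chr1", "chr1", "chr2", "chr2"],
                                "position_bp": [10, 20, 10, 20]})
        k = compute_kinship(toy_probs(rows, markers=markers), mode="all")
        assert k.overall[0, 1] == 0.0

    def test_loco_excludes_own_chromosome(self):
        g = tiny_genomes(seed=4)
        k = compute_kinship(g, mode="loco")
        chroms = g.markers["chromosome"].to_numpy()
        for c in np.unique(chroms):
            sel = chroms != c
            manual = np.einsum("mia,mja->ij", g.probs[sel], g.probs[sel]) / sel.sum()
            assert np.allclose(k.loco[c], manual, atol=1e-12)

    def test_psd_and_entry_range(self):
        g = tiny_genomes(n_samples=24, seed=5)
        k = compute_kinship(g, mode="loco")
        for K in [k.overall, *k.loco.values()]:
            ev = np.linalg.eigvalsh(K)
            assert ev.min() > -1e-10
            assert K.min() >= 0.0 and K.max() <= 1.0 + 1e-12
            assert np.allclose(K, K.T)

    def test_single_chromosome_loco_rejected(self):
        g = tiny_genomes(n_chrom=1, seed=6)
        with pytest.raises(ValueError):
            compute_kinship(g, mode="loco")


class TestNullLMM:
    def test_identity_kinship_returns_h_zero(self):
        rng = np.random.default_rng(0)
        n = 30
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        nf = fit_null_lmm(y, X, np.eye(n))
        assert nf.h2 == pytest.approx(0.0, abs=1e-6)

    def test_heritability_recovered(self):
        g = simulate_genomes(SimConfig(), 8)
        k = compute_kinship(g, mode="all")
        K = k.overall
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0, None)
        rng = np.random.default_rng(1)
        hs = []
        scale = np.mean(np.diag(K))
        for _ in range(6):
            gvals = U @ (np.sqrt(d / scale) * rng.normal(size=len(d)))
            y = np.sqrt(0.5) * gvals + np.sqrt(0.5) * rng.normal(size=len(d))
            hs.append(fit_null_lmm(y, np.ones((len(d), 1)), K).h2)
        assert np.mean(hs) == pytest.approx(0.5, abs=0.2)

    def test_optimum_beats_boundaries(self):
        g = tiny_genomes(n_samples=40, seed=9)
        k = compute_kinship(g, mode="all")
        rng = np.random.default_rng(2)
        y = rng.normal(size=40)
        X = np.ones((40, 1))
        nf = fit_null_lmm(y, X, k.overall)
        from agingomics.qtl import _profile_loglik
        d, U = np.linalg.eigh(k.overall)
        yt, Xt = U.T @ y, U.T @ X
        assert nf.loglik >= _profile_loglik(yt, Xt, np.clip(d, 0, None), 0.0)[0] - 1e-9
        assert nf.loglik >= _profile_loglik(yt, Xt, np.clip(d, 0, None), 0.99)[0] - 1e-9

    def test_rank_deficient_covariates_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_null_lmm(np.zeros(10), np.ones((10, 2)), np.eye(10))


class TestScans:
    def test_fast_path_matches_bruteforce_gls(self):
        g = tiny_genomes(n_samples=20, seed=10)
        k = compute_kinship(g, mode="loco")
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        fast = scan_additive(y, g, k, X)
        slow = gls_scan_bruteforce(y, g, k, X)
        assert np.allclose(fast["lod"], np.clip(slow["lod"], 0, None), atol=1e-6)

    def test_lod_nonnegative_everywhere(self):
        g = tiny_genomes(n_samples=30, seed=11)
        k = compute_kinship(g, mode="loco")
        rng = np.random.default_rng(4)
        age = np.tile([0.5, 1.0, 1.5], 10)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        for _ in range(3):
            y = rng.normal(size=30)
            res = scan_interactive(y, g, k, X, age)
            assert (res["lod"] >= 0).all()
            assert (res["lod_int"] >= 0).all()

    def test_null_max_lod_moderate(self):
        g = simulate_genomes(SimConfig(), 12)
        kin = Kinship(overall=np.eye(185), loco={c: np.eye(185) for c in
                      g.markers["chromosome"].unique()}, sample_ids=g.sample_ids)
        rng = np.random.default_rng(5)
        y = rng.normal(size=185)
        res = scan_additive(y, g, kin, np.ones((185, 1)))
        assert res["lod"].max() < 6.0  # typical null genome-wide max ~< 4

    def test_planted_additive_qtl_found_with_expected_lod(self):
        g = simulate_genomes(SimConfig(), 13)
        k = compute_kinship(g, mode="loco")
        rng = np.random.default_rng(6)
        m = 117
        dosage = g.probs[m][:, :4].sum(axis=1)
        dosage = (dosage - dosage.mean()) / dosage.std()
        frac = 0.2
        y = np.sqrt(frac / (1 - frac)) * dosage + rng.normal(size=185)
        res = scan_additive(y, g, k, np.ones((185, 1)))
        assert res["lod"].idxmax() == m
        # R^2 -> LOD identity: expected (n/2) log10(1/(1-0.2)) ~= 8.97
        assert res["lod"].max() == pytest.approx(8.97, abs=3.0)

    def test_constant_age_makes_interaction_collinear(self):
        g = tiny_genomes(n_samples=24, seed=14)
        k = compute_kinship(g, mode="loco")
        rng = np.random.default_rng(7)
        y = rng.normal(size=24)
        res = scan_interactive(y, g, k, np.ones((24, 1)), np.full(24, 1.0))
        assert np.allclose(res["lod_int"], 0.0, atol=1e-8)

    def test_kinship_scaling_invariance(self):
        g = tiny_genomes(n_samples=24, seed=15)
        k = compute_kinship(g, mode="loco")
        k2 = Kinship(overall=3.0 * k.overall,
                     loco={c: 3.0 * K for c, K in k.loco.items()},
                     sample_ids=k.sample_ids)
        rng = np.random.default_rng(8)
        y = rng.normal(size=24)
        X = np.ones((24, 1))
        r1 = scan_additive(y, g, k, X)
        r2 = scan_additive(y, g, k2, X)
        assert np.allclose(r1["lod"], r2["lod"], atol=1e-4)


class TestResidualPermutation:
    def test_same_seed_same_threshold(self):
        g = tiny_genomes(n_samples=24, seed=16)
        k = compute_kinship(g, mode="loco")
        rng = np.random.default_rng(9)
        y = rng.normal(size=24)
        X = np.ones((24, 1))
        age = np.tile([0.5, 1.0, 1.5], 8)
        t1, m1 = residual_permutation_threshold(y, g, k, X, age, B=30, seed=5)
        t2, m2 = residual_permutation_threshold(y, g, k, X, age, B=30, seed=5)
        assert t1 == t2
        assert np.array_equal(m1, m2)

    def test_quantile_monotonicity(self):
        g = tiny_genomes(n_samples=24, seed=17)
        k = compute_kinship(g, mode="loco")
        rng = np.random.default_rng(10)
        y = rng.normal(size=24)
        age = np.tile([0.5, 1.0, 1.5], 8)
        _, maxima = residual_permutation_threshold(y, g, k, np.ones((24, 1)),
                                                   age, B=40, seed=6)
        qs = [np.quantile(maxima, q) for q in (0.0, 0.5, 0.95, 1.0)]
        assert qs == sorted(qs)
        assert qs[0] == maxima.min() and qs[-1] == maxima.max()


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["phenotype_id", "marker_id", "chromosome",
                                       "position_bp", "lod_int", "significant",
                                       "class", "gene_chromosome", "gene_position_bp"])


class TestPeaksAndHotspots:
    def test_below_suggestive_empty(self):
        scans = {"g1": pd.DataFrame({"marker_id": ["m1"], "chromosome": ["chr1"],
                                     "position_bp": [100], "lod_int": [6.0]})}
        genes = pd.DataFrame({"gene_id": ["g1"], "chromosome": ["chr1"],
                              "position_bp": [100]})
        peaks = call_age_qtl_peaks(scans, 7.75, 6.0, genes)
        assert len(peaks) == 0  # 6.0 is not > 6.0

    def test_local_vs_distal_classification(self):
        scans = {"g1": pd.DataFrame({"marker_id": ["m1", "m2"],
                                     "chromosome": ["chr1", "chr2"],
                                     "position_bp": [100, 200],
                                     "lod_int": [8.0, 9.0]})}
        genes = pd.DataFrame({"gene_id": ["g1"], "chromosome": ["chr1"],
                              "position_bp": [100]})
        peaks = call_age_qtl_peaks(scans, 7.75, 6.0, genes).set_index("chromosome")
        assert peaks.loc["chr1", "class"] == "local"
        assert peaks.loc["chr2", "class"] == "distal"
        assert peaks.loc["chr2", "significant"]

    def test_hotspot_count_strictly_greater_than_30(self):
        def mk(n):
            return peaks_frame([(f"p{i}", "m", "chr1", 2_000_000, 7.0, True,
                                 "distal", "chr9", 1) for i in range(n)])
        assert len(find_hotspots(mk(30))) == 0   # exactly 30: not a hotspot
        hs = find_hotspots(mk(31))
        assert len(hs) == 1 and hs["qtl_count"].iloc[0] == 31

    def test_local_peaks_not_counted(self):
        peaks = peaks_frame([(f"p{i}", "m", "chr1", 2_000_000, 7.0, True,
                              "local", "chr1", 2_000_000) for i in range(40)])
        assert len(find_hotspots(peaks)) == 0

    def test_overlapping_windows_merged(self):
        rows = [(f"p{i}", "m", "chr1", 1_000_000 + 40_000 * i, 7.0, True,
                 "distal", "chr9", 1) for i in range(80)]
        hs = find_hotspots(peaks_frame(rows))
        assert len(hs) == 1
        assert hs["qtl_count"].iloc[0] == 80

    def test_refine_drops_uncorrelated_member(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=100)
        rows = {f"m{i}": base + rng.normal(0, 0.3, 100) for i in range(12)}
        rows["noise"] = rng.normal(size=100)
        mat = pd.DataFrame(rows).T
        kept = refine_hotspot_members(list(rows), mat)
        assert "noise" not in kept
        assert len(kept) == 12

    def test_refine_boundary_inclusive(self, monkeypatch):
        import agingomics.qtl as qtl_mod
        mat = pd.DataFrame(np.random.default_rng(12).normal(size=(3, 30)),
                           index=["a", "b", "c"])
        import agingomics.stoichiometry as st
        r = np.full((3, 3), 0.3)
        monkeypatch.setattr(st, "nan_pearson",
                            lambda X, min_n=2: (r.copy(), np.full((3, 3), 30)))
        kept = qtl_mod.refine_hotspot_members(["a", "b", "c"], mat)
        assert kept == ["a", "b", "c"]  # mean r exactly 0.3 is retained
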