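"""Genomic relationship matrix: formula fidelity, QC filters, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herit import (GenotypeMatrix, SimulationSpec, build_A, compare_G_A,
                   compute_G, filter_genotypes, gene_drop, impute_missing,
                   simulate_pedigree)


def brute_force_G(counts, theta):
    n, p = counts.shape
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            s = 0.0
            for j in range(p):
                s += ((counts[i, j] - 2 * theta[j]) * (counts[k, j] - 2 * theta[j])
                      / (2 * theta[j] * (1 - theta[j])))
            G[i, k] = s / p
    return G


def random_genotypes(seed, n=20, p=60):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.1, 0.9, p)
    counts = rng.binomial(2, theta, size=(n, p)).astype(float)
    # re-draw any column that came out monomorphic
    for j in range(p):
        while len(np.unique(counts[:, j])) == 1:
            counts[:, j] = rng.binomial(2, 0.5, n)
    return GenotypeMatrix(ids=[f"i{k}" for k in range(n)],
                          snp_ids=[f"s{j}" for j in range(p)], counts=counts)


class TestComputeG:
    def test_two_individual_hand_substitution(self):
        g = GenotypeMatrix(ids=["a", "b"], snp_ids=["s1"],
                           counts=np.array([[2.0], [0.0]]))
        assert g.theta[0] == 0.5  # empirical frequency (2 + 0) / 4
        G = compute_G(g)
        assert G.values[0, 0] == pytest.approx(2.0)
        assert G.values[0, 1] == pytest.approx(-2.0)
        assert G.values[1, 1] == pytest.approx(2.0)

    def test_identical_genotype_vectors(self):
        rng = np.random.default_rng(0)
        row = rng.binomial(2, 0.4, 30).astype(float)
        # two identical individuals leave every SNP monomorphic in-sample,
        # so standardize by an external frozen frequency
        g = GenotypeMatrix(ids=["a", "b"], snp_ids=[f"s{j}" for j in range(30)],
                           counts=np.vstack([row, row]), theta=np.full(30, 0.4))
        G = compute_G(g)
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])
        assert G.values[1, 1] == pytest.approx(G.values[0, 0])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_nested_loop_oracle(self, seed):
        g = random_genotypes(seed, n=20, p=60)
        G = compute_G(g)
        assert np.max(np.abs(G.values - brute_force_G(g.counts, g.theta))) < 1e-10

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_invariant_to_allele_coding_flip(self, seed):
        g = random_genotypes(seed, n=12, p=40)
        G1 = compute_G(g)
        G2 = compute_G(g.flip_coding())
        assert np.max(np.abs(G1.values - G2.values)) < 1e-10

    def test_monomorphic_snp_rejected(self):
        g = GenotypeMatrix(ids=["a", "b"], snp_ids=["s1"],
                           counts=np.array([[0.0], [0.0]]))
        with pytest.raises(ValueError, match="filter_genotypes"):
            compute_G(g)

    def test_missing_entries_rejected(self):
        g = GenotypeMatrix(ids=["a", "b"], snp_ids=["s1"],
                           counts=np.array([[np.nan], [1.0]]))
        with pytest.raises(ValueError, match="impute_missing"):
            compute_G(g)

    def test_diagonal_mean_near_one_with_insample_frequencies(self):
        spec = SimulationSpec(n_founders=500, n_generations=1,
                              offspring_per_mating=1, n_snps=5000, seed=4)
        ped = simulate_pedigree(spec)
        from herit.simulate import draw_founder_frequencies
        g = gene_drop(ped, draw_founder_frequencies(spec), seed=5)
        G = compute_G(filter_genotypes(g))
        assert abs(np.diag(G.values).mean() - 1.0) < 0.05

    def test_psd_when_p_exceeds_n(self):
        g = random_genotypes(7, n=15, p=200)
        G = compute_G(g)
        assert np.linalg.eigvalsh(G.values)[0] >= -1e-8


class TestFilter:
    def make_toy(self):
        """5 x 10 matrix: snps m1, m2 monomorphic (MAF 0), snp c1 has one
        missing call (call rate 0.8 < 0.9); the other 7 survive."""
        counts = np.tile([0.0, 1, 2, 1, 0], (10, 1)).T  # every column MAF 0.4
        counts[:, 1] = 0.0  # m1: all zero -> MAF 0
        counts[:, 2] = 2.0  # m2: all two -> MAF 0
        counts[0, 5] = np.nan  # c1: 4/5 = 0.8 called (still polymorphic)
        snp_ids = ["k0", "m1", "m2", "k1", "k2", "c1", "k3", "k4", "k5", "k6"]
        return GenotypeMatrix(ids=[f"i{k}" for k in range(5)],
                              snp_ids=snp_ids, counts=counts)

    def test_constructed_failures_and_log(self):
        g = filter_genotypes(self.make_toy())
        assert g.p == 7
        assert set(g.snp_ids) == {"k0", "k1", "k2", "k3", "k4", "k5", "k6"}
        log = g.exclusion_log
        assert set(log["token"]) == {"m1", "m2", "c1"}
        assert set(log.loc[log["reason"] == "maf", "token"]) == {"m1", "m2"}
        assert set(log.loc[log["reason"] == "call_rate", "token"]) == {"c1"}

    def test_clean_input_passes_through(self):
        g = random_genotypes(3)
        out = filter_genotypes(g)
        assert out.snp_ids == g.snp_ids and out.ids == g.ids
        assert np.array_equal(out.counts, g.counts)
        assert len(out.exclusion_log) == 0

    def test_individual_removal_rescues_snp(self):
        """An 85%-called individual is removed first; a SNP failing call
        rate only through that individual's missingness is then retained."""
        counts = np.tile([0.0, 1, 2, 1, 0], (20, 1)).T  # 5 ind x 20 snps
        counts[4, :3] = np.nan  # individual i4: 17/20 = 0.85 called
        g = GenotypeMatrix(ids=[f"i{k}" for k in range(5)],
                           snp_ids=[f"s{j}" for j in range(20)], counts=counts)
        # with i4 present, s0 has call rate 4/5 = 0.8 and would fail
        assert g.snp_call_rate[0] == pytest.approx(0.8)
        out = filter_genotypes(g)
        assert "i4" not in out.ids
        assert "s0" in out.snp_ids
        assert list(out.exclusion_log["token"]) == ["i4"]

    def test_everything_removed_is_an_error(self):
        counts = np.zeros((3, 4))  # all monomorphic
        g = GenotypeMatrix(ids=["a", "b", "c"], snp_ids=list("wxyz"),
                           counts=counts)
        with pytest.raises(ValueError, match="all SNPs removed"):
            filter_genotypes(g)

    def test_theta_frozen_after_filtering(self):
        g = self.make_toy()
        out = filter_genotypes(g)
        imputed = impute_missing(out, seed=0)
        assert np.array_equal(imputed.theta, out.theta)


class TestImpute:
    def test_degenerate_frequency_imputes_zero(self):
        counts = np.array([[0.0], [np.nan], [np.nan]])
        g = GenotypeMatrix(ids=list("abc"), snp_ids=["s"], counts=counts,
                           theta=np.array([0.0]))
        out = impute_missing(g, seed=0)
        assert np.all(out.counts == 0.0)

    def test_complete_input_identical_and_seed_independent(self):
        g = random_genotypes(1)
        a, b = impute_missing(g, seed=1), impute_missing(g, seed=99)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.counts, g.counts)

    def test_imputed_mean_matches_binomial_moment(self):
        n, p = 200, 500  # 1e5 imputed entries
        counts = np.full((n, p), np.nan)
        counts[0, :] = 1.0  # one observed row defines nothing; freeze theta
        g = GenotypeMatrix(ids=[f"i{k}" for k in range(n)],
                           snp_ids=[f"s{j}" for j in range(p)],
                           counts=counts, theta=np.full(p, 0.3))
        out = impute_missing(g, seed=3)
        imputed = out.counts[1:, :]
        se = np.sqrt(2 * 0.3 * 0.7 / imputed.size)
        assert abs(imputed.mean() - 0.6) < 3 * se

    def test_all_missing_column_is_an_error(self):
        counts = np.array([[np.nan], [np.nan]])
        g = GenotypeMatrix(ids=["a", "b"], snp_ids=["dead"], counts=counts)
        with pytest.raises(ValueError, match="dead"):
            impute_missing(g, seed=0)


class TestCompareGA:
    def test_identical_matrices_give_zero_deviation(self, family_pedigree):
        A = build_A(family_pedigree)
        from dataclasses import replace
        G = replace(A, kind="genomic_G")
        cmp_ = compare_G_A(G, A)
        assert np.all(cmp_.pairs["d"] == 0.0)
        assert np.all(cmp_.summary["var_G"].fillna(0.0) == 0.0)
        assert set(np.round(cmp_.summary["level"], 3)) <= {0.0, 0.125, 0.25, 0.5}

    def test_id_mismatch_reported(self, family_pedigree):
        A = build_A(family_pedigree)
        from dataclasses import replace
        G = replace(A, ids=["z" + t for t in A.ids])
        with pytest.raises(ValueError, match="id sets differ"):
            compare_G_A(G, A)

    def test_gene_dropped_bin_means_match_pedigree_levels(self, family_pedigree):
        """E[G] = A: with founder-frequency standardization, the per-level
        mean of G over gene-drop replicates approaches the pedigree level."""
        theta = np.random.default_rng(0).uniform(0.1, 0.5, 800)
        A = build_A(family_pedigree)
        reps = 40
        means = {}
        for r in range(reps):
            g = gene_drop(family_pedigree, theta, seed=100 + r)
            g.theta = g.theta_true  # standardize by the known frequencies
            cmp_ = compare_G_A(compute_G(g), A)
            for lv, m in zip(cmp_.summary["level"], cmp_.summary["mean_G"]):
                means.setdefault(round(lv, 3), []).append(m)
        for lv, vals in means.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - lv) < 4 * se + 1e-3
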