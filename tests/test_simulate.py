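"""Gene-dropping simulator: pedigree shape, Mendelian transmission, truth
bookkeeping, and missingness injection."""

import numpy as np
import pytest

from herit import (SimulationSpec, build_A, gene_drop, inject_missingness,
                   simulate_pedigree, simulate_phenotype)
from herit.simulate import draw_founder_frequencies, simulate_covariates


def spec_with(**kw):
    base = dict(n_founders=10, n_generations=2, offspring_per_mating=2,
                n_snps=50, seed=0)
    base.update(kw)
    return SimulationSpec(**base)


class TestPedigreeShape:
    def test_minimal_two_generation_family(self):
        ped = simulate_pedigree(spec_with(n_founders=2, n_generations=2))
        assert ped.n == 4
        assert ped.is_founder.sum() == 2
        kids = np.where(~ped.is_founder)[0]
        assert len(kids) == 2
        # the two children share both parents: full sibs
        assert ped.sire[kids[0]] == ped.sire[kids[1]]
        assert ped.dam[kids[0]] == ped.dam[kids[1]]

    def test_founders_only(self):
        ped = simulate_pedigree(spec_with(n_generations=1))
        assert ped.n == 10
        assert ped.is_founder.all()

    def test_three_generation_count_matches_direct_enumeration(self):
        # construction rules: pairs = min(males, females) with balanced
        # sexes, so generation sizes are deterministic
        n_f, opm = 20, 3
        gen2 = (n_f // 2) * opm
        gen3 = (gen2 // 2) * opm
        ped = simulate_pedigree(spec_with(n_founders=n_f, n_generations=3,
                                          offspring_per_mating=opm))
        assert ped.n == n_f + gen2 + gen3
        assert (ped.cohort == 2).sum() == gen2
        assert (ped.cohort == 3).sum() == gen3

    def test_structural_invariants(self):
        ped = simulate_pedigree(spec_with(n_founders=16, n_generations=4))
        nonf = ~ped.is_founder
        assert (ped.sire[nonf] >= 0).all() and (ped.dam[nonf] >= 0).all()
        # parents come from the previous generation, sire male / dam female
        for k in np.where(nonf)[0]:
            assert ped.cohort[ped.sire[k]] == ped.cohort[k] - 1
            assert ped.cohort[ped.dam[k]] == ped.cohort[k] - 1
            assert ped.sex[ped.sire[k]] == "M"
            assert ped.sex[ped.dam[k]] == "F"
        assert ped.is_topologically_sorted

    def test_too_few_founders(self):
        with pytest.raises(ValueError, match="cannot form matings"):
            spec_with(n_founders=1)

    def test_deterministic_given_seed(self):
        a = simulate_pedigree(spec_with(seed=42))
        b = simulate_pedigree(spec_with(seed=42))
        assert a.ids == b.ids
        assert np.array_equal(a.sire, b.sire) and np.array_equal(a.dam, b.dam)


class TestGeneDrop:
    def test_degenerate_frequencies(self):
        ped = simulate_pedigree(spec_with())
        g1 = gene_drop(ped, np.ones(5), seed=1)
        assert np.all(g1.counts == 2.0)
        g0 = gene_drop(ped, np.zeros(5), seed=1)
        assert np.all(g0.counts == 0.0)

    def test_mendelian_consistency_exhaustive(self):
        ped = simulate_pedigree(spec_with(n_founders=12, n_generations=3,
                                          n_snps=40, seed=3))
        g = gene_drop(ped, draw_founder_frequencies(spec_with(n_snps=40, seed=3)),
                      seed=5)
        allowed = {0: {0}, 1: {0, 1}, 2: {1}}  # transmissible alleles
        for k in np.where(~ped.is_founder)[0]:
            s, d = g.counts[ped.sire[k]], g.counts[ped.dam[k]]
            child = g.counts[k]
            for j in range(g.p):
                options = {a + b for a in allowed[int(s[j])] for b in allowed[int(d[j])]}
                assert int(child[j]) in options

    def test_founder_allele_frequency_conservation(self):
        theta = np.array([0.1, 0.25, 0.4, 0.5, 0.7])
        ped = simulate_pedigree(SimulationSpec(n_founders=2000, n_generations=1,
                                               offspring_per_mating=1, n_snps=5,
                                               seed=0))
        g = gene_drop(ped, theta, seed=2)
        sample_freq = g.counts.mean(axis=0) / 2.0
        tol = 3.5 * np.sqrt(theta * (1 - theta) / (2 * 2000))
        assert np.all(np.abs(sample_freq - theta) < tol)

    def test_unordered_pedigree_rejected(self, family_pedigree):
        import pandas as pd

        from herit import PedigreeTable
        df = family_pedigree.to_frame().iloc[::-1].reset_index(drop=True)
        shuffled = PedigreeTable.from_frame(df)  # valid, but child-first
        with pytest.raises(ValueError, match="topological order"):
            gene_drop(shuffled, np.full(3, 0.5), seed=0)


class TestPhenotype:
    def test_zero_heritability_gives_zero_breeding_values(self):
        spec = spec_with(true_h2=0.0)
        ped = simulate_pedigree(spec)
        g = gene_drop(ped, draw_founder_frequencies(spec), seed=1)
        pheno, truth = simulate_phenotype(ped, spec, genotypes=g)
        assert np.all(truth.true_breeding_values == 0.0)
        assert truth.true_sigma2_u == 0.0

    def test_variance_component_algebra(self):
        spec = spec_with(true_h2=0.5, total_variance=2.0)
        assert spec.sigma2_u == 1.0 and spec.sigma2_e == 1.0
        assert spec_with(true_h2=0.3, total_variance=10.0).sigma2_u == pytest.approx(3.0)

    def test_exactly_one_genetic_input(self):
        spec = spec_with()
        ped = simulate_pedigree(spec)
        with pytest.raises(ValueError, match="exactly one"):
            simulate_phenotype(ped, spec)

    def test_realized_heritability_bookkeeping(self):
        spec = spec_with(n_founders=400, n_generations=3, n_snps=1000,
                         true_h2=0.5, seed=7)
        ped = simulate_pedigree(spec)
        g = gene_drop(ped, draw_founder_frequencies(spec), seed=8)
        pheno, truth = simulate_phenotype(ped, spec, genotypes=g)
        u = truth.true_breeding_values
        cov = simulate_covariates(ped, spec)
        eps = pheno["pheno"].to_numpy() - u - (
            spec.covariate_effects["sex"] * cov["sex"]
            + spec.covariate_effects["age"] * cov["age"]
            + spec.covariate_effects["pc1"] * cov["pc1"]
            + spec.covariate_effects["pc2"] * cov["pc2"]
            + spec.covariate_effects["cohort2"] * (cov["cohort"] == 2)
            + spec.covariate_effects["cohort3"] * (cov["cohort"] == 3)
        ).to_numpy()
        realized = u.var() / (u.var() + eps.var())
        assert abs(realized - 0.5) < 0.06

    def test_infinitesimal_quadratic_form_identity(self):
        """E[u' A^-1 u / n] = sigma2_u when u ~ MVN(0, A * sigma2_u)."""
        spec = spec_with(n_founders=40, n_generations=3, genetic_model="infinitesimal",
                         true_h2=0.5, total_variance=2.0)
        ped = simulate_pedigree(spec)
        A = build_A(ped)
        Ainv = np.linalg.inv(A.values)
        reps = 300
        q = np.empty(reps)
        for r in range(reps):
            sp = spec_with(n_founders=40, n_generations=3,
                           genetic_model="infinitesimal", true_h2=0.5,
                           total_variance=2.0, seed=1000 + r)
            _, truth = simulate_phenotype(ped, sp, A=A)
            u = truth.true_breeding_values
            q[r] = u @ Ainv @ u / ped.n
        se = q.std(ddof=1) / np.sqrt(reps)
        assert abs(q.mean() - spec.sigma2_u) < 3 * se


class TestMissingness:
    def test_zero_rate_is_identity(self):
        ped = simulate_pedigree(spec_with())
        g = gene_drop(ped, np.full(10, 0.3), seed=0)
        assert inject_missingness(g, 0.0, seed=1) is g

    def test_observed_rate_within_binomial_error(self):
        ped = simulate_pedigree(SimulationSpec(n_founders=100, n_generations=1,
                                               offspring_per_mating=1,
                                               n_snps=10000, seed=0))
        g = gene_drop(ped, np.full(10000, 0.3), seed=1)
        gm = inject_missingness(g, 0.01, seed=2)
        frac = np.isnan(gm.counts).mean()
        assert abs(frac - 0.01) < 3 * np.sqrt(0.01 * 0.99 / 1e6)

    def test_all_missing_column_has_zero_call_rate(self):
        ped = simulate_pedigree(spec_with(n_founders=3, n_generations=1))
        g = gene_drop(ped, np.full(40, 0.5), seed=0)
        gm = inject_missingness(g, 0.5, seed=3)
        all_missing = np.isnan(gm.counts).all(axis=0)
        if all_missing.any():
            assert np.all(gm.snp_call_rate[all_missing] == 0.0)
        # call-rate bookkeeping always consistent with the mask
        assert np.allclose(gm.snp_call_rate, 1 - np.isnan(gm.counts).mean(axis=0))
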