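"""SFS construction, expected spectra, composite likelihood, conversions."""

import math
from fractions import Fraction

import numpy as np
import pytest

import tigerscan as ts
from tigerscan.coalsim import DemographicModel, PopulationSpec
from tigerscan.demography import (
    FoldedSFS,
    composite_log_likelihood,
    expected_sfs,
    fit_parameters,
    generations_to_years,
    sfs_from_genotypes,
    years_to_generations,
)

from conftest import make_gm


class TestSfsFromGenotypes:
    def test_folded_marginal_on_toy_matrix(self):
        # 2 diploids, three sites with minor-allele counts (1, 1, 2)
        g = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
        gm = make_gm(g, populations=["p", "p"])
        sfs = sfs_from_genotypes(gm, ["p"])
        assert sfs.sample_alleles == (4,)
        assert list(sfs.polymorphic_counts()) == [0, 2, 1, 0, 0]

    def test_monomorphic_sites_kept_in_total_only(self):
        g = np.zeros((2, 5), dtype=np.int8)
        gm = make_gm(g, populations=["p", "p"])
        sfs = sfs_from_genotypes(gm, ["p"])
        assert sfs.n_polymorphic == 0
        assert sfs.n_sites_total == 5

    def test_folding_invariance_under_allele_relabeling(self, rng):
        g = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        gm = make_gm(g, populations=["p", "p", "p", "q", "q", "q"])
        flipped = make_gm(2 - g, populations=["p", "p", "p", "q", "q", "q"])
        a = sfs_from_genotypes(gm, ["p", "q"])
        b = sfs_from_genotypes(flipped, ["p", "q"])
        assert np.array_equal(a.counts, b.counts)

    def test_missing_genotypes_rejected(self):
        g = np.zeros((2, 2), dtype=np.int8)
        g[0, 0] = -1
        gm = make_gm(g, populations=["p", "p"])
        with pytest.raises(ValueError, match="missing"):
            sfs_from_genotypes(gm, ["p"])


class TestExpectedSfs:
    def test_symmetric_demes_have_equal_marginals(self):
        model = DemographicModel(
            populations=[
                PopulationSpec("A", 500, 3, 300, parent="ROOT"),
                PopulationSpec("B", 500, 3, 300, parent="ROOT"),
            ],
            metapopulations=[PopulationSpec("ROOT", 500)],
            mutation_rate=1e-7,
        )
        probs = expected_sfs(model, 2_000, seed=5, window_length=5_000)
        sizes = (6, 6)
        sfs = FoldedSFS(["A", "B"], sizes, (probs * 1e6).astype(np.int64), 0)
        ma = sfs.marginal("A") / 1e6
        mb = sfs.marginal("B") / 1e6
        assert np.allclose(ma, mb, atol=0.02)

    def test_neutral_unfolded_spectrum_proportions(self):
        # single deme, n=4 lineages: xi_i proportional to 1/i
        model = DemographicModel(
            populations=[PopulationSpec("A", 500, sample_size=2)],
            mutation_rate=1e-7,
        )
        probs = expected_sfs(model, 4_000, seed=9, window_length=5_000, folded=False)
        an = 1 + 1 / 2 + 1 / 3
        expected = np.array([1, 1 / 2, 1 / 3]) / an
        assert np.allclose(probs[1:4], expected, atol=0.02)

    def test_probabilities_sum_to_one_over_polymorphic_cells(self):
        model = DemographicModel(
            populations=[PopulationSpec("A", 500, sample_size=2)], mutation_rate=1e-7
        )
        probs = expected_sfs(model, 500, seed=1, window_length=5_000)
        assert probs.sum() == pytest.approx(1.0)
        assert probs[0] == 0.0 and probs[-1] == 0.0


class TestCompositeLikelihood:
    def _sfs(self, counts):
        counts = np.asarray(counts, dtype=np.int64)
        return FoldedSFS(["p"], (len(counts) - 1,), counts, int(counts.sum()))

    def test_hand_computed_value(self):
        obs = self._sfs([0, 3, 1, 0])  # polymorphic counts (3, 1)
        probs = np.array([0.0, 0.75, 0.25, 0.0])
        cl = composite_log_likelihood(obs, probs)
        assert cl == pytest.approx(3 * math.log(0.75) + math.log(0.25), abs=1e-10)
        assert cl == pytest.approx(-2.24934, abs=1e-5)

    def test_observed_proportions_maximize(self, rng):
        obs = self._sfs([0, 30, 15, 5, 0])
        best = np.array([0.0, 30, 15, 5, 0.0]) / 50
        cl_best = composite_log_likelihood(obs, best)
        for _ in range(50):
            p = rng.dirichlet(np.ones(3))
            alt = np.array([0.0, *p, 0.0])
            assert composite_log_likelihood(obs, alt) <= cl_best + 1e-9

    def test_additive_over_independent_blocks(self):
        a = self._sfs([0, 3, 1, 0])
        b = self._sfs([0, 1, 2, 0])
        both = self._sfs([0, 4, 3, 0])
        probs = np.array([0.0, 0.6, 0.4, 0.0])
        assert composite_log_likelihood(both, probs) == pytest.approx(
            composite_log_likelihood(a, probs) + composite_log_likelihood(b, probs)
        )

    def test_mass_on_zero_probability_cell_errors(self):
        obs = self._sfs([0, 3, 1, 0])
        probs = np.array([0.0, 1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="zero-probability"):
            composite_log_likelihood(obs, probs)


class TestFit:
    def _two_deme(self, T, mu=1e-7):
        return DemographicModel(
            populations=[
                PopulationSpec("P1", 2_000, 4, T, 0.0, parent="ROOT"),
                PopulationSpec("P2", 2_000, 4, T, 0.0, parent="ROOT"),
            ],
            metapopulations=[PopulationSpec("ROOT", 5_000)],
            mutation_rate=mu,
        )

    def _observed(self, model, seed, n_windows=800):
        sims = ts.simulate_null_windows(model, n_windows, 10_000, seed)
        # pool the per-window spectra directly
        from tigerscan.demography import _fold_cell

        sizes = (8, 8)
        counts = np.zeros((9, 9), np.int64)
        total = 0
        for s in sims:
            g = s.genotypes
            c1 = g.allele_counts("P1")[0]
            c2 = g.allele_counts("P2")[0]
            for j in range(g.n_sites):
                counts[_fold_cell((int(c1[j]), int(c2[j])), sizes)] += 1
            total += g.n_sites
        return FoldedSFS(["P1", "P2"], sizes, counts, total)

    def test_zero_free_parameters_returns_template_evaluation(self):
        model = self._two_deme(800)
        obs = self._observed(model, seed=21, n_windows=200)
        res = fit_parameters(obs, model, [], [], seed=4, n_replicates=200)
        assert res.parameter_estimates == {}
        assert math.isfinite(res.log_composite_likelihood)

    def test_generating_model_beats_misspecified(self):
        # the generating model (with a founder bottleneck) should out-score
        # a bottleneck-free variant on its own data in most replicates
        gen = DemographicModel(
            populations=[
                PopulationSpec("P1", 2_000, 4, 800, 0.0, parent="ROOT"),
                PopulationSpec("P2", 2_000, 4, 800, 0.0, parent="ROOT"),
            ],
            metapopulations=[PopulationSpec("ROOT", 5_000)],
            bottlenecks=[ts.BottleneckEvent("P1", 700, 100, 50)],
            mutation_rate=1e-7,
        )
        mis = DemographicModel(
            populations=gen.populations,
            metapopulations=gen.metapopulations,
            mutation_rate=1e-7,
        )
        wins = 0
        for seed in range(5):
            obs = self._observed(gen, seed=100 + seed, n_windows=500)
            cl_gen = fit_parameters(obs, gen, [], [], seed=7, n_replicates=400).log_composite_likelihood
            cl_mis = fit_parameters(obs, mis, [], [], seed=7, n_replicates=400).log_composite_likelihood
            wins += cl_gen >= cl_mis
        assert wins >= 4

    def test_fit_deterministic_given_seed(self):
        model = self._two_deme(800)
        obs = self._observed(model, seed=31, n_windows=200)
        kw = dict(n_replicates=150, n_restarts=1, maxiter=8)
        r1 = fit_parameters(obs, model, ["P1.divergence_time"], [(200.0, 2_000.0)], seed=9, **kw)
        r2 = fit_parameters(obs, model, ["P1.divergence_time"], [(200.0, 2_000.0)], seed=9, **kw)
        assert r1.parameter_estimates == r2.parameter_estimates
        assert r1.log_composite_likelihood == r2.log_composite_likelihood


class TestTimeConversions:
    def test_published_divergence_bounds_in_generations(self):
        # 7,500-9,200 years at 5 years per generation
        assert years_to_generations(7_500, 5) == 1_500
        assert years_to_generations(9_200, 5) == 1_840

    def test_zero_and_exact_rational(self):
        assert years_to_generations(0, 5) == 0
        assert years_to_generations(7, 2) == Fraction(7, 2)

    def test_inverse_composition_is_identity(self):
        for years in (0, 5, 7_500, 123_456):
            gens = years_to_generations(years, 5)
            assert generations_to_years(gens, 5) == years

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            years_to_generations(-1, 5)
        with pytest.raises(ValueError):
            years_to_generations(10, 0)
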