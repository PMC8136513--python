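"""Structured-coalescent simulator: closed forms, determinism, symmetry,
and agreement with independent simulators (forward Wright-Fisher, msprime)."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import tigerscan as ts
from tigerscan.coalsim import (
    BottleneckEvent,
    DemographicModel,
    PopulationSpec,
    forward_wf_oracle,
    simulate_genealogy,
    simulate_null_windows,
    simulate_window,
)
from tigerscan.selscan import hudson_fst, window_mpbs


def single_pop(n=1, N=1_000, mu=1e-8, r=0.0):
    return DemographicModel(
        populations=[PopulationSpec("A", N, sample_size=n)],
        mutation_rate=mu,
        recombination_rate=r,
    )


def symmetric_model(n_pops=4, N=1_000, T=600, n=3, mu=5e-8, N_meta=1_000):
    pops = [
        PopulationSpec(f"P{k}", N, sample_size=n, divergence_time=T, parent="ROOT")
        for k in range(1, n_pops + 1)
    ]
    return DemographicModel(
        populations=pops,
        metapopulations=[PopulationSpec("ROOT", N_meta)],
        mutation_rate=mu,
    )


class TestModelValidation:
    def test_population_invariants(self):
        with pytest.raises(ValueError):
            PopulationSpec("A", 0)
        with pytest.raises(ValueError):
            PopulationSpec("A", 10, migration_rate=1.5)

    def test_child_cannot_outlive_parent(self):
        pops = [
            PopulationSpec("A", 100, 1, divergence_time=500, parent="B"),
            PopulationSpec("B", 100, 1, divergence_time=100, parent="ROOT"),
        ]
        with pytest.raises(ValueError, match="diverges after"):
            DemographicModel(populations=pops, metapopulations=[PopulationSpec("ROOT", 100)])

    def test_parent_cycle_detected(self):
        pops = [
            PopulationSpec("A", 100, 1, 100, parent="B"),
            PopulationSpec("B", 100, 1, 100, parent="A"),
        ]
        with pytest.raises(ValueError, match="root"):
            DemographicModel(populations=pops)

    def test_overlapping_bottlenecks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DemographicModel(
                populations=[PopulationSpec("A", 100, 1)],
                bottlenecks=[
                    BottleneckEvent("A", 10, 20, 10),
                    BottleneckEvent("A", 25, 10, 10),
                ],
            )

    def test_bottleneck_intensity_convention(self):
        b = BottleneckEvent("A", 10, 30, 50)
        assert b.intensity == pytest.approx(30 / (2 * 50))

    def test_zero_samples_errors(self):
        with pytest.raises(ValueError, match="sample"):
            simulate_window(single_pop(n=0), 1_000, seed=1)


class TestCoalescentMoments:
    def test_pairwise_coalescence_time_is_2n(self):
        model = single_pop(n=1, N=1_000)
        rng = np.random.default_rng(7)
        t2 = [simulate_genealogy(model, rng).tmrca for _ in range(2_000)]
        assert np.mean(t2) == pytest.approx(2_000, rel=0.05)

    def test_watterson_segregating_sites_n2(self):
        model = single_pop(n=1, N=1_000, mu=1e-8)
        s = [simulate_window(model, 50_000, seed=k).genotypes.n_sites for k in range(2_000)]
        assert np.mean(s) == pytest.approx(2.0, rel=0.10)

    def test_isolated_demes_fst_approaches_one(self):
        pops = [
            PopulationSpec("A", 200, 4, divergence_time=50_000, parent="ROOT"),
            PopulationSpec("B", 200, 4, divergence_time=50_000, parent="ROOT"),
        ]
        model = DemographicModel(
            populations=pops,
            metapopulations=[PopulationSpec("ROOT", 200)],
            mutation_rate=2e-7,
        )
        vals = []
        for k in range(100):
            gm = simulate_window(model, 20_000, seed=k).genotypes
            rec = hudson_fst(gm, ("A", "B"), min_sites=1)
            if rec.fst is not None:
                vals.append(rec.fst)
        assert 0.9 < np.mean(vals) < 1.0


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        model = symmetric_model()
        a = simulate_window(model, 20_000, seed=42)
        b = simulate_window(model, 20_000, seed=42)
        assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        assert np.array_equal(a.genotypes.positions, b.genotypes.positions)

    def test_null_windows_reproducible_and_distinct_across_master_seeds(self):
        model = symmetric_model()
        w1 = simulate_null_windows(model, 10, 10_000, seed=5)
        w2 = simulate_null_windows(model, 10, 10_000, seed=5)
        w3 = simulate_null_windows(model, 10, 10_000, seed=6)
        assert len(w1) == 10
        for a, b in zip(w1, w2):
            assert np.array_equal(a.genotypes.positions, b.genotypes.positions)
        assert any(
            not np.array_equal(a.genotypes.positions, c.genotypes.positions)
            for a, c in zip(w1, w3)
        )


class TestSymmetryAndMonotonicity:
    def test_exchangeable_demes_have_indistinguishable_mpbs(self):
        model = symmetric_model(N=1_000, T=600, n=3, mu=5e-8)
        pops = ["P1", "P2", "P3", "P4"]
        values = {p: [] for p in pops}
        for k in range(5_000):
            gm = simulate_window(model, 10_000, seed=k).genotypes
            v, _, _, _ = window_mpbs(gm, pops, min_sites=5)
            if v is not None:
                for p in pops:
                    values[p].append(v[p])
        arrays = [np.asarray(values[p]) for p in pops]
        for i in range(4):
            for j in range(i + 1, 4):
                assert ks_2samp(arrays[i], arrays[j]).pvalue > 0.01

    def test_smaller_focal_population_raises_mean_mpbs(self):
        base = symmetric_model(N=1_000, T=600, n=3, mu=5e-8)
        shrunk = ts.scale_population(base, "P1", 0.1)
        means = {}
        for name, model in (("base", base), ("shrunk", shrunk)):
            vals = []
            for k in range(400):
                gm = simulate_window(model, 10_000, seed=k).genotypes
                v, _, _, _ = window_mpbs(gm, ["P1", "P2", "P3", "P4"], min_sites=5)
                if v is not None:
                    vals.append(v["P1"])
            means[name] = np.mean(vals)
        assert means["shrunk"] > means["base"]


class TestRecombination:
    def test_arg_preserves_watterson_and_reduces_variance(self):
        m_r = single_pop(n=1, N=1_000, mu=1e-8, r=2e-8)
        m_0 = single_pop(n=1, N=1_000, mu=1e-8, r=0.0)
        s_r = [simulate_window(m_r, 50_000, seed=k).genotypes.n_sites for k in range(800)]
        s_0 = [simulate_window(m_0, 50_000, seed=k).genotypes.n_sites for k in range(800)]
        assert np.mean(s_r) == pytest.approx(2.0, rel=0.15)
        assert np.var(s_r) < np.var(s_0)


class TestForwardWrightFisherOracle:
    def test_refuses_large_models(self):
        with pytest.raises(ValueError, match="too large"):
            forward_wf_oracle(single_pop(N=5_000), 1_000, seed=1)

    def test_deterministic_given_seed(self):
        model = single_pop(N=100, mu=1e-7)
        a = forward_wf_oracle(model, 10_000, seed=3)
        b = forward_wf_oracle(model, 10_000, seed=3)
        assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes)

    def test_watterson_agreement(self):
        model = DemographicModel(
            populations=[PopulationSpec("A", 100, sample_size=2)],
            mutation_rate=1e-7,
        )
        s = [forward_wf_oracle(model, 20_000, seed=k).genotypes.n_sites for k in range(1_000)]
        a3 = 1 + 1 / 2 + 1 / 3
        expected = 4 * 100 * 1e-7 * 20_000 * a3
        assert np.mean(s) == pytest.approx(expected, rel=0.10)


class TestMsprimeCrossCheck:
    def test_two_deme_split_matches_msprime(self):
        msprime = pytest.importorskip("msprime")
        N, T, mu, L, n_rep = 500, 1_000, 5e-8, 20_000, 400
        model = DemographicModel(
            populations=[
                PopulationSpec("A", N, 3, divergence_time=T, parent="ROOT"),
                PopulationSpec("B", N, 3, divergence_time=T, parent="ROOT"),
            ],
            metapopulations=[PopulationSpec("ROOT", N)],
            mutation_rate=mu,
        )
        ours = []
        for k in range(n_rep):
            gm = simulate_window(model, L, seed=k).genotypes
            ours.append(gm.n_sites)
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=N)
        dem.add_population(name="B", initial_size=N)
        dem.add_population(name="ROOT", initial_size=N)
        dem.add_population_split(time=T, derived=["A", "B"], ancestral="ROOT")
        theirs = []
        rng_seeds = range(1, n_rep + 1)
        for sd in rng_seeds:
            tables = msprime.sim_ancestry(
                samples={"A": 3, "B": 3},
                demography=dem,
                sequence_length=L,
                random_seed=sd,
            )
            mts = msprime.sim_mutations(tables, rate=mu, random_seed=sd)
            theirs.append(mts.num_sites)
        se = np.hypot(np.std(ours) / np.sqrt(n_rep), np.std(theirs) / np.sqrt(n_rep))
        assert abs(np.mean(ours) - np.mean(theirs)) < 3 * se
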