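"""Genotype container, VCF round-trips, filters, window tiling, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tigerscan.variants import (
    MISSING,
    FilterConfig,
    apply_filters,
    genotype_pca,
    read_vcf,
    tile_windows,
    write_vcf,
)

from conftest import make_gm

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=sc1,length=2000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
sc1\t101\t.\tA\tT\t.\tPASS\t.\tGT:DP:GQ\t0/1:20:60\t1/1:15:50
sc1\t200\t.\tA\tAT\t.\tPASS\t.\tGT:DP:GQ\t0/0:20:60\t0/1:15:50
sc1\t300\t.\tC\tG,T\t.\tPASS\t.\tGT:DP:GQ\t0/0:20:60\t0/1:15:50
sc1\t400\t.\tG\tC\t.\tPASS\t.\tGT:DP:GQ\t0/0:9:60\t./.:.:.
sc1\t500\t.\tT\tA\t.\tPASS\t.\tGT:DP:GQ\t1/1:30:99\t0/0:25:80
"""


class TestReadVcf:
    def test_skips_indels_and_multiallelics_and_converts_coordinates(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(TOY_VCF)
        gm = read_vcf(path, {"a": "A", "b": "B"})
        assert gm.n_sites == 3  # indel and triallelic records skipped
        assert list(gm.positions) == [100, 399, 499]  # 1-based -> 0-based
        assert gm.genotypes[0, 0] == 1 and gm.genotypes[1, 0] == 2
        assert gm.genotypes[1, 1] == MISSING
        assert gm.depth[0, 1] == 9

    def test_unmapped_sample_errors(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(TOY_VCF)
        with pytest.raises(ValueError, match="population map"):
            read_vcf(path, {"a": "A"})

    def test_round_trip_is_identity(self, tmp_path, rng):
        g = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        g[1, 5] = MISSING
        gm = make_gm(g, populations=["A", "A", "B", "B"])
        out = tmp_path / "rt.vcf"
        write_vcf(gm, out)
        back = read_vcf(out, dict(zip(gm.sample_ids, gm.population_labels)))
        assert np.array_equal(back.genotypes, gm.genotypes)
        assert np.array_equal(back.positions, gm.positions)
        assert back.scaffolds == gm.scaffolds
        # second round trip is byte-identical
        out2 = tmp_path / "rt2.vcf"
        write_vcf(back, out2)
        assert out.read_bytes() == out2.read_bytes()


class TestFilters:
    def _toy(self):
        # 20 samples x 6 sites engineered so that, at the scan thresholds,
        # sites 1 and 2 fail MAF, site 3 fails missingness, and one genotype
        # at site 4 fails DP; sites 0, 4, 5 survive.
        n = 20
        g = np.zeros((n, 6), dtype=np.int8)
        g[:5, 0] = 1  # maf 5/40 = 0.125
        # site 1: monomorphic ref (maf 0)
        g[:, 2] = 2  # monomorphic alt (maf 0)
        g[:8, 3] = 1
        g[0, 3] = MISSING
        g[1, 3] = MISSING  # 2/20 = 10% missing
        g[:6, 4] = 2  # maf 12/40 = 0.3
        g[:4, 5] = 1  # maf 4/40 = 0.1
        dp = np.full((n, 6), 30, dtype=np.int32)
        dp[2, 4] = 5  # one low-depth genotype at a surviving site
        return make_gm(g, depth=dp)

    def test_stated_thresholds_on_constructed_matrix(self):
        gm = self._toy()
        cfg = FilterConfig(min_gq=0, min_dp=10, min_maf=0.025, max_missing_fraction=0.05, min_scaffold_length=0)
        out = apply_filters(gm, cfg)
        assert list(out.positions) == [0, 400, 500]
        assert out.genotypes[2, 1] == MISSING  # DP-masked call

    def test_all_zero_thresholds_are_identity(self):
        gm = self._toy()
        cfg = FilterConfig(0, 0, 0.0, 1.0, 0, require_complete=False)
        out = apply_filters(gm, cfg)
        assert np.array_equal(out.genotypes, gm.genotypes)
        assert out.n_sites == gm.n_sites

    def test_require_complete_drops_sites_with_missing_calls(self):
        g = np.zeros((4, 2), dtype=np.int8)
        g[:2, 0] = 1
        g[0, 1] = MISSING
        g[1:, 1] = 1
        gm = make_gm(g)
        cfg = FilterConfig(0, 0, 0.0, 1.0, 0, require_complete=True)
        out = apply_filters(gm, cfg)
        assert list(out.positions) == [0]

    def test_short_scaffolds_dropped(self):
        gm = self._toy()  # scaffold shorter than 1 Mb + margin
        cfg = FilterConfig(0, 0, 0.0, 1.0, min_scaffold_length=10_000_000)
        out = apply_filters(gm, cfg)
        assert out.n_sites == 0 and out.scaffolds == {}

    def test_filtering_is_idempotent(self):
        gm = self._toy()
        cfg = FilterConfig(min_maf=0.025, max_missing_fraction=0.05, min_scaffold_length=0)
        once = apply_filters(gm, cfg)
        twice = apply_filters(once, cfg)
        assert np.array_equal(once.genotypes, twice.genotypes)
        assert np.array_equal(once.positions, twice.positions)


class TestTileWindows:
    @pytest.mark.parametrize(
        "length,n_full",
        [(100_000, 6), (50_000, 1), (1_000_000, 96)],
    )
    def test_full_window_counts(self, length, n_full):
        ws = tile_windows({"s": length}, 50_000, 10_000)
        full = [w for w in ws if not w.partial]
        assert len(full) == n_full
        assert [w.start for w in full] == [k * 10_000 for k in range(n_full)]

    def test_short_scaffold_single_window(self):
        (w,) = tile_windows({"s": 7_000}, 50_000, 10_000)
        assert (w.start, w.end, w.partial) == (0, 7_000, True)

    def test_terminal_partial_rule(self):
        # tail of 40 kb >= half window -> emitted and flagged
        ws = tile_windows({"s": 100_000}, 50_000, 10_000)
        partials = [w for w in ws if w.partial]
        assert [(w.start, w.end) for w in partials] == [(60_000, 100_000)]
        # covered tail below half window -> suppressed (wide step)
        ws = tile_windows({"s": 130_000}, 50_000, 40_000)
        assert all(not w.partial for w in ws)
        # short uncovered tail still emitted to preserve coverage
        ws = tile_windows({"s": 132_000}, 50_000, 40_000)
        assert [(w.start, w.end) for w in ws if w.partial] == [(120_000, 132_000)]

    @given(length=st.integers(1_000, 2_000_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_every_base_covered(self, length):
        ws = tile_windows({"s": length}, 50_000, 10_000)
        covered = np.zeros(length, dtype=bool)
        for w in ws:
            covered[w.start : w.end] = True
        assert covered.all()


class TestGenotypePca:
    def test_two_homozygous_groups_split_on_pc1(self):
        g = np.array([[0] * 10] * 3 + [[2] * 10] * 3, dtype=np.int8)
        gm = make_gm(g, populations=["A"] * 3 + ["B"] * 3)
        coords, var = genotype_pca(gm, 2)
        assert var[0] > 0.999
        a, b = coords[:3, 0], coords[3:, 0]
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_sample_order_invariance_up_to_sign(self, rng):
        g = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        gm = make_gm(g)
        perm = rng.permutation(8)
        gmp = make_gm(g[perm])
        c1, _ = genotype_pca(gm, 2)
        c2, _ = genotype_pca(gmp, 2)
        for k in range(2):
            x, y = c1[perm, k], c2[:, k]
            assert np.allclose(x, y, atol=1e-8) or np.allclose(x, -y, atol=1e-8)

    def test_monomorphic_only_errors(self):
        gm = make_gm(np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValueError, match="polymorphic"):
            genotype_pca(gm)

    def test_four_population_structure_recovered(self):
        # simulated structured data: samples cluster with their own
        # population in PC1-PC2 space
        import tigerscan as ts
        from tigerscan.variants import GenotypeMatrix

        pops = [
            ts.PopulationSpec(p, 500, sample_size=5, divergence_time=1_500, parent="ROOT")
            for p in ("P1", "P2", "P3", "P4")
        ]
        model = ts.DemographicModel(
            populations=pops,
            metapopulations=[ts.PopulationSpec("ROOT", 2_000)],
            mutation_rate=5e-8,
        )
        sims = ts.simulate_null_windows(model, 40, 20_000, seed=11)
        gm = GenotypeMatrix.concatenate([s.genotypes for s in sims])
        coords, _ = genotype_pca(gm, 2)
        labels = np.array(gm.population_labels)
        centroids = {p: coords[labels == p].mean(axis=0) for p in set(labels)}
        correct = sum(
            min(centroids, key=lambda p: np.linalg.norm(coords[i] - centroids[p]))
            == labels[i]
            for i in range(gm.n_samples)
        )
        assert correct >= 0.95 * gm.n_samples
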