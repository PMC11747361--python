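import numpy as np
import pytest

from gapseq import popgen_windows as pg
from gapseq.simdata import simulate_two_pop_genotypes, write_popmap, write_vcf

from helpers import random_genotypes, tajima_d_oracle, wc_fst_oracle

# -- VCF fixture -------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=250000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
)


def _vcf(tmp_path, body, n_samples=10):
    names = "\t".join(f"s{i}" for i in range(n_samples))
    path = tmp_path / "in.vcf"
    path.write_text(
        VCF_HEADER
        + f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n"
        + body
    )
    return path


def _site(pos, qual, genotypes, depth=30, ref="A", alt="T"):
    cells = "\t".join(f"{g}:{depth}" for g in genotypes)
    return f"chr1\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT:DP\t{cells}\n"


GTS_BALANCED = ["0/0"] * 4 + ["0/1"] * 3 + ["1/1"] * 3  # alt freq 0.45


class TestFilterSnps:
    def test_low_qual_site_removed(self, tmp_path):
        body = _site(100, 150, GTS_BALANCED) + _site(200, 250, GTS_BALANCED)
        m = pg.filter_snps(_vcf(tmp_path, body))
        assert m.pos.tolist() == [199]

    def test_maf_bound(self, tmp_path):
        rare = ["0/1"] + ["0/0"] * 9  # alt freq 0.05 -> kept (inclusive)
        too_rare = ["0/0"] * 10
        too_rare[0] = "0/0"
        body = _site(100, 999, rare)
        m = pg.filter_snps(_vcf(tmp_path, body))
        assert m.n_sites == 1
        # alt frequency 0.04 is below the floor at 12+ samples
        body = _site(100, 999, ["0/1"] + ["0/0"] * 12)
        m = pg.filter_snps(_vcf(tmp_path, body, n_samples=13))
        assert m.n_sites == 0

    def test_call_rate_after_depth_mask(self, tmp_path):
        seven = [f"{g}" for g in GTS_BALANCED]
        body = _site(100, 999, GTS_BALANCED, depth=4)  # all masked -> dropped
        m = pg.filter_snps(_vcf(tmp_path, body))
        assert m.n_sites == 0
        # 7/10 called (0.7 < 0.8) removed; 8/10 kept
        gts7 = GTS_BALANCED[:7] + ["./."] * 3
        gts8 = GTS_BALANCED[:8] + ["./."] * 2
        body = _site(100, 999, gts7) + _site(200, 999, gts8)
        m = pg.filter_snps(_vcf(tmp_path, body))
        assert m.pos.tolist() == [199]

    def test_multiallelic_removed(self, tmp_path):
        body = _site(100, 999, GTS_BALANCED, alt="T,G")
        assert pg.filter_snps(_vcf(tmp_path, body)).n_sites == 0

    def test_record_order_invariance(self, tmp_path):
        s1 = _site(100, 999, GTS_BALANCED)
        s2 = _site(5000, 999, list(reversed(GTS_BALANCED)))
        a = pg.filter_snps(_vcf(tmp_path, s1 + s2))
        b = pg.filter_snps(_vcf(tmp_path, s2 + s1))
        assert a.pos.tolist() == b.pos.tolist()
        assert np.array_equal(a.gt, b.gt)

    def test_popmap_attached(self, tmp_path):
        body = _site(100, 999, GTS_BALANCED)
        popmap = {f"s{i}": ("p1" if i < 5 else "p2") for i in range(10)}
        m = pg.filter_snps(_vcf(tmp_path, body), popmap=popmap)
        assert m.pop_names() == ["p1", "p2"]
        assert len(m.pop_columns("p1")) == 5


class TestTajimaD:
    def test_four_haplotype_example(self):
        # haplotypes AAA, AAT, ATT, TTT as two diploids
        gt = np.array([[0, 1], [0, 2], [1, 2]], dtype=np.int8)
        assert pg.tajima_d(gt) == pytest.approx(0.16766, abs=1e-4)
        assert pg.tajima_d(gt) == pytest.approx(tajima_d_oracle(gt), abs=1e-12)

    def test_no_segregating_sites_missing(self):
        assert pg.tajima_d(np.zeros((5, 4), dtype=np.int8)) is None

    def test_excess_singletons_negative(self, rng):
        # 10 haplotypes (5 diploids), 5 singleton sites
        gt = np.zeros((5, 5), dtype=np.int8)
        for i in range(5):
            gt[i, i] = 1
        assert pg.tajima_d(gt) < 0

    def test_agrees_with_oracle_under_missingness(self, rng):
        for _ in range(100):
            gt = random_genotypes(rng, rng.integers(1, 30), rng.integers(4, 20))
            mine, ref = pg.tajima_d(gt), tajima_d_oracle(gt)
            if ref is None:
                assert mine is None
            else:
                assert mine == pytest.approx(ref, abs=1e-9)


class TestWcFst:
    def test_fixed_difference_is_one(self):
        gt = np.concatenate(
            [np.full((3, 10), 2, dtype=np.int8), np.zeros((3, 10), dtype=np.int8)], axis=1
        )
        labels = ["a"] * 10 + ["b"] * 10
        assert pg.wc_fst(gt, labels) == 1.0

    def test_monomorphic_is_missing(self):
        gt = np.zeros((4, 20), dtype=np.int8)
        assert pg.wc_fst(gt, ["a"] * 10 + ["b"] * 10) is None

    def test_locked_single_site_value(self):
        # pop1: 0/0 x3, 0/1 x2; pop2: 1/1 x3, 0/1 x2
        gt = np.array([[0, 0, 0, 1, 1, 2, 2, 2, 1, 1]], dtype=np.int8)
        labels = ["p1"] * 5 + ["p2"] * 5
        locked = 0.4852941176470588  # brute-force variance components
        assert pg.wc_fst(gt, labels) == pytest.approx(locked, abs=1e-12)
        assert wc_fst_oracle(gt, labels) == pytest.approx(locked, abs=1e-12)

    def test_three_populations_error(self):
        gt = np.zeros((1, 6), dtype=np.int8)
        with pytest.raises(ValueError):
            pg.wc_fst(gt, ["a", "a", "b", "b", "c", "c"])

    def test_bounds_on_random_inputs(self, rng):
        labels = ["a"] * 8 + ["b"] * 8
        for _ in range(200):
            gt = random_genotypes(rng, rng.integers(1, 20), 16)
            v = pg.wc_fst(gt, labels)
            if v is not None:
                assert -1.0 <= v <= 1.0 + 1e-12


def _matrix(positions, gt, n_per_pop=5, seq_len=250_000):
    pops = np.asarray(["p1"] * n_per_pop + ["p2"] * n_per_pop)
    samples = [f"s{i}" for i in range(2 * n_per_pop)]
    return pg.GenotypeMatrix(
        np.asarray(["chr1"] * len(positions)), np.asarray(positions),
        np.asarray(gt, dtype=np.int8), samples, pops, {"chr1": seq_len},
    )


class TestWindowScan:
    def test_tiling_includes_trailing_partial_window(self, rng):
        m = _matrix([10], random_genotypes(rng, 1, 10, 0))
        stats = pg.window_scan(m, pg.ScanParams(window=100_000, n_perm=1))
        assert [(w.start, w.end) for w in stats] == [
            (0, 100_000), (100_000, 200_000), (200_000, 250_000)
        ]

    def test_boundary_snp_in_second_window(self, rng):
        m = _matrix([100_000], random_genotypes(rng, 1, 10, 0))
        stats = pg.window_scan(m, pg.ScanParams(window=100_000, n_perm=1))
        assert [w.n_snps for w in stats] == [0, 1, 0]

    def test_empty_matrix_all_missing(self):
        m = _matrix([], np.zeros((0, 10), dtype=np.int8))
        stats = pg.window_scan(m, pg.ScanParams(window=100_000, n_perm=1))
        assert len(stats) == 3
        assert all(w.fst is None for w in stats)
        assert all(v is None for w in stats for v in w.tajima_d.values())


class TestPermutationOutliers:
    def test_planted_fixed_difference_window_flagged(self):
        truth = simulate_two_pop_genotypes(
            600, 25, fst_target=0.0, outlier_windows=[3], window=100_000,
            chrom_len=3_000_000, seed=77,
        )
        params = pg.ScanParams(window=100_000, n_perm=500, alpha=0.01, seed=1)
        stats = pg.window_scan(truth.matrix, params)
        planted = next(i for i, w in enumerate(stats) if w.start == 300_000)
        assert stats[planted].fst == pytest.approx(1.0)
        scan = pg.permutation_outliers(stats, truth.matrix, params)
        assert planted in scan.high_fst

    def test_alpha_one_flags_every_defined_window(self):
        truth = simulate_two_pop_genotypes(
            300, 10, fst_target=0.1, window=100_000, chrom_len=2_000_000, seed=5,
        )
        params = pg.ScanParams(window=100_000, n_perm=50, alpha=1.0, seed=2)
        stats = pg.window_scan(truth.matrix, params)
        scan = pg.permutation_outliers(stats, truth.matrix, params)
        defined = [i for i, w in enumerate(scan.stats) if w.p_fst_high is not None]
        assert scan.high_fst == defined and defined

    def test_pvalues_never_zero_and_at_most_one(self):
        truth = simulate_two_pop_genotypes(
            400, 10, fst_target=0.0, window=100_000, chrom_len=2_000_000, seed=9,
        )
        params = pg.ScanParams(window=100_000, n_perm=200, alpha=0.01, seed=3)
        scan = pg.permutation_outliers(pg.window_scan(truth.matrix, params),
                                       truth.matrix, params)
        ps = [w.p_fst_high for w in scan.stats if w.p_fst_high is not None]
        ps += [v for w in scan.stats for v in w.p_d_low.values() if v is not None]
        assert ps and all(0 < p <= 1 for p in ps)


class TestVcfRoundTrip:
    def test_simulated_vcf_survives_filters(self, tmp_path):
        truth = simulate_two_pop_genotypes(
            200, 12, fst_target=0.1, window=100_000, chrom_len=1_000_000, seed=21
        )
        vcf, popmap = tmp_path / "sim.vcf", tmp_path / "pops.tsv"
        write_vcf(truth, vcf)
        write_popmap(truth, popmap)
        m = pg.filter_snps(vcf, popmap=pg.read_popmap(popmap))
        # default QUAL/DP pass the filters; only MAF can drop sites
        assert m.n_sites >= 150
        assert m.seq_lengths == {"chr1": 1_000_000}
        kept = np.isin(truth.matrix.pos, m.pos)
        assert np.array_equal(truth.matrix.gt[kept], m.gt)
        assert m.pop_names() == ["pop1", "pop2"]
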