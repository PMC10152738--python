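"""Catalog hygiene, LD expansion, permutation nulls and meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smorfval import gwas_enrichment as ge
from smorfval.errors import DataError


def catalog_frame(rows):
    return pd.DataFrame(
        rows, columns=["rsid", "chrom", "pos", "ref", "alt", "p_value", "maf", "trait"]
    )


class TestFilterCatalog:
    def test_p_exactly_at_threshold_dropped(self):
        df = catalog_frame([
            ("rs1", "chr1", 100, "A", "G", 5e-8, 0.2, "t"),
            ("rs2", "chr1", 200, "A", "G", 4.9e-8, 0.2, "t"),
        ])
        out = ge.filter_catalog(df)
        assert list(out["rsid"]) == ["rs2"]

    def test_duplicate_rsid_collapsed(self):
        df = catalog_frame([
            ("rs1", "chr1", 100, "A", "G", 1e-9, 0.2, "t1"),
            ("rs1", "chr1", 100, "A", "G", 1e-9, 0.2, "t2"),
        ])
        assert len(ge.filter_catalog(df)) == 1

    def test_multiallelic_dropped(self):
        df = catalog_frame([
            ("rs1", "chr1", 100, "A", "G,T", 1e-9, 0.2, "t"),
            ("rs2", "chr1", 200, "A", "G", 1e-9, 0.2, "t"),
            ("rs3", "chr1", 200, "A", "T", 1e-9, 0.2, "t"),  # second allele at 200
        ])
        out = ge.filter_catalog(df)
        assert list(out["rsid"]) == []

    def test_missing_p_dropped_with_warning(self):
        df = catalog_frame([
            ("rs1", "chr1", 100, "A", "G", np.nan, 0.2, "t"),
            ("rs2", "chr1", 200, "A", "G", 1e-9, 0.2, "t"),
        ])
        assert list(ge.filter_catalog(df)["rsid"]) == ["rs2"]


class TestLdExpand:
    def _arrays(self):
        return pd.DataFrame(
            {"rsid": ["a1"], "chrom": ["chr1"], "pos": [1_000_000], "maf": [0.25]}
        )

    def _pairs(self, rows):
        return pd.DataFrame(
            rows, columns=["snv_a", "snv_b", "chrom_b", "pos_b", "maf_b", "r2"]
        )

    def test_r2_bound_inclusive(self):
        pairs = self._pairs([
            ("a1", "p1", "chr1", 1_000_100, 0.3, 0.79),
            ("a1", "p2", "chr1", 1_000_200, 0.3, 0.80),
        ])
        uni = ge.ld_expand(self._arrays(), pairs)
        assert set(uni.snvs["rsid"]) == {"a1", "p2"}

    def test_window_bound(self):
        pairs = self._pairs([
            ("a1", "far", "chr1", 2_000_001, 0.3, 0.9),
            ("a1", "near", "chr1", 2_000_000, 0.3, 0.9),
        ])
        uni = ge.ld_expand(self._arrays(), pairs)
        assert set(uni.snvs["rsid"]) == {"a1", "near"}

    def test_all_r2_below_threshold_adds_nothing(self):
        pairs = self._pairs([
            ("a1", "p1", "chr1", 1_000_100, 0.3, 0.5),
            ("a1", "p2", "chr1", 1_000_200, 0.3, 0.79),
        ])
        uni = ge.ld_expand(self._arrays(), pairs)
        assert list(uni.snvs["rsid"]) == ["a1"]

    def test_maf_floor_applied(self):
        arrays = pd.DataFrame(
            {"rsid": ["a1", "a2"], "chrom": ["chr1"] * 2,
             "pos": [100, 200], "maf": [0.005, 0.25]}
        )
        uni = ge.ld_expand(arrays, self._pairs([]))
        assert list(uni.snvs["rsid"]) == ["a2"]


class TestMafBins:
    @pytest.mark.parametrize(
        "maf,expected",
        [(0.01, 0), (0.0999, 0), (0.10, 1), (0.2999, 2), (0.30, 3), (0.50, 4),
         (0.0099, -1), (0.51, -1)],
    )
    def test_left_closed_bins(self, maf, expected):
        assert ge.maf_bin_index([maf])[0] == expected


class TestOverlapCount:
    def test_half_open_convention(self):
        index = ge.ExonIndex([("chr1", 100, 200)])
        snvs = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [100, 199, 200]})
        count, hits = ge.overlap_count(snvs, index)
        assert count == 2
        assert list(hits["pos"]) == [100, 199]

    def test_uniform_snvs_match_binomial_expectation(self):
        rng = np.random.default_rng(0)
        index = ge.ExonIndex([("chr1", 0, 10_000)])
        n = 20_000
        snvs = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(0, 100_000, size=n)}
        )
        count, _ = ge.overlap_count(snvs, index)
        # exonic fraction 0.1: binomial mean 2000, sd ~42
        assert abs(count - 2000) < 5 * np.sqrt(n * 0.1 * 0.9)


class TestPermutationBinTest:
    def test_observed_above_all_nulls(self):
        hits = np.zeros(1000, dtype=bool)
        p, null = ge.permutation_bin_test(hits, n_draw=10, observed=1, n_perm=10_000,
                                          rng=np.random.default_rng(0))
        assert p == pytest.approx(1 / 10_001)

    def test_observed_zero_gives_p_one(self):
        hits = np.ones(1000, dtype=bool)
        p, _ = ge.permutation_bin_test(hits, 10, 0, 1000, np.random.default_rng(0))
        assert p == 1.0

    def test_null_mean_matches_binomial_expectation(self):
        rng = np.random.default_rng(1)
        hits = np.zeros(1000, dtype=bool)
        hits[:300] = True
        _, null = ge.permutation_bin_test(hits, 50, 10, 5000, rng)
        assert null.mean() == pytest.approx(50 * 0.3, rel=0.05)

    def test_monotone_in_observed(self):
        rng = np.random.default_rng(2)
        hits = np.zeros(500, dtype=bool)
        hits[:100] = True
        draws = rng.integers(0, 500, size=(2000, 40))
        null = hits.astype(np.int8)[draws].sum(axis=1)
        ps = [ge.empirical_upper_p(null, o) for o in range(0, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_seeded_determinism(self):
        hits = np.zeros(500, dtype=bool)
        hits[:50] = True
        p1, n1 = ge.permutation_bin_test(hits, 30, 5, 2000, np.random.default_rng(9))
        p2, n2 = ge.permutation_bin_test(hits, 30, 5, 2000, np.random.default_rng(9))
        assert p1 == p2 and np.array_equal(n1, n2)

    def test_empty_bin_raises(self):
        with pytest.raises(DataError):
            ge.permutation_bin_test(np.array([], dtype=bool), 5, 0, 100,
                                    np.random.default_rng(0))


class TestFishersMeta:
    def test_all_ones(self):
        t, df, p = ge.fishers_meta([1, 1, 1, 1, 1])
        assert t == pytest.approx(0.0)
        assert df == 10 and p == pytest.approx(1.0)

    def test_two_halves(self):
        t, df, p = ge.fishers_meta([0.5, 0.5])
        assert t == pytest.approx(2.7726, abs=1e-3)
        assert p == pytest.approx(0.5966, abs=1e-3)

    def test_five_small_ps(self):
        # chi-square tail oracle at T = -10 ln(0.01), 10 df: 1.40e-6
        _, _, p = ge.fishers_meta([0.01] * 5)
        assert p < 1e-5
        assert p == pytest.approx(float(stats.chi2.sf(-2 * 5 * np.log(0.01), 10)))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(DataError):
            ge.fishers_meta([0.0, 0.5])


class TestDamagingPermutation:
    def test_all_damaging_pool_gives_p_one(self):
        pool = np.full(100, 0.99)
        p = ge.damaging_permutation(pool, n_total=18, observed_damaging=18,
                                    n_perm=2000, seed=0)
        assert p == 1.0

    def test_matches_exact_binomial_oracle(self):
        # pool half damaging: P(X >= 9 | n=18, q=0.5) ~ 0.5927
        pool = np.concatenate([np.full(500, 0.9), np.full(500, 0.1)])
        p = ge.damaging_permutation(pool, 18, 9, n_perm=20_000, seed=1)
        exact = float(stats.binom.sf(8, 18, 0.5))
        assert p == pytest.approx(exact, abs=0.02)

    def test_observed_above_total_raises(self):
        with pytest.raises(DataError):
            ge.damaging_permutation(np.array([0.9]), 5, 6)

    def test_fisher_exact_path(self):
        p = ge.fisher_exact_damaging(9, 18, 500, 1000)
        assert 0 < p <= 1


class TestRunEnrichment:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 5000
        snvs = pd.DataFrame({
            "rsid": [f"s{i}" for i in range(n)],
            "chrom": "chr1",
            "pos": rng.integers(0, 100_000, size=n),
            "maf": rng.uniform(0.01, 0.5, size=n),
        })
        snvs["bin"] = ge.maf_bin_index(snvs["maf"].to_numpy())
        universe = ge.BackgroundUniverse(snvs)
        index = ge.ExonIndex([("chr1", 0, 20_000)])
        return universe, index, rng

    def test_empty_bins_excluded_from_df(self):
        universe, index, rng = self._setup()
        catalog = pd.DataFrame({
            "rsid": ["c1", "c2"], "chrom": ["chr1"] * 2,
            "pos": [5, 6], "maf": [0.05, 0.15],
        })
        res = ge.run_enrichment(catalog, universe, index, n_perm=500, rng=rng)
        assert len(res.bins) == 2 and res.df == 4

    def test_enriched_catalog_detected(self):
        universe, index, rng = self._setup(3)
        inside = universe.snvs[universe.snvs["pos"] < 20_000]
        catalog = inside.sample(150, random_state=1)[["rsid", "chrom", "pos", "maf"]]
        res = ge.run_enrichment(catalog, universe, index, n_perm=2000, rng=rng)
        assert res.meta_p < 1e-4
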