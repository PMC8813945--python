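"""Fisher/binomial enrichment kernels, BH correction, GMT round trip."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regmeth import enrichment
from regmeth.regions import GenomicInterval, RegionSet


def reference_bh(p):
    """Independent step-up implementation used as oracle."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    # enforce monotonicity from the largest rank down
    for i in range(n - 2, -1, -1):
        ranked[i] = min(ranked[i], ranked[i + 1])
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def hypergeom_tail(a, query_size, set_size, universe_size):
    """P(X >= a) by explicit enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(a, min(query_size, set_size) + 1):
        total += (
            math.comb(set_size, x)
            * math.comb(universe_size - set_size, query_size - x)
            / math.comb(universe_size, query_size)
        )
    return total


class TestBH:
    def test_hand_computed_step_up(self):
        q = enrichment.bh_adjust([0.001, 0.01, 0.03, 0.5])
        assert np.allclose(q, [0.004, 0.02, 0.04, 0.5])

    def test_equal_and_single(self):
        assert np.allclose(enrichment.bh_adjust([0.2, 0.2, 0.2]), 0.2)
        assert enrichment.bh_adjust([0.07])[0] == pytest.approx(0.07)
        assert len(enrichment.bh_adjust([])) == 0

    def test_matches_reference_step_up(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 60))
            assert np.allclose(enrichment.bh_adjust(p), reference_bh(p), atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    def test_step_up_properties(self, p):
        q = enrichment.bh_adjust(p)
        assert (q <= 1.0).all()
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFisher:
    def _sets(self, members):
        return [enrichment.GeneSet("S", "pathway", frozenset(members))]

    def test_worked_example(self):
        universe = [f"g{i}" for i in range(100)]
        genes = self._sets(universe[:10])
        query = universe[:5] + universe[90:95]
        out = enrichment.fisher_enrichment(query, universe, genes)
        row = out.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (5, 5, 5, 85)
        assert row.odds_ratio == pytest.approx(17.0)
        assert row.p == pytest.approx(hypergeom_tail(5, 10, 10, 100), abs=1e-12)

    def test_saturated_query(self):
        universe = [f"g{i}" for i in range(30)]
        out = enrichment.fisher_enrichment(universe, universe, self._sets(universe[:7]))
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_zero_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        out = enrichment.fisher_enrichment(
            universe[20:25], universe, self._sets(universe[:7])
        )
        assert out.iloc[0].p == pytest.approx(1.0) and out.iloc[0].odds_ratio == 0.0

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(30):
            n_univ = int(rng.integers(20, 200))
            universe = [f"g{i}" for i in range(n_univ)]
            set_size = int(rng.integers(1, n_univ))
            query_size = int(rng.integers(1, n_univ))
            members = list(rng.choice(universe, set_size, replace=False))
            query = list(rng.choice(universe, query_size, replace=False))
            out = enrichment.fisher_enrichment(query, universe, self._sets(members))
            a = len(set(query) & set(members))
            expected = hypergeom_tail(a, query_size, set_size, n_univ)
            assert out.iloc[0].p == pytest.approx(expected, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment.fisher_enrichment([], [], self._sets(["g"]))


class TestBinomial:
    def test_degenerate_tails(self):
        assert enrichment.binomial_tail(0, 10, 0.3) == 1.0

    def test_matches_brute_force_sum(self):
        n, k, p0 = 94, 49, 0.3
        expected = sum(
            math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
        )
        assert enrichment.binomial_tail(k, n, p0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k,n,p0", [(3, 12, 0.5), (1, 5, 0.01), (20, 20, 0.9)])
    def test_matches_brute_force_random_cases(self, k, n, p0):
        expected = sum(
            math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
        )
        assert enrichment.binomial_tail(k, n, p0) == pytest.approx(expected, abs=1e-12)


class TestSnpEnrichment:
    def _universe(self):
        tested = [
            GenomicInterval("chr1", 100_000 * (i + 1), 100_000 * (i + 1) + 1000,
                            f"R{i}", "promoter")
            for i in range(20)
        ]
        return RegionSet(tested, "promoter")

    def test_counts_and_p0_default(self):
        tested = self._universe()
        dmrs = RegionSet([tested.lookup(f"R{i}") for i in range(5)], "promoter")
        snps = pd.DataFrame(
            {
                "rsid": [f"rs{i}" for i in range(6)],
                "chrom": "chr1",
                # 4 near DMR regions R0/R1, 1 near non-DMR R10, 1 nowhere
                "pos": [100_500, 101_200, 200_100, 204_000, 1_100_500, 50],
            }
        )
        res = enrichment.snp_dmr_enrichment(snps, dmrs, tested, window_bp=5000)
        assert (res.n_snps, res.k_hits) == (5, 4)
        assert res.p0 == pytest.approx(0.25)
        assert res.p_value == pytest.approx(
            enrichment.binomial_tail(4, 5, 0.25), abs=1e-15
        )

    def test_p0_one_gives_p_one(self):
        tested = self._universe()
        snps = pd.DataFrame({"rsid": ["rs1"], "chrom": ["chr1"], "pos": [100_500]})
        res = enrichment.snp_dmr_enrichment(snps, tested, tested, window_bp=5000)
        assert res.p_value == 1.0

    def test_no_profilable_snps_rejected(self):
        tested = self._universe()
        snps = pd.DataFrame({"rsid": ["rs1"], "chrom": ["chr9"], "pos": [5]})
        with pytest.raises(ValueError):
            enrichment.snp_dmr_enrichment(snps, tested, tested)

    def test_user_supplied_background(self):
        tested = self._universe()
        dmrs = RegionSet([tested.lookup("R0")], "promoter")
        snps = pd.DataFrame({"rsid": ["rs1"], "chrom": ["chr1"], "pos": [100_500]})
        res = enrichment.snp_dmr_enrichment(snps, dmrs, tested, p0=0.4)
        assert res.p0 == 0.4 and res.p_value == pytest.approx(0.4)


class TestSnpNullCalibration:
    def test_null_p_values_uniform(self, rng):
        """SNPs placed uniformly over tested regions: the binomial test's
        p-values are uniform. The statistic is discrete, so the check uses
        the randomized PIT p - V * P(X = k), which is exactly U(0,1) under
        the null."""
        from scipy import stats as ss

        from regmeth.cohort import place_snps

        tested = RegionSet(
            [
                GenomicInterval("chr1", 100_000 * (i + 1), 100_000 * (i + 1) + 1000,
                                f"R{i}", "promoter")
                for i in range(400)
            ],
            "promoter",
        )
        dmr_ids = [f"R{i}" for i in range(100)]
        dmrs = RegionSet([tested.lookup(r) for r in dmr_ids], "promoter")
        lookup = {iv.region_id: iv for iv in tested}
        tested_ids = [iv.region_id for iv in tested]
        n, p0 = 94, 0.25
        pit = []
        for _ in range(200):
            snps, _ = place_snps(rng, lookup, tested_ids, dmr_ids, n, near_dmr_prob=0.0)
            res = enrichment.snp_dmr_enrichment(snps, dmrs, tested)
            assert res.p0 == pytest.approx(p0)
            pmf_k = ss.binom.pmf(res.k_hits, n, p0)
            pit.append(res.p_value - rng.uniform() * pmf_k)
        assert ss.kstest(pit, "uniform").pvalue > 0.01


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = [
            enrichment.GeneSet("alpha", "hallmark", frozenset({"a", "b"})),
            enrichment.GeneSet("beta", "pathway", frozenset({"c"})),
        ]
        path = tmp_path / "sets.gmt"
        enrichment.write_gmt(sets, path)
        back = enrichment.read_gmt(path)
        assert {(s.name, s.category, s.members) for s in back} == {
            (s.name, s.category, s.members) for s in sets
        }
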