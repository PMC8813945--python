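"""Target mapping, functional DMRs, seDMRs, specificity and correlation analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regmeth import integration
from regmeth.regions import GenomicInterval, RegionSet


def _genes(n=10, coding_mask=None):
    coding = [True] * n if coding_mask is None else coding_mask
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n)],
            "promoter_region_id": [f"P{i}" for i in range(n)],
            "is_coding": coding,
        }
    )


class TestPromoterTargets:
    def test_one_to_one_links(self):
        links = integration.map_promoter_targets(_genes(100))
        assert len(links) == 100
        assert links["region_id"].is_unique and links["gene_id"].is_unique

    def test_noncoding_dropped(self):
        genes = _genes(3, coding_mask=[True, False, True])
        links = integration.map_promoter_targets(genes)
        assert set(links["gene_id"]) == {"G0", "G2"}

    def test_duplicate_promoter_rejected(self):
        genes = _genes(2)
        genes.loc[1, "promoter_region_id"] = "P0"
        with pytest.raises(ValueError, match="P0"):
            integration.map_promoter_targets(genes)

    def test_empty_input(self):
        assert integration.map_promoter_targets(_genes(0)).empty


class TestEnhancerTargets:
    def test_many_to_many(self):
        epi = pd.DataFrame(
            {
                "enhancer_id": ["E1", "E1", "E2"],
                "gene_id": ["G0", "G1", "G0"],
                "pet_count": [6, 7, 8],
            }
        )
        links = integration.map_enhancer_targets(epi, _genes(3))
        assert len(links) == 3 and links["gene_id"].nunique() == 2

    def test_matches_brute_force_join(self, rng):
        genes = _genes(50, coding_mask=list(rng.random(50) < 0.7))
        epi = pd.DataFrame(
            {
                "enhancer_id": [f"E{rng.integers(0, 20)}" for _ in range(200)],
                "gene_id": [f"G{rng.integers(0, 60)}" for _ in range(200)],  # some unknown
                "pet_count": rng.integers(5, 20, 200),
            }
        ).drop_duplicates(["enhancer_id", "gene_id"])
        links = integration.map_enhancer_targets(epi, genes)
        coding = set(genes.loc[genes["is_coding"], "gene_id"])
        expected = {
            (e, g)
            for e, g in epi[["enhancer_id", "gene_id"]].itertuples(index=False)
            if g in coding
        }
        assert set(links[["region_id", "gene_id"]].itertuples(index=False, name=None)) == expected


class TestFunctionalDmrs:
    def _tables(self):
        dmrs = pd.DataFrame(
            {
                "region_id": ["R1", "R2", "R3"],
                "kind": ["promoter"] * 3,
                "direction": ["hypo", "hypo", "hyper"],
                "is_dmr": [True, True, True],
            }
        )
        degs = pd.DataFrame(
            {
                "gene_id": ["A", "B", "C"],
                "direction": ["up", "down", "down"],
                "is_deg": [True, True, True],
            }
        )
        targets = pd.DataFrame(
            {
                "region_id": ["R1", "R2", "R3"],
                "gene_id": ["A", "B", "C"],
                "link_type": ["promoter_downstream"] * 3,
            }
        )
        return dmrs, degs, targets

    def test_opposite_direction_rule(self):
        pairs, summary = integration.define_functional_dmrs(*self._tables())
        by_region = pairs.set_index("region_id")["is_functional"]
        assert bool(by_region["R1"])       # hypo + up
        assert not bool(by_region["R2"])   # hypo + down
        assert bool(by_region["R3"])       # hyper + down
        assert summary.set_index("region_id")["is_functional_dmr"].sum() == 2

    def test_non_deg_target_never_functional(self):
        dmrs, degs, targets = self._tables()
        degs["is_deg"] = False
        pairs, _ = integration.define_functional_dmrs(dmrs, degs, targets)
        assert not pairs["is_functional"].any()


class TestSedmrs:
    def _layout(self, rng, n_enh=40, n_se=10):
        enh = []
        pos = 0
        for i in range(n_enh):
            pos += int(rng.integers(2000, 6000))
            enh.append(GenomicInterval("chr1", pos, pos + 500, f"E{i}", "enhancer"))
            pos += 500
        ses = []
        for i in range(n_se):
            start = int(rng.integers(0, pos))
            ses.append(
                GenomicInterval(
                    "chr1", start, start + int(rng.integers(1000, 20_000)),
                    f"SE{i}", "super_enhancer",
                )
            )
        return RegionSet(enh, "enhancer"), RegionSet(ses, "super_enhancer")

    def test_matches_brute_force_overlap_union(self, rng):
        enh_rs, se_rs = self._layout(rng)
        edmr_ids = list(rng.choice([iv.region_id for iv in enh_rs], 15, replace=False))
        edmrs = pd.DataFrame(
            {
                "region_id": edmr_ids,
                "direction": rng.choice(["hypo", "hyper"], 15),
                "is_dmr": True,
            }
        )
        targets = pd.DataFrame(
            {
                "region_id": edmr_ids * 2,
                "gene_id": [f"G{i}" for i in range(30)],
                "link_type": "epi",
            }
        )
        table = integration.define_sedmrs(se_rs, edmrs, enh_rs, targets)
        # brute force: overlap scan + target union
        dir_of = dict(zip(edmrs["region_id"], edmrs["direction"]))
        tgt_of = targets.groupby("region_id")["gene_id"].agg(set)
        expected_rows = {}
        for se in se_rs:
            hits = sorted(
                iv.region_id
                for iv in enh_rs
                if iv.region_id in dir_of
                and iv.start < se.end and se.start < iv.end
            )
            if hits:
                genes = set().union(*(tgt_of.get(h, set()) for h in hits))
                expected_rows[se.region_id] = (hits, genes)
        got = {
            r.se_id: (r.edmr_ids.split(","), set(filter(None, r.target_genes.split(","))))
            for r in table.itertuples(index=False)
        }
        assert got == expected_rows

    def test_se_without_edmr_absent(self):
        enh = RegionSet([GenomicInterval("chr1", 0, 100, "E0", "enhancer")], "enhancer")
        se = RegionSet(
            [GenomicInterval("chr1", 5000, 6000, "SE0", "super_enhancer")],
            "super_enhancer",
        )
        edmrs = pd.DataFrame(
            {"region_id": ["E0"], "direction": ["hypo"], "is_dmr": [True]}
        )
        targets = pd.DataFrame({"region_id": ["E0"], "gene_id": ["G"], "link_type": "epi"})
        assert integration.define_sedmrs(se, edmrs, enh, targets).empty


class TestSpecificGenes:
    def _matrices(self, rng, focal_boost):
        genes = [f"G{i}" for i in range(20)]
        base = rng.lognormal(3, 0.3, (20, 20))
        focal = pd.DataFrame(base * focal_boost[:, None], index=genes)
        groups = [
            pd.DataFrame(rng.lognormal(3, 0.3, (20, 20)), index=genes) for _ in range(3)
        ]
        return focal, groups

    def test_flat_gene_not_specific_tenfold_is(self, rng):
        boost = np.ones(20)
        boost[0] = 10.0
        focal, groups = self._matrices(rng, boost)
        specific = integration.define_specific_genes(focal, groups)
        assert "G0" in specific and "G1" not in specific

    def test_all_groups_conjunction(self, rng):
        boost = np.ones(20)
        boost[0] = 10.0
        focal, groups = self._matrices(rng, boost)
        # one comparison group matches the focal level for G0 -> not specific
        spoiler = groups[0].copy()
        spoiler.loc["G0"] = focal.loc["G0"].to_numpy()
        specific = integration.define_specific_genes(focal, [spoiler] + groups[1:])
        assert "G0" not in specific

    def test_small_group_rejected(self, rng):
        focal, groups = self._matrices(rng, np.ones(20))
        with pytest.raises(ValueError):
            integration.define_specific_genes(focal, [groups[0].iloc[:, :2]])


class TestCorrelation:
    def _inputs(self, meth_rows, expr_rows, n=8):
        samples = [f"s{i}" for i in range(n)]
        meth = pd.DataFrame.from_dict(meth_rows, orient="index")
        meth.columns = samples
        expr = pd.DataFrame.from_dict(expr_rows, orient="index")
        expr.columns = samples
        targets = pd.DataFrame(
            {
                "region_id": list(meth.index),
                "gene_id": list(expr.index),
                "link_type": "epi",
            }
        )
        return meth, expr, targets

    def test_perfect_inverse_monotone(self):
        meth, expr, targets = self._inputs(
            {"R": np.linspace(0.1, 0.9, 8)}, {"G": np.linspace(100, 10, 8)}
        )
        out = integration.correlate_methylation_expression(meth, expr, targets)
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_constant_expression_dropped(self):
        meth, expr, targets = self._inputs(
            {"R": np.linspace(0.1, 0.9, 8)}, {"G": np.full(8, 50.0)}
        )
        out = integration.correlate_methylation_expression(meth, expr, targets)
        assert out.empty and out.attrs["n_dropped"] == 1

    def test_low_expression_gene_excluded(self):
        meth, expr, targets = self._inputs(
            {"R": np.linspace(0.1, 0.9, 8)}, {"G": np.linspace(0.1, 0.9, 8)}
        )
        out = integration.correlate_methylation_expression(meth, expr, targets, min_expr=1.0)
        assert out.empty

    def test_matches_scipy_spearman(self, rng):
        samples = [f"s{i}" for i in range(20)]
        meth = pd.DataFrame(
            rng.uniform(0, 1, (50, 20)), index=[f"R{i}" for i in range(50)], columns=samples
        )
        expr = pd.DataFrame(
            rng.lognormal(3, 1, (50, 20)), index=[f"G{i}" for i in range(50)], columns=samples
        )
        targets = pd.DataFrame(
            {"region_id": meth.index, "gene_id": expr.index, "link_type": "epi"}
        )
        out = integration.correlate_methylation_expression(meth, expr, targets)
        for row in out.itertuples(index=False):
            expected = stats.spearmanr(
                meth.loc[row.region_id], expr.loc[row.gene_id]
            ).statistic
            assert row.rho == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self):
        meth, expr, targets = self._inputs(
            {"R": [0.1, 0.2, 0.3, 0.4]}, {"G": [1, 2, 3, 4]}, n=4
        )
        with pytest.raises(ValueError):
            integration.correlate_methylation_expression(meth, expr, targets)


class TestCompareCorrelations:
    def test_identical_groups_p_near_one(self):
        rhos = np.linspace(-0.9, 0.9, 50)
        p, m1, m2 = integration.compare_correlation_distributions(rhos, rhos)
        assert p > 0.99 and m1 == m2

    def test_shifted_group_detected_and_symmetric(self, rng):
        a = rng.uniform(-1, 0, 200) - 0.0
        b = np.clip(a + 0.5, -1, 1)
        p_ab, *_ = integration.compare_correlation_distributions(a, b)
        p_ba, *_ = integration.compare_correlation_distributions(b, a)
        assert p_ab < 1e-6 and p_ab == pytest.approx(p_ba)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            integration.compare_correlation_distributions([0.1], [0.2, 0.3, 0.4])
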