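"""Differential infiltration, IMR calling, overlap statistics, PMD stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regmeth import immune
from regmeth.enrichment import GeneSet
from regmeth.regions import GenomicInterval, RegionSet


def _fractions(rng, samples, n_ct=5, shift_ct=None, shift=0.0):
    logits = rng.normal(0, 0.5, (n_ct, len(samples)))
    if shift_ct is not None:
        is_tumor = (samples["tissue"] == "tumor").to_numpy()
        logits[shift_ct, is_tumor] += shift
    expl = np.exp(logits)
    return pd.DataFrame(
        expl / expl.sum(axis=0),
        index=[f"CT{i}" for i in range(n_ct)],
        columns=samples["sample_id"],
    )


def _samples(n_pairs):
    return pd.DataFrame(
        [
            {"sample_id": f"P{i}_{t}", "patient_id": f"P{i}", "tissue": tissue}
            for i in range(n_pairs)
            for t, tissue in (("T", "tumor"), ("N", "normal"))
        ]
    )


class TestDifferentialInfiltration:
    def test_identical_fractions_nothing_called(self, rng):
        samples = _samples(10)
        half = _fractions(rng, samples.iloc[::2].reset_index(drop=True))
        fractions = pd.DataFrame(
            np.repeat(half.to_numpy(), 2, axis=1),
            index=half.index,
            columns=samples["sample_id"],
        )
        out = immune.differential_infiltration(fractions, samples)
        assert not out["is_diff"].any()
        assert (out["p"] == 1.0).all()

    def test_planted_shift_detected(self, rng):
        samples = _samples(37)
        fractions = _fractions(rng, samples, shift_ct=0, shift=0.8)
        out = immune.differential_infiltration(fractions, samples)
        assert out.set_index("cell_type").loc["CT0", "is_diff"]

    def test_direction_flips_under_tissue_swap(self, rng):
        samples = _samples(12)
        fractions = _fractions(rng, samples, shift_ct=0, shift=0.8)
        swapped = samples.copy()
        swapped["tissue"] = swapped["tissue"].map({"tumor": "normal", "normal": "tumor"})
        a = immune.differential_infiltration(fractions, samples).set_index("cell_type")
        b = immune.differential_infiltration(fractions, swapped).set_index("cell_type")
        assert a.loc["CT0", "median_diff"] == pytest.approx(-b.loc["CT0", "median_diff"])
        assert a.loc["CT0", "p"] == pytest.approx(b.loc["CT0", "p"])


class TestDefineImrs:
    def test_monotone_coupling_rho_one(self, rng):
        samples = _samples(6)
        fractions = _fractions(rng, samples, n_ct=3)
        tumor_ids = samples.loc[samples["tissue"] == "tumor", "sample_id"]
        meth = pd.DataFrame(
            rng.uniform(0.2, 0.8, (4, len(samples))),
            index=[f"R{i}" for i in range(4)],
            columns=samples["sample_id"],
        )
        order = fractions.loc["CT0", tumor_ids].rank()
        meth.loc["R0", tumor_ids] = 0.1 + 0.1 * order.to_numpy()
        out = immune.define_imrs(meth, fractions, ["CT0"], samples, scope="tumor")
        row = out.set_index(["region_id", "cell_type"]).loc[("R0", "CT0")]
        assert row["rho"] == pytest.approx(1.0)

    def test_spearman_matches_scipy(self, rng):
        samples = _samples(10)
        fractions = _fractions(rng, samples, n_ct=4)
        meth = pd.DataFrame(
            rng.uniform(0, 1, (6, len(samples))),
            index=[f"R{i}" for i in range(6)],
            columns=samples["sample_id"],
        )
        out = immune.define_imrs(
            meth, fractions, list(fractions.index), samples, scope="all"
        )
        for row in out.itertuples(index=False):
            rho, p = stats.spearmanr(
                meth.loc[row.region_id], fractions.loc[row.cell_type]
            )
            assert row.rho == pytest.approx(rho, abs=1e-12)
            assert row.p == pytest.approx(p, abs=1e-9)

    def test_degenerate_region_skipped(self, rng):
        samples = _samples(6)
        fractions = _fractions(rng, samples, n_ct=2)
        meth = pd.DataFrame(
            np.vstack([np.full(len(samples), 0.5), rng.uniform(0, 1, len(samples))]),
            index=["flat", "ok"],
            columns=samples["sample_id"],
        )
        out = immune.define_imrs(meth, fractions, ["CT0"], samples, scope="all")
        assert set(out["region_id"]) == {"ok"}

    def test_too_few_samples_rejected(self, rng):
        samples = _samples(4)
        fractions = _fractions(rng, samples)
        meth = pd.DataFrame(
            rng.uniform(0, 1, (2, len(samples))),
            index=["R0", "R1"],
            columns=samples["sample_id"],
        )
        with pytest.raises(ValueError):
            immune.define_imrs(meth, fractions, ["CT0"], samples, scope="tumor")


class TestOverlapStats:
    def test_worked_example(self):
        # universe 200; DMR = first 100; IMR on R0..R79 and R100..R119
        imrs = pd.DataFrame(
            {
                "region_id": [f"R{i}" for i in range(200)],
                "cell_type": "CT0",
                "is_imr": [True] * 80 + [False] * 20 + [True] * 20 + [False] * 80,
            }
        )
        universe = [f"R{i}" for i in range(200)]
        dmrs = {f"R{i}" for i in range(100)}
        st = immune.imr_dmr_overlap_stats(imrs, universe, dmrs, "promoter")
        assert (st.a, st.b, st.c, st.d) == (80, 20, 20, 80)
        assert st.prop_dmr == pytest.approx(0.8)
        assert st.prop_nondmr == pytest.approx(0.2)
        assert st.odds_ratio == pytest.approx(16.0)

    def test_equal_proportions_or_one(self):
        imrs = pd.DataFrame(
            {
                "region_id": [f"R{i}" for i in range(40)],
                "cell_type": "CT0",
                "is_imr": [True, True, False, False] * 10,
            }
        )
        st = immune.imr_dmr_overlap_stats(
            imrs, [f"R{i}" for i in range(40)], {f"R{i}" for i in range(0, 40, 2)}, "x"
        )
        assert st.odds_ratio == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            immune.imr_dmr_overlap_stats(pd.DataFrame({"region_id": [], "is_imr": []}), [], set(), "x")


class TestPmdStratification:
    def test_partition_matches_brute_force(self, rng):
        regions = []
        for i in range(60):
            start = int(rng.integers(0, 1_000_000))
            regions.append(
                GenomicInterval("chr1", start, start + int(rng.integers(100, 3000)),
                                f"R{i}", "enhancer")
            )
        rs = RegionSet(regions, "enhancer")
        pmds = []
        for i in range(5):
            start = int(rng.integers(0, 900_000))
            pmds.append(
                GenomicInterval("chr1", start, start + int(rng.integers(50_000, 200_000)),
                                f"PMD{i}", "pmd")
            )
        pmd_rs = RegionSet(pmds, "pmd")
        imrs = pd.DataFrame(
            {"region_id": [f"R{i}" for i in range(60)], "cell_type": "CT0", "is_imr": True}
        )
        inside, outside = immune.stratify_by_pmd(imrs, rs, pmd_rs)
        assert len(inside) + len(outside) == len(imrs)
        assert not (set(inside["region_id"]) & set(outside["region_id"]))
        for rid in imrs["region_id"]:
            iv = rs.lookup(rid)
            overlaps = any(
                p.chrom == iv.chrom and p.start < iv.end and iv.start < p.end
                for p in pmd_rs
            )
            assert (rid in set(inside["region_id"])) == overlaps


class TestImrTargetEnrichment:
    def test_exact_set_ranks_first(self):
        universe = {f"g{i}" for i in range(50)}
        targets = pd.DataFrame(
            {"region_id": ["R0", "R1"], "gene_id": ["g0", "g1"], "link_type": "epi"}
        )
        sets = [
            GeneSet("match", "pathway", frozenset({"g0", "g1"})),
            GeneSet("other", "pathway", frozenset({f"g{i}" for i in range(30, 45)})),
        ]
        out = immune.imr_target_enrichment({"R0", "R1"}, targets, sets, universe)
        assert out.iloc[0]["set_name"] == "match"
        # universe intersection rule: out-of-universe genes change nothing
        sets2 = [
            GeneSet("match", "pathway", frozenset({"g0", "g1", "not_in_universe"})),
            sets[1],
        ]
        out2 = immune.imr_target_enrichment({"R0", "R1"}, targets, sets2, universe)
        assert out2.iloc[0]["p"] == pytest.approx(out.iloc[0]["p"])

    def test_empty_imr_set_empty_table(self):
        out = immune.imr_target_enrichment(
            set(), pd.DataFrame({"region_id": [], "gene_id": []}), [], {"g"}
        )
        assert out.empty
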