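"""Gene-set enrichment (Fisher + BH) and risk-SNP proximity enrichment (binomial).

The gene-set test is a one-sided Fisher exact test on the 2x2 table of
query membership vs. set membership within a gene universe, BH-corrected
across the tested collection. The SNP test asks whether more profiled SNPs
fall within a fixed window of a DMR than expected if each SNP landed near a
uniformly chosen testable region; the null hit probability defaults to the
DMR fraction among tested regions and the p-value is the upper binomial
tail P(X >= k).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import RegionSet, within_window


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p rank, q >= p, q <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT reader; the description column carries the set category."""
    sets = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                continue
            name, category, genes = cols[0], cols[1] or "unknown", cols[2:]
            sets.append(GeneSet(name, category, frozenset(g for g in genes if g)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.category, *sorted(gs.members)]) + "\n")


def fisher_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    sets: Sequence[GeneSet],
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of query genes in each set.

    Table per set: a = |query & set|, b = |query \\ set|, c = |set & universe
    \\ query|, d = rest of universe. Sets are intersected with the universe
    before testing; BH across the collection; sorted by q then name.
    Odds ratio is ad/bc (inf when bc = 0 and ad > 0); a Haldane-corrected
    column (+0.5 on every cell) is emitted alongside for plotting.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    rows = []
    for gs in sets:
        members = gs.members & universe
        a = len(query & members)
        b = len(query) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        if b * c == 0:
            odds = np.inf if a * d > 0 else 0.0
        else:
            odds = (a * d) / (b * c)
        odds_h = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {
                "set_name": gs.name,
                "category": gs.category,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "odds_ratio_haldane": odds_h,
                "p": p,
            }
        )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q"] = bh_adjust(result["p"])
        result = result.sort_values(["q", "p", "set_name"]).reset_index(drop=True)
    return result


@dataclass(frozen=True)
class SNPEnrichmentResult:
    n_snps: int          # SNPs that could be profiled (within window of a tested region)
    k_hits: int          # of those, SNPs within window of a DMR
    p0: float            # null per-SNP hit probability
    p_value: float       # upper-tail binomial P(X >= k_hits)

    def __post_init__(self) -> None:
        if not (0 <= self.k_hits <= self.n_snps):
            raise ValueError("k_hits out of range")


def binomial_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def _window_hits(
    snps: pd.DataFrame, region_sets, window_bp: int
) -> set[str]:
    """rsids within window_bp of any region in one or several RegionSets."""
    if isinstance(region_sets, RegionSet):
        region_sets = [region_sets]
    hit: set[str] = set()
    for rs in region_sets:
        for rsid, regions in within_window(snps, rs, window_bp).items():
            if regions:
                hit.add(rsid)
    return hit


def snp_dmr_enrichment(
    snps: pd.DataFrame,
    dmr_regions,
    tested_regions,
    window_bp: int = 5000,
    p0: float | None = None,
) -> SNPEnrichmentResult:
    """Binomial enrichment of SNPs within window_bp of a DMR.

    ``dmr_regions`` and ``tested_regions`` may each be a RegionSet or a list
    of RegionSets (promoter and enhancer universes are tested jointly).
    Only SNPs within the window of at least one tested region count as
    profiled. p0 defaults to |DMR regions| / |tested regions|; a
    user-supplied background may be passed instead.
    """
    if isinstance(dmr_regions, RegionSet):
        dmr_regions = [dmr_regions]
    if isinstance(tested_regions, RegionSet):
        tested_regions = [tested_regions]
    profiled = _window_hits(snps, tested_regions, window_bp)
    if not profiled:
        raise ValueError("no SNP lies within the window of any tested region")
    hits = _window_hits(
        snps[snps["rsid"].isin(profiled)], dmr_regions, window_bp
    )
    k = len(hits & profiled)
    n = len(profiled)
    if p0 is None:
        n_tested = sum(len(rs) for rs in tested_regions)
        if n_tested == 0:
            raise ValueError("empty tested region universe")
        p0 = sum(len(rs) for rs in dmr_regions) / n_tested
    if not (0 < p0 < 1):
        # degenerate backgrounds: the tail is 1 unless hits are impossible
        p_value = 1.0 if (p0 >= 1 or k == 0) else 0.0
        return SNPEnrichmentResult(n, k, float(p0), p_value)
    return SNPEnrichmentResult(n, k, float(p0), binomial_tail(k, n, p0))
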