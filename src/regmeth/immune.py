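"""Immune-infiltration analysis: differential abundance, IMRs, DMR overlap, PMDs.

Infiltration fractions (cell type x sample, columns summing to 1) are an
input — deconvolution is upstream of this package. Differentially abundant
cell types are found with a paired Wilcoxon signed-rank test (BH, q < 0.01).
Infiltration-associated methylation regions (IMRs) are regions whose
methylation correlates with a differentially abundant cell type's fraction
(Spearman, BH q < 0.01 across all (region, cell type) pairs within a
region kind). IMRs are then contrasted against DMR status (2x2 odds
ratios) and stratified by partially methylated domains (PMDs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet, bh_adjust, fisher_enrichment
from .regions import RegionSet, complete_pairs

logger = logging.getLogger(__name__)


def validate_fractions(fractions: pd.DataFrame, tol: float = 1e-6) -> None:
    if (fractions.to_numpy() < -tol).any():
        raise ValueError("negative infiltration fraction")
    sums = fractions.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=tol):
        raise ValueError("infiltration fractions must sum to 1 per sample")


def differential_infiltration(
    fractions: pd.DataFrame,
    samples: pd.DataFrame,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per cell type, paired signed-rank test of tumor vs normal fractions.

    Returns cell_type, median_diff, p, q, direction, is_diff (BH across cell
    types). Constant cell types get p = 1.
    """
    validate_fractions(fractions)
    pairs = complete_pairs(samples)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 complete tumor/normal pairs")
    rows = []
    for cell_type in fractions.index:
        tumor = fractions.loc[cell_type, pairs["tumor"]].to_numpy(dtype=float)
        normal = fractions.loc[cell_type, pairs["normal"]].to_numpy(dtype=float)
        diff = tumor - normal
        if np.allclose(diff, 0):
            p = 1.0
        else:
            _, p = stats.wilcoxon(tumor, normal)
        rows.append(
            {
                "cell_type": cell_type,
                "median_diff": float(np.median(diff)),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    out["direction"] = np.where(out["median_diff"] > 0, "up", "down")
    out["is_diff"] = out["q"] < q_threshold
    return out


def _spearman_matrix(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Row-of-a x row-of-b Spearman rho and t-approximation p over shared columns.

    Rows with zero variance yield NaN rho (callers skip them).
    """
    n = a.shape[1]
    ra = a.rank(axis=1).to_numpy(dtype=float)
    rb = b.rank(axis=1).to_numpy(dtype=float)
    ra = (ra - ra.mean(axis=1, keepdims=True))
    rb = (rb - rb.mean(axis=1, keepdims=True))
    sa = np.sqrt((ra**2).sum(axis=1))
    sb = np.sqrt((rb**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra @ rb.T) / np.outer(sa, sb)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), np.nan, np.where(np.isfinite(t), p, 0.0))
    return rho, p


def define_imrs(
    region_meth: pd.DataFrame,
    fractions: pd.DataFrame,
    cell_types: list[str],
    samples: pd.DataFrame,
    scope: str = "tumor",
    q_threshold: float = 0.01,
    dmr_ids: set[str] | None = None,
    kind: str | None = None,
) -> pd.DataFrame:
    """IMR records: Spearman of region beta vs cell-type fraction, BH jointly.

    scope selects the sample set ('tumor', 'normal' or 'all'); the default
    is tumor-only since infiltration is a tumor-microenvironment property.
    BH is applied across all tested (region, cell type) pairs of this call
    (i.e. within a region kind). is_imr marks q < q_threshold; degenerate
    constant rows are skipped and logged.
    """
    if not cell_types:
        raise ValueError("cell_types is empty")
    if scope == "all":
        in_scope = list(samples["sample_id"])
    elif scope in ("tumor", "normal"):
        in_scope = list(samples.loc[samples["tissue"] == scope, "sample_id"])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    in_scope = [s for s in in_scope if s in region_meth.columns and s in fractions.columns]
    if len(in_scope) < 5:
        raise ValueError("fewer than 5 samples in scope")

    meth = region_meth.loc[:, in_scope]
    frac = fractions.loc[cell_types, in_scope]
    rho, p = _spearman_matrix(meth, frac)

    region_ids = np.repeat(meth.index.to_numpy(), len(cell_types))
    ct = np.tile(np.asarray(cell_types, dtype=object), meth.shape[0])
    flat = pd.DataFrame(
        {"region_id": region_ids, "cell_type": ct, "rho": rho.ravel(), "p": p.ravel()}
    )
    degenerate = flat["rho"].isna()
    if degenerate.any():
        logger.info("define_imrs: skipped %d degenerate pairs", int(degenerate.sum()))
        flat = flat[~degenerate].reset_index(drop=True)
    flat["q"] = bh_adjust(flat["p"])
    flat["is_imr"] = flat["q"] < q_threshold
    if kind is not None:
        flat.insert(1, "kind", kind)
    flat["is_dmr"] = flat["region_id"].isin(dmr_ids or set())
    return flat


@dataclass(frozen=True)
class OverlapStats:
    kind: str
    a: int  # IMR & DMR
    b: int  # DMR, not IMR
    c: int  # IMR, not DMR
    d: int  # neither

    @property
    def prop_dmr(self) -> float:
        return self.a / (self.a + self.b) if (self.a + self.b) else float("nan")

    @property
    def prop_nondmr(self) -> float:
        return self.c / (self.c + self.d) if (self.c + self.d) else float("nan")

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else 0.0
        return (self.a * self.d) / (self.b * self.c)

    @property
    def odds_ratio_haldane(self) -> float:
        return ((self.a + 0.5) * (self.d + 0.5)) / ((self.b + 0.5) * (self.c + 0.5))


def imr_dmr_overlap_stats(
    imrs: pd.DataFrame,
    universe: list[str],
    dmr_ids: set[str],
    kind: str,
) -> OverlapStats:
    """2x2 of IMR status x DMR status over the testable region universe.

    A region counts as an IMR if any of its (region, cell type) records has
    q below threshold (per-region definition).
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty region universe")
    imr_regions = set(imrs.loc[imrs["is_imr"], "region_id"])
    dmr_ids = set(dmr_ids) & set(universe)
    a = b = c = d = 0
    for rid in universe:
        is_imr, is_dmr = rid in imr_regions, rid in dmr_ids
        if is_dmr and is_imr:
            a += 1
        elif is_dmr:
            b += 1
        elif is_imr:
            c += 1
        else:
            d += 1
    return OverlapStats(kind, a, b, c, d)


def stratify_by_pmd(
    imrs: pd.DataFrame,
    regions: RegionSet,
    pmd_regions: RegionSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split IMR records into (inside_pmd, outside_pmd) by any-overlap with a PMD.

    The partition is exhaustive and disjoint on input records.
    """
    inside_ids = set()
    for rid in imrs["region_id"].unique():
        iv = regions.lookup(rid)
        if pmd_regions.query(iv.chrom, iv.start, iv.end):
            inside_ids.add(rid)
    mask = imrs["region_id"].isin(inside_ids)
    inside = imrs[mask].copy()
    outside = imrs[~mask].copy()
    inside["pmd_status"] = "inside"
    outside["pmd_status"] = "outside"
    return inside.reset_index(drop=True), outside.reset_index(drop=True)


def imr_target_enrichment(
    imr_region_ids: set[str],
    targets: pd.DataFrame,
    gene_sets: list[GeneSet],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher enrichment of the genes regulated by the given IMR regions."""
    genes = sorted(
        set(targets.loc[targets["region_id"].isin(imr_region_ids), "gene_id"])
    )
    if not genes:
        logger.warning("imr_target_enrichment: empty gene list")
        return pd.DataFrame(
            columns=["set_name", "category", "a", "b", "c", "d",
                     "odds_ratio", "odds_ratio_haldane", "p", "q"]
        )
    return fisher_enrichment(genes, universe, gene_sets)
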