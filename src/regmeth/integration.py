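"""Target mapping, functional DMRs, seDMRs, and specificity-correlation analysis.

Promoter targets are the gene downstream of each promoter (one-to-one);
enhancer targets come from the PET-filtered enhancer-promoter interaction
map (many-to-many). A functional DMR is one whose target gene is a DEG in
the opposite direction to the methylation change. Super-enhancer DMRs are
super-enhancers overlapping at least one eDMR; their targets are the union
of the overlapping eDMRs' targets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionSet

logger = logging.getLogger(__name__)

_OPPOSITE = {("hypo", "up"), ("hyper", "down")}


def map_promoter_targets(genes: pd.DataFrame) -> pd.DataFrame:
    """One link per (promoter, downstream gene); non-coding genes are dropped.

    A promoter referenced by two genes violates the one-to-one contract and
    raises.
    """
    linked = genes[(genes["promoter_region_id"] != "") & genes["is_coding"]]
    dup = linked["promoter_region_id"].duplicated()
    if dup.any():
        bad = linked.loc[dup, "promoter_region_id"].iloc[0]
        raise ValueError(f"promoter {bad!r} referenced by more than one gene")
    out = pd.DataFrame(
        {
            "region_id": linked["promoter_region_id"].to_numpy(),
            "gene_id": linked["gene_id"].to_numpy(),
            "link_type": "promoter_downstream",
        }
    )
    return out.sort_values(["region_id", "gene_id"]).reset_index(drop=True)


def map_enhancer_targets(epi: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Enhancer links from the (already PET-filtered) EPI map.

    Links to genes absent from the annotation are dropped with a warning;
    links to non-coding genes are dropped silently (whitelist rule).
    """
    known = genes.set_index("gene_id")["is_coding"]
    unknown = ~epi["gene_id"].isin(known.index)
    if unknown.any():
        logger.warning(
            "dropping %d EPI links to unknown genes", int(unknown.sum())
        )
    kept = epi[~unknown]
    kept = kept[known.reindex(kept["gene_id"]).to_numpy(dtype=bool)]
    out = pd.DataFrame(
        {
            "region_id": kept["enhancer_id"].to_numpy(),
            "gene_id": kept["gene_id"].to_numpy(),
            "link_type": "epi",
        }
    )
    return out.sort_values(["region_id", "gene_id"]).reset_index(drop=True)


def define_functional_dmrs(
    dmrs: pd.DataFrame, degs: pd.DataFrame, targets: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional (DMR, target) pairs and per-DMR summary.

    A pair is functional iff the target gene is a DEG and the directions
    oppose (hypo & up, or hyper & down). A DMR is an F-DMR iff at least one
    of its pairs is functional.
    """
    called = dmrs[dmrs["is_dmr"]][["region_id", "kind", "direction"]]
    deg_info = degs.set_index("gene_id")[["direction", "is_deg"]]
    pairs = called.merge(targets[["region_id", "gene_id"]], on="region_id", how="inner")
    pairs["deg_direction"] = deg_info["direction"].reindex(pairs["gene_id"]).to_numpy()
    pairs["gene_is_deg"] = (
        deg_info["is_deg"].reindex(pairs["gene_id"]).fillna(False).to_numpy(dtype=bool)
    )
    opposite = np.array(
        [(m, e) in _OPPOSITE for m, e in zip(pairs["direction"], pairs["deg_direction"])],
        dtype=bool,
    )
    pairs["is_functional"] = pairs["gene_is_deg"].to_numpy() & opposite
    pairs.loc[~pairs["gene_is_deg"], "deg_direction"] = ""
    pairs = pairs.sort_values(["region_id", "gene_id"]).reset_index(drop=True)

    per_dmr = (
        pairs.groupby(["region_id", "kind", "direction"], as_index=False)
        .agg(
            n_targets=("gene_id", "nunique"),
            n_functional_targets=("is_functional", "sum"),
            is_functional_dmr=("is_functional", "any"),
        )
        .sort_values("region_id")
        .reset_index(drop=True)
    )
    return pairs, per_dmr


def define_sedmrs(
    super_enhancers: RegionSet,
    edmrs: pd.DataFrame,
    enhancer_regions: RegionSet,
    targets: pd.DataFrame,
) -> pd.DataFrame:
    """seDMRs: super-enhancers overlapping >= 1 called eDMR.

    Each row carries the overlapping eDMR ids, the set of their directions,
    and the union of their target genes. Functional seDMRs are obtained by
    re-applying the functional filter to those targets (see
    ``functional_sedmr_pairs``).
    """
    called = edmrs[edmrs["is_dmr"]]
    target_lists = targets.groupby("region_id")["gene_id"].agg(set)
    rows = []
    for se in super_enhancers:
        hits = [
            iv.region_id
            for iv in enhancer_regions.query(se.chrom, se.start, se.end)
            if iv.region_id in set(called["region_id"])
        ]
        if not hits:
            continue
        directions = sorted(
            set(called.set_index("region_id").loc[hits, "direction"])
        )
        genes: set[str] = set()
        for rid in hits:
            genes |= target_lists.get(rid, set())
        rows.append(
            {
                "se_id": se.region_id,
                "chrom": se.chrom,
                "start": se.start,
                "end": se.end,
                "edmr_ids": ",".join(sorted(hits)),
                "directions": ",".join(directions),
                "target_genes": ",".join(sorted(genes)),
                "n_edmrs": len(hits),
                "n_targets": len(genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "se_id", "chrom", "start", "end", "edmr_ids", "directions",
            "target_genes", "n_edmrs", "n_targets",
        ],
    )


def functional_sedmr_pairs(sedmrs: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """(seDMR, direction, gene) pairs passing the opposite-direction DEG filter."""
    deg_info = degs.set_index("gene_id")[["direction", "is_deg"]]
    rows = []
    for row in sedmrs.itertuples(index=False):
        for direction in row.directions.split(","):
            for gene in filter(None, row.target_genes.split(",")):
                if gene not in deg_info.index or not deg_info.at[gene, "is_deg"]:
                    continue
                if (direction, deg_info.at[gene, "direction"]) in _OPPOSITE:
                    rows.append(
                        {"se_id": row.se_id, "direction": direction, "gene_id": gene}
                    )
    return pd.DataFrame(rows, columns=["se_id", "direction", "gene_id"])


def define_specific_genes(
    focal: pd.DataFrame,
    comparison_groups: list[pd.DataFrame],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> set[str]:
    """Genes specific to the focal group against every comparison group.

    A gene qualifies iff, against each group, the fold change of group means
    exceeds fc_threshold and a one-sided rank-sum test (focal greater) has
    p < p_threshold. Groups are unpaired, hence the Mann-Whitney form of the
    rank test.
    """
    genes = focal.index
    for grp in comparison_groups:
        if grp.shape[1] < 3 or focal.shape[1] < 3:
            raise ValueError("each group needs at least 3 samples")
        if not genes.equals(grp.index):
            raise ValueError("gene universes differ across matrices")
    specific = np.ones(len(genes), dtype=bool)
    focal_mat = focal.to_numpy(dtype=float)
    for grp in comparison_groups:
        grp_mat = grp.to_numpy(dtype=float)
        fc = focal_mat.mean(axis=1) / np.maximum(grp_mat.mean(axis=1), 1e-12)
        _, p = stats.mannwhitneyu(
            focal_mat, grp_mat, axis=1, alternative="greater"
        )
        specific &= (fc > fc_threshold) & (p < p_threshold)
        if not specific.any():
            break
    return set(genes[specific])


def correlate_methylation_expression(
    region_meth: pd.DataFrame,
    expr: pd.DataFrame,
    targets: pd.DataFrame,
    min_expr: float = 1.0,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman rho between region methylation and target-gene expression.

    One row per (region, gene) link over the shared samples. Genes whose
    maximum expression is below min_expr are excluded; degenerate (constant)
    series yield undefined rho and the record is dropped (count kept in
    ``DataFrame.attrs['n_dropped']``).
    """
    shared = [s for s in region_meth.columns if s in expr.columns]
    if samples is not None:
        shared = [s for s in shared if s in set(samples)]
    if len(shared) < 5:
        raise ValueError("fewer than 5 shared samples")
    expressed = expr.loc[:, shared].max(axis=1) >= min_expr
    links = targets[
        targets["region_id"].isin(region_meth.index)
        & targets["gene_id"].isin(expr.index[expressed])
    ]
    meth_ranks = region_meth.loc[:, shared].rank(axis=1)
    expr_ranks = expr.loc[:, shared].rank(axis=1)
    rows, dropped = [], 0
    for region_id, gene_id in links[["region_id", "gene_id"]].itertuples(index=False):
        x = meth_ranks.loc[region_id].to_numpy(dtype=float)
        y = expr_ranks.loc[gene_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            dropped += 1
            continue
        rho = np.corrcoef(x, y)[0, 1]
        rows.append(
            {"region_id": region_id, "gene_id": gene_id, "rho": rho, "n": len(shared)}
        )
    out = pd.DataFrame(rows, columns=["region_id", "gene_id", "rho", "n"])
    out.attrs["n_dropped"] = dropped
    if dropped:
        logger.info("correlate_methylation_expression: dropped %d degenerate pairs", dropped)
    return out


def compare_correlation_distributions(
    specific_rhos, other_rhos
) -> tuple[float, float, float]:
    """Two-sided rank comparison of two rho samples; returns (p, median_a, median_b)."""
    a = np.asarray(list(specific_rhos), dtype=float)
    b = np.asarray(list(other_rhos), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 correlations")
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(p), float(np.median(a)), float(np.median(b))
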