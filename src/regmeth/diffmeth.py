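"""Region-level differential methylation between paired tumor/normal samples.

The pipeline summarises CpG beta values to region means, tests each region
with a paired t-test on M-values (log2 odds of methylation), and controls
the FDR with Benjamini-Hochberg separately within promoters and within
enhancers. A region is a DMR when q < 0.01; direction is hypo when the
tumor mean beta is below the matched normal mean.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .regions import RegionSet, complete_pairs

logger = logging.getLogger(__name__)


def filter_sites(
    beta: pd.DataFrame,
    blocklist: Iterable[str] = (),
    max_missing_frac: float = 1.0,
) -> pd.DataFrame:
    """Drop blocklisted sites and sites missing in more than max_missing_frac of samples."""
    blocked = set(blocklist)
    keep = ~beta.index.isin(blocked)
    missing_frac = beta.isna().mean(axis=1)
    keep &= (missing_frac <= max_missing_frac).to_numpy()
    out = beta.loc[keep]
    if out.empty:
        raise ValueError("all CpG sites removed by filtering")
    return out


def aggregate_region_methylation(
    beta: pd.DataFrame, region_map: Mapping[str, list[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """Region x sample matrix of mean beta over the region's non-missing sites.

    Regions where any sample has zero non-missing sites are dropped (logged);
    returns (region_meth, n_sites).
    """
    rows, ids, n_sites = [], [], []
    dropped = 0
    for region_id, site_ids in region_map.items():
        sites = [s for s in site_ids if s in beta.index]
        if not sites:
            dropped += 1
            continue
        block = beta.loc[sites]
        means = block.mean(axis=0, skipna=True)
        if means.isna().any():
            dropped += 1
            continue
        rows.append(means)
        ids.append(region_id)
        n_sites.append(len(sites))
    if dropped:
        logger.info("aggregate_region_methylation: dropped %d untestable regions", dropped)
    region_meth = pd.DataFrame(rows, index=ids, columns=beta.columns)
    return region_meth, pd.Series(n_sites, index=ids, name="n_sites")


def beta_to_m(beta, eps: float = 1e-3):
    """M-value: log2(b / (1 - b)) with b clipped to [eps, 1 - eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def _paired_t_rows(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-sample t-test against zero. All-zero rows get p = 1."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = ~np.isfinite(t)
    p[degenerate] = 1.0
    t[degenerate] = 0.0
    return t, p


def test_region(
    region_values: pd.Series, samples: pd.DataFrame
) -> tuple[float, float]:
    """Paired t-test for one region: per-patient M-value differences (tumor - normal).

    Returns (delta_beta, p). delta_beta is on the beta scale (mean of paired
    tumor - normal differences). Needs >= 3 complete pairs.
    """
    pairs = complete_pairs(samples)
    tumor = region_values[pairs["tumor"]].to_numpy(dtype=float)
    normal = region_values[pairs["normal"]].to_numpy(dtype=float)
    ok = ~(np.isnan(tumor) | np.isnan(normal))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete pairs: region untestable")
    m_diff = beta_to_m(tumor[ok]) - beta_to_m(normal[ok])
    _, p = _paired_t_rows(m_diff[None, :])
    delta_beta = float(np.mean(tumor[ok] - normal[ok]))
    return delta_beta, float(p[0])


def call_dmrs(
    region_meth: pd.DataFrame,
    samples: pd.DataFrame,
    kind: str,
    q_threshold: float = 0.01,
    regions: RegionSet | None = None,
    n_sites: pd.Series | None = None,
) -> pd.DataFrame:
    """DMR table for one region kind (BH within the kind's testable regions).

    Columns: region_id, kind, [chrom, start, end,] mean_beta_tumor,
    mean_beta_normal, delta_beta, p, q, direction, is_dmr[, n_sites].
    Missing betas are handled pairwise-complete per region; regions with
    fewer than 3 complete pairs are excluded from multiplicity correction.
    """
    pairs = complete_pairs(samples)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 complete tumor/normal pairs in cohort")
    tumor = region_meth[pairs["tumor"]].to_numpy(dtype=float)
    normal = region_meth[pairs["normal"]].to_numpy(dtype=float)
    complete = ~(np.isnan(tumor) | np.isnan(normal))
    n_complete = complete.sum(axis=1)
    testable = n_complete >= 3

    m_t, m_n = beta_to_m(tumor), beta_to_m(normal)
    p = np.full(region_meth.shape[0], np.nan)
    delta = np.full(region_meth.shape[0], np.nan)
    if complete.all():
        _, p_all = _paired_t_rows(m_t - m_n)
        p[:] = p_all
        delta[:] = (tumor - normal).mean(axis=1)
    else:
        for i in np.flatnonzero(testable):
            ok = complete[i]
            _, pi = _paired_t_rows((m_t[i, ok] - m_n[i, ok])[None, :])
            p[i] = pi[0]
            delta[i] = (tumor[i, ok] - normal[i, ok]).mean()

    q = np.full_like(p, np.nan)
    q[testable] = bh_adjust(p[testable])

    with np.errstate(invalid="ignore"):
        mean_t = np.nanmean(tumor, axis=1)
        mean_n = np.nanmean(normal, axis=1)
    out = pd.DataFrame(
        {
            "region_id": region_meth.index,
            "kind": kind,
            "mean_beta_tumor": mean_t,
            "mean_beta_normal": mean_n,
            "delta_beta": delta,
            "p": p,
            "q": q,
            "direction": np.where(delta < 0, "hypo", "hyper"),
            "is_dmr": (q < q_threshold) & testable,
            "testable": testable,
        }
    )
    if n_sites is not None:
        out["n_sites"] = n_sites.reindex(out["region_id"]).to_numpy()
    if regions is not None:
        coords = regions.to_frame().set_index("region_id")
        coords = coords.reindex(out["region_id"])
        out.insert(2, "chrom", coords["chrom"].to_numpy())
        out.insert(3, "start", coords["start"].to_numpy())
        out.insert(4, "end", coords["end"].to_numpy())
    return out.reset_index(drop=True)
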