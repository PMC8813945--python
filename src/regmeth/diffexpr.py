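"""Differential expression between paired tumor and normal samples.

Counts are normalized with median-of-ratios size factors, then each gene is
tested with a paired t-test on per-patient differences of
log2(normalized + 1). A gene is a DEG when |log2FC| > 2 (strict) and the
BH q-value is below 0.01.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffmeth import _paired_t_rows
from .enrichment import bh_adjust
from .regions import complete_pairs

logger = logging.getLogger(__name__)


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors; normalized value = count / size factor.

    The reference is the per-gene geometric mean over genes with all-nonzero
    counts. If no such gene exists, upper-quartile factors (rescaled to a
    geometric mean of 1) are used instead, with a log message.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts")
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("a sample has zero total counts")
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        ref = np.exp(np.log(mat[all_nonzero]).mean(axis=1))
        factors = np.median(mat[all_nonzero] / ref[:, None], axis=0)
    else:
        logger.warning("no gene with all-nonzero counts; using upper-quartile factors")
        uq = np.array([np.quantile(col[col > 0], 0.75) for col in mat.T])
        factors = uq / np.exp(np.mean(np.log(uq)))
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / size_factors
    return normalized, size_factors


def call_degs(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    lfc_threshold: float = 2.0,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """DEG table: gene_id, log2fc, p, q, direction, is_deg.

    log2fc is the mean per-patient difference of log2(normalized + 1)
    (tumor - normal); genes with zero variance of differences get p = 1.
    """
    pairs = complete_pairs(samples)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 complete tumor/normal pairs")
    normalized, _ = normalize_counts(counts)
    log_expr = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    cols = {s: i for i, s in enumerate(counts.columns)}
    t_idx = [cols[s] for s in pairs["tumor"]]
    n_idx = [cols[s] for s in pairs["normal"]]
    diffs = log_expr[:, t_idx] - log_expr[:, n_idx]
    _, p = _paired_t_rows(diffs)
    log2fc = diffs.mean(axis=1)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc > 0, "up", "down"),
            "is_deg": (np.abs(log2fc) > lfc_threshold) & (q < q_threshold),
        }
    )
    return out.reset_index(drop=True)
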