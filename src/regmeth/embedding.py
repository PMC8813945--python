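"""Dimension reduction of DMR beta profiles and entropy-scored 2-group clustering.

Samples are embedded in 2-D from their region-mean beta profiles (tSNE with
perplexity 10, or UMAP on the first 10 principal components), clustered with
k-means (k = 2), and the tumor/normal separation is scored with the
size-weighted Shannon entropy of tissue labels within clusters: 0 means
perfect separation, 1 means clusters carry no tissue information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # index = sample_id, columns = ["x", "y"]
    method: str
    params: dict


def embed(
    region_meth: pd.DataFrame,
    method: str = "tsne",
    seed: int = 42,
    perplexity: float = 10.0,
    n_pcs: int = 10,
) -> EmbeddingResult:
    """2-D embedding of samples from a region x sample beta matrix.

    tsne: t-SNE directly on sample profiles with the given perplexity.
    umap: PCA to the first n_pcs components, then UMAP.
    Both are seeded and reproducible at a fixed seed.
    """
    if region_meth.shape[1] < 5 or region_meth.shape[0] < 2:
        raise ValueError("need at least 5 samples and 2 regions")
    X = region_meth.to_numpy(dtype=float).T  # samples x regions
    n_samples = X.shape[0]
    if method == "tsne":
        if perplexity >= (n_samples - 1) / 3:
            raise ValueError(
                f"perplexity {perplexity} too large for {n_samples} samples; "
                f"use perplexity < {(n_samples - 1) / 3:.1f}"
            )
        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
        ).fit_transform(X)
        params = {"perplexity": perplexity, "seed": seed}
    elif method == "umap":
        import umap  # deferred: slow import

        n_comp = min(n_pcs, n_samples - 1, X.shape[1])
        pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", module="umap")
            warnings.filterwarnings("ignore", category=UserWarning)
            coords = umap.UMAP(
                n_components=2, random_state=seed, n_jobs=1
            ).fit_transform(pcs)
        params = {"n_pcs": n_comp, "seed": seed}
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    frame = pd.DataFrame(coords, index=region_meth.columns, columns=["x", "y"])
    return EmbeddingResult(frame, method, params)


def kmeans_cluster(coords: pd.DataFrame, k: int = 2, seed: int = 42) -> pd.Series:
    """k-means labels (10 restarts, best inertia). Label permutation is irrelevant."""
    X = coords[["x", "y"]].to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of samples")
    if np.allclose(X, X[0]):
        logger.warning("all points identical: single effective cluster")
        return pd.Series(np.zeros(X.shape[0], dtype=int), index=coords.index)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    return pd.Series(labels, index=coords.index, name="cluster")


def cluster_entropy(labels, tissues) -> float:
    """Size-weighted Shannon entropy of tissue labels within clusters (bits).

    H = sum_c (n_c / N) * [- sum_t p_ct log2 p_ct], with 0*log(0) = 0.
    For two tissue labels this lies in [0, 1].
    """
    labels = np.asarray(list(labels))
    tissues = np.asarray(list(tissues))
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.size != tissues.size:
        raise ValueError("labels and tissues differ in length")
    n = labels.size
    total = 0.0
    for c in np.unique(labels):
        mask = labels == c
        _, counts = np.unique(tissues[mask], return_counts=True)
        p = counts / counts.sum()
        h = -np.sum(p * np.log2(p, where=p > 0, out=np.zeros_like(p, dtype=float)))
        total += (mask.sum() / n) * h
    return float(total)


def compare_profiles(
    region_meth: pd.DataFrame,
    dmr_tables: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    methods: tuple[str, ...] = ("tsne", "umap"),
    seed: int = 42,
    k: int = 2,
    perplexity: float = 10.0,
) -> pd.DataFrame:
    """Entropy report for pDMR-only, eDMR-only and combined DMR profiles.

    dmr_tables maps kind ('promoter'/'enhancer') to a DMR table; profiles
    with zero called DMRs are skipped with a warning. Returns one row per
    (profile_kind, method) with the entropy and the cluster x tissue
    contingency cells.
    """
    profiles: dict[str, list[str]] = {}
    prom = dmr_tables.get("promoter")
    enh = dmr_tables.get("enhancer")
    if prom is not None:
        profiles["pDMR"] = list(prom.loc[prom["is_dmr"], "region_id"])
    if enh is not None:
        profiles["eDMR"] = list(enh.loc[enh["is_dmr"], "region_id"])
    if prom is not None and enh is not None:
        profiles["total"] = profiles["pDMR"] + profiles["eDMR"]

    tissue_of = samples.set_index("sample_id")["tissue"]
    rows = []
    for profile_kind, region_ids in profiles.items():
        region_ids = [r for r in region_ids if r in region_meth.index]
        if not region_ids:
            logger.warning("profile %s has zero DMRs; skipped", profile_kind)
            continue
        sub = region_meth.loc[region_ids]
        for method in methods:
            result = embed(sub, method=method, seed=seed, perplexity=perplexity)
            labels = kmeans_cluster(result.coords, k=k, seed=seed)
            tissues = tissue_of.reindex(labels.index)
            entropy = cluster_entropy(labels, tissues)
            contingency = (
                pd.crosstab(labels, tissues)
                .reindex(columns=["normal", "tumor"], fill_value=0)
            )
            rows.append(
                {
                    "profile_kind": profile_kind,
                    "method": method,
                    "n_regions": len(region_ids),
                    "entropy": entropy,
                    "contingency": ";".join(
                        f"c{c}:normal={int(row['normal'])},tumor={int(row['tumor'])}"
                        for c, row in contingency.iterrows()
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["profile_kind", "method", "n_regions", "entropy", "contingency"]
    )
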