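"""Synthetic paired tumor/normal cohort generator with planted ground truth.

Emulates every input of the analysis: a CpG-level beta matrix for paired
tumor/adjacent-normal samples (logit-normal noise, shared patient effects),
promoter/enhancer/super-enhancer/PMD annotations on a synthetic genome, an
enhancer-promoter interaction map with PET counts, negative-binomial
RNA-seq counts with planted inverse methylation-expression coupling, an
unpaired multi-group pan-cancer expression panel with planted tumor-type-
specific genes, immune-infiltration fractions with chosen regions coupled
to chosen cell types, and risk SNPs placed near or far from planted DMRs.

The planted tumor-side shift is applied on the logit scale with an offset
solved numerically (Gauss-Hermite expectation + root finding) so that the
region-mean shift on the *beta* scale equals ``delta_beta`` in expectation.
Every draw comes from one seeded generator: identical seeds give identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .enrichment import GeneSet, read_gmt, write_gmt
from .regions import (
    GenomicInterval,
    RegionSet,
    read_cpg_manifest,
    read_gene_annotation,
    read_regions,
    read_sample_sheet,
    read_snps,
    write_cpg_manifest,
    write_regions,
    write_snps,
)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _expected_beta(mu: float, sigma: float) -> float:
    """E[expit(mu + sigma * Z)], Z ~ N(0,1), by Gauss-Hermite quadrature."""
    vals = expit(mu + sigma * np.sqrt(2.0) * _GH_NODES)
    return float((vals * _GH_WEIGHTS).sum() / np.sqrt(np.pi))


def _solve_shifted_mu(mu_normal: float, sigma: float, beta_shift: float) -> float:
    """mu such that E[beta] = E[beta | mu_normal] + beta_shift (beta_shift signed)."""
    target = _expected_beta(mu_normal, sigma) + beta_shift
    lo, hi = -14.0, 14.0
    if not (_expected_beta(lo, sigma) < target < _expected_beta(hi, sigma)):
        raise ValueError(
            f"planted shift {beta_shift:+.3f} infeasible from base mean "
            f"{_expected_beta(mu_normal, sigma):.3f}"
        )
    return brentq(lambda m: _expected_beta(m, sigma) - target, lo, hi, xtol=1e-10)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 37 tumor/normal pairs; planted DMR
    fractions per region kind reproduce the observed pDMR/eDMR rates with
    hypomethylation dominance; thresholds downstream are the analysis
    defaults, not generator parameters.
    """

    n_pairs: int = 37
    n_genes: int = 6000
    n_promoters: int = 2000
    n_enhancers: int = 3000
    n_super_enhancers: int = 150
    cpgs_per_region_range: tuple[int, int] = (4, 12)
    # planted DMR fractions per kind (observed pDMR/eDMR rates of the cohort)
    dmr_fraction_hypo: dict = field(
        default_factory=lambda: {"promoter": 0.22, "enhancer": 0.17}
    )
    dmr_fraction_hyper: dict = field(
        default_factory=lambda: {"promoter": 0.095, "enhancer": 0.075}
    )
    delta_beta: float = 0.25
    beta_dispersion: float = 0.8   # site-level logit-scale s.d.
    site_offset_sd: float = 0.3    # per-site baseline offset (shared tumor/normal)
    patient_sd: float = 0.4        # patient random effect (shared tumor/normal)
    coupling_fraction: float = 0.3
    coupling_log2fc: float = 3.0
    nb_dispersion: float = 0.1
    n_other_cancer_groups: int = 5
    samples_per_group: int = 20
    n_specific_genes: int = 40
    specific_log2fc: float = 3.0
    n_celltypes: int = 10
    infiltration_coupled_regions: int = 120
    infiltration_coupling: float = 1.2  # logit units per latent s.d.
    n_celltypes_shifted: int = 3
    n_snps: int = 94
    snp_near_dmr_prob: float = 0.4
    snp_window_margin: int = 4500  # placement stays inside the 5 kb test window
    background_cpg_frac: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 3:
            raise ValueError("n_pairs must be >= 3")
        if not (0.0 < self.delta_beta < 1.0):
            raise ValueError("delta_beta must lie in (0, 1)")
        for kind in ("promoter", "enhancer"):
            hypo = self.dmr_fraction_hypo.get(kind, 0.0)
            hyper = self.dmr_fraction_hyper.get(kind, 0.0)
            for frac in (hypo, hyper):
                if not (0.0 <= frac <= 1.0):
                    raise ValueError("DMR fractions must lie in [0, 1]")
            if hypo + hyper > 1.0:
                raise ValueError(f"more planted DMRs than {kind} regions")
        if not (0.0 <= self.coupling_fraction <= 1.0):
            raise ValueError("coupling_fraction must lie in [0, 1]")
        if not (0.0 <= self.snp_near_dmr_prob <= 1.0):
            raise ValueError("snp_near_dmr_prob must lie in [0, 1]")
        lo, hi = self.cpgs_per_region_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid cpgs_per_region_range")


@dataclass
class PlantedTruth:
    true_dmrs: pd.DataFrame          # region_id, kind, direction
    true_functional: pd.DataFrame    # region_id, kind, direction, gene_id
    true_specific_genes: list[str]
    true_imr: pd.DataFrame           # region_id, kind, cell_type, sign
    snp_near_dmr: pd.DataFrame       # rsid, near_dmr


@dataclass
class CohortBundle:
    config: SyntheticConfig
    samples: pd.DataFrame            # sample_id, patient_id, tissue
    cpgs: pd.DataFrame               # site_id, chrom, pos
    beta: pd.DataFrame               # site x sample
    regions: dict[str, RegionSet]    # promoter / enhancer / super_enhancer / pmd
    epi: pd.DataFrame                # enhancer_id, gene_id, pet_count (unfiltered)
    genes: pd.DataFrame              # gene_id, promoter_region_id, is_coding
    counts: pd.DataFrame             # gene x sample (cohort)
    panel: dict[str, pd.DataFrame]   # group name -> gene x sample (normalized)
    fractions: pd.DataFrame          # cell type x sample
    snps: pd.DataFrame               # rsid, chrom, pos (0-based)
    gene_sets: list[GeneSet]
    truth: PlantedTruth


def _layout_genome(cfg: SyntheticConfig, rng: np.random.Generator):
    """Place promoters and enhancers on 10 chromosomes with >= 12 kb gaps.

    Gaps exceed twice the SNP test window so that a SNP placed near one
    region can never fall inside the window of a neighbouring one.
    """
    kinds = np.array(
        ["promoter"] * cfg.n_promoters + ["enhancer"] * cfg.n_enhancers
    )
    rng.shuffle(kinds)
    n_chroms = 10
    chrom_of = np.repeat(np.arange(n_chroms), int(np.ceil(len(kinds) / n_chroms)))[
        : len(kinds)
    ]
    promoters, enhancers = [], []
    chrom_ends = {}
    p_i = e_i = 0
    for c in range(n_chroms):
        cursor = 50_000
        chrom = f"chr{c + 1}"
        for kind in kinds[chrom_of == c]:
            cursor += int(rng.integers(12_000, 40_000))
            if kind == "promoter":
                length = int(rng.integers(800, 2000))
                rid = f"P{p_i:05d}"
                p_i += 1
                promoters.append(
                    GenomicInterval(chrom, cursor, cursor + length, rid, "promoter")
                )
            else:
                length = int(rng.integers(300, 1500))
                rid = f"E{e_i:05d}"
                e_i += 1
                enhancers.append(
                    GenomicInterval(chrom, cursor, cursor + length, rid, "enhancer")
                )
            cursor += length
        chrom_ends[chrom] = cursor + 50_000
    return RegionSet(promoters, "promoter"), RegionSet(enhancers, "enhancer"), chrom_ends


def _make_super_enhancers(
    cfg: SyntheticConfig, enhancers: RegionSet, rng: np.random.Generator
) -> RegionSet:
    ordered = sorted(enhancers, key=lambda iv: (iv.chrom, iv.start))
    ses, used = [], 0
    n_pick = min(cfg.n_super_enhancers, max(0, len(ordered) - 3))
    if n_pick == 0:
        return RegionSet([], "super_enhancer")
    idx = rng.choice(len(ordered) - 3, size=n_pick, replace=False)
    for i in sorted(int(j) for j in idx):
        span = int(rng.integers(1, 4))
        block = [ordered[i]]
        for j in range(i + 1, min(i + span, len(ordered))):
            if ordered[j].chrom == ordered[i].chrom:
                block.append(ordered[j])
        ses.append(
            GenomicInterval(
                block[0].chrom,
                max(0, block[0].start - 500),
                max(b.end for b in block) + 500,
                f"SE{used:04d}",
                "super_enhancer",
            )
        )
        used += 1
    return RegionSet(ses, "super_enhancer")


def _make_pmds(chrom_ends: dict[str, int], rng: np.random.Generator) -> RegionSet:
    pmds, i = [], 0
    for chrom, end in chrom_ends.items():
        cursor = 0
        while cursor < end:
            cursor += int(rng.integers(200_000, 800_000))
            length = int(rng.integers(150_000, 600_000))
            if cursor >= end:
                break
            pmds.append(
                GenomicInterval(chrom, cursor, min(cursor + length, end), f"PMD{i:04d}", "pmd")
            )
            i += 1
            cursor += length
    return RegionSet(pmds, "pmd")


def _plant_dmrs(cfg: SyntheticConfig, region_sets, rng) -> pd.DataFrame:
    rows = []
    for kind in ("promoter", "enhancer"):
        ids = np.array(region_sets[kind].ids)
        n = len(ids)
        n_hypo = int(round(cfg.dmr_fraction_hypo.get(kind, 0.0) * n))
        n_hyper = int(round(cfg.dmr_fraction_hyper.get(kind, 0.0) * n))
        if n_hypo + n_hyper > n:
            raise ValueError(f"more planted DMRs than {kind} regions")
        chosen = rng.choice(ids, size=n_hypo + n_hyper, replace=False)
        for rid in chosen[:n_hypo]:
            rows.append({"region_id": rid, "kind": kind, "direction": "hypo"})
        for rid in chosen[n_hypo:]:
            rows.append({"region_id": rid, "kind": kind, "direction": "hyper"})
    return pd.DataFrame(rows, columns=["region_id", "kind", "direction"])


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Generate the full bundle. Identical config + seed -> identical bundle."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # -- samples -----------------------------------------------------------
    patients = [f"PT{i:03d}" for i in range(cfg.n_pairs)]
    samples = pd.DataFrame(
        [
            {"sample_id": f"{p}_{t[0].upper()}", "patient_id": p, "tissue": t}
            for p in patients
            for t in ("tumor", "normal")
        ]
    )
    sample_ids = list(samples["sample_id"])
    is_tumor = (samples["tissue"] == "tumor").to_numpy()
    patient_idx = samples["patient_id"].map({p: i for i, p in enumerate(patients)}).to_numpy()

    # -- genome ------------------------------------------------------------
    promoters, enhancers, chrom_ends = _layout_genome(cfg, rng)
    region_sets = {"promoter": promoters, "enhancer": enhancers}
    region_sets["super_enhancer"] = _make_super_enhancers(cfg, enhancers, rng)
    region_sets["pmd"] = _make_pmds(chrom_ends, rng)

    truth_dmrs = _plant_dmrs(cfg, region_sets, rng)
    planted_dir = dict(zip(truth_dmrs["region_id"], truth_dmrs["direction"]))

    # -- genes & annotation -------------------------------------------------
    if cfg.n_genes < cfg.n_promoters:
        raise ValueError("need at least one gene per promoter")
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    is_coding = rng.random(cfg.n_genes) < 0.9
    promoter_of_gene = [""] * cfg.n_genes
    for i, rid in enumerate(promoters.ids):  # gene_i downstream of promoter_i
        promoter_of_gene[i] = rid
    genes = pd.DataFrame(
        {"gene_id": gene_ids, "promoter_region_id": promoter_of_gene, "is_coding": is_coding}
    )
    gene_of_promoter = {rid: gene_ids[i] for i, rid in enumerate(promoters.ids)}

    # -- CpG sites ----------------------------------------------------------
    lo, hi = cfg.cpgs_per_region_range
    site_rows = []
    region_site_counts: dict[str, int] = {}
    for kind in ("promoter", "enhancer"):
        for iv in region_sets[kind]:
            k = int(rng.integers(lo, hi + 1))
            k = min(k, iv.length)
            offsets = rng.choice(iv.length, size=k, replace=False)
            for off in sorted(int(o) for o in offsets):
                site_rows.append((iv.chrom, iv.start + off, iv.region_id))
            region_site_counts[iv.region_id] = k
    n_bg = int(cfg.background_cpg_frac * len(site_rows))
    chroms = list(chrom_ends)
    bg_chrom = rng.choice(chroms, size=n_bg)
    bg_pos = np.array([rng.integers(0, chrom_ends[c]) for c in bg_chrom])
    for c, p in zip(bg_chrom, bg_pos):
        if not promoters.query_point(c, int(p)) and not enhancers.query_point(c, int(p)):
            site_rows.append((c, int(p), ""))
    order = np.lexsort(
        ([r[1] for r in site_rows], [r[0] for r in site_rows])
    )
    site_rows = [site_rows[i] for i in order]
    cpgs = pd.DataFrame(
        {
            "site_id": [f"cg{i:07d}" for i in range(len(site_rows))],
            "chrom": [r[0] for r in site_rows],
            "pos": [r[1] for r in site_rows],
        }
    )
    site_region = np.array([r[2] for r in site_rows], dtype=object)

    # -- infiltration latents (needed before beta for coupling) -------------
    celltypes = [f"CT{i:02d}" for i in range(cfg.n_celltypes)]
    z = rng.standard_normal((cfg.n_celltypes, len(sample_ids)))
    alpha = rng.normal(0.0, 0.6, size=cfg.n_celltypes)
    shifts = np.zeros(cfg.n_celltypes)
    shift_pattern = np.array([1.0, -1.0, 0.6, 0.8, -0.7])
    n_shift = min(cfg.n_celltypes_shifted, cfg.n_celltypes)
    shifts[:n_shift] = shift_pattern[:n_shift]
    logits = alpha[:, None] + 0.5 * z + shifts[:, None] * is_tumor[None, :]
    expl = np.exp(logits)
    fractions = pd.DataFrame(expl / expl.sum(axis=0), index=celltypes, columns=sample_ids)

    # coupled (region, cell type, sign): preferentially enhancer DMRs
    shifted_cts = celltypes[:n_shift] if n_shift else celltypes[:1]
    pools = {
        "enh_dmr": list(truth_dmrs.query("kind == 'enhancer'")["region_id"]),
        "prom_dmr": list(truth_dmrs.query("kind == 'promoter'")["region_id"]),
        "enh_non": [r for r in enhancers.ids if r not in planted_dir],
        "prom_non": [r for r in promoters.ids if r not in planted_dir],
    }
    # coupling is planted predominantly on enhancer DMRs: the emulated study's
    # central observation is that infiltration-associated methylation sits on
    # enhancer DMRs far more than on promoter DMRs
    weights = {"enh_dmr": 0.7, "prom_dmr": 0.12, "enh_non": 0.12, "prom_non": 0.06}
    imr_rows = []
    n_coupled = cfg.infiltration_coupled_regions
    for pool_name, w in weights.items():
        pool = pools[pool_name]
        take = min(int(round(w * n_coupled)), len(pool))
        if take == 0:
            continue
        chosen = rng.choice(np.array(pool, dtype=object), size=take, replace=False)
        for rid in chosen:
            ct = str(rng.choice(shifted_cts))
            sign = int(rng.choice([-1, 1]))
            kind = "enhancer" if pool_name.startswith("enh") else "promoter"
            imr_rows.append(
                {"region_id": rid, "kind": kind, "cell_type": ct, "sign": sign}
            )
    truth_imr = pd.DataFrame(
        imr_rows, columns=["region_id", "kind", "cell_type", "sign"]
    )
    ct_index = {ct: i for i, ct in enumerate(celltypes)}

    # -- beta matrix ---------------------------------------------------------
    sigma_tot = float(
        np.sqrt(cfg.site_offset_sd**2 + cfg.patient_sd**2 + cfg.beta_dispersion**2)
    )
    all_region_ids = promoters.ids + enhancers.ids
    base_beta, mu_normal, mu_tumor = {}, {}, {}
    for rid in all_region_ids:
        direction = planted_dir.get(rid)
        if direction == "hypo":
            m0 = rng.uniform(cfg.delta_beta + 0.06, 0.94)
        elif direction == "hyper":
            m0 = rng.uniform(0.06, 0.94 - cfg.delta_beta)
        else:
            m0 = rng.uniform(0.08, 0.92)
        base_beta[rid] = m0
        mu_n = float(logit(m0))
        mu_normal[rid] = mu_n
        if direction is None:
            mu_tumor[rid] = mu_n
        else:
            shift = -cfg.delta_beta if direction == "hypo" else cfg.delta_beta
            mu_tumor[rid] = _solve_shifted_mu(mu_n, sigma_tot, shift)

    # region x sample mean logit (tissue-specific + infiltration coupling)
    mu_rs = np.empty((len(all_region_ids), len(sample_ids)))
    region_pos = {rid: i for i, rid in enumerate(all_region_ids)}
    for rid, i in region_pos.items():
        mu_rs[i] = np.where(is_tumor, mu_tumor[rid], mu_normal[rid])
    coupling = cfg.infiltration_coupling
    for row in truth_imr.itertuples(index=False):
        i = region_pos[row.region_id]
        zc = z[ct_index[row.cell_type]]
        mu_rs[i, is_tumor] += row.sign * coupling * zc[is_tumor]

    u_patient = rng.normal(0.0, cfg.patient_sd, size=cfg.n_pairs)
    n_sites = len(cpgs)
    site_mu = np.empty(n_sites)
    in_region = np.array([r != "" for r in site_region])
    bg_base = rng.uniform(0.05, 0.95, size=(~in_region).sum())
    site_offset = rng.normal(0.0, cfg.site_offset_sd, size=n_sites)

    logit_mat = np.empty((n_sites, len(sample_ids)))
    bg_i = 0
    site_region_idx = np.full(n_sites, -1)
    for s, rid in enumerate(site_region):
        if rid:
            site_region_idx[s] = region_pos[rid]
    in_mask = site_region_idx >= 0
    logit_mat[in_mask] = mu_rs[site_region_idx[in_mask]]
    logit_mat[~in_mask] = logit(bg_base)[:, None]
    logit_mat += site_offset[:, None]
    logit_mat += u_patient[patient_idx][None, :]
    logit_mat += rng.normal(0.0, cfg.beta_dispersion, size=logit_mat.shape)
    beta = pd.DataFrame(expit(logit_mat), index=cpgs["site_id"].to_numpy(), columns=sample_ids)

    # -- expression coupling -------------------------------------------------
    coupled_rows = []
    coupled_genes: set[str] = set()
    promoterless_coding = [
        gene_ids[i]
        for i in range(cfg.n_promoters, cfg.n_genes)
        if is_coding[i]
    ]
    rng.shuffle(promoterless_coding)
    free_gene_iter = iter(promoterless_coding)
    extra_epi_links = []
    for row in truth_dmrs.itertuples(index=False):
        if rng.random() >= cfg.coupling_fraction:
            continue
        if row.kind == "promoter":
            gid = gene_of_promoter[row.region_id]
            if not genes.set_index("gene_id").at[gid, "is_coding"]:
                continue
        else:
            gid = next(free_gene_iter, None)
            if gid is None:
                break
            extra_epi_links.append(
                {"enhancer_id": row.region_id, "gene_id": gid,
                 "pet_count": int(rng.integers(6, 30))}
            )
        coupled_genes.add(gid)
        coupled_rows.append(
            {"region_id": row.region_id, "kind": row.kind,
             "direction": row.direction, "gene_id": gid}
        )
    truth_functional = pd.DataFrame(
        coupled_rows, columns=["region_id", "kind", "direction", "gene_id"]
    )

    # -- EPI map (noise links + coupled links) -------------------------------
    noise_pool = np.array(
        [g for g in gene_ids if g not in coupled_genes], dtype=object
    )
    epi_rows = list(extra_epi_links)
    for rid in enhancers.ids:
        for _ in range(rng.poisson(1.5)):
            epi_rows.append(
                {
                    "enhancer_id": rid,
                    "gene_id": str(rng.choice(noise_pool)),
                    "pet_count": int(rng.integers(1, 20)),
                }
            )
    epi = (
        pd.DataFrame(epi_rows, columns=["enhancer_id", "gene_id", "pet_count"])
        .sort_values(["enhancer_id", "gene_id"])
        .reset_index(drop=True)
    )

    # -- cohort counts -------------------------------------------------------
    log_base = rng.normal(np.log(300.0), 1.0, size=cfg.n_genes)
    lib = np.exp(rng.normal(0.0, 0.15, size=len(sample_ids)))
    lfc = np.zeros(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for row in truth_functional.itertuples(index=False):
        sign = 1.0 if row.direction == "hypo" else -1.0  # inverse coupling
        lfc[gene_index[row.gene_id]] = sign * cfg.coupling_log2fc
    patient_effect = rng.normal(0.0, 0.2, size=(cfg.n_genes, cfg.n_pairs))
    log_mu = (
        log_base[:, None]
        + np.log(lib)[None, :]
        + lfc[:, None] * np.log(2.0) * is_tumor[None, :]
        + patient_effect[:, patient_idx]
    )
    mu = np.exp(log_mu)
    shape = 1.0 / cfg.nb_dispersion
    counts_mat = rng.poisson(rng.gamma(shape, mu * cfg.nb_dispersion))
    counts = pd.DataFrame(counts_mat, index=gene_ids, columns=sample_ids)

    # -- pan-cancer panel ----------------------------------------------------
    coupled_up = [
        r.gene_id for r in truth_functional.itertuples(index=False)
        if r.direction == "hypo"
    ]
    rng.shuffle(coupled_up)
    specific = coupled_up[: cfg.n_specific_genes]
    if len(specific) < cfg.n_specific_genes:
        filler = [g for g in promoterless_coding if g not in set(specific)]
        specific += filler[: cfg.n_specific_genes - len(specific)]
    specific_set = set(specific)
    panel = {}
    spec_boost = np.array(
        [cfg.specific_log2fc * np.log(2.0) if g in specific_set else 0.0 for g in gene_ids]
    )
    group_names = ["focal"] + [f"group_{i + 1}" for i in range(cfg.n_other_cancer_groups)]
    for name in group_names:
        group_effect = rng.normal(0.0, 0.15, size=cfg.n_genes)
        boost = spec_boost if name == "focal" else 0.0
        vals = np.exp(
            log_base[:, None]
            + group_effect[:, None]
            + (boost[:, None] if name == "focal" else 0.0)
            + rng.normal(0.0, 0.4, size=(cfg.n_genes, cfg.samples_per_group))
        )
        panel[name] = pd.DataFrame(
            vals,
            index=gene_ids,
            columns=[f"{name}_S{j:02d}" for j in range(cfg.samples_per_group)],
        )

    # -- SNPs ----------------------------------------------------------------
    lookup = {**{iv.region_id: iv for iv in promoters}, **{iv.region_id: iv for iv in enhancers}}
    snps, near_flags = place_snps(
        rng, lookup, all_region_ids, list(truth_dmrs["region_id"]),
        cfg.n_snps, cfg.snp_near_dmr_prob, cfg.snp_window_margin,
    )
    snp_truth = pd.DataFrame({"rsid": snps["rsid"], "near_dmr": near_flags})

    # -- gene sets -----------------------------------------------------------
    gene_sets = _make_gene_sets(cfg, truth_functional, gene_ids, rng)

    truth = PlantedTruth(
        true_dmrs=truth_dmrs,
        true_functional=truth_functional,
        true_specific_genes=list(specific),
        true_imr=truth_imr,
        snp_near_dmr=snp_truth,
    )
    return CohortBundle(
        config=cfg,
        samples=samples,
        cpgs=cpgs,
        beta=beta,
        regions=region_sets,
        epi=epi,
        genes=genes,
        counts=counts,
        panel=panel,
        fractions=fractions,
        snps=snps,
        gene_sets=gene_sets,
        truth=truth,
    )


def _make_gene_sets(cfg, truth_functional, gene_ids, rng) -> list[GeneSet]:
    """Synthetic gene-set collection: random sets plus sets enriched in
    planted targets (an enhancer-coupled 'hallmark' and a promoter-coupled
    'cancer_testis' set of 125 genes, mirroring the curated collections the
    analysis consumes)."""
    sets = []
    pool = np.array(gene_ids, dtype=object)
    enh_up = [
        r.gene_id for r in truth_functional.itertuples(index=False)
        if r.kind == "enhancer" and r.direction == "hypo"
    ]
    prom_up = [
        r.gene_id for r in truth_functional.itertuples(index=False)
        if r.kind == "promoter" and r.direction == "hypo"
    ]

    def sample_pool(size):
        return rng.choice(pool, size=min(size, len(pool)), replace=False)

    def planted_set(name, category, planted, size):
        take = min(len(planted), int(0.6 * size))
        members = set(rng.choice(np.array(planted, dtype=object), size=take, replace=False)) if take else set()
        members |= set(sample_pool(size - len(members)))
        return GeneSet(name, category, frozenset(str(g) for g in members))

    if enh_up:
        sets.append(planted_set("hallmark_planted_enhancer", "hallmark", enh_up, 120))
    if prom_up:
        sets.append(planted_set("cancer_testis_planted", "cancer_testis", prom_up, 125))
    for i in range(5):
        size = int(rng.integers(50, 200))
        sets.append(
            GeneSet(
                f"hallmark_random_{i}",
                "hallmark",
                frozenset(str(g) for g in sample_pool(size)),
            )
        )
    for i in range(8):
        size = int(rng.integers(30, 150))
        sets.append(
            GeneSet(
                f"pathway_random_{i}",
                "pathway",
                frozenset(str(g) for g in sample_pool(size)),
            )
        )
    for i, role in enumerate(("oncogene", "tumor_suppressor", "driver")):
        size = int(rng.integers(40, 120))
        sets.append(
            GeneSet(
                f"cancer_gene_role_{role}",
                "cancer_gene_role",
                frozenset(str(g) for g in sample_pool(size)),
            )
        )
    return sets


def place_snps(
    rng: np.random.Generator,
    lookup: dict[str, GenomicInterval],
    tested_ids: list[str],
    dmr_ids: list[str],
    n_snps: int,
    near_dmr_prob: float,
    margin: int = 4500,
) -> tuple[pd.DataFrame, list[bool]]:
    """Place SNPs near regions: each SNP lands within ``margin`` bp of a
    region chosen either from the DMR list (with probability
    ``near_dmr_prob``) or uniformly from all tested regions. Because the
    genome layout keeps regions > 2x the test window apart, a SNP is within
    the window of exactly the region it was placed at. Returns the SNP table
    (0-based positions) and per-SNP near-DMR flags.
    """
    dmr_set = set(dmr_ids)
    tested_arr = np.array(tested_ids, dtype=object)
    dmr_arr = np.array(dmr_ids, dtype=object)
    rows, flags = [], []
    for i in range(n_snps):
        near = bool(rng.random() < near_dmr_prob) and len(dmr_arr) > 0
        rid = str(rng.choice(dmr_arr if near else tested_arr))
        iv = lookup[rid]
        pos = int(rng.integers(max(0, iv.start - margin), iv.end + margin))
        rows.append({"rsid": f"rs{i + 1:06d}", "chrom": iv.chrom, "pos": pos})
        flags.append(near or (rid in dmr_set))
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos"]), flags


# ---------------------------------------------------------------------------
# I/O


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(bundle: CohortBundle, directory: str | Path) -> pd.DataFrame:
    """Write every table in the pipeline's external formats; returns the manifest.

    The manifest lists one (file, sha256) row per emitted file; checksums
    are stable across runs at a fixed seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ff = "%.6g"

    def tsv(frame: pd.DataFrame, name: str, index_label=None):
        frame.to_csv(directory / name, sep="\t", float_format=ff,
                     index=index_label is not None, index_label=index_label)

    for kind, regions in bundle.regions.items():
        write_regions(regions, directory / f"regions_{kind}.bed")
    write_cpg_manifest(bundle.cpgs, directory / "cpg_manifest.tsv")
    tsv(bundle.beta, "beta.tsv", index_label="site_id")
    tsv(bundle.counts, "counts.tsv", index_label="gene_id")
    for name, frame in bundle.panel.items():
        tsv(frame, f"panel_{name}.tsv", index_label="gene_id")
    tsv(bundle.epi, "epi.tsv")
    write_snps(bundle.snps, directory / "snps.tsv")
    tsv(bundle.fractions, "infiltration.tsv", index_label="cell_type")
    tsv(bundle.samples, "samples.tsv")
    tsv(bundle.genes, "genes.tsv")
    write_gmt(bundle.gene_sets, directory / "gene_sets.gmt")
    tsv(bundle.truth.true_dmrs, "truth_dmrs.tsv")
    tsv(bundle.truth.true_functional, "truth_functional.tsv")
    tsv(pd.DataFrame({"gene_id": bundle.truth.true_specific_genes}), "truth_specific_genes.tsv")
    tsv(bundle.truth.true_imr, "truth_imr.tsv")
    tsv(bundle.truth.snp_near_dmr, "truth_snp_near_dmr.tsv")
    cfg_dict = asdict(bundle.config)
    cfg_dict["cpgs_per_region_range"] = list(cfg_dict["cpgs_per_region_range"])
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)

    files = sorted(p for p in directory.iterdir() if p.is_file() and p.name != "manifest.tsv")
    manifest = pd.DataFrame(
        {"file": [p.name for p in files], "sha256": [_sha256(p) for p in files]}
    )
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_cohort(directory: str | Path) -> CohortBundle:
    """Load a bundle previously written by :func:`write_cohort`.

    Truth tables are loaded when present (they are for scoring, not for the
    analysis itself).
    """
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        cfg_dict = yaml.safe_load(fh)
    cfg_dict["cpgs_per_region_range"] = tuple(cfg_dict["cpgs_per_region_range"])
    for key in ("dmr_fraction_hypo", "dmr_fraction_hyper"):
        cfg_dict[key] = dict(cfg_dict[key])
    cfg = SyntheticConfig(**cfg_dict)

    regions = {
        kind: read_regions(directory / f"regions_{kind}.bed", kind)
        for kind in ("promoter", "enhancer", "super_enhancer", "pmd")
    }
    beta = pd.read_csv(directory / "beta.tsv", sep="\t", index_col="site_id")
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col="gene_id")
    panel = {}
    for path in sorted(directory.glob("panel_*.tsv")):
        panel[path.stem.removeprefix("panel_")] = pd.read_csv(
            path, sep="\t", index_col="gene_id"
        )
    fractions = pd.read_csv(directory / "infiltration.tsv", sep="\t", index_col="cell_type")

    def maybe(name: str) -> pd.DataFrame | None:
        path = directory / name
        return pd.read_csv(path, sep="\t") if path.exists() else None

    truth = PlantedTruth(
        true_dmrs=maybe("truth_dmrs.tsv"),
        true_functional=maybe("truth_functional.tsv"),
        true_specific_genes=(
            list(maybe("truth_specific_genes.tsv")["gene_id"])
            if (directory / "truth_specific_genes.tsv").exists()
            else []
        ),
        true_imr=maybe("truth_imr.tsv"),
        snp_near_dmr=maybe("truth_snp_near_dmr.tsv"),
    )
    return CohortBundle(
        config=cfg,
        samples=read_sample_sheet(directory / "samples.tsv"),
        cpgs=read_cpg_manifest(directory / "cpg_manifest.tsv"),
        beta=beta,
        regions=regions,
        epi=pd.read_csv(directory / "epi.tsv", sep="\t"),
        genes=read_gene_annotation(directory / "genes.tsv"),
        counts=counts,
        panel=panel,
        fractions=fractions,
        snps=read_snps(directory / "snps.tsv"),
        gene_sets=read_gmt(directory / "gene_sets.gmt"),
        truth=truth,
    )
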