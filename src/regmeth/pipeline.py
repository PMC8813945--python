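"""End-to-end orchestration of the promoter/enhancer methylation analysis.

Stages run in dependency order on a cohort bundle (synthetic or loaded from
disk): DMR calling per region kind, DEG calling, target mapping and
functional DMR / seDMR definition, embedding + entropy scoring, the
specificity-correlation contrast, gene-set and SNP enrichment, and the
immune-infiltration analysis. Every threshold is a named, overridable field
with the study's value as default. Outputs are deterministic at fixed
seeds; the run manifest (config echo, per-stage row counts, file checksums,
seed registry) is itself reproducible byte for byte, so wall-clock timings
are logged rather than written into it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, diffmeth, embedding, enrichment, immune, integration
from .cohort import CohortBundle, SyntheticConfig, generate_cohort, read_cohort
from .regions import RegionSet, assign_cpgs_to_regions, filter_epi_map

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "dmr", "deg", "targets", "embedding", "specificity",
    "enrichment", "snp", "immune",
)

_DEPS = {
    "dmr": (),
    "deg": (),
    "targets": ("dmr", "deg"),
    "embedding": ("dmr",),
    "specificity": ("dmr", "deg", "targets"),
    "enrichment": ("targets",),
    "snp": ("dmr",),
    "immune": ("dmr",),
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Thresholds default to the study's values; all are overridable."""

    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    outdir: str = "results/run"
    dmr_q: float = 0.01
    deg_lfc: float = 2.0
    deg_q: float = 0.01
    pet_min: int = 5
    snp_window: int = 5000
    imr_q: float = 0.01
    infil_q: float = 0.01
    specific_fc: float = 2.0
    specific_p: float = 0.05
    min_expr: float = 1.0
    imr_scope: str = "tumor"
    tsne_perplexity: float = 10.0
    embed_methods: tuple[str, ...] = ("tsne", "umap")
    seed: int = 42
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        for name in ("dmr_q", "deg_lfc", "deg_q", "imr_q", "infil_q",
                     "specific_fc", "specific_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            missing = [d for d in _DEPS[stage] if d not in self.stages]
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires {missing} to be enabled"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "cpgs_per_region_range" in syn:
                syn["cpgs_per_region_range"] = tuple(syn["cpgs_per_region_range"])
            raw["synthetic"] = SyntheticConfig(**syn)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "embed_methods" in raw:
            raw["embed_methods"] = tuple(raw["embed_methods"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Stage computations (importable on their own; the numbered analysis scripts
# and the acceptance tests call these directly).


def stage_cohort(config: PipelineConfig) -> CohortBundle:
    if config.input_dir is not None:
        return read_cohort(config.input_dir)
    if config.synthetic is None:
        raise ValueError("either input_dir or a synthetic config is required")
    return generate_cohort(config.synthetic)


def stage_dmr(bundle: CohortBundle, config: PipelineConfig) -> dict:
    """Per kind: region methylation matrix, site counts, and the DMR table."""
    out = {}
    for kind in ("promoter", "enhancer"):
        regions = bundle.regions[kind]
        region_map = assign_cpgs_to_regions(bundle.cpgs, regions)
        region_meth, n_sites = diffmeth.aggregate_region_methylation(
            bundle.beta, region_map
        )
        table = diffmeth.call_dmrs(
            region_meth,
            bundle.samples,
            kind=kind,
            q_threshold=config.dmr_q,
            regions=regions,
            n_sites=n_sites,
        )
        out[kind] = {"region_meth": region_meth, "n_sites": n_sites, "dmrs": table}
    return out


def stage_deg(bundle: CohortBundle, config: PipelineConfig) -> pd.DataFrame:
    return diffexpr.call_degs(
        bundle.counts, bundle.samples,
        lfc_threshold=config.deg_lfc, q_threshold=config.deg_q,
    )


def stage_targets(bundle: CohortBundle, dmr_out: dict, degs: pd.DataFrame,
                  config: PipelineConfig) -> dict:
    prom_targets = integration.map_promoter_targets(bundle.genes)
    epi = filter_epi_map(bundle.epi, min_pet=config.pet_min)
    enh_targets = integration.map_enhancer_targets(epi, bundle.genes)
    targets = pd.concat([prom_targets, enh_targets], ignore_index=True)
    dmrs = pd.concat([dmr_out["promoter"]["dmrs"], dmr_out["enhancer"]["dmrs"]],
                     ignore_index=True)
    pairs, per_dmr = integration.define_functional_dmrs(dmrs, degs, targets)
    sedmrs = integration.define_sedmrs(
        bundle.regions["super_enhancer"], dmr_out["enhancer"]["dmrs"],
        bundle.regions["enhancer"], enh_targets,
    )
    sedmr_pairs = integration.functional_sedmr_pairs(sedmrs, degs)
    return {
        "targets": targets,
        "promoter_targets": prom_targets,
        "enhancer_targets": enh_targets,
        "functional_pairs": pairs,
        "functional_dmrs": per_dmr,
        "sedmrs": sedmrs,
        "functional_sedmr_pairs": sedmr_pairs,
    }


def stage_embedding(bundle: CohortBundle, dmr_out: dict,
                    config: PipelineConfig) -> pd.DataFrame:
    region_meth = pd.concat(
        [dmr_out["promoter"]["region_meth"], dmr_out["enhancer"]["region_meth"]]
    )
    return embedding.compare_profiles(
        region_meth,
        {k: dmr_out[k]["dmrs"] for k in ("promoter", "enhancer")},
        bundle.samples,
        methods=config.embed_methods,
        seed=config.seed,
        perplexity=config.tsne_perplexity,
    )


def stage_specificity(bundle: CohortBundle, dmr_out: dict, targets: dict,
                      config: PipelineConfig) -> dict:
    focal = bundle.panel["focal"]
    comparisons = [v for k, v in sorted(bundle.panel.items()) if k != "focal"]
    specific = integration.define_specific_genes(
        focal, comparisons,
        fc_threshold=config.specific_fc, p_threshold=config.specific_p,
    )
    normalized, _ = diffexpr.normalize_counts(bundle.counts)
    corrs = []
    for kind, tkey in (("promoter", "promoter_targets"), ("enhancer", "enhancer_targets")):
        table = dmr_out[kind]["dmrs"]
        dmr_ids = set(table.loc[table["is_dmr"], "region_id"])
        links = targets[tkey]
        links = links[links["region_id"].isin(dmr_ids)]
        corr = integration.correlate_methylation_expression(
            dmr_out[kind]["region_meth"], normalized, links,
            min_expr=config.min_expr,
        )
        corr.insert(2, "kind", kind)
        corrs.append(corr)
    nonempty = [c for c in corrs if not c.empty]
    correlations = (
        pd.concat(nonempty, ignore_index=True) if nonempty else corrs[0]
    )
    correlations["is_specific_gene"] = correlations["gene_id"].isin(specific)
    contrast_rows = []
    for kind in ("promoter", "enhancer"):
        sub = correlations[correlations["kind"] == kind]
        spec_rho = sub.loc[sub["is_specific_gene"], "rho"]
        other_rho = sub.loc[~sub["is_specific_gene"], "rho"]
        if len(spec_rho) >= 3 and len(other_rho) >= 3:
            p, med_s, med_o = integration.compare_correlation_distributions(
                spec_rho, other_rho
            )
            contrast_rows.append(
                {"kind": kind, "p": p, "median_rho_specific": med_s,
                 "median_rho_other": med_o,
                 "n_specific": len(spec_rho), "n_other": len(other_rho)}
            )
    return {
        "specific_genes": sorted(specific),
        "correlations": correlations,
        "contrast": pd.DataFrame(
            contrast_rows,
            columns=["kind", "p", "median_rho_specific", "median_rho_other",
                     "n_specific", "n_other"],
        ),
    }


def stage_enrichment(bundle: CohortBundle, targets: dict,
                     config: PipelineConfig) -> pd.DataFrame:
    universe = set(bundle.genes.loc[bundle.genes["is_coding"], "gene_id"])
    pairs = targets["functional_pairs"]
    tables = []
    for kind in ("promoter", "enhancer"):
        for direction in ("hypo", "hyper"):
            sub = pairs[
                (pairs["kind"] == kind)
                & (pairs["direction"] == direction)
                & pairs["is_functional"]
            ]
            genes = sorted(set(sub["gene_id"]))
            if not genes:
                continue
            result = enrichment.fisher_enrichment(genes, universe, bundle.gene_sets)
            result.insert(0, "query", f"F-{kind[0]}DMR_{direction}")
            tables.append(result)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


def stage_snp(bundle: CohortBundle, dmr_out: dict,
              config: PipelineConfig) -> enrichment.SNPEnrichmentResult:
    dmr_sets, tested_sets = [], []
    for kind in ("promoter", "enhancer"):
        table = dmr_out[kind]["dmrs"]
        testable = table[table["testable"]]
        regions = bundle.regions[kind]
        tested_sets.append(
            RegionSet([regions.lookup(r) for r in testable["region_id"]], kind)
        )
        called = testable[testable["is_dmr"]]
        dmr_sets.append(
            RegionSet([regions.lookup(r) for r in called["region_id"]], kind)
        )
    return enrichment.snp_dmr_enrichment(
        bundle.snps, dmr_sets, tested_sets, window_bp=config.snp_window
    )


def stage_immune(bundle: CohortBundle, dmr_out: dict, targets: dict | None,
                 config: PipelineConfig) -> dict:
    diff = immune.differential_infiltration(
        bundle.fractions, bundle.samples, q_threshold=config.infil_q
    )
    cell_types = list(diff.loc[diff["is_diff"], "cell_type"])
    out = {"differential": diff, "imrs": {}, "overlap": [], "enrichment": []}
    if not cell_types:
        logger.warning("no differentially abundant cell types; IMR analysis skipped")
        out["overlap"] = pd.DataFrame()
        return out
    universe_genes = set(bundle.genes.loc[bundle.genes["is_coding"], "gene_id"])
    overlap_rows = []
    enr_tables = []
    for kind in ("promoter", "enhancer"):
        table = dmr_out[kind]["dmrs"]
        dmr_ids = set(table.loc[table["is_dmr"], "region_id"])
        imrs = immune.define_imrs(
            dmr_out[kind]["region_meth"], bundle.fractions, cell_types,
            bundle.samples, scope=config.imr_scope, q_threshold=config.imr_q,
            dmr_ids=dmr_ids, kind=kind,
        )
        universe = list(table.loc[table["testable"], "region_id"])
        stats = immune.imr_dmr_overlap_stats(imrs, universe, dmr_ids, kind)
        overlap_rows.append(
            {
                "kind": kind, "a": stats.a, "b": stats.b, "c": stats.c, "d": stats.d,
                "prop_dmr": stats.prop_dmr, "prop_nondmr": stats.prop_nondmr,
                "odds_ratio": stats.odds_ratio,
                "odds_ratio_haldane": stats.odds_ratio_haldane,
            }
        )
        inside, outside = immune.stratify_by_pmd(
            imrs, bundle.regions[kind], bundle.regions["pmd"]
        )
        imrs = pd.concat([inside, outside], ignore_index=True).sort_values(
            ["region_id", "cell_type"]
        ).reset_index(drop=True)
        out["imrs"][kind] = imrs
        if targets is not None:
            tkey = f"{kind}_targets"
            for pmd_status, part in (("inside", inside), ("outside", outside)):
                imr_dmr_ids = set(
                    part.loc[part["is_imr"] & part["is_dmr"], "region_id"]
                )
                enr = immune.imr_target_enrichment(
                    imr_dmr_ids, targets[tkey], bundle.gene_sets, universe_genes
                )
                if not enr.empty:
                    enr.insert(0, "query", f"IMR-{kind[0]}DMR_{pmd_status}_pmd")
                    enr_tables.append(enr)
    out["overlap"] = pd.DataFrame(overlap_rows)
    out["enrichment"] = (
        pd.concat(enr_tables, ignore_index=True) if enr_tables else pd.DataFrame()
    )
    return out


# ---------------------------------------------------------------------------
# Orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages, write TSV outputs + manifest.json, return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    timings: dict[str, float] = {}
    results: dict = {}

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineStageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s finished in %.1fs", name, timings[name])
        return result

    bundle = run_stage("cohort", stage_cohort, config)
    counts["cohort_samples"] = len(bundle.samples)
    counts["cohort_cpgs"] = len(bundle.cpgs)

    dmr_out = degs = targets = None
    if "dmr" in config.stages:
        dmr_out = run_stage("dmr", stage_dmr, bundle, config)
        for kind in ("promoter", "enhancer"):
            table = dmr_out[kind]["dmrs"]
            _write(table, outdir / f"dmr_{kind}.tsv")
            counts[f"dmr_{kind}_tested"] = int(table["testable"].sum())
            counts[f"dmr_{kind}_called"] = int(table["is_dmr"].sum())
            counts[f"dmr_{kind}_hypo"] = int(
                (table["is_dmr"] & (table["direction"] == "hypo")).sum()
            )
            counts[f"dmr_{kind}_hyper"] = int(
                (table["is_dmr"] & (table["direction"] == "hyper")).sum()
            )
    if "deg" in config.stages:
        degs = run_stage("deg", stage_deg, bundle, config)
        _write(degs, outdir / "degs.tsv")
        counts["deg_called"] = int(degs["is_deg"].sum())
    if "targets" in config.stages:
        targets = run_stage("targets", stage_targets, bundle, dmr_out, degs, config)
        _write(targets["targets"], outdir / "targets.tsv")
        _write(targets["functional_pairs"], outdir / "functional_pairs.tsv")
        _write(targets["functional_dmrs"], outdir / "functional_dmrs.tsv")
        _write(targets["sedmrs"], outdir / "sedmrs.tsv")
        _write(targets["functional_sedmr_pairs"], outdir / "functional_sedmr_pairs.tsv")
        counts["target_links"] = len(targets["targets"])
        counts["functional_pairs"] = int(targets["functional_pairs"]["is_functional"].sum())
        counts["functional_dmrs"] = int(targets["functional_dmrs"]["is_functional_dmr"].sum())
        counts["sedmrs"] = len(targets["sedmrs"])
    if "embedding" in config.stages:
        report = run_stage("embedding", stage_embedding, bundle, dmr_out, config)
        _write(report, outdir / "embedding_report.tsv")
        counts["embedding_profiles"] = len(report)
        results["embedding"] = report
    if "specificity" in config.stages:
        spec = run_stage("specificity", stage_specificity, bundle, dmr_out, targets, config)
        _write(pd.DataFrame({"gene_id": spec["specific_genes"]}),
               outdir / "specific_genes.tsv")
        _write(spec["correlations"], outdir / "correlations.tsv")
        _write(spec["contrast"], outdir / "correlation_contrast.tsv")
        counts["specific_genes"] = len(spec["specific_genes"])
        counts["correlation_links"] = len(spec["correlations"])
        results["specificity"] = spec
    if "enrichment" in config.stages:
        enr = run_stage("enrichment", stage_enrichment, bundle, targets, config)
        _write(enr, outdir / "enrichment_functional.tsv")
        counts["enrichment_tests"] = len(enr)
        results["enrichment"] = enr
    if "snp" in config.stages:
        snp = run_stage("snp", stage_snp, bundle, dmr_out, config)
        _write(
            pd.DataFrame(
                [{"n_snps": snp.n_snps, "k_hits": snp.k_hits,
                  "p0": snp.p0, "p_value": snp.p_value}]
            ),
            outdir / "snp_enrichment.tsv",
        )
        counts["snp_profiled"] = snp.n_snps
        counts["snp_hits"] = snp.k_hits
        results["snp"] = snp
    if "immune" in config.stages:
        imm = run_stage("immune", stage_immune, bundle, dmr_out, targets, config)
        _write(imm["differential"], outdir / "infiltration_differential.tsv")
        for kind, table in imm["imrs"].items():
            _write(table, outdir / f"imr_{kind}.tsv")
            counts[f"imr_{kind}_regions"] = int(
                table.loc[table["is_imr"], "region_id"].nunique()
            )
        if len(imm["overlap"]):
            _write(imm["overlap"], outdir / "imr_overlap.tsv")
        if len(imm["enrichment"]):
            _write(imm["enrichment"], outdir / "imr_enrichment.tsv")
        counts["infiltration_diff_celltypes"] = int(imm["differential"]["is_diff"].sum())
        results["immune"] = imm

    results.update({"bundle": bundle, "dmr": dmr_out, "degs": degs, "targets": targets})

    files = sorted(
        p.name for p in outdir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    cfg_echo = dataclasses.asdict(config)
    if cfg_echo.get("synthetic") is not None:
        cfg_echo["synthetic"]["cpgs_per_region_range"] = list(
            cfg_echo["synthetic"]["cpgs_per_region_range"]
        )
    cfg_echo["stages"] = list(cfg_echo["stages"])
    cfg_echo["embed_methods"] = list(cfg_echo["embed_methods"])
    skipped = [s for s in ALL_STAGES if s not in config.stages]
    manifest = {
        "config": cfg_echo,
        "counts": counts,
        "files": {name: _sha256(outdir / name) for name in files},
        "seeds": {
            "pipeline": config.seed,
            "synthetic": None if config.synthetic is None else config.synthetic.seed,
        },
        "skipped_stages": skipped,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("total runtime %.1fs", sum(timings.values()))
    manifest["_results"] = results  # in-memory only; not serialized
    manifest["_timings"] = timings
    return manifest
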