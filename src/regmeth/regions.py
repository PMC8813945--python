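"""Genomic data model, interval arithmetic, and readers/writers.

Internal coordinate convention is 0-based half-open (BED). SNP tables are
read as 1-based and converted on ingest. Chromosome names are normalized to
the ``chr``-prefixed dialect. Strand is carried but ignored by all overlap
operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from intervaltree import IntervalTree

REGION_KINDS = ("promoter", "enhancer", "super_enhancer", "pmd")


class RegionParseError(ValueError):
    """Raised when a BED/TSV row violates the interval contract."""


def normalize_chrom(name: str) -> str:
    name = str(name).strip()
    return name if name.startswith("chr") else f"chr{name}"


@dataclass(frozen=True)
class GenomicInterval:
    """One genomic region: 0-based half-open [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    region_id: str
    kind: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RegionParseError(
                f"interval {self.region_id}: start {self.start} >= end {self.end}"
            )
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """Collection of same-kind intervals with an O(log n + hits) point/range index."""

    def __init__(self, intervals: Iterable[GenomicInterval], kind: str | None = None):
        self.intervals: list[GenomicInterval] = list(intervals)
        if kind is None:
            if not self.intervals:
                raise ValueError("kind must be given for an empty RegionSet")
            kind = self.intervals[0].kind
        self.kind = kind
        self._by_id: dict[str, GenomicInterval] = {}
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            if iv.kind != self.kind:
                raise ValueError(
                    f"mixed kinds in RegionSet: {iv.kind} vs {self.kind}"
                )
            if iv.region_id in self._by_id:
                raise ValueError(f"duplicate region_id {iv.region_id!r}")
            self._by_id[iv.region_id] = iv
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv.region_id
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def lookup(self, region_id: str) -> GenomicInterval:
        return self._by_id[region_id]

    @property
    def ids(self) -> list[str]:
        return [iv.region_id for iv in self.intervals]

    def query(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All intervals overlapping [start, end) on chrom."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(
            (self._by_id[hit.data] for hit in tree.overlap(start, end)),
            key=lambda iv: (iv.start, iv.region_id),
        )

    def query_point(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """Intervals containing pos (half-open: start <= pos < end)."""
        return self.query(chrom, pos, pos + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "region_id": [iv.region_id for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )


def read_regions(path: str | Path, kind: str) -> RegionSet:
    """Read a 3+ column BED file (0-based half-open) into a RegionSet.

    The optional 4th column is the region id; rows without one get the
    auto-generated id ``<kind>_<chrom>_<start>_<end>``. The optional 6th
    column is strand.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise RegionParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise RegionParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            chrom = normalize_chrom(cols[0])
            region_id = (
                cols[3] if len(cols) >= 4 and cols[3] not in ("", ".")
                else f"{kind}_{chrom}_{start}_{end}"
            )
            strand = cols[5] if len(cols) >= 6 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, region_id, kind, strand)
                )
            except RegionParseError as exc:
                raise RegionParseError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(intervals, kind=kind)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    """Write BED (chrom, start, end, region_id, score, strand), sorted by chrom/start."""
    rows = sorted(regions, key=lambda iv: (iv.chrom, iv.start, iv.region_id))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.region_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# CpG manifests


def read_cpg_manifest(path: str | Path) -> pd.DataFrame:
    """TSV with header: site_id, chrom, pos (0-based)."""
    cpgs = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str})
    cpgs["chrom"] = cpgs["chrom"].map(normalize_chrom)
    if cpgs["site_id"].duplicated().any():
        raise RegionParseError("duplicate site_id in CpG manifest")
    if (cpgs["pos"] < 0).any():
        raise RegionParseError("negative CpG position")
    return cpgs[["site_id", "chrom", "pos"]]


def write_cpg_manifest(cpgs: pd.DataFrame, path: str | Path) -> None:
    cpgs.sort_values(["chrom", "pos", "site_id"]).to_csv(path, sep="\t", index=False)


def assign_cpgs_to_regions(
    cpgs: pd.DataFrame, regions: RegionSet
) -> dict[str, list[str]]:
    """Map region_id -> site_ids contained in the region (start <= pos < end).

    A site overlapping k regions appears in all k lists; regions with no
    sites map to empty lists (those regions are untestable downstream).
    """
    mapping: dict[str, list[str]] = {iv.region_id: [] for iv in regions}
    for site_id, chrom, pos in cpgs[["site_id", "chrom", "pos"]].itertuples(index=False):
        for iv in regions.query_point(chrom, int(pos)):
            mapping[iv.region_id].append(site_id)
    return mapping


# ---------------------------------------------------------------------------
# EPI map, SNPs, gene annotation, sample sheet


def read_epi_map(path: str | Path, min_pet: int = 5) -> pd.DataFrame:
    """Enhancer-promoter interaction table; keeps links with pet_count >= min_pet.

    Duplicate (enhancer_id, gene_id) pairs are collapsed keeping the maximum
    PET count. Unknown enhancer ids are allowed here; they are validated when
    targets are mapped.
    """
    epi = pd.read_csv(path, sep="\t", dtype={"enhancer_id": str, "gene_id": str})
    return filter_epi_map(epi, min_pet=min_pet)


def filter_epi_map(epi: pd.DataFrame, min_pet: int = 5) -> pd.DataFrame:
    if (epi["pet_count"] < 0).any():
        raise ValueError("negative pet_count in EPI map")
    collapsed = (
        epi.groupby(["enhancer_id", "gene_id"], as_index=False)["pet_count"].max()
    )
    kept = collapsed[collapsed["pet_count"] >= min_pet].reset_index(drop=True)
    return kept.sort_values(["enhancer_id", "gene_id"]).reset_index(drop=True)


def read_snps(path: str | Path) -> pd.DataFrame:
    """SNP table (rsid, chrom, pos). Positions are 1-based on disk; 0-based in memory."""
    snps = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    if snps["rsid"].duplicated().any():
        raise RegionParseError("duplicate rsid in SNP table")
    snps["chrom"] = snps["chrom"].map(normalize_chrom)
    snps["pos"] = snps["pos"].astype(int) - 1
    return snps[["rsid", "chrom", "pos"]]


def write_snps(snps: pd.DataFrame, path: str | Path) -> None:
    out = snps.copy()
    out["pos"] = out["pos"].astype(int) + 1  # back to 1-based on disk
    out.sort_values(["chrom", "pos", "rsid"]).to_csv(path, sep="\t", index=False)


def within_window(
    snps: pd.DataFrame, regions: RegionSet, window_bp: int = 5000
) -> dict[str, list[str]]:
    """rsid -> region_ids with pos in [start - window_bp, end + window_bp).

    The window is symmetric on both flanks and measured from the region
    edges; window_bp = 0 reduces to plain containment.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            max(0, iv.start - window_bp), iv.end + window_bp, iv.region_id
        )
    hits: dict[str, list[str]] = {}
    for rsid, chrom, pos in snps[["rsid", "chrom", "pos"]].itertuples(index=False):
        tree = trees.get(normalize_chrom(chrom))
        found = sorted(h.data for h in tree.overlap(int(pos), int(pos) + 1)) if tree else []
        hits[rsid] = found
    return hits


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene table: gene_id, promoter_region_id (empty allowed), is_coding."""
    genes = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "promoter_region_id": str}
    )
    genes["promoter_region_id"] = genes["promoter_region_id"].fillna("")
    genes["is_coding"] = genes["is_coding"].astype(bool)
    if genes["gene_id"].duplicated().any():
        raise RegionParseError("duplicate gene_id in gene annotation")
    return genes[["gene_id", "promoter_region_id", "is_coding"]]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet: sample_id, patient_id, tissue ({tumor, normal})."""
    samples = pd.read_csv(path, sep="\t", dtype=str)
    validate_sample_sheet(samples)
    return samples[["sample_id", "patient_id", "tissue"]]


def validate_sample_sheet(samples: pd.DataFrame) -> None:
    bad = set(samples["tissue"]) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}")
    dup = samples.groupby(["patient_id", "tissue"]).size()
    if (dup > 1).any():
        raise ValueError("a patient has more than one sample of the same tissue")


def complete_pairs(samples: pd.DataFrame) -> pd.DataFrame:
    """Patients with both a tumor and a normal sample.

    Returns a frame (patient_id, tumor, normal) in patient order; paired
    analyses use only these.
    """
    wide = samples.pivot(index="patient_id", columns="tissue", values="sample_id")
    for col in ("tumor", "normal"):
        if col not in wide:
            wide[col] = pd.NA
    paired = wide.dropna(subset=["tumor", "normal"]).reset_index()
    return paired[["patient_id", "tumor", "normal"]]
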