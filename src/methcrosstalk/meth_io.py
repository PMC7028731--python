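"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are held 0-based, half-open. The Bismark coverage
dialect is 1-based inclusive on disk and is shifted at the parsing boundary;
BED input is already 0-based half-open and passes through verbatim.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "GenomicInterval",
    "GeneModel",
    "MethCohort",
    "LogFCTable",
    "CqPanel",
    "UNDETERMINED",
    "read_bismark_cov",
    "write_bismark_cov",
    "merge_strand_counts",
    "assemble_cohort",
    "read_bed_track",
    "write_bed_track",
    "read_logfc_table",
    "write_logfc_tables",
    "read_cq_panel",
    "write_cq_panel",
    "read_sample_sheet",
]

GROUPS = ("case", "control")
MUTATION_STATES = ("positive", "negative", "unknown")

#: Sentinel accepted in Cq panel files for reactions that never crossed threshold.
UNDETERMINED = "Undetermined"


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: group label plus KRAS/BRAF mutation status."""

    sample_id: str
    group: str
    kras: str = "unknown"
    braf: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name, val in (("kras", self.kras), ("braf", self.braf)):
            if val not in MUTATION_STATES:
                raise ValueError(f"{name} must be one of {MUTATION_STATES}, got {val!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval with optional strand and name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with a strand-aware transcription start site."""

    interval: GenomicInterval
    gene_id: str

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand != "-" else iv.end - 1

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError("TSS must lie within the gene interval")


class MethCohort:
    """Per-CpG methylated/total read counts across case and control samples.

    Counts are dense float matrices of shape (n_sites, n_samples); a NaN
    total marks a site absent from that sample (union assembly). Sites are
    sorted by (chrom, pos) and shared across all samples.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        meth: np.ndarray,
        total: np.ndarray,
        samples: Sequence[SampleMeta],
    ):
        sites = sites.reset_index(drop=True)
        if list(sites.columns[:2]) != ["chrom", "pos"]:
            raise ValueError("sites frame must have columns (chrom, pos)")
        meth = np.asarray(meth, dtype=float)
        total = np.asarray(total, dtype=float)
        if meth.shape != total.shape or meth.shape != (len(sites), len(samples)):
            raise ValueError("count matrices must be (n_sites, n_samples)")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")
        with np.errstate(invalid="ignore"):
            if np.nanmin(meth, initial=0) < 0 or np.nanmin(total - meth, initial=0) < 0:
                raise ValueError("negative counts in cohort")
        self.sites = sites
        self.meth = meth
        self.total = total
        self.samples = list(samples)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_index(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.group == group], dtype=int)

    @property
    def case_index(self) -> np.ndarray:
        return self.group_index("case")

    @property
    def control_index(self) -> np.ndarray:
        return self.group_index("control")

    def betas(self) -> np.ndarray:
        """Per-site, per-sample methylation fraction; NaN where uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            b = self.meth / self.total
        b[self.total == 0] = np.nan
        return b

    def subset_sites(self, mask: np.ndarray) -> "MethCohort":
        return MethCohort(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask], self.total[mask], self.samples,
        )


@dataclass
class LogFCTable:
    """Per-gene log fold changes from one external dataset."""

    dataset_id: str
    kind: str  # expression | methylation
    rows: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("expression", "methylation"):
            raise ValueError(f"kind must be expression or methylation, got {self.kind!r}")


@dataclass
class CqPanel:
    """qPCR panel: per-sample target and reference quantification cycles.

    Undetermined reactions are stored as the ``max_cycles`` sentinel so that
    'no amplification' ranks as least methylated in threshold searches.
    """

    records: pd.DataFrame  # columns: sample_id, group, cq_target, cq_reference
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        req = ["sample_id", "group", "cq_target", "cq_reference"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"CqPanel missing columns {missing}")
        bad = set(self.records["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        for col in ("cq_target", "cq_reference"):
            v = self.records[col].to_numpy(dtype=float)
            if np.any(v <= 0) or np.any(v > self.max_cycles):
                raise ValueError(f"{col} values must lie in (0, {self.max_cycles}]")

    def group_values(self, group: str, column: str = "cq_target") -> np.ndarray:
        return self.records.loc[self.records["group"] == group, column].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Bismark coverage dialect
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_bismark_cov(path: str | Path, min_total: int = 5) -> pd.DataFrame:
    """Parse a Bismark coverage file into per-CpG counts.

    Columns on disk: chrom, start (1-based), end, percent methylation,
    count methylated, count unmethylated. The percent column is ignored in
    favour of the counts; positions come out 0-based; sites with
    total coverage below ``min_total`` are dropped.
    """
    recs = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 tab-separated fields")
            try:
                chrom = parts[0]
                start = int(parts[1])
                cm = int(parts[4])
                cu = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if cm < 0 or cu < 0:
                raise ParseError(f"{path}:{lineno}: negative counts")
            if start < 1:
                raise ParseError(f"{path}:{lineno}: 1-based start must be >= 1")
            if cm + cu < min_total:
                continue
            recs.append((chrom, start - 1, cm, cu))
    df = pd.DataFrame(recs, columns=["chrom", "pos", "count_meth", "count_unmeth"])
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["chrom", "pos"]).any():
        raise ParseError(f"{path}: duplicate (chrom, pos) records")
    return df


def write_bismark_cov(df: pd.DataFrame, path: str | Path) -> None:
    """Inverse of :func:`read_bismark_cov` (positions shift back to 1-based)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            total = row.count_meth + row.count_unmeth
            pct = 100.0 * row.count_meth / total if total else 0.0
            start1 = row.pos + 1
            fh.write(
                f"{row.chrom}\t{start1}\t{start1}\t{pct:.6g}\t{row.count_meth}\t{row.count_unmeth}\n"
            )


def merge_strand_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Sum plus/minus strand records of the same CpG unit (pos, pos+1).

    Off by default in the readers: input is normally already destranded.
    A record at pos+1 immediately following one at pos on the same
    chromosome is folded into the pos record.
    """
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out = []
    i = 0
    while i < len(df):
        row = df.iloc[i]
        if (
            i + 1 < len(df)
            and df.iloc[i + 1]["chrom"] == row["chrom"]
            and df.iloc[i + 1]["pos"] == row["pos"] + 1
        ):
            nxt = df.iloc[i + 1]
            out.append(
                (row["chrom"], int(row["pos"]),
                 int(row["count_meth"] + nxt["count_meth"]),
                 int(row["count_unmeth"] + nxt["count_unmeth"]))
            )
            i += 2
        else:
            out.append((row["chrom"], int(row["pos"]), int(row["count_meth"]), int(row["count_unmeth"])))
            i += 1
    return pd.DataFrame(out, columns=["chrom", "pos", "count_meth", "count_unmeth"])


def assemble_cohort(
    samples: Sequence[tuple[SampleMeta, pd.DataFrame]],
    mode: Literal["intersection", "union"] = "intersection",
) -> MethCohort:
    """Align per-sample CpG tables onto a shared site list.

    Intersection keeps sites covered in every sample; union keeps all sites
    with absences recorded as NaN totals.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"mode must be intersection or union, got {mode!r}")
    metas = [m for m, _ in samples]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id")
    groups = {m.group for m in metas}
    if groups != set(GROUPS):
        raise ValueError("need at least one case and one control sample")

    keyed = []
    for meta, df in samples:
        d = df.set_index(["chrom", "pos"])[["count_meth", "count_unmeth"]]
        keyed.append(d)
    if mode == "intersection":
        index = keyed[0].index
        for d in keyed[1:]:
            index = index.intersection(d.index)
        if len(index) == 0:
            raise ValueError("no sites shared by all samples in intersection mode")
    else:
        index = keyed[0].index
        for d in keyed[1:]:
            index = index.union(d.index)
    index = index.sortlevel([0, 1])[0]

    n_sites, n_samples = len(index), len(samples)
    meth = np.full((n_sites, n_samples), np.nan)
    total = np.full((n_sites, n_samples), np.nan)
    for j, d in enumerate(keyed):
        aligned = d.reindex(index)
        cm = aligned["count_meth"].to_numpy(dtype=float)
        cu = aligned["count_unmeth"].to_numpy(dtype=float)
        meth[:, j] = cm
        total[:, j] = cm + cu
    sites = pd.DataFrame({"chrom": index.get_level_values(0), "pos": index.get_level_values(1)})
    return MethCohort(sites, meth, total, metas)


# ---------------------------------------------------------------------------
# BED tracks
# ---------------------------------------------------------------------------

def read_bed_track(path: str | Path) -> list[GenomicInterval]:
    """BED3+ reader; 0-based half-open coordinates preserved verbatim."""
    out = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed_track(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def gene_track_to_models(track: Iterable[GenomicInterval]) -> list[GeneModel]:
    """Interpret a BED6 gene track as gene models (name column = gene id)."""
    return [GeneModel(iv, iv.name or f"{iv.chrom}:{iv.start}") for iv in track]


# ---------------------------------------------------------------------------
# logFC tables
# ---------------------------------------------------------------------------

def read_logfc_table(path: str | Path, kind: str) -> list[LogFCTable]:
    """Read a wide (gene_id + one column per dataset) or long TSV of logFCs.

    Empty cells mean the gene is absent from that dataset, never zero.
    Returns one table per dataset column.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["gene", "dataset", "logfc"] or cols[:3] == ["gene_id", "dataset", "logfc"]:
        long = df.rename(columns=dict(zip(df.columns, ["gene_id", "dataset", "logfc"])))
        if long.duplicated(["gene_id", "dataset"]).any():
            raise ParseError(f"{path}: duplicate (gene, dataset) rows")
        tables = []
        for ds, sub in long.groupby("dataset", sort=True):
            rows = {g: float(v) for g, v in zip(sub["gene_id"], sub["logfc"]) if pd.notna(v)}
            tables.append(LogFCTable(str(ds), kind, rows))
        return tables
    # wide form
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        raise ParseError(f"{path}: repeated gene rows")
    tables = []
    for ds in df.columns[1:]:
        rows = {
            str(g): float(v)
            for g, v in zip(df[gene_col], df[ds])
            if pd.notna(v) and str(v).strip() != ""
        }
        tables.append(LogFCTable(str(ds), kind, rows))
    return tables


def write_logfc_tables(tables: Sequence[LogFCTable], path: str | Path) -> None:
    genes = sorted({g for t in tables for g in t.rows})
    data = {"gene_id": genes}
    for t in tables:
        data[t.dataset_id] = [t.rows.get(g, np.nan) for g in genes]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Cq panels and sample sheets
# ---------------------------------------------------------------------------

_NA_CQ = {"na", "nan", "undetermined", ""}


def read_cq_panel(path: str | Path, max_cycles: float = 40.0) -> CqPanel:
    """TSV with columns sample, group, cq_target, cq_reference.

    'NA'/'Undetermined' cells become the ``max_cycles`` sentinel.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    ren = {"sample": "sample_id"}
    df = df.rename(columns=ren)
    req = ["sample_id", "group", "cq_target", "cq_reference"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    def parse_cq(v: str) -> float:
        if v is None or str(v).strip().lower() in _NA_CQ:
            return float(max_cycles)
        x = float(v)
        if x > max_cycles:
            raise ParseError(f"{path}: Cq {x} exceeds max_cycles={max_cycles}")
        return x

    out = df[req].copy()
    out["cq_target"] = [parse_cq(v) for v in df["cq_target"]]
    out["cq_reference"] = [parse_cq(v) for v in df["cq_reference"]]
    return CqPanel(out, max_cycles=float(max_cycles))


def write_cq_panel(panel: CqPanel, path: str | Path) -> None:
    panel.records.rename(columns={"sample_id": "sample"}).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """TSV with columns sample, group and optional kras, braf."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns={"sample": "sample_id"})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleMeta(
                sample_id=row.sample_id,
                group=row.group,
                kras=getattr(row, "kras", "unknown"),
                braf=getattr(row, "braf", "unknown"),
            )
        )
    return out
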