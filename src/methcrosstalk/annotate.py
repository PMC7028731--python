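"""CGI-context (island/shore/shelf/opensea) and genic-context annotation of DMRs.

Shores are the 2 kb flanks immediately outside a CpG island; shelves the
next 2 kb (2-4 kb from the island boundary); everything farther is open sea.
Genic context uses a strand-aware promoter window around the TSS (default
1.5 kb upstream to 0.5 kb downstream); the gene body is the gene span minus
its promoter; intergenic is everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dmr import DMR
from .meth_io import GeneModel, GenomicInterval

__all__ = [
    "AnnotationParams",
    "FeatureAnnotation",
    "classify_cgi_context",
    "classify_genic_context",
    "annotate_dmrs",
    "summarize_features",
    "GENIC_LABELS",
    "CGI_LABELS",
]

GENIC_LABELS = ("promoter", "genebody", "intergenic")
CGI_LABELS = ("island", "shore", "shelf", "opensea")

SHORE_BP = 2000
SHELF_BP = 4000


@dataclass(frozen=True)
class AnnotationParams:
    promoter_up: int = 1500
    promoter_down: int = 500


@dataclass(frozen=True)
class FeatureAnnotation:
    dmr_id: str
    direction: str
    features: frozenset[tuple[str, str]]  # (genic, cgi) pairs
    nearest_gene: str
    tss_distance: int  # signed, strand-aware: positive = downstream of TSS

    def __post_init__(self) -> None:
        assert self.features, "every DMR carries at least one feature pair"


class _CgiIndex:
    """Sorted per-chromosome island boundaries for fast context lookup."""

    def __init__(self, cgi_track: Iterable[GenomicInterval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per: dict[str, list[GenomicInterval]] = {}
        for iv in cgi_track:
            per.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in per.items():
            ivs.sort(key=lambda x: (x.start, x.end))
            self.by_chrom[chrom] = (
                np.array([iv.start for iv in ivs]),
                np.array([iv.end for iv in ivs]),
            )

    def distance(self, chrom: str, position: int) -> float:
        """0 inside an island, else bp to the nearest island boundary; inf if none."""
        if chrom not in self.by_chrom:
            return np.inf
        starts, ends = self.by_chrom[chrom]
        j = int(np.searchsorted(starts, position, side="right")) - 1
        best = np.inf
        if j >= 0:
            if position < ends[j]:
                return 0.0
            best = min(best, position - (ends[j] - 1))
        # islands are sorted by start but may overlap; scan a small window back
        for k in range(max(0, j - 3), j):
            if position < ends[k]:
                return 0.0
            best = min(best, position - (ends[k] - 1))
        if j + 1 < len(starts):
            best = min(best, starts[j + 1] - position)
        return best


def classify_cgi_context(position: int, cgi_track: Sequence[GenomicInterval] | _CgiIndex,
                         chrom: str | None = None) -> str:
    """Label one position: island, shore (<=2 kb of a boundary), shelf (2-4 kb), opensea.

    ``cgi_track`` may be a pre-built index (fast path) or a raw interval list,
    in which case ``chrom`` defaults to the track's single chromosome.
    """
    if isinstance(cgi_track, _CgiIndex):
        index = cgi_track
        if chrom is None:
            raise ValueError("chrom required with a prebuilt index")
    else:
        index = _CgiIndex(cgi_track)
        if chrom is None:
            chroms = set(index.by_chrom)
            if len(chroms) != 1:
                raise ValueError("chrom required for a multi-chromosome track")
            chrom = chroms.pop()
    d = index.distance(chrom, position)
    if d == 0:
        return "island"
    if d <= SHORE_BP:
        return "shore"
    if d <= SHELF_BP:
        return "shelf"
    return "opensea"


def promoter_window(gene: GeneModel, params: AnnotationParams = AnnotationParams()) -> GenomicInterval:
    """Strand-aware [TSS - up, TSS + down) window (mirrored on the minus strand)."""
    tss = gene.tss
    if gene.interval.strand == "-":
        start, end = tss - params.promoter_down + 1, tss + params.promoter_up + 1
    else:
        start, end = tss - params.promoter_up, tss + params.promoter_down
    return GenomicInterval(gene.interval.chrom, max(0, start), end, gene.interval.strand,
                           gene.gene_id)


def _genic_labels_at(position: int, chrom: str, genes: Sequence[GeneModel],
                     params: AnnotationParams) -> set[str]:
    labels: set[str] = set()
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        prom = promoter_window(g, params)
        in_prom = prom.start <= position < prom.end
        in_gene = g.interval.start <= position < g.interval.end
        if in_prom:
            labels.add("promoter")
        elif in_gene:
            labels.add("genebody")
    if not labels:
        labels.add("intergenic")
    return labels


def classify_genic_context(
    interval: GenomicInterval,
    gene_track: Sequence[GeneModel],
    promoter_up: int = 1500,
    promoter_down: int = 500,
) -> set[str]:
    """All genic labels an interval overlaps (promoter/genebody/intergenic)."""
    params = AnnotationParams(promoter_up, promoter_down)
    labels: set[str] = set()
    for g in gene_track:
        if g.interval.chrom != interval.chrom:
            continue
        prom = promoter_window(g, params)
        if interval.start < prom.end and prom.start < interval.end:
            labels.add("promoter")
        # gene body = gene span minus promoter
        for bs, be in _subtract(g.interval.start, g.interval.end, prom.start, prom.end):
            if interval.start < be and bs < interval.end:
                labels.add("genebody")
    if not labels:
        labels.add("intergenic")
    return labels


def _subtract(a0: int, a1: int, b0: int, b1: int) -> list[tuple[int, int]]:
    """Interval set [a0,a1) minus [b0,b1)."""
    out = []
    if a0 < min(a1, b0):
        out.append((a0, min(a1, b0)))
    if max(a0, b1) < a1:
        out.append((max(a0, b1), a1))
    return out


def nearest_tss(interval: GenomicInterval, genes: Sequence[GeneModel]) -> tuple[str, int]:
    """Nearest gene by |TSS - DMR midpoint|; ties go to the smaller gene id.

    The returned distance is signed and strand-aware: positive means the DMR
    midpoint lies downstream of the TSS in the gene's reading direction.
    """
    mid = interval.midpoint
    best: tuple[float, str, int] | None = None
    for g in genes:
        if g.interval.chrom != interval.chrom:
            continue
        d = mid - g.tss
        if g.interval.strand == "-":
            d = -d
        key = (abs(d), g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), g.gene_id, int(round(d)))
    if best is None:
        return ("", 0)
    return best[1], best[2]


def annotate_dmrs(
    dmrs: Sequence[DMR],
    cgi_track: Sequence[GenomicInterval],
    gene_track: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
    member_positions: Sequence[Sequence[int]] | None = None,
) -> list[FeatureAnnotation]:
    """Per-DMR feature pairs, formed per member CpG position.

    Each member position contributes (genic label at position, CGI label at
    position) pairs; a DMR spanning a promoter island into a gene-body shore
    therefore gets {(promoter, island), (genebody, shore)} rather than a
    full cross product. When ``member_positions`` is not given, positions are
    sampled every 50 bp across the DMR interval (endpoints included).
    """
    index = _CgiIndex(cgi_track)
    out = []
    for i, d in enumerate(dmrs):
        iv = d.interval
        if member_positions is not None:
            positions = list(member_positions[i])
        else:
            positions = list(range(iv.start, iv.end, 50)) + [iv.end - 1]
        pairs: set[tuple[str, str]] = set()
        for p in positions:
            cgi = classify_cgi_context(p, index, chrom=iv.chrom)
            for genic in _genic_labels_at(p, iv.chrom, gene_track, params):
                pairs.add((genic, cgi))
        gene_id, dist = nearest_tss(iv, gene_track)
        out.append(
            FeatureAnnotation(
                dmr_id=iv.name or f"dmr_{iv.chrom}_{iv.start}",
                direction=d.direction,
                features=frozenset(pairs),
                nearest_gene=gene_id,
                tss_distance=dist,
            )
        )
    return out


def summarize_features(annotations: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    """Fraction of DMRs per direction carrying each genic and each CGI label.

    A DMR counts once per label it carries, so fractions can sum past 1
    across labels within a direction.
    """
    rows = []
    for direction in ("hyper", "hypo"):
        anns = [a for a in annotations if a.direction == direction]
        n = len(anns)
        for label in GENIC_LABELS:
            k = sum(1 for a in anns if any(g == label for g, _ in a.features))
            rows.append((direction, "genic", label, n, k / n if n else np.nan))
        for label in CGI_LABELS:
            k = sum(1 for a in anns if any(c == label for _, c in a.features))
            rows.append((direction, "cgi", label, n, k / n if n else np.nan))
    return pd.DataFrame(rows, columns=["direction", "axis", "label", "n_dmrs", "fraction"])


def annotations_to_frame(annotations: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    """Flat TSV-ready view: one row per DMR with semicolon-joined labels."""
    rows = []
    for a in annotations:
        labels = ";".join(f"{g}:{c}" for g, c in sorted(a.features))
        rows.append((a.dmr_id, a.direction, labels, a.nearest_gene, a.tss_distance))
    return pd.DataFrame(
        rows, columns=["dmr_id", "direction", "labels", "nearest_gene", "tss_distance"]
    )
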