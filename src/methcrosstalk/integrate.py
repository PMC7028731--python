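"""Methylation-expression concordance integration.

External differential tables (per-gene logFC from several expression and
methylation cohorts) are thresholded into gene calls, combined with the
current experiment's differentially methylated genes, and reduced to the
set of robust genes whose methylation and expression change in the
functionally concordant directions (hypermethylated/down-regulated or
hypomethylated/up-regulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotate import FeatureAnnotation
from .dmr import DMR
from .meth_io import LogFCTable

__all__ = [
    "ThresholdParams",
    "GeneCall",
    "ConcordantGene",
    "threshold_calls",
    "concordance_class",
    "current_dmg_calls",
    "select_robust_genes",
    "crosstab_classes",
]

KLASSES = ("hyper_down", "hyper_up", "hypo_down", "hypo_up")
FUNCTIONAL_KLASSES = ("hyper_down", "hypo_up")


@dataclass(frozen=True)
class ThresholdParams:
    """Differential cut-offs: expression |FC| > 2, methylation |delta| > 0.1.

    ``expr_cut_scale`` decides whether the expression cut of 2 applies to the
    linear fold change (|logFC| > 1, the default) or directly to the logFC.
    """

    expr_fc: float = 2.0
    meth_delta: float = 0.1
    max_p: float = 0.05
    max_adj_p: float = 0.05
    expr_cut_scale: str = "linear"  # linear | log2

    @property
    def expr_logfc_cut(self) -> float:
        import math

        return math.log2(self.expr_fc) if self.expr_cut_scale == "linear" else self.expr_fc


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    source: str          # dataset id or "current"
    kind: str            # expression | methylation
    logfc: float
    status: str          # up/down or hyper/hypo
    passes: bool

    def __post_init__(self) -> None:
        pos = {"up", "hyper"}
        if self.logfc > 0 and self.status not in pos:
            raise ValueError("status sign must agree with logfc sign")
        if self.logfc < 0 and self.status in pos:
            raise ValueError("status sign must agree with logfc sign")


@dataclass(frozen=True)
class ConcordantGene:
    gene_id: str
    klass: str
    support: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.klass not in KLASSES:
            raise ValueError(f"unknown concordance class {self.klass!r}")


def threshold_calls(
    table: LogFCTable,
    p_values: Mapping[str, float] | None = None,
    adj_p_values: Mapping[str, float] | None = None,
    params: ThresholdParams = ThresholdParams(),
) -> list[GeneCall]:
    """Turn one logFC table into per-gene calls with strict magnitude cuts."""
    cut = params.expr_logfc_cut if table.kind == "expression" else params.meth_delta
    out = []
    for gene, lfc in sorted(table.rows.items()):
        if table.kind == "expression":
            status = "up" if lfc > 0 else "down"
        else:
            status = "hyper" if lfc > 0 else "hypo"
        ok = abs(lfc) > cut
        if p_values is not None:
            ok = ok and p_values.get(gene, 1.0) < params.max_p
        if adj_p_values is not None:
            ok = ok and adj_p_values.get(gene, 1.0) < params.max_adj_p
        out.append(GeneCall(gene, table.dataset_id, table.kind, float(lfc), status, bool(ok)))
    return out


def concordance_class(meth_status: str, expr_status: str) -> str:
    """Total map of {hyper,hypo} x {up,down} onto the four concordance classes."""
    if meth_status not in ("hyper", "hypo"):
        raise ValueError(f"meth_status must be hyper or hypo, got {meth_status!r}")
    if expr_status not in ("up", "down"):
        raise ValueError(f"expr_status must be up or down, got {expr_status!r}")
    return f"{meth_status}_{expr_status}"


def current_dmg_calls(
    dmrs: Sequence[DMR],
    annotations: Sequence[FeatureAnnotation],
    gene_promoter_body_map: Mapping[str, Iterable[str]] | None = None,
) -> list[GeneCall]:
    """Genes carrying a called DMR over their promoter or gene body.

    By default a DMR maps to its nearest-TSS gene when it touches a promoter
    or gene-body feature; an explicit dmr_id -> gene_ids mapping overrides.
    """
    by_gene: dict[str, list[tuple[DMR, FeatureAnnotation]]] = {}
    ann_by_id = {a.dmr_id: a for a in annotations}
    for d in dmrs:
        did = d.interval.name or f"dmr_{d.interval.chrom}_{d.interval.start}"
        a = ann_by_id.get(did)
        if a is None:
            continue
        if gene_promoter_body_map is not None:
            genes = list(gene_promoter_body_map.get(did, []))
        else:
            genic = {g for g, _ in a.features}
            genes = [a.nearest_gene] if genic & {"promoter", "genebody"} and a.nearest_gene else []
        for g in genes:
            by_gene.setdefault(g, []).append((d, a))
    out = []
    for gene in sorted(by_gene):
        dmr, _ = max(by_gene[gene], key=lambda t: t[0].fds)
        sign = 1.0 if dmr.direction == "hyper" else -1.0
        out.append(
            GeneCall(gene, "current", "methylation", sign * dmr.fds, dmr.direction, True)
        )
    return out


def _supported_status(
    gene: str,
    tables: Sequence[LogFCTable],
    params: ThresholdParams,
    min_support: int,
) -> tuple[str | None, tuple[str, ...]]:
    """Direction a gene supports in >= min_support tables, or None.

    Passing tables must agree on one direction; any sign conflict among
    passing tables voids the gene.
    """
    statuses: dict[str, list[str]] = {}
    for t in tables:
        if gene not in t.rows:
            continue
        call = [c for c in threshold_calls(t, params=params) if c.gene_id == gene][0]
        if call.passes:
            statuses.setdefault(call.status, []).append(t.dataset_id)
    if len(statuses) != 1:
        return None, ()
    status, datasets = next(iter(statuses.items()))
    if len(datasets) < min_support:
        return None, ()
    return status, tuple(datasets)


def select_robust_genes(
    current_dmgs: Sequence[GeneCall],
    expr_tables: Sequence[LogFCTable],
    meth_tables: Sequence[LogFCTable],
    min_expr_support: int | None = None,
    min_meth_support: int | None = None,
    params: ThresholdParams = ThresholdParams(),
    functional_only: bool = True,
) -> list[ConcordantGene]:
    """Intersect current DMGs with consistently supported external calls.

    A gene is robust iff (a) it is a current-experiment DMG, (b) it passes
    the expression threshold with one consistent direction in at least
    ``min_expr_support`` expression tables, (c) it passes the methylation
    threshold with direction matching the current call in at least
    ``min_meth_support`` methylation tables, and (d) its concordance class is
    functional (hyper_down or hypo_up) unless ``functional_only`` is off.
    Support defaults to all provided tables of each kind.
    """
    if not expr_tables or not meth_tables:
        raise ValueError("need at least one expression and one methylation table")
    if min_expr_support is None:
        min_expr_support = len(expr_tables)
    if min_meth_support is None:
        min_meth_support = len(meth_tables)

    out = []
    for call in sorted(current_dmgs, key=lambda c: c.gene_id):
        if not call.passes or call.kind != "methylation":
            continue
        expr_status, expr_support = _supported_status(
            call.gene_id, expr_tables, params, min_expr_support
        )
        if expr_status is None:
            continue
        meth_status, meth_support = _supported_status(
            call.gene_id, meth_tables, params, min_meth_support
        )
        if meth_status is None or meth_status != call.status:
            continue
        klass = concordance_class(call.status, expr_status)
        if functional_only and klass not in FUNCTIONAL_KLASSES:
            continue
        out.append(ConcordantGene(call.gene_id, klass, expr_support + meth_support))
    return out


def crosstab_classes(common_degs: Iterable[ConcordantGene]) -> dict[str, int]:
    """Counts per concordance class plus their total."""
    counts = {k: 0 for k in KLASSES}
    for g in common_degs:
        counts[g.klass] += 1
    counts["total"] = sum(counts[k] for k in KLASSES)
    return counts
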