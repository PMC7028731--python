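"""Synthetic bisulfite cohorts, genome tracks, external logFC tables and Cq panels.

The generative model for methylation counts is a logit-normal/beta-binomial
hierarchy: each CpG has a context baseline beta (island 0.08, shore 0.35,
shelf 0.60, open sea 0.75); planted hyper DMRs shift the logit of case-sample
betas up by ``delta_logit`` (hypo: down); per-site-per-sample biological
noise is Normal on the logit scale; read depth is Poisson and methylated
counts are beta-binomial with a precision parameter. Hyper DMRs are planted
in promoter CpG islands and hypo DMRs in open-sea gene bodies, so that the
annotated feature distributions of called DMRs mirror what is seen in
colorectal tumours (hypermethylation concentrated in islands, hypomethylation
in open sea).

The Cq panel model maps a methylated-template quantity q to
Cq = C0 - log2(q) + Normal(0, sd); plasma case templates are diluted by a
single tumour-fraction scalar. Every generator is a pure function of its
config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .meth_io import (
    CqPanel,
    GeneModel,
    GenomicInterval,
    MethCohort,
    SampleMeta,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlantedDmr",
    "generate_genome_tracks",
    "generate_methylation_cohort",
    "generate_expression_cohort",
    "generate_external_datasets",
    "generate_cq_panels",
]

# context baselines chosen so hyper DMRs arise naturally in islands/shores
# and hypo DMRs in open sea
BASELINE_BETA = {"island": 0.08, "shore": 0.35, "shelf": 0.60, "opensea": 0.75}

_STAGE = {"tracks": 11, "cohort": 23, "expression": 37, "external": 53, "cq": 71}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_case: int = 6
    n_ctrl: int = 6
    n_genes: int = 200
    chrom_length: int = 4_000_000
    mean_coverage: float = 20.0
    n_hyper_dmr: int = 30
    n_hypo_dmr: int = 20
    # biomarker-grade subset of the hyper DMRs: near-unmethylated in normal
    # tissue with a deep tumour shift, the regime MethyLight markers live in
    n_marker_dmr: int = 5
    marker_beta_ctrl: float = 0.004
    marker_delta_logit: float = 5.0
    delta_logit: float = 2.5
    sample_sd: float = 0.2
    dispersion: float = 50.0
    frac_concordant: float = 0.6
    external_noise_sd: float = 0.05
    dropout: float = 0.0
    tumor_fraction: float = 0.05
    # track geometry
    gene_length: int = 8000
    island_halfwidth: int = 500       # islands are 1 kb, centred on the TSS
    cgi_fraction: float = 0.6
    island_cpg_spacing: int = 10
    background_cpg_spacing: int = 100
    # qPCR model
    cq_c0: float = 38.0
    cq_noise_sd: float = 0.3
    cq_detection_floor: float = 1.0   # template copies below this never amplify
    cq_reference_mean: float = 25.0
    tissue_copies: float = 1000.0
    plasma_copies: float = 200.0
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_ctrl", "n_genes", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.tumor_fraction <= 1):
            raise ValueError("tumor_fraction must lie in (0, 1]")
        if not (0 <= self.frac_concordant <= 1):
            raise ValueError("frac_concordant must lie in [0, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])


@dataclass(frozen=True)
class PlantedDmr:
    interval: GenomicInterval
    direction: str            # hyper | hypo
    gene_id: str
    true_delta_beta: float    # signed realized mean-beta shift
    marker_grade: bool = False  # near-zero control methylation, deep shift


@dataclass
class SimTruth:
    planted_dmrs: list[PlantedDmr]
    concordant_genes: dict[str, str]       # gene_id -> hyper_down | hypo_up
    discordant_genes: list[str]
    expr_logfc: dict[str, float]           # true per-gene expression log2 FC
    meth_effect: dict[str, float]          # true per-gene methylation delta-beta

    @property
    def planted_by_gene(self) -> dict[str, PlantedDmr]:
        return {p.gene_id: p for p in self.planted_dmrs}


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def generate_genome_tracks(config: SimConfig) -> tuple[list[GenomicInterval], list[GeneModel]]:
    """Evenly spaced gene models on one chromosome with CGIs at ~60% of TSSs."""
    spacing = config.chrom_length // config.n_genes
    if spacing < 20_000:
        raise ValueError(
            f"overcrowded genome: {config.n_genes} genes need >= {config.n_genes * 20_000} bp, "
            f"got {config.chrom_length}"
        )
    rng = config.rng("tracks")
    chrom = "chr1"
    genes: list[GeneModel] = []
    islands: list[GenomicInterval] = []
    has_cgi = rng.random(config.n_genes) < config.cgi_fraction
    for i in range(config.n_genes):
        start = i * spacing + 6000
        strand = "+" if i % 2 == 0 else "-"
        iv = GenomicInterval(chrom, start, start + config.gene_length, strand, f"G{i:04d}")
        g = GeneModel(iv, f"G{i:04d}")
        genes.append(g)
        if has_cgi[i]:
            islands.append(
                GenomicInterval(
                    chrom,
                    g.tss - config.island_halfwidth,
                    g.tss + config.island_halfwidth,
                    ".",
                    f"CGI_{i:04d}",
                )
            )
    islands.sort(key=lambda x: (x.chrom, x.start))
    return islands, genes


def _cpg_positions(config: SimConfig, islands: list[GenomicInterval]) -> np.ndarray:
    pos = set(range(0, config.chrom_length, config.background_cpg_spacing))
    for iv in islands:
        pos.update(range(iv.start, iv.end, config.island_cpg_spacing))
    return np.array(sorted(pos), dtype=np.int64)


def _cgi_distance(positions: np.ndarray, islands: list[GenomicInterval]) -> np.ndarray:
    """bp to the nearest island boundary, 0 inside an island (vectorized)."""
    if not islands:
        return np.full(len(positions), np.inf)
    starts = np.array([iv.start for iv in islands])
    ends = np.array([iv.end for iv in islands])
    j = np.searchsorted(starts, positions, side="right") - 1
    dist = np.full(len(positions), np.inf)
    valid = j >= 0
    jj = np.clip(j, 0, None)
    inside = valid & (positions < ends[jj])
    dist[inside] = 0.0
    left = valid & ~inside
    dist[left] = positions[left] - (ends[jj[left]] - 1)
    nxt = j + 1
    has_next = nxt < len(starts)
    cand = np.where(has_next, starts[np.clip(nxt, 0, len(starts) - 1)] - positions, np.inf)
    return np.minimum(dist, np.where(cand > 0, cand, np.inf))


def _context_labels(positions: np.ndarray, islands: list[GenomicInterval]) -> np.ndarray:
    d = _cgi_distance(positions, islands)
    out = np.full(len(positions), "opensea", dtype=object)
    out[d <= 4000] = "shelf"
    out[d <= 2000] = "shore"
    out[d == 0] = "island"
    return out


# ---------------------------------------------------------------------------
# methylation cohort
# ---------------------------------------------------------------------------

def _plant_regions(config: SimConfig, genes: list[GeneModel],
                   islands: list[GenomicInterval],
                   rng: np.random.Generator) -> list[tuple[GeneModel, str]]:
    """Pick genes for hyper (promoter-island) and hypo (open-sea body) DMRs."""
    cgi_gene_ids = {iv.name.replace("CGI_", "G") for iv in islands}
    with_cgi = [g for g in genes if g.gene_id in cgi_gene_ids]
    without = [g for g in genes if g.gene_id not in cgi_gene_ids]
    if len(with_cgi) < config.n_hyper_dmr:
        raise ValueError("not enough CGI genes for the requested hyper DMRs")
    hyper = [with_cgi[i] for i in rng.choice(len(with_cgi), config.n_hyper_dmr, replace=False)]
    pool = [g for g in genes if g not in hyper]
    if len(pool) < config.n_hypo_dmr:
        raise ValueError("not enough genes for the requested hypo DMRs")
    hypo = [pool[i] for i in rng.choice(len(pool), config.n_hypo_dmr, replace=False)]
    return [(g, "hyper") for g in hyper] + [(g, "hypo") for g in hypo]


def _region_interval(gene: GeneModel, direction: str, config: SimConfig) -> GenomicInterval:
    """Planted footprint: hyper inside the promoter island, hypo in open-sea body."""
    tss = gene.tss
    sgn = 1 if gene.interval.strand != "-" else -1
    if direction == "hyper":
        lo, hi = tss - 400 * 1, tss + 400
    else:
        # 4.6-5.4 kb downstream of the TSS: inside the gene body, > 4 kb from
        # any island boundary, hence open sea
        a, b = tss + sgn * 4600, tss + sgn * 5400
        lo, hi = min(a, b), max(a, b)
    return GenomicInterval(gene.interval.chrom, lo, hi + 1)


def generate_methylation_cohort(
    config: SimConfig,
    tracks: tuple[list[GenomicInterval], list[GeneModel]] | None = None,
) -> tuple[MethCohort, SimTruth]:
    """Simulate per-CpG counts for the case/control design plus ground truth."""
    if tracks is None:
        tracks = generate_genome_tracks(config)
    islands, genes = tracks
    rng = config.rng("cohort")

    positions = _cpg_positions(config, islands)
    context = _context_labels(positions, islands)
    beta0 = np.array([BASELINE_BETA[c] for c in context])

    planted = _plant_regions(config, genes, islands, rng)
    if config.n_marker_dmr > config.n_hyper_dmr:
        raise ValueError("n_marker_dmr cannot exceed n_hyper_dmr")
    effect = np.zeros(len(positions))
    planted_dmrs: list[PlantedDmr] = []
    n_marker_left = config.n_marker_dmr
    for gene, direction in planted:
        iv = _region_interval(gene, direction, config)
        mask = (positions >= iv.start) & (positions < iv.end)
        marker = direction == "hyper" and n_marker_left > 0
        if marker:
            # marker-grade region: controls nearly unmethylated, deep shift;
            # delta_logit == 0 stands for the global null and silences it too
            beta0[mask] = config.marker_beta_ctrl
            shift = config.marker_delta_logit if config.delta_logit != 0 else 0.0
            n_marker_left -= 1
        else:
            shift = config.delta_logit if direction == "hyper" else -config.delta_logit
        effect[mask] = shift
        b0 = float(np.mean(beta0[mask])) if mask.any() else BASELINE_BETA["island"]
        true_db = float(expit(logit(b0) + shift) - b0)
        planted_dmrs.append(PlantedDmr(iv, direction, gene.gene_id, true_db, marker))

    n_samples = config.n_case + config.n_ctrl
    is_case = np.array([1.0] * config.n_case + [0.0] * config.n_ctrl)
    S = len(positions)

    lp = logit(beta0)[:, None] + effect[:, None] * is_case[None, :]
    lp = lp + rng.normal(0.0, config.sample_sd, size=(S, n_samples))
    p = expit(lp)
    depth = rng.poisson(config.mean_coverage, size=(S, n_samples))
    a = p * config.dispersion
    b = (1.0 - p) * config.dispersion
    pp = rng.beta(a, b)
    meth = rng.binomial(depth, pp).astype(float)
    total = depth.astype(float)

    samples = [
        SampleMeta(f"T{i + 1:02d}", "case",
                   kras="positive" if i < 3 else "negative",
                   braf="positive" if i == 3 else "negative")
        for i in range(config.n_case)
    ] + [SampleMeta(f"N{i + 1:02d}", "control") for i in range(config.n_ctrl)]

    sites = pd.DataFrame({"chrom": "chr1", "pos": positions})
    cohort = MethCohort(sites, meth, total, samples)

    truth = _assign_expression_truth(config, planted_dmrs, genes)
    return cohort, truth


def _assign_expression_truth(config: SimConfig, planted_dmrs: list[PlantedDmr],
                             genes: list[GeneModel]) -> SimTruth:
    rng = config.rng("expression")
    concordant: dict[str, str] = {}
    discordant: list[str] = []
    expr_logfc = {g.gene_id: 0.0 for g in genes}
    meth_effect = {g.gene_id: 0.0 for g in genes}

    n_planted = len(planted_dmrs)
    n_conc = int(round(config.frac_concordant * n_planted))
    # marker-grade genes are concordant by construction (the MDM is drawn
    # from the hypermethylated/down-regulated robust genes); the rest of the
    # concordant quota is drawn at random
    conc_set = {p.gene_id for p in planted_dmrs if p.marker_grade}
    order = rng.permutation(n_planted)
    for i in order:
        if len(conc_set) >= n_conc:
            break
        conc_set.add(planted_dmrs[i].gene_id)

    for k, p in enumerate(planted_dmrs):
        meth_effect[p.gene_id] = p.true_delta_beta
        magnitude = 2.0 + rng.uniform(0.0, 1.0)
        concordant_sign = -1.0 if p.direction == "hyper" else 1.0
        if p.gene_id in conc_set:
            expr_logfc[p.gene_id] = concordant_sign * magnitude
            concordant[p.gene_id] = "hyper_down" if p.direction == "hyper" else "hypo_up"
        else:
            discordant.append(p.gene_id)
            if k % 2 == 0:  # sign-violating effect
                expr_logfc[p.gene_id] = -concordant_sign * magnitude
            else:           # sub-threshold effect
                expr_logfc[p.gene_id] = float(rng.uniform(-0.8, 0.8))
    return SimTruth(planted_dmrs, concordant, sorted(discordant), expr_logfc, meth_effect)


# ---------------------------------------------------------------------------
# expression cohort and external datasets
# ---------------------------------------------------------------------------

def generate_expression_cohort(
    config: SimConfig, truth: SimTruth, within_sd: float = 0.3
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample log2 expression table plus the realized cohort logFC.

    Baseline log2 expression is Normal(8, 1.5) per gene; case samples add the
    gene's true logFC; per-sample noise is Normal(0, within_sd).
    """
    rng = config.rng("expression").spawn(1)[0]
    genes = sorted(truth.expr_logfc)
    n = config.n_case + config.n_ctrl
    baseline = rng.normal(8.0, 1.5, size=len(genes))
    lfc = np.array([truth.expr_logfc[g] for g in genes])
    is_case = np.array([1.0] * config.n_case + [0.0] * config.n_ctrl)
    expr = (
        baseline[:, None]
        + lfc[:, None] * is_case[None, :]
        + rng.normal(0.0, within_sd, size=(len(genes), n))
    )
    cols = [f"T{i + 1:02d}" for i in range(config.n_case)] + [
        f"N{i + 1:02d}" for i in range(config.n_ctrl)
    ]
    table = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=cols)
    realized = table.iloc[:, : config.n_case].mean(axis=1) - table.iloc[:, config.n_case :].mean(axis=1)
    return table, realized.rename("logfc")


def generate_external_datasets(
    config: SimConfig,
    truth: SimTruth,
    n_expr: int = 4,
    n_meth: int = 4,
) -> tuple[list["LogFCTable"], list["LogFCTable"]]:
    """External-cohort replicate tables: true effect + dataset noise, with dropout.

    Expression tables carry log2 fold changes; methylation tables carry
    delta-beta-scale effects, as GEO methylation-array comparisons report.
    """
    from .meth_io import LogFCTable

    rng = config.rng("external")
    genes = sorted(truth.expr_logfc)
    expr_truth = np.array([truth.expr_logfc[g] for g in genes])
    meth_truth = np.array([truth.meth_effect[g] for g in genes])

    def make(kind: str, base: np.ndarray, i: int) -> LogFCTable:
        vals = base + rng.normal(0.0, config.external_noise_sd, size=len(genes))
        keep = rng.random(len(genes)) >= config.dropout
        rows = {g: float(v) for g, v, k in zip(genes, vals, keep) if k}
        prefix = "EXPR" if kind == "expression" else "METH"
        return LogFCTable(f"{prefix}_DS{i + 1}", kind, rows)

    expr_tables = [make("expression", expr_truth, i) for i in range(n_expr)]
    meth_tables = [make("methylation", meth_truth, i) for i in range(n_meth)]
    return expr_tables, meth_tables


# ---------------------------------------------------------------------------
# Cq panels
# ---------------------------------------------------------------------------

def generate_cq_panels(
    config: SimConfig,
    context: Literal["tissue", "plasma"],
    m_case: float = 0.40,
    m_ctrl: float = 0.005,
    n_case: int | None = None,
    n_ctrl: int | None = None,
) -> CqPanel:
    """Simulate a MethyLight panel for the designated marker region.

    Tissue template quantity is proportional to the group methylation
    fraction; plasma case templates follow the dilution
    tumor_fraction * m_case + (1 - tumor_fraction) * m_ctrl. Quantities below
    the detection floor, or cycles past ``max_cycles``, come out undetermined
    (stored as the max_cycles sentinel).
    """
    if context not in ("tissue", "plasma"):
        raise ValueError("context must be tissue or plasma")
    rng = config.rng("cq").spawn(2)[0 if context == "tissue" else 1]
    if context == "tissue":
        n_case = 39 if n_case is None else n_case
        n_ctrl = 47 if n_ctrl is None else n_ctrl
        copies = config.tissue_copies
        q_case = copies * m_case
        q_ctrl = copies * m_ctrl
    else:
        n_case = 22 if n_case is None else n_case
        n_ctrl = 20 if n_ctrl is None else n_ctrl
        copies = config.plasma_copies
        tf = config.tumor_fraction
        q_case = copies * (tf * m_case + (1 - tf) * m_ctrl)
        q_ctrl = copies * m_ctrl

    rows = []
    for group, n, q in (("case", n_case, q_case), ("control", n_ctrl, q_ctrl)):
        for i in range(n):
            if q < config.cq_detection_floor:
                cq = config.max_cycles
            else:
                cq = config.cq_c0 - np.log2(q) + rng.normal(0.0, config.cq_noise_sd)
                cq = float(min(cq, config.max_cycles))
            ref = float(
                np.clip(rng.normal(config.cq_reference_mean, config.cq_noise_sd),
                        1e-3, config.max_cycles)
            )
            prefix = "P" if context == "plasma" else "F"
            gid = "C" if group == "case" else "N"
            rows.append((f"{prefix}{gid}{i + 1:02d}", group, float(min(cq, config.max_cycles)), ref))
    records = pd.DataFrame(rows, columns=["sample_id", "group", "cq_target", "cq_reference"])
    return CqPanel(records, max_cycles=config.max_cycles)
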