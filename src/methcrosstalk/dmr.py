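"""Differentially methylated region calling from bisulfite count cohorts.

The caller works in four stages: (1) form candidate regions as maximal runs
of consecutive CpGs whose case-minus-control mean beta difference shares one
sign and clears a per-site magnitude floor; (2) score each candidate with a
two-sided Fisher exact test on group-pooled read counts; (3) adjust p-values
across candidates with Benjamini-Hochberg; (4) screen survivors with a
group-label permutation test on the region's pooled |Δβ|. Reported regions
must span more than 200 bp (strict), with p < 0.05, FDR q < 0.05 and
permutation type-I estimate < 0.01, and carry a fold difference score
|log2((β_case+ε)/(β_ctrl+ε))| whose theoretical maximum at ε = 0.01 is
log2(101) ≈ 6.66.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, log2
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .meth_io import GenomicInterval, MethCohort

__all__ = [
    "DmrParams",
    "CandidateRegion",
    "DMR",
    "compute_beta",
    "fold_difference_score",
    "form_candidate_regions",
    "test_region",
    "adjust_fdr",
    "permutation_screen",
    "permutation_null_max_stats",
    "region_delta_stat",
    "call_dmrs",
]


@dataclass(frozen=True)
class DmrParams:
    """Tunable thresholds of the caller; defaults give the published filter set."""

    min_site_delta: float = 0.1   # per-site |Δβ| floor for run membership
    max_gap: int = 300            # bp; larger inter-CpG distance breaks a run
    min_cpgs: int = 5             # minimum member CpGs per candidate
    min_length: int = 200         # bp; retained DMRs must span MORE than this
    max_p: float = 0.05
    max_q: float = 0.05
    max_perm_p: float = 0.01
    epsilon: float = 0.01         # FDS pseudo-fraction
    n_perm: int = 200
    exact_perm_limit: int = 1000  # enumerate label splits exactly up to this count
    seed: int = 0


@dataclass(frozen=True)
class CandidateRegion:
    interval: GenomicInterval
    site_index: tuple[int, ...]   # row indices into the cohort's site table
    direction: str                # hyper | hypo


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    direction: str
    n_cpgs: int
    beta_case: float
    beta_ctrl: float
    fds: float
    p_value: float
    q_value: float
    perm_p: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.beta_case <= 1.0 and 0.0 <= self.beta_ctrl <= 1.0
        assert self.fds >= 0.0
        assert 0.0 <= self.q_value <= 1.0
        expected = "hyper" if self.beta_case > self.beta_ctrl else "hypo"
        assert self.direction == expected, "direction must follow the beta ordering"


def compute_beta(count_meth: int, count_unmeth: int) -> float:
    """Methylation fraction methylated/(methylated+unmethylated)."""
    total = count_meth + count_unmeth
    if total <= 0:
        raise ValueError("beta undefined for zero total coverage")
    return count_meth / total


def fold_difference_score(beta_case: float, beta_ctrl: float, epsilon: float = 0.01) -> float:
    """|log2((β_case+ε)/(β_ctrl+ε))|; bounded by log2((1+ε)/ε)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not (0 <= beta_case <= 1 and 0 <= beta_ctrl <= 1):
        raise ValueError("betas must lie in [0, 1]")
    return abs(log2((beta_case + epsilon) / (beta_ctrl + epsilon)))


def fds_max(epsilon: float = 0.01) -> float:
    """Theoretical maximum of the fold difference score at the given ε."""
    return log2((1 + epsilon) / epsilon)


def _group_mean_betas(cohort: MethCohort) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mean of per-sample betas within each group (NaN-skipping)."""
    b = cohort.betas()
    with np.errstate(invalid="ignore"):
        mc = np.nanmean(b[:, cohort.case_index], axis=1)
        mn = np.nanmean(b[:, cohort.control_index], axis=1)
    return mc, mn


def form_candidate_regions(
    cohort: MethCohort,
    min_site_delta: float = 0.1,
    max_gap: int = 300,
    min_cpgs: int = 5,
) -> list[CandidateRegion]:
    """Maximal same-sign runs of per-site Δβ = mean_case - mean_ctrl.

    A run breaks on sign change, on |Δβ| < min_site_delta (the site is
    skipped and ends any open run), on a chromosome change, or when the
    distance to the previous member exceeds ``max_gap``. Δβ exactly 0 is a
    sign mismatch. Runs shorter than ``min_cpgs`` sites are discarded.
    """
    mc, mn = _group_mean_betas(cohort)
    delta = mc - mn
    chroms = cohort.sites["chrom"].to_numpy()
    pos = cohort.sites["pos"].to_numpy()

    out: list[CandidateRegion] = []
    run: list[int] = []
    run_sign = 0

    def flush() -> None:
        nonlocal run, run_sign
        if len(run) >= min_cpgs:
            first, last = run[0], run[-1]
            iv = GenomicInterval(str(chroms[first]), int(pos[first]), int(pos[last]) + 1)
            out.append(
                CandidateRegion(iv, tuple(run), "hyper" if run_sign > 0 else "hypo")
            )
        run, run_sign = [], 0

    for i in range(cohort.n_sites):
        d = delta[i]
        sign = 0 if (np.isnan(d) or abs(d) < min_site_delta or d == 0) else (1 if d > 0 else -1)
        if run:
            broken = (
                sign != run_sign
                or chroms[i] != chroms[run[-1]]
                or pos[i] - pos[run[-1]] > max_gap
            )
            if broken:
                flush()
        if sign != 0:
            if not run:
                run_sign = sign
            run.append(i)
    flush()
    return out


def test_region(region: CandidateRegion, cohort: MethCohort) -> tuple[float, float, float]:
    """Fisher exact p on the 2x2 of group-pooled (meth, unmeth) counts.

    Returns (p, beta_case, beta_ctrl) where the betas are pooled-count ratios.
    """
    idx = np.asarray(region.site_index)
    m, t = cohort.meth[idx], cohort.total[idx]
    ci, ni = cohort.case_index, cohort.control_index
    meth_case = np.nansum(m[:, ci])
    tot_case = np.nansum(t[:, ci])
    meth_ctrl = np.nansum(m[:, ni])
    tot_ctrl = np.nansum(t[:, ni])
    if tot_case == 0 or tot_ctrl == 0:
        raise ValueError("region has no coverage in one group")
    table = np.array(
        [
            [meth_case, tot_case - meth_case],
            [meth_ctrl, tot_ctrl - meth_ctrl],
        ]
    ).round().astype(np.int64)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), float(meth_case / tot_case), float(meth_ctrl / tot_ctrl)


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _label_splits(
    n: int, n_case: int, n_perm: int, seed: int, exact_limit: int
) -> tuple[np.ndarray, bool]:
    """Case-indicator matrix (n_splits, n): exhaustive when feasible, else sampled."""
    if comb(n, n_case) <= exact_limit:
        sets = list(combinations(range(n), n_case))
        mat = np.zeros((len(sets), n), dtype=bool)
        for i, s in enumerate(sets):
            mat[i, list(s)] = True
        return mat, True
    rng = np.random.default_rng(seed)
    mat = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        mat[i, rng.permutation(n)[:n_case]] = True
    return mat, False


def _split_deltas(cohort: MethCohort, splits: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Per-site Δβ (mean case beta - mean control beta) for every label split.

    Returns (n_sites, n_splits); NaN-aware via mask-weighted means.
    """
    b = cohort.betas()
    mask = (~np.isnan(b)).astype(float)
    b0 = np.nan_to_num(b)
    out = np.empty((cohort.n_sites, splits.shape[0]))
    for lo in range(0, splits.shape[0], chunk):
        w_case = splits[lo : lo + chunk].T.astype(float)   # (n, c)
        w_ctrl = 1.0 - w_case
        with np.errstate(invalid="ignore", divide="ignore"):
            mc = (b0 @ w_case) / (mask @ w_case)
            mn = (b0 @ w_ctrl) / (mask @ w_ctrl)
        out[:, lo : lo + chunk] = mc - mn
    return out


def _max_run_stat(
    delta: np.ndarray,
    chroms: np.ndarray,
    pos: np.ndarray,
    min_site_delta: float,
    max_gap: int,
    min_cpgs: int,
) -> float:
    """Largest |mean Δβ| over any same-sign candidate run for one split."""
    best = 0.0
    if len(pos) == 0:
        return best
    gap_break = np.empty(len(pos), dtype=bool)
    gap_break[0] = True
    gap_break[1:] = (pos[1:] - pos[:-1] > max_gap) | (chroms[1:] != chroms[:-1])
    for sign in (1.0, -1.0):
        ok = sign * delta >= min_site_delta
        ok &= ~np.isnan(delta)
        if not ok.any():
            continue
        # block id increments at every run break or non-member site
        boundary = ~ok | gap_break
        block = np.cumsum(boundary)
        idx = np.flatnonzero(ok)
        blk = block[idx]
        # segment means per block among member sites
        uniq, start = np.unique(blk, return_index=True)
        counts = np.diff(np.append(start, len(idx)))
        sums = np.add.reduceat(delta[idx], start)
        good = counts >= min_cpgs
        if good.any():
            best = max(best, float(np.max(np.abs(sums[good] / counts[good]))))
    return best


def region_delta_stat(region: CandidateRegion, cohort: MethCohort) -> float:
    """Observed region statistic: |mean over member CpGs of per-site Δβ|."""
    mc, mn = _group_mean_betas(cohort)
    d = (mc - mn)[np.asarray(region.site_index)]
    return float(abs(np.nanmean(d)))


def permutation_null_max_stats(
    cohort: MethCohort,
    params: "DmrParams" = None,
    n_perm: int = 200,
    seed: int = 0,
    exact_limit: int = 1000,
    min_site_delta: float = 0.1,
    max_gap: int = 300,
    min_cpgs: int = 5,
    exclude_sites: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Genome-wide max candidate-run |Δβ| under every group-label split.

    Returns (max_stats, exact_mode). The statistic mirrors the caller's
    region formation: for each relabelling, the largest |mean Δβ| over any
    maximal same-sign run of >= min_cpgs CpGs is recorded, so a region's
    permutation p-value accounts for the genome-wide search that selected it.

    ``exclude_sites`` (row indices into the cohort's site table) drops the
    given sites from the scan. The caller passes the member sites of the
    candidates under consideration so that real differential signal does not
    contaminate the background null through partially aligned relabellings.
    """
    if params is not None:
        min_site_delta = params.min_site_delta
        max_gap = params.max_gap
        min_cpgs = params.min_cpgs
        n_perm = params.n_perm
        exact_limit = params.exact_perm_limit
    if exclude_sites is not None and len(exclude_sites) > 0:
        keep = np.ones(cohort.n_sites, dtype=bool)
        keep[np.asarray(exclude_sites, dtype=int)] = False
        cohort = cohort.subset_sites(keep)
    n = len(cohort.samples)
    n_case = len(cohort.case_index)
    splits, exact = _label_splits(n, n_case, n_perm, seed, exact_limit)
    deltas = _split_deltas(cohort, splits)
    chroms = cohort.sites["chrom"].to_numpy()
    pos = cohort.sites["pos"].to_numpy()
    stats_ = np.array(
        [
            _max_run_stat(deltas[:, j], chroms, pos, min_site_delta, max_gap, min_cpgs)
            for j in range(splits.shape[0])
        ]
    )
    return stats_, exact


def permutation_screen(
    region: CandidateRegion,
    cohort: MethCohort,
    n_perm: int = 200,
    seed: int = 0,
    exact_limit: int = 1000,
    null_max_stats: tuple[np.ndarray, bool] | None = None,
    min_site_delta: float = 0.1,
    max_gap: int = 300,
    min_cpgs: int = 5,
) -> float:
    """Permutation type-I estimate for one region against the genome-wide null.

    All C(n, n_case) label splits are enumerated when their count is at most
    ``exact_limit`` (924 for the 6-vs-6 design); the estimate is then
    count(max-stat >= |Δβ_obs|) / n_splits, the observed split included.
    Otherwise ``n_perm`` seeded random splits are drawn and the add-one
    estimator (1 + count) / (1 + n_perm) is used. Comparing against the
    genome-wide *maximal* run statistic (rather than the region's own
    relabelled statistic) corrects for the selection of the region as an
    extreme same-sign run in the first place.
    """
    obs = region_delta_stat(region, cohort)
    if null_max_stats is None:
        null_max_stats = permutation_null_max_stats(
            cohort,
            n_perm=n_perm,
            seed=seed,
            exact_limit=exact_limit,
            min_site_delta=min_site_delta,
            max_gap=max_gap,
            min_cpgs=min_cpgs,
        )
    stats_, exact = null_max_stats
    count = int(np.sum(stats_ >= obs - 1e-12))
    if exact:
        return count / len(stats_)
    return (1 + count) / (1 + len(stats_))


def call_dmrs(cohort: MethCohort, params: DmrParams = DmrParams()) -> list[DMR]:
    """Full caller: form -> Fisher test -> BH -> permutation screen -> filter."""
    cands = form_candidate_regions(
        cohort, params.min_site_delta, params.max_gap, params.min_cpgs
    )
    if not cands:
        return []
    tested = [test_region(c, cohort) for c in cands]
    pvals = [p for p, _, _ in tested]
    qvals = adjust_fdr(pvals)

    # regions reaching the permutation stage; their sites are left out of the
    # background scan so true signal cannot inflate the permutation null
    screened = [
        (c, t, q)
        for c, t, q in zip(cands, tested, qvals)
        if c.interval.length > params.min_length and t[0] < params.max_p and q < params.max_q
    ]
    null_stats: tuple[np.ndarray, bool] | None = None
    if screened:
        exclude = np.concatenate([np.asarray(c.site_index) for c, _, _ in screened])
        null_stats = permutation_null_max_stats(
            cohort, params, seed=params.seed, exclude_sites=exclude
        )
    out: list[DMR] = []
    for c, (p, bc, bn), q in screened:
        perm_p = permutation_screen(
            c, cohort, n_perm=params.n_perm, seed=params.seed,
            exact_limit=params.exact_perm_limit, null_max_stats=null_stats,
            min_site_delta=params.min_site_delta, max_gap=params.max_gap,
            min_cpgs=params.min_cpgs,
        )
        if perm_p >= params.max_perm_p:
            continue
        direction = "hyper" if bc > bn else "hypo"
        out.append(
            DMR(
                interval=GenomicInterval(
                    c.interval.chrom, c.interval.start, c.interval.end,
                    name=f"dmr_{c.interval.chrom}_{c.interval.start}",
                ),
                direction=direction,
                n_cpgs=len(c.site_index),
                beta_case=bc,
                beta_ctrl=bn,
                fds=fold_difference_score(bc, bn, params.epsilon),
                p_value=p,
                q_value=float(q),
                perm_p=perm_p,
            )
        )
    out.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return out
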