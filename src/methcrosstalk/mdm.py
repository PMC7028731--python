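"""Methylated-DNA-marker (MDM) scoring and four-criterion selection.

Each candidate region gets per-sample pooled methylation, and from it a
case/control fold change, an absolute methylation difference, a rank-based
AUC with Mann-Whitney p-value, and the control-group mean methylation. The
published selection demands FC > 20, AMD > 0.10, AUC > 0.80 with p < 0.01,
and control methylation < 1% (all strict), describing a marker that is
essentially unmethylated in normal tissue yet strongly methylated in tumours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .meth_io import GenomicInterval, MethCohort

__all__ = [
    "MarkerStats",
    "MdmCriteria",
    "region_sample_betas",
    "compute_marker_stats",
    "select_mdm",
]


@dataclass(frozen=True)
class MarkerStats:
    region_id: str
    fc: float
    amd: float
    auc: float
    p_value: float
    ctrl_meth: float

    def __post_init__(self) -> None:
        assert -1.0 <= self.amd <= 1.0
        assert 0.0 <= self.auc <= 1.0
        assert self.fc >= 0.0


@dataclass(frozen=True)
class MdmCriteria:
    min_fc: float = 20.0
    min_amd: float = 0.10
    min_auc: float = 0.80
    max_p: float = 0.01
    max_ctrl_meth: float = 0.01
    fc_floor: float = 1e-4    # denominator floor: controls can be fully unmethylated
    mirror_hypo: bool = False  # evaluate mirrored criteria for hypo candidates


def region_sample_betas(region: GenomicInterval, cohort: MethCohort) -> np.ndarray:
    """Per-sample pooled beta over the region's member CpGs (NaN if uncovered)."""
    mask = (
        (cohort.sites["chrom"] == region.chrom)
        & (cohort.sites["pos"] >= region.start)
        & (cohort.sites["pos"] < region.end)
    ).to_numpy()
    if not mask.any():
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} covers no CpGs")
    m = np.nansum(cohort.meth[mask], axis=0)
    t = np.nansum(cohort.total[mask], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = m / t
    b[t == 0] = np.nan
    return b


def rank_auc(case: np.ndarray, ctrl: np.ndarray) -> float:
    """U/(n_case*n_ctrl): fraction of (case, control) pairs with case > control, ties half."""
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("empty group")
    u = stats.mannwhitneyu(case, ctrl, alternative="two-sided").statistic
    return float(u) / (case.size * ctrl.size)


def _rank_p(case: np.ndarray, ctrl: np.ndarray) -> float:
    n = case.size + ctrl.size
    ties = len(np.unique(np.concatenate([case, ctrl]))) < n
    method = "exact" if (n <= 12 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method).pvalue)


def compute_marker_stats(
    region: GenomicInterval,
    cohort: MethCohort,
    region_id: str | None = None,
    fc_floor: float = 1e-4,
) -> MarkerStats:
    """FC, AMD, AUC, rank p and control methylation for one candidate region."""
    betas = region_sample_betas(region, cohort)
    case = betas[cohort.case_index]
    ctrl = betas[cohort.control_index]
    case = case[~np.isnan(case)]
    ctrl = ctrl[~np.isnan(ctrl)]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("region has no covered samples in one group")
    mean_case, mean_ctrl = float(np.mean(case)), float(np.mean(ctrl))
    return MarkerStats(
        region_id=region_id or (region.name or f"{region.chrom}:{region.start}-{region.end}"),
        fc=mean_case / max(mean_ctrl, fc_floor),
        amd=mean_case - mean_ctrl,
        auc=rank_auc(case, ctrl),
        p_value=_rank_p(case, ctrl),
        ctrl_meth=mean_ctrl,
    )


def _passes(s: MarkerStats, c: MdmCriteria, mirrored: bool) -> bool:
    if not mirrored:
        return (
            s.fc > c.min_fc
            and abs(s.amd) > c.min_amd
            and s.amd > 0
            and s.auc > c.min_auc
            and s.p_value < c.max_p
            and s.ctrl_meth < c.max_ctrl_meth
        )
    # hypo mirror: deep loss of methylation from a fully methylated control
    fc_inv = (1.0 / s.fc) if s.fc > 0 else np.inf
    return (
        fc_inv > c.min_fc
        and abs(s.amd) > c.min_amd
        and s.amd < 0
        and (1.0 - s.auc) > c.min_auc
        and s.p_value < c.max_p
        and (1.0 - s.ctrl_meth) < c.max_ctrl_meth
    )


def select_mdm(
    stats_list: Sequence[MarkerStats],
    criteria: MdmCriteria = MdmCriteria(),
) -> list[MarkerStats]:
    """Markers passing all four criteria, ranked (AUC desc, FC desc, id asc).

    The first entry of the returned list is the top MDM. With
    ``criteria.mirror_hypo`` set, hypomethylation candidates are screened
    against the mirrored criteria as well.
    """
    passing = [s for s in stats_list if _passes(s, criteria, mirrored=False)]
    if criteria.mirror_hypo:
        passing += [s for s in stats_list if _passes(s, criteria, mirrored=True)]
    passing.sort(key=lambda s: (-s.auc, -s.fc, s.region_id))
    return passing
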