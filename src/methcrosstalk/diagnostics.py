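"""Cq-based diagnostic evaluation of a methylated DNA marker.

Signals are quantification cycles, optionally reference-normalized
(delta Cq = target - reference); in either mode a lower signal means more
methylated template, so a sample is called positive when its signal falls at
or below the decision threshold. Thresholds are picked to maximize
sensitivity subject to a specificity floor, and a threshold frozen on tissue
data can be re-applied unchanged to plasma panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .meth_io import CqPanel

__all__ = [
    "DiagnosticResult",
    "ExpressionResult",
    "normalize_cq",
    "select_threshold_at_specificity",
    "evaluate_diagnostic",
    "relative_expression_ddct",
    "evaluate_plasma",
]


@dataclass(frozen=True)
class DiagnosticResult:
    threshold: float
    sensitivity: float
    specificity: float
    n_case: int
    n_ctrl: int
    t_statistic: float
    p_value: float
    mean_cq_case: float
    mean_cq_ctrl: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.sensitivity <= 1.0
        assert 0.0 <= self.specificity <= 1.0


@dataclass(frozen=True)
class ExpressionResult:
    """Relative expression by 2^-ddCt, reported in both orientations."""

    fold_b_vs_a: float
    fold_a_vs_b: float
    ddct: float

    def __post_init__(self) -> None:
        assert self.fold_b_vs_a > 0 and self.fold_a_vs_b > 0


def normalize_cq(panel: CqPanel, mode: str = "delta") -> np.ndarray:
    """Per-sample signal: raw target Cq, or target minus reference (delta).

    Lower signal means more methylated in both modes. Delta mode refuses
    undetermined reference reactions (the sample cannot be normalized).
    """
    if mode not in ("raw", "delta"):
        raise ValueError("mode must be raw or delta")
    tgt = panel.records["cq_target"].to_numpy(dtype=float)
    if mode == "raw":
        return tgt
    ref = panel.records["cq_reference"].to_numpy(dtype=float)
    bad = ref >= panel.max_cycles
    if bad.any():
        names = panel.records.loc[bad, "sample_id"].tolist()
        raise ValueError(f"undetermined reference Cq in delta mode for samples {names}")
    return tgt - ref


def select_threshold_at_specificity(
    signals: Sequence[float],
    labels: Sequence[str],
    spec_target: float,
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity subject to specificity >= spec_target.

    A sample is positive iff signal <= threshold. Candidates are the
    midpoints between adjacent sorted unique signals plus -inf/+inf
    sentinels; ties in sensitivity resolve toward the smaller (more
    stringent) threshold. Returns (threshold, sensitivity, specificity).
    """
    if spec_target > 1.0:
        raise ValueError("spec_target cannot exceed 1")
    signals = np.asarray(signals, dtype=float)
    labels = np.asarray(labels)
    case = signals[labels == "case"]
    ctrl = signals[labels == "control"]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both classes required")
    uniq = np.unique(signals)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    best = None
    for t in candidates:
        sens = float(np.mean(case <= t))
        spec = float(np.mean(ctrl > t))
        if spec < spec_target:
            continue
        if best is None or sens > best[1] + 1e-12:
            best = (float(t), sens, spec)
    if best is None:  # spec_target attainable at -inf always; defensive
        best = (-np.inf, 0.0, 1.0)
    return best


def evaluate_diagnostic(
    panel: CqPanel,
    threshold: float | None = None,
    spec_target: float | None = None,
    mode: str = "delta",
) -> DiagnosticResult:
    """Sensitivity/specificity at a fixed or specificity-targeted threshold.

    Exactly one of ``threshold`` and ``spec_target`` must be given. The
    Welch two-sample t-test runs on the analysis-scale signals; group mean
    Cqs are reported on the raw cycle scale.
    """
    if (threshold is None) == (spec_target is None):
        raise ValueError("supply exactly one of threshold and spec_target")
    signals = normalize_cq(panel, mode=mode)
    labels = panel.records["group"].to_numpy()
    case = signals[labels == "case"]
    ctrl = signals[labels == "control"]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both classes required")
    if spec_target is not None:
        threshold, _, _ = select_threshold_at_specificity(signals, labels, spec_target)
    sens = float(np.mean(case <= threshold))
    spec = float(np.mean(ctrl > threshold))
    if np.ptp(case) == 0 and np.ptp(ctrl) == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(case, ctrl, equal_var=False)
    raw = panel.records["cq_target"].to_numpy(dtype=float)
    return DiagnosticResult(
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        n_case=int(case.size),
        n_ctrl=int(ctrl.size),
        t_statistic=float(t_stat),
        p_value=float(p),
        mean_cq_case=float(np.mean(raw[labels == "case"])),
        mean_cq_ctrl=float(np.mean(raw[labels == "control"])),
    )


def relative_expression_ddct(panel_group_a: CqPanel, panel_group_b: CqPanel) -> ExpressionResult:
    """2^-ddCt relative expression between two single-group panels.

    dCq per group = mean(target Cq) - mean(reference Cq); ddCq = dCq_A -
    dCq_B; expression of B relative to A is 2^ddCq and of A relative to B is
    2^-ddCq (their product is exactly 1).
    """
    dcq = []
    for panel in (panel_group_a, panel_group_b):
        ref = panel.records["cq_reference"].to_numpy(dtype=float)
        if np.any(ref >= panel.max_cycles):
            raise ValueError("undetermined reference Cq; cannot normalize")
        tgt = panel.records["cq_target"].to_numpy(dtype=float)
        dcq.append(float(np.mean(tgt) - np.mean(ref)))
    ddct = dcq[0] - dcq[1]
    return ExpressionResult(fold_b_vs_a=2.0 ** ddct, fold_a_vs_b=2.0 ** (-ddct), ddct=ddct)


def evaluate_plasma(
    tissue_threshold: float, plasma_panel: CqPanel, mode: str = "delta"
) -> DiagnosticResult:
    """Re-score a plasma panel with the tissue-frozen threshold, unchanged."""
    if len(plasma_panel.records) == 0:
        raise ValueError("empty plasma panel")
    return evaluate_diagnostic(plasma_panel, threshold=tissue_threshold, mode=mode)
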