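"""Per-feature-class classification and methylation clustering.

Feature matrices hold per-sample pooled DMR methylation restricted to one
(genic, CGI) feature class; a linear maximum-margin classifier under
stratified cross-validation measures how well that class separates cases
from controls. Hierarchical clustering of the most variable CpGs (average
linkage on 1 - Pearson correlation) recovers case subgroups, which are then
cross-tabulated against KRAS/BRAF mutation status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .annotate import FeatureAnnotation
from .dmr import DMR
from .mdm import region_sample_betas
from .meth_io import MethCohort

__all__ = [
    "FeatureMatrix",
    "build_feature_matrix",
    "crossval_margin_classifier",
    "train_test_margin_classifier",
    "cluster_and_correlate",
]


@dataclass
class FeatureMatrix:
    values: pd.DataFrame      # rows samples x columns DMR ids
    labels: np.ndarray        # "case"/"control" per row
    feature: tuple[str, str]  # (genic, cgi)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix must be fully imputed")
        if self.values.shape[1] < 1:
            raise ValueError("feature matrix needs at least one column")


def build_feature_matrix(
    dmrs: Sequence[DMR],
    annotations: Sequence[FeatureAnnotation],
    cohort: MethCohort,
    feature: tuple[str, str],
) -> FeatureMatrix:
    """Samples x DMRs matrix of pooled betas for one (genic, cgi) class.

    Sites a sample never covered are imputed with the cross-sample mean of
    that DMR.
    """
    ann_by_id = {a.dmr_id: a for a in annotations}
    cols = {}
    for d in dmrs:
        did = d.interval.name or f"dmr_{d.interval.chrom}_{d.interval.start}"
        a = ann_by_id.get(did)
        if a is None or feature not in a.features:
            continue
        cols[did] = region_sample_betas(d.interval, cohort)
    if not cols:
        raise ValueError(f"no DMR carries the feature {feature}")
    mat = pd.DataFrame(cols, index=cohort.sample_ids)
    mat = mat.fillna(mat.mean(axis=0))
    labels = np.array([s.group for s in cohort.samples])
    return FeatureMatrix(mat, labels, feature)


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    acc = float(np.mean(y_true == y_pred))
    case = y_true == "case"
    ctrl = ~case
    sens = float(np.mean(y_pred[case] == "case")) if case.any() else np.nan
    spec = float(np.mean(y_pred[ctrl] == "control")) if ctrl.any() else np.nan
    return acc, sens, spec


def crossval_margin_classifier(
    matrix: FeatureMatrix, k: int = 10, seed: int = 0
) -> tuple[float, float, float]:
    """Stratified k-fold linear SVM (C=1); metrics averaged over folds.

    Columns are standardized with training-fold statistics only. k is
    reduced (with a warning) to the minority class size when needed.
    """
    X = matrix.values.to_numpy(dtype=float)
    y = matrix.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes required")
    min_class = int(counts.min())
    if k > min_class:
        warnings.warn(f"reducing k from {k} to minority class size {min_class}")
        k = min_class
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, senss, specs = [], [], []
    for train, test in skf.split(X, y):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=1.0)
        clf.fit((X[train] - mu) / sd, y[train])
        pred = clf.predict((X[test] - mu) / sd)
        a, s, p = _fold_metrics(y[test], pred)
        accs.append(a)
        senss.append(s)
        specs.append(p)
    return (
        float(np.mean(accs)),
        float(np.nanmean(senss)),
        float(np.nanmean(specs)),
    )


def train_test_margin_classifier(
    train: FeatureMatrix, test: FeatureMatrix
) -> tuple[float, float, float]:
    """Pre-split variant: fit on one matrix, score on the other."""
    common = [c for c in train.values.columns if c in test.values.columns]
    if not common:
        raise ValueError("train and test matrices share no columns")
    Xtr = train.values[common].to_numpy(dtype=float)
    Xte = test.values[common].to_numpy(dtype=float)
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=1.0)
    clf.fit((Xtr - mu) / sd, train.labels)
    pred = clf.predict((Xte - mu) / sd)
    return _fold_metrics(test.labels, pred)


def _canonical_labels(assign: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance, for input-order invariance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(assign)
    for i, a in enumerate(assign):
        if a not in mapping:
            mapping[a] = len(mapping) + 1
        out[i] = mapping[a]
    return out


def cluster_and_correlate(
    cohort: MethCohort,
    top_n_variable: int | None = None,
    k_clusters: int = 3,
    cluster_group: str | None = "case",
) -> tuple[dict[str, int], pd.DataFrame, pd.DataFrame]:
    """Hierarchical clustering of variable CpGs plus pairwise correlations.

    Selects the ``top_n_variable`` CpGs by cross-sample beta variance (all
    CpGs when None), computes sample-sample Pearson correlations on
    mean-imputed betas, clusters the chosen group (default: cases only, as
    tumour subgrouping) with average linkage on 1 - r cut at ``k_clusters``,
    and cross-tabulates cluster membership against KRAS/BRAF status.
    """
    b = cohort.betas()
    site_mean = np.nanmean(b, axis=1)
    filled = np.where(np.isnan(b), site_mean[:, None], b)
    var = filled.var(axis=1)
    if top_n_variable is not None:
        order = np.argsort(var)[::-1][:top_n_variable]
        filled = filled[np.sort(order)]
    if np.allclose(filled.var(axis=1).sum(), 0):
        raise ValueError("selected CpGs are constant across samples; correlations undefined")

    corr = pd.DataFrame(
        np.corrcoef(filled.T), index=cohort.sample_ids, columns=cohort.sample_ids
    )

    if cluster_group is None:
        idx = np.arange(len(cohort.samples))
    else:
        idx = cohort.group_index(cluster_group)
    names = [cohort.sample_ids[i] for i in idx]
    sub = corr.loc[names, names].to_numpy()
    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    k = min(k_clusters, len(names))
    if len(names) < 2:
        assign = np.ones(len(names), dtype=int)
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        assign = fcluster(Z, t=k, criterion="maxclust")
    assign = _canonical_labels(assign)
    assignment = dict(zip(names, (int(a) for a in assign)))

    meta = {s.sample_id: s for s in cohort.samples}
    rows = []
    for name in names:
        s = meta[name]
        rows.append((name, assignment[name], s.kras, s.braf))
    frame = pd.DataFrame(rows, columns=["sample_id", "cluster", "kras", "braf"])
    crosstab = (
        frame.groupby(["cluster", "kras", "braf"]).size().rename("n").reset_index()
    )
    return assignment, crosstab, corr
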