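"""End-to-end pipeline: simulate -> dmr -> annotate -> integrate -> mdm ->
classify -> diagnose -> plasma, driven by one config with a single seed.

Per-stage seeds derive from the global seed by stable hashing of
(seed, stage name), so toggling one stage never shifts another stage's
randomness. Every output file lands in the run directory and is recorded
with a SHA-256 content hash in the manifest; a rerun with the same config
reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotate as ann_mod
from . import classify as clf_mod
from . import diagnostics as diag_mod
from . import dmr as dmr_mod
from . import integrate as int_mod
from . import mdm as mdm_mod
from . import meth_io, simulate

log = logging.getLogger("methcrosstalk")

STAGES = (
    "simulate", "dmr", "annotate", "integrate",
    "mdm", "classify", "diagnose", "plasma",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    sim: dict[str, Any] = field(default_factory=dict)
    dmr: dict[str, Any] = field(default_factory=dict)
    annotate: dict[str, Any] = field(default_factory=dict)
    integrate: dict[str, Any] = field(default_factory=dict)
    mdm: dict[str, Any] = field(default_factory=dict)
    classify: dict[str, Any] = field(default_factory=dict)
    diagnose: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "stages":
                cfg.stages.update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute enabled stages in dependency order and write a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "files": {}}
    state: dict[str, Any] = {}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = [str(p.relative_to(out)) for p in paths]
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    for stage in STAGES:
        if not config.stages.get(stage, True):
            log.info("stage %s disabled", stage)
            continue
        log.info("running stage %s", stage)
        try:
            paths = _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:  # abort with stage name, keep partial outputs
            _write_manifest(out, manifest)
            raise PipelineError(stage, exc) from exc
        record(stage, *paths)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict[str, Any]) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, out: Path) -> list[Path]:
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
    sc = simulate.SimConfig(**sim_kwargs)
    tracks = simulate.generate_genome_tracks(sc)
    cohort, truth = simulate.generate_methylation_cohort(sc, tracks)
    expr_tables, meth_tables = simulate.generate_external_datasets(sc, truth)
    state.update(sim_config=sc, tracks=tracks, cohort=cohort, truth=truth,
                 expr_tables=expr_tables, meth_tables=meth_tables)

    paths = []
    cgi, genes = tracks
    p = out / "cgi.bed"
    meth_io.write_bed_track(cgi, p)
    paths.append(p)
    p = out / "genes.bed"
    meth_io.write_bed_track([g.interval for g in genes], p)
    paths.append(p)
    for j, s in enumerate(cohort.samples):
        df = pd.DataFrame(
            {
                "chrom": cohort.sites["chrom"],
                "pos": cohort.sites["pos"],
                "count_meth": cohort.meth[:, j].astype(int),
                "count_unmeth": (cohort.total[:, j] - cohort.meth[:, j]).astype(int),
            }
        )
        p = out / f"{s.sample_id}.cov"
        meth_io.write_bismark_cov(df, p)
        paths.append(p)
    p = out / "samples.tsv"
    with open(p, "w") as fh:
        fh.write("sample\tgroup\tkras\tbraf\n")
        for s in cohort.samples:
            fh.write(f"{s.sample_id}\t{s.group}\t{s.kras}\t{s.braf}\n")
    paths.append(p)
    p = out / "logfc_expression.tsv"
    meth_io.write_logfc_tables(expr_tables, p)
    paths.append(p)
    p = out / "logfc_methylation.tsv"
    meth_io.write_logfc_tables(meth_tables, p)
    paths.append(p)
    p = out / "truth.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "planted_dmrs": [
                    {
                        "chrom": d.interval.chrom,
                        "start": d.interval.start,
                        "end": d.interval.end,
                        "direction": d.direction,
                        "gene_id": d.gene_id,
                        "true_delta_beta": d.true_delta_beta,
                    }
                    for d in truth.planted_dmrs
                ],
                "concordant_genes": truth.concordant_genes,
                "discordant_genes": truth.discordant_genes,
            },
            fh,
            indent=2,
        )
    paths.append(p)
    return paths


def _stage_dmr(config: RunConfig, state: dict, out: Path) -> list[Path]:
    params = dmr_mod.DmrParams(**{**config.dmr, "seed": stage_seed(config.seed, "dmr")})
    dmrs = dmr_mod.call_dmrs(state["cohort"], params)
    state["dmrs"] = dmrs
    p = out / "dmrs.bed"
    with open(p, "w") as fh:
        fh.write("#chrom\tstart\tend\tid\tfds\tdirection\tn_cpgs\tbeta_case\tbeta_ctrl\tp\tq\tperm_p\n")
        for d in dmrs:
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t{d.interval.name}"
                f"\t{d.fds:.4f}\t{d.direction}\t{d.n_cpgs}\t{d.beta_case:.4f}\t{d.beta_ctrl:.4f}"
                f"\t{d.p_value:.3e}\t{d.q_value:.3e}\t{d.perm_p:.3e}\n"
            )
    return [p]


def _stage_annotate(config: RunConfig, state: dict, out: Path) -> list[Path]:
    cgi, genes = state["tracks"]
    params = ann_mod.AnnotationParams(**config.annotate)
    annotations = ann_mod.annotate_dmrs(state["dmrs"], cgi, genes, params)
    state["annotations"] = annotations
    p1 = out / "annotations.tsv"
    ann_mod.annotations_to_frame(annotations).to_csv(p1, sep="\t", index=False)
    p2 = out / "feature_summary.tsv"
    ann_mod.summarize_features(annotations).to_csv(p2, sep="\t", index=False)
    return [p1, p2]


def _stage_integrate(config: RunConfig, state: dict, out: Path) -> list[Path]:
    params = int_mod.ThresholdParams(**config.integrate)
    current = int_mod.current_dmg_calls(state["dmrs"], state["annotations"])
    robust = int_mod.select_robust_genes(
        current, state["expr_tables"], state["meth_tables"], params=params
    )
    state["robust_genes"] = robust
    p = out / "robust_genes.tsv"
    with open(p, "w") as fh:
        fh.write("gene_id\tclass\tsupport\n")
        for g in robust:
            fh.write(f"{g.gene_id}\t{g.klass}\t{','.join(g.support)}\n")
    return [p]


def _stage_mdm(config: RunConfig, state: dict, out: Path) -> list[Path]:
    criteria = mdm_mod.MdmCriteria(**config.mdm)
    robust_ids = {g.gene_id for g in state["robust_genes"]}
    truth = state["truth"]
    cohort = state["cohort"]
    stats = []
    for d in state["dmrs"]:
        try:
            stats.append(mdm_mod.compute_marker_stats(d.interval, cohort))
        except ValueError:
            continue
    ranked = mdm_mod.select_mdm(stats, criteria)
    state["mdm_stats"] = stats
    state["mdm_ranked"] = ranked
    state["top_mdm"] = ranked[0] if ranked else None
    p = out / "mdm_stats.tsv"
    passing_ids = {s.region_id for s in ranked}
    with open(p, "w") as fh:
        fh.write("region_id\tfc\tamd\tauc\tp_value\tctrl_meth\tpasses\ttop_mdm\n")
        top_id = ranked[0].region_id if ranked else ""
        for s in sorted(stats, key=lambda x: x.region_id):
            fh.write(
                f"{s.region_id}\t{s.fc:.4g}\t{s.amd:.4f}\t{s.auc:.4f}\t{s.p_value:.3e}"
                f"\t{s.ctrl_meth:.5f}\t{int(s.region_id in passing_ids)}"
                f"\t{int(s.region_id == top_id)}\n"
            )
    return [p]


def _stage_classify(config: RunConfig, state: dict, out: Path) -> list[Path]:
    seed = stage_seed(config.seed, "classify")
    rows = []
    present: dict[tuple[str, str], int] = {}
    for a in state["annotations"]:
        for f in a.features:
            present[f] = present.get(f, 0) + 1
    for feature, n in sorted(present.items()):
        if n < 2:
            continue
        mat = clf_mod.build_feature_matrix(
            state["dmrs"], state["annotations"], state["cohort"], feature
        )
        acc, sens, spec = clf_mod.crossval_margin_classifier(mat, seed=seed, **config.classify)
        rows.append((f"{feature[0]}:{feature[1]}", n, acc, sens, spec))
    p1 = out / "classifier_accuracy.tsv"
    pd.DataFrame(rows, columns=["feature", "n_dmrs", "accuracy", "sensitivity", "specificity"]).to_csv(
        p1, sep="\t", index=False, float_format="%.4f"
    )
    assignment, crosstab, corr = clf_mod.cluster_and_correlate(state["cohort"])
    p2 = out / "clusters.tsv"
    pd.DataFrame(sorted(assignment.items()), columns=["sample_id", "cluster"]).to_csv(
        p2, sep="\t", index=False
    )
    p3 = out / "cluster_mutation_crosstab.tsv"
    crosstab.to_csv(p3, sep="\t", index=False)
    p4 = out / "correlation_matrix.tsv"
    corr.to_csv(p4, sep="\t", float_format="%.4f")
    return [p1, p2, p3, p4]


def _marker_fractions(state: dict) -> tuple[float, float]:
    top = state.get("top_mdm")
    if top is not None:
        ctrl = max(top.ctrl_meth, 1e-4)
        return float(top.amd + top.ctrl_meth), float(ctrl)
    return 0.40, 0.005


def _stage_diagnose(config: RunConfig, state: dict, out: Path) -> list[Path]:
    sc: simulate.SimConfig = state["sim_config"]
    sc = dataclasses.replace(sc, seed=stage_seed(config.seed, "diagnose"))
    m_case, m_ctrl = _marker_fractions(state)
    panel = simulate.generate_cq_panels(sc, "tissue", m_case=m_case, m_ctrl=m_ctrl)
    res = diag_mod.evaluate_diagnostic(panel, spec_target=config.diagnose.get("spec_target", 1.0))
    state["tissue_threshold"] = res.threshold
    p1 = out / "tissue_panel.tsv"
    meth_io.write_cq_panel(panel, p1)
    p2 = out / "tissue_diagnostics.json"
    with open(p2, "w") as fh:
        json.dump(dataclasses.asdict(res), fh, indent=2)
    return [p1, p2]


def _stage_plasma(config: RunConfig, state: dict, out: Path) -> list[Path]:
    sc: simulate.SimConfig = state["sim_config"]
    sc = dataclasses.replace(sc, seed=stage_seed(config.seed, "plasma"))
    m_case, m_ctrl = _marker_fractions(state)
    panel = simulate.generate_cq_panels(sc, "plasma", m_case=m_case, m_ctrl=m_ctrl)
    res = diag_mod.evaluate_plasma(state["tissue_threshold"], panel)
    p1 = out / "plasma_panel.tsv"
    meth_io.write_cq_panel(panel, p1)
    p2 = out / "plasma_diagnostics.json"
    with open(p2, "w") as fh:
        json.dump(dataclasses.asdict(res), fh, indent=2)
    return [p1, p2]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "dmr": _stage_dmr,
    "annotate": _stage_annotate,
    "integrate": _stage_integrate,
    "mdm": _stage_mdm,
    "classify": _stage_classify,
    "diagnose": _stage_diagnose,
    "plasma": _stage_plasma,
}
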