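"""Stage-wise pipeline orchestration with file artifacts and count logging.

Each stage reads its inputs (raw files or upstream artifacts in the run
directory), runs the corresponding library operation, writes plain-text
artifacts, and records a ``<stage>.log.json`` with the parameters used and
the survivor counts at every filter — the pipeline's primary provenance.
Stages, in dependency order::

    simulate -> qc -> cluster / volcano / tshyper -> integrate
                                      \\-> panel -> classify
                                      \\-> burden
    summarize (collects everything)

Determinism: for a fixed config and seed, every artifact is byte-identical
across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import burden as mburden
from . import cluster as mcluster
from . import io as mio
from . import panels as mpanels
from . import simulate as msim
from . import tshyper as mts
from . import volcano as mvolcano
from .containers import BetaMatrix, ValidationError

logger = logging.getLogger("cimpkit")

STAGES = (
    "simulate",
    "qc",
    "cluster",
    "volcano",
    "tshyper",
    "integrate",
    "panel",
    "classify",
    "burden",
    "summarize",
)


class MissingArtifactError(FileNotFoundError):
    """An upstream stage has not produced a required artifact yet."""


@dataclasses.dataclass
class PipelineConfig:
    """All inputs, thresholds and group definitions for a run.

    Thresholds default to the standard printed criteria of this analysis
    family; every one is overridable from YAML.
    """

    outdir: str = "cimp_run"
    # inputs (ignored by the simulate stage, which writes its own)
    beta_path: str | None = None
    beta_dialect: str = "plain_tsv"
    detection_p_path: str | None = None
    annotation_path: str | None = None
    samples_path: str | None = None
    expression_path: str | None = None
    #: explicit core cohort for the completeness rule; never inferred.
    core_samples: list[str] | None = None
    # thresholds
    detection_alpha: float = 0.01
    top_k: int = 4500
    volcano_delta: float = 0.4
    volcano_alpha: float = 0.01
    volcano_test: str = "welch_t"
    tshyper_normal_max: float = 0.2
    tshyper_delta: float = 0.4
    gene_min_island_probes: int = 2
    expr_ratio_max: float = 0.6667
    expr_alpha: float = 0.05
    panel_high_beta: float = 0.5
    panel_low_beta: float = 0.2
    panel_top_k: int = 25
    panel_min_high_count: int | None = None
    cimp_cutoff: float = 0.35
    subtype_cutoff: float = 0.35
    non_cimp_cutoff: float = 0.2
    burden_normal_max: float = 0.2
    burden_high_beta: float = 0.5
    # group definitions
    cimp_cohorts: list[str] = dataclasses.field(
        default_factory=lambda: ["HLRCC", "SDHB-RCC"]
    )
    subtype_cohort: str = "HLRCC"
    seed: int = 0
    simulation: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        for field, lo, hi in (
            ("detection_alpha", 0, 1),
            ("volcano_alpha", 0, 1),
            ("expr_alpha", 0, 1),
            ("tshyper_normal_max", 0, 1),
            ("burden_normal_max", 0, 1),
            ("panel_high_beta", 0, 1),
            ("panel_low_beta", 0, 1),
            ("burden_high_beta", 0, 1),
        ):
            value = getattr(self, field)
            if not lo < value < hi:
                raise ValidationError(f"{field}={value} outside ({lo}, {hi})")
        if self.volcano_delta <= 0 or self.tshyper_delta <= 0:
            raise ValidationError("effect-size thresholds must be positive")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# artifact helpers
# ---------------------------------------------------------------------------

def _out(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_log(config: PipelineConfig, stage: str, payload: dict[str, Any]) -> None:
    path = _out(config) / f"{stage}.log.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    logger.info("stage %s: %s", stage, {k: v for k, v in payload.items() if k != "params"})


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name}; run the {produced_by!r} stage first"
        )
    return path


def _load_filtered(config: PipelineConfig) -> BetaMatrix:
    return mio.read_beta_matrix(_require(_out(config) / "filtered_beta.tsv", "qc"))


def _load_metadata(config: PipelineConfig):
    out = _out(config)
    ann_path = config.annotation_path or str(out / "annotation.tsv")
    samp_path = config.samples_path or str(out / "samples.csv")
    annotation = mio.load_probe_annotation(_require(Path(ann_path), "simulate"))
    samples = mio.read_sample_sheet(_require(Path(samp_path), "simulate"))
    return annotation, samples


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> dict[str, Any]:
    sim_config = msim.config_from_dict(dict(config.simulation or {}, seed=config.seed)
                                       if config.simulation is not None
                                       else {"seed": config.seed})
    cohort = msim.simulate_cohort(sim_config)
    paths = msim.export_fixture(cohort, _out(config))
    # point the rest of the run at the fixture
    config.beta_path = str(paths["beta"])
    config.annotation_path = str(paths["annotation"])
    config.samples_path = str(paths["samples"])
    config.expression_path = str(paths["expression"])
    if config.core_samples is None:
        config.core_samples = list(cohort.beta.sample_ids)
    return {
        "n_probes": cohort.beta.shape[0],
        "n_samples": cohort.beta.shape[1],
        "n_cimp_tumors": sum(
            s.n_tumors for s in sim_config.cohorts if s.is_cimp
        ),
        "params": {"seed": sim_config.seed, "universe_seed": sim_config.universe_seed},
    }


def stage_qc(config: PipelineConfig) -> dict[str, Any]:
    if config.beta_path is None:
        raise ValidationError("config.beta_path is required for the qc stage")
    beta = mio.read_beta_matrix(config.beta_path, dialect=config.beta_dialect)
    n_input = beta.shape[0]
    n_masked = 0
    if config.detection_p_path is not None:
        detection = pd.read_csv(config.detection_p_path, sep="\t", index_col=0)
        before = int(beta.missing_mask.to_numpy().sum())
        beta = mio.apply_detection_mask(beta, detection, alpha=config.detection_alpha)
        n_masked = int(beta.missing_mask.to_numpy().sum()) - before
    if config.core_samples is None:
        raise ValidationError(
            "core_samples must be set explicitly for the completeness filter"
        )
    beta = mio.drop_incomplete_probes(beta, config.core_samples)
    mio.write_beta_matrix(beta, _out(config) / "filtered_beta.tsv")
    return {
        "n_probes_input": n_input,
        "n_cells_masked": n_masked,
        "n_probes_complete": beta.shape[0],
        "n_samples": beta.shape[1],
        "params": {
            "detection_alpha": config.detection_alpha,
            "n_core_samples": len(config.core_samples),
        },
    }


def stage_cluster(config: PipelineConfig) -> dict[str, Any]:
    beta = _load_filtered(config)
    annotation, _ = _load_metadata(config)
    k = min(config.top_k, beta.shape[0])
    selected = mcluster.top_variable_probes(beta, k)
    result = mcluster.hierarchical_cluster(beta, probes=selected)
    enrichment = mcluster.region_enrichment(selected, annotation, beta.probe_ids)
    out = _out(config)
    pd.Series(result.sample_order, name="sample_id").to_csv(
        out / "cluster_sample_order.tsv", sep="\t", index_label="position"
    )
    (out / "dendrogram.nwk").write_text(result.to_newick() + "\n")
    (out / "enrichment.json").write_text(
        json.dumps(
            {
                "selected_counts": enrichment.selected_counts,
                "universe_counts": enrichment.universe_counts,
                "fold_enrichment": enrichment.fold_enrichment,
                "island_p_value": enrichment.p_value,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {
        "n_selected": int(k),
        "island_fold": enrichment.island_fold,
        "island_p_value": enrichment.p_value,
        "params": {"top_k": config.top_k},
    }


def stage_volcano(config: PipelineConfig) -> dict[str, Any]:
    beta = _load_filtered(config)
    annotation, samples = _load_metadata(config)
    out = _out(config)
    summary: dict[str, Any] = {}
    for cohort in samples.cohorts:
        tumors, normals = samples.paired(cohort)
        if len(tumors) < 2 or len(normals) < 2:
            continue
        result = mvolcano.volcano(
            beta,
            list(tumors),
            list(normals),
            delta=config.volcano_delta,
            alpha=config.volcano_alpha,
            test=config.volcano_test,
        )
        counts = mvolcano.count_calls_by_region(result, annotation)
        regions = annotation.region_of(result.table.index)
        result.table.assign(region=regions.to_numpy()).to_csv(
            out / f"volcano_{cohort}.tsv", sep="\t", index_label="probe_id",
            float_format="%.6g",
        )
        summary[cohort] = {
            "n_pairs": int(min(len(tumors), len(normals))),
            "by_region": counts.to_dict(orient="index"),
            "total_hyper": int((result.calls == "hyper").sum()),
            "total_hypo": int((result.calls == "hypo").sum()),
        }
    (out / "volcano_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    return {
        "cohorts": sorted(summary),
        "total_hyper": {c: summary[c]["total_hyper"] for c in summary},
        "params": {
            "delta": config.volcano_delta,
            "alpha": config.volcano_alpha,
            "test": config.volcano_test,
        },
    }


def stage_tshyper(config: PipelineConfig) -> dict[str, Any]:
    beta = _load_filtered(config)
    annotation, samples = _load_metadata(config)
    out = _out(config)
    results = []
    counts: dict[str, Any] = {}
    for cohort in samples.cohorts:
        tumors = samples.tumors(cohort)
        normals = samples.normals(cohort)
        if len(tumors) == 0 or len(normals) == 0:
            continue
        res = mts.call_ts_hyper(
            beta,
            list(tumors),
            list(normals),
            normal_max=config.tshyper_normal_max,
            delta=config.tshyper_delta,
            annotation=annotation,
            cohort=cohort,
        )
        res.table.to_csv(
            out / f"tshyper_{cohort}.tsv", sep="\t", index_label="probe_id",
            float_format="%.6g",
        )
        region_counts = res.region_counts()
        counts[cohort] = {
            "n_probes": int(len(res.probes)),
            "by_region": {k: int(v) for k, v in region_counts.items()},
        }
        results.append(res)
    overlap = None
    cimp_results = [r for r in results if r.cohort in config.cimp_cohorts]
    if len(cimp_results) >= 2:
        overlap = mts.cross_cohort_overlap(cimp_results, restrict_to="island")
        (out / "tshyper_overlap.json").write_text(
            json.dumps(overlap, indent=2, sort_keys=True)
        )
    (out / "tshyper_summary.json").write_text(
        json.dumps(counts, indent=2, sort_keys=True)
    )
    return {
        "per_cohort": {c: counts[c]["n_probes"] for c in counts},
        "island_overlap_all": None if overlap is None else overlap["intersection_all"],
        "params": {
            "normal_max": config.tshyper_normal_max,
            "delta": config.tshyper_delta,
        },
    }


def stage_integrate(config: PipelineConfig) -> dict[str, Any]:
    beta = _load_filtered(config)
    annotation, samples = _load_metadata(config)
    out = _out(config)
    expr_path = config.expression_path or str(out / "expression.tsv")
    expression = mio.read_expression_matrix(_require(Path(expr_path), "simulate"))
    cohort = config.subtype_cohort
    tumors = samples.tumors(cohort)
    normals = samples.normals(cohort)
    res = mts.call_ts_hyper(
        beta,
        list(tumors),
        list(normals),
        normal_max=config.tshyper_normal_max,
        delta=config.tshyper_delta,
        annotation=annotation,
        cohort=cohort,
    )
    genes = mts.genes_from_probes(res, annotation, config.gene_min_island_probes)
    expr_tumors = [s for s in tumors if s in expression.sample_ids]
    expr_normals = [s for s in normals if s in expression.sample_ids]
    calls = mts.integrate_expression(
        genes,
        expression,
        expr_tumors,
        expr_normals,
        ratio_max=config.expr_ratio_max,
        alpha=config.expr_alpha,
    )
    calls.to_csv(out / "gene_calls.tsv", sep="\t", float_format="%.6g")
    return {
        "cohort": cohort,
        "n_methylated_genes": int(len(genes)),
        "n_evaluable": int(calls["evaluable"].sum()),
        "n_downregulated": int(calls["downregulated"].sum()),
        "params": {
            "min_island_probes": config.gene_min_island_probes,
            "ratio_max": config.expr_ratio_max,
            "alpha": config.expr_alpha,
        },
    }


def stage_panel(config: PipelineConfig) -> dict[str, Any]:
    beta = _load_filtered(config)
    annotation, samples = _load_metadata(config)
    out = _out(config)
    cimp_tumors = [
        s for c in config.cimp_cohorts for s in samples.tumors(c)
    ]
    others = [s for s in beta.sample_ids if s not in set(cimp_tumors)]
    cimp_panel = mpanels.select_panel(
        beta, cimp_tumors, others, annotation,
        high_beta=config.panel_high_beta, low_beta=config.panel_low_beta,
        min_high_count=config.panel_min_high_count, top_k=config.panel_top_k,
        name="cimp",
    )
    subtype_tumors = list(samples.tumors(config.subtype_cohort))
    non_subtype = [s for s in beta.sample_ids if s not in set(subtype_tumors)]
    # the subtype rule tolerates a small number of low tumors, mirroring the
    # >= 13/15 style occupancy used for subtype-specific marker discovery
    subtype_min = max(1, int(np.ceil(len(subtype_tumors) * 13 / 15)))
    subtype_panel = mpanels.select_panel(
        beta, subtype_tumors, non_subtype, annotation,
        high_beta=config.panel_high_beta, low_beta=config.panel_low_beta,
        min_high_count=subtype_min, top_k=config.panel_top_k,
        name="subtype",
    )
    mpanels.write_panel(cimp_panel, out / "panel_cimp.tsv", out / "panel_cimp.json")
    mpanels.write_panel(subtype_panel, out / "panel_subtype.tsv", out / "panel_subtype.json")
    return {
        "cimp_panel_size": len(cimp_panel),
        "subtype_panel_size": len(subtype_panel),
        "params": {
            "high_beta": config.panel_high_beta,
            "low_beta": config.panel_low_beta,
            "top_k": config.panel_top_k,
            "subtype_min_high_count": subtype_min,
        },
    }


def _load_panel(path: Path, name: str, config: PipelineConfig) -> mpanels.PanelDefinition:
    stats = pd.read_csv(_require(path, "panel"), sep="\t", index_col=0)
    return mpanels.PanelDefinition(
        name=name,
        probes=tuple(stats.index.astype(str)),
        stats=stats.drop(columns=["rank"], errors="ignore"),
        high_beta=config.panel_high_beta,
        low_beta=config.panel_low_beta,
        min_high_count=1,
        top_k=config.panel_top_k,
        rank_by="group_p_value",
    )


def stage_classify(config: PipelineConfig) -> dict[str, Any]:
    beta = _load_filtered(config)
    out = _out(config)
    cimp_panel = _load_panel(out / "panel_cimp.tsv", "cimp", config)
    subtype_panel = _load_panel(out / "panel_subtype.tsv", "subtype", config)
    scores = mpanels.score_and_classify(
        beta, cimp_panel, subtype_panel,
        cimp_cutoff=config.cimp_cutoff,
        subtype_cutoff=config.subtype_cutoff,
        non_cimp_cutoff=config.non_cimp_cutoff,
    )
    scores.to_csv(out / "classification.tsv", sep="\t", index_label="sample_id",
                  float_format="%.6g")
    return {
        "class_counts": scores["sample_class"].value_counts().to_dict(),
        "params": {
            "cimp_cutoff": config.cimp_cutoff,
            "subtype_cutoff": config.subtype_cutoff,
            "non_cimp_cutoff": config.non_cimp_cutoff,
        },
    }


def stage_burden(config: PipelineConfig) -> dict[str, Any]:
    beta = _load_filtered(config)
    annotation, samples = _load_metadata(config)
    out = _out(config)
    normals = list(samples.normals())
    reference = mburden.normal_unmethylated_probes(
        beta, normals, annotation, max_beta=config.burden_normal_max
    )
    tumors = [s for c in config.cimp_cohorts for s in samples.tumors(c)]
    table = mburden.burden_table(beta, tumors, reference, config.burden_high_beta)
    table = table.join(samples.df[["cohort", "size_cm", "age_years", "is_primary"]])
    table.to_csv(out / "burden.tsv", sep="\t", index_label="sample_id",
                 float_format="%.6g")
    fits: dict[str, Any] = {}
    for cohort in config.cimp_cohorts:
        sub = table[(table["cohort"] == cohort) & table["is_primary"]]
        fits[cohort] = {}
        for covariate, model in (("size_cm", "linear"), ("age_years", "exponential")):
            pairs = sub[["burden", covariate]].dropna()
            n_dropped = len(sub) - len(pairs)
            if n_dropped:
                logger.info("burden fit %s~%s: dropped %d tumors without %s",
                            cohort, covariate, n_dropped, covariate)
            try:
                fit = mburden.correlate_burden(sub["burden"], sub[covariate], model=model)
                fits[cohort][covariate] = dict(
                    model=fit.model, n=fit.n, r=fit.r, r_squared=fit.r_squared,
                    p_value=fit.p_value, n_dropped=n_dropped, **fit.params,
                )
            except ValidationError as exc:
                fits[cohort][covariate] = {"error": str(exc), "n_dropped": n_dropped}
    (out / "burden_fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
    return {
        "n_reference_probes": int(len(reference)),
        "burden_range": [int(table["burden"].min()), int(table["burden"].max())]
        if len(table) else None,
        "params": {
            "normal_max": config.burden_normal_max,
            "high_beta": config.burden_high_beta,
        },
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "cluster": stage_cluster,
    "volcano": stage_volcano,
    "tshyper": stage_tshyper,
    "integrate": stage_integrate,
    "panel": stage_panel,
    "classify": stage_classify,
    "burden": stage_burden,
}


def run_stage(stage: str, config: PipelineConfig) -> dict[str, Any]:
    """Run one named stage; writes artifacts, a log JSON, and the resolved
    config snapshot next to the outputs."""
    if stage == "summarize":
        return summarize(Path(config.outdir))
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    payload = _STAGE_FUNCS[stage](config)
    _write_log(config, stage, payload)
    config.to_yaml(_out(config) / "resolved_config.yaml")
    return payload


def run_all(config: PipelineConfig, include_simulate: bool = True) -> dict[str, Any]:
    """Run every stage in dependency order and return the summary."""
    stages = [s for s in STAGES if s != "summarize"]
    if not include_simulate:
        stages.remove("simulate")
    for stage in stages:
        run_stage(stage, config)
    summary = summarize(Path(config.outdir))
    return summary


SUMMARY_KEYS = (
    "n_probes_input",
    "n_probes_complete",
    "cluster_island_fold",
    "cluster_island_p_value",
    "volcano_total_hyper",
    "tshyper_per_cohort",
    "tshyper_island_overlap_all",
    "n_methylated_genes",
    "n_downregulated_genes",
    "cimp_panel_size",
    "subtype_panel_size",
    "class_counts",
    "n_reference_probes",
    "burden_range",
    "burden_fit_r_squared",
)


def summarize(run_dir: str | Path) -> dict[str, Any]:
    """Collect headline counts from all stage logs into one JSON.

    Missing stages yield explicit ``None`` values so partial runs are
    machine-readable too.
    """
    run_dir = Path(run_dir)

    def _read(stage: str) -> dict[str, Any] | None:
        path = run_dir / f"{stage}.log.json"
        return json.loads(path.read_text()) if path.exists() else None

    qc = _read("qc")
    cl = _read("cluster")
    vo = _read("volcano")
    ts = _read("tshyper")
    ig = _read("integrate")
    pa = _read("panel")
    cf = _read("classify")
    bu = _read("burden")
    fits_path = run_dir / "burden_fits.json"
    fits = json.loads(fits_path.read_text()) if fits_path.exists() else None

    def _fit_r2(fits_dict):
        if not fits_dict:
            return None
        out = {}
        for cohort, per_cov in fits_dict.items():
            out[cohort] = {
                cov: fit.get("r_squared") for cov, fit in per_cov.items()
            }
        return out

    summary = {
        "n_probes_input": qc and qc.get("n_probes_input"),
        "n_probes_complete": qc and qc.get("n_probes_complete"),
        "cluster_island_fold": cl and cl.get("island_fold"),
        "cluster_island_p_value": cl and cl.get("island_p_value"),
        "volcano_total_hyper": vo and vo.get("total_hyper"),
        "tshyper_per_cohort": ts and ts.get("per_cohort"),
        "tshyper_island_overlap_all": ts and ts.get("island_overlap_all"),
        "n_methylated_genes": ig and ig.get("n_methylated_genes"),
        "n_downregulated_genes": ig and ig.get("n_downregulated"),
        "cimp_panel_size": pa and pa.get("cimp_panel_size"),
        "subtype_panel_size": pa and pa.get("subtype_panel_size"),
        "class_counts": cf and cf.get("class_counts"),
        "n_reference_probes": bu and bu.get("n_reference_probes"),
        "burden_range": bu and bu.get("burden_range"),
        "burden_fit_r_squared": _fit_r2(fits),
    }
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
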