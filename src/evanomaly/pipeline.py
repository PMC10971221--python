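"""End-to-end orchestration of the anomaly-detection workflow.

Steps, per run: log-transform the peak areas; pool the donor-space points
of all conditions and density-filter them to the primary cluster; score
each condition's retained points with an isolation forest; for every
requested comparison take the cluster-filtered, outlier-flagged proteins,
compute their cross-condition displacements, threshold at mean + k*SD, and
attach the descriptive layer (t-test tier, log fold change, within-group
variances and CVs). Outputs are one results TSV per comparison, Venn
region counts per comparison family, and a machine-readable summary JSON.

Every stage is a pure function of (input, config, seed): rerunning with
the same config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import io as tabio
from .density import (ClusterAssignment, OpticsParams, extract_clusters,
                      filter_to_cluster, optics_order, select_primary_cluster,
                      suggest_eps)
from .descriptives import (ProteinStats, abs_var_diff,
                           coefficient_of_variation, protein_ttest,
                           quadratic_fit, venn_regions, within_group_variance)
from .distance import (AnomalySet, ComparisonSpec, anomaly_threshold,
                       comparison_distances)
from .forest import ForestParams, OutlierLabeling, fit_isolation_forest, \
    outlier_union
from .io import AbundanceTable
from .preprocess import donor_points, log_transform

__all__ = ["RunConfig", "ComparisonResult", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

# Fixed fan-out offset so one global seed reproduces every stochastic stage.
_FOREST_SEED_OFFSET = 1009


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs; every field maps to a config-file key."""

    comparisons: Sequence[ComparisonSpec]
    input: str | Path | None = None
    dialect: str = "wide_tsv"
    log_base: Any = 2
    nonpositive_policy: str = "drop_protein"
    epsilon: float | None = None
    optics_min_pts: int = 50
    optics_eps: float | str = 0.05          # a radius, or "auto" for suggest_eps
    selection_rule: str = "largest_all_positive"
    membership_rule: str = "both"
    forest_n_trees: int = 500
    forest_subsample: int | None = None
    forest_contamination: float | str = 0.10
    pairing_rule: str = "union"
    threshold_k: float = 1.0
    sd_ddof: int = 1
    out_dir: str | Path | None = None
    seed: int = 1337

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        comps = [ComparisonSpec(**c) if isinstance(c, Mapping) else c
                 for c in raw.pop("comparisons")]
        return cls(comparisons=comps, **raw)


@dataclasses.dataclass
class ComparisonResult:
    comparison: ComparisonSpec
    anomalies: AnomalySet
    stats: dict[str, ProteinStats]
    eligible: set[str]
    fit: dict[str, float] | None   # quadratic logFC-vs-d fit, when defined


@dataclasses.dataclass
class PipelineResult:
    table: AbundanceTable
    assignment: ClusterAssignment
    labelings: dict[str, OutlierLabeling]
    comparisons: dict[str, ComparisonResult]
    venn: dict[str, dict[str, int]]
    summary: dict[str, Any]


def _stats_for(logtable, accession: str, comp: ComparisonSpec) -> ProteinStats:
    ref = logtable.values(accession, comp.reference)
    trt = logtable.values(accession, comp.treatment)
    p, tier = protein_ttest(ref, trt)
    v_ref = within_group_variance(ref)
    v_trt = within_group_variance(trt)
    return ProteinStats(
        accession=accession, p_value=p, tier=tier,
        var_ref=v_ref, var_trt=v_trt, abs_var_diff=abs_var_diff(v_ref, v_trt),
        cv_ref=coefficient_of_variation(ref),
        cv_trt=coefficient_of_variation(trt),
    )


def run_pipeline(config: RunConfig,
                 table: AbundanceTable | None = None) -> PipelineResult:
    """Run the full workflow; pass ``table`` to skip reading ``config.input``."""
    if table is None:
        if config.input is None:
            raise ValueError("config.input or an in-memory table is required")
        table = tabio.read_abundance_table(config.input, config.dialect)
    for comp in config.comparisons:
        for cond in (comp.reference, comp.treatment):
            if cond not in table.conditions:
                raise ValueError(
                    f"comparison {comp.label!r} references unknown condition "
                    f"{cond!r}; available: {table.conditions}")

    logtable = log_transform(table, base=config.log_base,
                             nonpositive_policy=config.nonpositive_policy,
                             epsilon=config.epsilon)
    logger.info("log-transformed %d proteins (%d dropped)",
                len(logtable.proteins), len(logtable.dropped_proteins))

    pooled = []
    for cond in table.conditions:
        pooled.extend(donor_points(logtable, cond))
    logger.info("pooled %d donor-space points over %d conditions",
                len(pooled), len(table.conditions))

    params = OpticsParams(min_pts=config.optics_min_pts, eps=1.0)
    if config.optics_eps == "auto":
        eps = suggest_eps(pooled, config.optics_min_pts)
        logger.info("suggest_eps chose extraction radius %.4g", eps)
    else:
        eps = float(config.optics_eps)
    params = OpticsParams(min_pts=config.optics_min_pts, eps=eps)
    assignment = optics_order(pooled, params)
    extract_clusters(assignment, eps)
    select_primary_cluster(assignment, logtable, config.selection_rule)
    sizes = assignment.cluster_sizes()
    logger.info("OPTICS found %d clusters %s; selected cluster %d",
                len(sizes), sizes, assignment.selected_cluster_id)

    sel = assignment.selected_cluster_id
    in_cluster: dict[str, set[str]] = {}
    for point, label in zip(assignment.points, assignment.labels):
        if label == sel:
            in_cluster.setdefault(point.condition, set()).add(point.accession)

    labelings: dict[str, OutlierLabeling] = {}
    for i, cond in enumerate(table.conditions):
        keep = in_cluster.get(cond, set())
        pts = [p for p in donor_points(logtable, cond) if p.accession in keep]
        fp = ForestParams(n_trees=config.forest_n_trees,
                          subsample_size=config.forest_subsample,
                          contamination=config.forest_contamination,
                          seed=config.seed + _FOREST_SEED_OFFSET * (i + 1))
        labelings[cond] = fit_isolation_forest(pts, fp)
        logger.info("condition %s: %d in-cluster points, %d flagged outliers",
                    cond, len(pts), len(labelings[cond].outliers))

    comparisons: dict[str, ComparisonResult] = {}
    for comp in config.comparisons:
        clustered = filter_to_cluster(assignment, comp, config.membership_rule)
        flagged = outlier_union(labelings, comp, config.pairing_rule)
        eligible = clustered & flagged
        records = comparison_distances(logtable, eligible, comp)
        if len(records) < 2:
            logger.warning("comparison %s: %d eligible records, skipping",
                           comp.label, len(records))
            continue
        anomalies = anomaly_threshold(records, k=config.threshold_k,
                                      comparison=comp, sd_ddof=config.sd_ddof)
        stats = {r.accession: _stats_for(logtable, r.accession, comp)
                 for r in anomalies.records}
        fit = None
        x = np.array([r.logFC for r in records])
        if len(records) >= 3 and not np.all(x == x[0]):
            q = quadratic_fit([r.logFC for r in records],
                              [r.d for r in records])
            fit = {"a": q.a, "b": q.b, "c": q.c, "r_squared": q.r_squared}
        comparisons[comp.label] = ComparisonResult(
            comparison=comp, anomalies=anomalies, stats=stats,
            eligible=eligible, fit=fit)
        logger.info("comparison %s: tau=%.4g, %d/%d flagged anomalous",
                    comp.label, anomalies.tau, len(anomalies.flagged),
                    len(records))

    # Venn region counts per comparison family (same reference/treatment
    # names across biomaterials).
    families: dict[str, dict[str, set[str]]] = {}
    for res in comparisons.values():
        comp = res.comparison
        fam = f"{comp.reference}_vs_{comp.treatment}"
        name = comp.experiment or comp.label
        families.setdefault(fam, {})[name] = set(res.anomalies.flagged)
    venn = {fam: venn_regions(sets) for fam, sets in families.items()
            if len(sets) in (2, 3)}

    summary: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "log_base": str(config.log_base),
            "nonpositive_policy": config.nonpositive_policy,
            "optics_min_pts": config.optics_min_pts,
            "optics_eps": eps,
            "selection_rule": config.selection_rule,
            "membership_rule": config.membership_rule,
            "forest_n_trees": config.forest_n_trees,
            "forest_contamination": config.forest_contamination,
            "pairing_rule": config.pairing_rule,
            "threshold_k": config.threshold_k,
            "sd_ddof": config.sd_ddof,
        },
        "n_proteins": len(table.proteins),
        "n_dropped": len(logtable.dropped_proteins),
        "clusters": {str(k): v for k, v in sizes.items()},
        "selected_cluster": assignment.selected_cluster_id,
        "comparisons": {
            label: {
                "tau": res.anomalies.tau,
                "n_eligible": len(res.anomalies.records),
                "n_flagged": len(res.anomalies.flagged),
                "flagged": sorted(res.anomalies.flagged),
                "quadratic_fit": res.fit,
            }
            for label, res in comparisons.items()
        },
    }

    result = PipelineResult(table=table, assignment=assignment,
                            labelings=labelings, comparisons=comparisons,
                            venn=venn, summary=summary)
    if config.out_dir is not None:
        _write_outputs(result, logtable, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, logtable, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for label, res in result.comparisons.items():
        rows = []
        for rec in res.anomalies.records:
            st = res.stats[rec.accession]
            pid = result.table.protein(rec.accession)
            rows.append({
                "accession": rec.accession,
                "gene": pid.gene,
                "name": pid.name,
                "distance": rec.d,
                "threshold_flag": rec.accession in res.anomalies.flagged,
                "p_value": st.p_value,
                "tier": st.tier,
                "logFC": rec.logFC,
                "var_ref": st.var_ref,
                "var_trt": st.var_trt,
                "abs_var_diff": st.abs_var_diff,
            })
        tabio.write_results_table(rows, out_dir / f"{label}.tsv")
    for fam, regions in result.venn.items():
        with open(out_dir / f"venn_{fam}.json", "w") as fh:
            json.dump(regions, fh, indent=2, sort_keys=True)
            fh.write("\n")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
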