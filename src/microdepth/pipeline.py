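"""End-to-end orchestration: simulate-or-load, rarefaction, partitioning,
alpha/beta statistics, fertility/random-forest drivers, per-layer networks
and function mapping, driven by one AnalysisConfig and one global seed.

Each stage draws its own sub-seed from the global seed via a fixed
derivation, so a stage re-run in isolation reproduces its in-pipeline
output. Stages run in dependency order; a failure stops the run and the
report lists the stages that completed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import functions as func_mod
from . import network as net_mod
from . import partition as part_mod
from ._seeds import stage_seed
from .io import (AnalysisConfig, CountTable, SampleMetadata, SoilVariables,
                 TaxonomyTable, ValidationError, LAYERS, load_dataset,
                 write_counts, write_json, write_metadata, write_soil,
                 write_taxonomy)
from .simulate import SimulationParams, simulate_dataset

logger = logging.getLogger("microdepth")

ALL_STAGES = ("input", "rarefy", "partition", "alpha", "beta", "drivers",
              "network", "functions")


@dataclass
class RunReport:
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def add(self, name: str, outputs: list[str], elapsed: float,
            seed: int | None = None) -> None:
        self.stages.append({"stage": name, "outputs": outputs,
                            "wall_time_s": round(elapsed, 3), "seed": seed})

    def to_json(self) -> dict:
        return {"config": self.config, "seed": self.seed,
                "stages": self.stages, "warnings": self.warnings,
                "failed_stage": self.failed_stage}


def run_pipeline(out_dir: str | Path,
                 config: AnalysisConfig | None = None,
                 input_paths: dict | None = None,
                 sim_params: SimulationParams | None = None,
                 stages: tuple[str, ...] = ALL_STAGES) -> RunReport:
    """Run the analysis end to end, writing TSV/JSON outputs under out_dir.

    Exactly one of ``input_paths`` (dict with counts/metadata and optional
    taxonomy/soil paths) or ``sim_params`` must be supplied.
    """
    config = config or AnalysisConfig()
    if (input_paths is None) == (sim_params is None):
        raise ValidationError("supply exactly one of input_paths or sim_params")
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dict(config.__dict__), seed=config.seed)

    state: dict = {}
    try:
        _stage_input(state, report, out, config, input_paths, sim_params)
        if "rarefy" in stages:
            _stage_rarefy(state, report, out, config)
        if "partition" in stages:
            _stage_partition(state, report, out, config)
        if "alpha" in stages:
            _stage_alpha(state, report, out, config)
        if "beta" in stages:
            _stage_beta(state, report, out, config)
        if "drivers" in stages:
            _stage_drivers(state, report, out, config)
        if "network" in stages:
            _stage_network(state, report, out, config)
        if "functions" in stages:
            _stage_functions(state, report, out, config)
    except Exception as exc:
        report.failed_stage = state.get("_current", "input")
        report.warnings.append(f"failed at {report.failed_stage}: {exc}")
        write_json(report.to_json(), out / "run_report.json")
        raise
    write_json(report.to_json(), out / "run_report.json")
    return report


def _timed(state, report, name):
    state["_current"] = name
    return time.perf_counter()


def _stage_input(state, report, out, config, input_paths, sim_params):
    t0 = _timed(state, report, "input")
    if sim_params is not None:
        table, meta, tax, soil, truth = simulate_dataset(sim_params)
        write_counts(table, out / "counts.tsv")
        write_metadata(meta, out / "metadata.tsv")
        write_taxonomy(tax, out / "taxonomy.tsv")
        write_soil(soil, out / "soil.tsv")
        write_json(truth, out / "ground_truth.json")
        state["ground_truth"] = truth
        outputs = ["counts.tsv", "metadata.tsv", "taxonomy.tsv", "soil.tsv",
                   "ground_truth.json"]
        seed = sim_params.seed
    else:
        table, meta, tax, soil = load_dataset(
            input_paths["counts"], input_paths["metadata"],
            input_paths.get("taxonomy"), input_paths.get("soil"))
        outputs, seed = [], None
    state.update(table=table, metadata=meta, taxonomy=tax, soil=soil)
    report.add("input", outputs, time.perf_counter() - t0, seed)


def _stage_rarefy(state, report, out, config):
    t0 = _timed(state, report, "rarefy")
    table = state["table"]
    depth = config.rarefaction_depth or int(table.sample_totals().min())
    seed = stage_seed(config.seed, "rarefy")
    rarefied = part_mod.rarefy(table, depth, seed)
    dropped = set(table.sample_ids) - set(rarefied.sample_ids)
    if dropped:
        report.warnings.append(f"rarefy dropped samples: {sorted(dropped)}")
    state["table"] = rarefied
    write_counts(rarefied, out / "counts_rarefied.tsv")
    report.add("rarefy", ["counts_rarefied.tsv"], time.perf_counter() - t0, seed)


def _stage_partition(state, report, out, config):
    t0 = _timed(state, report, "partition")
    table, meta = state["table"], state["metadata"]
    classes = part_mod.classify_abundance(table, config.rare_threshold,
                                          config.abundant_threshold)
    state["classes"] = classes
    part_mod.classes_to_frame(classes).to_csv(out / "abundance_classes.tsv", sep="\t")
    props = part_mod.rare_proportions(table, classes, meta)
    props.to_csv(out / "rare_proportions.tsv", sep="\t")
    state["rare_proportions"] = props
    seed = stage_seed(config.seed, "enrichment")
    enrich = part_mod.enrichment_classify(table, meta, config.enrichment_q)
    enr = pd.DataFrame({"enriched_in": [e.enriched_in for e in enrich],
                        "statistic": [e.statistic for e in enrich],
                        "q_value": [e.q_value for e in enrich]},
                       index=pd.Index([e.asv_id for e in enrich], name="asv_id"))
    tern = part_mod.ternary_coordinates(table, meta)
    enr.join(tern).to_csv(out / "enrichment.tsv", sep="\t")
    state["enrichment"] = enrich
    report.add("partition", ["abundance_classes.tsv", "rare_proportions.tsv",
                             "enrichment.tsv"], time.perf_counter() - t0, seed)


def _stage_alpha(state, report, out, config):
    t0 = _timed(state, report, "alpha")
    table, meta = state["table"], state["metadata"]
    div = alpha_mod.diversity_frame(alpha_mod.alpha_diversity(table))
    div.to_csv(out / "alpha_diversity.tsv", sep="\t")
    state["alpha"] = div
    anova_rows = []
    for response in ("richness", "evenness"):
        res = alpha_mod.two_way_anova(div[response], meta)
        frame = res.to_frame()
        frame.insert(0, "response", response)
        anova_rows.append(frame)
    pd.concat(anova_rows).to_csv(out / "anova.tsv", sep="\t")
    report.add("alpha", ["alpha_diversity.tsv", "anova.tsv"],
               time.perf_counter() - t0)


def _stage_beta(state, report, out, config):
    t0 = _timed(state, report, "beta")
    table, meta = state["table"], state["metadata"]
    d = beta_mod.bray_curtis(table)
    d.to_dataframe().to_csv(out / "bray_curtis.tsv", sep="\t")
    state["distance"] = d
    res = beta_mod.pcoa(d)
    n_axes = min(5, res.coordinates.shape[1])
    coords = pd.DataFrame(res.coordinates[:, :n_axes], index=res.sample_ids,
                          columns=[f"PCo{k + 1}" for k in range(n_axes)])
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id")
    seed = stage_seed(config.seed, "permanova")
    perm = beta_mod.permanova(d, meta, "layer + time + layer:time",
                              config.n_permutations, seed)
    perm.to_frame().to_csv(out / "permanova.tsv", sep="\t")
    state["permanova"] = perm
    report.add("beta", ["bray_curtis.tsv", "pcoa_coordinates.tsv",
                        "permanova.tsv"], time.perf_counter() - t0, seed)


def _stage_drivers(state, report, out, config):
    t0 = _timed(state, report, "drivers")
    soil = state.get("soil")
    if soil is None:
        report.warnings.append("drivers stage skipped: no soil variables")
        report.add("drivers", [], time.perf_counter() - t0)
        return
    fert = alpha_mod.fertility_index(soil)
    fert.to_frame().to_csv(out / "fertility_index.tsv", sep="\t",
                           index_label="sample_id")
    state["fertility"] = fert
    div = state.get("alpha")
    seed = stage_seed(config.seed, "rf")
    preds = soil.table.reindex(fert.index)
    outputs = ["fertility_index.tsv"]
    if div is not None:
        rows = []
        for response in ("richness", "evenness"):
            recs = alpha_mod.rf_importance(
                preds, div[response].reindex(preds.index),
                n_trees=config.rf_trees,
                n_response_permutations=config.rf_response_permutations,
                seed=seed)
            for r in recs:
                rows.append({"response": response, "predictor": r.predictor,
                             "importance_pct_inc_mse": r.importance,
                             "p_value": r.p_value})
        pd.DataFrame(rows).to_csv(out / "rf_importance.tsv", sep="\t", index=False)
        outputs.append("rf_importance.tsv")
    report.add("drivers", outputs, time.perf_counter() - t0, seed)


def _stage_network(state, report, out, config):
    t0 = _timed(state, report, "network")
    table, meta = state["table"], state["metadata"]
    seed = stage_seed(config.seed, "network")
    nets, metrics, outputs = {}, {}, []
    for layer in LAYERS:
        try:
            net = net_mod.build_cooccurrence_network(
                table, meta, layer,
                config.network_abundance_threshold,
                config.network_occurrence_threshold,
                config.rho_min, config.q_max)
        except ValidationError as exc:
            report.warnings.append(f"network[{layer}]: {exc}")
            continue
        nets[layer] = net
        modules, q = net_mod.detect_modules(net, seed)
        metrics[layer] = net_mod.network_metrics(net, modules, q).to_dict()
        topo = net_mod.topology_frame(net_mod.zi_pi(
            net, modules, config.zi_threshold, config.pi_threshold))
        topo.to_csv(out / f"network_{layer}_topology.tsv", sep="\t")
        edges = pd.DataFrame(
            [{"asv_a": a, "asv_b": b, "rho": d["rho"], "q": d["q"],
              "sign": d["sign"]} for a, b, d in net.edges(data=True)])
        edges.to_csv(out / f"network_{layer}_edges.tsv", sep="\t", index=False)
        outputs += [f"network_{layer}_topology.tsv", f"network_{layer}_edges.tsv"]
    if len(nets) >= 2:
        metrics["shared_nodes"] = net_mod.compare_networks(nets)
    write_json(metrics, out / "network_metrics.json")
    outputs.append("network_metrics.json")
    state["networks"] = nets
    report.add("network", outputs, time.perf_counter() - t0, seed)


def _stage_functions(state, report, out, config):
    t0 = _timed(state, report, "functions")
    table, tax = state["table"], state.get("taxonomy")
    if tax is None:
        report.warnings.append("functions stage skipped: no taxonomy")
        report.add("functions", [], time.perf_counter() - t0)
        return
    rules = func_mod.FunctionRules.from_tsv(func_mod.DEFAULT_RULES)
    group_table, assignments, frac = func_mod.map_functions(table, tax, rules)
    group_table.to_csv(out / "function_profiles.tsv", sep="\t")
    attr = func_mod.function_attribution(table, assignments, tax, "phylum")
    attr.to_csv(out / "function_attribution.tsv", sep="\t", index=False)
    state["function_profiles"] = group_table
    state["assigned_fraction"] = frac
    write_json({"assigned_asv_fraction": frac,
                "n_groups": int((group_table.sum() > 0).sum())},
               out / "function_summary.json")
    report.add("functions", ["function_profiles.tsv", "function_attribution.tsv",
                             "function_summary.json"], time.perf_counter() - t0)
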