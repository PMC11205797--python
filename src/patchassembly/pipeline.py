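"""End-to-end orchestration: simulate/read -> rarefy -> all analysis stages.

Each stage writes tidy TSV outputs under one directory and logs the thresholds
it actually applied; a single master seed derives independent per-stage seeds
so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assembly import assembly_metrics, partition_processes, partition_table
from .dataset import (AbundanceTable, AnalysisConfig, Phylogeny,
                      SampleMetadata, ValidationError, rarefy, read_dataset,
                      stage_seed)
from .diversity import (alpha_diversity_table, diversity_sar_summary,
                        habitat_heterogeneity, sar_table, within_patch_beta)
from .network import (get_profile, build_network, subnetwork_table,
                      topology_area_regression)
from .neutral import fit_ncm
from .niche import classify_taxa, subset_by_category
from .simulate import PatchLayout, SimulationParams, simulate_dataset

log = logging.getLogger("patchassembly")


@dataclass
class PipelineReport:
    """What ran, where outputs went, and how long each stage took."""

    config: AnalysisConfig
    out_dir: str
    stages: dict[str, str] = field(default_factory=dict)      # name -> ok/failed/skipped
    outputs: dict[str, str] = field(default_factory=dict)     # name -> path
    runtimes: dict[str, float] = field(default_factory=dict)  # name -> seconds
    state: dict = field(default_factory=dict, repr=False)     # in-memory results

    @property
    def ok(self) -> bool:
        return all(s == "ok" for s in self.stages.values())

    def write_manifest(self) -> str:
        path = Path(self.out_dir) / "manifest.json"
        doc = {"seed": self.config.seed, "stages": self.stages,
               "outputs": self.outputs, "runtimes_s": self.runtimes,
               "config": {k: v for k, v in self.config.__dict__.items()}}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=str)
        return str(path)


def _load_inputs(config: AnalysisConfig
                 ) -> tuple[AbundanceTable, Phylogeny, SampleMetadata]:
    if config.simulate:
        sim_kwargs = dict(config.simulate)
        layout_kwargs = sim_kwargs.pop("layout", None)
        layout = PatchLayout(**layout_kwargs) if layout_kwargs else PatchLayout()
        # the generator derives its own per-stage streams from this seed
        sim_kwargs.setdefault("seed", config.seed)
        params = SimulationParams(**sim_kwargs)
        ds = simulate_dataset(params, layout)
        return ds.table, ds.phylogeny, ds.metadata
    inputs = config.inputs
    for key in ("counts", "tree", "metadata"):
        if key not in inputs:
            raise ValidationError(
                f"config.inputs missing {key!r} (or enable the simulate stage)")
    return read_dataset(inputs["counts"], inputs["tree"], inputs["metadata"])


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> PipelineReport:
    """Run simulate/read -> rarefy -> diversity/SAR -> niche -> NCM ->
    assembly -> network, honoring the configured taxon subset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=config, out_dir=str(out))
    state = report.state

    def _load():
        state["table"], state["phylo"], state["meta"] = _load_inputs(config)
        log.info("loaded %d taxa x %d samples", state["table"].n_taxa,
                 state["table"].n_samples)

    def _rarefy():
        depth = config.rarefaction_depth or int(state["table"].sample_sums().min())
        log.info("rarefying to depth %d", depth)
        state["table"] = rarefy(state["table"], depth,
                                stage_seed(config.seed, "rarefy"))
        state["phylo"] = state["phylo"].prune_to(state["table"].taxon_ids)
        path = out / "rarefied_counts.tsv"
        state["table"].to_tsv(path)
        report.outputs["rarefied_counts"] = str(path)

    def _niche():
        state["niche"] = classify_taxa(
            state["table"], state["meta"], n_perm=config.n_permutations,
            alpha=config.alpha, seed=stage_seed(config.seed, "niche"))
        path = out / "niche_breadth.tsv"
        state["niche"].table.to_csv(path, sep="\t")
        report.outputs["niche_breadth"] = str(path)
        # the analysis table for downstream stages honors the subset filter
        state["analysis_table"] = subset_by_category(
            state["table"], state["niche"], config.subset)
        log.info("niche categories: %s; analysing subset=%s (%d taxa)",
                 state["niche"].counts(), config.subset,
                 state["analysis_table"].n_taxa)

    def _diversity():
        tab, meta = state["analysis_table"], state["meta"]
        alpha_diversity_table(tab).to_csv(out / "alpha_diversity.tsv", sep="\t")
        beta = within_patch_beta(tab, meta)
        het = habitat_heterogeneity(
            meta, standardize=config.standardize_heterogeneity)
        pd.DataFrame({"beta_bray_curtis": beta, "heterogeneity": het}
                     ).to_csv(out / "beta_heterogeneity.tsv", sep="\t")
        fits = diversity_sar_summary(
            tab, meta, standardize_heterogeneity=config.standardize_heterogeneity)
        sar_table(fits).to_csv(out / "sar_regressions.tsv", sep="\t")
        state["sar"] = fits
        for key in ("alpha_diversity", "beta_heterogeneity", "sar_regressions"):
            report.outputs[key] = str(out / f"{key}.tsv")

    def _ncm():
        tab = state["analysis_table"]
        if tab.sample_sums().nunique() > 1:
            # taxon subsets break the even depth; re-rarefy to the subset min
            depth = int(tab.sample_sums().min())
            log.info("re-rarefying %s subset to depth %d for the NCM",
                     config.subset, depth)
            tab = rarefy(tab, depth, stage_seed(config.seed, "ncm-rarefy"))
        fit = fit_ncm(tab)
        state["ncm"] = fit
        fit.table.to_csv(out / "ncm_taxa.tsv", sep="\t")
        pd.DataFrame([{"m": fit.m, "Nm": fit.Nm, "r2": fit.r2, "N": fit.N,
                       "n_samples": fit.n_samples, "n_taxa": fit.n_taxa}]
                     ).to_csv(out / "ncm_fit.tsv", sep="\t", index=False)
        report.outputs["ncm_fit"] = str(out / "ncm_fit.tsv")
        log.info("NCM: m=%.4g R2=%.3f", fit.m, fit.r2)

    def _assembly():
        log.info("null models with n_null=%d", config.n_null)
        metrics = assembly_metrics(
            state["analysis_table"], state["phylo"], n_null=config.n_null,
            seed=stage_seed(config.seed, "assembly"))
        state["assembly_metrics"] = metrics
        metrics.to_csv(out / "assembly_pairs.tsv", sep="\t")
        parts = partition_processes(metrics, state["meta"])
        state["partitions"] = parts
        partition_table(parts).to_csv(out / "assembly_partition.tsv", sep="\t")
        report.outputs["assembly_partition"] = str(out / "assembly_partition.tsv")

    def _network():
        profile = get_profile(config.network_profile,
                              absolute_rho=config.absolute_rho,
                              adjust_p=config.adjust_p)
        log.info("network profile %s: prevalence>=%.2f rho>%.2f p<%.3g",
                 profile.name, profile.min_prevalence, profile.rho_cutoff,
                 profile.p_cutoff)
        net = build_network(state["analysis_table"], profile)
        state["network"] = net
        net.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        stats = subnetwork_table(net, state["analysis_table"])
        state["subnetworks"] = stats
        stats.to_csv(out / "subnetworks.tsv", sep="\t")
        try:
            fits = topology_area_regression(stats, state["meta"])
            state["topology_sar"] = fits
            sar_table(fits).to_csv(out / "topology_sar.tsv", sep="\t")
            report.outputs["topology_sar"] = str(out / "topology_sar.tsv")
        except ValidationError as exc:
            # sparse networks can leave modularity undefined almost everywhere
            log.warning("topology regression skipped: %s", exc)
        report.outputs["network_edges"] = str(out / "network_edges.tsv")
        report.outputs["subnetworks"] = str(out / "subnetworks.tsv")

    stage_order = [("load", _load), ("rarefy", _rarefy), ("niche", _niche),
                   ("diversity", _diversity), ("ncm", _ncm),
                   ("assembly", _assembly), ("network", _network)]
    aborted = False
    for name, fn in stage_order:
        if aborted:
            report.stages[name] = "skipped"
            continue
        t0 = time.perf_counter()
        try:
            fn()
            report.stages[name] = "ok"
        except Exception as exc:
            report.stages[name] = f"failed: {exc}"
            log.error("stage %s failed: %s", name, exc)
            aborted = True
        finally:
            report.runtimes[name] = round(time.perf_counter() - t0, 3)

    report.outputs["manifest"] = report.write_manifest()
    return report
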