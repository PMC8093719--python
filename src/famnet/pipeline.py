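"""End-to-end pipeline: simulate/ingest -> QC + consolidation -> parentage
-> network -> centrality -> community -> spatial -> report.

Every run is driven by a :class:`PipelineConfig` (constructed directly or
loaded from YAML), writes its artifacts into one output directory, and
finishes with a manifest of SHA-256 content hashes plus a structured log of
all parameters and seeds, so identical configurations produce byte-
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import centrality as centrality_mod
from . import community as community_mod
from . import genotypes as genotypes_mod
from . import pednet, spatial
from .parentage import ParentageConfig, assign_parentage, fitness_counts, \
    reconstruct_unsampled_parents
from .simulate import SimulationConfig, apply_sampling_and_error, \
    draw_allele_frequencies, simulate_population, write_genotype_csv, \
    write_pedigree_csv

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("famnet")

STAGES = ("simulate", "ingest", "qc", "parentage", "network",
          "centrality", "community", "spatial", "report")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` is true (a synthetic population is generated from
    ``sim``) or ``genotype_csv`` points at an input genotype table.  All
    stochastic stages derive their seeds from ``seed``.
    """

    out_dir: str = "famnet_out"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig | None = None
    genotype_csv: str | None = None
    areas_geojson: str | None = None       # else: area labels from samples
    max_mismatch: int = 2
    min_loci: int = 5
    parentage: ParentageConfig = field(default_factory=ParentageConfig)
    alpha: float = 1.0
    centrality_on_primary_component: bool = True
    removal_threshold: float = 4.0
    removal_mode: str = "recompute"
    k_areas: int = 4
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if isinstance(raw.get("sim"), dict):
            sim = dict(raw["sim"])
            if isinstance(sim.get("area_layout"), list):
                sim["area_layout"] = tuple(
                    spatial_cluster(**c) if isinstance(c, dict) else c
                    for c in sim["area_layout"])
            raw["sim"] = SimulationConfig(**sim)
        if isinstance(raw.get("parentage"), dict):
            raw["parentage"] = ParentageConfig(**raw["parentage"])
        if isinstance(raw.get("stages"), list):
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.simulate:
            if not self.genotype_csv:
                raise ValueError("genotype_csv is required when simulate=false")
            if not Path(self.genotype_csv).exists():
                raise FileNotFoundError(self.genotype_csv)
        if self.areas_geojson and not Path(self.areas_geojson).exists():
            raise FileNotFoundError(self.areas_geojson)
        if self.removal_mode not in ("static", "recompute"):
            raise ValueError(f"removal_mode {self.removal_mode!r}")


def spatial_cluster(**kwargs):
    from .simulate import AreaCluster

    if "center" in kwargs and isinstance(kwargs["center"], list):
        kwargs["center"] = tuple(kwargs["center"])
    return AreaCluster(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_record(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the enabled stages in order and return the artifact manifest
    (relative path -> SHA-256).  Configuration errors raise before any
    stage executes; a stage failure still writes the partial manifest with
    a failure record."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    record = {"config": _config_record(config), "stages_run": [],
              "failure": None}

    def emit(name: str) -> Path:
        return out / name

    def register(*names: str) -> None:
        for name in names:
            manifest[name] = _sha256(out / name)

    enabled = [s for s in STAGES if s in config.stages]
    state: dict = {}
    try:
        for stage in enabled:
            t0 = time.perf_counter()
            _run_stage(stage, config, state, emit, register)
            record["stages_run"].append(stage)
            log.info("stage %s finished in %.2fs", stage,
                     time.perf_counter() - t0)
    except Exception as exc:
        record["failure"] = f"{type(exc).__name__}: {exc}"
        _finish(out, manifest, record, register)
        raise
    _finish(out, manifest, record, register)
    return manifest


def _finish(out: Path, manifest: dict, record: dict, register) -> None:
    with open(out / "run_log.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
    register("run_log.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _run_stage(stage: str, config: PipelineConfig, state: dict,
               emit, register) -> None:
    if stage == "simulate":
        if not config.simulate:
            return
        sim = config.sim or SimulationConfig(seed=config.seed)
        if sim.seed != config.seed:
            sim = dataclasses.replace(sim, seed=config.seed)
        freqs = draw_allele_frequencies(sim.n_loci, sim.alleles_per_locus,
                                        seed=sim.seed + 7919)
        pop = simulate_population(sim, freqs)
        samples = apply_sampling_and_error(pop, sim, freqs)
        state.update(sim=sim, true_freqs=freqs, population=pop,
                     samples=samples)
        write_genotype_csv(samples, emit("genotypes.csv"),
                           loci=list(freqs.loci))
        write_pedigree_csv(pop, emit("true_pedigree.csv"))
        freqs.to_csv(emit("true_frequencies.csv"))
        register("genotypes.csv", "true_pedigree.csv", "true_frequencies.csv")
        if pop.empty_generations:
            log.warning("empty generations: %s", pop.empty_generations)

    elif stage == "ingest":
        if config.simulate:
            return
        state["samples"] = genotypes_mod.read_genotype_csv(config.genotype_csv)

    elif stage == "qc":
        samples = state["samples"]
        result = genotypes_mod.consolidate_individuals(
            samples, max_mismatch=config.max_mismatch,
            min_loci=config.min_loci)
        scored = {s.sample_id: len(s.genotype) >= config.min_loci
                  for s in samples}
        pairs = []
        for ind in result.individuals:
            members = sorted(ind.member_samples)
            pairs += list(zip(members[:-1], members[1:]))
        qc = genotypes_mod.qc_summary(samples, scored, pairs,
                                      unique_of=result.sample_to_individual)
        state.update(consolidation=result, qc=qc,
                     individuals=result.individuals)
        genotypes_mod.write_individuals_csv(result.individuals,
                                            emit("individuals.csv"))
        qc.to_csv(emit("qc.csv"))
        with open(emit("consolidation_audit.log"), "w") as fh:
            fh.write("\n".join(result.audit_lines()) + "\n")
        register("individuals.csv", "qc.csv", "consolidation_audit.log")

    elif stage == "parentage":
        individuals = state["individuals"]
        freqs = genotypes_mod.estimate_allele_frequencies(individuals)
        freqs.to_csv(emit("frequencies.csv"))
        table = assign_parentage(individuals, freqs, config.parentage)
        table = reconstruct_unsampled_parents(table, individuals, freqs,
                                              config.parentage)
        state.update(freqs=freqs, pedigree=table)
        table.to_csv(emit("pedigree.csv"))
        fit = fitness_counts(table)
        with open(emit("fitness.csv"), "w") as fh:
            fh.write("individual_id,offspring_count\n")
            for iid in sorted(fit):
                fh.write(f"{iid},{fit[iid]}\n")
        register("frequencies.csv", "pedigree.csv", "fitness.csv")

    elif stage == "network":
        g = pednet.build_network(state["pedigree"], state["individuals"])
        pednet.validate_familial_invariants(g)
        comps = pednet.connected_components(g)
        state.update(network=g, components=comps)
        pednet.write_graphml(g, emit("network.graphml"))
        pednet.write_edge_list_csv(g, emit("edges.csv"))
        pednet.write_node_table_csv(g, emit("nodes.csv"))
        with open(emit("components.json"), "w") as fh:
            json.dump({"n_components": comps.n_components,
                       "sizes": comps.sizes,
                       "largest_share_pct": comps.largest_share_pct},
                      fh, indent=2)
        register("network.graphml", "edges.csv", "nodes.csv",
                 "components.json")

    elif stage == "centrality":
        g = state["network"]
        if config.centrality_on_primary_component and g.number_of_nodes():
            # node measures are ranked within the primary network; small
            # satellite components would otherwise read as artificially
            # central (eccentricity 0)
            import networkx as nx

            main = max(nx.weakly_connected_components(g), key=len)
            g = g.subgraph(main)
        table = centrality_mod.centrality_table(g, alpha=config.alpha)
        state["centrality"] = table
        table.to_csv(emit("centrality.csv"))
        corr = centrality_mod.centrality_correlations(table)
        corr.to_csv(emit("correlations.csv"))
        pca = centrality_mod.pca_contributions(table)
        pca.contributions.to_csv(emit("pca_contributions.csv"))
        state["pca"] = pca
        register("centrality.csv", "correlations.csv",
                 "pca_contributions.csv")

    elif stage == "community":
        g = state["network"]
        dist = community_mod.betweenness_distribution(g)
        state["distribution"] = dist
        with open(emit("betweenness_distribution.csv"), "w") as fh:
            fh.write("score,count\n")
            for s, c in dist.to_rows():
                fh.write(f"{s},{c}\n")
        trace = community_mod.remove_high_betweenness_edges(
            g, config.removal_threshold, config.removal_mode)
        state["removal"] = trace
        with open(emit("removal_trace.csv"), "w") as fh:
            fh.write("parent_id,offspring_id,score\n")
            for (u, v), s in trace.removed:
                fh.write(f"{u},{v},{s}\n")
        register("betweenness_distribution.csv", "removal_trace.csv")

    elif stage == "spatial":
        individuals = state["individuals"]
        if config.areas_geojson:
            areas = spatial.read_geojson_areas(config.areas_geojson)
            membership = spatial.assign_local_areas(individuals, areas)
        else:  # label-based areas from the samples' strata
            membership = {i.individual_id: i.area for i in individuals
                          if i.area}
        reports = spatial.area_report(state["network"], membership)
        k = min(config.k_areas, len(reports.table) // 2)
        comparison = None
        if k >= 1:
            comparison = spatial.compare_area_groups(
                state["centrality"], membership, reports, k=k)
        else:
            log.warning("too few areas (%d) for group comparison",
                        len(reports.table))
        state.update(membership=membership, area_reports=reports,
                     comparison=comparison)
        reports.to_csv(emit("area_report.csv"))
        register("area_report.csv")
        if comparison is not None:
            comparison.group_summaries.to_csv(emit("group_summaries.csv"),
                                              index=False)
            with open(emit("group_comparison.json"), "w") as fh:
                json.dump({
                    "high_areas": comparison.high_areas,
                    "low_areas": comparison.low_areas,
                    "ratio_centrality_correlations": {
                        m: (None if r != r else round(r, 4))
                        for m, r in comparison.correlations.items()},
                    "undefined": comparison.undefined_correlations,
                }, fh, indent=2, sort_keys=True)
            register("group_summaries.csv", "group_comparison.json")

    elif stage == "report":
        comps = state.get("components")
        dist = state.get("distribution")
        trace = state.get("removal")
        summary = {"n_samples": len(state.get("samples", []))}
        if "individuals" in state:
            summary["n_individuals"] = len(state["individuals"])
        if "qc" in state:
            summary["mean_success_pct"] = state["qc"].mean_success_pct
        if "pedigree" in state:
            summary["n_inferred_parents"] = len(
                state["pedigree"].inferred_parents())
        if comps is not None:
            summary["n_components"] = comps.n_components
            summary["largest_component_share_pct"] = comps.largest_share_pct
        if dist is not None and dist.total_edges:
            at_min, above = community_mod.distribution_summary(
                dist, state.get("removal").threshold if trace else 4.0)
            summary["pct_edges_at_min_score"] = at_min
            summary["pct_edges_above_threshold"] = above
        if trace is not None:
            summary["n_edges_removed"] = trace.n_removed
            summary["final_n_components"] = trace.final_components.n_components
        with open(emit("report.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        register("report.json")
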