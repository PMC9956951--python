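"""End-to-end orchestration: simulate -> extract -> lineage-filter ->
discover -> dedup -> network -> SCULU -> tally, as one seeded, configured,
logged run.

Genomes are analyzed sequentially in a configured order; each lineage's
discovered subfamily consensi are deduplicated against the union of the
prior library and all earlier lineages' contributions, so later genomes
contribute fewer novel subfamilies when activity is shared (the
second-genome effect). Stage outputs are plain FASTA/TSV files so any stage
can be rerun in isolation, and the run report is deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io_formats import (ConsensusRecord, write_consensus_library,
                         write_instances_fasta, write_network)
from .synthetic_data import SimulationConfig, SimulatedData, run_simulation
from .lineage_specificity import PresenceParams, extract_full_length, \
    sequential_filter
from .subfamily_discovery import (apply_arich_mask, filter_n_runs,
                                  partition_subfamilies, stack_to_consensus)
from .library_curation import classify_against_library, tally_lineage_specific
from .network_builder import SubfamilyNetwork, build_network, detect_polytomies
from .sculu import MergePlan, SculuParams, merge_until_stable

logger = logging.getLogger("subfamnet")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; fully serializable to YAML."""

    outdir: str = "run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis_order: list[str] = field(
        default_factory=lambda: ["marmoset", "squirrel", "owl", "capuchin"])
    prior_anchor_nodes: list[str] = field(
        default_factory=lambda: ["AluS_sim", "ta10_sim", "ta15_sim"])
    min_subfamily_size: int = 10
    max_n_run: int = 1
    presence: PresenceParams = field(default_factory=PresenceParams)
    sculu: SculuParams = field(default_factory=SculuParams)

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed
        self.sculu.seed = self.seed

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [clean(v) for v in obj]
            return obj
        return clean(self)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        presence = data.pop("presence", {})
        sculu = data.pop("sculu", {})
        for key in ("polya_range", "arich_region"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        if "scoring" in presence:
            presence.pop("scoring")
        for key in ("mask_region",):
            if key in sculu and sculu[key] is not None:
                sculu[key] = tuple(sculu[key])
        if "scoring" in sculu:
            sculu.pop("scoring")
        return cls(simulation=SimulationConfig(**sim),
                   presence=PresenceParams(**presence),
                   sculu=SculuParams(**sculu), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    outdir: Path
    report: dict
    library: list[ConsensusRecord]
    network: SubfamilyNetwork
    merge_plan: MergePlan
    members: dict[str, str]              # instance id -> final subfamily
    lineage_of: dict[str, str]
    sim: SimulatedData


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and write a deterministic run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    simcfg = config.simulation
    mask = simcfg.arich_region

    sim = _stage("simulate")(run_simulation)(simcfg)
    sim.write(outdir / "sim")

    tree = sim.tree
    root_name = tree.root
    missing_anchor = [n for n in config.prior_anchor_nodes if n not in tree.nodes]
    if missing_anchor:
        raise ValueError(f"prior_anchor_nodes not in subfamily tree: {missing_anchor}")
    if root_name not in config.prior_anchor_nodes:
        raise ValueError("the family root consensus must be a prior anchor")
    library: list[ConsensusRecord] = [
        ConsensusRecord(n, tree.nodes[n].sequence, "repbase",
                        tree.nodes[n].family_group)
        for n in config.prior_anchor_nodes]
    root_record = library[config.prior_anchor_nodes.index(root_name)]
    consensus_lengths = {n: len(tree.nodes[n]) for n in tree.nodes}

    order = config.analysis_order
    unknown = [lg for lg in order if lg not in sim.genomes]
    if unknown:
        raise ValueError(f"analysis_order lineages not simulated: {unknown}")

    members: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    instance_seqs: dict[str, str] = {}
    per_lineage_stats = {}
    group_map: dict[str, str] = {r.name: r.family_group for r in library}

    for lineage in order:
        genome = sim.genomes[lineage]
        elements = _stage(f"extract[{lineage}]")(extract_full_length)(
            sim.hits[lineage], genome, consensus_lengths,
            flank_length=simcfg.flank_length)
        comparisons = [(lg, sim.genomes[lg]) for lg in order if lg != lineage]
        specific, audit = _stage(f"filter[{lineage}]")(sequential_filter)(
            elements, comparisons, config.presence)
        audit.to_csv(outdir / f"audit_{lineage}.tsv", sep="\t", index=False)
        instances = {el.id: el.element_sequence for el in specific}
        kept, removed = filter_n_runs(instances, config.max_n_run)
        logger.info("%s: %d full-length, %d lineage-specific, %d after N filter",
                    lineage, len(elements), len(specific), len(kept))
        write_instances_fasta(kept, outdir / f"specific_{lineage}.fa")
        instance_seqs.update(kept)

        stacked = _stage(f"coseg[{lineage}]")(stack_to_consensus)(
            kept, root_record)
        apply_arich_mask(stacked, mask)
        clusters = _stage(f"coseg[{lineage}]")(partition_subfamilies)(
            stacked, config.min_subfamily_size)
        candidates = [
            ConsensusRecord(f"{c.name}_{lineage}", c.consensus.sequence,
                            lineage, "other")
            for c in clusters]
        report = _stage(f"dedup[{lineage}]")(classify_against_library)(
            candidates, library, mask_region=mask)
        report.table.to_csv(outdir / f"dedup_{lineage}.tsv",
                            sep="\t", index=False)
        novel = report.final_library
        library.extend(novel)
        for rec in novel:
            group_map[rec.name] = rec.family_group
        for cluster in clusters:
            final_name = report.name_map[f"{cluster.name}_{lineage}"]
            for iid in cluster.member_ids:
                members[iid] = final_name
                lineage_of[iid] = lineage
        per_lineage_stats[lineage] = {
            "full_length": len(elements),
            "lineage_specific": len(specific),
            "n_filtered": len(removed),
            "clusters": len(clusters),
            "novel_subfamilies": len(novel),
        }

    write_consensus_library(library, outdir / "library.fa")

    network = _stage("network")(build_network)(
        library, root_name, mask_region=mask)
    for fmt in ("tsv", "dot", "graphml"):
        write_network(network, outdir / f"network.{fmt}", fmt)
    polytomies = detect_polytomies(network)

    # SCULU over the final library entries that have annotated instances
    inst_by_subfam: dict[str, dict[str, str]] = {}
    for iid, sf in members.items():
        inst_by_subfam.setdefault(sf, {})[iid] = instance_seqs[iid]
    sculu_names = [r for r in library if r.name in inst_by_subfam]
    passthrough = [r.name for r in library if r.name not in inst_by_subfam]
    plan = _stage("sculu")(merge_until_stable)(
        sculu_names, inst_by_subfam, config.sculu)
    with (outdir / "sculu_plan.tsv").open("w") as fh:
        fh.write("old_name\tnew_name\n")
        for old in sorted(plan.name_map):
            fh.write(f"{old}\t{plan.name_map[old]}\n")

    by_group, by_subfamily = _stage("tally")(tally_lineage_specific)(
        members, lineage_of, group_map)
    by_group.to_csv(outdir / "tally_by_group.tsv", sep="\t")
    by_subfamily.to_csv(outdir / "tally_by_subfamily.tsv", sep="\t")

    report_dict = {
        "seed": config.seed,
        "analysis_order": order,
        "per_lineage": per_lineage_stats,
        "novel_subfamily_counts": [
            per_lineage_stats[lg]["novel_subfamilies"] for lg in order],
        "library_size": len(library),
        "network": {
            "n_nodes": len(network.nodes),
            "n_edges": len(network.edges),
            "n_polytomies": len(polytomies),
            "excluded": network.excluded,
        },
        "sculu": {
            "n_groups": len(plan.groups) + len(passthrough),
            "n_merged_groups": sum(1 for g in plan.groups if len(g) > 1),
            "unmerged": sorted(
                [g[0] for g in plan.groups if len(g) == 1] + passthrough),
            "iterations": plan.n_iterations,
        },
        "tally_by_group": {
            lg: {col: int(by_group.loc[lg, col]) for col in by_group.columns}
            for lg in by_group.index},
        "config": config.to_dict(),
    }
    with (outdir / "report.json").open("w") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", outdir)
    return RunResult(outdir=outdir, report=report_dict, library=library,
                     network=network, merge_plan=plan, members=members,
                     lineage_of=lineage_of, sim=sim)
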