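"""Synthetic SINE expansion data with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a small
species tree whose genomes carry full-length ~300-nt SINE copies with 600-nt
flanks; a nested subfamily tree defined by inherited diagnostic
substitutions planted outside a middle A-rich region; per-copy background
divergence; poly-A tails; occasional N-run contamination; and a fraction of
insertions on internal species-tree branches left polymorphic across
descendant lineages (incomplete lineage sorting).

Everything is drawn from one seeded generator in a documented order
(subfamily tree first, then insertion events in subfamily-preorder /
branch-preorder / copy-index order), so an identical seed yields bytewise
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .io_formats import (ConsensusRecord, RepeatHitRecord,
                         write_bed, write_genome_fasta,
                         write_instances_fasta, write_repeat_table,
                         write_consensus_library)
from .lineage_specificity import FlankedElement

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Species tree (tiny rooted topology; a branch is named by its child node)
# ---------------------------------------------------------------------------

def default_species_tree() -> dict:
    """Four platyrrhine-style lineages, two cherries."""
    return {
        "name": "root",
        "children": [
            {"name": "anc_callithrichidae_aotidae",
             "children": [{"name": "marmoset"}, {"name": "owl"}]},
            {"name": "anc_cebidae",
             "children": [{"name": "capuchin"}, {"name": "squirrel"}]},
        ],
    }


def tree_preorder(node: dict) -> Iterator[dict]:
    yield node
    for child in node.get("children", []):
        yield from tree_preorder(child)


def tree_tips(node: dict) -> list[str]:
    return [n["name"] for n in tree_preorder(node) if not n.get("children")]


def tree_descendants(tree: dict, name: str) -> list[str]:
    """Tip lineages below (and including) the node called ``name``."""
    for node in tree_preorder(tree):
        if node["name"] == name:
            return tree_tips(node)
    raise KeyError(f"no species-tree node named {name!r}")


def tree_clades(tree: dict) -> set[frozenset[str]]:
    return {frozenset(tree_tips(n)) for n in tree_preorder(tree)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_subfamily_tree_spec() -> dict:
    """A five-node chain from the family consensus to a young burst subfamily.

    Mirrors the J/S -> Sc -> Ta10 -> Ta15 ancestry shape, with the youngest
    (Ta15-like) branch configured as the expansion burst.
    """
    return {
        "name": "AluS_sim", "family_group": "S",
        "children": [{
            "name": "sc_sim", "mutations": 3, "family_group": "S",
            "children": [{
                "name": "ta10_sim", "mutations": 4, "family_group": "Ta10",
                "children": [{
                    "name": "ta15_sim", "mutations": 4, "family_group": "Ta15",
                    "children": [{
                        "name": "ta15a_sim", "mutations": 3,
                        "family_group": "Ta15", "children": [],
                    }],
                }],
            }],
        }],
    }


def default_copies() -> dict[str, dict[str, int]]:
    """Copies per subfamily per species-tree branch (branch = child node name).

    Tip-branch copies are lineage-specific; internal-branch copies are shared
    by the branch's descendants. The Ta15-like subfamilies carry the majority
    of lineage-specific copies in every lineage (the burst pattern).
    """
    tips = ["marmoset", "owl", "capuchin", "squirrel"]
    internals = ["anc_callithrichidae_aotidae", "anc_cebidae"]
    copies: dict[str, dict[str, int]] = {
        "AluS_sim": {t: 10 for t in tips} | {"root": 5},
        "sc_sim": {t: 15 for t in tips},
        "ta10_sim": {t: 15 for t in tips} | {b: 5 for b in internals},
        "ta15_sim": {t: 60 for t in tips} | {b: 5 for b in internals},
        "ta15a_sim": {t: 30 for t in tips},
    }
    return copies


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the package's study conditions.

    ``copies`` maps subfamily name -> species-tree branch -> copy count;
    counts on tip branches are the planted lineage-specific insertions.
    ``background_divergence`` is substitutions per site per copy;
    ``polya_range`` is the (inclusive) uniform range of poly-A tail lengths;
    ``ils_fraction`` is the fraction of internal-branch insertions left
    polymorphic across the branch's descendant lineages.
    """

    consensus_length: int = 300
    species_tree: dict = field(default_factory=default_species_tree)
    subfamily_tree_spec: dict = field(default_factory=default_subfamily_tree_spec)
    copies: dict = field(default_factory=default_copies)
    background_divergence: float = 0.02
    polya_range: tuple[int, int] = (5, 50)
    n_contamination_prob: float = 0.02
    n_run_length: int = 10
    ils_fraction: float = 0.1
    flank_length: int = 600
    arich_region: tuple[int, int] = (130, 150)
    kappa: float | None = None          # transition/transversion bias; None = uniform
    indel_rate: float = 0.0             # per-site indel probability in copies
    spacer_length: int = 50
    seed: int = 0

    @property
    def lineages(self) -> list[str]:
        return tree_tips(self.species_tree)

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def validate(self) -> None:
        for p, label in [(self.background_divergence, "background_divergence"),
                         (self.n_contamination_prob, "n_contamination_prob"),
                         (self.ils_fraction, "ils_fraction"),
                         (self.indel_rate, "indel_rate")]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{label} must lie in [0, 1], got {p}")
        if self.consensus_length <= 0 or self.flank_length < 0:
            raise ValueError("lengths must be positive")
        s, e = self.arich_region
        if not (0 <= s <= e <= self.consensus_length):
            raise ValueError("arich_region outside the consensus")
        branches = {n["name"] for n in tree_preorder(self.species_tree)}
        for sf, per_branch in self.copies.items():
            for branch, count in per_branch.items():
                if branch not in branches:
                    raise ValueError(f"copies[{sf!r}]: unknown branch {branch!r}")
                if count < 0:
                    raise ValueError("copy counts must be non-negative")


# ---------------------------------------------------------------------------
# Subfamily tree
# ---------------------------------------------------------------------------

@dataclass
class SubfamilyTreeTruth:
    """Planted subfamily consensi plus their diagnostic substitutions.

    ``diagnostics[name]`` is the inherited list of (column, ancestral base,
    derived base) from the root down to that node — a node carries the union
    of its ancestors' diagnostic substitutions plus its own.
    """

    nodes: dict[str, ConsensusRecord]
    edges: list[tuple[str, str, int]]           # (parent, child, mutation_count)
    diagnostics: dict[str, list[tuple[int, str, str]]]
    root: str

    def preorder(self) -> list[str]:
        order = [self.root]
        children: dict[str, list[str]] = {}
        for p, c, _ in self.edges:
            children.setdefault(p, []).append(c)
        i = 0
        while i < len(order):
            order[i:i + 1] = [order[i]] + children.get(order[i], [])
            i += 1
        return order


def simulate_subfamily_tree(config: SimulationConfig,
                            rng: np.random.Generator | None = None
                            ) -> SubfamilyTreeTruth:
    """Plant a subfamily tree by accumulating inherited diagnostic substitutions.

    The root consensus is uniform over {A,C,G,T} except for a planted A-run
    over ``arich_region``; each child differs from its parent at exactly the
    requested number of unmasked, previously unmutated positions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.consensus_length
    s, e = config.arich_region
    root_seq = BASES[rng.integers(0, 4, size=L)]
    root_seq[s:e] = "A"

    spec_root = config.subfamily_tree_spec
    nodes: dict[str, ConsensusRecord] = {}
    edges: list[tuple[str, str, int]] = []
    diagnostics: dict[str, list[tuple[int, str, str]]] = {}
    masked = set(range(s, e))

    def visit(spec_node: dict, parent_seq: np.ndarray,
              parent_name: str | None, path_diag: list) -> None:
        name = spec_node["name"]
        if name in nodes:
            raise ValueError(f"duplicate subfamily name {name!r} in tree spec")
        if parent_name is None:
            seq = parent_seq.copy()
            own: list[tuple[int, str, str]] = []
        else:
            m = int(spec_node["mutations"])
            used = {pos for pos, _, _ in path_diag}
            avail = sorted(set(range(L)) - masked - used)
            if m > len(avail):
                raise ValueError(
                    f"subfamily {name!r}: requested {m} diagnostic mutations but "
                    f"only {len(avail)} unmasked unmutated positions remain")
            cols = rng.choice(len(avail), size=m, replace=False)
            seq = parent_seq.copy()
            own = []
            for ci in sorted(int(c) for c in cols):
                pos = avail[ci]
                old = str(seq[pos])
                alt = [b for b in "ACGT" if b != old]
                seq[pos] = alt[int(rng.integers(0, 3))]
                own.append((pos, old, str(seq[pos])))
            edges.append((parent_name, name, m))
        diagnostics[name] = path_diag + own
        nodes[name] = ConsensusRecord(
            name, "".join(seq), source_lineage="sim",
            family_group=spec_node.get("family_group", "other"))
        for child in spec_node.get("children", []):
            visit(child, seq, name, diagnostics[name])

    visit(spec_root, root_seq, None, [])
    return SubfamilyTreeTruth(nodes=nodes, edges=edges,
                              diagnostics=diagnostics, root=spec_root["name"])


# ---------------------------------------------------------------------------
# Genomes, elements and truth table
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    genomes: dict[str, dict[str, str]]          # lineage -> contig -> sequence
    hits: dict[str, list[RepeatHitRecord]]      # lineage -> repeat hits
    elements: dict[str, list[FlankedElement]]   # lineage -> flanked copies
    truth: pd.DataFrame
    tree: SubfamilyTreeTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lineage, genome in self.genomes.items():
            write_genome_fasta(genome, outdir / f"genome_{lineage}.fa")
            write_repeat_table(self.hits[lineage], outdir / f"hits_{lineage}.tsv")
            write_bed(self.hits[lineage], outdir / f"hits_{lineage}.bed")
            write_instances_fasta(
                {el.id: el.element_sequence for el in self.elements[lineage]},
                outdir / f"elements_{lineage}.fa")
        write_consensus_library(list(self.tree.nodes.values()),
                                outdir / "true_subfamilies.fa")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(seq: str, divergence: float, rng: np.random.Generator,
            kappa: float | None) -> tuple[str, list[int]]:
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < divergence)
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for pos in hit:
        old = arr[pos]
        alts = [b for b in "ACGT" if b != old]
        if kappa is None:
            arr[pos] = alts[int(rng.integers(0, 3))]
        else:
            w = np.array([kappa if b == transitions[old] else 1.0 for b in alts])
            arr[pos] = rng.choice(alts, p=w / w.sum())
    return "".join(arr), [int(p) for p in hit]


def _ils_subset(descendants: list[str], clades: set[frozenset[str]],
                rng: np.random.Generator) -> list[str]:
    """Random nonempty proper subset of the descendants, preferring one that
    is not itself a clade of the species tree (possible only with >= 3
    descendants; two-tip branches fall back to a single-tip subset)."""
    for _ in range(50):
        mask = rng.random(len(descendants)) < 0.5
        subset = [d for d, m in zip(descendants, mask) if m]
        if 0 < len(subset) < len(descendants) and frozenset(subset) not in clades:
            return subset
    keep = int(rng.integers(0, len(descendants)))
    return [descendants[keep]]


def simulate_genomes(tree: SubfamilyTreeTruth, config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SimulatedData:
    """Instantiate insertion events on the species tree and emit genomes.

    Each copy is its subfamily consensus with Bernoulli background
    substitutions, a sampled poly-A tail and an optional N-run; orthologous
    insertions share identical flanks (and copy sequence) across carrier
    lineages, and every insertion locus — filled or empty — is present in
    every genome, so flank-anchored presence checks can see empty sites.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lineages = config.lineages
    clades = tree_clades(config.species_tree)
    L = config.consensus_length

    events = []
    counter = 0
    branch_order = [n["name"] for n in tree_preorder(config.species_tree)]
    for sf in tree.preorder():
        per_branch = config.copies.get(sf, {})
        for branch in branch_order:
            descendants = tree_descendants(config.species_tree, branch)
            for _ in range(int(per_branch.get(branch, 0))):
                eid = f"ev{counter:05d}"
                counter += 1
                copy_seq, mut_pos = _mutate(tree.nodes[sf].sequence,
                                            config.background_divergence,
                                            rng, config.kappa)
                if config.indel_rate > 0:
                    copy_seq = _apply_indels(copy_seq, config.indel_rate, rng)
                lo, hi = config.polya_range
                tail = int(rng.integers(lo, hi + 1)) if hi >= lo and hi > 0 else 0
                copy_seq += "A" * tail
                has_n = False
                if config.n_contamination_prob > 0 and \
                        rng.random() < config.n_contamination_prob and \
                        len(copy_seq) > config.n_run_length:
                    start = int(rng.integers(0, len(copy_seq) - config.n_run_length))
                    copy_seq = (copy_seq[:start] + "N" * config.n_run_length
                                + copy_seq[start + config.n_run_length:])
                    has_n = True
                is_internal = len(descendants) > 1
                ils = bool(is_internal and rng.random() < config.ils_fraction)
                present = (_ils_subset(descendants, clades, rng)
                           if ils else list(descendants))
                left = _random_seq(rng, config.flank_length)
                right = _random_seq(rng, config.flank_length)
                spacer = _random_seq(rng, config.spacer_length)
                events.append({
                    "id": eid, "subfamily": sf, "branch": branch,
                    "copy": copy_seq, "left": left, "right": right,
                    "spacer": spacer, "present": present, "ils": ils,
                    "mut_pos": mut_pos, "polya_len": tail, "has_n_run": has_n,
                })

    genomes: dict[str, dict[str, str]] = {}
    hits: dict[str, list[RepeatHitRecord]] = {lg: [] for lg in lineages}
    elements: dict[str, list[FlankedElement]] = {lg: [] for lg in lineages}
    for lineage in lineages:
        contig = f"chr_{lineage}"
        parts: list[str] = []
        offset = 0
        for ev in events:
            present = lineage in ev["present"]
            parts.append(ev["left"])
            offset += len(ev["left"])
            if present:
                start, end = offset, offset + len(ev["copy"])
                parts.append(ev["copy"])
                offset = end
                n_sub = len(ev["mut_pos"])
                hits[lineage].append(RepeatHitRecord(
                    contig=contig, start=start, end=end, strand="+",
                    consensus_name=ev["subfamily"],
                    percent_divergence=round(100.0 * n_sub / L, 2),
                    consensus_span=(1, L)))
                elements[lineage].append(FlankedElement(
                    id=f"{ev['id']}_{lineage}",
                    element_sequence=ev["copy"],
                    left_flank=ev["left"], right_flank=ev["right"],
                    genome=lineage, contig=contig,
                    start=start, end=end, strand="+"))
            parts.append(ev["right"])
            offset += len(ev["right"])
            parts.append(ev["spacer"])
            offset += len(ev["spacer"])
        genomes[lineage] = {contig: "".join(parts)}

    rows = []
    for ev in events:
        row = {
            "instance_id": ev["id"], "subfamily": ev["subfamily"],
            "branch": ev["branch"], "ils": ev["ils"],
            "n_background_mutations": len(ev["mut_pos"]),
            "mutation_positions": ";".join(map(str, ev["mut_pos"])),
            "polya_len": ev["polya_len"], "has_n_run": ev["has_n_run"],
        }
        for lg in lineages:
            row[f"present_{lg}"] = lg in ev["present"]
        rows.append(row)
    truth = pd.DataFrame(rows)
    return SimulatedData(genomes=genomes, hits=hits, elements=elements,
                         truth=truth, tree=tree)


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue                              # deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append(str(BASES[int(rng.integers(0, 4))]))  # insertion
    return "".join(out)


def run_simulation(config: SimulationConfig) -> SimulatedData:
    """Simulate the subfamily tree and the genomes from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_subfamily_tree(config, rng)
    return simulate_genomes(tree, config, rng)
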