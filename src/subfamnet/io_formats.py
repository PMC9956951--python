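"""External representations and shared domain vocabulary.

All internal coordinates are 0-based half-open; all emitted tables are
1-based inclusive. FASTA output is wrapped at 60 columns; unwrapped input
is accepted. Consensus sequences may contain IUPAC ambiguity codes
(consensus building can emit them); instance sequences may not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

FAMILY_GROUPS = ("J", "S", "Ta7", "Ta10", "Ta15", "other")

# Strict instance alphabet vs. the consensus alphabet (adds IUPAC ambiguity).
INSTANCE_ALPHABET = frozenset("ACGTN")
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHV")
CONSENSUS_ALPHABET = INSTANCE_ALPHABET | IUPAC_AMBIGUITY

_FASTA_WRAP = 60


class DuplicateNameError(ValueError):
    """Two records in one library share a name."""


@dataclass
class ConsensusRecord:
    """A named subfamily consensus with provenance tags.

    ``source_lineage`` records the genome of discovery (e.g. "marmoset",
    "owl", "ceb", "repbase", "sim"); ``family_group`` places the subfamily
    in one of the major family branches (J / S / Ta7 / Ta10 / Ta15 / other).
    """

    name: str
    sequence: str
    source_lineage: str = "sim"
    family_group: str = "other"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("consensus record needs a non-empty name")
        if not self.sequence:
            raise ValueError(f"consensus {self.name!r}: empty sequence")
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - CONSENSUS_ALPHABET
        if bad:
            raise ValueError(
                f"consensus {self.name!r}: illegal characters {sorted(bad)}")
        self.sequence = seq
        if self.family_group not in FAMILY_GROUPS:
            raise ValueError(
                f"consensus {self.name!r}: unknown family group "
                f"{self.family_group!r} (expected one of {FAMILY_GROUPS})")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatHitRecord:
    """One repeat-annotation hit (RepeatMasker-style, in a clean TSV schema).

    Coordinates are 0-based half-open on the contig; ``consensus_span`` is
    (first, last) matched consensus positions, 1-based inclusive, with
    first <= last regardless of strand.
    """

    contig: str
    start: int
    end: int
    strand: str
    consensus_name: str
    percent_divergence: float
    consensus_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"hit {self.contig}:{self.start}-{self.end}: need 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not (0.0 <= self.percent_divergence <= 100.0):
            raise ValueError("percent_divergence outside [0, 100]")
        first, last = self.consensus_span
        if first > last:  # minus-strand spans are normalized on read
            self.consensus_span = (last, first)
        if self.consensus_span[0] < 1:
            raise ValueError("consensus_span is 1-based; first position >= 1")


@dataclass(frozen=True)
class NetworkEdgeRecord:
    """Parent -> child subfamily edge labeled with its diagnostic-mutation count."""

    parent: str
    child: str
    mutation_count: int

    def __post_init__(self) -> None:
        if self.parent != self.child and self.mutation_count < 1:
            raise ValueError(
                f"edge {self.parent}->{self.child}: mutation_count must be >= 1 "
                "for distinct subfamilies (exact duplicates are removed upstream)")
        if self.mutation_count < 0:
            raise ValueError("mutation_count must be non-negative")


# ---------------------------------------------------------------------------
# FASTA consensus libraries
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str, str]:
    """Parse '>name [source_lineage] [family_group]'; bracketed tags optional."""
    parts = header.split()
    name = parts[0]
    tags = [p[1:-1] for p in parts[1:] if p.startswith("[") and p.endswith("]")]
    lineage = tags[0] if len(tags) >= 1 else "sim"
    group = tags[1] if len(tags) >= 2 else "other"
    return name, lineage, group


def read_consensus_library(path: str | Path) -> list[ConsensusRecord]:
    """Read a FASTA consensus library.

    Lowercase is uppercased, U mapped to T; characters outside the consensus
    alphabet are rejected; duplicate names are a hard error.
    """
    path = Path(path)
    records: list[ConsensusRecord] = []
    seen: set[str] = set()
    name = lineage = group = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal name
        if name is None:
            return
        if name in seen:
            raise DuplicateNameError(f"duplicate record name {name!r} in {path}")
        seen.add(name)
        records.append(ConsensusRecord(name, "".join(chunks), lineage, group))

    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, lineage, group = _parse_header(line[1:])
                chunks = []
            else:
                chunks.append(line)
    flush()
    if not records:
        warnings.warn(f"empty consensus library: {path}")
    return records


def write_consensus_library(records: Sequence[ConsensusRecord],
                            path: str | Path) -> None:
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise DuplicateNameError(f"duplicate record name(s) {dup}")
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.name} [{rec.source_lineage}] [{rec.family_group}]\n")
            for i in range(0, len(rec.sequence), _FASTA_WRAP):
                fh.write(rec.sequence[i:i + _FASTA_WRAP] + "\n")


def read_instances_fasta(path: str | Path) -> dict[str, str]:
    """Read instance sequences (strict {A,C,G,T,N} alphabet) as id -> sequence."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        bad = set(seq) - INSTANCE_ALPHABET
        if bad:
            raise ValueError(f"instance {name!r}: illegal characters {sorted(bad)}")
        if name in out:
            raise DuplicateNameError(f"duplicate instance id {name!r}")
        out[name] = seq

    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    flush()
    return out


def write_instances_fasta(instances: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for iid, seq in instances.items():
            fh.write(f">{iid}\n")
            for i in range(0, len(seq), _FASTA_WRAP):
                fh.write(seq[i:i + _FASTA_WRAP] + "\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA as contig -> sequence (uppercased)."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks).upper()
    return out


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), _FASTA_WRAP):
                fh.write(seq[i:i + _FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# Repeat-hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ["contig", "start", "end", "strand", "consensus_name",
                "percent_divergence", "cons_start", "cons_end"]


def read_repeat_table(path: str | Path) -> list[RepeatHitRecord]:
    """Read a TSV repeat-hit table (1-based inclusive coordinates on disk).

    Contig coordinates are converted to 0-based half-open; minus-strand
    consensus spans are normalized so first <= last.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    hits: list[RepeatHitRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        start = int(row.start) - 1          # 1-based inclusive -> 0-based half-open
        end = int(row.end)
        if start >= end:
            raise ValueError(f"{path} line {lineno}: start > end after conversion")
        strand = str(row.strand)
        if strand not in ("+", "-"):
            raise ValueError(f"{path} line {lineno}: unknown strand {strand!r}")
        cfirst, clast = int(row.cons_start), int(row.cons_end)
        if cfirst > clast:
            cfirst, clast = clast, cfirst
        hits.append(RepeatHitRecord(
            contig=str(row.contig), start=start, end=end, strand=strand,
            consensus_name=str(row.consensus_name),
            percent_divergence=float(row.percent_divergence),
            consensus_span=(cfirst, clast)))
    return hits


def write_repeat_table(hits: Iterable[RepeatHitRecord], path: str | Path) -> None:
    rows = [{
        "contig": h.contig,
        "start": h.start + 1,               # back to 1-based inclusive
        "end": h.end,
        "strand": h.strand,
        "consensus_name": h.consensus_name,
        "percent_divergence": h.percent_divergence,
        "cons_start": h.consensus_span[0],
        "cons_end": h.consensus_span[1],
    } for h in hits]
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_bed(hits: Iterable[RepeatHitRecord], path: str | Path) -> None:
    """BED6 (0-based half-open, as BED requires)."""
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\t{h.consensus_name}\t"
                     f"{h.percent_divergence:g}\t{h.strand}\n")


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("tsv", "dot", "graphml")


def _network_graph(network) -> nx.DiGraph:
    g = nx.DiGraph()
    for rec in network.nodes.values():
        g.add_node(rec.name, source_lineage=rec.source_lineage,
                   family_group=rec.family_group, sequence=rec.sequence,
                   is_root=(rec.name == network.root))
    for e in network.edges:
        g.add_edge(e.parent, e.child, mutation_count=e.mutation_count,
                   label=str(e.mutation_count))
    return g


def write_network(network, path: str | Path, fmt: str = "tsv") -> None:
    """Serialize a subfamily network as edge-TSV, DOT or GraphML.

    The TSV carries node records in ``# node`` comment lines so the file
    round-trips (``read_network_tsv``); DOT/GraphML label edges with the
    mutation count and attach lineage/group node attributes.
    """
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; expected {NETWORK_FORMATS}")
    path = Path(path)
    if fmt == "tsv":
        with path.open("w") as fh:
            fh.write(f"# root\t{network.root}\n")
            for rec in network.nodes.values():
                fh.write(f"# node\t{rec.name}\t{rec.source_lineage}\t"
                         f"{rec.family_group}\t{rec.sequence}\n")
            fh.write("parent\tchild\tmutation_count\n")
            for e in network.edges:
                fh.write(f"{e.parent}\t{e.child}\t{e.mutation_count}\n")
    elif fmt == "dot":
        with path.open("w") as fh:
            fh.write("digraph subfamilies {\n")
            for rec in network.nodes.values():
                fh.write(f'  "{rec.name}" [lineage="{rec.source_lineage}", '
                         f'group="{rec.family_group}"];\n')
            for e in network.edges:
                fh.write(f'  "{e.parent}" -> "{e.child}" '
                         f'[label="{e.mutation_count}"];\n')
            fh.write("}\n")
    else:
        nx.write_graphml(_network_graph(network), path)


def read_network_tsv(path: str | Path):
    """Rebuild (nodes, edges, root) from an edge-TSV written by write_network."""
    nodes: dict[str, ConsensusRecord] = {}
    edges: list[NetworkEdgeRecord] = []
    root = None
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# root\t"):
                root = line.split("\t")[1]
            elif line.startswith("# node\t"):
                _, name, lineage, group, seq = line.split("\t")
                nodes[name] = ConsensusRecord(name, seq, lineage, group)
            elif line.startswith("parent\t"):
                continue
            else:
                parent, child, count = line.split("\t")
                edges.append(NetworkEdgeRecord(parent, child, int(count)))
    if root is None:
        raise ValueError(f"{path}: no root record")
    return nodes, edges, root
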