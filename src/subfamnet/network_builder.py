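"""Subfamily network by stepwise accumulation of diagnostic mutations.

Every non-root subfamily is attached to the candidate parent minimizing its
diagnostic distance (substitution count under the shared alignment scoring,
excluding the A-rich mask and end gaps; internal indel runs count as one
event each). Candidate parents are nodes of strictly older age rank — by
default the iterated distance to the family root — so the result is a DAG.
Ties on distance attach to the candidate closest to the root; remaining
ties are recorded as a polytomy (multiple parent edges), mirroring the
unresolved multifurcations seen when subfamilies differ by single
uniquely-variable substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ._pairwise import Scoring, DEFAULT_SCORING, align_pair
from .io_formats import ConsensusRecord, NetworkEdgeRecord


class FamilyMismatchError(ValueError):
    """Two sequences align below the identity floor — not the same family."""


@dataclass
class SubfamilyNetwork:
    nodes: dict[str, ConsensusRecord]
    edges: list[NetworkEdgeRecord]
    root: str
    polytomy_children: set[str] = field(default_factory=set)  # multi-parent nodes
    excluded: list[str] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for rec in self.nodes.values():
            g.add_node(rec.name, source_lineage=rec.source_lineage,
                       family_group=rec.family_group)
        for e in self.edges:
            g.add_edge(e.parent, e.child, mutation_count=e.mutation_count)
        return g

    def parents_of(self, name: str) -> list[NetworkEdgeRecord]:
        return [e for e in self.edges if e.child == name]

    def children_of(self, name: str) -> list[NetworkEdgeRecord]:
        return [e for e in self.edges if e.parent == name]

    def validate(self, mask_region=None, indel_mode: str = "run",
                 scoring: Scoring = DEFAULT_SCORING) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("subfamily network contains a cycle")
        for name in self.nodes:
            if name != self.root and not self.parents_of(name):
                raise ValueError(f"non-root node {name!r} has no parent edge")
        for e in self.edges:
            d = diagnostic_distance(self.nodes[e.parent], self.nodes[e.child],
                                    mask_region=mask_region,
                                    indel_mode=indel_mode, scoring=scoring)
            if d != e.mutation_count:
                raise ValueError(
                    f"edge {e.parent}->{e.child} labeled {e.mutation_count} "
                    f"but recomputed distance is {d}")


def diagnostic_distance(a: ConsensusRecord, b: ConsensusRecord,
                        mask_region: tuple[int, int] | None = None,
                        indel_mode: str = "run",
                        min_identity: float = 0.5,
                        scoring: Scoring = DEFAULT_SCORING) -> int:
    """Mutation count between two consensi under the shared alignment scoring.

    Substituted columns are counted excluding the A-rich ``mask_region``
    (in ``a``'s coordinates) and excluding end gaps; internal indel runs
    count as one event each (``indel_mode``: "run", "column" or "ignore").
    Raises :class:`FamilyMismatchError` below ``min_identity``.
    """
    if indel_mode not in ("run", "column", "ignore"):
        raise ValueError(f"unknown indel_mode {indel_mode!r}")
    aln = align_pair(a.sequence, b.sequence, scoring, mode="glocal")
    ident = aln.identity()
    if ident < min_identity:
        raise FamilyMismatchError(
            f"{a.name} vs {b.name}: identity {ident:.2f} < {min_identity}; "
            "not members of the same family")
    s, e = mask_region if mask_region else (0, 0)
    cols = list(aln.walk())
    sub_idx = [i for i, (t, q) in enumerate(cols) if t is not None and q is not None]
    if not sub_idx:
        raise FamilyMismatchError(f"{a.name} vs {b.name}: nothing aligned")
    first, last = sub_idx[0], sub_idx[-1]
    count = 0
    in_gap = False
    for i in range(first, last + 1):
        t, q = cols[i]
        if t is None or q is None:                      # internal indel column
            masked = t is not None and mask_region and s <= t < e
            if indel_mode == "column" and not masked:
                count += 1
            elif indel_mode == "run" and not in_gap and not masked:
                count += 1
            in_gap = True
            continue
        in_gap = False
        if mask_region and s <= t < e:
            continue
        if a.sequence[t] != b.sequence[q]:
            count += 1
    return count


def build_network(library: list[ConsensusRecord], root_name: str,
                  age_rank: dict[str, int] | None = None,
                  mask_region: tuple[int, int] | None = None,
                  indel_mode: str = "run",
                  scoring: Scoring = DEFAULT_SCORING,
                  max_refine_iterations: int = 5) -> SubfamilyNetwork:
    """Attach every subfamily to its nearest older candidate parent.

    Age rank defaults to the distance to the root, refined iteratively (the
    rank becomes the path length from the root through chosen parents) until
    attachments are stable. Nodes that cannot be aligned to any candidate
    are excluded and reported.
    """
    names = [r.name for r in library]
    if root_name not in names:
        raise ValueError(f"root {root_name!r} not in library")
    if len(set(names)) != len(names):
        raise ValueError("library contains duplicate names; curate it first")
    nodes = {r.name: r for r in library}

    dist: dict[tuple[str, str], int | None] = {}

    def d(x: str, y: str) -> int | None:
        key = (x, y) if x <= y else (y, x)
        if key not in dist:
            try:
                dist[key] = diagnostic_distance(
                    nodes[key[0]], nodes[key[1]], mask_region=mask_region,
                    indel_mode=indel_mode, scoring=scoring)
            except FamilyMismatchError:
                dist[key] = None
        return dist[key]

    rank: dict[str, int | None] = {root_name: 0}
    excluded: list[str] = []
    for name in names:
        if name == root_name:
            continue
        rank[name] = d(root_name, name)
        if rank[name] is None:
            excluded.append(name)
    active = [n for n in names if rank.get(n) is not None]

    parents: dict[str, list[tuple[str, int]]] = {}
    for _ in range(max_refine_iterations):
        new_parents: dict[str, list[tuple[str, int]]] = {}
        for name in active:
            if name == root_name:
                continue
            candidates = [c for c in active
                          if c != name and (c == root_name
                                            or rank[c] < rank[name])]
            scored = []
            for c in candidates:
                dd = d(c, name)
                if dd is not None:
                    scored.append((dd, rank[c], c))
            if not scored:
                if name not in excluded:
                    excluded.append(name)
                continue
            scored.sort()
            best_d, best_rank, _ = scored[0]
            ties = [(dd, rk, c) for dd, rk, c in scored
                    if dd == best_d and rk == best_rank]
            new_parents[name] = sorted((c, dd) for dd, rk, c in ties)
        new_rank = {root_name: 0}
        changed = False
        for name in active:
            if name == root_name or name not in new_parents:
                new_rank[name] = rank[name]
                continue
            parent, dd = new_parents[name][0]
            r = (new_rank.get(parent, rank[parent]) or 0) + dd \
                if parent != root_name else dd
            new_rank[name] = r
        if new_parents == parents and new_rank == rank:
            break
        parents, rank = new_parents, new_rank

    edges: list[NetworkEdgeRecord] = []
    polytomy_children: set[str] = set()
    for name in sorted(parents):
        plist = parents[name]
        if len(plist) > 1:
            polytomy_children.add(name)
        for parent, dd in plist:
            edges.append(NetworkEdgeRecord(parent, name, dd))
    active_nodes = {n: nodes[n] for n in active if n not in excluded or n == root_name}
    return SubfamilyNetwork(nodes=active_nodes, edges=edges, root=root_name,
                            polytomy_children=polytomy_children,
                            excluded=sorted(set(excluded)))


@dataclass(frozen=True)
class Polytomy:
    kind: str                      # "equal_children" or "multiple_parents"
    center: str                    # the parent (or the multi-parent child)
    members: tuple[str, ...]
    mutation_count: int


def detect_polytomies(network: SubfamilyNetwork) -> list[Polytomy]:
    """Parents with >= 2 equally distant children, plus multi-parent nodes."""
    out: list[Polytomy] = []
    by_parent: dict[str, dict[int, list[str]]] = {}
    by_child: dict[str, list[NetworkEdgeRecord]] = {}
    for e in network.edges:
        by_parent.setdefault(e.parent, {}).setdefault(
            e.mutation_count, []).append(e.child)
        by_child.setdefault(e.child, []).append(e)
    for parent in sorted(by_parent):
        for count in sorted(by_parent[parent]):
            children = sorted(by_parent[parent][count])
            if len(children) >= 2:
                out.append(Polytomy("equal_children", parent,
                                    tuple(children), count))
    for child in sorted(by_child):
        edges = by_child[child]
        if len(edges) >= 2:
            out.append(Polytomy("multiple_parents", child,
                                tuple(sorted(e.parent for e in edges)),
                                edges[0].mutation_count))
    return out
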