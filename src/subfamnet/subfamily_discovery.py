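"""Subfamily discovery from co-segregating mutations.

Lineage-specific instances are stacked into the coordinate system of a
family consensus, a middle A-rich region is masked out, and instances are
partitioned into subfamilies by greedy recursive splitting on the
top-supported set of co-segregating derived bases (di/tri-segregation, as
in COSEG). A subfamily must have at least ``min_subfamily_size`` members
(default 10) that agree across the candidate diagnostic positions.

Splitting uses sets of two or three co-segregating mutations by default: a
single mutation column cannot co-segregate with anything, and at realistic
background divergence isolated columns routinely collect ten carriers by
chance alone. Single-column diagnostics are still enumerated and reported
by :func:`find_cosegregating` for inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._pairwise import Scoring, DEFAULT_SCORING, align_pair
from .io_formats import ConsensusRecord

GAP = "-"
_ACGT = "ACGT"


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class StackedAlignment:
    """Instances projected into consensus coordinates.

    ``rows`` is an (n_instances x consensus_length) array of single
    characters; deletions are ``-``. Insertions relative to the consensus
    (including any poly-A tail beyond the 3' end, recorded at position L)
    are kept aside per instance so each input sequence can be reconstructed
    exactly. ``mask`` marks columns excluded from co-segregation statistics.
    """

    consensus_name: str
    consensus: str
    ids: list[str]
    rows: np.ndarray
    insertions: dict[str, list[tuple[int, str]]]
    mask: np.ndarray
    excluded: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return len(self.ids)

    def reconstruct(self, instance_id: str) -> str:
        """Rebuild the original instance from its row plus insertions."""
        i = self.ids.index(instance_id)
        ins = dict()
        for pos, s in self.insertions.get(instance_id, []):
            ins[pos] = ins.get(pos, "") + s
        out = []
        for col in range(len(self.consensus)):
            out.append(ins.get(col, ""))
            ch = self.rows[i, col]
            if ch != GAP:
                out.append(ch)
        out.append(ins.get(len(self.consensus), ""))
        return "".join(out)


@dataclass(frozen=True)
class DiagnosticSet:
    """1-3 derived-base columns whose carriers co-segregate."""

    positions: tuple[tuple[int, str], ...]   # (column, derived base), col-sorted
    support: int

    def __post_init__(self):
        if not (1 <= len(self.positions) <= 3):
            raise ValueError("diagnostic sets have arity 1-3")

    @property
    def arity(self) -> int:
        return len(self.positions)


@dataclass
class SubfamilyCluster:
    name: str
    member_ids: list[str]
    diagnostic_path: list[DiagnosticSet]
    consensus: ConsensusRecord
    size: int


# ---------------------------------------------------------------------------
# N-run filtering
# ---------------------------------------------------------------------------

def filter_n_runs(instances: dict[str, str], max_n_run: int = 1
                  ) -> tuple[dict[str, str], list[str]]:
    """Drop instances containing any run of N longer than ``max_n_run``."""
    needle = "N" * (max_n_run + 1)
    kept: dict[str, str] = {}
    removed: list[str] = []
    for iid, seq in instances.items():
        if needle in seq:
            removed.append(iid)
        else:
            kept[iid] = seq
    return kept, removed


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def stack_to_consensus(instances: dict[str, str],
                       family_consensus: ConsensusRecord,
                       scoring: Scoring = DEFAULT_SCORING,
                       min_identity: float = 0.5) -> StackedAlignment:
    """Pairwise-align every instance to the family consensus and stack rows.

    Alignment is global in the instance with free end gaps in the consensus
    (poly-A tails hang off the 3' end at no cost and land in the insertion
    store, not in columns). Instances aligning at identity below
    ``min_identity`` are excluded and logged — they are likely not family
    members at all.
    """
    if not instances:
        raise ValueError("no instances to stack")
    cons = family_consensus.sequence
    L = len(cons)
    ids, rows_list = [], []
    insertions: dict[str, list[tuple[int, str]]] = {}
    excluded: list[tuple[str, float]] = []
    for iid in sorted(instances):              # canonical order for determinism
        seq = instances[iid]
        aln = align_pair(cons, seq, scoring, mode="glocal")
        ident = aln.identity()
        if ident < min_identity:
            excluded.append((iid, ident))
            continue
        row = np.full(L, GAP, dtype="<U1")
        ins: list[tuple[int, str]] = []
        pending: list[str] = []
        for t, q in aln.walk():
            if t is None:
                pending.append(seq[q])
                continue
            if pending:
                ins.append((t, "".join(pending)))
                pending = []
            if q is not None:
                row[t] = seq[q]
        if pending:
            ins.append((L, "".join(pending)))
        ids.append(iid)
        rows_list.append(row)
        if ins:
            insertions[iid] = ins
    rows = np.vstack(rows_list) if rows_list else np.empty((0, L), dtype="<U1")
    return StackedAlignment(
        consensus_name=family_consensus.name, consensus=cons, ids=ids,
        rows=rows, insertions=insertions,
        mask=np.zeros(L, dtype=bool), excluded=excluded)


def apply_arich_mask(alignment: StackedAlignment,
                     region: tuple[int, int]) -> StackedAlignment:
    """Mask [start, end) columns out of all co-segregation statistics."""
    start, end = region
    if start > end:
        raise ValueError(f"inverted mask region {region}")
    if end > len(alignment.consensus):
        raise ValueError("mask region outside consensus")
    alignment.mask[start:end] = True
    return alignment


# ---------------------------------------------------------------------------
# Co-segregation
# ---------------------------------------------------------------------------

def _derived_events(rows: np.ndarray, consensus: str, mask: np.ndarray,
                    min_support: int):
    """Candidate (column, derived base) events with carrier vectors."""
    cons = np.array(list(consensus))
    events: list[tuple[int, str]] = []
    vecs: list[np.ndarray] = []
    for base in _ACGT:
        hits = rows == base
        counts = hits.sum(axis=0)
        cols = np.flatnonzero((cons != base) & ~mask & (counts >= min_support))
        for col in cols:
            events.append((int(col), base))
            vecs.append(hits[:, col])
    order = np.argsort([c * 8 + _ACGT.index(b) for c, b in events])
    events = [events[i] for i in order]
    M = (np.vstack([vecs[i] for i in order]) if events
         else np.empty((0, rows.shape[0]), dtype=bool))
    return events, M


def _candidate_sets(rows: np.ndarray, consensus: str, mask: np.ndarray,
                    min_support: int, max_arity: int, coherence: float,
                    min_arity: int = 1):
    """All coherent diagnostic sets: (event-index tuple, support, carriers)."""
    events, M = _derived_events(rows, consensus, mask, min_support)
    E = len(events)
    if E == 0:
        return [], events, M
    marg = M.sum(axis=1).astype(int)
    out = []
    if min_arity <= 1:
        for i in range(E):
            out.append(((i,), int(marg[i]), M[i]))
    coh_pairs: dict[tuple[int, int], tuple[int, np.ndarray]] = {}
    if max_arity >= 2:
        joint = (M.astype(np.int32) @ M.T.astype(np.int32))
        for i in range(E):
            for j in range(i + 1, E):
                if events[i][0] == events[j][0]:
                    continue                      # same column, disjoint bases
                s = int(joint[i, j])
                if s >= min_support and s >= coherence * max(marg[i], marg[j]):
                    coh_pairs[(i, j)] = (s, M[i] & M[j])
                    if min_arity <= 2:
                        out.append(((i, j), s, M[i] & M[j]))
    if max_arity >= 3:
        keys = sorted(coh_pairs)
        adjacency: dict[int, set[int]] = {}
        for i, j in keys:
            adjacency.setdefault(i, set()).add(j)
        for i, j in keys:
            for k in sorted(adjacency.get(j, set()) & adjacency.get(i, set())):
                vec = coh_pairs[(i, j)][1] & M[k]
                s = int(vec.sum())
                if s >= min_support and \
                        s >= coherence * max(marg[i], marg[j], marg[k]):
                    out.append(((i, j, k), s, vec))
    return out, events, M


def _sort_key(events):
    def key(item):
        idxs, support, _ = item
        cols = sorted(events[i][0] for i in idxs)
        bases = [b for _, b in sorted(events[i] for i in idxs)]
        return (-support, cols[0], bases[0], -len(idxs), tuple(cols), tuple(bases))
    return key


def find_cosegregating(alignment: StackedAlignment,
                       min_support: int = 10,
                       max_arity: int = 3,
                       coherence: float = 0.9) -> list[DiagnosticSet]:
    """Maximal co-segregating diagnostic sets, ordered by support.

    Single positions, pairs and triples of unmasked derived-base columns are
    enumerated; a set qualifies when its joint carrier count reaches
    ``min_support`` and the carriers agree (joint count >= ``coherence``
    times each marginal count). Sets wholly contained in a qualifying larger
    set are pruned, so perfectly linked columns are reported once, as one
    set. Ties are broken by leftmost column, then alphabetical base.
    """
    cands, events, _ = _candidate_sets(
        alignment.rows, alignment.consensus, alignment.mask,
        min_support, max_arity, coherence)
    kept_index_sets = [frozenset(idxs) for idxs, _, _ in cands]
    pruned = []
    for n, (idxs, support, vec) in enumerate(cands):
        s = kept_index_sets[n]
        if any(s < other for other in kept_index_sets):
            continue
        pruned.append((idxs, support, vec))
    pruned.sort(key=_sort_key(events))
    return [
        DiagnosticSet(
            positions=tuple(sorted(events[i] for i in idxs)),
            support=support)
        for idxs, support, _ in pruned
    ]


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _column_majority(rows: np.ndarray, fallback: str) -> str:
    """Per-column majority base; ties (and all-gap columns) fall back."""
    counts = np.stack([(rows == b).sum(axis=0) for b in _ACGT])
    best = counts.max(axis=0)
    out = []
    for col in range(rows.shape[1]):
        if best[col] == 0:
            out.append(fallback[col])
            continue
        tied = [b for bi, b in enumerate(_ACGT) if counts[bi, col] == best[col]]
        if len(tied) == 1:
            out.append(tied[0])
        elif fallback[col] in tied:
            out.append(fallback[col])
        else:
            out.append(tied[0])
    return "".join(out)


def _closure(seed_idxs: tuple[int, ...], seed_vec: np.ndarray,
             events, M: np.ndarray, marg: np.ndarray,
             coherence: float) -> list[int]:
    """Extend a seed set with every event whose carriers agree with it."""
    out = set(seed_idxs)
    n_seed = int(seed_vec.sum())
    for e in range(len(events)):
        if e in out:
            continue
        joint = int((seed_vec & M[e]).sum())
        if joint >= coherence * max(n_seed, int(marg[e])):
            out.add(e)
    return sorted(out)


def partition_subfamilies(alignment: StackedAlignment,
                          min_subfamily_size: int = 10,
                          max_arity: int = 3,
                          coherence: float = 0.9,
                          min_split_arity: int = 2,
                          reassign: bool = True,
                          name_prefix: str = "sub") -> list[SubfamilyCluster]:
    """Greedy recursive partition of instances into subfamilies.

    At each node the top-supported co-segregating set (of at least
    ``min_split_arity`` mutations) is extended to its coherent closure;
    instances carrying a majority of the closure's derived bases split off
    into a child whose consensus is rebuilt by column majority (ties to the
    parent base); the search then recurses on both sides. A final
    nearest-consensus reassignment pass cleans up instances whose own copy
    happens to be mutated at a diagnostic column. Clusters are named
    ``sub_000``, ``sub_001``, ... in discovery (pre-order) order.
    """
    n = alignment.n_instances
    ids = np.array(alignment.ids)
    rows = alignment.rows
    mask = alignment.mask
    family_cons = alignment.consensus

    if n < min_subfamily_size:
        warnings.warn(
            f"only {n} instances (< min_subfamily_size={min_subfamily_size}); "
            "returning a single cluster")
        cons = _column_majority(rows, family_cons) if n else family_cons
        return [SubfamilyCluster(
            name=f"{name_prefix}_000", member_ids=list(alignment.ids),
            diagnostic_path=[],
            consensus=ConsensusRecord(f"{name_prefix}_000", cons),
            size=n)]

    found: list[tuple[np.ndarray, str, list[DiagnosticSet]]] = []

    def visit(member_idx: np.ndarray, node_cons: str,
              path: list[DiagnosticSet]) -> None:
        remaining = member_idx
        children: list[tuple[np.ndarray, str, list[DiagnosticSet]]] = []
        while len(remaining) > min_subfamily_size:
            sub = rows[remaining]
            cands, events, M = _candidate_sets(
                sub, node_cons, mask, min_subfamily_size, max_arity,
                coherence, min_arity=min_split_arity)
            if not cands:
                break
            marg = M.sum(axis=1).astype(int) if len(events) else np.array([])
            cands.sort(key=_sort_key(events))
            accepted = None
            for idxs, support, vec in cands:
                clo = _closure(idxs, vec, events, M, marg, coherence)
                carried = M[clo].sum(axis=0)
                member_mask = carried >= (len(clo) // 2 + 1)
                size = int(member_mask.sum())
                if min_subfamily_size <= size < len(remaining):
                    dset = DiagnosticSet(
                        positions=tuple(sorted(events[i] for i in idxs)),
                        support=support)
                    accepted = (member_mask, dset)
                    break
            if accepted is None:
                break
            member_mask, dset = accepted
            child_idx = remaining[member_mask]
            remaining = remaining[~member_mask]
            child_cons = _column_majority(rows[child_idx], node_cons)
            children.append((child_idx, child_cons, path + [dset]))
        node_final_cons = _column_majority(rows[remaining], node_cons) \
            if len(remaining) else node_cons
        found.append((remaining, node_final_cons, path))
        for child_idx, child_cons, child_path in children:
            visit(child_idx, child_cons, child_path)

    visit(np.arange(n), family_cons, [])

    # drop empty residual nodes (every member moved into children)
    found = [(idx, cons, path) for idx, cons, path in found if len(idx)]

    assign = np.empty(n, dtype=int)
    consensi = []
    paths = []
    for k, (idx, cons, path) in enumerate(found):
        assign[idx] = k
        consensi.append(cons)
        paths.append(path)

    if reassign and len(consensi) > 1:
        assign = _reassign(rows, mask, consensi, assign)
        # enforce the minimum size after reassignment
        while len(consensi) > 1:
            sizes = np.bincount(assign, minlength=len(consensi))
            small = [k for k in range(len(consensi))
                     if 0 < sizes[k] < min_subfamily_size]
            empty = [k for k in range(len(consensi)) if sizes[k] == 0]
            if not small and not empty:
                break
            drop = set(small) | set(empty)
            keep = [k for k in range(len(consensi)) if k not in drop]
            if not keep:
                keep = [int(np.argmax(sizes))]
            sub_cons = [consensi[k] for k in keep]
            assign_new = _reassign(rows, mask, sub_cons,
                                   _project(assign, keep))
            assign = assign_new
            consensi = sub_cons
            paths = [paths[k] for k in keep]
        # rebuild consensi from final membership
        consensi = [
            _column_majority(rows[assign == k], consensi[k])
            for k in range(len(consensi))]

    clusters = []
    for k in range(len(consensi)):
        members = ids[assign == k]
        name = f"{name_prefix}_{k:03d}"
        clusters.append(SubfamilyCluster(
            name=name, member_ids=sorted(members.tolist()),
            diagnostic_path=paths[k],
            consensus=ConsensusRecord(name, consensi[k]),
            size=int((assign == k).sum())))
    return clusters


def _project(assign: np.ndarray, keep: list[int]) -> np.ndarray:
    """Map old cluster indices onto the kept subset (dropped -> nearest later)."""
    remap = {old: new for new, old in enumerate(keep)}
    out = np.array([remap.get(a, -1) for a in assign])
    out[out == -1] = 0     # placeholder; _reassign moves these to the nearest
    return out


def _reassign(rows: np.ndarray, mask: np.ndarray, consensi: list[str],
              current: np.ndarray) -> np.ndarray:
    """Assign each instance to the nearest consensus (unmasked Hamming);
    ties keep the current assignment."""
    n = rows.shape[0]
    informative = ~mask
    valid = informative[None, :] & np.isin(rows, list(_ACGT))
    dists = np.empty((n, len(consensi)), dtype=int)
    for k, cons in enumerate(consensi):
        carr = np.array(list(cons))
        dists[:, k] = ((rows != carr[None, :]) & valid).sum(axis=1)
    best = dists.min(axis=1)
    out = current.copy()
    for i in range(n):
        if dists[i, current[i]] > best[i]:
            out[i] = int(np.argmin(dists[i]))
    return out
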