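"""Label-uncertainty subfamily merging (SCULU-style).

Subfamilies should be reliably separable: an instance that belongs to one
subfamily should be very unlikely to be assigned to another by chance.
Instances of each subfamily are locally aligned to every subfamily
consensus; the scores (in bits, match = +1 bit under the default scoring)
are turned into a normalized annotation confidence per instance,

    confidence_i = 2^(s_i - s_max) / sum_j 2^(s_j - s_max),

and a pair of subfamilies is non-separable when at least a fraction ``phi``
of either side's instances places confidence >= ``tau`` on the other side.
Non-separable pairs are unioned (transitive closure), merged consensi are
rebuilt as the column majority over the pooled members, and the procedure
iterates until a full pass yields no merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pairwise import Scoring, DEFAULT_SCORING, align_pair
from .io_formats import ConsensusRecord
from .subfamily_discovery import (StackedAlignment, _column_majority,
                                  stack_to_consensus)


@dataclass
class SculuParams:
    tau: float = 0.1            # confidence threshold for a "confused" instance
    phi: float = 0.1            # confused-instance fraction for non-separability
    instance_cap: int = 100     # per-subfamily instance sample cap
    seed: int = 0
    max_iterations: int = 20
    mask_region: tuple[int, int] | None = (130, 150)
    scoring: Scoring = field(default_factory=lambda: DEFAULT_SCORING)


@dataclass
class MergePlan:
    """Partition of subfamilies into reliably separable groups.

    Multi-member groups are named ``merged_1``, ``merged_2``, ... after
    sorting by size then lexicographically, so the largest merged groups
    carry the highest indices; singletons keep their original names.
    """

    groups: list[list[str]]
    name_map: dict[str, str]
    merged_consensi: list[ConsensusRecord]
    n_iterations: int


def _masked_bit_score(consensus: str, instance: str, scoring: Scoring,
                      mask_region: tuple[int, int] | None) -> float:
    """Best local alignment score in bits, skipping A-rich mask columns.

    The alignment is computed against the full consensus (excising the mask
    first would distort coordinates); the score is then re-accumulated
    along the alignment path with every column whose consensus position
    falls inside the mask contributing nothing. With the default scoring a
    perfect instance scores one bit per unmasked aligned column.
    """
    aln = align_pair(consensus, instance, scoring, mode="local")
    s, e = mask_region if mask_region else (0, 0)
    cols = list(aln.walk())
    span = [i for i, (t, q) in enumerate(cols) if t is not None and q is not None]
    if not span:
        return 0.0
    score = 0.0
    in_gap = False
    last_t = None
    for t, q in cols[span[0]:span[-1] + 1]:
        if t is not None:
            last_t = t
        if t is not None and q is not None:
            in_gap = False
            if mask_region and s <= t < e:
                continue
            score += scoring.match if consensus[t] == instance[q] \
                else scoring.mismatch
        elif t is None and q is not None:
            # insertion in the instance; attribute to the current position
            if mask_region and last_t is not None and s <= last_t < e:
                continue
            score += scoring.gap_extend if in_gap else scoring.gap_open
            in_gap = True
        elif t is not None and q is None:
            if mask_region and s <= t < e:
                continue
            score += scoring.gap_extend if in_gap else scoring.gap_open
            in_gap = True
    return score


def score_instances(instances: dict[str, dict[str, str]],
                    consensi: list[ConsensusRecord],
                    params: SculuParams | None = None
                    ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Score sampled instances of every subfamily against every consensus.

    Returns (score matrix in bits: rows = instance ids, columns = subfamily
    names; membership: instance id -> own subfamily). Sampling beyond the
    per-subfamily cap is seeded and deterministic.
    """
    params = params or SculuParams()
    names = [c.name for c in consensi]
    missing = [n for n in names if not instances.get(n)]
    if missing:
        raise ValueError(f"subfamilies with no instances: {missing}")
    rng = np.random.default_rng(params.seed)
    membership: dict[str, str] = {}
    sampled: list[tuple[str, str]] = []
    for name in names:
        pool = sorted(instances[name])
        if len(pool) > params.instance_cap:
            take = rng.choice(len(pool), size=params.instance_cap, replace=False)
            pool = [pool[i] for i in sorted(take)]
        for iid in pool:
            membership[iid] = name
            sampled.append((iid, instances[name][iid]))
    mat = np.empty((len(sampled), len(names)))
    for j, cons in enumerate(consensi):
        for i, (_, seq) in enumerate(sampled):
            mat[i, j] = _masked_bit_score(cons.sequence, seq,
                                          params.scoring, params.mask_region)
    scores = pd.DataFrame(mat, index=[iid for iid, _ in sampled], columns=names)
    return scores, membership


def annotation_confidence(row: np.ndarray) -> np.ndarray:
    """Normalized base-2 softmax of one instance's bit scores.

    Subtracting the row maximum keeps the exponentiation stable; the result
    always sums to 1.
    """
    row = np.asarray(row, dtype=float)
    if row.size == 0:
        raise ValueError("empty score row")
    w = np.exp2(row - row.max())
    return w / w.sum()


def confidence_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    values = np.apply_along_axis(annotation_confidence, 1, scores.to_numpy())
    return pd.DataFrame(values, index=scores.index, columns=scores.columns)


def pair_separability(a: str, b: str, confidences: pd.DataFrame,
                      membership: dict[str, str],
                      tau: float = 0.1, phi: float = 0.1) -> bool:
    """True when the two subfamilies are reliably separable.

    An instance of ``a`` is confused when its confidence for ``b`` reaches
    ``tau``; the pair is non-separable when the confused fraction reaches
    ``phi`` in either direction.
    """
    if a == b:
        raise ValueError("pair_separability needs two distinct subfamilies")
    for own, other in ((a, b), (b, a)):
        ids = [iid for iid in confidences.index if membership[iid] == own]
        if not ids:
            continue
        confused = (confidences.loc[ids, other] >= tau).sum()
        if confused / len(ids) >= phi:
            return False
    return True


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:             # deterministic representative
                ra, rb = rb, ra
            self.parent[rb] = ra


def _merged_consensus(member_instances: dict[str, str],
                      anchor: ConsensusRecord,
                      scoring: Scoring) -> str:
    """Column majority of the pooled members stacked onto the anchor consensus."""
    stacked: StackedAlignment = stack_to_consensus(
        member_instances, anchor, scoring)
    return _column_majority(stacked.rows, anchor.sequence)


def merge_until_stable(consensi: list[ConsensusRecord],
                       instances: dict[str, dict[str, str]],
                       params: SculuParams | None = None) -> MergePlan:
    """Merge non-separable subfamily pairs until a full pass is stable.

    Non-separable pairs are unioned (so merging is transitive); merged
    consensi are rebuilt as the majority over pooled members, anchored on
    the largest constituent subfamily; scoring and confidence are then
    recomputed against the reduced consensus set.
    """
    params = params or SculuParams()
    orig_names = [c.name for c in consensi]
    # working state: group id -> (consensus record, pooled instances, members)
    work = {c.name: (c, dict(instances[c.name]), [c.name]) for c in consensi}

    for iteration in range(1, params.max_iterations + 1):
        names = sorted(work)
        recs = [work[n][0] for n in names]
        inst = {n: work[n][1] for n in names}
        if len(names) == 1:
            return _finalize(work, orig_names, iteration - 1)
        scores, membership = score_instances(inst, recs, params)
        conf = confidence_matrix(scores)
        uf = _UnionFind(names)
        merged_any = False
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if not pair_separability(a, b, conf, membership,
                                         params.tau, params.phi):
                    uf.union(a, b)
                    merged_any = True
        if not merged_any:
            return _finalize(work, orig_names, iteration - 1)
        groups: dict[str, list[str]] = {}
        for n in names:
            groups.setdefault(uf.find(n), []).append(n)
        new_work = {}
        for rep, group_names in groups.items():
            members: list[str] = []
            pooled: dict[str, str] = {}
            for gn in group_names:
                members.extend(work[gn][2])
                pooled.update(work[gn][1])
            if len(group_names) == 1:
                new_work[rep] = work[rep]
                continue
            anchor = max((work[gn][0] for gn in group_names),
                         key=lambda r: (len(instances.get(r.name, {})), r.name))
            cons_seq = _merged_consensus(pooled, anchor, params.scoring)
            rec = ConsensusRecord(rep, cons_seq, anchor.source_lineage,
                                  anchor.family_group)
            new_work[rep] = (rec, pooled, sorted(members))
        work = new_work
    raise RuntimeError(
        f"SCULU merge did not converge within {params.max_iterations} "
        f"iterations; current groups: "
        f"{sorted(v[2] for v in work.values())}")


def _finalize(work, orig_names: list[str], n_iterations: int) -> MergePlan:
    groups = sorted((sorted(v[2]) for v in work.values()),
                    key=lambda g: (len(g), g))
    name_map: dict[str, str] = {}
    merged_consensi: list[ConsensusRecord] = []
    merged_no = 0
    by_members = {tuple(sorted(v[2])): v for v in work.values()}
    for group in groups:
        rec = by_members[tuple(group)][0]
        if len(group) == 1:
            name_map[group[0]] = group[0]
            merged_consensi.append(ConsensusRecord(
                group[0], rec.sequence, rec.source_lineage, rec.family_group))
        else:
            merged_no += 1
            new_name = f"merged_{merged_no}"
            for member in group:
                name_map[member] = new_name
            merged_consensi.append(ConsensusRecord(
                new_name, rec.sequence, rec.source_lineage, rec.family_group))
    assert set(name_map) == set(orig_names)
    return MergePlan(groups=groups, name_map=name_map,
                     merged_consensi=merged_consensi,
                     n_iterations=n_iterations)
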