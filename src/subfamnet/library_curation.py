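"""Consensus-library deduplication, family-group assignment and tallies.

Newly discovered subfamily consensi are aligned against every entry of the
prior library; exact matches (zero mismatches and no internal gaps over the
mutually aligned span, end gaps ignored) are removed, everything else is
kept as novel. Percent divergence is reported excluding the A-rich mask,
consistent with discovery. Each candidate is also assigned the family group
(J / S / Ta10 / Ta15) of its best-scoring match among the designated group
anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._pairwise import Scoring, DEFAULT_SCORING, align_pair
from .io_formats import ConsensusRecord

ANCHOR_GROUPS = ("J", "S", "Ta10", "Ta15")


@dataclass
class CurationReport:
    """Per-candidate dedup outcome plus the resulting non-overlapping library."""

    table: pd.DataFrame           # candidate, best_match, percent_divergence,
                                  # action, family_group, final_name
    final_library: list[ConsensusRecord]
    name_map: dict[str, str] = field(default_factory=dict)   # candidate -> final name


def _alignment_stats(entry: ConsensusRecord, candidate: ConsensusRecord,
                     scoring: Scoring,
                     mask_region: tuple[int, int] | None):
    """(score, mismatches_unmasked, aligned_unmasked, exact) for one pair.

    ``exact`` means zero mismatches anywhere in the mutually aligned span
    and no internal gaps (end gaps ignored) — the full-span criterion, not
    the mask-excluded one used for the divergence percentage.
    """
    aln = align_pair(entry.sequence, candidate.sequence, scoring, mode="glocal")
    s, e = mask_region if mask_region else (0, 0)
    mism_unmasked = aligned_unmasked = 0
    mism_all = 0
    internal_gap = False
    cols = list(aln.walk())
    # trim end gaps: first/last substitution columns delimit the mutual span
    sub_idx = [i for i, (t, q) in enumerate(cols) if t is not None and q is not None]
    if not sub_idx:
        return aln.score, 0, 0, False
    first, last = sub_idx[0], sub_idx[-1]
    for i in range(first, last + 1):
        t, q = cols[i]
        if t is None or q is None:
            internal_gap = True
            continue
        mismatch = entry.sequence[t] != candidate.sequence[q]
        if mismatch:
            mism_all += 1
        if not (mask_region and s <= t < e):
            aligned_unmasked += 1
            if mismatch:
                mism_unmasked += 1
    exact = (mism_all == 0) and not internal_gap
    return aln.score, mism_unmasked, aligned_unmasked, exact


def classify_against_library(candidates: list[ConsensusRecord],
                             library: list[ConsensusRecord],
                             mask_region: tuple[int, int] | None = (130, 150),
                             scoring: Scoring = DEFAULT_SCORING
                             ) -> CurationReport:
    """Deduplicate candidates against a prior library and assign groups.

    Each candidate keeps its best match by alignment score; exact matches
    are removed (``removed-exact-match``), everything else is kept
    (``kept-novel``). With an empty library all candidates are kept-novel
    with group "other".
    """
    anchors = [r for r in library if r.family_group in ANCHOR_GROUPS]
    rows = []
    kept: list[ConsensusRecord] = []
    name_map: dict[str, str] = {}
    for cand in candidates:
        best = None
        for entry in library:
            score, mism, aligned, exact = _alignment_stats(
                entry, cand, scoring, mask_region)
            rec = (score, entry, mism, aligned, exact)
            if best is None or score > best[0]:
                best = rec
        group = "other"
        if anchors:
            best_anchor = max(
                anchors,
                key=lambda a: align_pair(a.sequence, cand.sequence,
                                         scoring, mode="glocal").score)
            group = best_anchor.family_group
        if best is None:
            rows.append({"candidate": cand.name, "best_match": None,
                         "percent_divergence": float("nan"),
                         "action": "kept-novel", "family_group": group,
                         "final_name": cand.name})
            kept.append(ConsensusRecord(cand.name, cand.sequence,
                                        cand.source_lineage, group))
            name_map[cand.name] = cand.name
            continue
        score, entry, mism, aligned, exact = best
        divergence = 100.0 * mism / aligned if aligned else float("nan")
        if exact:
            rows.append({"candidate": cand.name, "best_match": entry.name,
                         "percent_divergence": 0.0,
                         "action": "removed-exact-match",
                         "family_group": entry.family_group,
                         "final_name": entry.name})
            name_map[cand.name] = entry.name
        else:
            rows.append({"candidate": cand.name, "best_match": entry.name,
                         "percent_divergence": divergence,
                         "action": "kept-novel", "family_group": group,
                         "final_name": cand.name})
            kept.append(ConsensusRecord(cand.name, cand.sequence,
                                        cand.source_lineage, group))
            name_map[cand.name] = cand.name
    table = pd.DataFrame(rows, columns=["candidate", "best_match",
                                        "percent_divergence", "action",
                                        "family_group", "final_name"])
    return CurationReport(table=table, final_library=kept, name_map=name_map)


def merge_libraries(libraries: list[list[ConsensusRecord]],
                    mask_region: tuple[int, int] | None = (130, 150),
                    scoring: Scoring = DEFAULT_SCORING
                    ) -> tuple[list[ConsensusRecord], pd.DataFrame]:
    """Merge libraries in analysis order; earlier libraries take precedence.

    Each later library is deduplicated against the union of all earlier
    ones. A name collision between distinct sequences renames the later
    record with its lineage suffix (logged in the report).
    """
    merged: list[ConsensusRecord] = []
    reports = []
    for lib_no, lib in enumerate(libraries):
        if not merged:
            survivors = list(lib)
        else:
            report = classify_against_library(lib, merged, mask_region, scoring)
            report.table["library_index"] = lib_no
            reports.append(report.table)
            survivors = report.final_library
        existing = {r.name for r in merged}
        for rec in survivors:
            if rec.name in existing:
                new_name = f"{rec.name}_{rec.source_lineage}"
                warnings.warn(f"name collision: {rec.name!r} renamed {new_name!r}")
                rec = ConsensusRecord(new_name, rec.sequence,
                                      rec.source_lineage, rec.family_group)
            existing.add(rec.name)
            merged.append(rec)
    log = (pd.concat(reports, ignore_index=True) if reports
           else pd.DataFrame(columns=["candidate", "best_match",
                                      "percent_divergence", "action",
                                      "family_group", "final_name",
                                      "library_index"]))
    return merged, log


def tally_lineage_specific(members: dict[str, str],
                           lineage_of: dict[str, str],
                           group_map: dict[str, str]
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lineage x family-group and lineage x subfamily counts.

    ``members`` maps instance id -> subfamily; ``lineage_of`` maps instance
    id -> lineage; ``group_map`` maps subfamily -> family group. Row/column
    sums equal the number of input instances.
    """
    unmapped = sorted(set(members) - set(lineage_of))
    if unmapped:
        raise KeyError(f"instances without a lineage assignment: {unmapped[:10]}"
                       f"{'...' if len(unmapped) > 10 else ''}")
    missing_groups = sorted({sf for sf in members.values() if sf not in group_map})
    if missing_groups:
        raise KeyError(f"subfamilies without a family group: {missing_groups}")
    df = pd.DataFrame({
        "instance": list(members),
        "subfamily": [members[i] for i in members],
        "lineage": [lineage_of[i] for i in members],
    })
    df["family_group"] = df["subfamily"].map(group_map)
    by_group = df.pivot_table(index="lineage", columns="family_group",
                              values="instance", aggfunc="count",
                              fill_value=0)
    by_subfamily = df.pivot_table(index="lineage", columns="subfamily",
                                  values="instance", aggfunc="count",
                                  fill_value=0)
    return by_group, by_subfamily
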