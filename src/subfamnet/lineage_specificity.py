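"""Lineage-specific element ascertainment.

Extracts full-length elements (with their flanking sequence) from
repeat-hit tables and screens them against an ordered list of comparison
genomes: an element called present in any round is removed before the next
round, and the survivors of every round are the lineage-specific set.

Presence is decided by exact k-mer anchoring of the element's flanks into
the target genome followed by a local alignment of the enclosed region to
the element — a desk-scale, deterministic stand-in for seeded whole-genome
alignment of flanked elements. An orthologous site found empty (flanks
adjacent, nothing alignable between them) is an absence call; an element
whose flanks cannot be anchored at all is ambiguous, retained but flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._pairwise import Scoring, DEFAULT_SCORING, align_pair, revcomp
from .io_formats import RepeatHitRecord


@dataclass
class FlankedElement:
    """One genomic TE copy with 5'/3' flanks; the unit of lineage filtering."""

    id: str
    element_sequence: str
    left_flank: str
    right_flank: str
    genome: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    left_padded: bool = False     # flank hit a contig edge and was N-padded
    right_padded: bool = False


@dataclass
class PresenceCall:
    element_id: str
    target_genome: str
    verdict: str                  # present / absent / ambiguous
    element_coverage_fraction: float = 0.0
    n_anchor_hits: int = 0


@dataclass
class PresenceParams:
    """Knobs of the flank-anchored presence check.

    ``k``: exact anchor length; ``anchor_stride``: spacing of anchor k-mers
    sampled from each flank starting at its inner edge; ``presence_threshold``:
    minimum fraction of the element locally aligned at the orthologous site
    to call it present; ``span_slack``: extra nucleotides allowed between
    co-linear anchors beyond the element length.
    """

    k: int = 20
    n_anchors: int = 5
    anchor_stride: int = 40
    presence_threshold: float = 0.5
    span_slack: int = 300
    scoring: Scoring = field(default_factory=lambda: DEFAULT_SCORING)


# ---------------------------------------------------------------------------
# Full-length extraction
# ---------------------------------------------------------------------------

def extract_full_length(hits: list[RepeatHitRecord],
                        genome: dict[str, str],
                        consensus_lengths: dict[str, int],
                        min_cov: float = 0.95,
                        max_start: int = 5,
                        flank_length: int = 600) -> list[FlankedElement]:
    """Retain full-length hits and attach their flanking sequence.

    A hit is full-length when its consensus span covers at least ``min_cov``
    of the matched consensus and starts within the first ``max_start``
    consensus positions. Minus-strand elements are reverse-complemented to
    consensus orientation with flanks swapped; flanks running off a contig
    edge are N-padded and flagged.
    """
    out: list[FlankedElement] = []
    counter = 0
    for hit in hits:
        if hit.contig not in genome:
            raise KeyError(f"contig {hit.contig!r} missing from genome FASTA")
        clen = consensus_lengths.get(hit.consensus_name)
        if clen is None:
            raise KeyError(f"unknown consensus {hit.consensus_name!r}")
        first, last = hit.consensus_span
        if (last - first + 1) / clen < min_cov or first > max_start:
            continue
        contig_seq = genome[hit.contig]
        lpad = max(0, flank_length - hit.start)
        left = "N" * lpad + contig_seq[max(0, hit.start - flank_length):hit.start]
        rpad = max(0, (hit.end + flank_length) - len(contig_seq))
        right = contig_seq[hit.end:hit.end + flank_length] + "N" * rpad
        element = contig_seq[hit.start:hit.end]
        if hit.strand == "-":
            element = revcomp(element)
            left, right = revcomp(right), revcomp(left)
            lpad, rpad = rpad, lpad
        out.append(FlankedElement(
            id=f"{hit.contig}_{hit.start}_{hit.end}_{counter}",
            element_sequence=element, left_flank=left, right_flank=right,
            genome="", contig=hit.contig, start=hit.start, end=hit.end,
            strand=hit.strand, left_padded=lpad > 0, right_padded=rpad > 0))
        counter += 1
    return out


# ---------------------------------------------------------------------------
# Presence calling
# ---------------------------------------------------------------------------

def _anchor_kmers(element: FlankedElement, params: PresenceParams
                  ) -> list[tuple[str, str, int]]:
    """(kmer, side, offset-from-inner-edge) anchors from both flanks."""
    anchors = []
    k, stride = params.k, params.anchor_stride
    lf, rf = element.left_flank, element.right_flank
    for i in range(params.n_anchors):
        off = i * stride
        if off + k <= len(lf):
            kmer = lf[len(lf) - k - off:len(lf) - off]
            if "N" not in kmer:
                anchors.append((kmer, "left", off))
        if off + k <= len(rf):
            kmer = rf[off:off + k]
            if "N" not in kmer:
                anchors.append((kmer, "right", off))
    return anchors


def _scan_positions(contig_seq: str, kmers: set[str], k: int) -> dict[str, list[int]]:
    """One pass over the contig collecting occurrence positions of the k-mers."""
    found: dict[str, list[int]] = {}
    for i in range(len(contig_seq) - k + 1):
        sub = contig_seq[i:i + k]
        if sub in kmers:
            found.setdefault(sub, []).append(i)
    return found


def _call_one(element: FlankedElement, occurrences: dict[str, list[int]],
              contigs: dict[str, str], target_name: str,
              params: PresenceParams) -> PresenceCall:
    anchors = _anchor_kmers(element, params)
    lefts: list[int] = []     # projected inner edge of the left flank
    rights: list[int] = []
    n_hits = 0
    for kmer, side, off in anchors:
        for pos in occurrences.get(kmer, []):
            n_hits += 1
            if side == "left":
                lefts.append(pos + params.k + off)
            else:
                rights.append(pos - off)
    best_cov = None
    elen = len(element.element_sequence)
    max_span = elen + params.span_slack
    # contig sequences are concatenated for position lookup by the caller
    contig_seq = contigs[target_name]
    for li in lefts:
        for ri in rights:
            span = ri - li
            if -params.span_slack // 4 <= span <= max_span:
                enclosed = contig_seq[max(0, li):max(0, ri)]
                if not enclosed:
                    cov = 0.0
                else:
                    aln = align_pair(enclosed, element.element_sequence,
                                     params.scoring, mode="local")
                    cov = aln.aligned_query_fraction()
                if best_cov is None or cov > best_cov:
                    best_cov = cov
    if best_cov is None:
        return PresenceCall(element.id, element.genome, "ambiguous",
                            0.0, n_hits)
    verdict = "present" if best_cov >= params.presence_threshold else "absent"
    return PresenceCall(element.id, element.genome, verdict, best_cov, n_hits)


def presence_calls(elements: list[FlankedElement],
                   genome: dict[str, str],
                   params: PresenceParams | None = None) -> list[PresenceCall]:
    """Presence calls for many elements against one genome (single scan)."""
    params = params or PresenceParams()
    all_kmers: set[str] = set()
    for el in elements:
        all_kmers.update(kmer for kmer, _, _ in _anchor_kmers(el, params))
    calls: list[PresenceCall] = []
    # scan each contig once; anchor occurrences are contig-local positions
    per_contig = {name: _scan_positions(seq, all_kmers, params.k)
                  for name, seq in genome.items()}
    for el in elements:
        best: PresenceCall | None = None
        for contig_name, occ in per_contig.items():
            call = _call_one(el, occ, genome, contig_name, params)
            if best is None or _call_rank(call) > _call_rank(best):
                best = call
        calls.append(best if best is not None
                     else PresenceCall(el.id, el.genome, "ambiguous"))
    return calls


def _call_rank(call: PresenceCall) -> tuple[int, float]:
    order = {"ambiguous": 0, "absent": 1, "present": 2}
    return order[call.verdict], call.element_coverage_fraction


def presence_in_genome(element: FlankedElement, genome: dict[str, str],
                       params: PresenceParams | None = None) -> PresenceCall:
    """Single-element convenience wrapper over presence_calls."""
    return presence_calls([element], genome, params)[0]


# ---------------------------------------------------------------------------
# Sequential filter
# ---------------------------------------------------------------------------

def sequential_filter(elements: list[FlankedElement],
                      comparison_genomes: list[tuple[str, dict[str, str]]],
                      params: PresenceParams | None = None
                      ) -> tuple[list[FlankedElement], pd.DataFrame]:
    """Sequentially screen elements against comparison genomes in order.

    After each genome, elements called present are removed before the next
    comparison; survivors of all rounds are the lineage-specific candidates.
    Ambiguous (no-anchor) elements are retained but flagged in the audit
    table rather than silently dropped. Returns (survivors, audit).
    """
    params = params or PresenceParams()
    if not comparison_genomes:
        warnings.warn("sequential_filter: empty comparison list; "
                      "returning input unchanged")
        return list(elements), pd.DataFrame(
            columns=["element_id", "round", "target_genome", "verdict",
                     "coverage", "n_anchor_hits"])
    audit_rows = []
    remaining = list(elements)
    ambiguous_ids: set[str] = set()
    for round_no, (target_name, genome) in enumerate(comparison_genomes, start=1):
        calls = presence_calls(remaining, genome, params)
        keep: list[FlankedElement] = []
        for el, call in zip(remaining, calls):
            audit_rows.append({
                "element_id": el.id, "round": round_no,
                "target_genome": target_name, "verdict": call.verdict,
                "coverage": call.element_coverage_fraction,
                "n_anchor_hits": call.n_anchor_hits})
            if call.verdict == "present":
                continue
            if call.verdict == "ambiguous":
                ambiguous_ids.add(el.id)
            keep.append(el)
        remaining = keep
    audit = pd.DataFrame(audit_rows)
    audit["flagged_ambiguous"] = audit["element_id"].isin(ambiguous_ids)
    return remaining, audit
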