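"""Shared pairwise-alignment machinery.

Every alignment in the pipeline uses one affine scoring scheme so that
instance stacking, library deduplication, network distances and SCULU
scoring are mutually consistent:

    match +1, mismatch -2, gap open -5 (first gap base), gap extend -1.

Two aligner flavours are used:

* "glocal": global in the query (instance/candidate), free end gaps in the
  target (consensus), so poly-A tails and other query overhangs hang off
  the consensus ends at no cost.
* "local": Smith-Waterman, for presence checks and SCULU bit scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from Bio import Align

GAP = "-"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scoring; defaults shared across the whole pipeline."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


def make_glocal_aligner(scoring: Scoring = DEFAULT_SCORING) -> Align.PairwiseAligner:
    """Global in the query, free end gaps in the target (the consensus)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # Gaps in the target = query overhang beyond the consensus ends: free.
    aligner.open_left_insertion_score = 0.0
    aligner.extend_left_insertion_score = 0.0
    aligner.open_right_insertion_score = 0.0
    aligner.extend_right_insertion_score = 0.0
    return aligner


def make_local_aligner(scoring: Scoring = DEFAULT_SCORING) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


@dataclass
class AlignedPair:
    """One best pairwise alignment, with column-walk helpers.

    ``target`` is the reference/consensus sequence, ``query`` the instance.
    """

    target: str
    query: str
    score: float
    blocks_target: tuple
    blocks_query: tuple

    def walk(self) -> Iterator[tuple[int | None, int | None]]:
        """Yield (target_index, query_index); None marks a gap on that side.

        Unaligned end regions of either sequence are included (as gap
        columns), so the walk covers both sequences entirely.
        """
        t_prev, q_prev = 0, 0
        for (ts, te), (qs, qe) in zip(self.blocks_target, self.blocks_query):
            for t in range(t_prev, ts):
                yield t, None
            for q in range(q_prev, qs):
                yield None, q
            for t, q in zip(range(ts, te), range(qs, qe)):
                yield t, q
            t_prev, q_prev = te, qe
        for t in range(t_prev, len(self.target)):
            yield t, None
        for q in range(q_prev, len(self.query)):
            yield None, q

    def identity(self) -> float:
        """Matches / alignment columns over the mutual span.

        Internal gap columns count toward the denominator; end overhangs do
        not. Returns 0.0 if nothing aligned.
        """
        cols = list(self.walk())
        sub = [i for i, (t, q) in enumerate(cols)
               if t is not None and q is not None]
        if not sub:
            return 0.0
        matches = total = 0
        for t, q in cols[sub[0]:sub[-1] + 1]:
            total += 1
            if t is not None and q is not None and self.target[t] == self.query[q]:
                matches += 1
        return matches / total

    def aligned_query_fraction(self) -> float:
        aligned = sum(1 for t, q in self.walk() if t is not None and q is not None)
        return aligned / len(self.query) if self.query else 0.0


def align_pair(target: str, query: str,
               scoring: Scoring = DEFAULT_SCORING,
               mode: str = "glocal") -> AlignedPair:
    """Best pairwise alignment of ``query`` against ``target``.

    Deterministic: the first optimal alignment reported by the aligner is
    used throughout the pipeline.
    """
    aligner = make_glocal_aligner(scoring) if mode == "glocal" else make_local_aligner(scoring)
    aln = aligner.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    return AlignedPair(target=target, query=query, score=aln.score,
                       blocks_target=tuple(map(tuple, t_blocks)),
                       blocks_query=tuple(map(tuple, q_blocks)))
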