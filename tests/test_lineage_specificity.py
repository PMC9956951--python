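"""Full-length extraction, flank-anchored presence calls, sequential filter."""

import numpy as np
import pytest

from subfamnet._pairwise import revcomp
from subfamnet.io_formats import RepeatHitRecord
from subfamnet.lineage_specificity import (FlankedElement, PresenceParams,
                                           extract_full_length,
                                           presence_in_genome,
                                           sequential_filter)

RNG = np.random.default_rng(1234)


def _seq(n: int, rng=RNG) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def _hit(contig, start, end, span, strand="+", name="cons"):
    return RepeatHitRecord(contig=contig, start=start, end=end, strand=strand,
                           consensus_name=name, percent_divergence=1.0,
                           consensus_span=span)


class TestExtractFullLength:
    def test_full_span_retained_partial_dropped(self):
        element = _seq(300)
        contig = _seq(700) + element + _seq(700)
        genome = {"c1": contig}
        lengths = {"cons": 300}
        hits = [_hit("c1", 700, 1000, (1, 300)),     # full -> kept
                _hit("c1", 700, 1000, (150, 300)),   # 50% coverage -> dropped
                _hit("c1", 700, 1000, (10, 300))]    # starts late -> dropped
        out = extract_full_length(hits, genome, lengths, flank_length=600)
        assert len(out) == 1
        el = out[0]
        assert el.element_sequence == element
        assert el.left_flank == contig[100:700]
        assert el.right_flank == contig[1000:1600]
        assert not el.left_padded and not el.right_padded

    def test_minus_strand_reverse_complemented_flanks_swapped(self):
        element = _seq(300)
        left, right = _seq(650), _seq(650)
        contig = left + revcomp(element) + right
        out = extract_full_length(
            [_hit("c1", 650, 950, (1, 300), strand="-")],
            {"c1": contig}, {"cons": 300}, flank_length=600)
        (el,) = out
        assert el.element_sequence == element
        assert el.left_flank == revcomp(right[:600])
        assert el.right_flank == revcomp(left[-600:])

    def test_contig_edge_flanks_padded_and_flagged(self):
        contig = _seq(50) + _seq(300) + _seq(700)
        out = extract_full_length(
            [_hit("c1", 50, 350, (1, 300))], {"c1": contig},
            {"cons": 300}, flank_length=600)
        (el,) = out
        assert el.left_padded and not el.right_padded
        assert el.left_flank.startswith("N" * 550)
        assert len(el.left_flank) == 600

    def test_missing_contig_errors(self):
        with pytest.raises(KeyError, match="contig"):
            extract_full_length([_hit("nope", 0, 10, (1, 10))],
                                {"c1": "ACGT"}, {"cons": 10})


def _element_and_site(rng, with_element=True, divergence=0.0):
    """A flanked element plus a target genome holding its orthologous site."""
    element = _seq(330, rng)
    left, right = _seq(600, rng), _seq(600, rng)
    ortho = element
    if divergence:
        arr = np.array(list(element))
        for pos in np.flatnonzero(rng.random(len(arr)) < divergence):
            arr[pos] = [b for b in "ACGT" if b != arr[pos]][int(rng.integers(0, 3))]
        ortho = "".join(arr)
    site = left + (ortho if with_element else "") + right
    genome = {"t": _seq(400, rng) + site + _seq(400, rng)}
    el = FlankedElement(id="e1", element_sequence=element, left_flank=left,
                        right_flank=right, genome="src", contig="c",
                        start=0, end=330)
    return el, genome


class TestPresence:
    def test_orthologous_copy_called_present_with_high_coverage(self):
        rng = np.random.default_rng(8)
        el, genome = _element_and_site(rng, with_element=True, divergence=0.02)
        call = presence_in_genome(el, genome)
        assert call.verdict == "present"
        assert call.element_coverage_fraction > 0.9

    def test_empty_orthologous_site_called_absent(self):
        rng = np.random.default_rng(9)
        el, genome = _element_and_site(rng, with_element=False)
        call = presence_in_genome(el, genome)
        assert call.verdict == "absent"
        assert call.element_coverage_fraction < 0.5

    def test_unanchorable_flanks_ambiguous_not_a_crash(self):
        rng = np.random.default_rng(10)
        el, _ = _element_and_site(rng)
        call = presence_in_genome(el, {"t": _seq(2000, rng)})
        assert call.verdict == "ambiguous"
        assert call.n_anchor_hits == 0


class TestSequentialFilter:
    def _setup(self, rng):
        shared, g_with = _element_and_site(rng, with_element=True)
        shared.id = "shared"
        specific, g_without = _element_and_site(rng, with_element=False)
        specific.id = "specific"
        # merge both sites into each comparison genome
        def merge(a, b):
            return {"t": a["t"] + b["t"]}
        g1 = merge(g_with, g_without)       # shared present here
        site2_left = specific.left_flank + specific.right_flank
        g2 = {"t": _seq(300, rng) + shared.left_flank + shared.right_flank
              + site2_left + _seq(300, rng)}   # both sites empty
        return [shared, specific], [("g1", g1), ("g2", g2)]

    def test_present_element_removed_and_not_rescored(self):
        rng = np.random.default_rng(11)
        elements, genomes = self._setup(rng)
        survivors, audit = sequential_filter(elements, genomes)
        assert [el.id for el in survivors] == ["specific"]
        shared_rows = audit[audit["element_id"] == "shared"]
        assert shared_rows["round"].tolist() == [1]   # never scored in round 2

    def test_absent_everywhere_survives_all_rounds(self):
        rng = np.random.default_rng(12)
        elements, genomes = self._setup(rng)
        survivors, audit = sequential_filter(elements, genomes)
        spec_rows = audit[audit["element_id"] == "specific"]
        assert spec_rows["round"].tolist() == [1, 2]
        assert set(spec_rows["verdict"]) == {"absent"}

    def test_survivors_invariant_under_comparison_order(self):
        rng = np.random.default_rng(13)
        elements, genomes = self._setup(rng)
        s1, _ = sequential_filter(elements, genomes)
        s2, _ = sequential_filter(elements, genomes[::-1])
        assert {el.id for el in s1} == {el.id for el in s2}

    def test_empty_comparison_list_warns_and_passes_through(self):
        rng = np.random.default_rng(14)
        el, _ = _element_and_site(rng)
        with pytest.warns(UserWarning, match="empty comparison"):
            survivors, audit = sequential_filter([el], [])
        assert survivors == [el] and audit.empty

    def test_no_element_both_retained_and_present(self):
        rng = np.random.default_rng(15)
        elements, genomes = self._setup(rng)
        survivors, audit = sequential_filter(elements, genomes)
        present_ids = set(audit.loc[audit["verdict"] == "present", "element_id"])
        assert not (present_ids & {el.id for el in survivors})
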