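"""N-run filtering, stacking, masking, co-segregation and partitioning."""

import itertools

import numpy as np
import pytest

from conftest import make_instances, mutate_positions
from subfamnet.subfamily_discovery import (apply_arich_mask, filter_n_runs,
                                           find_cosegregating,
                                           partition_subfamilies,
                                           stack_to_consensus)


# ---------------------------------------------------------------------------
# N-run filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seq,max_n_run,removed", [
    ("ACGTNNNNNACGT", 1, True),       # default rule: any run longer than 1 N
    ("ACGTACGTACGT", 1, False),
    ("ACG" + "N" * 5 + "T", 5, False),  # threshold boundary: 5 Ns kept
    ("ACG" + "N" * 6 + "T", 5, True),   # 6 Ns removed
])
def test_filter_n_runs_boundaries(seq, max_n_run, removed):
    kept, dropped = filter_n_runs({"x": seq}, max_n_run)
    assert ("x" in dropped) == removed
    assert ("x" in kept) != removed


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def test_identical_instance_gives_gapfree_row(family_consensus):
    st = stack_to_consensus({"i": family_consensus.sequence}, family_consensus)
    assert "".join(st.rows[0]) == family_consensus.sequence
    assert st.insertions == {}


def test_planted_substitution_lands_in_its_column(family_consensus):
    seq = mutate_positions(family_consensus.sequence, [40])
    st = stack_to_consensus({"i": seq}, family_consensus)
    diff = np.flatnonzero(st.rows[0] != np.array(list(family_consensus.sequence)))
    assert diff.tolist() == [40]


def test_polya_tail_lands_in_insertions_not_columns(family_consensus):
    seq = family_consensus.sequence + "A" * 30
    st = stack_to_consensus({"i": seq}, family_consensus)
    L = len(family_consensus.sequence)
    assert "".join(st.rows[0]) == family_consensus.sequence
    assert st.insertions["i"] == [(L, "A" * 30)]


def test_reconstruction_reproduces_input_exactly(family_consensus):
    """Row + insertions is a lossless encoding, also with indels."""
    rng = np.random.default_rng(5)
    seqs = {}
    base = family_consensus.sequence
    seqs["sub"] = mutate_positions(base, [10, 200], rng)
    seqs["del"] = base[:50] + base[53:] + "A" * 12       # internal deletion
    seqs["ins"] = base[:70] + "TTGC" + base[70:]          # internal insertion
    seqs["noisy"] = "".join(make_instances(base, 1, 0.05, rng, "x",
                                           polya=(5, 20)).values())
    st = stack_to_consensus(seqs, family_consensus)
    for iid, seq in seqs.items():
        assert st.reconstruct(iid) == seq


def test_low_identity_instance_excluded(family_consensus):
    rng = np.random.default_rng(6)
    junk = "".join(rng.choice(list("ACGT"), 300))
    st = stack_to_consensus(
        {"good": family_consensus.sequence, "junk": junk}, family_consensus)
    assert st.ids == ["good"]
    assert [iid for iid, _ in st.excluded] == ["junk"]


def test_1000_simulated_substitutions_all_land_in_true_columns(
        family_consensus):
    """With indels off, every planted substitution projects to its column."""
    rng = np.random.default_rng(7)
    base = family_consensus.sequence
    insts, planted = {}, {}
    for k in range(1000):
        pos = sorted(rng.choice(300, size=int(rng.integers(1, 7)),
                                replace=False))
        iid = f"i{k:04d}"
        insts[iid] = mutate_positions(base, [int(p) for p in pos], rng)
        planted[iid] = set(int(p) for p in pos)
    st = stack_to_consensus(insts, family_consensus)
    ref = np.array(list(base))
    for row, iid in zip(st.rows, st.ids):
        assert set(np.flatnonzero(row != ref).tolist()) == planted[iid]


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def test_mask_region_and_identity(family_consensus):
    st = stack_to_consensus({"i": family_consensus.sequence}, family_consensus)
    apply_arich_mask(st, (130, 150))
    assert st.mask.sum() == 20 and st.mask[130] and not st.mask[150]
    st.mask[:] = False
    apply_arich_mask(st, (0, 0))
    assert st.mask.sum() == 0
    with pytest.raises(ValueError, match="inverted"):
        apply_arich_mask(st, (10, 5))


# ---------------------------------------------------------------------------
# Co-segregation
# ---------------------------------------------------------------------------

def _brute_force_sets(rows, consensus, mask, min_support, coherence=0.9):
    """Independent enumeration of maximal coherent diagnostic sets."""
    n, L = rows.shape
    events = []
    for col in range(L):
        if mask[col]:
            continue
        for base in "ACGT":
            if base == consensus[col]:
                continue
            vec = rows[:, col] == base
            if vec.sum() >= min_support:
                events.append(((col, base), vec))
    cands = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations(range(len(events)), r):
            cols = [events[i][0][0] for i in combo]
            if len(set(cols)) < r:
                continue
            joint = np.logical_and.reduce([events[i][1] for i in combo])
            s = int(joint.sum())
            margs = [int(events[i][1].sum()) for i in combo]
            if s >= min_support and all(s >= coherence * m for m in margs):
                cands[frozenset(events[i][0] for i in combo)] = s
    maximal = {k: v for k, v in cands.items()
               if not any(k < other for other in cands)}
    return maximal


def test_cosegregating_pair_reported_once_with_joint_support(family_consensus):
    """60/100 instances share G@10 + T@20 jointly -> one arity-2 set."""
    base = family_consensus.sequence
    variant = mutate_positions(base, [10, 20])
    insts = {f"p{k:03d}": base for k in range(40)}
    insts |= {f"v{k:03d}": variant for k in range(60)}
    st = stack_to_consensus(insts, family_consensus)
    apply_arich_mask(st, (130, 150))
    sets = find_cosegregating(st, min_support=10)
    assert len(sets) == 1
    assert sets[0].support == 60 and sets[0].arity == 2
    assert [c for c, _ in sets[0].positions] == [10, 20]


def test_nine_joint_carriers_below_min_support_not_returned(family_consensus):
    base = family_consensus.sequence
    variant = mutate_positions(base, [10, 20])
    insts = {f"p{k:03d}": base for k in range(100)}
    insts |= {f"v{k:03d}": variant for k in range(9)}
    st = stack_to_consensus(insts, family_consensus)
    apply_arich_mask(st, (130, 150))
    assert find_cosegregating(st, min_support=10) == []


def test_masked_diagnostics_never_reported(family_consensus):
    """A diagnostic planted inside the A-rich mask is invisible."""
    base = family_consensus.sequence
    inside = mutate_positions(base, [135, 140])
    outside = mutate_positions(base, [40, 60])
    insts = {f"a{k:03d}": inside for k in range(50)}
    insts |= {f"b{k:03d}": outside for k in range(50)}
    st = stack_to_consensus(insts, family_consensus)
    apply_arich_mask(st, (130, 150))
    sets = find_cosegregating(st, min_support=10)
    reported = {c for ds in sets for c, _ in ds.positions}
    assert reported == {40, 60}


def test_cosegregating_matches_brute_force_enumeration(family_consensus):
    """Randomized alignment vs independent itertools enumeration."""
    rng = np.random.default_rng(17)
    base = family_consensus.sequence
    va = mutate_positions(base, [25, 90, 210], rng)
    vb = mutate_positions(base, [55], rng)
    insts = {}
    insts |= make_instances(base, 30, 0.01, rng, "r")
    insts |= make_instances(va, 25, 0.01, rng, "a")
    insts |= make_instances(vb, 20, 0.01, rng, "b")
    st = stack_to_consensus(insts, family_consensus)
    apply_arich_mask(st, (130, 150))
    got = {frozenset(ds.positions): ds.support
           for ds in find_cosegregating(st, min_support=10)}
    expected = _brute_force_sets(st.rows, st.consensus, st.mask, 10)
    assert got == expected


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def test_identical_instances_one_cluster_with_their_consensus(family_consensus):
    seq = mutate_positions(family_consensus.sequence, [5])
    insts = {f"i{k:03d}": seq for k in range(100)}
    st = stack_to_consensus(insts, family_consensus)
    apply_arich_mask(st, (130, 150))
    clusters = partition_subfamilies(st, 10)
    assert len(clusters) == 1
    assert clusters[0].consensus.sequence == seq
    assert clusters[0].size == 100


def test_two_variants_split_with_consensi_differing_at_planted_columns(
        family_consensus):
    base = family_consensus.sequence
    variant = mutate_positions(base, [30, 80])
    insts = {f"a{k:03d}": base for k in range(50)}
    insts |= {f"b{k:03d}": variant for k in range(50)}
    st = stack_to_consensus(insts, family_consensus)
    apply_arich_mask(st, (130, 150))
    clusters = partition_subfamilies(st, 10)
    assert len(clusters) == 2
    c0, c1 = (c.consensus.sequence for c in clusters)
    diff = [i for i, (x, y) in enumerate(zip(c0, c1)) if x != y]
    assert diff == [30, 80]
    sizes = sorted(c.size for c in clusters)
    assert sizes == [50, 50]


def test_min_size_rule_nine_vs_ten(family_consensus):
    """A 9-copy variant is never a cluster; a 10-copy variant is."""
    base = family_consensus.sequence
    variant = mutate_positions(base, [30, 80])
    for n_var, expected in [(9, 1), (10, 2)]:
        insts = {f"a{k:03d}": base for k in range(100)}
        insts |= {f"b{k:03d}": variant for k in range(n_var)}
        st = stack_to_consensus(insts, family_consensus)
        apply_arich_mask(st, (130, 150))
        clusters = partition_subfamilies(st, 10)
        assert len(clusters) == expected
        assert all(c.size >= 10 for c in clusters)


def test_partition_is_exhaustive_and_disjoint(five_subfamily_tree):
    tree, cfg = five_subfamily_tree
    rng = np.random.default_rng(12)
    insts = {}
    for sf in tree.preorder():
        insts |= make_instances(tree.nodes[sf].sequence, 60, 0.02, rng,
                                sf, polya=(5, 50))
    st = stack_to_consensus(insts, tree.nodes[tree.root])
    apply_arich_mask(st, cfg.arich_region)
    clusters = partition_subfamilies(st, 10)
    all_members = [iid for c in clusters for iid in c.member_ids]
    assert sorted(all_members) == sorted(st.ids)      # partition of the input
    assert len(set(all_members)) == len(all_members)  # disjoint
    masked = set(range(*cfg.arich_region))
    for c in clusters:
        for ds in c.diagnostic_path:
            assert not ({col for col, _ in ds.positions} & masked)


def test_partition_deterministic_under_input_order(five_subfamily_tree):
    tree, cfg = five_subfamily_tree
    rng = np.random.default_rng(30)
    insts = {}
    for sf in tree.preorder():
        insts |= make_instances(tree.nodes[sf].sequence, 40, 0.02, rng, sf)
    shuffled = dict(reversed(list(insts.items())))
    results = []
    for variant in (insts, shuffled):
        st = stack_to_consensus(variant, tree.nodes[tree.root])
        apply_arich_mask(st, cfg.arich_region)
        clusters = partition_subfamilies(st, 10)
        results.append([(c.name, tuple(c.member_ids), c.consensus.sequence)
                        for c in clusters])
    assert results[0] == results[1]


def test_fewer_than_min_size_returns_single_cluster_with_warning(
        family_consensus):
    insts = {f"i{k}": family_consensus.sequence for k in range(4)}
    st = stack_to_consensus(insts, family_consensus)
    with pytest.warns(UserWarning, match="min_subfamily_size"):
        clusters = partition_subfamilies(st, 10)
    assert len(clusters) == 1 and clusters[0].size == 4
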