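# Methods

This note documents the models, algorithms and numerical choices behind
`subfamnet`, the defaults and why they were chosen, and what the synthetic
data does and does not establish about real genomes.

## Alignment scoring

One affine scheme is used everywhere: match +1, mismatch −2, gap open −5
(charged on the first gap base), gap extension −1. Instance-to-consensus
alignments are *glocal* — global in the instance, free end gaps in the
consensus — so a poly-A tail hangs off the consensus 3′ end at no cost and
is stored as an insertion rather than occupying columns. Presence checks
and SCULU scoring use local (Smith–Waterman) alignments with the same
substitution/gap costs. Alignments come from Biopython's
`PairwiseAligner`; the first optimal alignment is used throughout, which
makes every downstream quantity deterministic.

Alignment identity is defined over the mutual span: matches divided by all
columns between the first and last aligned pair, counting internal gap
columns, with end overhangs excluded. This cleanly separates family
members (≈ 0.95–1.0) from unrelated sequence (≈ 0.4) where a
substitution-columns-only definition does not; instances or consensi below
0.5 identity are rejected as non-family.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- **Subfamily tree.** A root consensus (default 300 nt, uniform over
  {A,C,G,T}) with a planted A-run over columns 130–150 — the "middle
  A-rich region", made explicit and configurable because its coordinates
  vary between family consensi in practice. Each child subfamily differs
  from its parent at exactly the requested number of unmasked, previously
  unmutated positions; diagnostic substitutions are inherited down the
  tree.
- **Copies.** Each copy is its subfamily consensus plus i.i.d. Bernoulli
  substitutions (default 2 %/site, uniform over the three alternative
  bases; a transition bias κ is available but off so that discovery never
  depends on it), a uniform 5–50-nt poly-A tail, and, with probability
  0.02, a planted 10-nt N run (mirroring the N-contaminated assembly
  sequence that has to be filtered before subfamily analysis). Indels are
  off by default so Hamming oracles stay exact; a per-site rate is
  available.
- **Species tree and presence.** Four lineages in two cherries. An
  insertion on a tip branch is lineage-specific; on an internal branch it
  is carried by the branch's descendants. A fraction (default 0.1, a pure
  test knob — no empirical rate is implied) of internal-branch insertions
  is instead assigned a random proper subset of the descendants,
  emulating insertion polymorphisms that sort incongruently during rapid
  speciation (ILS). Every insertion locus, filled or empty, is present in
  every genome with identical 600-nt flanks, so orthologous sites can be
  found and empty sites observed.
- **Determinism.** One seeded generator, sampled in a documented order
  (tree first, then events in subfamily-preorder × branch-preorder × copy
  order); identical seeds give bytewise-identical FASTA/TSV outputs.

Default copy numbers (per subfamily per tip branch: 10 ancestral S, 15 Sc,
15 Ta10, 60 Ta15, 30 Ta15-derived) put roughly 70 % of each lineage's
insertions in the Ta15-like burst, the qualitative pattern reported for
platyrrhine genomes, while keeping a whole four-genome run under a minute.

What passing on this data does **not** show: robustness to real assembly
artifacts (segmental duplications, truncated or rearranged copies), CpG
hypermutability, indel-rich old subfamilies, or genome-scale search
performance. The generator makes the *statistical logic* of the pipeline
testable, not its behaviour on raw assemblies.

## Lineage filtering

Full-length extraction keeps repeat hits whose consensus span covers
≥ 95 % of the matched consensus and starts within its first 5 positions,
then attaches fixed-length flanks (N-padded and flagged at contig edges);
minus-strand elements are reverse-complemented with flanks swapped.

Presence of an element in another genome is decided by exact k-mer
anchoring (k = 20, five anchors per flank spaced 40 nt from the inner
edges) — a deterministic, desk-scale stand-in for seeded whole-genome
alignment. A co-linear left/right anchor pair within a plausible span
projects an orthologous region, which is locally aligned to the element;
the call is *present* at element coverage ≥ 0.5, *absent* below it
(typically an empty site between adjacent flanks), *ambiguous* when no
anchor pair is found. The 0.5 threshold deliberately scores truncated
orthologs as present: a half-present element is shared, not a new
insertion. Ambiguous elements are retained but flagged — silently dropping
them would bias lineage-specific counts.

The sequential filter removes elements called present after each round.
Because each verdict depends only on the element and one target genome,
the surviving set is invariant under permutation of the comparison order
(verified by test); the sequential arrangement only saves work.

## Subfamily discovery

Instances are stacked into family-consensus coordinates; the A-rich mask
hides columns from all co-segregation statistics (the consensus sequence
itself still carries the region).

A *diagnostic set* is 1–3 (column, derived base) events whose joint
carrier count reaches the support threshold and whose carriers agree —
joint count ≥ 0.9 × each marginal count. The coherence factor 0.9 is a
design choice (no published value exists); it is configurable and logged.
Only *maximal* coherent sets are reported: perfectly linked columns appear
once, as one set.

Partitioning splits greedily: the top-supported set (ordered by support,
then leftmost column, then base) is extended to its coherent closure, and
instances carrying a **majority** of the closure's derived bases form a
child cluster whose consensus is rebuilt by column majority (ties fall
back to the parent base); the search recurses on both sides and stops when
no set reaches the minimum subfamily size (default 10, the "ten or more
identical sequences" rule, interpreted as identity across the candidate
diagnostic positions — full-sequence identity is vanishingly rare at 2 %
divergence). Two deliberate robustness choices:

- **Splits require at least two co-segregating mutations.** A single
  column cannot co-segregate with anything, and at 2 % divergence an
  isolated (column, base) event collects ≥ 10 carriers by chance roughly
  once per thousand instances, which would mint spurious subfamilies.
  Di/tri-segregation is also what the co-segregation rationale is about.
  Single-column diagnostics are still enumerated for inspection.
- **Majority membership plus a final reassignment.** Requiring a member
  to carry *every* closure mutation would lose the ~6 % of true members
  whose own copy is mutated at a diagnostic column. Members therefore
  join on a majority of the closure, and one final nearest-consensus
  (unmasked Hamming) pass reassigns stragglers; ties keep the current
  assignment; clusters that fall below the minimum size are dissolved
  into their nearest neighbour. In noise-free settings both rules reduce
  to the strict definition, and every member carries every diagnostic on
  its cluster's path.

Clusters are named `sub_000`, `sub_001`, … in discovery (pre-order)
order; the pipeline suffixes the discovery lineage (`sub_000_owl` style).
Input order cannot affect the result: instances are pre-sorted by id.

## Library curation

Candidates are aligned to every prior-library entry; the best match by
score decides. *Exact match* means zero mismatches and no internal gaps
over the mutually aligned span, end gaps ignored — only true duplicates
are removed, one-mutation neighbours survive (they are visible as
1-mutation edges in the network). Percent divergence is reported excluding
the A-rich mask, consistent with discovery (the choice is ours; nothing is
published either way). Family groups (J/S/Ta10/Ta15) are assigned by the
best-scoring designated anchor. Libraries merge sequentially with earlier
libraries taking precedence; name collisions between distinct sequences
are renamed with a lineage suffix and logged.

## Network construction

The diagnostic distance between two consensi counts substituted columns
under the shared alignment, excluding the A-rich mask and end gaps;
internal indel runs count as one event each by default (configurable to
per-column or zero — the convention used for published figures is not
stated anywhere, so it is configuration here). Each non-root subfamily
attaches to the candidate parent minimizing this distance, candidates
being nodes of strictly older age rank — the iterated distance to the
family root. (Allowing equal-rank candidates would permit two-cycles; the
strict ordering preserves acyclicity and every documented example.) Ties
on distance attach to the candidate nearest the root; remaining ties
become recorded polytomies with multiple parent edges. Edge labels are
audited by recomputation (`SubfamilyNetwork.validate`). With ≥ 3 mutations
per edge and branches sharing no mutations, attachment recovers the
planted tree exactly; 1-mutation edges produce the polytomies the method
is expected to surface rather than resolve.

## SCULU merging

Instance scores are best local-alignment scores in bits (one bit per
matched unmasked column at default scoring). The mask is excluded by
re-accumulating the score along the alignment path and skipping columns
inside the A-rich region — excising the mask before aligning would
distort coordinates. Confidence is the base-2 softmax of a row, stabilized
by subtracting the row maximum; rows sum to 1 to machine precision.

Defaults τ = 0.1, φ = 0.1, 100 sampled instances per subfamily
(seed-controlled): the published description fixes neither, so these are
explicit design decisions, exposed in configuration and logged. Merging
unions all non-separable pairs (union–find, hence transitive), rebuilds
each merged consensus as the column majority of the pooled members
anchored on the largest constituent, rescores against the reduced set and
repeats until a pass makes no merge (error after 20 iterations). Merged
groups are named `merged_1`, `merged_2`, … after sorting by size then
lexicographically, so the largest groups carry the highest indices;
singletons keep their names. Raising τ never increases the number of
merges (tested over a τ grid).

## Pipeline and problem sizes

The orchestrated run writes every stage artifact as plain FASTA/TSV and a
`report.json` that contains no timestamps, so identical config + seed
reproduce it byte for byte. Conservation is audited: every
lineage-specific instance lands in exactly one subfamily member list and
one tally cell.

Problem sizes used by the test suite and the acceptance script — chosen
as the package's desk-scale study conditions: discovery benchmark 5
subfamilies × 200 copies at 2 % divergence (1,000 instances); presence
screen ~1,170 element/genome decisions over four ~1-Mb genomes; distance
oracle 1,000 consensus pairs; SCULU benchmark 12 subfamilies × 40
instances at 3 % divergence; full pipeline 545 insertion events across
four genomes.

## Known limitations

- The k-mer presence check assumes orthologous flanks are locally exact;
  highly diverged or rearranged flanks yield *ambiguous*, never a guess.
- Consensus building is plain column majority (ties to parent); no
  CpG-aware two-state consensus.
- The network uses greedy nearest-older-parent attachment, not a global
  optimization; with single-mutation edges the correct parent can be
  ambiguous in principle, which is surfaced as polytomies.
- Instance sampling caps make SCULU results depend (deterministically) on
  the seed when subfamilies exceed the cap.
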