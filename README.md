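# subfamnet

Discovery, curation, merging and evolutionary networking of SINE
retrotransposon subfamilies across related genomes.

## The problem

*Alu* elements — ~300-nt primate SINEs — expand in bursts from active
source copies. Each burst inherits the diagnostic nucleotide substitutions
of its source, so the family decomposes into discrete **subfamilies**, each
summarized by a consensus sequence. Comparative studies characterize the
subfamily repertoire of each newly sequenced genome by:

1. extracting full-length elements with flanking sequence and keeping those
   **lineage-specific** (absent at the orthologous, flank-matched site in
   every comparison genome, screened sequentially);
2. grouping the lineage-specific copies into subfamilies by
   **co-segregating mutations** (di/tri-segregation, COSEG-style), with a
   middle A-rich region excluded and a minimum subfamily size of 10;
3. deduplicating the discovered consensi against previously published
   libraries (only exact matches are removed — one-mutation neighbours are
   real subfamilies);
4. building a **network** in which every subfamily attaches to the parent
   minimizing its diagnostic-mutation distance, with edges labeled by that
   count and equal-distance attachments kept as polytomies; and
5. merging subfamilies whose instances cannot be reliably told apart,
   using score-based annotation confidence (**SCULU**): instance *i* scored
   in bits against every consensus *j* gets confidence
   `c_ij = 2^(s_ij − s_max) / Σ_k 2^(s_ik − s_max)`, and a pair merges when
   ≥ φ of either side's instances place confidence ≥ τ on the other side.

`subfamnet` implements this whole pipeline as a tested, seeded library and
CLI. Whole-genome assemblies are not needed to verify it: a built-in
generator simulates a four-lineage species tree carrying nested subfamily
structure, per-copy background divergence, poly-A tails, N-run
contamination and incomplete-lineage-sorting insertion polymorphisms, with
a full ground-truth table, so every stage can be checked against planted
truth at desk scale.

## Worked example

```python
from subfamnet import RunConfig, run_pipeline

result = run_pipeline(RunConfig(outdir="run", seed=1))
print(result.report["novel_subfamily_counts"])
print(result.report["tally_by_group"]["owl"])
```

prints

```
[2, 0, 0, 0]
{'S': 25, 'Ta10': 16, 'Ta15': 86}
```

The four genomes are analyzed in order (marmoset, squirrel, owl, capuchin).
All five simulated subfamilies are active in every lineage, so the first
genome contributes every novel consensus not already in the prior anchor
library (here 2) and later genomes contribute none — the second-genome
effect. The tally rows show that the young burst subfamilies (tagged Ta15)
account for the large majority of lineage-specific insertions in each
lineage, the signature of a recent expansion burst. The run directory holds
every intermediate as plain FASTA/TSV plus `network.tsv/.dot/.graphml`,
`sculu_plan.tsv` and a deterministic `report.json`.

The same stages are available as shell commands:

```bash
subfamnet simulate --out sim --seed 1
subfamnet coseg --instances sim/elements_marmoset.fa \
    --family-consensus sim/true_subfamilies.fa \
    --out subfams.fa --members members.tsv
subfamnet network --library subfams.fa --root AluS_sim --out net.tsv
```

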