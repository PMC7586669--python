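# texapt

Detection and reconstruction of **transposable-element domestication**
events — protein-coding genes that evolved from transposon sequences —
for comparative genomicists studying lineage-restricted gene birth
(e.g. L1-derived gene families on the mammalian X chromosome).

## What it computes

**The domestication screen.** A gene is a candidate domesticated
transposon when, jointly:

1. **overlap** — the union of annotated TE fragments covers more than 50%
   of its coding region: `f = |CDS ∩ ∪TE| / |CDS| > 0.5` (strict);
2. **coding potential** — its best transcript scores above 800 on a
   0–1000 coding-potential scale combining ORF length
   (`round(900·min(1, n_codons/300))`), Kozak context (+50 for a purine
   at −3, +50 for G at +4), an NMD penalty (−200 when the stop codon lies
   more than 50 nt upstream of the last exon–exon junction) and upstream
   ORFs (−25 each, floored at −100);
3. **conservation** — an intact ORF exists in more than one species
   (ortholog ORF length ≥ 0.7× the reference, configurable).

**Composite reconstruction.** A locus is segmented against a TE consensus
library (exact-seed, ungapped X-drop extension, greedy chaining) to
recover segment sources, orientations, twin-priming **inversion
junctions** and the **target-site duplication** (TSD), and composites can
be re-assembled from consensus slices (inverted segments
reverse-complemented, TSD on both flanks). Percent identity between a
derived gene and its source consensus is computed under explicit gap
policies.

**Allele arithmetic.** CRISPR deletions given as 1-based inclusive
coordinates (`length = end − start + 1`) are classified by the mod-3 rule:
in-frame (residues removed = deleted CDS bases / 3) or frameshift, with
the premature stop located by translating the mutant CDS.

**Expression.** Corrected RPKM with mappability-corrected effective
lengths: `cRPKM = 10⁹·c / (ℓ_eff·M)` where `ℓ_eff` counts read-length
start positions unique across the whole transcriptome; row rescaling and
average-linkage (UPGMA) clustering under Pearson distance `1 − r`.

**Enrichment.** Exact hypergeometric upper tail `P(X ≥ k)` of a gene
family within differentially expressed gene sets, per dataset at
α = 0.05.

All stages run end-to-end on a bundled synthetic-genome generator that
plants composite TE-derived genes (with TSDs and inversion junctions),
negatives failing exactly one criterion each, count tables and DE lists —
with a truth manifest for every record.

## Worked example

Generate a small fixture and screen it:

```sh
$ texapt simulate --seed 3 --positives 2 --negatives 4 --out simdir
wrote 6 genes to simdir
$ texapt screen --gtf simdir/genes.gtf --rmout simdir/repeats.out \
    --genome simdir/genome.fa --orthologs simdir/orthologs --out report.tsv
2 / 6 genes pass
$ head -3 report.tsv
gene_id	transcript_id	cds_length	te_bases	te_fraction	coding_score	n_species_conserved	pass_overlap	pass_score	pass_conservation	verdict
NEG0001	NEG0001.t1	1233	1017	0.824818	314	3	True	False	True	False
POS0000	POS0000.t1	1137	767	0.674582	1000	3	True	True	True	True
```

`NEG0001` has heavy TE overlap (82%) and a conserved locus but a
frame-broken ORF (score 314 ≤ 800), so it is rejected; `POS0000` clears
all three filters (67% TE overlap, score 1000, ORF intact in 3 species).
Exactly the two planted positives pass.

Deletion-allele arithmetic from coordinates:

```python
>>> from texapt import parse_region, interval_length, classify_deletion
>>> from texapt.synthetic_data import synthetic_bex3_like_locus
>>> interval_length(parse_region("chrX:136271327-136271522"))
196
>>> tx, cds = synthetic_bex3_like_locus()
>>> a = classify_deletion(tx, cds, parse_region("chrX:136271359-136271505"))
>>> a.consequence, a.aa_removed
('in_frame_deletion', 49)
```

The 147-bp deletion is in frame and removes 49 residues; the 196-bp one
(196 mod 3 = 1) shifts the frame and translation of the mutant CDS finds
a premature stop at codon 76 of the synthetic fixture.

## Layout

- `texapt.io_annotations` — GTF / RepeatMasker `.out` parsing, TE class
  filter, 1-based inclusive interval arithmetic
- `texapt.screen` — CDS×TE overlap, ORF conservation, the screen
- `texapt.coding_potential` — ORF discovery and the coding score
- `texapt.ancestry` — composite assembly/segmentation, TSD, identity
- `texapt.alleles` — deletion consequence arithmetic
- `texapt.expression` — effective length, cRPKM, rescaling, UPGMA
- `texapt.enrichment` — hypergeometric over-representation
- `texapt.synthetic_data` — fixture generator with truth manifests
- `texapt.cli` — the `texapt` command

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
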