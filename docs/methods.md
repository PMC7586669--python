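# Methods

## Coordinate conventions

All internal coordinates are 1-based and inclusive on both ends, the
convention shared by GTF and RepeatMasker `.out` and the one under which
published deletion coordinates reproduce their printed lengths
(`end − start + 1`; e.g. chrX:136271327-136271522 spans 196 bp). Offsets
on spliced transcript sequences are 0-based. Any BED export would be
0-based half-open and labelled as such; none is currently emitted.

## The screen

The screen classifies a gene as a candidate domesticated transposon when
three filters pass jointly. Decisions taken where the procedure is
genuinely open:

* **Strand-agnostic overlap.** Retrotransposition by twin priming
  inserts part of the element in inverted orientation, so requiring TE
  fragments on the gene's strand would reject exactly the composite
  insertions of interest. A `strand_aware` flag permits the stricter
  re-run.
* **Union semantics.** Repeat fragments are flattened before counting so
  nested or adjacent RepeatMasker rows never double-count a CDS base.
  Per-repeat attribution is reported separately and may overlap.
* **Strict thresholds.** "Above 50%" and "above 800" are strict
  inequalities; a gene at exactly half overlap, or a transcript at
  exactly 800 points, fails.
* **Isoform policy.** A gene is represented by its transcript with the
  highest overlap fraction (ties: higher coding score, then lexicographic
  transcript id). The permissive `max` reading is the default; a
  `longest_cds` (canonical-like) policy is available.
* **Conservation.** A species conserves the ORF when its ortholog
  sequence contains an ATG-initiated, stop-terminated ORF at least 0.7×
  the reference ORF length (in codons). The ratio is exposed; 0.7 admits
  modest terminal erosion while rejecting frame-destroying changes. The
  criterion needs more than one species including the reference
  (`min_other_species = 1`).
* **TE class filter.** The allow-list {DNA, LINE, SINE, LTR, RC,
  Retroposon} and drop-list {Simple_repeat, Low_complexity, Satellite,
  rRNA, tRNA, snRNA, scRNA, srpRNA, Unknown, ARTEFACT} are configurable;
  classes on neither list are dropped with a warning (a conservative
  screen never counts unvetted annotation toward overlap).

## Coding-potential score

The score is a transparent additive surrogate for black-box
coding-potential classifiers, built from the four classic signals with a
strict pass threshold of 800 on a 0–1000 scale:

| component | default | rationale |
|---|---|---|
| ORF length | `round(900 · min(1, n_codons/300))` | saturates at 300 codons; dominant signal |
| Kozak | +50 purine at −3, +50 G at +4 | the two informative context positions |
| NMD | −200 if stop > 50 nt upstream of the last junction | the standard 50-nt rule |
| uORFs | −25 per uORF of ≥ 2 codons, floor −100 | initiation competition |

The length weight of 900 makes the maximum attainable total 1000
(900 + 100 Kozak), so the 800 threshold sits at a meaningful operating
point: a perfect-context ORF needs ~234 codons to pass, a context-free
one ~267, and either penalty can push a borderline transcript under. An
ORF at the 5' end of the sequence has no −3 context and can earn only
the +4 term. The main ORF is the longest ATG-initiated,
stop-terminated ORF (ties to the 5'-most start); a transcript without
one scores 0. All weights are configuration fields (`CodingWeights`).

## Composite reconstruction

Segmentation uses exact 12-mer seeding against each consensus in both
orientations, ungapped X-drop extension (match +1, mismatch −1, X-drop
8), greedy chaining of non-overlapping blocks by score, and fusion of
co-diagonal same-source blocks across substitution islands (gap ≤ 40 bp,
equal on locus and consensus). Ungapped chaining is sufficient for the
substitution-divergence regime the generator models and keeps every step
auditable; it is not a RepeatMasker replacement.

**Boundary canonicalisation.** When a base adjacent to a true segment
boundary happens to equal the consensus continuation of the neighbouring
segment (probability 1/4 per boundary base), two segmentations explain
the locus byte-for-byte and the boundary is formally unidentifiable.
Analogous to indel left-alignment in variant calling, boundaries are
normalised to *maximal exact extension with upstream priority*: each
block is trimmed to terminal exact runs of ≥ 6 matches (removing
mismatch-bridged chance extensions), extended while the exact consensus
continuation holds, and contested bases between adjacent blocks are
assigned to the upstream one. `canonicalize_spec` maps any assembly
specification to the same form by pure string arithmetic, which is what
makes the assemble→segment round trip exact at 0% divergence.

**TSD detection** searches the terminal 30 bp (configurable) of the
uncovered flanks for the longest duplicated suffix/prefix of length ≥ 6
with ≤ 1 mismatch, reflecting typical L1 target-site duplication sizes.
For random 30-bp flanks the probability of a spurious exact ≥ 8-mer hit
is ≈ 23·4⁻⁸ ≈ 3.5 × 10⁻³ per pair.

**Percent identity** defaults to excluding gap columns from the
denominator for both nucleotide and protein comparisons; counting gaps
as mismatches is selectable, and reports always name the policy. When
sequences are unaligned a global alignment (match +1, mismatch −1, gap
−2, no affine term) is produced first via Biopython.

## Deletion alleles

Deleted CDS bases are counted against the spliced CDS; the mod-3 rule
sets the consequence. For in-frame deletions, `aa_removed = bases/3`
counts whole codons lost; breakpoints inside codons fuse a substitute
codon at the junction and are flagged (`boundary_substitution`) rather
than altering the count — the reading under which a 147-bp deletion
"removes 49 amino acids". Frameshift alleles are translated to the first
stop of the mutant CDS. The bundled `synthetic_bex3_like_locus` fixture
is a deterministic synthetic stand-in (not the real gene's sequence)
placed at the published coordinates so that both printed deletions fall
inside its CDS; its codons around the knockout breakpoint are chosen so
the shifted frame exposes a premature TAA near the fusion point.

## Expression

`cRPKM = 10⁹ · c / (ℓ_eff · M)` with `ℓ_eff` the number of read-length
(default 50 nt) start positions whose k-mer occurs exactly once in the
whole transcriptome, and `M` the sample's total mapped reads. The 10⁹
constant fixes the "per kilobase per million" normalisation explicitly,
since descriptions of the metric vary in where the 10³ sits. Read
mapping itself is out of scope: counts are consumed, and uniqueness is
modelled at the exact k-mer level, which preserves the metric's defining
correction (a duplicated transcript pair has zero effective length in
both copies) deterministically and without downloads. Missing or partial
ortholog transcripts can be supplied as extra FASTA entries merged
before indexing. Zero effective length yields a missing value, never a
silent zero.

Row clustering is UPGMA on `1 − r` (Pearson) with ties broken by the
smallest pair of cluster indices; the implementation is in-package to
fix the tie-break and is cross-checked against scipy's average-linkage
on tie-free inputs.

## Enrichment

The upper tail is inclusive (`P(X ≥ k)`), the standard
over-representation convention, computed exactly via
`scipy.stats.hypergeom`. The universe is the set of genes tested in the
given dataset, not the whole genome. No cross-dataset multiple-testing
correction is applied by default, matching the per-dataset α = 0.05
design; Benjamini–Hochberg is available behind a flag.

## Synthetic data: what it emulates and what it does not

The generator's defaults define the study conditions: 20 planted
domestications and 200 negatives on one reference chromosome, 10%
per-copy TE divergence (substitutions only), ORFs of 350–450 codons in
Kozak context, 6–16 bp TSDs, TE fractions of 0.60–0.95 for positives and
0.25–0.45 for overlap-negatives, three species, a five-fold DE
enrichment of a 14-gene family over a 10% base rate at a universe of
2000 genes. Each negative fails exactly one criterion: sub-threshold
overlap, exact-50% overlap (two genes, probing the strict inequality),
frame-broken ORF (premature stops leave no ORF ≥ 120 codons), or
reference-only conservation (ortholog ORFs destroyed outside the
reference). Positives use ≥ 350-codon ORFs so intact genes sit well
above the 800-point threshold while frame-broken ones fall far below —
the separation the screen assumes.

Consensus sequences are synthetic random DNA (real repeat libraries are
redistribution-restricted); runs against a real RepeatMasker library are
a documented optional path via the same FASTA interface. Non-reference
species are emitted as per-gene ortholog transcript FASTAs — what the
conservation criterion consumes — rather than as full genomes.

Randomness: every artifact draws from `default_rng([master_seed,
crc32(artifact_id)])`, so outputs are byte-identical per (config, seed)
and adding an artifact never perturbs existing ones.

What passing tests therefore show — and do not: recovery is demonstrated
under substitution-only divergence ≤ 15% with uniform base composition;
real genomes add indels, nested insertions, segmental duplication and
ancient (> 30% diverged) copies, for which this screen, like the
annotation it consumes, loses sensitivity. An indel-free generator was a
deliberate trade for an auditable ungapped segmenter; degradation at
higher divergence is reported by the tests, not asserted.

## Problem sizes and numerical choices

Fixture sizes (220 genes, ~0.7 Mb genome, 50-spec round trips, 100
Poisson replicates, 200 power / 1000 null enrichment replicates) are
chosen so the entire suite and the acceptance script each complete in
seconds on one CPU while keeping Monte-Carlo standard errors small
relative to the asserted margins. Merge heights in UPGMA are exact
floating-point averages; score clamping bounds the coding total to
[0, 1000]; hypergeometric tails use scipy's exact survival function
(verified against combinatorial enumeration for N ≤ 20 in the tests).

## Known limitations

* The genome-wide candidate counts of any particular annotation freeze
  are not reproducible offline; the screen's correctness is demonstrated
  on planted truth instead.
* The coding score is a calibrated surrogate, not a re-implementation of
  any published classifier's exact point values; only its decision
  semantics (strict 800 on a ~1000 scale, four components) are fixed.
* The segmenter's boundary convention resolves formally unidentifiable
  boundaries deterministically; against real, indel-containing loci the
  reported junction positions carry the usual ±few-bp ambiguity of
  ungapped methods.
* Cross-species expression comparison assumes ortholog count tables are
  provided; ortholog assignment itself is out of scope.
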