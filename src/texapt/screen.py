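"""The domestication screen: which coding genes are built from TEs?

A gene is called a candidate domesticated transposon when three filters
pass jointly:

(i)   more than half of its coding region is covered by the union of
      annotated transposable-element fragments (strict ``fraction > 0.5``);
(ii)  its best transcript looks protein-coding, i.e. the coding-potential
      score strictly exceeds 800 (see :mod:`texapt.coding_potential`);
(iii) the open reading frame is conserved in more than one species.

Overlap is strand-agnostic by default: retrotransposition frequently
inserts fragments in inverted orientation (twin priming), so a same-strand
requirement would miss exactly the composite insertions this screen is
after.  A strand-aware re-run is available via ``ScreenParams``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from .coding_potential import (
    CodingPotentialScore,
    CodingWeights,
    DEFAULT_WEIGHTS,
    coding_score,
    find_main_orf,
)
from .io_annotations import (
    GenomeInterval,
    RepeatFeature,
    TranscriptModel,
    filter_te_classes,
    transcript_sequence,
)

__all__ = [
    "OverlapResult",
    "ConservationEvidence",
    "CandidateGene",
    "ScreenParams",
    "cds_te_overlap",
    "orf_conserved",
    "run_screen",
    "write_screen_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Per-transcript CDS x TE overlap accounting.

    ``overlapped_bases`` counts CDS positions covered by the *union* of
    repeat intervals (nested or adjacent RepeatMasker rows never double
    count).  ``per_repeat`` attributes bases per repeat name individually,
    so attribution may overlap; only the union total defines ``fraction``.
    """

    transcript_id: str
    cds_length: int
    overlapped_bases: int
    fraction: float
    per_repeat: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class ConservationEvidence:
    species_with_intact_orf: tuple[str, ...]
    n_species: int
    reference_included: bool


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    best_transcript: str
    overlap: OverlapResult
    coding: CodingPotentialScore
    conservation: ConservationEvidence
    pass_overlap: bool
    pass_score: bool
    pass_conservation: bool

    @property
    def verdict(self) -> bool:
        return self.pass_overlap and self.pass_score and self.pass_conservation


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds and policies of the screen.

    ``min_overlap`` and ``min_score`` are strict lower bounds ("above 50%",
    "above 800").  ``min_other_species`` counts conserving species beyond
    the reference; ``isoform_policy`` selects the transcript representing a
    gene ('max' = best overlap fraction, 'longest_cds' = canonical-like).
    """

    min_overlap: float = 0.5
    min_score: int = 800
    min_other_species: int = 1
    min_length_ratio: float = 0.7
    strand_aware: bool = False
    isoform_policy: str = "max"
    reference_species: str = "reference"
    filter_repeats: bool = True
    weights: CodingWeights = field(default_factory=CodingWeights)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = merged[-1]
        if s <= pe + 1:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def cds_te_overlap(
    tx: TranscriptModel,
    repeats: Sequence[RepeatFeature],
    strand_aware: bool = False,
) -> OverlapResult:
    """Fraction of the CDS covered by the union of repeat intervals.

    Repeats are expected to be TE-filtered already.  Coverage is computed
    per CDS base against the flattened union of same-chromosome repeat
    spans, so the result is deterministic for any input ordering and
    monotone in the repeat set.
    """
    if tx.cds_length == 0:
        raise ValueError(
            f"transcript {tx.transcript_id} has no CDS; cannot compute coding overlap"
        )
    relevant = [
        r
        for r in repeats
        if r.location.chrom == tx.chrom
        and (not strand_aware or r.location.strand == tx.strand)
    ]
    union = _merge_intervals([(r.location.start, r.location.end) for r in relevant])
    covered = 0
    for c in tx.cds:
        for s, e in union:
            if s > c.end:
                break
            covered += max(0, min(e, c.end) - max(s, c.start) + 1)
    per_repeat: dict[str, int] = {}
    for r in relevant:
        bases = sum(c.intersection_bp(r.location) for c in tx.cds)
        if bases:
            per_repeat[r.repeat_name] = per_repeat.get(r.repeat_name, 0) + bases
    return OverlapResult(
        transcript_id=tx.transcript_id,
        cds_length=tx.cds_length,
        overlapped_bases=covered,
        fraction=covered / tx.cds_length,
        per_repeat=tuple(sorted(per_repeat.items())),
    )


def orf_conserved(
    orthologs: Mapping[str, str],
    reference: str,
    min_other_species: int = 1,
    min_length_ratio: float = 0.7,
) -> ConservationEvidence:
    """Which species carry an intact ORF comparable to the reference's?

    A species conserves the ORF when its nucleotide sequence contains an
    ATG-initiated, stop-terminated ORF at least ``min_length_ratio`` times
    the reference ORF length (in codons).  The criterion passes when the
    qualifying count reaches ``min_other_species + 1`` including the
    reference; the pass decision itself is taken by the caller.
    """
    if reference not in orthologs:
        raise KeyError(f"reference species {reference!r} missing from ortholog set")
    ref_orf = find_main_orf(orthologs[reference]) if orthologs[reference] else None
    if ref_orf is None:
        return ConservationEvidence((), 0, False)
    needed = min_length_ratio * ref_orf.n_codons
    conserving: list[str] = []
    for species in sorted(orthologs):
        seq = orthologs[species]
        if not seq:
            warnings.warn(f"empty ortholog sequence for species {species!r}", stacklevel=2)
            continue
        orf = find_main_orf(seq)
        if orf is not None and orf.n_codons >= needed:
            conserving.append(species)
    return ConservationEvidence(
        species_with_intact_orf=tuple(conserving),
        n_species=len(conserving),
        reference_included=reference in conserving,
    )


def run_screen(
    genes: Iterable[TranscriptModel],
    repeats: Sequence[RepeatFeature],
    genome: Mapping[str, object],
    orthologs: Mapping[str, Mapping[str, str]],
    params: ScreenParams = ScreenParams(),
) -> list[CandidateGene]:
    """Screen every coding gene and return one verdict per gene.

    ``orthologs`` maps gene_id to a per-species dict of ortholog transcript
    sequences (the reference species included).  Genes with no coding
    transcript are skipped with a log entry; chromosomes absent from the
    repeat annotation simply contribute zero overlap.  Output is sorted by
    descending overlap fraction, then gene_id — fully deterministic and
    invariant to input record order.
    """
    te_repeats = filter_te_classes(repeats) if params.filter_repeats else list(repeats)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in genes:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    results: list[CandidateGene] = []
    for gene_id in sorted(by_gene):
        coding_txs = [t for t in by_gene[gene_id] if t.cds_length > 0]
        if not coding_txs:
            logger.info("gene %s has no coding transcript; skipped", gene_id)
            continue
        evaluated: list[tuple[TranscriptModel, OverlapResult, CodingPotentialScore]] = []
        for tx in sorted(coding_txs, key=lambda t: t.transcript_id):
            ov = cds_te_overlap(tx, te_repeats, strand_aware=params.strand_aware)
            sc = coding_score(tx, transcript_sequence(tx, genome), params.weights)
            evaluated.append((tx, ov, sc))
        if params.isoform_policy == "longest_cds":
            best = max(
                evaluated,
                key=lambda e: (e[0].cds_length, e[2].total, _neg_id(e[0].transcript_id)),
            )
        else:  # 'max': best overlap fraction, ties by score then lexicographic id
            best = max(
                evaluated,
                key=lambda e: (e[1].fraction, e[2].total, _neg_id(e[0].transcript_id)),
            )
        tx, ov, sc = best
        gene_orths = orthologs.get(gene_id)
        if gene_orths:
            cons = orf_conserved(
                gene_orths,
                reference=params.reference_species,
                min_other_species=params.min_other_species,
                min_length_ratio=params.min_length_ratio,
            )
        else:
            cons = ConservationEvidence((), 0, False)
        results.append(
            CandidateGene(
                gene_id=gene_id,
                best_transcript=tx.transcript_id,
                overlap=ov,
                coding=sc,
                conservation=cons,
                pass_overlap=ov.fraction > params.min_overlap,
                pass_score=sc.total > params.min_score,
                pass_conservation=(
                    cons.reference_included
                    and cons.n_species >= params.min_other_species + 1
                ),
            )
        )
    results.sort(key=lambda c: (-c.overlap.fraction, c.gene_id))
    return results


class _neg_id:
    """Inverts lexicographic order so max() prefers the smallest id on ties."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg_id") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_id) and self.s == other.s


REPORT_COLUMNS = (
    "gene_id",
    "transcript_id",
    "cds_length",
    "te_bases",
    "te_fraction",
    "coding_score",
    "n_species_conserved",
    "pass_overlap",
    "pass_score",
    "pass_conservation",
    "verdict",
)


def write_screen_report(candidates: Sequence[CandidateGene], out: TextIO) -> None:
    """Write the ranked candidate table as TSV."""
    out.write("\t".join(REPORT_COLUMNS) + "\n")
    for c in candidates:
        out.write(
            "\t".join(
                map(
                    str,
                    (
                        c.gene_id,
                        c.best_transcript,
                        c.overlap.cds_length,
                        c.overlap.overlapped_bases,
                        f"{c.overlap.fraction:.6f}",
                        c.coding.total,
                        c.conservation.n_species,
                        c.pass_overlap,
                        c.pass_score,
                        c.pass_conservation,
                        c.verdict,
                    ),
                )
            )
            + "\n"
        )
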