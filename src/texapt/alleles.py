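"""Consequence arithmetic for CRISPR deletion alleles.

Given a transcript model, its CDS sequence and a deleted genomic interval,
the module classifies the allele as an in-frame deletion, a frameshift or
non-coding, counts deleted CDS bases and removed residues, and — for
frameshifts — locates the premature stop codon by direct translation of
the mutant CDS.  Coordinates are 1-based inclusive, the convention forced
by the published deletion arithmetic (``end - start + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io_annotations import GenomeInterval, TranscriptModel

__all__ = [
    "DeletionAllele",
    "IN_FRAME",
    "FRAMESHIFT",
    "NON_CODING",
    "interval_length",
    "parse_region",
    "classify_deletion",
]

IN_FRAME = "in_frame_deletion"
FRAMESHIFT = "frameshift"
NON_CODING = "non_coding"


@dataclass(frozen=True)
class DeletionAllele:
    """Classified consequence of one deletion allele.

    ``aa_removed`` is defined for in-frame deletions only (whole codons
    lost; ``boundary_substitution`` flags deletions whose breakpoints fall
    inside codons, fusing a substitute codon at the junction).
    ``premature_stop_codon_index`` is the 0-based codon index of the first
    stop in the translated mutant CDS, for frameshift alleles.
    """

    name: str
    deleted: GenomeInterval
    consequence: str
    deleted_cds_bases: int
    aa_removed: int | None = None
    boundary_substitution: bool = False
    premature_stop_codon_index: int | None = None


def interval_length(iv: GenomeInterval) -> int:
    """Length in bp of a 1-based inclusive interval: ``end - start + 1``."""
    return iv.length


def parse_region(text: str) -> GenomeInterval:
    """Parse a ``chr:start-end`` string into a :class:`GenomeInterval`."""
    return GenomeInterval.from_string(text)


def _cds_genomic_positions(tx: TranscriptModel) -> list[int]:
    """Genomic positions of CDS bases, ordered along the coding sequence."""
    positions: list[int] = []
    for iv in tx.cds:
        positions.extend(range(iv.start, iv.end + 1))
    if tx.strand == "-":
        positions.reverse()
    return positions


def classify_deletion(
    tx: TranscriptModel,
    cds_seq: str,
    deleted: GenomeInterval,
    name: str = "allele",
) -> DeletionAllele:
    """Classify a genomic deletion against a transcript's CDS.

    ``cds_seq`` is the spliced CDS in transcription orientation and must
    match the model's CDS length.  The mod-3 rule on deleted CDS bases sets
    the consequence; frameshift alleles are translated to find the first
    premature stop.
    """
    if deleted.chrom != tx.chrom:
        raise ValueError(
            f"deletion on {deleted.chrom} but transcript {tx.transcript_id} on {tx.chrom}"
        )
    cds_seq = cds_seq.upper()
    positions = _cds_genomic_positions(tx)
    if len(positions) != len(cds_seq):
        raise ValueError(
            f"CDS sequence length {len(cds_seq)} does not match model "
            f"({len(positions)} bp) for {tx.transcript_id}"
        )
    removed = [
        i for i, pos in enumerate(positions) if deleted.start <= pos <= deleted.end
    ]
    n_removed = len(removed)
    if n_removed == 0:
        return DeletionAllele(
            name=name, deleted=deleted, consequence=NON_CODING, deleted_cds_bases=0
        )
    if n_removed % 3 != 0:
        removed_set = set(removed)
        mutant = "".join(b for i, b in enumerate(cds_seq) if i not in removed_set)
        mutant = mutant[: len(mutant) - len(mutant) % 3]
        protein = str(Seq(mutant).translate())
        stop = protein.find("*")
        return DeletionAllele(
            name=name,
            deleted=deleted,
            consequence=FRAMESHIFT,
            deleted_cds_bases=n_removed,
            premature_stop_codon_index=stop if stop >= 0 else None,
        )
    contiguous = removed[-1] - removed[0] + 1 == n_removed
    codon_aligned = contiguous and removed[0] % 3 == 0
    return DeletionAllele(
        name=name,
        deleted=deleted,
        consequence=IN_FRAME,
        deleted_cds_bases=n_removed,
        aa_removed=n_removed // 3,
        boundary_substitution=not codon_aligned,
    )
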