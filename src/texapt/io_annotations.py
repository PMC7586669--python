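"""Readers and writers for gene-model and repeat-annotation formats.

Every genomic coordinate handled by this package is **1-based and inclusive
on both ends**, the convention shared by GTF and RepeatMasker ``.out``
files: an interval ``start..end`` spans ``end - start + 1`` bases.  BED-style
exports, where offered, are 0-based half-open and labelled as such.

The module defines the three domain types consumed by the rest of the
pipeline — :class:`GenomeInterval`, :class:`TranscriptModel` and
:class:`RepeatFeature` — together with strict parsers that fail loudly
(naming the offending line or transcript) rather than silently coercing
malformed input.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomeInterval",
    "TranscriptModel",
    "RepeatFeature",
    "AnnotationError",
    "ParseError",
    "ValidationError",
    "parse_gtf",
    "write_gtf",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "filter_te_classes",
    "DEFAULT_TE_CLASSES",
    "DEFAULT_NON_TE_CLASSES",
    "fetch",
    "transcript_sequence",
    "cds_sequence",
]

VALID_STRANDS = frozenset({"+", "-", "."})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationError(ValueError):
    """Base class for annotation-layer failures."""


class ParseError(AnnotationError):
    """Raised when an input line cannot be parsed; names the line number."""


class ValidationError(AnnotationError):
    """Raised when parsed records violate a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 1-based, fully inclusive genomic span with strand.

    ``length == end - start + 1``; a single-base interval has start == end.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"interval end ({self.end}) precedes start ({self.start}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersection_bp(self, other: "GenomeInterval") -> int:
        """Number of bases shared with ``other`` (strand-agnostic)."""
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    @classmethod
    def from_string(cls, text: str, strand: str = ".") -> "GenomeInterval":
        """Parse a ``chr:start-end`` region string (1-based inclusive)."""
        m = re.fullmatch(r"([\w.]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ParseError(f"cannot parse region {text!r}; expected chrom:start-end")
        chrom, start, end = m.group(1), m.group(2), m.group(3)
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")), strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript isoform.

    Exons are kept sorted by genomic coordinate and must not overlap; every
    CDS interval must lie within a single exon.  CDS length is reported in
    bases without assuming divisibility by three (annotation reality).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomeInterval] = field(default_factory=list)
    cds: list[GenomeInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start <= prev.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS {c.start}-{c.end} "
                    "not contained in any exon"
                )

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    @property
    def mature_length(self) -> int:
        return sum(iv.length for iv in self.exons)

    def exons_in_transcription_order(self) -> list[GenomeInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker alignment row.

    ``consensus_span`` is the matched interval on the repeat consensus
    (1-based, bp); ``divergence_pct`` the percent mismatch to consensus.
    """

    location: GenomeInterval
    repeat_name: str
    repeat_class: str
    repeat_family: str = ""
    divergence_pct: float = 0.0
    consensus_span: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence_pct <= 100.0):
            raise ValidationError(
                f"divergence {self.divergence_pct} for {self.repeat_name} outside [0, 100]"
            )
        if self.consensus_span[1] < self.consensus_span[0]:
            raise ValidationError(
                f"consensus span {self.consensus_span} inverted for {self.repeat_name}"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(text))
    if "gene_id" not in attrs or "transcript_id" not in attrs:
        raise ParseError(
            f"GTF line {lineno}: attributes must carry gene_id and transcript_id"
        )
    return attrs


def parse_gtf(lines: Iterable[str]) -> list[TranscriptModel]:
    """Parse GTF ``exon``/``CDS`` records into :class:`TranscriptModel` objects.

    Other feature types are ignored.  Coordinates are taken verbatim
    (1-based inclusive).  Malformed lines raise :class:`ParseError` naming
    the line number; a CDS interval outside every exon of its transcript
    raises :class:`ValidationError` naming the transcript.
    """
    # transcript_id -> [gene_id, chrom, strand, exons, cds]
    acc: dict[str, list] = {}
    order: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(
                f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
        if feature not in ("exon", "CDS"):
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"GTF line {lineno}: non-numeric coordinate") from None
        try:
            iv = GenomeInterval(chrom, start, end, strand)
        except ValidationError as exc:
            raise ParseError(f"GTF line {lineno}: {exc}") from None
        attrs = _parse_attributes(attr_s, lineno)
        tid = attrs["transcript_id"]
        if tid not in acc:
            acc[tid] = [attrs["gene_id"], chrom, strand, [], []]
            order.append(tid)
        rec = acc[tid]
        if rec[1] != chrom or rec[2] != strand:
            raise ParseError(
                f"GTF line {lineno}: transcript {tid} spans multiple chromosomes/strands"
            )
        rec[3 if feature == "exon" else 4].append(iv)
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=acc[tid][0],
            chrom=acc[tid][1],
            strand=acc[tid][2],
            exons=acc[tid][3],
            cds=acc[tid][4],
        )
        for tid in order
    ]


def write_gtf(models: Iterable[TranscriptModel], source: str = "texapt") -> Iterator[str]:
    """Serialise transcript models to GTF lines (inverse of :func:`parse_gtf`)."""
    for tx in models:
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        for feature, ivs in (("exon", tx.exons), ("CDS", tx.cds)):
            for iv in ivs:
                yield "\t".join(
                    (
                        tx.chrom,
                        source,
                        feature,
                        str(iv.start),
                        str(iv.end),
                        ".",
                        tx.strand,
                        ".",
                        attrs,
                    )
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

RM_HEADER = (
    "   SW   perc perc perc  query      position in query           matching"
    "       repeat              position in repeat",
    "score   div. del. ins.  sequence    begin end          (left)  repeat"
    "         class/family      begin  end    (left)    ID",
    "",
)


def parse_repeatmasker_out(lines: Iterable[str]) -> list[RepeatFeature]:
    """Parse the whitespace-delimited RepeatMasker ``.out`` table.

    The three standard header lines (two captions plus a blank) are
    skipped.  Orientation ``C`` maps to strand ``-``; the ``class/family``
    column is split on the first ``/`` with an empty family when absent.
    Consensus coordinates follow the RepeatMasker layout: columns
    ``begin end (left)`` on the plus strand and ``(left) end begin`` for
    ``C`` alignments.
    """
    feats: list[RepeatFeature] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        cols = line.split()
        if not cols[0].lstrip("-").isdigit():
            if lineno <= 3:
                continue  # caption lines
            raise ParseError(f".out line {lineno}: non-numeric score field {cols[0]!r}")
        if len(cols) < 14:
            raise ParseError(
                f".out line {lineno}: expected >= 14 whitespace-separated columns, got {len(cols)}"
            )
        try:
            div = float(cols[1])
            qstart, qend = int(cols[5]), int(cols[6])
            strand_code = cols[8]
            name = cols[9]
            clsfam = cols[10]
            rm_cols = [c.strip("()") for c in cols[11:14]]
            if strand_code == "+":
                cons = (int(rm_cols[0]), int(rm_cols[1]))
                strand = "+"
            elif strand_code == "C":
                cons = (int(rm_cols[2]), int(rm_cols[1]))
                strand = "-"
            else:
                raise ParseError(
                    f".out line {lineno}: orientation must be '+' or 'C', got {strand_code!r}"
                )
        except ValueError:
            raise ParseError(f".out line {lineno}: non-numeric coordinate") from None
        rclass, _, rfamily = clsfam.partition("/")
        feats.append(
            RepeatFeature(
                location=GenomeInterval(cols[4], qstart, qend, strand),
                repeat_name=name,
                repeat_class=rclass,
                repeat_family=rfamily,
                divergence_pct=div,
                consensus_span=cons,
            )
        )
    return feats


def write_repeatmasker_out(features: Iterable[RepeatFeature]) -> Iterator[str]:
    """Serialise repeat features back to ``.out`` rows (with header)."""
    yield from RM_HEADER
    for i, f in enumerate(features, start=1):
        clsfam = (
            f"{f.repeat_class}/{f.repeat_family}" if f.repeat_family else f.repeat_class
        )
        cb, ce = f.consensus_span
        if f.location.strand == "-":
            orient, rcols = "C", (f"({0})", str(ce), str(cb))
        else:
            orient, rcols = "+", (str(cb), str(ce), f"({0})")
        yield (
            f"{1000:>5} {f.divergence_pct:>5.1f}  0.0  0.0  "
            f"{f.location.chrom:<12} {f.location.start:>8} {f.location.end:>8} (0) "
            f"{orient} {f.repeat_name:<14} {clsfam:<18} "
            f"{rcols[0]:>6} {rcols[1]:>6} {rcols[2]:>7} {i:>5}"
        )


# ---------------------------------------------------------------------------
# TE class filtering
# ---------------------------------------------------------------------------

#: RepeatMasker classes retained as bona fide transposable elements.
DEFAULT_TE_CLASSES = frozenset({"DNA", "LINE", "SINE", "LTR", "RC", "Retroposon"})

#: Classes discarded as non-TE annotation (simple/low-complexity/structural RNA).
DEFAULT_NON_TE_CLASSES = frozenset(
    {
        "Simple_repeat",
        "Low_complexity",
        "Satellite",
        "rRNA",
        "tRNA",
        "snRNA",
        "scRNA",
        "srpRNA",
        "Unknown",
        "ARTEFACT",
    }
)


def filter_te_classes(
    features: Sequence[RepeatFeature],
    allow: frozenset[str] | set[str] | None = None,
    drop: frozenset[str] | set[str] | None = None,
) -> list[RepeatFeature]:
    """Keep only repeat features whose class is on the TE allow-list.

    Classes on neither list are dropped with a warning (a conservative
    screen: unannotated classes never count toward TE overlap).  The input
    is not modified and relative order is preserved; the operation is
    idempotent.
    """
    allow = DEFAULT_TE_CLASSES if allow is None else frozenset(allow)
    drop = DEFAULT_NON_TE_CLASSES if drop is None else frozenset(drop)
    kept: list[RepeatFeature] = []
    unknown: set[str] = set()
    for f in features:
        base = f.repeat_class.rstrip("?")  # RepeatMasker marks uncertain classes "LINE?"
        if base in allow:
            kept.append(f)
        elif base not in drop:
            unknown.add(f.repeat_class)
    if unknown:
        warnings.warn(
            f"dropping repeat classes on neither allow nor drop list: {sorted(unknown)}",
            stacklevel=2,
        )
    return kept


# ---------------------------------------------------------------------------
# sequence access
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Extract ``chrom:start-end`` (1-based inclusive) as an upper-case string.

    Works with plain ``{chrom: str}`` dicts as well as indexed FASTA
    handles (e.g. ``pyfaidx.Fasta``) — anything whose per-chromosome value
    supports slicing.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not present in sequence source")
    return str(genome[chrom][start - 1 : end]).upper()


def transcript_sequence(tx: TranscriptModel, genome: Mapping[str, object]) -> str:
    """Spliced (mature) transcript sequence in transcription orientation."""
    seq = "".join(fetch(genome, tx.chrom, iv.start, iv.end) for iv in tx.exons)
    return reverse_complement(seq) if tx.strand == "-" else seq


def cds_sequence(tx: TranscriptModel, genome: Mapping[str, object]) -> str:
    """Spliced CDS sequence in transcription orientation."""
    seq = "".join(fetch(genome, tx.chrom, iv.start, iv.end) for iv in tx.cds)
    return reverse_complement(seq) if tx.strand == "-" else seq
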