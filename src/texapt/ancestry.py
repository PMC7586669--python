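"""Composite retroelement reconstruction.

Non-LTR retrotransposition can leave a locus assembled from several
consensus-derived fragments: target-primed reverse transcription flanks
the insertion with a short target-site duplication (TSD), and twin priming
internally inverts part of the element, leaving an inversion junction
where orientation flips.  This module provides the forward operation —
assembling an ancestral composite from consensus segments — and the
inverse one — re-segmenting an observed locus against a consensus library,
recovering segment sources, orientations, inversion junctions and the TSD.

Boundary canonicalisation
-------------------------
When a base adjacent to a true segment boundary happens to coincide with
the consensus continuation of the neighbouring segment, two different
segmentations explain the locus byte-for-byte and the boundary is formally
unidentifiable.  Analogous to indel left-alignment in variant calling, the
package fixes a canonical convention: boundaries are resolved by *maximal
exact extension with upstream priority* (the first segment additionally
extends leftward into the 5' flank).  :func:`segment_composite` normalises
its output to this convention and :func:`canonicalize_spec` maps any
assembly specification to the same form, making round trips exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

from .io_annotations import reverse_complement

__all__ = [
    "SegmentRequest",
    "CompositeSegment",
    "CompositeElement",
    "TsdHit",
    "IdentityReport",
    "assemble_composite",
    "detect_tsd",
    "segment_composite",
    "canonicalize_spec",
    "percent_identity",
]

FORWARD = "forward"
INVERTED = "inverted"


@dataclass(frozen=True)
class SegmentRequest:
    """One requested consensus slice of a composite (1-based inclusive span)."""

    source_name: str
    start: int
    end: int
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, INVERTED):
            raise ValueError(f"orientation must be forward|inverted, got {self.orientation!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"malformed consensus span {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CompositeSegment:
    """A consensus-derived block placed on the locus (both spans 1-based)."""

    source_name: str
    consensus_start: int
    consensus_end: int
    orientation: str
    locus_start: int
    locus_end: int

    @property
    def length(self) -> int:
        return self.locus_end - self.locus_start + 1


@dataclass(frozen=True)
class CompositeElement:
    """An ordered set of segments with TSD and inversion junctions.

    ``inversion_junctions`` holds the 1-based locus position of the first
    base of the downstream segment at every orientation flip between
    adjacent segments.
    """

    segments: tuple[CompositeSegment, ...]
    tsd: str
    inversion_junctions: tuple[int, ...]
    assembled_length: int

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.locus_start <= a.locus_end:
                raise ValueError("composite segments must be ordered and non-overlapping")


@dataclass(frozen=True)
class TsdHit:
    sequence: str
    length: int
    mismatches: int


@dataclass(frozen=True)
class IdentityReport:
    aligned_columns: int
    identical_columns: int
    percent_identity: float
    gap_policy: str


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _segment_sequence(req: SegmentRequest, library: Mapping[str, str]) -> str:
    if req.source_name not in library:
        raise KeyError(f"consensus {req.source_name!r} not in library")
    cons = library[req.source_name]
    if req.end > len(cons):
        raise ValueError(
            f"span {req.start}-{req.end} outside consensus {req.source_name} "
            f"(length {len(cons)})"
        )
    sub = cons[req.start - 1 : req.end].upper()
    return reverse_complement(sub) if req.orientation == INVERTED else sub


def assemble_composite(
    requests: Sequence[SegmentRequest],
    library: Mapping[str, str],
    tsd: str = "",
) -> tuple[CompositeElement, str]:
    """Concatenate consensus slices (inverted ones reverse-complemented)
    between two copies of the TSD.

    Returns the structural description together with the assembled
    nucleotide sequence ``tsd + segments + tsd``.
    """
    tsd = tsd.upper()
    pieces: list[str] = [tsd]
    segments: list[CompositeSegment] = []
    junctions: list[int] = []
    pos = len(tsd)
    for i, req in enumerate(requests):
        seq = _segment_sequence(req, library)
        segments.append(
            CompositeSegment(
                source_name=req.source_name,
                consensus_start=req.start,
                consensus_end=req.end,
                orientation=req.orientation,
                locus_start=pos + 1,
                locus_end=pos + len(seq),
            )
        )
        if i > 0 and requests[i - 1].orientation != req.orientation:
            junctions.append(pos + 1)
        pieces.append(seq)
        pos += len(seq)
    pieces.append(tsd)
    full = "".join(pieces)
    element = CompositeElement(
        segments=tuple(segments),
        tsd=tsd,
        inversion_junctions=tuple(junctions),
        assembled_length=len(full),
    )
    return element, full


# ---------------------------------------------------------------------------
# target-site duplication
# ---------------------------------------------------------------------------


def detect_tsd(
    upstream_flank: str,
    downstream_flank: str,
    min_len: int = 6,
    max_mismatch: int = 1,
    window: int = 30,
) -> TsdHit | None:
    """Longest suffix of the upstream flank duplicated as a prefix of the
    downstream flank.

    Only the terminal ``window`` bases of each flank are searched (typical
    L1 TSDs are 6-20 bp).  Candidates need length >= ``min_len`` and at
    most ``max_mismatch`` mismatches; the longest wins, and for a given
    length the suffix/prefix register admits a single candidate, so fewer
    mismatches is the secondary preference across equal-length windows.
    """
    up = upstream_flank.upper()[-window:]
    down = downstream_flank.upper()[:window]
    best: TsdHit | None = None
    for length in range(min(len(up), len(down)), min_len - 1, -1):
        a = up[-length:]
        b = down[:length]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm <= max_mismatch:
            cand = TsdHit(sequence=a, length=length, mismatches=mm)
            if best is None or cand.length > best.length or (
                cand.length == best.length and cand.mismatches < best.mismatches
            ):
                best = cand
            break  # longest-first scan: first acceptable length is maximal
    return best


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


class _Target:
    """A consensus sequence in one orientation, with coordinate mapping."""

    __slots__ = ("name", "orientation", "seq", "cons_len")

    def __init__(self, name: str, orientation: str, seq: str, cons_len: int) -> None:
        self.name = name
        self.orientation = orientation
        self.seq = seq
        self.cons_len = cons_len

    def consensus_span(self, t_start: int, length: int) -> tuple[int, int]:
        """Map a 0-based slice of the oriented target to 1-based consensus coords."""
        if self.orientation == FORWARD:
            return t_start + 1, t_start + length
        return self.cons_len - (t_start + length) + 1, self.cons_len - t_start


@dataclass
class _Block:
    target: _Target
    q_start: int  # 0-based inclusive on locus
    q_end: int
    t_start: int  # 0-based inclusive on oriented target
    score: int = 0

    @property
    def length(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def t_end(self) -> int:
        return self.t_start + self.length - 1


def _xdrop_extend(q: str, t: str, qi: int, ti: int, k: int, xdrop: int) -> tuple[int, int, int]:
    """Ungapped X-drop extension of a length-k exact seed in both directions.

    Returns (q_start, q_end, t_start) of the maximally scoring block, with
    the earliest maximum preferred so extensions never end on a mismatch.
    """
    # rightward
    score = k
    best_score, best_i = score, qi + k - 1
    i, j = qi + k, ti + k
    while i < len(q) and j < len(t):
        score += 1 if q[i] == t[j] else -1
        if score > best_score:
            best_score, best_i = score, i
        if best_score - score >= xdrop:
            break
        i += 1
        j += 1
    q_end = best_i
    # leftward
    score = best_score
    best_left = score
    left_i = qi
    i, j = qi - 1, ti - 1
    while i >= 0 and j >= 0:
        score += 1 if q[i] == t[j] else -1
        if score > best_left:
            best_left, left_i = score, i
        if best_left - score >= xdrop:
            break
        i -= 1
        j -= 1
    q_start = left_i
    return q_start, q_end, ti - (qi - q_start)


def _polish(block: _Block, q: str, end_run: int) -> _Block | None:
    """Trim block ends to terminal exact runs of >= end_run matches, then
    extend each end by maximal exact continuation.

    Bridged chance extensions (a mismatch followed by a couple of lucky
    matches) are removed; contiguous exact continuation past the planted
    boundary is kept, matching the canonical convention.
    """
    t = block.target.seq
    n = block.length
    mask = [q[block.q_start + i] == t[block.t_start + i] for i in range(n)]
    run = 0
    a = None
    for i in range(n):
        run = run + 1 if mask[i] else 0
        if run >= end_run:
            a = i - end_run + 1
            break
    if a is None:
        return None
    run = 0
    b = None
    for i in range(n - 1, -1, -1):
        run = run + 1 if mask[i] else 0
        if run >= end_run:
            b = i + end_run - 1
            break
    if b is None or b < a:
        return None
    qs, qe = block.q_start + a, block.q_start + b
    ts = block.t_start + a
    # maximal exact extension on both ends
    while qe + 1 < len(q) and ts + (qe - qs) + 1 < len(t) and q[qe + 1] == t[ts + (qe - qs) + 1]:
        qe += 1
    while qs - 1 >= 0 and ts - 1 >= 0 and q[qs - 1] == t[ts - 1]:
        qs -= 1
        ts -= 1
    length = qe - qs + 1
    matches = sum(1 for i in range(length) if q[qs + i] == t[ts + i])
    return _Block(block.target, qs, qe, ts, score=2 * matches - length)


def _find_blocks(
    q: str, targets: list[_Target], seed_len: int, xdrop: int, end_run: int
) -> list[_Block]:
    blocks: list[_Block] = []
    for target in targets:
        t = target.seq
        index: dict[str, list[int]] = {}
        for i in range(len(t) - seed_len + 1):
            index.setdefault(t[i : i + seed_len], []).append(i)
        seen_diag: dict[int, int] = {}  # diagonal -> q_end already explained
        for qi in range(len(q) - seed_len + 1):
            for ti in index.get(q[qi : qi + seed_len], ()):
                d = qi - ti
                if seen_diag.get(d, -1) >= qi:
                    continue
                qs, qe, ts = _xdrop_extend(q, t, qi, ti, seed_len, xdrop)
                seen_diag[d] = qe
                polished = _polish(_Block(target, qs, qe, ts), q, end_run)
                if polished is not None:
                    blocks.append(polished)
    # dedupe identical spans (multiple seeds in one block)
    uniq: dict[tuple, _Block] = {}
    for b in blocks:
        key = (b.target.name, b.target.orientation, b.q_start, b.q_end, b.t_start)
        uniq[key] = b
    return list(uniq.values())


def _greedy_select(blocks: list[_Block], min_block: int) -> list[_Block]:
    order = sorted(
        blocks,
        key=lambda b: (-b.score, b.q_start, b.target.name, b.target.orientation),
    )
    accepted: list[_Block] = []
    for b in order:
        qs, qe, ts = b.q_start, b.q_end, b.t_start
        conflict = False
        for acc in accepted:
            if acc.q_start <= qe and qs <= acc.q_end:
                if acc.q_start <= qs and acc.q_end < qe:
                    delta = acc.q_end + 1 - qs
                    qs += delta
                    ts += delta
                elif acc.q_end >= qe and acc.q_start > qs:
                    qe = acc.q_start - 1
                else:
                    conflict = True
                    break
        if conflict or qe - qs + 1 < min_block:
            continue
        accepted.append(_Block(b.target, qs, qe, ts, score=b.score))
    accepted.sort(key=lambda b: b.q_start)
    return accepted


def _resolve_boundaries(blocks: list[_Block], q: str, min_block: int) -> list[_Block]:
    """Move contested bases to the upstream block (canonical convention)."""
    out: list[_Block] = []
    for b in blocks:
        if out:
            prev = out[-1]
            t = prev.target.seq
            qe, te = prev.q_end, prev.t_end
            while (
                qe + 1 <= b.q_end
                and te + 1 < len(t)
                and q[qe + 1] == t[te + 1]
            ):
                qe += 1
                te += 1
            if qe != prev.q_end:
                out[-1] = _Block(prev.target, prev.q_start, qe, prev.t_start, prev.score)
                delta = qe + 1 - b.q_start
                if delta > 0:
                    if b.length - delta < min_block:
                        continue
                    b = _Block(b.target, b.q_start + delta, b.q_end, b.t_start + delta, b.score)
        out.append(b)
    return out


def _merge_adjacent(blocks: list[_Block], max_merge_gap: int) -> list[_Block]:
    """Fuse co-diagonal same-source blocks separated by a substitution island."""
    out: list[_Block] = []
    for b in blocks:
        if out:
            a = out[-1]
            same = (
                a.target.name == b.target.name
                and a.target.orientation == b.target.orientation
            )
            q_gap = b.q_start - a.q_end - 1
            t_gap = b.t_start - a.t_end - 1
            if same and 0 <= q_gap <= max_merge_gap and q_gap == t_gap:
                out[-1] = _Block(
                    a.target, a.q_start, b.q_end, a.t_start, a.score + b.score - q_gap
                )
                continue
        out.append(b)
    return out


def segment_composite(
    locus_seq: str,
    library: Mapping[str, str],
    min_block: int = 30,
    seed_len: int = 12,
    xdrop: int = 8,
    end_run: int = 6,
    max_merge_gap: int = 40,
    tsd_min_len: int = 6,
    tsd_max_mismatch: int = 1,
) -> CompositeElement:
    """Decompose a locus into consensus-derived segments.

    Exact ``seed_len``-mer seeding, ungapped X-drop extension, greedy
    chaining of non-overlapping blocks, canonical boundary resolution and
    fusion of co-diagonal blocks across substitution islands.  Uncovered
    5'/3' flanks are scanned for a target-site duplication.  Returns an
    empty :class:`CompositeElement` when no block reaches ``min_block``.
    """
    if not library:
        raise ValueError("consensus library is empty")
    q = locus_seq.upper()
    targets: list[_Target] = []
    for name in sorted(library):
        cons = library[name].upper()
        targets.append(_Target(name, FORWARD, cons, len(cons)))
        targets.append(_Target(name, INVERTED, reverse_complement(cons), len(cons)))
    blocks = _find_blocks(q, targets, seed_len, xdrop, end_run)
    blocks = _greedy_select(blocks, min_block)
    blocks = _resolve_boundaries(blocks, q, min_block)
    blocks = _merge_adjacent(blocks, max_merge_gap)
    blocks = [b for b in blocks if b.length >= min_block]
    if not blocks:
        return CompositeElement((), "", (), len(q))

    segments: list[CompositeSegment] = []
    junctions: list[int] = []
    for i, b in enumerate(blocks):
        cs, ce = b.target.consensus_span(b.t_start, b.length)
        segments.append(
            CompositeSegment(
                source_name=b.target.name,
                consensus_start=cs,
                consensus_end=ce,
                orientation=b.target.orientation,
                locus_start=b.q_start + 1,
                locus_end=b.q_end + 1,
            )
        )
        if i > 0 and blocks[i - 1].target.orientation != b.target.orientation:
            junctions.append(b.q_start + 1)
    prefix = q[: blocks[0].q_start]
    suffix = q[blocks[-1].q_end + 1 :]
    tsd = ""
    if len(prefix) >= tsd_min_len and len(suffix) >= tsd_min_len:
        hit = detect_tsd(prefix, suffix, min_len=tsd_min_len, max_mismatch=tsd_max_mismatch)
        if hit is not None:
            tsd = hit.sequence
    return CompositeElement(
        segments=tuple(segments),
        tsd=tsd,
        inversion_junctions=tuple(junctions),
        assembled_length=len(q),
    )


def canonicalize_spec(
    requests: Sequence[SegmentRequest],
    library: Mapping[str, str],
    tsd: str = "",
) -> tuple[list[CompositeSegment], str, str, tuple[int, ...]]:
    """Canonical form of an assembly spec under the boundary convention.

    Pure string arithmetic, independent of the segmentation machinery:
    each segment's end extends by maximal exact consensus continuation
    (upstream priority at internal boundaries; the first segment also
    extends leftward into the 5' flank).  Returns the canonical segments,
    the residual 5'/3' flanks and the inversion-junction positions.
    """
    tsd = tsd.upper()
    oriented: list[tuple[SegmentRequest, str, int]] = []  # (req, target string, t_start)
    for req in requests:
        cons = library[req.source_name].upper()
        if req.orientation == FORWARD:
            oriented.append((req, cons, req.start - 1))
        else:
            oriented.append(
                (req, reverse_complement(cons), len(cons) - req.end)
            )
    locus = tsd + "".join(
        t[ts : ts + req.length] for req, t, ts in oriented
    ) + tsd

    spans: list[tuple[int, int, int]] = []  # (locus_start0, t_start, length) post-extension
    cursor = len(tsd)
    claimed = 0  # end of upstream claims (0-based exclusive)
    starts: list[int] = []
    pos = len(tsd)
    for req, _, _ in oriented:
        starts.append(pos)
        pos += req.length
    for i, (req, t, ts) in enumerate(oriented):
        s = starts[i]
        length = req.length
        if i == 0:
            while s > 0 and ts > 0 and locus[s - 1] == t[ts - 1]:
                s -= 1
                ts -= 1
                length += 1
        if s < claimed:  # upstream segment claimed our head
            delta = claimed - s
            s += delta
            ts += delta
            length -= delta
        while s + length < len(locus) and ts + length < len(t) and locus[s + length] == t[ts + length]:
            length += 1
        spans.append((s, ts, length))
        claimed = s + length
    segments: list[CompositeSegment] = []
    junctions: list[int] = []
    for i, ((req, t, _), (s, ts, length)) in enumerate(zip(oriented, spans)):
        cons_len = len(library[req.source_name])
        if req.orientation == FORWARD:
            cs, ce = ts + 1, ts + length
        else:
            cs, ce = cons_len - (ts + length) + 1, cons_len - ts
        segments.append(
            CompositeSegment(req.source_name, cs, ce, req.orientation, s + 1, s + length)
        )
        if i > 0 and requests[i - 1].orientation != req.orientation:
            junctions.append(s + 1)
    prefix = locus[: spans[0][0]]
    suffix = locus[spans[-1][0] + spans[-1][2] :]
    return segments, prefix, suffix, tuple(junctions)


# ---------------------------------------------------------------------------
# percent identity
# ---------------------------------------------------------------------------

EXCLUDE_GAPS = "exclude_gap_columns"
GAPS_AS_MISMATCH = "count_gaps_as_mismatch"


def _global_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def percent_identity(
    seq_a: str,
    seq_b: str,
    aligned: bool = False,
    gap_policy: str = EXCLUDE_GAPS,
) -> IdentityReport:
    """Percent identity between two sequences (nucleotide or protein).

    With ``aligned=False`` a global alignment is produced first (match +1,
    mismatch -1, gap -2, no affine term).  ``gap_policy`` selects whether
    gap columns are excluded from the denominator or counted as
    mismatches.
    """
    if gap_policy not in (EXCLUDE_GAPS, GAPS_AS_MISMATCH):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    a, b = (seq_a.upper(), seq_b.upper())
    if aligned:
        if len(a) != len(b):
            raise ValueError("pre-aligned sequences must have equal length")
    else:
        a, b = _global_align(a, b)
    columns = len(a)
    identical = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    if gap_policy == EXCLUDE_GAPS:
        compared = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    else:
        compared = columns
    pct = 100.0 * identical / compared if compared else 0.0
    return IdentityReport(
        aligned_columns=columns,
        identical_columns=identical,
        percent_identity=pct,
        gap_policy=gap_policy,
    )
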