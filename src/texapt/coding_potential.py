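"""A transparent coding-potential score for spliced transcripts.

The screen's second filter asks whether a transcript looks protein-coding,
combining four classic signals: the length of the main open reading frame,
the Kozak context of its initiator ATG, vulnerability to nonsense-mediated
decay (the 50-nt rule), and the burden of upstream ORFs.  This module
implements those four components as an auditable additive score on a
0–1000 scale with a strict pass threshold of 800, so that "score above
800" keeps its decision semantics while every point is attributable to a
named, configurable weight:

===========================  =======================================
component                    default
===========================  =======================================
ORF length                   ``round(900 * min(1, n_codons / 300))``
Kozak context                +50 for a purine at −3, +50 for G at +4
NMD (50-nt rule)             −200 when the stop codon sits > 50 nt
                             upstream of the last exon–exon junction
upstream ORFs                −25 per uORF of ≥ 2 codons, floored at −100
===========================  =======================================

The total is clamped to [0, 1000].  A transcript with no ATG-initiated
ORF scores 0.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .io_annotations import TranscriptModel

__all__ = [
    "OrfCall",
    "CodingWeights",
    "CodingPotentialScore",
    "DEFAULT_WEIGHTS",
    "find_main_orf",
    "find_all_orfs",
    "kozak_points",
    "nmd_points",
    "uorf_points",
    "coding_score",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfCall:
    """An ATG-initiated ORF located on a mature transcript sequence.

    Offsets are 0-based on the spliced sequence; ``end_offset`` points just
    past the stop codon, so ``end_offset - start_offset`` is divisible by 3
    and ``n_codons`` excludes the stop.
    """

    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        if (self.end_offset - self.start_offset) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        if self.end_offset - self.start_offset < 6:
            raise ValueError("ORF must comprise at least start and stop codons")

    @property
    def n_codons(self) -> int:
        return (self.end_offset - self.start_offset) // 3 - 1

    @property
    def frame(self) -> int:
        return self.start_offset % 3


@dataclass(frozen=True)
class CodingWeights:
    """Tunable weights of the coding-potential score (points)."""

    length_max_points: int = 900
    length_saturation_codons: int = 300
    kozak_minus3: int = 50
    kozak_plus4: int = 50
    nmd_penalty: int = -200
    nmd_distance_nt: int = 50
    uorf_penalty: int = -25
    uorf_floor: int = -100
    clamp_max: int = 1000
    threshold: int = 800


DEFAULT_WEIGHTS = CodingWeights()


@dataclass(frozen=True)
class CodingPotentialScore:
    orf_length_component: int
    kozak_component: int
    nmd_penalty: int
    uorf_penalty: int
    total: int
    passes: bool
    orf: OrfCall | None


# ---------------------------------------------------------------------------
# ORF discovery
# ---------------------------------------------------------------------------


def _stop_positions_by_frame(seq: str) -> list[list[int]]:
    stops: list[list[int]] = [[], [], []]
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops[i % 3].append(i)
    return stops


def find_all_orfs(mature_seq: str) -> list[OrfCall]:
    """All ATG-initiated, stop-terminated ORFs on the forward sequence."""
    seq = mature_seq.upper()
    stops = _stop_positions_by_frame(seq)
    orfs: list[OrfCall] = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        frame_stops = stops[i % 3]
        j = bisect.bisect_left(frame_stops, i + 3)
        if j < len(frame_stops):
            orfs.append(OrfCall(i, frame_stops[j] + 3))
    return orfs


def find_main_orf(mature_seq: str) -> OrfCall | None:
    """Longest ATG-initiated ORF; ties broken by the 5'-most start.

    Returns ``None`` (an explicit no-call) when the sequence contains no
    ATG with an in-frame stop.
    """
    best: OrfCall | None = None
    for orf in find_all_orfs(mature_seq):
        if best is None or orf.n_codons > best.n_codons:
            best = orf
    return best


# ---------------------------------------------------------------------------
# score components
# ---------------------------------------------------------------------------


def kozak_points(
    mature_seq: str, orf: OrfCall, weights: CodingWeights = DEFAULT_WEIGHTS
) -> int:
    """Points for the Kozak initiation context (purine at −3, G at +4).

    An ORF starting within the first three bases has no −3 context and can
    only earn the +4 term.
    """
    seq = mature_seq.upper()
    pts = 0
    if orf.start_offset >= 3 and seq[orf.start_offset - 3] in "AG":
        pts += weights.kozak_minus3
    plus4 = orf.start_offset + 3
    if plus4 < len(seq) and seq[plus4] == "G":
        pts += weights.kozak_plus4
    return pts


def nmd_points(
    tx: TranscriptModel, orf: OrfCall, weights: CodingWeights = DEFAULT_WEIGHTS
) -> int:
    """Nonsense-mediated-decay penalty under the 50-nt rule.

    A stop codon more than ``nmd_distance_nt`` bases upstream of the last
    exon–exon junction marks the transcript for degradation (−200 points by
    default).  Single-exon transcripts carry no junction and never incur
    the penalty.
    """
    mature_len = tx.mature_length
    if orf.end_offset > mature_len:
        raise ValueError(
            f"ORF end {orf.end_offset} exceeds mature length {mature_len} "
            f"of transcript {tx.transcript_id}"
        )
    ordered = tx.exons_in_transcription_order()
    if len(ordered) < 2:
        return 0
    last_junction = mature_len - ordered[-1].length
    if last_junction - orf.end_offset > weights.nmd_distance_nt:
        return weights.nmd_penalty
    return 0


def uorf_points(
    mature_seq: str, orf: OrfCall, weights: CodingWeights = DEFAULT_WEIGHTS
) -> int:
    """Penalty for upstream ORFs wholly 5' of the main start.

    Each ATG initiating an ORF of at least two codons whose stop ends at or
    before the main start counts once; the penalty is floored.
    """
    n = sum(
        1
        for u in find_all_orfs(mature_seq[: orf.start_offset])
        if u.n_codons >= 2
    )
    return max(n * weights.uorf_penalty, weights.uorf_floor)


def coding_score(
    tx: TranscriptModel,
    mature_seq: str,
    weights: CodingWeights = DEFAULT_WEIGHTS,
) -> CodingPotentialScore:
    """Composite coding-potential score of a spliced transcript.

    ``mature_seq`` must be the spliced sequence of ``tx`` (lengths are
    checked).  ``passes`` is strict: ``total > threshold``.
    """
    if len(mature_seq) != tx.mature_length:
        raise ValueError(
            f"mature sequence length {len(mature_seq)} does not match exon total "
            f"{tx.mature_length} for transcript {tx.transcript_id}"
        )
    orf = find_main_orf(mature_seq)
    if orf is None:
        return CodingPotentialScore(0, 0, 0, 0, 0, False, None)
    length_pts = round(
        weights.length_max_points
        * min(1.0, orf.n_codons / weights.length_saturation_codons)
    )
    kozak = kozak_points(mature_seq, orf, weights)
    nmd = nmd_points(tx, orf, weights)
    uorf = uorf_points(mature_seq, orf, weights)
    total = max(0, min(weights.clamp_max, length_pts + kozak + nmd + uorf))
    return CodingPotentialScore(
        orf_length_component=length_pts,
        kozak_component=kozak,
        nmd_penalty=nmd,
        uorf_penalty=uorf,
        total=total,
        passes=total > weights.threshold,
        orf=orf,
    )
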