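"""Composite assembly, TSD detection, segmentation and percent identity."""

import numpy as np
import pytest

from texapt.ancestry import (
    SegmentRequest,
    assemble_composite,
    canonicalize_spec,
    detect_tsd,
    percent_identity,
    segment_composite,
)
from texapt.io_annotations import reverse_complement
from texapt.synthetic_data import mutate, random_dna


def random_spec(trial, library):
    """One random two-segment (forward + inverted) composite request."""
    tr = np.random.default_rng(1000 + trial)
    tsd = random_dna(int(tr.integers(6, 17)), tr)
    lens = {name: len(seq) for name, seq in library.items()}
    l1 = int(tr.integers(200, 800))
    s1 = int(tr.integers(1, lens["consA"] - l1 + 2))
    l2 = int(tr.integers(150, 600))
    s2 = int(tr.integers(1, lens["consB"] - l2 + 2))
    reqs = [
        SegmentRequest("consA", s1, s1 + l1 - 1, "forward"),
        SegmentRequest("consB", s2, s2 + l2 - 1, "inverted"),
    ]
    return reqs, tsd


class TestAssemble:
    def test_single_forward_segment_is_consensus_substring(self, consensus_library):
        req = SegmentRequest("consA", 11, 110, "forward")
        element, seq = assemble_composite([req], consensus_library)
        assert seq == consensus_library["consA"][10:110]
        assert element.tsd == "" and element.inversion_junctions == ()

    def test_single_inverted_segment_is_reverse_complement(self, consensus_library):
        req = SegmentRequest("consB", 5, 64, "inverted")
        _, seq = assemble_composite([req], consensus_library)
        assert seq == reverse_complement(consensus_library["consB"][4:64])

    def test_reverse_complement_involution(self, consensus_library):
        sub = consensus_library["consA"][100:400]
        assert reverse_complement(reverse_complement(sub)) == sub

    def test_length_and_junction_arithmetic(self, consensus_library):
        reqs = [
            SegmentRequest("consA", 1, 500, "forward"),
            SegmentRequest("consB", 1, 300, "inverted"),
        ]
        element, seq = assemble_composite(reqs, consensus_library, tsd="AATCGGAA")
        assert element.assembled_length == len(seq) == 500 + 300 + 2 * 8
        assert element.inversion_junctions == (8 + 500 + 1,)
        assert element.segments[0].locus_start == 9
        assert element.segments[1].locus_end == 8 + 800

    def test_unknown_consensus_is_error(self, consensus_library):
        with pytest.raises(KeyError):
            assemble_composite([SegmentRequest("nope", 1, 10)], consensus_library)

    def test_span_out_of_range_is_error(self, consensus_library):
        with pytest.raises(ValueError, match="outside consensus"):
            assemble_composite([SegmentRequest("consA", 1, 10**6)], consensus_library)

    def test_assembled_length_invariant_on_random_specs(self, consensus_library):
        for trial in range(30):
            reqs, tsd = random_spec(trial, consensus_library)
            element, seq = assemble_composite(reqs, consensus_library, tsd)
            seg_total = sum(s.length for s in element.segments)
            assert element.assembled_length == seg_total + 2 * len(tsd) == len(seq)


def tsd_oracle(up, down, min_len, max_mm):
    """All-substrings search over the suffix/prefix register."""
    for L in range(min(len(up), len(down)), min_len - 1, -1):
        a, b = up[-L:], down[:L]
        mm = sum(x != y for x, y in zip(a, b))
        if mm <= max_mm:
            return (a, L, mm)
    return None


class TestDetectTsd:
    def test_exact_planted_duplication(self):
        hit = detect_tsd("GGGGGAATCGGA", "AATCGGAGGGGG", min_len=6, max_mismatch=0)
        assert hit.sequence == "AATCGGA" and hit.mismatches == 0

    def test_random_flanks_yield_none(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            up = random_dna(30, rng)
            down = random_dna(30, rng)
            if detect_tsd(up, down, min_len=8, max_mismatch=0) is not None:
                hits += 1
        assert hits == 0  # spurious 8-mer hit probability ~ 2e-3 per pair

    def test_matches_exhaustive_oracle_on_planted_tsds(self):
        rng = np.random.default_rng(9)
        for trial in range(100):
            r = np.random.default_rng(5000 + trial)
            up = random_dna(int(r.integers(20, 61)), r)
            down = random_dna(int(r.integers(20, 61)), r)
            t = random_dna(int(r.integers(6, 21)), r)
            tl = list(t)
            if r.random() < 0.5 and tl:
                tl[int(r.integers(len(tl)))] = "A"  # up to one mismatch
            up = up[: -len(t)] + t
            down = "".join(tl) + down[len(t) :]
            got = detect_tsd(up, down, min_len=6, max_mismatch=1, window=60)
            want = tsd_oracle(up[-60:], down[:60], 6, 1)
            got_t = (got.sequence, got.length, got.mismatches) if got else None
            assert got_t == want


class TestSegmentation:
    def test_self_match_single_forward_segment(self, consensus_library):
        locus = consensus_library["consA"]
        element = segment_composite(locus, consensus_library)
        assert len(element.segments) == 1
        seg = element.segments[0]
        assert seg.source_name == "consA" and seg.orientation == "forward"
        assert (seg.locus_start, seg.locus_end) == (1, len(locus))
        assert (seg.consensus_start, seg.consensus_end) == (1, len(locus))

    def test_empty_result_when_nothing_matches(self, consensus_library):
        rng = np.random.default_rng(2)
        element = segment_composite(random_dna(500, rng), consensus_library)
        assert element.segments == ()

    def test_round_trip_exact_at_zero_divergence(self, consensus_library):
        """Sources, orientations, spans, junction and TSD recovered exactly
        (against the canonical boundary convention) for 50 random specs."""
        for trial in range(50):
            reqs, tsd = random_spec(trial, consensus_library)
            _, seq = assemble_composite(reqs, consensus_library, tsd)
            rec = segment_composite(seq, consensus_library)
            canon, prefix, suffix, junctions = canonicalize_spec(
                reqs, consensus_library, tsd
            )
            got = [
                (s.source_name, s.orientation, s.consensus_start, s.consensus_end,
                 s.locus_start, s.locus_end)
                for s in rec.segments
            ]
            want = [
                (s.source_name, s.orientation, s.consensus_start, s.consensus_end,
                 s.locus_start, s.locus_end)
                for s in canon
            ]
            assert got == want, f"trial {trial}"
            assert rec.inversion_junctions == junctions
            expected_tsd = ""
            if len(prefix) >= 6 and len(suffix) >= 6:
                hit = detect_tsd(prefix, suffix)
                if hit is not None:
                    expected_tsd = hit.sequence
            assert rec.tsd == expected_tsd

    def test_recovery_at_ten_percent_divergence(self, consensus_library):
        """>= 95% of covered bases carry the correct source and orientation."""
        rates = []
        for trial in range(20):
            reqs, tsd = random_spec(trial, consensus_library)
            element, seq = assemble_composite(reqs, consensus_library, tsd)
            mutated = mutate(seq, 10.0, np.random.default_rng(trial))
            rec = segment_composite(mutated, consensus_library)
            truth = {}
            for s in element.segments:
                for p in range(s.locus_start, s.locus_end + 1):
                    truth[p] = (s.source_name, s.orientation)
            covered = correct = 0
            for s in rec.segments:
                for p in range(s.locus_start, s.locus_end + 1):
                    covered += 1
                    correct += truth.get(p) == (s.source_name, s.orientation)
            assert covered > 0
            rates.append(correct / covered)
        assert min(rates) >= 0.95

    def test_empty_library_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            segment_composite("ACGT" * 100, {})


class TestPercentIdentity:
    def test_identical_sequences(self):
        rep = percent_identity("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
        assert rep.percent_identity == 100.0

    def test_one_mismatch_in_four(self):
        rep = percent_identity("ACGT", "ACGA")
        assert rep.percent_identity == 75.0

    def test_gap_policies_differ(self):
        a, b = "ACGTACGT--", "ACGTACGTTT"
        excl = percent_identity(a, b, aligned=True, gap_policy="exclude_gap_columns")
        incl = percent_identity(a, b, aligned=True, gap_policy="count_gaps_as_mismatch")
        assert excl.percent_identity == 100.0
        assert incl.percent_identity == 80.0
        assert excl.gap_policy == "exclude_gap_columns"

    def test_protein_identity_is_symmetric(self):
        a = "MESKVLDLLGQFHLPSGQW"
        b = "MESRVLELLGKFHLPAGQW"
        assert percent_identity(a, b).percent_identity == pytest.approx(
            percent_identity(b, a).percent_identity
        )

    def test_prealigned_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="equal length"):
            percent_identity("ACGT", "ACG", aligned=True)
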