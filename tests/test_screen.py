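"""CDS/TE overlap arithmetic, ORF conservation and the full screen."""

import numpy as np
import pytest

from texapt.coding_potential import STOP_CODONS
from texapt.io_annotations import GenomeInterval, RepeatFeature, TranscriptModel
from texapt.screen import (
    ScreenParams,
    cds_te_overlap,
    orf_conserved,
    run_screen,
)
from texapt.synthetic_data import mutate, random_dna


def make_tx(cds_spans, exon_spans=None, tid="t1", gid="g1"):
    exon_spans = exon_spans or cds_spans
    return TranscriptModel(
        tid,
        gid,
        "chr1",
        "+",
        exons=[GenomeInterval("chr1", s, e) for s, e in exon_spans],
        cds=[GenomeInterval("chr1", s, e) for s, e in cds_spans],
    )


def make_repeat(start, end, name="TE1", chrom="chr1", strand="+"):
    return RepeatFeature(
        location=GenomeInterval(chrom, start, end, strand),
        repeat_name=name,
        repeat_class="LINE",
        repeat_family="L1",
    )


def brute_force_overlap(tx, repeats):
    """Per-base membership counting over every CDS position (oracle)."""
    te_positions = set()
    for r in repeats:
        if r.location.chrom == tx.chrom:
            te_positions.update(range(r.location.start, r.location.end + 1))
    covered = 0
    for c in tx.cds:
        covered += sum(1 for p in range(c.start, c.end + 1) if p in te_positions)
    return covered


class TestCdsTeOverlap:
    def test_full_cover(self):
        tx = make_tx([(101, 400)])
        res = cds_te_overlap(tx, [make_repeat(1, 1000)])
        assert res.fraction == 1.0 and res.overlapped_bases == 300

    def test_half_cover_by_construction(self):
        tx = make_tx([(101, 200), (301, 400)])
        res = cds_te_overlap(tx, [make_repeat(101, 200)])
        assert res.fraction == 0.5

    def test_zero_cds_is_error(self):
        tx = TranscriptModel(
            "t", "g", "chr1", "+", exons=[GenomeInterval("chr1", 1, 100)]
        )
        with pytest.raises(ValueError, match="no CDS"):
            cds_te_overlap(tx, [])

    def test_nested_repeats_do_not_double_count(self):
        tx = make_tx([(101, 300)])
        reps = [make_repeat(101, 300), make_repeat(150, 200), make_repeat(100, 301)]
        res = cds_te_overlap(tx, reps)
        assert res.overlapped_bases == 200

    def test_random_layouts_match_per_base_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(120):
            n_cds = int(rng.integers(1, 4))
            spans, pos = [], int(rng.integers(1, 50))
            for _ in range(n_cds):
                length = int(rng.integers(10, 200))
                spans.append((pos, pos + length - 1))
                pos += length + int(rng.integers(1, 100))
            tx = make_tx(spans)
            reps = []
            for _ in range(int(rng.integers(0, 6))):
                s = int(rng.integers(1, pos))
                reps.append(make_repeat(s, s + int(rng.integers(1, 300))))
            res = cds_te_overlap(tx, reps)
            assert res.overlapped_bases == brute_force_overlap(tx, reps)
            assert res.fraction == pytest.approx(res.overlapped_bases / tx.cds_length)

    def test_monotone_in_repeat_set(self):
        rng = np.random.default_rng(8)
        tx = make_tx([(100, 600)])
        reps = [
            make_repeat(int(s), int(s) + int(rng.integers(10, 150)))
            for s in rng.integers(1, 700, size=8)
        ]
        prev = 0
        for k in range(len(reps) + 1):
            cur = cds_te_overlap(tx, reps[:k]).overlapped_bases
            assert cur >= prev
            prev = cur

    def test_order_invariance(self):
        tx = make_tx([(100, 500)])
        reps = [make_repeat(50, 150), make_repeat(400, 700), make_repeat(200, 260)]
        a = cds_te_overlap(tx, reps)
        b = cds_te_overlap(tx, list(reversed(reps)))
        assert a == b

    def test_other_chromosome_contributes_nothing(self):
        tx = make_tx([(100, 400)])
        assert cds_te_overlap(tx, [make_repeat(1, 1000, chrom="chr2")]).fraction == 0.0

    def test_strand_agnostic_by_default(self):
        tx = make_tx([(100, 400)])
        res = cds_te_overlap(tx, [make_repeat(1, 1000, strand="-")])
        assert res.fraction == 1.0
        res_aware = cds_te_overlap(tx, [make_repeat(1, 1000, strand="-")], strand_aware=True)
        assert res_aware.fraction == 0.0


def brute_force_longest_orf(seq):
    """Exhaustive 3-frame ATG..stop scan (codons before the stop)."""
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                best = max(best, (j - i) // 3)
                break
    return best


class TestOrfConserved:
    ORF = "ATG" + "GCT" * 120 + "TAA"

    def test_identity_case_passes_with_three_species(self):
        orths = {"reference": self.ORF, "sp1": self.ORF, "sp2": self.ORF}
        ev = orf_conserved(orths, reference="reference", min_other_species=1)
        assert ev.n_species == 3 and ev.reference_included

    def test_all_truncated_orthologs_fail(self):
        broken = "ATG" + "GCT" * 10 + "TAA" + "C" * 300
        orths = {"reference": self.ORF, "sp1": broken, "sp2": broken}
        ev = orf_conserved(orths, reference="reference")
        assert ev.species_with_intact_orf == ("reference",)

    def test_missing_reference_is_error(self):
        with pytest.raises(KeyError, match="reference"):
            orf_conserved({"sp1": self.ORF}, reference="reference")

    def test_empty_sequence_warns_and_does_not_conserve(self):
        orths = {"reference": self.ORF, "sp1": ""}
        with pytest.warns(UserWarning, match="empty"):
            ev = orf_conserved(orths, reference="reference")
        assert "sp1" not in ev.species_with_intact_orf

    def test_detection_matches_three_frame_scan_at_5pct_divergence(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            seq = "TT" + "ATG" + mutate("GCT" * 150, 5.0, np.random.default_rng(trial)) + "TAA"
            ref_len = brute_force_longest_orf(self.ORF)
            orths = {"reference": self.ORF, "sp1": seq}
            ev = orf_conserved(orths, reference="reference", min_length_ratio=0.7)
            qualifies = brute_force_longest_orf(seq) >= 0.7 * ref_len
            assert ("sp1" in ev.species_with_intact_orf) == qualifies


class TestRunScreen:
    def test_planted_truth_recovery(self, default_dataset):
        """All 20 planted domestications recovered, all 200 negatives rejected."""
        ds = default_dataset
        res = run_screen(ds.transcripts, ds.repeats, ds.genome, ds.orthologs)
        truth = dict(zip(ds.manifest.gene_id, ds.manifest.is_domesticated))
        assert len(res) == len(truth)
        for c in res:
            assert c.verdict == truth[c.gene_id], c.gene_id

    def test_unsatisfiable_threshold_passes_nothing(self, small_dataset):
        ds = small_dataset
        res = run_screen(
            ds.transcripts,
            ds.repeats,
            ds.genome,
            ds.orthologs,
            ScreenParams(min_overlap=1.01),
        )
        assert not any(c.verdict for c in res)

    def test_exactly_half_overlap_fails_strict_criterion(self, default_dataset):
        ds = default_dataset
        boundary = set(
            ds.manifest[ds.manifest.kind == "boundary_overlap"].gene_id
        )
        assert boundary, "fixture must plant exact-boundary genes"
        res = {c.gene_id: c for c in run_screen(ds.transcripts, ds.repeats, ds.genome, ds.orthologs)}
        for gid in boundary:
            assert res[gid].overlap.fraction == 0.5
            assert res[gid].pass_overlap is False

    def test_verdicts_invariant_under_input_permutation(self, small_dataset):
        ds = small_dataset
        base = run_screen(ds.transcripts, ds.repeats, ds.genome, ds.orthologs)
        rng = np.random.default_rng(4)
        txs = list(ds.transcripts)
        reps = list(ds.repeats)
        rng.shuffle(txs)
        rng.shuffle(reps)
        shuffled = run_screen(txs, reps, ds.genome, ds.orthologs)
        assert [(c.gene_id, c.verdict, c.overlap.fraction) for c in base] == [
            (c.gene_id, c.verdict, c.overlap.fraction) for c in shuffled
        ]

    def test_output_sorted_by_descending_fraction_then_gene_id(self, small_dataset):
        ds = small_dataset
        res = run_screen(ds.transcripts, ds.repeats, ds.genome, ds.orthologs)
        keys = [(-c.overlap.fraction, c.gene_id) for c in res]
        assert keys == sorted(keys)

    def test_noncoding_gene_skipped(self, small_dataset):
        ds = small_dataset
        noncoding = TranscriptModel(
            "nc.t1", "NC_GENE", "chr_ref", "+", exons=[GenomeInterval("chr_ref", 1, 50)]
        )
        res = run_screen(
            list(ds.transcripts) + [noncoding], ds.repeats, ds.genome, ds.orthologs
        )
        assert "NC_GENE" not in {c.gene_id for c in res}

    def test_chromosome_absent_from_repeats_gives_zero_overlap(self, small_dataset):
        ds = small_dataset
        seq = "TTTACC" + "ATG" + "GGT" + "GCT" * 400 + "TAA"
        genome = dict(ds.genome)
        genome["chr_lone"] = seq
        tx = TranscriptModel(
            "lone.t1",
            "LONE",
            "chr_lone",
            "+",
            exons=[GenomeInterval("chr_lone", 1, len(seq))],
            cds=[GenomeInterval("chr_lone", 7, len(seq))],
        )
        res = run_screen(
            list(ds.transcripts) + [tx], ds.repeats, genome, ds.orthologs
        )
        lone = next(c for c in res if c.gene_id == "LONE")
        assert lone.overlap.fraction == 0.0 and not lone.verdict
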