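"""Download-free synthetic fixtures with planted ground truth.

The generator emulates the statistical structure the screening pipeline
assumes, without any external downloads:

* a reference genome carrying planted TE-derived coding genes — composite
  insertions of two consensus segments (the second inverted, mimicking
  twin priming) flanked by a target-site duplication, with an intact long
  ORF in Kozak context — alongside negative controls that fail exactly one
  criterion each (sub-threshold overlap, frame-broken ORF, or an ORF
  present in the reference only);
* RepeatMasker-style annotation rows for every planted TE fragment plus
  simple-repeat decoys;
* per-gene ortholog transcript sets across species, with substitution
  divergence that preserves (or deliberately destroys) the reading frame;
* transcript count tables with known mappability structure (including a
  duplicated transcript pair with zero effective length);
* case/control differential-expression gene lists with a configurable
  enrichment of a designated gene family.

Every emitted artifact draws from its own pseudo-random stream derived
from ``(master seed, artifact id)``, so adding an artifact never perturbs
existing ones and identical configurations are byte-identical.
Substitution-only mutation is the default; the planted composites stay
alignable by the ungapped segmenter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry import SegmentRequest, assemble_composite
from .coding_potential import STOP_CODONS, find_main_orf
from .io_annotations import (
    GenomeInterval,
    RepeatFeature,
    TranscriptModel,
    write_gtf,
    write_repeatmasker_out,
)

__all__ = [
    "SimulationConfig",
    "ScreenDataset",
    "mutate",
    "random_dna",
    "build_te_library",
    "plant_domesticated_gene",
    "generate_screen_dataset",
    "write_screen_dataset",
    "generate_expression_dataset",
    "simulate_counts",
    "simulate_de_lists",
    "synthetic_bex3_like_locus",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

# gene architecture (bp): two short non-coding exons, then the ORF exon,
# mirroring the organisation of the archetypal TE-derived gene.
EXON1_LEN = 60
EXON2_LEN = 80
INTRON1_LEN = 120
INTRON2_LEN = 150
UTR3_LEN = 150
SPACER_LEN = 400

POSITIVE = "positive"
NEG_LOW_OVERLAP = "low_overlap"
NEG_BOUNDARY = "boundary_overlap"
NEG_BROKEN = "broken_orf"
NEG_REFERENCE_ONLY = "reference_only"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults model the regime the screen is designed for: 20 planted
    domestications against 200 negatives, per-copy TE divergence of 10%
    (comfortably below the ~15% beyond which recovery is no longer
    asserted), ORFs of 350-450 codons, L1-sized TSDs, and a five-fold
    family enrichment in DE lists over a 10% base rate.
    """

    seed: int = 0
    n_species: int = 3
    background_gc: float = 0.42
    te_library: tuple[tuple[str, str, int], ...] = (
        ("HAL1b", "LINE/L1", 1800),
        ("L1MEe", "LINE/L1", 1500),
        ("L1ME4a", "LINE/L1", 1200),
    )
    n_positive_genes: int = 20
    n_negative_genes: int = 200
    divergence_pct: float = 10.0
    orf_codons: tuple[int, int] = (350, 450)
    tsd_len: tuple[int, int] = (6, 16)
    te_fraction: tuple[float, float] = (0.6, 0.95)
    negative_overlap: tuple[float, float] = (0.25, 0.45)
    # expression
    n_transcripts: int = 10
    transcript_len: tuple[int, int] = (300, 800)
    read_length: int = 50
    library_depth: int = 200_000
    tissues: tuple[str, ...] = ("brain", "cerebellum", "heart", "liver", "kidney")
    # differential expression
    n_universe: int = 2000
    family_size: int = 14
    n_de_datasets: int = 6
    base_de_rate: float = 0.10
    de_enrichment_fold: float = 5.0


def _rng(seed: int, artifact: str) -> np.random.Generator:
    """Independent stream for one artifact: seeded by (master seed, id)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(artifact.encode())])


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def mutate(seq: str, divergence_pct: float, rng: np.random.Generator | int) -> str:
    """Substitute bases i.i.d. at rate ``divergence_pct / 100`` (no indels).

    Each hit position receives one of the three alternative bases with
    equal probability, so at 100% divergence the expected realised
    mismatch fraction is 1.0 (every position substituted).
    """
    if not (0.0 <= divergence_pct <= 100.0):
        raise ValueError("divergence must be in [0, 100]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    arr = np.frombuffer(seq.upper().encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < divergence_pct / 100.0)[0]
    if hits.size:
        base_idx = {b: i for i, b in enumerate(BASES)}
        offsets = rng.integers(1, 4, size=hits.size)
        for pos, off in zip(hits, offsets):
            cur = base_idx.get(arr[pos], 0)
            arr[pos] = BASES[(cur + off) % 4]
    return arr.tobytes().decode()


def build_te_library(config: SimulationConfig) -> tuple[dict[str, str], dict[str, str]]:
    """Synthetic consensus library: (name -> sequence, name -> class/family)."""
    rng = _rng(config.seed, "te_library")
    seqs: dict[str, str] = {}
    classes: dict[str, str] = {}
    for name, clsfam, length in config.te_library:
        seqs[name] = random_dna(length, rng, config.background_gc)
        classes[name] = clsfam
    return seqs, classes


# ---------------------------------------------------------------------------
# gene planting
# ---------------------------------------------------------------------------


def _scrub_inframe_stops(seq: list[str], start: int, n_codons: int) -> None:
    """Remove stop codons from codons 1..n_codons-1 of the ORF at ``start``."""
    for i in range(start + 3, start + 3 * n_codons, 3):
        if "".join(seq[i : i + 3]) in STOP_CODONS:
            seq[i + 2] = "C"  # TAA->TAC, TAG->TAC, TGA->TGC


def _scrub_upstream_atgs(seq: list[str], limit: int) -> None:
    """Destroy every ATG before ``limit`` (prevents uORF/alternative starts)."""
    for i in range(limit - 2):
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
            seq[i + 1] = "C"


def _break_orf(seq: list[str], max_codons: int) -> None:
    """Plant stop codons until no ORF of >= max_codons remains."""
    while True:
        orf = find_main_orf("".join(seq))
        if orf is None or orf.n_codons < max_codons:
            return
        mid = orf.start_offset + 3 * (orf.n_codons // 2)
        seq[mid : mid + 3] = list("TAA")


@dataclass
class _PlantedGene:
    gene_id: str
    kind: str
    transcript: TranscriptModel
    gene_seq: str
    spacer_seq: str
    repeats: list[RepeatFeature]
    orthologs: dict[str, str]
    manifest: dict


@dataclass
class ScreenDataset:
    """In-memory screening fixture with its truth manifest."""

    config: SimulationConfig
    transcripts: list[TranscriptModel]
    repeats: list[RepeatFeature]
    genome: dict[str, str]
    orthologs: dict[str, dict[str, str]]
    manifest: pd.DataFrame
    library: dict[str, str]


def plant_domesticated_gene(
    gene_id: str,
    kind: str,
    config: SimulationConfig,
    library: Mapping[str, str],
    lib_classes: Mapping[str, str],
    chrom: str,
    gene_start: int,
) -> _PlantedGene:
    """Build one gene locus of the requested kind at ``gene_start``.

    ``positive`` genes satisfy all three screen criteria; each negative
    kind is constructed to fail exactly one: ``low_overlap`` (TE union
    covers 25-45% of the CDS), ``boundary_overlap`` (exactly 50%, failing
    the strict threshold), ``broken_orf`` (premature stops leave no ORF of
    >= 120 codons), ``reference_only`` (orthologous ORFs destroyed outside
    the reference species).
    """
    rng = _rng(config.seed, f"gene:{gene_id}")
    names = list(library)
    tsd_len = int(rng.integers(config.tsd_len[0], config.tsd_len[1] + 1))
    tsd = random_dna(tsd_len, rng, config.background_gc)
    seg1_len = int(rng.integers(1000, 1301))
    seg2_len = int(rng.integers(500, 701))
    s1 = int(rng.integers(1, len(library[names[0]]) - seg1_len + 2))
    s2 = int(rng.integers(1, len(library[names[1]]) - seg2_len + 2))
    requests = [
        SegmentRequest(names[0], s1, s1 + seg1_len - 1, "forward"),
        SegmentRequest(names[1], s2, s2 + seg2_len - 1, "inverted"),
    ]
    element, composite = assemble_composite(requests, library, tsd)
    diverged = mutate(composite, config.divergence_pct, rng)

    n_codons = int(rng.integers(config.orf_codons[0], config.orf_codons[1] + 1))
    if kind == NEG_BOUNDARY and n_codons % 2 == 0:
        n_codons += 1  # odd codon count -> even CDS length -> exact halves
    cds_len = 3 * (n_codons + 1)
    seg_total = seg1_len + seg2_len
    te_end0 = tsd_len + seg_total - 1  # 0-based end of TE-annotated region
    if kind == NEG_BOUNDARY:
        covered = cds_len // 2
    elif kind == NEG_LOW_OVERLAP:
        covered = round(rng.uniform(*config.negative_overlap) * cds_len)
    else:
        covered = round(rng.uniform(*config.te_fraction) * cds_len)
    covered = max(60, min(covered, cds_len - 3, seg_total - 20))
    orf_start0 = te_end0 - covered + 1
    orf_end0 = orf_start0 + cds_len - 1
    tail = max(0, orf_end0 + 1 - len(diverged))
    exon3 = list(diverged + random_dna(tail + UTR3_LEN, rng, config.background_gc))

    exon1 = random_dna(EXON1_LEN, rng, config.background_gc)
    exon2 = random_dna(EXON2_LEN, rng, config.background_gc)
    mature = list(exon1 + exon2 + "".join(exon3))
    m_s = EXON1_LEN + EXON2_LEN + orf_start0  # ORF start on mature sequence
    # carve the ORF: start codon, Kozak context, clean frame, terminal stop
    mature[m_s : m_s + 3] = list("ATG")
    mature[m_s - 3] = "A"
    mature[m_s + 3] = "G"
    _scrub_inframe_stops(mature, m_s, n_codons)
    mature[m_s + 3 * n_codons : m_s + 3 * n_codons + 3] = list("TAA")
    _scrub_upstream_atgs(mature, m_s)
    if kind == NEG_BROKEN:
        mature[m_s + 150 : m_s + 153] = list("TAA")
        _break_orf(mature, 120)
    mature_str = "".join(mature)
    exon1 = mature_str[:EXON1_LEN]
    exon2 = mature_str[EXON1_LEN : EXON1_LEN + EXON2_LEN]
    exon3_str = mature_str[EXON1_LEN + EXON2_LEN :]

    intron1 = random_dna(INTRON1_LEN, rng, config.background_gc)
    intron2 = random_dna(INTRON2_LEN, rng, config.background_gc)
    gene_seq = exon1 + intron1 + exon2 + intron2 + exon3_str

    g1 = gene_start
    e1 = GenomeInterval(chrom, g1, g1 + EXON1_LEN - 1, "+")
    g2 = e1.end + INTRON1_LEN + 1
    e2 = GenomeInterval(chrom, g2, g2 + EXON2_LEN - 1, "+")
    g3 = e2.end + INTRON2_LEN + 1
    e3 = GenomeInterval(chrom, g3, g3 + len(exon3_str) - 1, "+")
    cds_iv = GenomeInterval(chrom, g3 + orf_start0, g3 + orf_end0, "+")
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        exons=[e1, e2, e3],
        cds=[cds_iv],
    )

    repeats: list[RepeatFeature] = []
    pos = g3 + tsd_len  # genomic start of the first TE segment
    for req, seg in zip(requests, element.segments):
        repeats.append(
            RepeatFeature(
                location=GenomeInterval(
                    chrom,
                    pos,
                    pos + req.length - 1,
                    "+" if req.orientation == "forward" else "-",
                ),
                repeat_name=req.source_name,
                repeat_class=lib_classes[req.source_name].split("/")[0],
                repeat_family=lib_classes[req.source_name].partition("/")[2],
                divergence_pct=config.divergence_pct,
                consensus_span=(req.start, req.end),
            )
        )
        pos += req.length
    spacer = random_dna(SPACER_LEN, rng, config.background_gc)
    repeats.append(
        RepeatFeature(
            location=GenomeInterval(
                chrom, gene_start + len(gene_seq) + 50, gene_start + len(gene_seq) + 99, "+"
            ),
            repeat_name="(TA)n",
            repeat_class="Simple_repeat",
            repeat_family="",
            divergence_pct=5.0,
            consensus_span=(1, 50),
        )
    )

    # orthologs: reference mature transcript plus per-species diverged copies
    species = [f"species_{i}" for i in range(1, config.n_species)]
    orthologs: dict[str, str] = {"reference": mature_str}
    conserved = ["reference"]
    for sp in species:
        copy = list(mutate(mature_str, config.divergence_pct, _rng(config.seed, f"orth:{gene_id}:{sp}")))
        if kind == NEG_REFERENCE_ONLY:
            _break_orf(copy, max(30, int(0.6 * n_codons)))
        else:
            copy[m_s : m_s + 3] = list("ATG")
            _scrub_inframe_stops(copy, m_s, n_codons)
            copy[m_s + 3 * n_codons : m_s + 3 * n_codons + 3] = list("TAA")
            conserved.append(sp)
        orthologs[sp] = "".join(copy)
    if kind == NEG_BROKEN:
        conserved = ["reference"] + species  # frame intactness is the broken axis

    fraction_planted = covered / cds_len
    manifest = {
        "gene_id": gene_id,
        "kind": kind,
        "is_domesticated": kind == POSITIVE,
        "te_fraction_planted": fraction_planted,
        "cds_length": cds_len,
        "orf_codons": n_codons,
        "segment_sources": ",".join(r.source_name for r in requests),
        "segment_orientations": ",".join(r.orientation for r in requests),
        "tsd": tsd,
        "inversion_junction_composite": element.inversion_junctions[0],
        "conserved_species": ",".join(conserved),
    }
    return _PlantedGene(
        gene_id=gene_id,
        kind=kind,
        transcript=tx,
        gene_seq=gene_seq,
        spacer_seq=spacer,
        repeats=repeats,
        orthologs=orthologs,
        manifest=manifest,
    )


def _negative_kinds(n: int) -> list[str]:
    """Deterministic mix of negative kinds: overlap/ORF/conservation failures."""
    kinds: list[str] = []
    cycle = (NEG_LOW_OVERLAP, NEG_BROKEN, NEG_REFERENCE_ONLY)
    for i in range(n):
        kinds.append(cycle[i % 3])
    # always include at least two exact-boundary genes when room permits
    for i in range(min(2, n)):
        kinds[-(i + 1)] = NEG_BOUNDARY
    return kinds


def generate_screen_dataset(config: SimulationConfig = SimulationConfig()) -> ScreenDataset:
    """Reference genome + annotations + orthologs with a truth manifest.

    Gene loci are laid out head-to-tail on one reference chromosome with
    fixed spacers; every annotation record traces to exactly one manifest
    row.
    """
    library, lib_classes = build_te_library(config)
    chrom = "chr_ref"
    jobs: list[tuple[str, str]] = [
        (f"POS{i:04d}", POSITIVE) for i in range(config.n_positive_genes)
    ]
    jobs += [
        (f"NEG{i:04d}", kind)
        for i, kind in enumerate(_negative_kinds(config.n_negative_genes))
    ]

    pieces: list[str] = []
    pos = 1
    transcripts: list[TranscriptModel] = []
    repeats: list[RepeatFeature] = []
    orthologs: dict[str, dict[str, str]] = {}
    rows: list[dict] = []
    for gene_id, kind in jobs:
        planted = plant_domesticated_gene(
            gene_id, kind, config, library, lib_classes, chrom, pos
        )
        pieces.append(planted.gene_seq)
        pieces.append(planted.spacer_seq)
        transcripts.append(planted.transcript)
        repeats.extend(planted.repeats)
        orthologs[gene_id] = planted.orthologs
        rows.append(planted.manifest)
        pos += len(planted.gene_seq) + len(planted.spacer_seq)
    genome = {chrom: "".join(pieces)}
    manifest = pd.DataFrame(rows)
    return ScreenDataset(
        config=config,
        transcripts=transcripts,
        repeats=repeats,
        genome=genome,
        orthologs=orthologs,
        manifest=manifest,
        library=library,
    )


def write_screen_dataset(ds: ScreenDataset, outdir: str | Path) -> None:
    """Write the dataset as plain-text files (FASTA/GTF/.out/TSV)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in ds.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(out / "genes.gtf", "w") as fh:
        for line in write_gtf(ds.transcripts):
            fh.write(line + "\n")
    with open(out / "repeats.out", "w") as fh:
        for line in write_repeatmasker_out(ds.repeats):
            fh.write(line + "\n")
    with open(out / "te_library.fa", "w") as fh:
        for name, seq in ds.library.items():
            fh.write(f">{name}\n{seq}\n")
    orth_dir = out / "orthologs"
    orth_dir.mkdir(exist_ok=True)
    for gene_id, per_species in ds.orthologs.items():
        with open(orth_dir / f"{gene_id}.fa", "w") as fh:
            for sp, seq in sorted(per_species.items()):
                fh.write(f">{sp}\n{seq}\n")
    ds.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression fixtures
# ---------------------------------------------------------------------------


def generate_expression_dataset(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Transcriptome (with one duplicated pair) and planted expression levels.

    Levels are relative abundances per tissue sample, log-uniform across
    transcripts with a brain-enriched block, mirroring tissue-restricted
    expression.
    """
    rng = _rng(config.seed, "transcriptome")
    transcriptome: dict[str, str] = {}
    for i in range(config.n_transcripts):
        length = int(rng.integers(config.transcript_len[0], config.transcript_len[1] + 1))
        transcriptome[f"tx{i:03d}"] = random_dna(length, rng, config.background_gc)
    # duplicated pair: both copies lose every mappable position
    dup = random_dna(400, rng, config.background_gc)
    transcriptome["dupA"] = dup
    transcriptome["dupB"] = dup
    lrng = _rng(config.seed, "levels")
    levels = pd.DataFrame(
        np.exp(lrng.uniform(np.log(1.0), np.log(100.0), size=(len(transcriptome), len(config.tissues)))),
        index=list(transcriptome),
        columns=list(config.tissues),
    )
    return transcriptome, levels


def simulate_counts(
    config: SimulationConfig,
    levels: pd.DataFrame,
    transcriptome: Mapping[str, str],
    seed: int | None = None,
    depth_scale: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson count table with mean ∝ level × mappable positions × depth.

    Returns (counts, sample sheet); the sheet records each sample's actual
    total mapped reads.  A level of zero always yields zero counts.
    """
    from .expression import effective_length

    seed = config.seed if seed is None else seed
    eff = effective_length(transcriptome, config.read_length)
    mappable = np.array(
        [eff[t].mappable_start_positions for t in levels.index], dtype=float
    )
    raw_mean = levels.to_numpy(dtype=float) * mappable[:, None]
    counts = np.zeros_like(raw_mean, dtype=np.int64)
    sheet_rows = []
    for j, sample in enumerate(levels.columns):
        scale = 1.0 if depth_scale is None else float(depth_scale.get(sample, 1.0))
        col = raw_mean[:, j]
        norm = col.sum()
        mean = col / norm * config.library_depth * scale if norm > 0 else col
        srng = _rng(seed, f"counts:{sample}")
        counts[:, j] = srng.poisson(mean)
        sheet_rows.append(
            {
                "sample": sample,
                "species": "reference",
                "tissue": sample,
                "total_mapped": int(counts[:, j].sum()),
            }
        )
    return (
        pd.DataFrame(counts, index=levels.index, columns=levels.columns),
        pd.DataFrame(sheet_rows),
    )


# ---------------------------------------------------------------------------
# differential-expression fixtures
# ---------------------------------------------------------------------------


def simulate_de_lists(
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
    fold: float | None = None,
) -> tuple[list[str], dict[str, list[str]], dict[str, list[str]], pd.DataFrame]:
    """Per-dataset DE lists with planted family over-representation.

    Family genes enter each DE list with probability ``min(1, fold × base
    rate)``; background genes at the base rate.  ``fold = 1`` produces null
    datasets.  Returns (family, de_lists, universes, truth).
    """
    seed = config.seed if seed is None else seed
    fold = config.de_enrichment_fold if fold is None else fold
    if fold < 1:
        raise ValueError("enrichment fold must be >= 1")
    family = [f"FAM{i:03d}" for i in range(config.family_size)]
    background = [f"G{i:05d}" for i in range(config.n_universe - config.family_size)]
    universe_genes = family + background
    p_fam = min(1.0, fold * config.base_de_rate)
    de_lists: dict[str, list[str]] = {}
    universes: dict[str, list[str]] = {}
    rows = []
    for d in range(config.n_de_datasets):
        dataset = f"dataset_{d:02d}"
        rng = _rng(seed, f"de:{dataset}")
        de: list[str] = []
        for g in family:
            if rng.random() < p_fam:
                de.append(g)
        for g in background:
            if rng.random() < config.base_de_rate:
                de.append(g)
        de_lists[dataset] = de
        universes[dataset] = list(universe_genes)
        rows.append(
            {
                "dataset": dataset,
                "n_de": len(de),
                "family_in_de": sum(1 for g in de if g.startswith("FAM")),
                "fold": fold,
            }
        )
    return family, de_lists, universes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic deletion fixture
# ---------------------------------------------------------------------------


def synthetic_bex3_like_locus() -> tuple[TranscriptModel, str]:
    """Synthetic single-exon CDS fixture at the published deletion coordinates.

    A fully deterministic stand-in (synthetic, not the real gene): a
    201-codon CDS on chrX positioned so that the published 147-bp deletion
    is CDS-internal and codon-aligned, while the published 196-bp deletion
    shifts the frame and — by construction of the codons around the
    breakpoint — exposes a premature TAA shortly downstream of the fusion
    point when the mutant CDS is translated.
    """
    cds_start = 136_271_101
    n_codons_total = 201  # incl. stop
    codons = ["GCT"] * n_codons_total
    codons[0] = "ATG"
    codons[75] = "GGT"
    codons[140] = "GGT"
    codons[141] = "CTA"
    codons[142] = "AAA"
    codons[200] = "TAA"
    cds_seq = "".join(codons)
    cds_end = cds_start + len(cds_seq) - 1
    exon = GenomeInterval("chrX", cds_start - 100, cds_end + 100, "+")
    tx = TranscriptModel(
        transcript_id="Bex3_like.t1",
        gene_id="Bex3_like",
        chrom="chrX",
        strand="+",
        exons=[exon],
        cds=[GenomeInterval("chrX", cds_start, cds_end, "+")],
    )
    return tx, cds_seq
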