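"""Mappability-corrected expression quantification (cRPKM) and clustering.

The corrected RPKM of a transcript divides its read count not by the raw
transcript length but by the number of read-length start positions whose
k-mer is unique across the whole transcriptome:

    cRPKM = 1e9 * c / (l_eff * M)

with ``c`` the mapped read count, ``l_eff`` the mappable start positions
and ``M`` the sample's total mapped reads.  Positions whose read-long
sequence recurs anywhere (including in the same transcript) are excluded
from both copies, so a duplicated transcript pair has zero effective
length.  Read mapping itself is out of scope: the module consumes a count
table and models mappability at the exact k-mer level.

For cross-tissue displays, genes are rescaled per row and clustered with
1 - Pearson correlation distance under average (UPGMA) linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EffectiveLength",
    "effective_length",
    "crpkm",
    "expression_matrix",
    "relative_matrix",
    "cluster_rows",
]


@dataclass(frozen=True)
class EffectiveLength:
    transcript_id: str
    read_length: int
    mappable_start_positions: int
    raw_length: int

    def __post_init__(self) -> None:
        cap = max(0, self.raw_length - self.read_length + 1)
        if not (0 <= self.mappable_start_positions <= cap):
            raise ValueError(
                f"{self.transcript_id}: mappable positions {self.mappable_start_positions} "
                f"outside [0, {cap}]"
            )


def effective_length(
    transcriptome: Mapping[str, str] | Iterable[tuple[str, str]],
    read_length: int = 50,
) -> dict[str, EffectiveLength]:
    """Count read-length start positions unique across the transcriptome.

    A k-mer occurring more than once anywhere — in another transcript or
    elsewhere in the same one — removes *all* its start positions, so both
    transcripts of a duplicated pair score zero.  Duplicate transcript ids
    are an error.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    items = (
        list(transcriptome.items())
        if isinstance(transcriptome, Mapping)
        else list(transcriptome)
    )
    ids = [tid for tid, _ in items]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate transcript ids in transcriptome")
    census: dict[str, int] = {}
    for _, seq in items:
        s = seq.upper()
        for i in range(len(s) - read_length + 1):
            kmer = s[i : i + read_length]
            census[kmer] = census.get(kmer, 0) + 1
    out: dict[str, EffectiveLength] = {}
    for tid, seq in items:
        s = seq.upper()
        n = sum(
            1
            for i in range(len(s) - read_length + 1)
            if census[s[i : i + read_length]] == 1
        )
        out[tid] = EffectiveLength(
            transcript_id=tid,
            read_length=read_length,
            mappable_start_positions=n,
            raw_length=len(s),
        )
    return out


def crpkm(count: float, eff: EffectiveLength, total_mapped: float) -> float:
    """Corrected RPKM: ``1e9 * count / (mappable_positions * total_mapped)``.

    Scale-invariant to library depth (scaling count and total together).
    Zero effective length yields a missing value (NaN) with a warning,
    never a silent zero.
    """
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    if eff.mappable_start_positions == 0:
        warnings.warn(
            f"transcript {eff.transcript_id} has zero effective length; cRPKM undefined",
            stacklevel=2,
        )
        return float("nan")
    return 1e9 * count / (eff.mappable_start_positions * total_mapped)


def expression_matrix(
    counts: pd.DataFrame,
    eff: Mapping[str, EffectiveLength],
    total_mapped: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """cRPKM matrix (transcripts x samples) from a count table.

    ``counts`` rows are transcript ids, columns sample names; every sample
    needs a positive total in ``total_mapped``.  Transcripts with zero
    effective length carry NaN across all samples.
    """
    totals = pd.Series(total_mapped, dtype=float)
    missing = [s for s in counts.columns if s not in totals.index]
    if missing:
        raise KeyError(f"samples without total mapped reads: {missing}")
    values = np.empty(counts.shape, dtype=float)
    for i, tid in enumerate(counts.index):
        e = eff[tid]
        if e.mappable_start_positions == 0:
            warnings.warn(
                f"transcript {tid} has zero effective length; cRPKM undefined",
                stacklevel=2,
            )
            values[i, :] = np.nan
            continue
        for j, sample in enumerate(counts.columns):
            values[i, j] = crpkm(float(counts.iat[i, j]), e, float(totals[sample]))
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def relative_matrix(
    matrix: pd.DataFrame, mode: str = "row_zscore"
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene rescaling across samples for relative-expression display.

    ``row_zscore`` centres and scales each row (population sd); constant
    rows map to all-zero.  ``row_minmax`` maps each row onto [0, 1];
    constant rows map to 0.5.  Degenerate (constant) rows are returned as
    a flag list alongside the rescaled matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples per row to rescale")
    values = matrix.to_numpy(dtype=float)
    degenerate: list[str] = []
    out = np.empty_like(values)
    for i, row_name in enumerate(matrix.index):
        row = values[i]
        if mode == "row_zscore":
            sd = row.std()
            if sd == 0:
                out[i] = 0.0
                degenerate.append(str(row_name))
            else:
                out[i] = (row - row.mean()) / sd
        elif mode == "row_minmax":
            span = row.max() - row.min()
            if span == 0:
                out[i] = 0.5
                degenerate.append(str(row_name))
            else:
                out[i] = (row - row.min()) / span
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), degenerate


def cluster_rows(matrix: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) hierarchy of rows under Pearson distance.

    Distance is ``1 - r`` between row profiles, so identical rows merge at
    height 0 and perfectly anti-correlated ones at height 2.  Ties are
    broken deterministically by the smallest pair of cluster indices.
    Returns a scipy-style linkage matrix (children, height, cluster size).
    A constant row has undefined correlation and raises, naming the row.
    """
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to cluster")
    sds = values.std(axis=1)
    for name, sd in zip(matrix.index, sds):
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"row {name!r} is constant; Pearson distance undefined")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist[i, j])
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best_pair = min(
            (pair for pair in d if pair[0] in active and pair[1] in active),
            key=lambda p: (d[p], p),
        )
        i, j = best_pair
        h = d[best_pair]
        si, sj = active[i], active[j]
        linkage[step] = (i, j, h, si + sj)
        del active[i], active[j]
        new_d: dict[int, float] = {}
        for k in active:
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            new_d[k] = (si * dik + sj * djk) / (si + sj)
        active[next_id] = si + sj
        for k, val in new_d.items():
            d[(min(k, next_id), max(k, next_id))] = val
        next_id += 1
    return linkage
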