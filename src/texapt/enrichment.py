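"""Hypergeometric over-representation of a gene family in DE gene sets.

For each dataset: with ``N`` genes tested (the universe), ``K`` of them in
the family of interest, ``n`` differentially expressed and ``k`` in the
intersection, the enrichment p-value is the exact upper tail
``P(X >= k)`` of Hypergeometric(N, K, n) — inclusive of ``k``, the
standard over-representation convention.  Significance is judged per
dataset at ``alpha`` (0.05 by default) with no cross-dataset correction;
a Benjamini-Hochberg option is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

__all__ = ["EnrichmentResult", "hypergeom_upper_tail", "run_enrichment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    dataset_id: str
    population_size: int  # N: genes in the universe
    family_size: int  # K: family genes present in the universe
    de_set_size: int  # n: DE genes in the universe
    overlap: int  # k: family genes among DE genes
    p_value: float
    significant: bool
    q_value: float | None = None
    dropped_de_genes: int = 0


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact ``P(X >= k)`` for X ~ Hypergeometric(N, K, n).

    Bounds are validated; ``k = 0`` returns exactly 1.0.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _normalize(genes: Iterable[str]) -> set[str]:
    return {g.strip().upper() for g in genes if g and g.strip()}


def run_enrichment(
    family: Sequence[str],
    de_lists: Mapping[str, Sequence[str]],
    universe: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """One hypergeometric test per dataset.

    Gene identifiers are normalised (case-insensitive, stripped) before
    intersection; DE genes absent from their dataset's universe are
    dropped with a logged count.  A family disjoint from the universe is
    handled degenerately (K = 0, p = 1) with a warning rather than an
    error.  Output order follows sorted dataset ids; results are fully
    deterministic.
    """
    fam = _normalize(family)
    results: list[EnrichmentResult] = []
    for dataset_id in sorted(de_lists):
        if dataset_id not in universe:
            raise KeyError(f"no universe supplied for dataset {dataset_id!r}")
        uni = _normalize(universe[dataset_id])
        if not uni:
            raise ValueError(f"empty universe for dataset {dataset_id!r}")
        de_raw = _normalize(de_lists[dataset_id])
        de = de_raw & uni
        dropped = len(de_raw) - len(de)
        if dropped:
            logger.info(
                "dataset %s: dropped %d DE genes absent from the universe",
                dataset_id,
                dropped,
            )
        fam_in_uni = fam & uni
        if not fam_in_uni:
            logger.warning("dataset %s: family absent from universe", dataset_id)
        N, K, n = len(uni), len(fam_in_uni), len(de)
        k = len(fam_in_uni & de)
        p = hypergeom_upper_tail(N, K, n, k)
        results.append(
            EnrichmentResult(
                dataset_id=dataset_id,
                population_size=N,
                family_size=K,
                de_set_size=n,
                overlap=k,
                p_value=p,
                significant=p < alpha,
                dropped_de_genes=dropped,
            )
        )
    if bh_correct and results:
        m = len(results)
        order = sorted(range(m), key=lambda i: results[i].p_value)
        qs = [0.0] * m
        running = 1.0
        for rank_from_last, idx in enumerate(reversed(order)):
            rank = m - rank_from_last
            running = min(running, results[idx].p_value * m / rank)
            qs[idx] = running
        results = [
            EnrichmentResult(
                dataset_id=r.dataset_id,
                population_size=r.population_size,
                family_size=r.family_size,
                de_set_size=r.de_set_size,
                overlap=r.overlap,
                p_value=r.p_value,
                significant=qs[i] < alpha,
                q_value=qs[i],
                dropped_de_genes=r.dropped_de_genes,
            )
            for i, r in enumerate(results)
        ]
    return results
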