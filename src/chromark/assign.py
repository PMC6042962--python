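"""Peak-to-gene assignment by closest transcription start site.

Distance semantics mirror a closest-feature search against TSS points: a
peak containing the TSS is at distance 0; otherwise the distance is from
the nearer peak edge (``start`` or ``end - 1``) to the TSS. Distance is
strand-agnostic. Ties are broken deterministically by lexicographically
smallest gene_id and flagged. Non-Pol II genes (Pol III, tRNA, rRNA) can
be removed from the candidate set before the search, so an excluded gene
can never absorb a peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import GeneModel, GenomicInterval, PeakSet

logger = logging.getLogger(__name__)


@dataclass
class PeakGeneAssignment:
    peak: GenomicInterval
    gene_id: str | None  # None when no gene shares the peak's chromosome
    distance: float  # bases; 0 iff the TSS lies within the peak; inf if unassigned
    tie: bool = False


def filter_genes(
    genes: Sequence[GeneModel], exclude_polIII_tRNA_rRNA: bool = True
) -> list[GeneModel]:
    """Drop Pol III, tRNA and rRNA genes when the flag is set."""
    if not exclude_polIII_tRNA_rRNA:
        return list(genes)
    kept = [
        g
        for g in genes
        if g.polymerase != "PolIII" and g.biotype not in ("tRNA", "rRNA")
    ]
    if not kept:
        logger.warning("gene filter removed every gene")
    return kept


class _TssIndex:
    """Per-chromosome TSS arrays for vectorized closest-point queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        ordered = sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id))
        tmp: dict[str, tuple[list[int], list[str]]] = {}
        for g in ordered:
            pos, ids = tmp.setdefault(g.chrom, ([], []))
            pos.append(g.tss)
            ids.append(g.gene_id)
        self.by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {
            c: (np.asarray(pos), ids) for c, (pos, ids) in tmp.items()
        }

    def closest(self, peak: GenomicInterval) -> PeakGeneAssignment:
        entry = self.by_chrom.get(peak.chrom)
        if entry is None:
            return PeakGeneAssignment(peak, None, math.inf)
        tss, ids = entry
        inside = (tss >= peak.start) & (tss < peak.end)
        dist = np.where(
            inside,
            0,
            np.minimum(np.abs(tss - peak.start), np.abs(tss - (peak.end - 1))),
        )
        best = dist.min()
        winners = np.flatnonzero(dist == best)
        names = sorted(ids[i] for i in winners)
        return PeakGeneAssignment(peak, names[0], float(best), tie=len(names) > 1)


def closest_tss(
    peak: GenomicInterval, genes: Sequence[GeneModel]
) -> PeakGeneAssignment:
    """Gene whose TSS minimizes the distance to the peak interval."""
    if not genes:
        raise ValueError("gene list is empty")
    return _TssIndex(genes).closest(peak)


def assign_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    exclude_polIII_tRNA_rRNA: bool = True,
) -> list[PeakGeneAssignment]:
    """Closest-TSS assignment for every peak after biotype filtering.

    Input gene order does not matter; the TSS index sorts internally.
    """
    candidates = filter_genes(genes, exclude_polIII_tRNA_rRNA)
    if not candidates:
        return [PeakGeneAssignment(p.interval, None, math.inf) for p in peaks]
    index = _TssIndex(candidates)
    return [index.closest(p.interval) for p in peaks]


def distinct_gene_ids(assignments: Sequence[PeakGeneAssignment]) -> list[str]:
    """Sorted distinct assigned gene ids (unassigned records dropped) — the
    gene list handed to enrichment."""
    return sorted({a.gene_id for a in assignments if a.gene_id is not None})
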