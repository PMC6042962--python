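"""Synthetic genomes, coverage pairs, count matrices and term maps with
planted truth.

Every generator is a pure function of its parameters and an explicit
integer seed, so downstream stages can be tested against exactly known
ground truth without any external data. The coverage model is the simplest
one that exercises the whole occupancy path: a flat background with
rectangular fold-enrichment blocks, optionally Poisson-sampled per base and
globally rescaled to emulate unequal sequencing depth. Counts follow a
negative-binomial with mean ``m`` and variance ``m + phi * m**2``
(``phi = 0`` degenerates to Poisson), the standard RNA-seq noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CoverageTrack, GeneModel, GenomicInterval, polymerase_for_biotype
from .profiles import ExpressionMatrix


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, used as test oracle."""

    enriched_regions: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    enriched_term: tuple[str, set[str]] | None = None

    def __post_init__(self) -> None:
        for iv, fold in self.enriched_regions:
            if fold <= 1:
                raise ValueError(f"planted fold must be > 1, got {fold} at {iv}")
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("up and down DE gene sets must be disjoint")


def generate_genome(
    n_chroms: int = 1,
    chrom_length: int = 500_000,
    n_genes: int = 100,
    frac_non_polII: float = 0.1,
    seed: int = 0,
    margin: int = 3_000,
) -> list[GeneModel]:
    """Place non-overlapping genes with random strands on ``n_chroms``
    chromosomes of equal length.

    ``frac_non_polII`` of genes (rounded) are labelled tRNA (Pol III),
    rRNA, or other Pol III-transcribed, mimicking the annotation classes a
    ChIP-seq gene list is filtered on. Genes keep ``margin`` bases clear of
    chromosome ends so promoter flanks stay on-chromosome.
    """
    rng = np.random.default_rng(seed)
    n_non = int(round(frac_non_polII * n_genes))
    # Which gene indices (in final positional order) are non-Pol II.
    non_idx = set(rng.choice(n_genes, size=n_non, replace=False).tolist())

    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gene_no = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        k = per_chrom[ci]
        lengths = []
        kinds = []
        for _ in range(k):
            if gene_no + len(lengths) in non_idx:
                biotype = rng.choice(["tRNA", "rRNA", "other"], p=[0.5, 0.3, 0.2])
                lengths.append(int(rng.integers(100, 300)))
            else:
                biotype = "protein_coding"
                lengths.append(int(rng.integers(800, 2500)))
            kinds.append(str(biotype))
        gap_budget = chrom_length - 2 * margin - sum(lengths)
        if gap_budget < k + 1:
            raise ValueError(
                f"cannot pack {k} genes into {chrom_length} bases; "
                "increase chrom_length or reduce n_genes"
            )
        gaps = rng.multinomial(gap_budget - (k + 1), [1.0 / (k + 1)] * (k + 1)) + 1
        pos = margin
        for j in range(k):
            pos += int(gaps[j])
            start, end = pos, pos + lengths[j]
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = kinds[j]
            poly = "PolIII" if biotype == "other" else polymerase_for_biotype(biotype)
            gene_no += 1
            genes.append(
                GeneModel(
                    f"gene_{gene_no:04d}",
                    GenomicInterval(chrom, start, end, strand),
                    biotype,
                    poly,
                )
            )
            pos = end
    return genes


def chrom_sizes_for(
    genes: Sequence[GeneModel],
    regions: Sequence[tuple[GenomicInterval, float]] = (),
    margin: int = 3_000,
) -> dict[str, int]:
    """Genome extents implied by a gene set (plus optional planted regions)."""
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end + margin)
    for iv, _ in regions:
        sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end + margin)
    return sizes


def plant_promoter_regions(
    genes: Sequence[GeneModel],
    gene_ids: Sequence[str],
    fold: float = 3.0,
    half_width: int = 250,
) -> list[tuple[GenomicInterval, float]]:
    """Rectangular enriched regions centered on the TSS of chosen genes.

    Raises if any two regions would overlap (planted regions must be
    disjoint for the truth to be unambiguous).
    """
    by_id = {g.gene_id: g for g in genes}
    regions = []
    for gid in gene_ids:
        g = by_id[gid]
        start = max(0, g.tss - half_width)
        regions.append((GenomicInterval(g.chrom, start, g.tss + half_width + 1), fold))
    regions.sort(key=lambda r: (r[0].chrom, r[0].start))
    for (a, _), (b, _) in zip(regions, regions[1:]):
        if a.overlaps(b):
            raise ValueError(f"planted promoter regions overlap: {a} / {b}")
    return regions


def generate_coverage_pair(
    genes: Sequence[GeneModel],
    planted_regions: Sequence[tuple[GenomicInterval, float]],
    background_level: float = 50.0,
    depth_ratio: float = 1.0,
    noise: str = "none",
    seed: int = 0,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[CoverageTrack, CoverageTrack, PlantedTruth]:
    """Build an (IP, input) coverage pair with planted enrichment.

    The input track has expectation ``background_level`` everywhere; the IP
    track has ``background_level * fold`` inside each planted region and
    background elsewhere, then the whole IP track is scaled by
    ``depth_ratio`` to emulate unequal library depth. ``noise="none"``
    yields the exact piecewise-constant means; ``noise="poisson"`` draws
    per-base counts from them.
    """
    if background_level <= 0:
        raise ValueError("background_level must be positive")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    regions = sorted(planted_regions, key=lambda r: (r[0].chrom, r[0].start))
    for (a, _), (b, _) in zip(regions, regions[1:]):
        if a.overlaps(b):
            raise ValueError(f"planted regions overlap: {a} / {b}")
    sizes = dict(chrom_sizes) if chrom_sizes else chrom_sizes_for(genes, regions)
    for iv, _ in regions:
        if iv.chrom not in sizes or iv.end > sizes[iv.chrom]:
            raise ValueError(f"planted region {iv} outside the genome")

    rng = np.random.default_rng(seed)
    ip_vals: dict[str, np.ndarray] = {}
    in_vals: dict[str, np.ndarray] = {}
    for chrom in sorted(sizes):
        n = sizes[chrom]
        ip_mean = np.full(n, background_level, dtype=float)
        in_mean = np.full(n, background_level, dtype=float)
        for iv, fold in regions:
            if iv.chrom == chrom:
                ip_mean[iv.start : iv.end] = background_level * fold
        ip_mean *= depth_ratio
        if noise == "poisson":
            ip_vals[chrom] = rng.poisson(ip_mean).astype(float)
            in_vals[chrom] = rng.poisson(in_mean).astype(float)
        else:
            ip_vals[chrom] = ip_mean
            in_vals[chrom] = in_mean
    truth = PlantedTruth(enriched_regions=list(regions))
    return CoverageTrack("ip", ip_vals), CoverageTrack("input", in_vals), truth


def _draw_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean m, var m + phi m^2) via gamma-Poisson; Poisson when phi=0."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(means)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    return rng.poisson(lam)


def generate_counts(
    genes: Sequence[GeneModel],
    n_samples_per_group: int = 3,
    baseline_mean: float = 200.0,
    planted_log2fc: Mapping[str, float] | None = None,
    dispersion: float = 0.0,
    seed: int = 0,
    group_names: tuple[str, str] = ("A", "B"),
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Two-group count matrix with planted per-gene log2 fold changes.

    Group ``B`` means are ``baseline_mean * 2**log2fc``; group ``A`` means
    are the baseline. Samples are named ``<group>_<i>``.
    """
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    planted = dict(planted_log2fc or {})
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    lfc = np.array([planted.get(g, 0.0) for g in gene_ids])
    mean_a = np.full(len(genes), baseline_mean)
    mean_b = baseline_mean * 2.0**lfc
    cols: dict[str, np.ndarray] = {}
    for i in range(n_samples_per_group):
        cols[f"{group_names[0]}_{i + 1}"] = _draw_counts(rng, mean_a, dispersion)
    for i in range(n_samples_per_group):
        cols[f"{group_names[1]}_{i + 1}"] = _draw_counts(rng, mean_b, dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"), dtype=int)
    lengths = pd.Series({g.gene_id: g.length for g in genes}, name="length")
    truth = PlantedTruth(
        de_genes_up={g for g, v in planted.items() if v > 0},
        de_genes_down={g for g, v in planted.items() if v < 0},
    )
    return ExpressionMatrix(counts, lengths), truth


def generate_three_condition_counts(
    genes: Sequence[GeneModel],
    n_samples_per_group: int = 2,
    baseline_mean: float = 200.0,
    planted_log2fc: Mapping[str, float] | None = None,
    reversion: float = 1.0,
    dispersion: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Counts for the condition-vs-mutant design: wild type in glucose
    (``wt_glu``), wild type in glycerol (``wt_gly``, with the planted
    condition response), and mutant in glycerol (``mut_gly``).

    The mutant reverts the fraction ``reversion`` of each gene's condition
    response on the log2 scale: its mean is
    ``baseline * 2**(lfc * (1 - reversion))``. ``reversion=1`` makes the
    mutant-in-glycerol means identical to wild-type glucose, the
    anti-identity construction whose expression scatter has r = -1.
    """
    planted = dict(planted_log2fc or {})
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    lfc = np.array([planted.get(g, 0.0) for g in gene_ids])
    means = {
        "wt_glu": np.full(len(genes), baseline_mean),
        "wt_gly": baseline_mean * 2.0**lfc,
        "mut_gly": baseline_mean * 2.0 ** (lfc * (1.0 - reversion)),
    }
    cols: dict[str, np.ndarray] = {}
    for group, m in means.items():
        for i in range(n_samples_per_group):
            cols[f"{group}_{i + 1}"] = _draw_counts(rng, m, dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"), dtype=int)
    lengths = pd.Series({g.gene_id: g.length for g in genes}, name="length")
    truth = PlantedTruth(
        de_genes_up={g for g, v in planted.items() if v > 0},
        de_genes_down={g for g, v in planted.items() if v < 0},
    )
    return ExpressionMatrix(counts, lengths), truth


def generate_term_map(
    genes: Sequence[GeneModel],
    n_terms: int = 20,
    genes_per_term: int = 15,
    planted_term: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random GO-style term membership plus one planted term, verbatim."""
    gene_ids = [g.gene_id for g in genes]
    rng = np.random.default_rng(seed)
    term_map: dict[str, set[str]] = {}
    for t in range(n_terms):
        members = rng.choice(gene_ids, size=min(genes_per_term, len(gene_ids)), replace=False)
        term_map[f"TERM:{t + 1:04d}"] = set(members.tolist())
    if planted_term is not None:
        name, members = planted_term
        missing = set(members) - set(gene_ids)
        if missing:
            raise ValueError(f"planted members not in gene set: {sorted(missing)}")
        term_map[name] = set(members)
    return term_map
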