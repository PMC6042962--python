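"""Readers and writers for the text formats the pipeline touches.

Supported dialects:

* gene annotation — GTF/GFF with ``gene_id`` and ``gene_biotype`` attribute
  keys (1-based inclusive coordinates, converted on read/write), or BED6
  with an optional seventh biotype column;
* coverage — bedGraph (0-based half-open, non-overlapping records);
* peaks — BED6 with the score column holding the mean fold-change rounded
  to three decimals.

All files are UTF-8, tab-delimited text.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .model import (
    BIOTYPES,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    polymerase_for_biotype,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record; the message names the file and line number."""


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attrs(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read genes from a GTF/GFF or BED file into the internal convention.

    GTF coordinates (1-based inclusive) become 0-based half-open. Unknown
    biotypes map to ``other``; the polymerase class is derived from the
    biotype unless a ``polymerase`` attribute/column overrides it. Records
    without a usable strand are rejected and reported, not silently kept.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    is_bed = path.suffix.lower() == ".bed"
    genes: list[GeneModel] = []
    rejected = 0
    for lineno, line in enumerate(text, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if is_bed:
                gene = _gene_from_bed_fields(fields)
            else:
                gene = _gene_from_gtf_fields(fields)
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if gene is None:
            continue
        if gene == "rejected":
            rejected += 1
            logger.warning("%s:%d: record without strand rejected", path, lineno)
            continue
        genes.append(gene)
    if rejected:
        logger.warning("%s: %d records rejected (missing strand)", path, rejected)
    if not genes:
        logger.warning("%s: no gene records found", path)
    return genes


def _gene_from_gtf_fields(fields: list[str]):
    if len(fields) < 9:
        raise ParseError(f"expected 9 tab-separated GTF fields, got {len(fields)}")
    chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
    if feature not in ("gene", "transcript"):
        return None
    if feature == "transcript":
        return None
    try:
        start_i, end_i = int(start), int(end)
    except ValueError:
        raise ParseError(f"non-integer coordinates {start!r}/{end!r}")
    if strand not in ("+", "-"):
        return "rejected"
    attr = _parse_gtf_attrs(attrs)
    if "gene_id" not in attr:
        raise ParseError("missing gene_id attribute")
    biotype = attr.get("gene_biotype", "other")
    if biotype not in BIOTYPES:
        biotype = "other"
    polymerase = attr.get("polymerase", polymerase_for_biotype(biotype))
    # GTF is 1-based inclusive; internal is 0-based half-open.
    interval = GenomicInterval(chrom, start_i - 1, end_i, strand)
    return GeneModel(attr["gene_id"], interval, biotype, polymerase)


def _gene_from_bed_fields(fields: list[str]):
    if len(fields) < 6:
        raise ParseError(f"expected >= 6 BED fields, got {len(fields)}")
    chrom, start, end, name, _score, strand = fields[:6]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError:
        raise ParseError(f"non-integer coordinates {start!r}/{end!r}")
    if strand not in ("+", "-"):
        return "rejected"
    biotype = fields[6] if len(fields) > 6 else "protein_coding"
    if biotype not in BIOTYPES:
        biotype = "other"
    polymerase = fields[7] if len(fields) > 7 else polymerase_for_biotype(biotype)
    return GeneModel(name, GenomicInterval(chrom, start_i, end_i, strand), biotype, polymerase)


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes as GTF ``gene`` features (1-based inclusive on disk)."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}"; '
                f'polymerase "{g.polymerase}";'
            )
            fh.write(
                f"{g.chrom}\tchromark\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_bedgraph(
    path: str | Path,
    sample_id: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Read a bedGraph into a dense per-base coverage track.

    Records must be 0-based half-open, non-overlapping and non-negative.
    Unspecified positions hold 0. Chromosome vector lengths come from
    ``chrom_sizes`` when given, otherwise from the rightmost record end.
    """
    path = Path(path)
    records: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if value < 0:
            raise ParseError(f"{path}:{lineno}: negative coverage value {value}")
        if end <= start:
            raise ParseError(f"{path}:{lineno}: empty or inverted record")
        records.setdefault(chrom, []).append((start, end, value))

    values: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ParseError(f"{path}: overlapping bedGraph records on {chrom}")
        size = max(e for _, e, _ in recs)
        if chrom_sizes is not None:
            declared = chrom_sizes.get(chrom, size)
            if declared < size:
                raise ParseError(f"{path}: record beyond declared size of {chrom}")
            size = declared
        vec = np.zeros(size, dtype=float)
        for s, e, v in recs:
            vec[s:e] = v
        values[chrom] = vec
    if chrom_sizes is not None:
        for chrom, size in chrom_sizes.items():
            values.setdefault(chrom, np.zeros(size, dtype=float))
    return CoverageTrack(sample_id or path.stem, values)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as bedGraph, run-length encoding constant
    stretches and omitting zero runs (read back with ``chrom_sizes`` to
    restore trailing zeros exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.chroms:
            vec = track[chrom]
            if len(vec) == 0:
                continue
            # boundaries of constant runs
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        chrom, size = line.split("\t")[:2]
        sizes[chrom] = int(size)
    return sizes


BED_HEADER = "# chrom\tstart\tend\tname\tscore\tstrand"


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a peak set as BED6; score = mean fold-change to 3 decimals."""
    peaks.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(BED_HEADER + "\n")
        for i, p in enumerate(peaks, start=1):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{p.score:.3f}\t{iv.strand}\n"
            )


def read_bed(path: str | Path, resort: bool = False) -> PeakSet:
    """Read a BED6 peak file; unsorted input is an error unless ``resort``."""
    path = Path(path)
    peaks: list[Peak] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected >= 5 BED fields")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        score = float(fields[4])
        strand = fields[5] if len(fields) > 5 else "."
        peaks.append(Peak(GenomicInterval(chrom, start, end, strand), score))
    keys = [(p.interval.chrom, p.interval.start) for p in peaks]
    if keys != sorted(keys):
        if not resort:
            raise ParseError(f"{path}: peaks not sorted (pass resort=True to re-sort)")
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return PeakSet(peaks)


def write_term_map(term_map: Mapping[str, set[str] | list[str]], path: str | Path) -> None:
    """Write a term map as two-column TSV (gene_id, term_id) with header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tterm_id\n")
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{gene}\t{term}\n")


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene_id, term_id) TSV into term -> gene set."""
    term_map: dict[str, set[str]] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if lineno == 1 and line.lower().startswith("gene_id"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        gene, term = parts[0], parts[1]
        term_map.setdefault(term, set()).add(gene)
    return term_map
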