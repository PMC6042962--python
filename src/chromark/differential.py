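"""Differential occupancy between two conditions over consensus peaks.

This is a deliberately simple, fully specified stand-in for replicate-aware
differential-binding machinery: build a consensus region set as the merged
union of the two conditions' peaks, sum depth-scaled (per-million) coverage
per region and condition, and label regions up/down by a pseudocount-1 log2
fold change, optionally gated by a Fisher exact test on rounded per-million
counts. It reproduces the analytic role of a differential-binding step
without claiming numerical equivalence to any replicate-modelling package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CoverageTrack, GenomicInterval, Peak, PeakSet, sort_peaks


@dataclass
class DifferentialPeak:
    interval: GenomicInterval
    signal_a: float  # per-million summed coverage, condition A
    signal_b: float  # per-million summed coverage, condition B
    log2fc: float  # log2((signal_b + 1) / (signal_a + 1))
    label: str  # up / down / unchanged (B relative to A)
    p_value: float | None = None


def build_consensus(
    peaks_a: PeakSet, peaks_b: PeakSet, merge_gap: int = 0
) -> PeakSet:
    """Union of both interval sets, merged when the gap is <= ``merge_gap``
    (the default 0 merges only overlapping or book-ended intervals)."""
    peaks = sort_peaks(
        [Peak(p.interval, 0.0) for p in peaks_a] + [Peak(p.interval, 0.0) for p in peaks_b]
    )
    out: list[Peak] = []
    for p in peaks:
        if out:
            prev = out[-1]
            if (
                prev.interval.chrom == p.interval.chrom
                and p.interval.start - prev.interval.end <= merge_gap
            ):
                if p.interval.end > prev.interval.end:
                    out[-1] = Peak(
                        GenomicInterval(
                            prev.interval.chrom, prev.interval.start, p.interval.end
                        ),
                        0.0,
                    )
                continue
        out.append(p)
    return PeakSet(out, source_params={"consensus_merge_gap": merge_gap})


def score_regions(regions: PeakSet, track: CoverageTrack) -> np.ndarray:
    """Per-region summed coverage scaled to the track's library total
    (reads-per-million-style units)."""
    total = track.total_signal
    if total <= 0:
        raise ValueError("cannot score regions against a zero-total track")
    sums = np.empty(len(regions))
    for i, p in enumerate(regions):
        iv = p.interval
        if iv.chrom not in track or iv.end > len(track[iv.chrom]):
            raise ValueError(f"region {iv} outside track {track.sample_id}")
        sums[i] = track[iv.chrom][iv.start : iv.end].sum()
    return sums / total * 1e6


def differential_call(
    consensus: PeakSet,
    ip_a: CoverageTrack,
    ip_b: CoverageTrack,
    lfc_threshold: float = 1.0,
    test: str = "none",
    alpha: float = 0.05,
) -> list[DifferentialPeak]:
    """Label each consensus region up/down/unchanged for condition B
    relative to condition A.

    ``log2fc = log2((b + 1) / (a + 1))`` on per-million sums; a region is
    up when log2fc >= +threshold (down symmetric). With ``test="fisher"``
    the label must additionally pass a 2x2 Fisher exact test of (rounded
    region per-million count vs library remainder) at ``alpha``; the test
    operates on rounded scaled sums and is documented as approximate.
    """
    if test not in ("none", "fisher"):
        raise ValueError(f"unknown test {test!r}")
    if len(consensus) == 0:
        return []
    sig_a = score_regions(consensus, ip_a)
    sig_b = score_regions(consensus, ip_b)
    results: list[DifferentialPeak] = []
    for p, a, b in zip(consensus, sig_a, sig_b):
        # difference of logs, not log of ratio: exactly antisymmetric
        lfc = float(np.log2(b + 1.0) - np.log2(a + 1.0))
        pval: float | None = None
        significant = True
        if test == "fisher":
            ra, rb = int(round(a)), int(round(b))
            table = [[ra, int(1e6) - ra], [rb, int(1e6) - rb]]
            pval = float(stats.fisher_exact(table)[1])
            significant = pval < alpha
        if lfc >= lfc_threshold and significant:
            label = "up"
        elif lfc <= -lfc_threshold and significant:
            label = "down"
        else:
            label = "unchanged"
        results.append(DifferentialPeak(p.interval, float(a), float(b), lfc, label, pval))
    return results


def differential_table(results: list[DifferentialPeak]) -> pd.DataFrame:
    """Flatten differential calls into the output table layout."""
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in results],
            "start": [r.interval.start for r in results],
            "end": [r.interval.end for r in results],
            "signal_a": [r.signal_a for r in results],
            "signal_b": [r.signal_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value if r.p_value is not None else np.nan for r in results],
            "label": [r.label for r in results],
        }
    )
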