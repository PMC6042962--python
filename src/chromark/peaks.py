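"""Fold-change peak calling on IP/input coverage pairs.

The caller declares a peak wherever the depth-normalized per-base
IP/input ratio stays at or above a fold threshold (default 2) for a
minimum run of bases (default 50), then merges peaks separated by less
than a merge gap (default 400 bases).

Conventions, fixed here because the thresholds alone do not pin them down:

* "extending for" ``min_run`` bases means run length >= min_run
  (a 50-base run qualifies at the default);
* "closer than" ``merge_gap`` is a strict inequality on the half-open gap
  ``next.start - prev.end`` — a gap of exactly 400 does not merge;
* a pseudocount is added to both numerator and denominator before the
  ratio, so empty positions score 1.0 rather than blowing up;
* both tracks are first scaled to the mean of their two totals, because a
  raw 2-fold cut is meaningless across unequal sequencing depths.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .model import CoverageTrack, GenomicInterval, Peak, PeakSet, sort_peaks


@dataclass(frozen=True)
class PeakCallParams:
    fold_threshold: float = 2.0
    min_run: int = 50
    merge_gap: int = 400
    pseudocount: float = 1.0
    depth_normalize: bool = True

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def normalize_pair(
    ip: CoverageTrack, input_: CoverageTrack
) -> tuple[CoverageTrack, CoverageTrack]:
    """Scale both tracks so each totals the mean of the two library totals.

    Per-base shape is unchanged; only the global scale moves.
    """
    if set(ip.values) != set(input_.values):
        raise ValueError("IP and input tracks cover different chromosomes")
    t_ip, t_in = ip.total_signal, input_.total_signal
    if t_ip == 0 or t_in == 0:
        raise ValueError("cannot depth-normalize a zero-total track")
    target = 0.5 * (t_ip + t_in)
    return ip.scaled(target / t_ip), input_.scaled(target / t_in)


def fold_change_track(
    ip: CoverageTrack, input_: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-base ratio ``(ip + eps) / (input + eps)``; strictly positive."""
    if set(ip.values) != set(input_.values):
        raise ValueError("IP and input tracks cover different chromosomes")
    ratio = {}
    for chrom in ip.values:
        a, b = ip[chrom], input_[chrom]
        if len(a) != len(b):
            raise ValueError(f"chromosome {chrom} length mismatch between tracks")
        ratio[chrom] = (a + pseudocount) / (b + pseudocount)
    return CoverageTrack("fold_change", ratio)


def call_raw_peaks(
    ratio: CoverageTrack, fold_threshold: float = 2.0, min_run: int = 50
) -> PeakSet:
    """Maximal runs of consecutive positions with ratio >= threshold; runs
    shorter than ``min_run`` are discarded. Peak score = mean ratio over
    the run."""
    peaks: list[Peak] = []
    for chrom in ratio.chroms:
        vec = ratio[chrom]
        above = vec >= fold_threshold
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                peaks.append(
                    Peak(GenomicInterval(chrom, int(s), int(e)), float(vec[s:e].mean()))
                )
    return PeakSet(sort_peaks(peaks))


def merge_peaks(peaks: PeakSet, merge_gap: int = 400) -> PeakSet:
    """Union same-chromosome peaks whose gap is strictly less than
    ``merge_gap``, iterated to a fixed point.

    Merged scores are the length-weighted mean of the member scores (gap
    bases contribute no weight). A single left-to-right sweep already
    reaches the fixed point for sorted input, but the loop guards the
    invariant regardless.
    """
    merged = list(peaks.peaks)
    changed = True
    while changed:
        changed = False
        out: list[Peak] = []
        for p in merged:
            if out:
                prev = out[-1]
                same = prev.interval.chrom == p.interval.chrom
                gap = p.interval.start - prev.interval.end
                if same and gap < merge_gap:
                    w1, w2 = prev.interval.length, p.interval.length
                    score = (prev.score * w1 + p.score * w2) / (w1 + w2)
                    out[-1] = Peak(
                        GenomicInterval(
                            prev.interval.chrom, prev.interval.start, p.interval.end
                        ),
                        score,
                    )
                    changed = True
                    continue
            out.append(p)
        merged = out
    result = PeakSet(merged, source_params=dict(peaks.source_params))
    result.validate(min_gap=merge_gap)
    return result


def call_peaks(
    ip: CoverageTrack, input_: CoverageTrack, params: PeakCallParams | None = None
) -> PeakSet:
    """Full caller: depth-normalize, ratio with pseudocount, threshold-run
    detection, proximity merge. The returned set records the parameters it
    was called with."""
    params = params or PeakCallParams()
    if params.depth_normalize:
        ip, input_ = normalize_pair(ip, input_)
    ratio = fold_change_track(ip, input_, params.pseudocount)
    raw = call_raw_peaks(ratio, params.fold_threshold, params.min_run)
    merged = merge_peaks(raw, params.merge_gap)
    merged.source_params = asdict(params)
    return merged
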