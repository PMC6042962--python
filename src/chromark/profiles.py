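"""Metagene profiles, RPKM, expression quantiles, a differential-expression
stand-in and the condition-vs-mutant dependence scatter.

Metagene construction follows the occupancy-plot recipe: per-gene signal
vectors are taken either anchored at the TSS (+/- flank bases, oriented
5'->3') or scaled over the transcript (base-resolution flanks around a gene
body linearly resampled to a fixed grid), mean-smoothed with a centered
101-base window, and averaged positionwise across genes. Smoothing is
applied per gene before averaging; for complete data the two orders
commute, and the gene-first order is well defined when some genes have
missing flank positions near chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .model import CoverageTrack, GeneModel
from .stats import bh_adjust, pearson_correlation


@dataclass
class MetageneProfile:
    mode: str  # "tss_anchored" or "transcript_scaled"
    positions: np.ndarray  # bases relative to anchor, or scaled units with flanks
    mean_signal: np.ndarray
    n_genes: np.ndarray  # contributing genes per position


class ExpressionMatrix:
    """Gene x sample integer counts with gene lengths and derived RPKM."""

    def __init__(self, counts: pd.DataFrame, gene_lengths: pd.Series):
        missing = counts.index.difference(gene_lengths.index)
        if len(missing):
            raise ValueError(f"genes without lengths: {list(missing[:5])}")
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.gene_lengths = gene_lengths.loc[counts.index].astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def rpkm_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            rpkm(
                self.counts.to_numpy(dtype=float),
                self.gene_lengths.to_numpy(),
                self.library_sizes.to_numpy(dtype=float),
            ),
            index=self.counts.index,
            columns=self.counts.columns,
        )


def smooth_mean(signal: np.ndarray, window: int = 101) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges and skips
    missing (NaN) entries, so output length equals input length."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(signal, dtype=float)
    if window == 1:
        return x.copy()
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(finite.astype(float), kernel, mode="same")
    out = np.full(x.shape, np.nan)
    ok = counts > 0
    out[ok] = sums[ok] / counts[ok]
    return out


def anchored_profile(
    track: CoverageTrack, gene: GeneModel, flank: int = 2000
) -> np.ndarray:
    """Signal at TSS-flank .. TSS+flank in 5'->3' orientation (length
    2*flank+1). Positions beyond chromosome ends are NaN."""
    vec = track[gene.chrom]
    out = np.full(2 * flank + 1, np.nan)
    lo, hi = gene.tss - flank, gene.tss + flank + 1
    src_lo, src_hi = max(lo, 0), min(hi, len(vec))
    if src_lo < src_hi:
        out[src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
    if gene.strand == "-":
        out = out[::-1]
    return out


def scaled_profile(
    track: CoverageTrack,
    gene: GeneModel,
    flank: int = 500,
    body_points: int = 1000,
) -> np.ndarray:
    """Base-resolution flanks around a gene body linearly resampled to
    ``body_points`` positions; oriented 5'->3'.

    When the body length equals ``body_points`` the interpolation nodes are
    the integers, so the body is returned unchanged.
    """
    if gene.length < 2:
        raise ValueError(f"gene {gene.gene_id} too short to scale")
    vec = track[gene.chrom]
    iv = gene.interval

    def window(lo: int, hi: int) -> np.ndarray:
        out = np.full(hi - lo, np.nan)
        s, e = max(lo, 0), min(hi, len(vec))
        if s < e:
            out[s - lo : e - lo] = vec[s:e]
        return out

    left = window(iv.start - flank, iv.start)
    right = window(iv.end, iv.end + flank)
    body = vec[iv.start : iv.end].astype(float)
    grid = np.linspace(0.0, len(body) - 1.0, body_points)
    body_rs = np.interp(grid, np.arange(len(body)), body)
    profile = np.concatenate([left, body_rs, right])
    if gene.strand == "-":
        profile = profile[::-1]
    return profile


def metagene_average(
    per_gene_matrix: np.ndarray,
    mode: str = "tss_anchored",
    positions: np.ndarray | None = None,
) -> MetageneProfile:
    """Positionwise mean over genes, ignoring missing entries; the count of
    contributing genes is recorded per position."""
    m = np.asarray(per_gene_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("need a non-empty gene x position matrix")
    finite = np.isfinite(m)
    n_genes = finite.sum(axis=0)
    sums = np.where(finite, m, 0.0).sum(axis=0)
    mean = np.full(m.shape[1], np.nan)
    ok = n_genes > 0
    mean[ok] = sums[ok] / n_genes[ok]
    if positions is None:
        positions = np.arange(m.shape[1])
    return MetageneProfile(mode, np.asarray(positions), mean, n_genes)


def metagene_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    mode: str = "tss_anchored",
    flank: int = 2000,
    body_points: int = 1000,
    smooth_window: int = 101,
) -> MetageneProfile:
    """Full metagene pipeline: per-gene vectors, per-gene smoothing, then
    the positionwise average."""
    if mode == "tss_anchored":
        rows = [anchored_profile(track, g, flank) for g in genes]
        positions = np.arange(-flank, flank + 1)
    elif mode == "transcript_scaled":
        rows = [scaled_profile(track, g, flank, body_points) for g in genes]
        positions = np.concatenate(
            [np.arange(-flank, 0, dtype=float), np.linspace(0, 1, body_points), 1 + np.arange(1, flank + 1, dtype=float)]
        )
    else:
        raise ValueError(f"unknown metagene mode {mode!r}")
    smoothed = [smooth_mean(r, smooth_window) for r in rows]
    return metagene_average(np.vstack(smoothed), mode=mode, positions=positions)


def rpkm(
    counts: np.ndarray, gene_lengths: np.ndarray, library_sizes: np.ndarray
) -> np.ndarray:
    """Reads per kilobase of transcript per million mapped reads:
    count / (length_kb * library_millions)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    return counts / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)


def quantile_groups(values: pd.Series, n_groups: int = 5) -> pd.Series:
    """Split genes into ``n_groups`` contiguous expression groups of (near-)
    equal size; group 1 is the lowest-expression group.

    Genes are sorted ascending by value with gene-id tie-breaking for
    determinism; when the count is not divisible, the first ``n mod k``
    groups take the extra gene.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if len(values) < n_groups:
        raise ValueError("fewer genes than groups")
    if not np.all(np.isfinite(values.to_numpy(dtype=float))):
        raise ValueError("values must be finite")
    order = values.to_frame("v").reset_index()
    idcol = order.columns[0]
    order = order.sort_values(["v", idcol], kind="stable")
    n, k = len(order), n_groups
    base, extra = divmod(n, k)
    sizes = [base + 1 if i < extra else base for i in range(k)]
    labels = np.repeat(np.arange(1, k + 1), sizes)
    out = pd.Series(labels, index=order[idcol].to_numpy(), name="group")
    return out.loc[values.index]


def de_genes(
    expr: ExpressionMatrix,
    group_labels: pd.Series | dict[str, str],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression via an exact conditional binomial.

    Counts are pooled per group; under the null, a gene's pooled group-B
    count given the gene total is Binomial(total, L_B / (L_A + L_B)) with
    L the pooled library sizes, tested two-sided, BH-adjusted. A gene is
    differentially expressed when adjusted p < alpha and its pseudocount-1
    per-million log2 fold change is at least ``lfc_threshold`` in absolute
    value. This is a fully specified stand-in for count-GLM machinery and
    ignores replicate-level dispersion (see the methods note).
    """
    labels = pd.Series(group_labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga = labels.index[labels == groups[0]]
    gb = labels.index[labels == groups[1]]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("each group needs at least one sample")
    a = expr.counts[ga].sum(axis=1).to_numpy()
    b = expr.counts[gb].sum(axis=1).to_numpy()
    la = float(expr.library_sizes[ga].sum())
    lb = float(expr.library_sizes[gb].sum())
    p_null = lb / (la + lb)
    totals = a + b
    pvals = np.ones(len(totals))
    for i, (bi, ti) in enumerate(zip(b, totals)):
        if ti > 0:
            pvals[i] = _sps.binomtest(int(bi), int(ti), p_null).pvalue
    cpm_a = a / la * 1e6
    cpm_b = b / lb * 1e6
    lfc = np.log2((cpm_b + 1.0) / (cpm_a + 1.0))
    adj = bh_adjust(pvals)
    de = (adj < alpha) & (np.abs(lfc) >= lfc_threshold)
    return pd.DataFrame(
        {
            "gene_id": expr.genes,
            "count_a": a,
            "count_b": b,
            "log2fc": lfc,
            "p_value": pvals,
            "adj_p": adj,
            "de": de,
        }
    ).set_index("gene_id")


def dependence_scatter(
    expr_wt_glu: pd.Series,
    expr_wt_gly: pd.Series,
    expr_mut_gly: pd.Series,
    gene_subset: list[str] | None = None,
) -> tuple[pd.Series, pd.Series, float]:
    """Condition-dependence vs mutant-dependence expression scatter.

    x = log2((glycerol_wt + 1) / (glucose_wt + 1)) and
    y = log2((glycerol_mut + 1) / (glycerol_wt + 1)) on per-million-scaled
    expression; returns (x, y, Pearson r). ``r`` is NaN when either axis is
    constant (e.g. mutant identical to wild type).
    """
    idx = expr_wt_glu.index
    if not (idx.equals(expr_wt_gly.index) and idx.equals(expr_mut_gly.index)):
        raise ValueError("expression vectors must share one gene index")
    if gene_subset is not None:
        offenders = sorted(set(gene_subset) - set(idx))
        if offenders:
            raise ValueError(f"subset genes missing from expression: {offenders}")
        idx = pd.Index(sorted(set(gene_subset)))

    def cpm(v: pd.Series) -> pd.Series:
        return v / v.sum() * 1e6

    glu, gly, mut = cpm(expr_wt_glu), cpm(expr_wt_gly), cpm(expr_mut_gly)
    x = np.log2((gly[idx] + 1.0) / (glu[idx] + 1.0))
    y = np.log2((mut[idx] + 1.0) / (gly[idx] + 1.0))
    r = pearson_correlation(x.to_numpy(), y.to_numpy())
    return x.rename("x"), y.rename("y"), r
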