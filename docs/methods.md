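# Methods

This note records the models, conventions and design choices behind
`chromark`, in the order the pipeline runs.

## Coordinates and containers

All internal coordinates are 0-based half-open (`[start, end)`, the BED
convention); GTF/GFF's 1-based inclusive coordinates are converted at the
I/O boundary, and the round trip is the identity. The TSS of a minus-strand
gene is the interval's last base (`end − 1`); this is the standard
convention and matters for every TSS-anchored computation. Coverage is
dense per-base float vectors per chromosome. Synthetic genomes are at most
a few megabases, so dense storage costs a few MB and keeps the ratio,
smoothing and profile code simple; run-length encoding is used only on
disk (bedGraph). Because bedGraph omits zero runs, reading a track back
bit-exactly requires the chromosome sizes sidecar the writers emit.

## Peak calling

The caller applies the 2-fold IP/input criterion per base on
depth-normalized tracks, requires runs of ≥ 50 bases, and merges peaks
separated by < 400 bases. Choices the thresholds alone do not fix:

- **Run length**: "extending for 50 bases" is read as length ≥ 50, so a
  50-base run qualifies.
- **Merge gap**: "closer than 400" is a strict inequality on the half-open
  gap `next.start − prev.end`; a gap of exactly 400 does not merge.
  Merging iterates to a fixed point (merging two peaks can bring the union
  within range of a third); merged scores are length-weighted means.
- **Pseudocount**: ε = 1 signal unit is added to numerator and denominator
  before the ratio, so empty positions score 1.0 instead of dividing by
  zero, with negligible bias at well-covered positions.
- **Depth normalization**: both tracks are scaled to the mean of the two
  library totals (on by default). A raw fold cut is meaningless across
  unequal depths; this choice makes the called ratio independent of the
  simulated `depth_ratio`, which tests assert exactly.

One consequence worth knowing: because enriched regions inflate the IP
library total, mean-of-totals scaling shrinks the in-region ratio to
`fold · G / (G + (fold−1)·L)` for planted fraction `L/G` — about 2% below
the planted fold in our fixtures. The effective calling threshold is
therefore very slightly above the nominal fold; fixtures plant folds
comfortably away from the boundary (3 and 1.5 around the 2-fold cut), and
the exact-recovery tests assert the closed form above rather than the
nominal fold.

The fold-change evaluation is per base, not windowed or pre-smoothed; the
alternative readings would blur peak boundaries, and the per-base rule is
the only one whose noise-free recovery is base-exact.

## Differential occupancy

Replicate-aware differential-binding modelling is out of scope; the
stand-in is: consensus = merged union of both conditions' peak intervals
(gap ≤ 0 merges, i.e. only overlapping or book-ended intervals at the
default), per-region per-million summed coverage per condition, and
`log2fc = log2(b+1) − log2(a+1)` computed as a *difference of logs* so
that swapping conditions negates it exactly (the antisymmetry tests assert
equality, not approximate equality). Default call: |log2fc| ≥ 1. The
optional Fisher exact gate tests the 2×2 table (rounded region per-million
count vs per-million remainder) at α = 0.05; rounding scaled sums to
integers makes it approximate, which is documented rather than hidden.
Note the consensus merge uses `gap ≤ merge_gap` (so the default 0 joins
adjacent intervals) while peak-calling merge uses the strict `<` rule —
the two operations intentionally differ.

No claim is made that these labels match any replicate-modelling package
numerically; the planted-truth tests check the analytic role (all and only
condition-specific planted regions labelled up on noise-free data).

## Gene assignment

Distance is measured from the peak *interval* to the TSS *point*: zero if
the TSS lies inside the peak, otherwise the distance from the nearer edge
(using `end − 1` as the right edge, consistent with closed-interval
closest-feature semantics). Distance is strand-agnostic. Ties are broken
by lexicographically smallest gene id and flagged, so results are
deterministic and order-independent (asserted by shuffling tests). The
Pol III/tRNA/rRNA filter is applied to the candidate set *before* the
search, so an excluded gene can never absorb a peak that would otherwise
report a Pol II neighbour; this is the stricter of the two possible
orderings and is applied consistently. The implementation vectorizes the
per-chromosome distance computation; a brute-force O(n·m) scan is kept in
the tests as the oracle.

## Enrichment statistics

The over-representation p-value is the upper tail P(X ≥ k) of the
hypergeometric law, accumulated in log space from `gammaln` binomials, and
matches exact rational enumeration to < 1e−12 over every configuration
with N ≤ 25. Fold enrichment is (k/n)/(K/N); a term absent from the
universe (K = 0) is reported as missing rather than 0 or ∞. Inclusion
follows the raw-p rule (p < 0.05 and k ≥ 2) because that is the reported
convention for this analysis; BH adjustment is exposed behind a flag as
the safer default for larger term collections. The universe defaults to
the filtered Pol II gene set, configurable. BH is implemented directly
from the step-up definition and cross-checked against statsmodels.

## Profiles and expression

- `smooth_mean` is a centred moving average whose window shrinks at array
  edges and skips missing values (NaN); window 101, odd windows only.
- TSS-anchored profiles span ± 2000 bases in 5′→3′ orientation (vectors
  reversed for minus-strand genes); positions beyond chromosome ends are
  missing, and the metagene records how many genes contribute at each
  position.
- Transcript-scaled profiles take ± 500-base flanks at base resolution and
  linearly resample the gene body to 1000 points. 1000 is a display-
  resolution choice (no canonical bin count exists); when a body is
  exactly 1000 bases the resampling grid hits the integers and the body is
  returned unchanged, which the tests use as a fixed point.
- Smoothing is applied per gene *before* averaging. For complete data the
  two orders commute; gene-first is the well-defined choice when flank
  positions are missing near chromosome ends.
- RPKM = count / (length_kb × library_millions). Quantile groups sort
  ascending by value with gene-id tie-breaking, and the first `n mod k`
  groups absorb the remainder, so group sizes differ by at most one;
  group 1 is the lowest-expression group.
- The DE stand-in is an exact conditional binomial on pooled counts: given
  a gene's total across both groups, the group-B count is Binomial(total,
  L_B/(L_A+L_B)) under the null, tested two-sided and BH-adjusted; the
  decision rule is adjusted p < 0.05 and |log2fc| ≥ 1 on pseudocount-1
  per-million values. Pooling ignores replicate-level (biological)
  dispersion, so with overdispersed counts the test is anticonservative —
  it is calibrated (type I ≤ α) only at dispersion 0, which is what the
  null simulations assert. Count-GLM machinery is deliberately out of
  scope.
- The dependence scatter per-million-scales each condition's expression
  vector, takes x = log₂((gly+1)/(glu+1)) and y = log₂((mut+1)/(gly+1)),
  and reports Pearson r with pairwise missing dropping. When the mutant
  exactly reverts the condition response (mut = glu), y = −x by
  construction and r = −1 to floating-point accuracy; when the mutant
  equals wild type, y ≡ 0 and r is reported missing (zero variance), not
  0.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed). Coverage pairs
are a flat background (default 50 counts/base, a realistic per-base depth
for a well-covered small genome) with rectangular fold-enrichment blocks,
optional global IP scaling (`depth_ratio`) for unequal library depth, and
per-base Poisson sampling. Counts are negative-binomial with variance
m + φm² (φ = 0 → Poisson). The default study fixture plants 6
condition-specific and 3 shared promoter regions of fold 3 on a 300 kb,
60-gene genome with 10% non-Pol II genes, a +2 log₂ expression response at
the up genes and a fully reverting mutant, and one term holding exactly
the up genes.

Not modelled: fragment-length effects, GC/mappability bias, nucleosome
structure, peak-shape asymmetry, read-level sampling, biological replicate
variability in coverage, or correlated noise along the genome. Passing the
planted-truth tests therefore demonstrates algorithmic correctness of the
pipeline's rules on data satisfying its assumptions — not calling
performance on real chromatin, where background is non-uniform and the
2-fold/50-base/400-base constants interact with fragment statistics.

## Problem sizes and numerics

Test and acceptance runs use genomes of 100–300 kb with 30–100 genes,
20-replicate noise studies, and 1,000-gene count simulations — sizes
chosen so the full suite runs in well under a minute while leaving each
statistical check adequately powered (e.g. 100 planted regions for the
95% recovery bound; binomial slack 2·√(α(1−α)/1000) on the type-I rate).
Degenerate inputs are errors, not silent passes: zero-total tracks,
even smoothing windows, empty gene lists, genes absent from the universe,
regions outside the genome, non-disjoint planted regions. All output
files are plain TSV/BED/bedGraph/JSON with fixed formatting and no
timestamps, so identical config + seed reproduces byte-identical runs.

## CFU viability

The chronological-lifespan utility divides each time point's colony count
by the day-3 count and reports percentages (day 3 ≡ 100%); a zero or
missing reference day is an error.
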