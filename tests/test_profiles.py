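"""Metagene construction, RPKM, quantiles, DE stand-in, dependence scatter."""

import numpy as np
import pandas as pd
import pytest

from chromark import simulate as sim
from chromark.model import CoverageTrack, GeneModel, GenomicInterval
from chromark.profiles import (
    ExpressionMatrix,
    anchored_profile,
    de_genes,
    dependence_scatter,
    metagene_average,
    metagene_profile,
    quantile_groups,
    rpkm,
    scaled_profile,
    smooth_mean,
)


def coord_track(length=50_000, chrom="chr1"):
    """Track whose value at each position equals the genomic coordinate."""
    return CoverageTrack("coord", {chrom: np.arange(length, dtype=float)})


def gene(gid, start, end, strand="+", chrom="chr1"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


class TestSmoothMean:
    def test_constant_signal_invariant(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(smooth_mean(x, 101), x)

    def test_window_one_is_identity(self, rng):
        x = rng.uniform(size=100)
        np.testing.assert_array_equal(smooth_mean(x, 1), x)

    def test_impulse_spreads_to_plateau(self):
        """An impulse of height 101 becomes a plateau of 1 over 101
        positions — checked against a direct convolution oracle."""
        x = np.zeros(1_001)
        x[500] = 101.0
        got = smooth_mean(x, 101)
        oracle = np.convolve(x, np.ones(101) / 101, mode="same")
        np.testing.assert_allclose(got, oracle)
        assert np.all(got[450:551] == pytest.approx(1.0))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_mean(np.zeros(10), 4)

    def test_edges_shrink_to_available_positions(self):
        x = np.arange(10.0)
        got = smooth_mean(x, 5)
        assert got[0] == pytest.approx(np.mean(x[:3]))  # window [0, 2]
        assert got[-1] == pytest.approx(np.mean(x[-3:]))

    def test_interior_mean_preserved(self, rng):
        x = rng.uniform(size=2_000)
        got = smooth_mean(x, 101)
        assert got[200:-200].mean() == pytest.approx(x[200:-200].mean(), rel=5e-3)


class TestAnchoredProfile:
    def test_plus_strand_ascending_coordinates(self):
        g = gene("g", 10_000, 12_000, "+")
        prof = anchored_profile(coord_track(), g, flank=2_000)
        np.testing.assert_array_equal(prof, np.arange(8_000, 12_001))

    def test_minus_strand_descending(self):
        g = gene("g", 10_000, 12_000, "-")  # TSS at 11999
        prof = anchored_profile(coord_track(), g, flank=2_000)
        np.testing.assert_array_equal(prof, np.arange(13_999, 9_998, -1))

    def test_chromosome_start_boundary_missing(self):
        g = gene("g", 100, 1_000, "+")
        prof = anchored_profile(coord_track(), g, flank=2_000)
        assert np.isnan(prof[:1_900]).all()
        assert np.isfinite(prof[1_900:]).all()


class TestScaledProfile:
    def test_body_length_equal_to_grid_is_identity(self):
        g = gene("g", 10_000, 11_000, "+")
        prof = scaled_profile(coord_track(), g, flank=500, body_points=1_000)
        np.testing.assert_array_equal(prof[500:1_500], np.arange(10_000, 11_000))

    def test_constant_body_stays_constant(self):
        track = CoverageTrack("c", {"chr1": np.full(20_000, 4.2)})
        g = gene("g", 5_000, 8_123, "+")
        prof = scaled_profile(track, g, flank=100, body_points=777)
        np.testing.assert_allclose(prof, 4.2)

    def test_linear_ramp_resampled_exactly(self):
        """Linear interpolation of a linear ramp is the same ramp on the new
        grid (closed form)."""
        g = gene("g", 10_000, 13_000, "+")
        prof = scaled_profile(coord_track(), g, flank=0, body_points=500)
        expected = 10_000 + np.linspace(0, 2_999, 500)
        np.testing.assert_allclose(prof, expected)

    def test_minus_strand_orientation_flip(self):
        g_plus = gene("g", 10_000, 11_000, "+")
        g_minus = gene("g", 10_000, 11_000, "-")
        p = scaled_profile(coord_track(), g_plus, flank=10, body_points=100)
        m = scaled_profile(coord_track(), g_minus, flank=10, body_points=100)
        np.testing.assert_allclose(m, p[::-1])


class TestMetageneAverage:
    def test_identical_genes_equal_single_profile(self):
        row = np.sin(np.linspace(0, 3, 201))
        prof = metagene_average(np.tile(row, (10, 1)))
        np.testing.assert_allclose(prof.mean_signal, row)
        assert np.all(prof.n_genes == 10)

    def test_opposite_profiles_cancel(self):
        row = np.linspace(-1, 1, 50)
        prof = metagene_average(np.vstack([row, -row]))
        np.testing.assert_allclose(prof.mean_signal, 0, atol=1e-15)

    def test_matches_naive_loop_with_missing_data(self, rng):
        m = rng.uniform(size=(50, 120))
        m[rng.random(m.shape) < 0.2] = np.nan
        prof = metagene_average(m)
        for j in range(m.shape[1]):
            col = m[:, j][np.isfinite(m[:, j])]
            if len(col):
                assert prof.mean_signal[j] == pytest.approx(col.mean())
            assert prof.n_genes[j] == len(col)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            metagene_average(np.empty((0, 10)))

    def test_full_pipeline_smooths_before_averaging(self):
        track = CoverageTrack("t", {"chr1": np.zeros(30_000)})
        track["chr1"][10_000] = 101.0
        g = gene("g", 10_000, 12_000, "+")
        prof = metagene_profile(track, [g], flank=2_000, smooth_window=101)
        center = 2_000  # TSS position in the profile
        assert prof.mean_signal[center] == pytest.approx(1.0)


class TestRpkm:
    def test_unit_case(self):
        out = rpkm(np.array([[10.0]]), np.array([1_000.0]), np.array([1e6]))
        assert out[0, 0] == pytest.approx(10.0)

    def test_scaling_laws(self):
        base = rpkm(np.array([[10.0]]), np.array([1_000.0]), np.array([1e6]))[0, 0]
        assert rpkm(np.array([[10.0]]), np.array([1_000.0]), np.array([2e6]))[
            0, 0
        ] == pytest.approx(base / 2)
        assert rpkm(np.array([[10.0]]), np.array([2_000.0]), np.array([1e6]))[
            0, 0
        ] == pytest.approx(base / 2)

    def test_zero_length_or_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm(np.ones((1, 1)), np.array([0.0]), np.array([1e6]))
        with pytest.raises(ValueError):
            rpkm(np.ones((1, 1)), np.array([100.0]), np.array([0.0]))

    def test_expression_matrix_invariants(self, genome):
        expr, _ = sim.generate_counts(genome, seed=0)
        assert (expr.library_sizes == expr.counts.sum(axis=0)).all()
        manual = rpkm(
            expr.counts.to_numpy(float),
            expr.gene_lengths.to_numpy(),
            expr.library_sizes.to_numpy(float),
        )
        np.testing.assert_allclose(expr.rpkm_matrix.to_numpy(), manual)


class TestQuantileGroups:
    def test_even_split(self):
        v = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        groups = quantile_groups(v, 5)
        assert groups.value_counts().sort_index().tolist() == [2] * 5

    def test_remainder_goes_to_first_groups(self):
        v = pd.Series(np.arange(11.0), index=[f"g{i:02d}" for i in range(11)])
        sizes = quantile_groups(v, 5).value_counts().sort_index().tolist()
        assert sizes == [3, 2, 2, 2, 2]

    def test_group_one_is_lowest_expression(self):
        v = pd.Series([5.0, 1.0, 9.0, 3.0], index=list("abcd"))
        groups = quantile_groups(v, 2)
        assert groups["b"] == 1 and groups["c"] == 2

    def test_partition_properties(self, rng):
        v = pd.Series(rng.uniform(size=103), index=[f"g{i:03d}" for i in range(103)])
        groups = quantile_groups(v, 5)
        assert set(groups.index) == set(v.index)
        sizes = groups.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_fewer_genes_than_groups_rejected(self):
        with pytest.raises(ValueError):
            quantile_groups(pd.Series([1.0], index=["g"]), 5)


class TestDeGenes:
    def test_duplicated_columns_yield_no_de(self, genome):
        expr, _ = sim.generate_counts(genome, n_samples_per_group=3, seed=8)
        cols = expr.counts[["A_1", "A_2", "A_3"]]
        dup = pd.concat([cols, cols.add_suffix("dup")], axis=1)
        table = de_genes(
            ExpressionMatrix(dup, expr.gene_lengths),
            {c: ("A" if not c.endswith("dup") else "B") for c in dup.columns},
        )
        assert table["de"].sum() == 0
        np.testing.assert_allclose(table["log2fc"], 0.0)

    def test_planted_strong_effects_all_recovered(self, genome):
        planted = {g.gene_id: 3.0 for g in genome[:4]}
        expr, truth = sim.generate_counts(
            genome, n_samples_per_group=3, baseline_mean=200.0,
            planted_log2fc=planted, dispersion=0.0, seed=21,
        )
        labels = {c: c.split("_")[0] for c in expr.counts.columns}
        table = de_genes(expr, labels)
        recovered = set(table.index[table["de"]])
        assert truth.de_genes_up <= recovered

    def test_degenerate_labels_rejected(self, genome):
        expr, _ = sim.generate_counts(genome, seed=0)
        with pytest.raises(ValueError):
            de_genes(expr, {c: "same" for c in expr.counts.columns})


class TestDependenceScatter:
    @staticmethod
    def three_vectors(rng, n=200):
        idx = pd.Index([f"g{i:03d}" for i in range(n)])
        glu = pd.Series(rng.integers(50, 500, size=n).astype(float), index=idx)
        gly = glu * rng.uniform(0.25, 4.0, size=n)
        return idx, glu, gly

    def test_mutant_equal_to_wt_gives_missing_r(self, rng):
        idx, glu, gly = self.three_vectors(rng)
        x, y, r = dependence_scatter(glu, gly, gly.copy())
        np.testing.assert_allclose(y, 0.0)
        assert np.isnan(r)

    def test_full_reversion_anti_identity(self, rng):
        """Mutant expression identical to the glucose baseline makes
        y = -x exactly and r = -1."""
        idx, glu, gly = self.three_vectors(rng)
        x, y, r = dependence_scatter(glu, gly, glu.copy())
        np.testing.assert_allclose(y.to_numpy(), -x.to_numpy(), atol=1e-12)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_partial_reversion_matches_analytic_correlation(self):
        """y = -0.5 x + noise: the generative correlation is
        -0.5 sd(x) / sqrt(0.25 var(x) + var(noise))."""
        rng = np.random.default_rng(99)
        n = 2_000
        idx = pd.Index([f"g{i:04d}" for i in range(n)])
        x = rng.normal(0, 1.0, size=n)
        noise = rng.normal(0, 0.5, size=n)
        y = -0.5 * x + noise
        from chromark.stats import pearson_correlation

        r = pearson_correlation(x, y)
        analytic = -0.5 / np.sqrt(0.25 + 0.25)
        assert r == pytest.approx(analytic, abs=0.1)

    def test_subset_restriction_and_offender_error(self, rng):
        idx, glu, gly = self.three_vectors(rng)
        x, y, r = dependence_scatter(glu, gly, glu.copy(), gene_subset=list(idx[:50]))
        assert len(x) == 50
        with pytest.raises(ValueError, match="ghost"):
            dependence_scatter(glu, gly, glu, gene_subset=["ghost"])
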