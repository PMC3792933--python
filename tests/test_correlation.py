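import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcespect import correlation as corr
from oracles import (mean_ranks, ols_brute, quantile_linear, rank_decile_sizes,
                     spearman_brute)


def make_table(x, y, dataset_id="d"):
    n = len(x)
    return pd.DataFrame({
        "dataset_id": [dataset_id] * n,
        "i": np.arange(n), "j": np.zeros(n, int), "k": np.zeros(n, int),
        corr.SPECT_COLUMN: np.asarray(y, dtype=float),
        "p": np.asarray(x, dtype=float),
    })


class TestBuildVoxelTable:
    def test_row_per_mask_voxel(self, rng):
        mask = np.zeros((10, 10, 1), dtype=bool)
        mask.ravel()[:100] = True
        spect = rng.uniform(size=mask.shape)
        t = corr.build_voxel_table(spect, {"p": rng.uniform(size=mask.shape)},
                                   mask, "d1")
        assert len(t) == 100

    def test_vessel_exclusion_via_mask(self, rng):
        mask = np.ones((4, 4, 1), dtype=bool)
        mask[0, 0, 0] = False  # vessel voxel subtracted upstream
        t = corr.build_voxel_table(np.ones(mask.shape), {}, mask, "d1")
        assert len(t) == 15
        assert not ((t.i == 0) & (t.j == 0)).any()

    def test_gated_zero_retained(self):
        mask = np.ones((3, 1, 1), dtype=bool)
        kt = np.array([[[0.0]], [[0.1]], [[0.2]]])
        t = corr.build_voxel_table(np.ones(mask.shape), {"ktrans": kt}, mask, "d")
        assert (t.ktrans == 0).sum() == 1
        assert len(t) == 3

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            corr.build_voxel_table(np.ones((2, 2, 2)),
                                   {"p": np.ones((3, 2, 2))},
                                   np.ones((2, 2, 2), dtype=bool), "d")


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(0, 3, 30)
        rho, p = corr.spearman(make_table(x, np.exp(x)), "p")
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_antitone_gives_minus_one(self):
        x = np.arange(15.0)
        rho, _ = corr.spearman(make_table(x, -x), "p")
        assert rho == pytest.approx(-1.0)

    def test_tied_table_matches_brute_force(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 1.5, 2.5, 0.5, 3.5])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 2.5, 1.5, 0.5, 3.0])
        rho, _ = corr.spearman(make_table(x, y), "p")
        assert rho == pytest.approx(spearman_brute(x, y), abs=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="'p'"):
            corr.spearman(make_table(np.ones(20), np.arange(20.0)), "p")

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            corr.spearman(make_table(np.arange(5.0), np.arange(5.0)), "p")

    def test_nan_rows_excluded(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30) * 0.1
        x2 = x.copy()
        x2[:5] = np.nan
        rho_full, _ = corr.spearman(make_table(x[5:], y[5:]), "p")
        rho_nan, _ = corr.spearman(make_table(x2, y), "p")
        assert rho_nan == pytest.approx(rho_full, abs=1e-12)


class TestDeciles:
    def test_simple_partition(self):
        t = make_table(np.arange(1.0, 101.0), np.arange(1.0, 101.0))
        d = corr.decile_summary(t, corr.SPECT_COLUMN, "p")
        assert list(d["n"]) == [10] * 10
        assert d["median"][0] == pytest.approx(5.5)

    def test_uneven_sizes_103(self):
        vals = np.random.default_rng(0).permutation(103).astype(float)
        t = make_table(vals, vals)
        d = corr.decile_summary(t, "p", corr.SPECT_COLUMN)
        assert list(d["n"]) == rank_decile_sizes(103)
        assert list(d["n"]) == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]

    def test_constant_summarize(self):
        t = make_table(np.arange(50.0), np.full(50, 4.2))
        d = corr.decile_summary(t, "p", corr.SPECT_COLUMN)
        assert np.allclose(d["median"], 4.2)
        assert np.allclose(d["q1"], 4.2)
        assert np.allclose(d["q3"], 4.2)

    def test_quartiles_match_linear_interpolation_oracle(self, rng):
        vals = rng.normal(size=40)
        t = make_table(np.arange(40.0), vals)
        d = corr.decile_summary(t, "p", corr.SPECT_COLUMN)
        first = vals[np.argsort(np.arange(40.0), kind="stable")][:4]
        assert d["q1"][0] == pytest.approx(quantile_linear(first, 0.25), abs=1e-12)
        assert d["q3"][0] == pytest.approx(quantile_linear(first, 0.75), abs=1e-12)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            corr.decile_indices(np.arange(5.0))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(10, 300), st.integers(0, 10_000))
    def test_bins_partition_rows(self, n, seed):
        vals = np.random.default_rng(seed).integers(0, 20, n).astype(float)
        bins = corr.decile_indices(vals)
        counts = np.bincount(bins, minlength=11)[1:]
        assert counts.sum() == n
        assert list(counts) == rank_decile_sizes(n)

    def test_width_mode(self):
        vals = np.array([0.0, 0.1, 0.2, 5.0, 9.9, 10.0] + [5.0] * 6)
        bins = corr.decile_indices(vals, mode="width")
        assert bins[0] == 1 and bins[5] == 10


class TestPooledRegression:
    def _tables(self, f, n=200, n_ds=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for d in range(n_ds):
            y = rng.uniform(0, 1, n)
            x = f(y) + noise * rng.normal(size=n)
            out.append(make_table(x, y, f"d{d}"))
        return out

    def test_linear_medians_give_r2_one(self):
        tables = self._tables(lambda y: 2.0 * y + 1.0)
        slope, intercept, r2, p = corr.pooled_regression(tables, "p")
        assert r2 == pytest.approx(1.0, abs=0.02)
        assert slope > 0
        assert p < 1e-6

    def test_constant_medians_give_zero_slope(self):
        tables = self._tables(lambda y: np.full_like(y, 3.0))
        slope, intercept, r2, p = corr.pooled_regression(tables, "p")
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_oracle(self):
        tables = self._tables(lambda y: np.sqrt(y), noise=0.05, seed=3)
        slope, intercept, r2, p = corr.pooled_regression(tables, "p")
        _, _, _, _, medians, _ = corr.pooled_regression(
            tables, "p", return_details=True)
        s_o, i_o, r2_o = ols_brute(np.arange(1, 11), medians)
        assert slope == pytest.approx(s_o, abs=1e-12)
        assert intercept == pytest.approx(i_o, abs=1e-12)
        assert r2 == pytest.approx(r2_o, abs=1e-12)

    def test_needs_two_datasets(self):
        with pytest.raises(ValueError):
            corr.pooled_regression([make_table(np.arange(20.0),
                                               np.arange(20.0))], "p")

    def test_missing_decile_raises(self):
        t = make_table(np.full(20, np.nan), np.arange(20.0))
        with pytest.raises(ValueError, match="decile"):
            corr.pooled_regression([t, t], "p")


class TestStatisticsOracleSweep:
    """Randomized equivalence against brute-force implementations (1e-12)."""

    def test_spearman_and_quantiles_and_ols(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(12, 200))
            x = rng.integers(0, max(3, n // 3), n).astype(float)  # force ties
            y = x * rng.normal(1, 0.5) + rng.integers(0, 5, n)
            t = make_table(x, y)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = corr.spearman(t, "p")
            assert rho == pytest.approx(spearman_brute(x, y), abs=1e-12)
            d = corr.decile_summary(t, "p", corr.SPECT_COLUMN)
            bins = corr.decile_indices(x)
            for b in range(1, 11):
                yb = y[bins == b]
                assert d["n"][b - 1] == yb.size
                assert d["median"][b - 1] == pytest.approx(
                    quantile_linear(yb, 0.5), abs=1e-12)
                assert d["q1"][b - 1] == pytest.approx(
                    quantile_linear(yb, 0.25), abs=1e-12)
                assert d["q3"][b - 1] == pytest.approx(
                    quantile_linear(yb, 0.75), abs=1e-12)

    def test_spearman_monotone_invariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r1, _ = corr.spearman(make_table(x, y), "p")
        r2, _ = corr.spearman(make_table(np.exp(x), y), "p")
        r3, _ = corr.spearman(make_table(x, np.exp(y / 4)), "p")
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-12)
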