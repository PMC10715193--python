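import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogscale import FitInput, bin_points, make_fit_input, ols_fit
from cogscale.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    ValidationError,
)


def normal_equations(x, y):
    """Closed-form least squares, kept independent of ols_fit."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestOlsFit:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = ols_fit(FitInput(x=x, y=0.5 * x + 0.3))
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(0.3, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.slope_ci95 == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_solution(self):
        """(0,0),(1,1),(2,1): slope 1/2, intercept 1/6, rss 1/6."""
        fit = ols_fit(FitInput(x=[0, 1, 2], y=[0, 1, 1]))
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(1 / 6)
        assert fit.rss == pytest.approx(1 / 6)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(0, 2, n)
        if np.ptp(x) == 0:
            x[0] += 1.0
        y = rng.normal(0, 2, n)
        fit = ols_fit(FitInput(x=x, y=y))
        slope, intercept = normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_constant_x_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            ols_fit(FitInput(x=[1.0, 1.0, 1.0], y=[0.0, 1.0, 2.0]))

    def test_scale_invariance_of_slope(self, rng):
        x = rng.uniform(2, 5, 50)
        y = 1.2 * x - 0.5 + rng.normal(0, 0.1, 50)
        base = ols_fit(FitInput(x=x, y=y))
        # multiplying raw counts by 10 adds 1 to log10 y
        shifted = ols_fit(FitInput(x=x, y=y + 1.0))
        assert shifted.slope == pytest.approx(base.slope, abs=1e-12)
        assert shifted.intercept == pytest.approx(base.intercept + 1.0, abs=1e-10)

    def test_ci_uses_t_quantile(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 3, 10)
        y = x + rng.normal(0, 0.2, 10)
        fit = ols_fit(FitInput(x=x, y=y))
        tq = stats.t.ppf(0.975, df=8)
        assert fit.slope_ci95 == pytest.approx(tq * fit.slope_se)


class TestMakeFitInput:
    def test_log10_transform_and_zero_drop(self, het_matrix):
        matrix, _ = het_matrix
        inp = make_fit_input(matrix, "J")
        nonzero = matrix.counts["J"] > 0
        assert inp.n == int(nonzero.sum())
        assert inp.n_dropped_zero == int((~nonzero).sum())
        np.testing.assert_allclose(
            np.sort(inp.x), np.sort(np.log10(matrix.total[nonzero].to_numpy()))
        )

    def test_explicit_log_values(self, taxon_map):
        from cogscale.annotations import CategoryCountMatrix

        counts = pd.DataFrame(
            {"K": [10, 100, 5], "J": [990, 9900, 5]},
            index=pd.Index(["org1", "org2", "org3"]),
        )
        m = CategoryCountMatrix(counts=counts, taxon=taxon_map)
        inp = make_fit_input(m, "K")
        assert inp.x[0] == pytest.approx(3.0)
        assert inp.y[:2] == pytest.approx([1.0, 2.0])

    def test_pseudocount_keeps_zeros(self, het_matrix):
        matrix, _ = het_matrix
        inp = make_fit_input(matrix, "J", zero_policy="pseudocount")
        assert inp.n_dropped_zero == 0
        assert inp.n == len(matrix.organisms)

    def test_insufficient_points_error(self, tiny_matrix):
        with pytest.raises(InsufficientDataError):
            make_fit_input(tiny_matrix, "J")  # only one organism has J

    def test_unknown_category(self, tiny_matrix):
        with pytest.raises(ValidationError):
            make_fit_input(tiny_matrix, "Z")


class TestBinning:
    def test_collinear_points_unchanged_slope(self, rng):
        x = rng.uniform(0, 5, 200)
        inp = FitInput(x=x, y=2.0 * x + 1.0)
        binned = bin_points(inp, n_bins=10)
        fit = ols_fit(binned)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)

    def test_binning_counterweights_oversampled_region(self, rng):
        # mid-range points carry a systematic offset and dominate by number
        x_true = np.linspace(0, 5, 40)
        x_biased = rng.uniform(2.2, 2.8, 400)
        x = np.concatenate([x_true, x_biased])
        y = 1.0 * x + np.where((x > 2.2) & (x < 2.8), 0.5, 0.0)
        inp = FitInput(x=x, y=y)
        raw = ols_fit(inp)
        binned = ols_fit(bin_points(inp, n_bins=20))
        assert abs(binned.slope - 1.0) < abs(raw.slope - 1.0)

    def test_binned_close_to_unbinned_on_well_sampled_data(self, het_matrix):
        matrix, _ = het_matrix
        inp = make_fit_input(matrix, "E")
        raw = ols_fit(inp)
        binned = ols_fit(bin_points(inp, n_bins=20))
        assert abs(binned.slope - raw.slope) < 2 * raw.slope_ci95

    def test_single_occupied_bin_insufficient(self):
        x = np.full(20, 1.0)
        x[0] = 1.001  # tiny span: everything lands in <3 bins
        with pytest.raises(InsufficientDataError):
            bin_points(FitInput(x=x, y=np.ones(20)), n_bins=3)
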