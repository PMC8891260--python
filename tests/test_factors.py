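"""Factor distributions and quasi-random scenario generation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import triang

from vaxtea import (
    ParameterError,
    build_scenarios,
    central_scenario,
    sobol_points,
    triangular_inverse_cdf,
    uniform_inverse_cdf,
)


class TestInverseCdfs:
    @pytest.mark.parametrize(
        "low,mode,high,u,expected",
        [
            (1000, 2000, 20000, 0.0, 1000.0),  # lower bound
            (1000, 2000, 20000, 1.0, 20000.0),  # upper bound
            (3, 5, 7, 0.5, 5.0),  # symmetric: median = mode
            (1000, 2000, 20000, 0.5, 6923.3),  # analytic right-branch quantile
        ],
    )
    def test_triangular_quantiles(self, low, mode, high, u, expected):
        assert triangular_inverse_cdf(low, mode, high, u) == pytest.approx(
            expected, rel=1e-4
        )

    def test_triangular_matches_scipy(self):
        """Independent cross-check against scipy's triangular distribution."""
        low, mode, high = 2.0, 30.0, 200.0
        u = np.linspace(0, 1, 101)
        ours = triangular_inverse_cdf(low, mode, high, u)
        ref = triang.ppf(u, c=(mode - low) / (high - low), loc=low, scale=high - low)
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    @pytest.mark.parametrize("u,expected", [(0, 0.0), (1, 15.0), (0.5, 7.5)])
    def test_uniform_quantiles(self, u, expected):
        assert uniform_inverse_cdf(0, 15, u) == expected

    def test_uniform_midpoint(self):
        assert uniform_inverse_cdf(30, 80, 0.5) == 55.0

    @pytest.mark.parametrize(
        "call",
        [
            lambda: triangular_inverse_cdf(5, 2, 4, 0.5),  # mode below low
            lambda: triangular_inverse_cdf(5, 5, 5, 0.5),  # degenerate support
            lambda: uniform_inverse_cdf(7, 7, 0.5),
            lambda: triangular_inverse_cdf(0, 1, 2, 1.5),  # u out of range
        ],
    )
    def test_invalid_parameters_raise(self, call):
        with pytest.raises(ParameterError):
            call()

    @given(
        st.floats(0, 1),
        st.floats(0, 1),
        st.floats(-100, 100),
        st.floats(0.01, 100),
        st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=200)
    def test_triangular_monotone_and_bounded(self, u1, u2, low, width, mode_frac):
        high = low + width
        mode = low + mode_frac * width
        x1 = triangular_inverse_cdf(low, mode, high, u1)
        x2 = triangular_inverse_cdf(low, mode, high, u2)
        tol = 1e-9 * (high - low)  # float cancellation near the bounds
        assert low - tol <= x1 <= high + tol
        if u1 <= u2:
            assert x1 <= x2 + tol


class TestSobolPoints:
    def test_unit_cube_range(self):
        pts = sobol_points(500, 7)
        assert pts.shape == (500, 7)
        assert pts.min() >= 0 and pts.max() < 1

    def test_uniformity_of_mean(self):
        pts = sobol_points(2**10, 1)
        assert abs(pts.mean() - 0.5) < 0.01

    def test_beats_pseudorandom_discrepancy(self):
        """Per-axis max ECDF deviation of the Sobol set should beat a
        pseudo-random set of equal size on nearly every axis."""
        n, d = 2**12, 7
        sob = sobol_points(n, d)
        rng = np.random.default_rng(123)
        psr = rng.random((n, d))

        def axis_disc(x):
            xs = np.sort(x, axis=0)
            grid = (np.arange(1, n + 1) / n)[:, None]
            return np.abs(xs - grid).max(axis=0)

        wins = (axis_disc(sob) < axis_disc(psr)).sum()
        assert wins >= 6

    def test_deterministic_given_metadata(self):
        a = sobol_points(100, 5, skip=1)
        b = sobol_points(100, 5, skip=1)
        np.testing.assert_array_equal(a, b)
        s1 = sobol_points(100, 5, scramble=True, seed=9)
        s2 = sobol_points(100, 5, scramble=True, seed=9)
        np.testing.assert_array_equal(s1, s2)


class TestBuildScenarios:
    def test_forced_central_point_quantiles(self, cfg):
        """u = 0.5 everywhere hits the mode of the symmetric titre triangle
        and the analytic median of the left-skewed labour triangle."""
        fs = cfg.platform("mrna").factor_set
        scen = build_scenarios(fs, 1, u=np.full((1, fs.dimension), 0.5))
        row = scen.values.iloc[0]
        assert row["titre"] == pytest.approx(5.0)
        # tri(5, 23, 30): median = 5 + sqrt(0.5 * 25 * 18) = 20
        assert row["labour_rate"] == pytest.approx(20.0)

    def test_avv_has_no_cap_price_factor(self, cfg):
        fs = cfg.platform("avv").factor_set
        assert fs.dimension == 6
        assert "cap_price" not in fs.names
        assert cfg.platform("mrna").factor_set.dimension == 7

    def test_design_is_reproducible(self, cfg):
        fs = cfg.platform("sarna").factor_set
        a = build_scenarios(fs, 256, scramble=True, seed=4)
        b = build_scenarios(fs, 256, scramble=True, seed=4)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_all_samples_respect_factor_bounds(self, cfg, designs):
        for platform, scen in designs.items():
            for f in cfg.platform(platform).factor_set.factors:
                col = scen.values[f.name]
                assert col.min() >= f.low and col.max() <= f.high

    def test_central_scenario_is_baseline(self, cfg):
        base = central_scenario(cfg.platform("avv").factor_set).iloc[0]
        assert base["scale"] == 2000.0
        assert base["failure_pct"] == 7.5
        assert base["qc_pct"] == 55.0

    def test_csv_roundtrip_preserves_design(self, cfg, tmp_path):
        fs = cfg.platform("mrna").factor_set
        scen = build_scenarios(fs, 64, scramble=True, seed=2)
        path = tmp_path / "design.csv"
        scen.to_csv(path)
        back = type(scen).from_csv(path)
        assert back.platform == "mrna"
        assert back.metadata["sequence"] == "sobol"
        np.testing.assert_allclose(back.values.to_numpy(), scen.values.to_numpy())


class TestSamplingMoments:
    def test_triangular_mean_and_median_converge(self):
        low, mode, high = 1000.0, 2000.0, 20000.0
        n = 100_000
        u = sobol_points(n, 1).ravel()
        x = triangular_inverse_cdf(low, mode, high, u)
        mean_exact = (low + mode + high) / 3
        var_exact = (
            low**2 + mode**2 + high**2 - low * mode - low * high - mode * high
        ) / 18
        se = np.sqrt(var_exact / n)
        assert abs(x.mean() - mean_exact) < 3 * se
        assert np.median(x) == pytest.approx(6923.3, rel=2e-3)
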