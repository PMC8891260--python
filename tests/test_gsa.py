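"""Variance-based sensitivity analysis: estimators, metamodel, rankings."""

import numpy as np
import pytest

from vaxtea import (
    ParameterError,
    additivity_gap,
    fit_rshdmr,
    load_config,
    saltelli_design,
    sobol_indices,
)
from vaxtea.factors import sobol_points
from vaxtea.kpis import compute_kpis
from vaxtea.reporting import run_gsa

# Ishigami benchmark (a=7, b=0.1): closed-form variance decomposition
ISHIGAMI_A, ISHIGAMI_B = 7.0, 0.1
_V1 = 0.5 * (1 + ISHIGAMI_B * np.pi**4 / 5) ** 2
_V2 = ISHIGAMI_A**2 / 8
_V13 = 8 * ISHIGAMI_B**2 * np.pi**8 / 225
_V = _V1 + _V2 + _V13
ISHIGAMI_SI = np.array([_V1 / _V, _V2 / _V, 0.0])
ISHIGAMI_ST = np.array([(_V1 + _V13) / _V, _V2 / _V, _V13 / _V])


def ishigami(u: np.ndarray) -> np.ndarray:
    x = -np.pi + 2 * np.pi * u
    return (
        np.sin(x[:, 0])
        + ISHIGAMI_A * np.sin(x[:, 1]) ** 2
        + ISHIGAMI_B * x[:, 2] ** 4 * np.sin(x[:, 0])
    )


def _estimate(func, n, d, seed=5, n_boot=500):
    design = saltelli_design(n, d, scramble=True, seed=seed)
    ya, yb = func(design.a), func(design.b)
    yab = np.vstack([func(m) for m in design.ab])
    return sobol_indices(ya, yb, yab, n_boot=n_boot, seed=0)


class TestDesign:
    def test_evaluation_count(self):
        design = saltelli_design(8, 3)
        assert design.n_evaluations == 8 * 5
        assert design.all_points().shape == (40, 3)

    def test_cross_block_construction(self):
        design = saltelli_design(16, 4, scramble=True, seed=1)
        for i, m in enumerate(design.ab):
            np.testing.assert_array_equal(m[:, i], design.b[:, i])
            other = [j for j in range(4) if j != i]
            np.testing.assert_array_equal(m[:, other], design.a[:, other])

    def test_blocks_come_from_disjoint_columns_of_one_stream(self):
        design = saltelli_design(32, 2)
        joint = sobol_points(32, 4, skip=1)
        np.testing.assert_array_equal(design.a, joint[:, :2])
        np.testing.assert_array_equal(design.b, joint[:, 2:])


class TestSobolIndices:
    def test_additive_linear_model(self):
        """Y = X1 + 2 X2 on U(0,1)^2: variances 1/12 and 4/12."""
        res = _estimate(lambda u: u[:, 0] + 2 * u[:, 1], 2**12, 2)
        np.testing.assert_allclose(res.si, [0.2, 0.8], atol=0.01)
        np.testing.assert_allclose(res.st, res.si, atol=0.01)

    def test_ishigami_matches_closed_form(self):
        res = _estimate(ishigami, 2**13, 3)
        assert np.all(np.abs(res.si - ISHIGAMI_SI) <= 3 * res.si_se)
        assert np.all(np.abs(res.st - ISHIGAMI_ST) <= 3 * res.st_se)

    def test_constant_output_flagged(self):
        n = 64
        res = sobol_indices(np.ones(n), np.ones(n), np.ones((3, n)))
        assert not res.defined
        assert np.isnan(res.si).all()

    def test_estimates_stable_when_doubling_n(self):
        r1 = _estimate(ishigami, 2**11, 3, seed=2)
        r2 = _estimate(ishigami, 2**12, 3, seed=2)
        width = r1.si_ci[:, 1] - r1.si_ci[:, 0]
        assert np.all(np.abs(r1.si - r2.si) < width)

    def test_negative_estimates_clipped_only_for_display(self):
        res = _estimate(ishigami, 2**10, 3, seed=8, n_boot=50)
        frame = res.to_frame(clip_negative=True)
        assert (frame["Si"] >= 0).all()
        # raw estimate of the interaction-only factor may legitimately be < 0
        assert res.si[2] == pytest.approx(0.0, abs=0.05)


class TestAdditivityGap:
    def test_additive_model_has_no_gap(self):
        res = _estimate(lambda u: u[:, 0] + 2 * u[:, 1], 2**12, 2)
        assert np.all(np.abs(additivity_gap(res)) < 0.01)

    def test_ishigami_interaction_factor_gap(self):
        res = _estimate(ishigami, 2**13, 3)
        gap = additivity_gap(res)
        assert gap[2] == pytest.approx(_V13 / _V, abs=0.02)

    def test_technoeconomic_model_is_nearly_additive(self, cfg):
        """Interactions between input factors on the KPIs are minor."""
        res = run_gsa("avv", cfg, n_base=1024, seed=3, n_boot=50)
        for kpi, r in res.items():
            assert additivity_gap(r).max() < 0.15, kpi


class TestRshdmr:
    def test_recovers_additive_polynomial_indices(self):
        x = sobol_points(4096, 3, scramble=True, seed=4)
        y = x[:, 0] + 2 * x[:, 1] ** 2 + 0.5
        fit = fit_rshdmr(x, y, max_order=3)
        direct = _estimate(lambda u: u[:, 0] + 2 * u[:, 1] ** 2 + 0.5, 2**12, 3)
        np.testing.assert_allclose(fit.si, direct.si, atol=0.02)

    def test_constant_term_is_sample_mean(self):
        rng = np.random.default_rng(1)
        x = rng.random((2000, 2))
        y = 3 * x[:, 0] - x[:, 1] + 7
        fit = fit_rshdmr(x, y, max_order=2)
        assert fit.f0 == pytest.approx(y.mean(), rel=1e-2)

    def test_too_few_scenarios_rejected(self):
        x = np.random.default_rng(2).random((50, 7))
        with pytest.raises(ParameterError):
            fit_rshdmr(x, x[:, 0], max_order=3)

    def test_surrogate_quality_on_held_out_scenarios(self, cfg):
        """The metamodel predicts unseen doses/yr scenarios with R^2 >= 0.9
        (the reciprocal dose dependence needs the richer 5th-order basis
        with pairwise terms)."""
        pcfg = cfg.platform("mrna")
        u_fit = sobol_points(10_000, 7, scramble=True, seed=11)
        u_val = sobol_points(1250, 7, scramble=True, seed=12)
        y_fit = compute_kpis(pcfg.factor_set.transform(u_fit), pcfg)["doses_per_year"]
        y_val = compute_kpis(pcfg.factor_set.transform(u_val), pcfg)["doses_per_year"]
        fit = fit_rshdmr(u_fit, y_fit.to_numpy(), max_order=5, include_pairs=True)
        assert fit.validate(u_val, y_val.to_numpy()) >= 0.9


class TestFactorRankings:
    def test_avv_output_driven_by_scale_then_titre_then_dose(self, cfg):
        res = run_gsa("avv", cfg, n_base=2048, seed=2, n_boot=50,
                      kpi_columns=["doses_per_year"])["doses_per_year"]
        si = dict(zip(cfg.platform("avv").factor_set.names, res.si))
        assert si["scale"] >= si["titre"] >= si["dose_amount"]
        assert si["dose_amount"] > si["labour_rate"]

    @pytest.mark.parametrize("platform", ["mrna", "sarna"])
    def test_rna_output_driven_by_dose_then_scale(self, cfg, platform):
        res = run_gsa(platform, cfg, n_base=2048, seed=2, n_boot=50,
                      kpi_columns=["doses_per_year"])["doses_per_year"]
        si = dict(zip(cfg.platform(platform).factor_set.names, res.si))
        assert si["dose_amount"] >= si["scale"]
        assert si["scale"] > si["labour_rate"]
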