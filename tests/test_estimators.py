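"""MR estimators against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from medmr import (
    HarmonizedSet,
    SimConfig,
    bwmr,
    cochran_q,
    harmonize,
    ivw,
    mr_egger,
    run_methods,
    simulate_three_trait_gwas,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from medmr.estimators import _weighted_median, _mode_bandwidth
from medmr.exceptions import (
    DegenerateDesignError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)

from conftest import make_harmonized


def _hs(gamma, Gamma, sy, sx=0.01):
    n = len(gamma)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(1, n + 1)],
            "gamma_hat": gamma,
            "sigma_x": np.broadcast_to(sx, n).astype(float),
            "Gamma_hat": Gamma,
            "sigma_y": np.broadcast_to(sy, n).astype(float),
        }
    )
    return HarmonizedSet("exp", "out", df)


class TestWald:
    def test_ratio_arithmetic(self):
        est = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.5, 0.01, 0.0, 0.02).beta == 0.0

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        hs = _hs([0.5], [0.1], [0.02])
        est = ivw(hs)
        ref = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_two_snp_closed_form(self):
        hs = _hs([1.0, 1.0], [0.2, 0.2], [0.02, 0.02])
        est = ivw(hs, mode="fixed")
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.02 / np.sqrt(2))

    def test_matches_wls_oracle(self, clean_harmonized):
        g, _, G, sy = clean_harmonized.arrays()
        res = sm.WLS(G, g[:, None], weights=1 / sy**2).fit()
        est = ivw(clean_harmonized, mode="fixed")
        assert est.beta == pytest.approx(res.params[0], abs=1e-10)
        # statsmodels scales the covariance by the residual variance;
        # the fixed-effect SE corresponds to unit scale
        se_unit = res.bse[0] / np.sqrt(res.scale)
        assert est.se == pytest.approx(se_unit, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, clean_harmonized):
        fx = ivw(clean_harmonized, mode="fixed")
        mr = ivw(clean_harmonized, mode="multiplicative_random")
        assert mr.beta == fx.beta
        assert mr.se >= fx.se


class TestEgger:
    def test_noiseless_line_recovered(self):
        g = np.array([0.1, 0.2, 0.4])
        hs = _hs(g, 0.05 + 0.3 * g, [0.02] * 3)
        est = mr_egger(hs)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.aux["egger_intercept"] == pytest.approx(0.05, abs=1e-12)
        assert est.aux["residual_sd"] == pytest.approx(0.0, abs=1e-6)

    def test_collinear_design_errors(self):
        hs = _hs([0.2, 0.2, 0.2], [0.1, 0.1, 0.1], [0.02] * 3)
        with pytest.raises(DegenerateDesignError):
            mr_egger(hs)

    def test_too_few_instruments(self):
        hs = _hs([0.1, 0.2], [0.02, 0.04], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hs)

    def test_matches_wls_oracle(self, clean_harmonized):
        g, _, G, sy = clean_harmonized.arrays()
        sign = np.where(g < 0, -1.0, 1.0)  # Egger's gamma>=0 orientation
        g, G = g * sign, G * sign
        res = sm.WLS(G, sm.add_constant(g), weights=1 / sy**2).fit()
        est = mr_egger(clean_harmonized)
        assert est.beta == pytest.approx(res.params[1], abs=1e-10)
        assert est.aux["egger_intercept"] == pytest.approx(res.params[0], abs=1e-10)
        scale = max(1.0, res.scale)
        np.testing.assert_allclose(
            [est.aux["egger_intercept_se"], est.se],
            res.bse / np.sqrt(res.scale) * np.sqrt(scale),
            atol=1e-10,
        )

    def test_invariant_to_per_snp_sign_flips(self, clean_harmonized):
        ref = mr_egger(clean_harmonized)
        df = clean_harmonized.df.copy()
        rng = np.random.default_rng(0)
        flip = np.where(rng.random(len(df)) < 0.5, -1.0, 1.0)
        df["gamma_hat"] *= flip
        df["Gamma_hat"] *= flip
        flipped = mr_egger(HarmonizedSet("exp", "out", df))
        assert flipped.beta == pytest.approx(ref.beta)
        assert flipped.aux["egger_intercept"] == pytest.approx(ref.aux["egger_intercept"])


class TestWeightedMedian:
    def test_equal_weight_odd_count(self):
        assert _weighted_median(np.array([0.1, 0.2, 0.9]), np.ones(3)) == pytest.approx(0.2)

    def test_two_values_interpolate(self):
        assert _weighted_median(np.array([0.1, 0.3]), np.ones(2)) == pytest.approx(0.2)

    def test_heavy_weight_dominates(self):
        est = _weighted_median(np.array([0.1, 0.5]), np.array([10.0, 0.1]))
        assert est < 0.15

    def test_estimator_on_clean_data(self, clean_harmonized):
        est = weighted_median(clean_harmonized, n_boot=200, seed=1)
        assert est.beta == pytest.approx(-0.11, abs=0.05)
        assert est.se > 0


class TestWeightedMode:
    def test_dominant_cluster(self):
        ratios = np.array([0.2, 0.2, 0.2, 0.8])
        g = np.ones(4)
        hs = _hs(g, ratios, [0.02] * 4)
        h = _mode_bandwidth(ratios, 1.0)
        est = weighted_mode(hs, n_boot=50, seed=0)
        assert abs(est.beta - 0.2) <= h

    def test_degenerate_bandwidth_returns_common_ratio(self):
        hs = _hs([0.1, 0.2, 0.4], [0.04, 0.08, 0.16], [0.02] * 3)
        est = weighted_mode(hs)
        assert est.beta == pytest.approx(0.4)
        fixed_se = 1.0 / np.sqrt(np.sum(np.array([0.1, 0.2, 0.4]) ** 2) / 0.02**2)
        assert est.se == pytest.approx(fixed_se)

    def test_argmax_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(5)
        n = 40
        g = rng.uniform(0.05, 0.3, n)
        G = -0.1 * g + rng.normal(0, 0.02, n)
        hs = _hs(g, G, [0.02] * n)
        est = weighted_mode(hs, n_boot=10, seed=0)

        ratios = G / g
        sx, sy = 0.01, 0.02
        w = 1.0 / (sy**2 / g**2 + G**2 * sx**2 / g**4)
        h = est.aux["bandwidth"]
        fine = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 100_000)
        dens = np.sum(
            w[:, None] * np.exp(-0.5 * ((fine[None, :] - ratios[:, None]) / h) ** 2),
            axis=0,
        )
        oracle = fine[np.argmax(dens)]
        coarse_step = (ratios.max() - ratios.min() + 6 * h) / 511
        assert abs(est.beta - oracle) <= coarse_step


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        hs = _hs([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], [0.02] * 3)
        q, p = cochran_q(hs, 0.2)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_two_snp_hand_computation(self):
        # ratios 0.1 and 0.3 with equal information gamma^2/sigma_y^2 = 25
        hs = _hs([1.0, 1.0], [0.1, 0.3], [0.2, 0.2])
        beta = ivw(hs, mode="fixed").beta
        assert beta == pytest.approx(0.2)
        q, _ = cochran_q(hs, beta)
        expected = 25 * (0.1 - 0.2) ** 2 + 25 * (0.3 - 0.2) ** 2
        assert q == pytest.approx(expected)


class TestBWMR:
    def test_null_components_reduce_to_fixed_ivw(self, clean_harmonized):
        fx = ivw(clean_harmonized, mode="fixed")
        est = bwmr(clean_harmonized, fix_null=True)
        assert est.beta == pytest.approx(fx.beta, abs=1e-8)
        assert est.se == pytest.approx(fx.se, abs=1e-8)

    def test_downweights_gross_outlier(self):
        cfg = SimConfig(
            seed=8, palindromic_frac=0.0, n_mediator_instruments=0,
            outlier_ids_and_shifts={"rs5": 10.0},
        )
        x, _, y, _, truth = simulate_three_trait_gwas(cfg)
        hs = harmonize(x, y, truth.instrument_ids)
        est = bwmr(hs)
        w = est.aux["weights"][hs.snp_ids.index("rs5")]
        assert w < 0.1
        ivw_with = ivw(hs, mode="fixed").beta
        ivw_without = ivw(hs.drop_snps(["rs5"]), mode="fixed").beta
        assert abs(est.beta - ivw_without) < abs(est.beta - ivw_with)

    def test_agrees_with_ivw_on_clean_data(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, palindromic_frac=0.0, n_mediator_instruments=0)
            x, _, y, _, truth = simulate_three_trait_gwas(cfg)
            hs = harmonize(x, y, truth.instrument_ids)
            iv = ivw(hs)
            hits += abs(bwmr(hs).beta - iv.beta) < 0.5 * iv.se
        assert hits >= 18


class TestEquivariance:
    @given(k=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    def test_scale_equivariance(self, k, seed):
        hs = make_harmonized(n=12, seed=seed)
        scaled = HarmonizedSet(
            "exp", "out",
            hs.df.assign(Gamma_hat=hs.df["Gamma_hat"] * k, sigma_y=hs.df["sigma_y"] * k),
        )
        for fn in (lambda h: ivw(h), lambda h: mr_egger(h)):
            a, b = fn(hs), fn(scaled)
            assert b.beta == pytest.approx(k * a.beta, rel=1e-9)
            assert b.se == pytest.approx(k * a.se, rel=1e-9)

    @given(seed=st.integers(0, 100))
    def test_sign_equivariance(self, seed):
        hs = make_harmonized(n=12, seed=seed)
        negated = HarmonizedSet("exp", "out", hs.df.assign(Gamma_hat=-hs.df["Gamma_hat"]))
        for fn in (
            lambda h: ivw(h),
            lambda h: mr_egger(h),
            lambda h: weighted_median(h, n_boot=20, seed=0),
        ):
            assert fn(negated).beta == pytest.approx(-fn(hs).beta, rel=1e-9, abs=1e-12)


def test_run_methods_single_snp_falls_back_to_wald():
    hs = _hs([0.5], [0.1], [0.02])
    out = run_methods(hs, ["ivw", "egger"])
    assert list(out) == ["wald"]
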