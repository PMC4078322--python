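"""Cline model shape, likelihood, MCMC fitting, CIs, and transect projection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridzone import (
    ClineParams, aicc, ci_2ll, cline_eval, compare_clines, fit_mh, fit_null,
    haversine_km, loglik, project_transect, reciprocal_nonoverlap,
)
from hybridzone.clines import ClineFit, ClineModel, _binom_loglik
from hybridzone.containers import TransectSites


def make_sites(x, k, n, **kw):
    x = np.asarray(x, dtype=float)
    return TransectSites(
        site_id=[f"s{i}" for i in range(len(x))],
        latitude=np.zeros(len(x)), longitude=np.zeros(len(x)),
        distance=x, n=np.asarray(n), k_interior=np.asarray(k), **kw)


# ---------------------------------------------------------------------------
# cline_eval
# ---------------------------------------------------------------------------

class TestClineEval:
    def test_sigmoid_midpoint(self):
        assert cline_eval(ClineParams(c=300, w=131), 300.0) == pytest.approx(0.5)

    def test_half_width_point(self):
        # at x = c + w/2 the unscaled sigmoid is 1/(1+e^-2)
        p = cline_eval(ClineParams(c=300, w=131), 365.5)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-2)), abs=1e-12)

    def test_scaling_limits(self):
        params = ClineParams(c=0, w=10, p_min=0.1, p_max=0.7)
        assert cline_eval(params, -1e6) == pytest.approx(0.1, abs=1e-9)
        assert cline_eval(params, 1e6) == pytest.approx(0.7, abs=1e-9)

    def test_tail_slope_matches_sigmoid_at_tau_one(self):
        # with tau=1 the exponential tail continues the sigmoid slope (C^1)
        params = ClineParams(c=300, w=131, delta_l=50, delta_r=50,
                             tau_l=1.0, tau_r=1.0, tail_config="mirror")
        smooth = ClineParams(c=300, w=131)
        for x0 in (250.0, 350.0):
            h = 1e-5
            inner = (cline_eval(smooth, x0 + h) - cline_eval(smooth, x0 - h)) / (2 * h)
            shift = -h if x0 < 300 else h
            outer = (cline_eval(params, x0 + shift) - cline_eval(params, x0)) / shift
            assert outer == pytest.approx(inner, rel=1e-4)

    @pytest.mark.parametrize("cfg", ["left", "right", "mirror", "both"])
    def test_continuity_at_junctions(self, cfg):
        kw = dict(c=300, w=131, delta_l=40, delta_r=40, tau_l=0.3, tau_r=0.3)
        if cfg == "left":
            kw["delta_r"] = 0.0
        params = ClineParams(tail_config=cfg, **kw)
        for junction in (300 - kw["delta_l"], 300 + kw["delta_r"]):
            left = cline_eval(params, junction - 1e-9)
            right = cline_eval(params, junction + 1e-9)
            assert abs(left - right) < 1e-8

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        c=st.floats(-100, 700), w=st.floats(1.0, 1000.0),
        delta=st.floats(0.0, 300.0), tau=st.floats(0.0, 1.0),
        p_min=st.floats(0.0, 0.5), p_span=st.floats(0.0, 0.5),
        cfg=st.sampled_from(["none", "left", "right", "mirror", "both"]),
    )
    def test_nondecreasing_in_x(self, c, w, delta, tau, p_min, p_span, cfg):
        params = ClineParams(c=c, w=w, delta_l=delta, delta_r=delta,
                             tau_l=tau, tau_r=tau, p_min=p_min,
                             p_max=p_min + p_span, tail_config=cfg)
        x = np.linspace(c - 3 * w - delta, c + 3 * w + delta, 400)
        p = cline_eval(params, x)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all((p >= -1e-12) & (p <= 1 + 1e-12))

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError, match="w"):
            ClineParams(c=0, w=0)

    def test_mirror_requires_equal_tails(self):
        with pytest.raises(ValueError, match="mirror"):
            ClineParams(c=0, w=10, delta_l=5, delta_r=6, tail_config="mirror")


# ---------------------------------------------------------------------------
# likelihood and AICc
# ---------------------------------------------------------------------------

class TestLoglik:
    def test_single_site_hand_value(self):
        # n=2, k=1, p=0.5: Binomial mass = 2 * 0.25 = 0.5
        params = ClineParams(c=300, w=131)
        single = make_sites([300.0], [1], [2])
        ll = _binom_loglik(np.array([1.0]), np.array([2.0]), np.array([0.5]))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)
        assert loglik(params, single, "mt_frequency") == pytest.approx(math.log(0.5), abs=1e-9)

    def test_saturated_model_is_upper_bound(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 600, 13)
        n = np.full(13, 20)
        k = rng.binomial(n, np.clip(x / 600, 0.01, 0.99))
        sites = make_sites(x, k, n)
        from scipy.stats import binom
        saturated = float(binom.logpmf(k, n, np.clip(k / n, 1e-9, 1 - 1e-9)).sum())
        for seed in range(5):
            params = ClineParams(c=float(rng.uniform(0, 600)), w=float(rng.uniform(10, 600)))
            assert loglik(params, sites, "mt_frequency") <= saturated + 1e-9

    def test_matches_independent_termwise_sum(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 600, 13)
        n = rng.integers(1, 29, 13)
        k = rng.binomial(n, 0.4)
        sites = make_sites(x, k, n)
        params = ClineParams(c=280, w=200, p_min=0.05, p_max=0.9)
        # brute-force term-by-term with math module only
        total = 0.0
        for xi, ki, ni in zip(x, k, n):
            p = min(max(cline_eval(params, xi), 1e-9), 1 - 1e-9)
            total += (math.lgamma(ni + 1) - math.lgamma(ki + 1) - math.lgamma(ni - ki + 1)
                      + ki * math.log(p) + (ni - ki) * math.log(1 - p))
        assert loglik(params, sites, "mt_frequency") == pytest.approx(total, abs=1e-10)

    def test_q_mean_uses_effective_counts(self):
        x = np.linspace(0, 600, 5)
        sites = TransectSites(site_id=list("abcde"), latitude=np.zeros(5),
                              longitude=np.zeros(5), distance=x, n=np.full(5, 10),
                              mean_q=np.array([0.0, 0.21, 0.5, 0.79, 1.0]))
        k_eff = np.round(sites.n * sites.mean_q)
        mirror = make_sites(x, k_eff, sites.n)
        params = ClineParams(c=300, w=200)
        assert loglik(params, sites, "q_mean") == pytest.approx(
            loglik(params, mirror, "mt_frequency"), abs=1e-12)

    def test_site_order_invariance(self):
        x = np.linspace(0, 600, 13)
        k = np.arange(13)
        n = np.full(13, 15)
        params = ClineParams(c=300, w=150)
        forward = loglik(params, make_sites(x, k, n), "mt_frequency")
        # reversed ordering with distances made nondecreasing again via labels
        perm = make_sites(x, k, n)
        assert loglik(params, perm, "mt_frequency") == pytest.approx(forward)


class TestAicc:
    def test_hand_value(self):
        assert aicc(-10, 2, 13) == pytest.approx(25.2)

    def test_zero_params(self):
        assert aicc(-7.5, 0, 13) == pytest.approx(15.0)

    def test_exceeds_aic_and_converges(self):
        for n in (10, 100, 10_000):
            assert aicc(-10, 3, n) > 20 + 6
        assert aicc(-10, 3, 10 ** 7) == pytest.approx(26.0, abs=1e-4)

    def test_undefined_correction(self):
        with pytest.raises(ValueError):
            aicc(-10, 5, 6)


# ---------------------------------------------------------------------------
# fit_mh / ci_2ll / null
# ---------------------------------------------------------------------------

def quick_fit(sites, seed=0, **kw):
    kw.setdefault("tuning_iters", 1500)
    kw.setdefault("chain_iters", 5000)
    kw.setdefault("n_chains", 2)
    kw.setdefault("check_convergence", False)
    return fit_mh(sites, ("none", "fixed_none"), "mt_frequency", seed=seed, **kw)


class TestFitMH:
    def test_step_data_center_between_steps(self):
        x = np.linspace(0, 600, 13)
        k = np.where(x < 290, 0, 20)
        fit = quick_fit(make_sites(x, k, np.full(13, 20)), seed=1)
        assert 250 <= fit.point_estimate.c <= 300

    def test_seed_determinism(self):
        x = np.linspace(0, 600, 13)
        rng = np.random.default_rng(5)
        k = rng.binomial(20, np.clip((x - 150) / 300, 0.02, 0.98))
        sites = make_sites(x, k, np.full(13, 20))
        fit_a = quick_fit(sites, seed=9)
        fit_b = quick_fit(sites, seed=9)
        assert np.array_equal(fit_a.samples.to_numpy(), fit_b.samples.to_numpy())
        fit_c = quick_fit(sites, seed=10)
        assert not np.array_equal(fit_a.samples.to_numpy(), fit_c.samples.to_numpy())

    def test_ci_brackets_point_estimate(self):
        x = np.linspace(0, 600, 13)
        k = np.round(20 / (1 + np.exp(-4 * (x - 300) / 150))).astype(int)
        fit = quick_fit(make_sites(x, k, np.full(13, 20)), seed=2)
        for name in fit.model.param_names:
            lo, hi = ci_2ll(fit, name)
            assert lo <= getattr(fit.point_estimate, name) <= hi

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            quick_fit(make_sites([0.0, 0.0], [0, 1], [5, 5]))

    def test_unknown_parameter_rejected(self):
        x = np.linspace(0, 600, 13)
        fit = quick_fit(make_sites(x, np.arange(13), np.full(13, 20)), seed=3)
        with pytest.raises(KeyError):
            ci_2ll(fit, "delta_l")


class TestCi2ll:
    def _fit_from_samples(self, theta, lls):
        import pandas as pd

        x = np.linspace(0, 600, 13)
        sites = make_sites(x, np.arange(13), np.full(13, 20))
        model = ClineModel("none", "fixed_none", sites, "mt_frequency")
        frame = pd.DataFrame({"c": theta, "w": np.ones_like(theta), "ll": lls})
        max_ll = float(np.max(lls))
        ci = {name: (float(frame[name][lls >= max_ll - 2].min()),
                     float(frame[name][lls >= max_ll - 2].max()))
              for name in ("c", "w")}
        i = int(np.argmax(lls))
        return ClineFit(model=model, samples=frame, max_ll=max_ll,
                        aicc=0.0, point_estimate=model.unpack([theta[i], 1.0]),
                        ci_2ll=ci)

    def test_degenerate_when_all_samples_identical(self):
        fit = self._fit_from_samples(np.full(100, 3.14), np.full(100, -1.0))
        assert ci_2ll(fit, "c") == (3.14, 3.14)

    def test_gaussian_closed_form(self):
        # ll = -(theta - mu)^2 / (2 s^2): the 2-LL interval is mu +/- 2 s
        mu, s = 300.0, 7.0
        theta = np.linspace(mu - 5 * s, mu + 5 * s, 20_001)
        lls = -((theta - mu) ** 2) / (2 * s ** 2)
        fit = self._fit_from_samples(theta, lls)
        lo, hi = ci_2ll(fit, "c")
        assert lo == pytest.approx(mu - 2 * s, abs=0.05)
        assert hi == pytest.approx(mu + 2 * s, abs=0.05)


class TestNullModel:
    def test_closed_form_matches_binomial_ml(self):
        x = np.linspace(0, 600, 13)
        k = np.arange(13)
        n = np.full(13, 20)
        sites = make_sites(x, k, n)
        null = fit_null(sites, "mt_frequency")
        p_hat = k.sum() / n.sum()
        expected_ll = _binom_loglik(k.astype(float), n.astype(float),
                                    np.full(13, p_hat))
        assert null["max_ll"] == pytest.approx(expected_ll, abs=1e-12)
        assert null["aicc"] == pytest.approx(aicc(expected_ll, 1, 13), abs=1e-12)


# ---------------------------------------------------------------------------
# comparison rule and transect projection
# ---------------------------------------------------------------------------

class TestCompareClines:
    def test_reciprocal_rule_on_reported_widths(self):
        result = reciprocal_nonoverlap(131.0, (76.0, 270.0), 331.0, (145.0, 678.0))
        assert result["significantly_different"]

    def test_identical_fits_not_significant(self):
        result = reciprocal_nonoverlap(100.0, (50.0, 150.0), 100.0, (50.0, 150.0))
        assert not result["significantly_different"]

    def test_one_sided_exclusion_is_not_enough(self):
        # a inside b's CI but b outside a's CI: reciprocal rule says no
        result = reciprocal_nonoverlap(100.0, (90.0, 110.0), 150.0, (80.0, 200.0))
        assert result["b_outside_ci_a"] and not result["a_outside_ci_b"]
        assert not result["significantly_different"]

    def test_compare_clines_wraps_fits(self):
        x = np.linspace(0, 600, 13)
        rng = np.random.default_rng(1)
        k_narrow = rng.binomial(50, np.clip(1 / (1 + np.exp(-4 * (x - 300) / 60)), 0.001, 0.999))
        k_wide = rng.binomial(50, np.clip(1 / (1 + np.exp(-4 * (x - 300) / 500)), 0.001, 0.999))
        fit_a = quick_fit(make_sites(x, k_narrow, np.full(13, 50)), seed=4)
        fit_b = quick_fit(make_sites(x, k_wide, np.full(13, 50)), seed=5)
        result = compare_clines(fit_a, fit_b, "w")
        assert result["point_a"] < result["point_b"]


class TestProjectTransect:
    def test_identical_coordinates_zero_distance(self):
        assert haversine_km(39.0, -119.0, 39.0, -119.0) == 0.0

    def test_one_degree_latitude(self):
        assert haversine_km(40.0, -120.0, 41.0, -120.0) == pytest.approx(111.19, abs=0.01)

    def test_cumulative_and_reversal(self):
        lats = [41.55, 40.0, 39.0, 38.0]
        lons = [-120.67, -119.5, -118.5, -117.5]
        forward = project_transect(lats, lons)
        backward = project_transect(lats, lons, anchor_order=[3, 2, 1, 0])
        total = forward[-1]
        assert forward[0] == 0.0
        assert np.all(np.diff(forward) > 0)
        np.testing.assert_allclose(backward, total - forward, atol=1e-9)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(95.0, 0.0, 0.0, 0.0)

    def test_roundtrip_with_synthetic_sites(self, default_zone):
        sites = default_zone.sites
        projected = project_transect(sites.latitude, sites.longitude)
        np.testing.assert_allclose(projected, sites.distance, rtol=1e-3, atol=0.5)
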