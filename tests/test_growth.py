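"""Growth model: VB curve, log likelihood, priors, posterior summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from elasmodemo import (
    GrowthParams,
    LengthAtAgeRecord,
    VonBertalanffyGrowth,
    log_likelihood,
    make_priors,
    summarize_posterior,
    vb_mean,
)

from conftest import TRUE_GROWTH


@st.composite
def growth_params(draw):
    k = draw(st.floats(0.02, 1.5))
    dw0 = draw(st.floats(50.0, 1500.0))
    dw_inf = dw0 + draw(st.floats(100.0, 4000.0))
    sigma2 = draw(st.floats(1e-4, 0.5))
    return GrowthParams(k=k, dw_inf=dw_inf, dw0=dw0, sigma2=sigma2)


class TestVbMean:
    def test_age_zero_returns_size_at_birth(self):
        p = GrowthParams(k=0.3, dw_inf=2000, dw0=750)
        assert vb_mean(0, p) == pytest.approx(750.0)

    def test_asymptote(self):
        p = GrowthParams(k=0.12, dw_inf=2995, dw0=880)
        assert vb_mean(1000, p) == pytest.approx(2995.0)

    def test_known_value_at_age_five(self):
        # independent hand computation: 2995 - 2115*e^(-0.6)
        p = GrowthParams(k=0.12, dw_inf=2995, dw0=880)
        assert vb_mean(5, p) == pytest.approx(2995 - 2115 * math.exp(-0.6), rel=1e-12)

    def test_rejects_negative_age(self):
        with pytest.raises(ValueError):
            vb_mean(-1, GrowthParams(k=0.1, dw_inf=2000, dw0=800))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(growth_params())
    def test_strictly_increasing_and_bounded(self, p):
        ages = np.arange(51)
        w = vb_mean(ages, p)
        assert np.all(np.diff(w) >= 0)
        assert np.all(w <= p.dw_inf)
        # strictly increasing wherever the exponential has not underflowed
        live = np.exp(-p.k * ages[1:]) > 1e-12
        assert np.all(np.diff(w)[live] > 0)
        assert np.all(w[:-1][live] < p.dw_inf)


class TestGrowthParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k=-0.1, dw_inf=2000, dw0=800),
            dict(k=0.1, dw_inf=700, dw0=800),  # dw_inf <= dw0
            dict(k=0.1, dw_inf=2000, dw0=-5),
            dict(k=0.1, dw_inf=2000, dw0=800, sigma2=0),
            dict(k=0.1, dw_inf=2000, dw0=800, kappa=1.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GrowthParams(**kwargs)


class TestLogLikelihood:
    def test_zero_residual_single_record(self):
        p = GrowthParams(k=0.2, dw_inf=2500, dw0=800, sigma2=0.04)
        rec = LengthAtAgeRecord(3, float(vb_mean(3, p)))
        assert log_likelihood([rec], p) == pytest.approx(
            -0.5 * math.log(2 * math.pi * 0.04), rel=1e-12
        )

    def test_additivity_under_duplication(self):
        p = GrowthParams(k=0.15, dw_inf=2800, dw0=850, sigma2=0.02)
        recs = [LengthAtAgeRecord(a, w) for a, w in [(0, 900), (4, 1700), (9, 2300)]]
        assert log_likelihood(recs * 2, p) == pytest.approx(
            2 * log_likelihood(recs, p), rel=1e-12
        )

    def test_matches_independent_normal_density_sum(self):
        p = GrowthParams(k=0.15, dw_inf=2800, dw0=850, sigma2=0.02)
        recs = [LengthAtAgeRecord(a, w) for a, w in [(1, 1000.0), (5, 1900.0), (12, 2500.0)]]
        expected = sum(
            stats.norm.logpdf(
                math.log(r.disc_width),
                math.log(float(vb_mean(r.age, p))),
                math.sqrt(p.sigma2),
            )
            for r in recs
        )
        assert log_likelihood(recs, p) == pytest.approx(expected, rel=1e-12)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([], TRUE_GROWTH)

    def test_maximised_at_generating_parameters(self):
        """On noise-free data the profile log likelihood peaks at the truth."""
        ages = np.arange(16)
        widths = vb_mean(ages, TRUE_GROWTH)
        recs = [LengthAtAgeRecord(int(a), float(w)) for a, w in zip(ages, widths)]

        def profile_ll(k, dw_inf, dw0):
            p = GrowthParams(k=k, dw_inf=dw_inf, dw0=dw0, sigma2=1.0)
            mu = np.log(vb_mean(ages, p))
            resid = np.log(widths) - mu
            s2 = max(float(np.mean(resid**2)), 1e-300)  # profiled variance
            return log_likelihood(recs, GrowthParams(k=k, dw_inf=dw_inf, dw0=dw0, sigma2=s2))

        truth_ll = profile_ll(TRUE_GROWTH.k, TRUE_GROWTH.dw_inf, TRUE_GROWTH.dw0)
        for k in (0.08, 0.12, 0.18):
            for dw_inf in (2800.0, 3000.0, 3300.0):
                for dw0 in (800.0, 900.0, 1000.0):
                    if (k, dw_inf, dw0) == (0.12, 3000.0, 900.0):
                        continue
                    assert profile_ll(k, dw_inf, dw0) < truth_ll


class TestPriors:
    def test_strong_kappa_hyperprior_mean(self):
        spec = make_priors("strong")
        assert spec.entries["kappa"].mean == pytest.approx(1000 / 990)
        assert spec.entries["kappa"].mean == pytest.approx(1.01, abs=1e-3)

    def test_uninformative_entries_are_bounded_uniforms(self):
        spec = make_priors("uninformative")
        assert spec.entries["k"] .dist == "uniform" and spec.entries["k"].params == (0.0, 2.0)
        assert spec.entries["dw_inf"].params == (0.0, 4000.0)
        assert spec.entries["dw0"].params == (0.0, 2000.0)
        assert spec.entries["kappa"].params == (0.7, 1.3)
        assert spec.entries["sigma2"].dist == "half_cauchy"

    def test_weaker_preset_widens_not_recentres(self):
        strong, weaker = make_priors("strong"), make_priors("weaker")
        assert weaker.entries["dw0"].params == (880.0, 300.0)
        assert strong.entries["dw0"].params == (880.0, 200.0)
        assert weaker.entries["kappa"].mean == pytest.approx(200 / 198)

    @pytest.mark.parametrize("bad", ["Strong ", "flat", "", "STRONG"])
    def test_unknown_preset_rejected(self, bad):
        with pytest.raises(ValueError):
            make_priors(bad)

    def test_log_prior_is_minus_inf_outside_support(self):
        spec = make_priors("strong")
        inside = np.array([0.12, 3000.0, 900.0, 1.01, 0.01])
        assert np.isfinite(spec.log_prior(inside))[0]
        for bad in (
            [0.12, 800.0, 900.0, 1.01, 0.01],   # dw_inf < dw0
            [0.12, 3000.0, 900.0, 1.5, 0.01],   # kappa outside truncation
            [0.12, 3000.0, 900.0, 1.01, -0.1],  # negative variance
        ):
            assert spec.log_prior(np.array(bad))[0] == -np.inf


def _draws_frame(values, n_chains=4):
    values = np.asarray(values, dtype=float)
    per = len(values) // n_chains
    return pd.DataFrame(
        {
            "chain": np.repeat(np.arange(n_chains), per),
            "iteration": np.tile(np.arange(per), n_chains),
            "theta": values[: per * n_chains],
        }
    )


class TestSummarizePosterior:
    def test_constant_draws(self):
        s = summarize_posterior(_draws_frame(np.full(4000, 3.25)))
        row = s["theta"]
        assert row["mean"] == row["ci_low"] == row["ci_high"] == 3.25

    def test_uniform_grid_quantiles(self):
        grid = np.arange(1, 10001) / 10000.0
        s = summarize_posterior(_draws_frame(grid, n_chains=1))
        row = s["theta"]
        assert row["mean"] == pytest.approx(0.50005, rel=1e-12)
        assert row["ci_low"] == pytest.approx(0.025, abs=1e-3)
        assert row["ci_high"] == pytest.approx(0.975, abs=1e-3)

    def test_bounds_ordered(self):
        rng = np.random.default_rng(0)
        s = summarize_posterior(_draws_frame(rng.normal(size=4000)))
        row = s["theta"]
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]
        assert np.isfinite(row["rhat"]) and np.isfinite(row["ess"])

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(pd.DataFrame(columns=["chain", "iteration", "k"]))


class TestFitGrowth:
    def test_requires_minimum_data(self):
        recs = [LengthAtAgeRecord(0, 900.0), LengthAtAgeRecord(1, 1100.0)]
        with pytest.raises(ValueError):
            VonBertalanffyGrowth().fit(recs)

    def test_fixed_seed_reproduces_draws(self, truncated_records):
        kwargs = dict(
            priors="uninformative", n_walkers=12, n_warmup=80, n_samples=80,
            random_state=42,
        )
        a = VonBertalanffyGrowth(**kwargs).fit(truncated_records)
        b = VonBertalanffyGrowth(**kwargs).fit(truncated_records)
        pd.testing.assert_frame_equal(a.draws_, b.draws_)

    def test_draws_respect_support(self, recovery_fit):
        d = recovery_fit.draws_
        assert (d["k"] > 0).all()
        assert (d["dw_inf"] > d["dw0"]).all() and (d["dw0"] > 0).all()
        assert (d["sigma2"] > 0).all()
        assert d["kappa"].between(0.7, 1.3).all()

    def test_predict_follows_vb_curve(self, recovery_fit):
        w = recovery_fit.predict([0, 5, 10])
        assert w[0] == pytest.approx(recovery_fit.dw0_)
        assert np.all(np.diff(w) > 0)

    def test_sklearn_param_round_trip(self):
        est = VonBertalanffyGrowth(priors="weaker", random_state=1)
        clone = VonBertalanffyGrowth(**est.get_params())
        assert clone.get_params() == est.get_params()
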