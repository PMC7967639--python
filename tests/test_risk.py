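import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahrisk.registry import CONGENERS, DEFAULT_TEFS
from pahrisk.risk import (DistributionSpec, MonteCarloResult, RiskParams,
                          calibrate_body_weight, ilcr_point,
                          lognormal_from_arithmetic, monte_carlo_ilcr,
                          sample_distribution, sensitivity_analysis,
                          summarize_percentiles, teq, teq_contributions)

# analytic reference for the default child scenario at TEQ 1, BW 70:
# 1e-6 * 3.85 * 12 * 6 * 250 / (70 * 25550)
ILCR_UNIT_70KG = 1e-6 * 3.85 * 12 * 6 * 250 / (70 * 25550)


class TestTEQ:
    def test_reference_congener(self, make_profile):
        assert teq(make_profile({"BaP": 1.0})) == pytest.approx(1.0,
                                                                abs=1e-12)

    def test_dba_unit_potency(self, make_profile):
        assert teq(make_profile({"DbA": 2.0})) == pytest.approx(2.0,
                                                                abs=1e-12)

    def test_hand_sum(self, make_profile):
        p = make_profile({"NAP": 100.0, "BaA": 10.0, "BaP": 1.0})
        assert teq(p) == pytest.approx(0.1 + 1.0 + 1.0, abs=1e-12)

    @given(st.lists(st.floats(0, 1e3), min_size=16, max_size=16),
           st.integers(0, 15), st.floats(0.01, 10))
    @settings(max_examples=100, deadline=None)
    def test_linear_and_monotone(self, values, idx, bump):
        from pahrisk.profiles import CongenerProfile
        conc = dict(zip(CONGENERS, values))
        base = teq(CongenerProfile("s", conc=conc))
        conc2 = dict(conc)
        conc2[CONGENERS[idx]] += bump
        bumped = teq(CongenerProfile("s", conc=conc2))
        assert bumped >= base
        expected = base + bump * DEFAULT_TEFS[CONGENERS[idx]]
        assert bumped == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_contributions(self, make_profile):
        assert teq_contributions(make_profile({"BaP": 3.0}))["BaP"] == 100.0
        c = teq_contributions(make_profile({"BaP": 1.0, "DbA": 1.0}))
        assert c["BaP"] == c["DbA"] == 50.0
        equal = teq_contributions(make_profile({c: 1.0 for c in CONGENERS}))
        assert equal["BaP"] == pytest.approx(
            100.0 / sum(DEFAULT_TEFS.values()))
        assert sum(equal.values()) == pytest.approx(100.0)

    def test_zero_teq_contributions_error(self, make_profile):
        with pytest.raises(ValueError, match="zero"):
            teq_contributions(make_profile({}))


class TestDeterministicILCR:
    def test_zero_teq(self):
        assert ilcr_point(0.0, RiskParams(BW=70)) == 0.0

    def test_reference_adult_value(self):
        assert ilcr_point(1.0, RiskParams(BW=70.0)) == pytest.approx(
            ILCR_UNIT_70KG, rel=1e-12)
        assert ILCR_UNIT_70KG == pytest.approx(3.875e-8, rel=1e-3)

    def test_monotone_in_teq_and_bw(self):
        risks = [ilcr_point(t, RiskParams(BW=32)) for t in (1, 2, 5, 20)]
        assert all(a < b for a, b in zip(risks, risks[1:]))
        by_bw = [ilcr_point(10.0, RiskParams(BW=b))
                 for b in np.linspace(10, 120, 25)]
        assert all(a > b for a, b in zip(by_bw, by_bw[1:]))

    def test_implausible_bw_warns(self):
        with pytest.warns(UserWarning, match="plausible"):
            RiskParams(BW=5.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RiskParams(AT=0.0)
        with pytest.raises(ValueError):
            ilcr_point(-1.0, RiskParams(BW=32))

    def test_body_weight_calibration_round_trip(self):
        bw = calibrate_body_weight(17.35, 1.13e-6)
        assert ilcr_point(17.35, RiskParams(BW=bw)) == pytest.approx(
            1.13e-6, rel=1e-12)


class TestLognormalMoments:
    def test_degenerate(self):
        assert lognormal_from_arithmetic(1.0, 0.0) == (0.0, 0.0)

    def test_table_values(self):
        mu, sigma = lognormal_from_arithmetic(2.21, 2.51)
        assert mu == pytest.approx(0.3787, abs=1e-4)
        assert sigma == pytest.approx(0.9102, abs=1e-4)

    @given(m=st.floats(0.01, 1e3), s=st.floats(0, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_moments(self, m, s):
        mu, sigma = lognormal_from_arithmetic(m, s)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(m, rel=1e-9)
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert var == pytest.approx(s**2, rel=1e-6, abs=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_arithmetic(0.0, 1.0)


class TestSampling:
    def test_constant(self, rng):
        spec = DistributionSpec("IR", "constant", {"value": 12.0})
        assert np.all(sample_distribution(spec, rng, 100) == 12.0)

    def test_logistic_mean(self, rng):
        spec = DistributionSpec("TEQ", "logistic",
                                {"mean": 17.35, "scale": 1.74})
        x = sample_distribution(spec, rng, 100_000)
        se = 1.74 * math.pi / math.sqrt(3) / math.sqrt(len(x))
        assert abs(x.mean() - 17.35) < 4 * se

    def test_lognormal_arithmetic_mean(self, rng):
        spec = DistributionSpec("TEQ", "lognormal_arithmetic",
                                {"mean": 2.21, "sd": 2.51})
        x = sample_distribution(spec, rng, 200_000)
        assert abs(x.mean() - 2.21) < 4 * 2.51 / math.sqrt(len(x))

    def test_negative_binomial_truncated(self, rng):
        spec = DistributionSpec("BW", "negative_binomial",
                                {"p": 0.5, "r": 0.2})  # mass at 0
        x = sample_distribution(spec, rng, 5000)
        assert x.min() >= 1.0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            DistributionSpec("x", "triangular", {"a": 1})

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("BW", "negative_binomial", {"p": 1.5, "r": 2})
        with pytest.raises(ValueError):
            DistributionSpec("TEQ", "lognormal_arithmetic",
                             {"mean": -1, "sd": 1})


class TestMonteCarlo:
    def test_degenerate_specs_equal_point_estimate(self):
        teq_spec = DistributionSpec("TEQ", "constant", {"value": 1.0})
        bw_spec = DistributionSpec("BW", "constant", {"value": 70.0})
        res = monte_carlo_ilcr(teq_spec, bw_spec, RiskParams(BW=70),
                               n_iter=500, seed=7)
        assert np.all(res.draws == ILCR_UNIT_70KG)
        assert res.percentiles[95.0] == res.mean == ILCR_UNIT_70KG

    def test_seed_reproducibility(self):
        teq_spec = DistributionSpec("TEQ", "logistic",
                                    {"mean": 17.35, "scale": 1.74})
        bw_spec = DistributionSpec("BW", "negative_binomial",
                                   {"p": 0.206, "r": 8.3})
        a = monte_carlo_ilcr(teq_spec, bw_spec, n_iter=2000, seed=42)
        b = monte_carlo_ilcr(teq_spec, bw_spec, n_iter=2000, seed=42)
        c = monte_carlo_ilcr(teq_spec, bw_spec, n_iter=2000, seed=43)
        assert np.array_equal(a.draws, b.draws)
        assert not np.array_equal(a.draws, c.draws)

    def test_mean_converges_to_analytic_expectation(self):
        # constant BW, logistic TEQ: E[ILCR] = E[TEQ] x unit risk at BW
        teq_spec = DistributionSpec("TEQ", "logistic",
                                    {"mean": 17.35, "scale": 1.74})
        bw_spec = DistributionSpec("BW", "constant", {"value": 32.0})
        expected = ilcr_point(17.35, RiskParams(BW=32.0))
        err = []
        for n in (1000, 100_000):
            res = monte_carlo_ilcr(teq_spec, bw_spec, RiskParams(BW=32.0),
                                   n_iter=n, seed=5)
            err.append(abs(res.mean - expected) / expected)
        assert err[1] < err[0]
        assert err[1] < 0.01

    def test_all_draws_nonnegative(self):
        teq_spec = DistributionSpec("TEQ", "logistic",
                                    {"mean": 0.5, "scale": 2.0})
        bw_spec = DistributionSpec("BW", "constant", {"value": 32.0})
        res = monte_carlo_ilcr(teq_spec, bw_spec, RiskParams(BW=32.0),
                               n_iter=5000, seed=1)
        assert res.draws.min() >= 0.0

    def test_invalid_n_iter(self):
        spec = DistributionSpec("x", "constant", {"value": 1.0})
        with pytest.raises(ValueError):
            monte_carlo_ilcr(spec, spec, n_iter=0)


class TestPercentiles:
    def test_constant_draws(self):
        p = summarize_percentiles(np.full(100, 3.0), (5.0, 50.0, 95.0))
        assert all(v == 3.0 for v in p.values())

    def test_logistic_closed_form_tail(self):
        rng = np.random.default_rng(11)
        m, s = 17.35, 1.74
        draws = rng.logistic(m, s, 1_000_000)
        p95 = summarize_percentiles(draws, (95.0,))[95.0]
        assert p95 == pytest.approx(m + s * math.log(19), rel=5e-3)

    def test_small_vector_interpolation(self):
        p95 = summarize_percentiles(np.arange(1.0, 101.0), (95.0,))[95.0]
        assert 95.0 <= p95 <= 96.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_percentiles(np.array([]))


class TestSensitivity:
    @staticmethod
    def _result(draws, teq_draws, bw_draws):
        draws = np.asarray(draws, dtype=float)
        return MonteCarloResult(
            draws=draws, teq_draws=np.asarray(teq_draws, float),
            bw_draws=np.asarray(bw_draws, float), seed=0,
            mean=float(draws.mean()),
            percentiles=summarize_percentiles(draws, (50.0,)))

    def test_single_varying_input_gets_all_variance(self, rng):
        t = rng.lognormal(1, 0.5, 1000)
        res = self._result(t * 1e-7, t, np.full(1000, 32.0))
        with pytest.warns(UserWarning, match="one varying"):
            entries = sensitivity_analysis(res)
        assert len(entries) == 1
        assert entries[0].variable == "TEQ"
        assert entries[0].contribution == 1.0

    def test_bw_rank_correlation_negative(self):
        from pahrisk.synthetic import generate_risk_inputs
        teq_spec, bw_spec, rp = generate_risk_inputs("exposed")
        res = monte_carlo_ilcr(teq_spec, bw_spec, rp, n_iter=4000, seed=3)
        entries = {e.variable: e for e in sensitivity_analysis(res)}
        assert entries["BW"].rank_correlation < 0
        assert entries["TEQ"].rank_correlation > 0
        total = sum(e.contribution for e in entries.values())
        assert total == pytest.approx(1.0, abs=0.02)

    def test_symmetric_inputs_split_contribution(self, rng):
        x1, x2 = rng.normal(size=(2, 100_000))
        res = self._result(x1 + x2 + 20.0, x1, x2)
        entries = {e.variable: e for e in sensitivity_analysis(res)}
        assert entries["TEQ"].contribution == pytest.approx(0.5, abs=0.03)
        assert entries["BW"].contribution == pytest.approx(0.5, abs=0.03)

    def test_all_constant_rejected(self):
        res = self._result(np.full(10, 1.0), np.full(10, 2.0),
                           np.full(10, 3.0))
        with pytest.raises(ValueError, match="constant"):
            sensitivity_analysis(res)
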