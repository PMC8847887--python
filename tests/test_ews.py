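"""Early-warning-signal indicators against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tippingews import (
    EWSConfig,
    NoiseConfig,
    detrend,
    ews_feature_vector,
    kendall_tau,
    model_library,
    rolling_indicator,
    simulate_sde,
    truncate_pre_transition,
)
from tippingews.ews import INDICATORS, feature_names


# ---------------------------------------------------------------- oracles


def _naive_rolling(resid, window, indicator, original=None):
    """Brute-force per-window recomputation, independent of the vectorised path."""
    out = []
    for i in range(len(resid) - window + 1):
        w = np.asarray(resid[i : i + window], dtype=float)
        if indicator == "SD":
            out.append(np.std(w, ddof=1))
        elif indicator == "CV":
            m = np.mean(original[i : i + window])
            out.append(np.std(w, ddof=1) / abs(m) if m != 0 else np.nan)
        elif indicator in ("AR1", "RR"):
            a, b = w[:-1], w[1:]
            if np.std(a) == 0 or np.std(b) == 0:
                out.append(np.nan)
                continue
            r = np.corrcoef(a, b)[0, 1]
            out.append(r if indicator == "AR1" else (1.0 / abs(r) if r != 0 else np.nan))
        elif indicator == "ACF1":
            a, b = w[:-1], w[1:]
            va = np.var(a)
            out.append(np.cov(a, b, ddof=0)[0, 1] / va if va > 0 else np.nan)
        elif indicator == "DR":
            spec = np.abs(np.fft.rfft(w)) ** 2
            spec = spec[1:]
            nf = spec.size
            n_low = max(1, int(np.floor(0.05 * nf)))
            n_high = max(1, int(np.floor(0.5 * nf)))
            hi = spec[nf - n_high :].sum()
            out.append(spec[:n_low].sum() / hi if hi > 0 else np.nan)
    return np.asarray(out)


class TestDetrend:
    def test_constant_series_zero_residuals(self):
        r = detrend(np.full(50, 3.7), bandwidth=5)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_linear_ramp_removed_away_from_edges(self):
        """A symmetric kernel reproduces a linear trend exactly in the
        interior (beyond ~3 bandwidths from either edge)."""
        x = np.linspace(0, 10, 200)
        r = detrend(x, bandwidth=10)
        assert np.max(np.abs(r[40:160])) < 0.01
        assert np.max(np.abs(r)) > 0.1  # edges do deviate

    def test_smoothing_reduces_variance(self, rng):
        x = rng.standard_normal(300)
        r = detrend(x, bandwidth=10)
        assert np.var(r) <= np.var(x)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detrend(np.ones(2), 5)
        with pytest.raises(ValueError):
            detrend(np.ones(50), 0)


class TestRollingIndicators:
    @pytest.mark.parametrize("indicator", INDICATORS)
    def test_matches_bruteforce_oracle(self, indicator, rng):
        """Vectorised rolling statistics equal naive per-window recomputation."""
        for _ in range(10):
            n = int(rng.integers(60, 150))
            x = np.cumsum(rng.standard_normal(n)) + 5.0
            resid = detrend(x, bandwidth=0.2 * n)
            window = int(rng.integers(20, 41))
            got = rolling_indicator(resid, window, indicator, original=x)
            want = _naive_rolling(resid, window, indicator, original=x)
            np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-10, equal_nan=True)

    def test_sd_constant_window_zero(self):
        vals = rolling_indicator(np.zeros(50), 10, "SD")
        np.testing.assert_array_equal(vals, 0.0)

    def test_ar1_recovers_known_coefficient(self):
        """Windows over a long AR(1) process centre on its true coefficient,
        cross-checked against the full-sequence Yule-Walker estimate."""
        from tippingews import generate_coloured_noise

        x = generate_coloured_noise(5000, NoiseConfig(k=0.6, sigma=1.0), seed=0)
        vals = rolling_indicator(x, 400, "AR1")
        yw = np.corrcoef(x[:-1], x[1:])[0, 1]  # full-sequence estimate
        assert np.median(vals) == pytest.approx(yw, abs=0.05)
        assert np.median(vals) == pytest.approx(0.6, abs=0.05)

    def test_rr_is_reciprocal_of_ar1(self, rng):
        x = rng.standard_normal(100)
        ar1 = rolling_indicator(x, 30, "AR1")
        rr = rolling_indicator(x, 30, "RR")
        np.testing.assert_allclose(rr, 1.0 / np.abs(ar1), equal_nan=True)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            rolling_indicator(np.ones(10), 11, "SD")
        with pytest.raises(ValueError):
            rolling_indicator(np.ones(10), 5, "XYZ")


class TestKendallTau:
    def test_monotone_sequences(self):
        assert kendall_tau([1, 2, 3, 4]) == 1.0
        assert kendall_tau([4, 3, 2, 1]) == -1.0

    def test_all_ties_is_nan(self):
        assert np.isnan(kendall_tau([1.0, 1.0, 1.0, 1.0]))

    def test_nans_dropped_pairwise(self):
        assert kendall_tau([1, np.nan, 2, np.nan, 3]) == 1.0

    def test_too_few_finite_values_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(kendall_tau([np.nan, 1.0]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bounded(self, values):
        tau = kendall_tau(np.asarray(values))
        assert np.isnan(tau) or -1.0 <= tau <= 1.0


class TestFeatureVector:
    def test_length_is_grid_product(self, rng):
        x = rng.standard_normal(300)
        cfg = EWSConfig(indicators=("SD", "AR1"))
        v = ews_feature_vector(x, cfg)
        assert v.shape == (18,)  # 2 x 3 x 3
        full = ews_feature_vector(x, EWSConfig())
        assert full.shape == (54,)
        assert len(feature_names()) == 54

    def test_constant_series_maps_to_zero(self):
        v = ews_feature_vector(np.full(200, 2.0), EWSConfig(indicators=("SD",)))
        np.testing.assert_array_equal(v, 0.0)

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="largest window"):
            ews_feature_vector(np.ones(30), EWSConfig(units_mode="points"))

    def test_taus_bounded(self, rng):
        v = ews_feature_vector(np.cumsum(rng.standard_normal(200)), EWSConfig())
        assert np.all(np.abs(v) <= 1.0)


class TestCSDSignatures:
    def test_stationary_noise_has_centred_sd_trend(self, rng):
        """On white noise the SD trend statistic is centred at zero."""
        taus = []
        cfg = EWSConfig(indicators=("SD",), bandwidths=(20.0,), window_sizes=(40.0,))
        for _ in range(200):
            taus.append(ews_feature_vector(rng.standard_normal(150), cfg)[0])
        taus = np.asarray(taus)
        sem = taus.std(ddof=1) / np.sqrt(taus.size)
        assert abs(taus.mean()) < 3 * sem + 0.02

    def test_fold_pretipping_trends_positive(self):
        """Critical slowing down: rising variance and autocorrelation ahead of
        a fold bifurcation."""
        lib = {m.name: m for m in model_library()}
        cfg = EWSConfig(indicators=("SD", "AR1"), bandwidths=(20.0,), window_sizes=(50.0,))
        sd_taus, ar_taus = [], []
        for seed in range(12):
            s = simulate_sde(lib["fold_grazed"], NoiseConfig(k=0.0, sigma=1.0), seed=seed)
            s.label = "C.T."
            s = truncate_pre_transition(s, lib["fold_grazed"])
            v = ews_feature_vector(s.values, cfg)
            sd_taus.append(v[0])
            ar_taus.append(v[1])
        assert np.median(sd_taus) > 0
        assert np.median(ar_taus) > 0
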