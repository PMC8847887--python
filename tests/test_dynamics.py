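"""Simulator correctness: integrator accuracy, labelling, dataset structure."""

import numpy as np
import pytest

from tippingews import (
    CT,
    NT,
    ST,
    NoiseConfig,
    SimulationError,
    assign_label,
    build_dataset,
    model_library,
    simulate_sde,
    subsample_series,
    truncate_pre_transition,
)
from tippingews.models import ModelSpec
from tippingews.simulate import LabelledSeries


def _spec(drift, diffusion, **kw):
    base = dict(
        name="test",
        drift=drift,
        diffusion=diffusion,
        p_start=0.0,
        p_end=0.0,
        bifurcation_type="none",
        p_crit=None,
        x0_sampler=lambda rng, n: np.ones(n),
    )
    base.update(kw)
    return ModelSpec(**base)


class TestIntegrator:
    def test_deterministic_exponential_decay(self):
        """With g = 0 the scheme integrates dX/dt = -X to e^(-t) at O(dt)."""
        spec = _spec(lambda x, p: -x, lambda x: np.zeros_like(x))
        s = simulate_sde(spec, NoiseConfig(sigma=0.0), length=1000, dt=0.01, seed=0)
        exact = np.exp(-s.times * 0.01 * 100 / 100)  # t = T * record_every
        exact = np.exp(-s.times)
        # only early times are resolvable above float noise
        err = np.max(np.abs(s.values[:10] - exact[:10]))
        assert err < 0.05  # O(dt) global error at t <= 10

    def test_first_order_convergence(self):
        """Halving dt roughly halves the deviation from the analytic solution."""
        spec = _spec(lambda x, p: -x, lambda x: np.zeros_like(x))
        errs = []
        for dt in (0.02, 0.01):
            s = simulate_sde(
                spec, NoiseConfig(sigma=0.0), length=100, dt=dt, record_every=0.1, seed=0
            )
            t = s.times * 0.1
            errs.append(np.max(np.abs(s.values - np.exp(-t))))
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 2.5

    def test_ou_stationary_variance(self):
        """dX = -X dt + g dW has stationary variance g^2 sigma^2 / 2."""
        spec = _spec(lambda x, p: -x, lambda x: 0.2 * np.ones_like(x))
        s = simulate_sde(
            spec, NoiseConfig(k=0.0, sigma=1.0), length=100_000, dt=0.01,
            record_every=0.01, seed=1,
        )
        x = s.values[2000:]
        assert np.var(x) == pytest.approx(0.02, rel=0.1)

    def test_blowup_raises_simulation_error(self):
        spec = _spec(lambda x, p: x**3, lambda x: np.zeros_like(x))
        with pytest.raises(SimulationError, match="blow-up"):
            simulate_sde(spec, NoiseConfig(sigma=0.0), length=400, dt=0.01, seed=0)

    def test_seeded_reproducibility(self):
        spec = _spec(lambda x, p: -x, lambda x: 0.1 * np.ones_like(x))
        a = simulate_sde(spec, NoiseConfig(k=0.4, sigma=1.0), length=50, seed=5)
        b = simulate_sde(spec, NoiseConfig(k=0.4, sigma=1.0), length=50, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestLabelling:
    def test_fold_reaching_crit_is_catastrophic(self):
        fold = next(m for m in model_library() if m.bifurcation_type == "fold")
        assert assign_label(fold, True) == CT

    @pytest.mark.parametrize("btype", ["transcritical", "pitchfork", "hopf"])
    def test_continuous_bifurcations_are_smooth(self, btype):
        m = next(m for m in model_library() if m.bifurcation_type == btype)
        assert assign_label(m, True) == ST

    def test_unreached_ramp_is_no_transition(self):
        for m in model_library():
            assert assign_label(m, False) == NT

    def test_no_transition_model_cannot_reach(self):
        m = next(m for m in model_library() if m.bifurcation_type == "none")
        with pytest.raises(ValueError):
            assign_label(m, True)


def _series(n=400, crossing=None, label=NT, model_name="m"):
    return LabelledSeries(
        values=np.random.default_rng(0).standard_normal(n),
        times=np.arange(1, n + 1, dtype=float),
        label=label,
        model_name=model_name,
        noise=NoiseConfig(),
        crossing_index=crossing,
    )


class TestTruncation:
    def test_no_transition_series_unchanged(self):
        s = _series()
        m = next(x for x in model_library() if x.bifurcation_type == "none")
        assert truncate_pre_transition(s, m, margin=10) is s

    @pytest.mark.parametrize("margin,expected", [(0, 350), (50, 300)])
    def test_prefix_arithmetic(self, margin, expected):
        # crossing at the 350th time point (0-based index 349)
        s = _series(crossing=349, label=CT)
        m = model_library()[0]
        out = truncate_pre_transition(s, m, margin=margin)
        assert len(out) == expected
        assert out.truncation_index == expected - 1

    def test_excessive_margin_errors(self):
        s = _series(crossing=349, label=CT)
        with pytest.raises(ValueError, match="margin"):
            truncate_pre_transition(s, model_library()[0], margin=349)


class TestSubsampling:
    def test_identity_at_full_fraction(self):
        s = _series()
        assert subsample_series(s, 1.0) is s

    def test_fraction_count_and_order(self):
        s = _series(400)
        out = subsample_series(s, 0.4, seed=0)
        assert len(out) == 160
        assert np.all(np.diff(out.times) > 0)
        assert out.label == s.label

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            subsample_series(_series(), fraction)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            subsample_series(_series(400), 0.004)


class TestDatasetBuild:
    def test_balance_split_and_white_noise(self, small_dataset_w):
        ds = small_dataset_w
        labels = [s.label for s in ds.series]
        assert all(labels.count(c) == 10 for c in (CT, ST, NT))
        assert len(ds.train) == 24 and len(ds.test) == 6
        assert all(s.noise.k == 0.0 for s in ds.series)

    def test_split_proportions_exact(self):
        ds = build_dataset("W", 10, length=100, seed=0, dt=0.1)
        assert len(ds.test) == 6  # 2 per class

    def test_coloured_bands(self):
        ds = build_dataset("C", 10, length=200, seed=2, dt=0.05)
        for s, sp in zip(ds.series, ds.split):
            if sp == "train":
                assert abs(s.noise.k) <= 0.4
            else:
                assert 0.4 < abs(s.noise.k) <= 0.8

    def test_deterministic_under_seed(self):
        a = build_dataset("W", 5, length=60, seed=9, dt=0.1)
        b = build_dataset("W", 5, length=60, seed=9, dt=0.1)
        for x, y in zip(a.series, b.series):
            np.testing.assert_array_equal(x.values, y.values)
            assert x.model_name == y.model_name
        assert a.split == b.split

    def test_refuses_tiny_classes(self):
        with pytest.raises(ValueError):
            build_dataset("W", 4, seed=0)

    def test_transition_series_truncated(self, small_dataset_w):
        for s in small_dataset_w.series:
            if s.label in (CT, ST):
                assert len(s) < 400
                assert s.truncation_index is not None
            else:
                assert len(s) == 400


class TestJumpStructure:
    def test_fold_jumps_transcritical_does_not(self):
        """Simulated past p_crit, a fold collapse dwarfs the local noise while
        a transcritical passage stays smooth."""
        lib = {m.name: m for m in model_library()}
        noise = NoiseConfig(k=0.0, sigma=1.0)

        def jump_ratio(spec):
            s = simulate_sde(spec, noise, length=400, dt=0.01, seed=3)
            x = s.values
            cross = s.crossing_index
            pre = x[cross - 60 : cross]
            t = np.arange(pre.size)
            resid = pre - np.polyval(np.polyfit(t, pre, 1), t)  # detrended
            drop = pre[-1] - np.min(x[cross : cross + 30])
            return drop / np.std(resid)

        assert jump_ratio(lib["fold_grazed"]) > 5.0
        assert jump_ratio(lib["transcritical_harvest"]) < 5.0
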