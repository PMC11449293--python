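"""Basic response curve, area-signal synthesis, spike detection."""

import numpy as np
import pandas as pd
import pytest

from plateletpop import (
    ActivationResult,
    BasicResponseCurve,
    TraceSet,
    detect_first_spike,
    detect_first_spikes,
    fit_basic_curve,
    normalize_trace,
    synthesize_area_signal,
)
from plateletpop.synthetic import spike_template, spike_template_peak_offset


class TestBasicResponseCurve:
    def test_zero_before_activation_and_clamped(self):
        curve = BasicResponseCurve(coef=[-1.0, 1.0], t_max=10.0)  # t - 1
        assert curve(-5.0) == 0.0
        assert curve(0.5) == 0.0  # negative value clamped
        assert curve(3.0) == pytest.approx(2.0)

    def test_holds_end_value_beyond_support(self):
        curve = BasicResponseCurve(coef=[0.0, 1.0], t_max=10.0)
        assert curve(25.0) == pytest.approx(curve(10.0)) == pytest.approx(10.0)


class TestFitBasicCurve:
    def test_exact_polynomial_recovered(self):
        t = np.linspace(0, 20, 200)
        coef = np.array([0.3, 1.2, -0.15, 0.004])
        v = np.polynomial.polynomial.polyval(t, coef)
        curve = fit_basic_curve(t, v, degree=3, t_max=20.0)
        assert np.allclose(curve.coef, coef, rtol=1e-8, atol=1e-10)
        assert curve.residual_rms < 1e-10

    def test_growth_decay_fit_beats_noise(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 60, 181)
        clean = 3.0 * (t / 12.0) * np.exp(1.0 - t / 12.0)  # smooth bump
        noisy = clean + rng.normal(0, 0.05, t.size)
        curve = fit_basic_curve(t, noisy, degree=5, t_max=60.0)
        assert curve.residual_rms < 2 * 0.05
        fitted = np.array([curve(x) for x in t])
        assert np.sqrt(np.mean((fitted - clean) ** 2)) < 0.05

    def test_constant_trace_warns_and_returns_flat(self):
        t = np.linspace(0, 10, 50)
        with pytest.warns(UserWarning, match="degenerate"):
            curve = fit_basic_curve(t, np.full(50, 2.0), baseline=2.0, t_max=10.0)
        assert curve(5.0) == 0.0

    def test_low_degree_rejected(self):
        with pytest.raises(ValueError):
            fit_basic_curve([0, 1, 2], [0, 1, 2], degree=1)


class TestSynthesizeAreaSignal:
    curve = BasicResponseCurve(coef=[0.0, 0.5, -0.005], t_max=50.0, baseline=1.0)

    def test_common_shift_reproduces_curve(self):
        act = ActivationResult(ta=np.full(20, 7.0))
        grid = np.linspace(0, 40, 121)
        out = synthesize_area_signal(act, np.ones(20, dtype=int), self.curve, grid)
        expected = 1.0 + np.array([self.curve(t - 7.0) for t in grid])
        assert np.allclose(out["area_1"].to_numpy(), expected)

    def test_no_activation_gives_flat_baseline(self):
        act = ActivationResult(ta=np.full(10, np.nan))
        out = synthesize_area_signal(
            act, np.ones(10, dtype=int), self.curve, np.linspace(0, 10, 31)
        )
        assert np.allclose(out["area_1"], 1.0)

    def test_two_subpopulations_average_pointwise(self):
        ta = np.array([0.0] * 5 + [10.0] * 5)
        grid = np.linspace(0, 40, 161)
        out = synthesize_area_signal(act := ActivationResult(ta=ta),
                                     np.ones(10, dtype=int), self.curve, grid)
        expected = 1.0 + 0.5 * (self.curve(grid) + self.curve(grid - 10.0))
        assert np.allclose(out["area_1"].to_numpy(), expected)

    def test_binned_matches_exact(self):
        rng = np.random.default_rng(5)
        ta = np.sort(rng.uniform(0, 30, 400))
        areas = np.ones(400, dtype=int)
        grid = np.arange(0, 40, 1 / 3)
        act = ActivationResult(ta=ta)
        exact = synthesize_area_signal(act, areas, self.curve, grid, method="exact")
        binned = synthesize_area_signal(
            act, areas, self.curve, grid, method="binned", oversample=8
        )
        err = np.abs(exact["area_1"] - binned["area_1"]).max()
        assert err < 5e-3 * exact["area_1"].max()

    def test_empty_area_warns(self):
        act = ActivationResult(ta=np.array([1.0]))
        with pytest.warns(UserWarning, match="no cells"):
            out = synthesize_area_signal(
                act, np.array([1]), self.curve, [0.0, 1.0], area_indices=[1, 2]
            )
        assert np.allclose(out["area_2"], 1.0)

    def test_roundtrip_cell_average_equals_area_signal(self):
        # per-cell traces built from the same curve, averaged, must equal
        # the direct per-area synthesis to numerical precision
        rng = np.random.default_rng(6)
        ta = rng.uniform(0, 20, 50)
        grid = np.linspace(0, 40, 121)
        cells = 1.0 + np.stack([self.curve(grid - a) for a in ta])
        out = synthesize_area_signal(
            ActivationResult(ta=ta), np.ones(50, dtype=int), self.curve, grid
        )
        assert np.allclose(cells.mean(axis=0), out["area_1"].to_numpy(), atol=1e-12)


class TestNormalizeTrace:
    def make(self, values):
        return pd.DataFrame({"time_s": np.arange(len(values), dtype=float),
                             "area_1": values})

    def test_constant_becomes_ones(self):
        out = normalize_trace(self.make([3.0] * 10), flash_time=5.0)
        assert np.allclose(out["area_1"], 1.0)

    def test_division_by_preflash_mean(self):
        df = self.make([2.0] * 5 + [5.0] * 5)
        out = normalize_trace(df, flash_time=4.5)
        assert out["area_1"].iloc[-1] == pytest.approx(2.5)

    def test_idempotent(self):
        df = self.make(np.linspace(1, 4, 12))
        once = normalize_trace(df, flash_time=6.0)
        twice = normalize_trace(once, flash_time=6.0)
        assert np.allclose(once["area_1"], twice["area_1"])

    def test_zero_preflash_mean_rejected(self):
        with pytest.raises(ValueError, match="zero pre-flash"):
            normalize_trace(self.make([0.0] * 5 + [1.0] * 5), flash_time=4.5)


class TestDetectFirstSpike:
    times = np.arange(0, 120, 1 / 3)

    def noisy_trace(self, rng, spikes=(), noise=0.05, amplitude=5.0):
        v = 1.0 + rng.normal(0, noise, self.times.size)
        for t0 in spikes:
            v += spike_template(self.times - t0, amplitude=amplitude)
        return v

    def test_single_spike_found_at_peak_frame(self):
        rng = np.random.default_rng(0)
        onset = 70.0
        v = self.noisy_trace(rng, spikes=[onset])
        found = detect_first_spike(v, self.times, flash_time=60.0)
        assert found == pytest.approx(onset + spike_template_peak_offset(), abs=1 / 3)

    def test_preflash_spike_ignored(self):
        rng = np.random.default_rng(1)
        v = self.noisy_trace(rng, spikes=[20.0])
        assert detect_first_spike(v, self.times, flash_time=60.0) is None

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            detect_first_spike([1.0, 1.0], [0.0, 1.0], flash_time=0.5)

    def test_noise_only_false_positive_rate(self):
        # with an 8-noise-unit prominence requirement, pure noise should
        # essentially never yield a spike
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            v = self.noisy_trace(rng)
            if detect_first_spike(v, self.times, flash_time=60.0) is not None:
                hits += 1
        assert hits == 0

    def test_recovery_within_frame_at_low_noise(self):
        # at the default noise level the sampled peak is unambiguous:
        # >= 95% within one frame, all within two
        rng = np.random.default_rng(3)
        onsets = rng.uniform(62.0, 100.0, 200)
        values = np.stack(
            [self.noisy_trace(rng, spikes=[t0], noise=0.05) for t0 in onsets]
        )
        found = detect_first_spikes(
            TraceSet(times=self.times, values=values), flash_time=60.0
        )
        err = np.abs(found - (onsets + spike_template_peak_offset()))
        assert np.mean(err <= 1 / 3 + 1e-9) >= 0.95
        assert np.all(err <= 2 / 3 + 1e-9)

    def test_recovery_rate_at_snr_10(self):
        # SNR 10: the template top is flat relative to the noise, so the
        # detected frame wanders a little, but >= 99% stay within 2 s
        rng = np.random.default_rng(2)
        onsets = rng.uniform(62.0, 100.0, 200)
        values = np.stack(
            [self.noisy_trace(rng, spikes=[t0], noise=0.5) for t0 in onsets]
        )
        found = detect_first_spikes(
            TraceSet(times=self.times, values=values), flash_time=60.0
        )
        err = np.abs(found - (onsets + spike_template_peak_offset()))
        assert np.mean(err <= 2.0) >= 0.99
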