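import numpy as np
import pytest
from scipy.signal import periodogram

from lumapulse.segmentation import RawTrace
from lumapulse.synthetic import make_protocol
from lumapulse.timeseries import (
    StimulusProtocol,
    average_across_rois,
    dff_bath,
    dff_visual,
    motion_oscillation_advisory,
    notch_filter,
    remove_motion_oscillation,
    remove_stimulus_band,
    stimulus_locked_epoch_average,
    visual_baseline_segments,
)


def _trace(values, fs, t0=0.0):
    return RawTrace(values=np.asarray(values, float), frame_rate_hz=fs,
                    t0_s=t0)


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestNotch:
    def test_dc_preserved_exactly_on_constant(self):
        tr = _trace(np.full(2000, 42.0), fs=20.0)
        out = notch_filter(tr, 0.04, 0.005)
        np.testing.assert_allclose(out.values, 42.0, atol=1e-8)

    def test_center_tone_strongly_attenuated(self):
        fs = 20.0
        t = np.arange(0, 600, 1 / fs)
        x = np.sin(2 * np.pi * 0.04 * t)
        out = notch_filter(_trace(x, fs), 0.04, 0.005)
        m = (t > 10) & (t < 590)
        assert _rms(out.values[m]) <= 0.05 * _rms(x[m])

    def test_tone_at_5x_center_passes(self):
        fs = 20.0
        t = np.arange(0, 600, 1 / fs)
        x = np.sin(2 * np.pi * 0.2 * t)
        out = notch_filter(_trace(x, fs), 0.04, 0.005)
        m = (t > 10) & (t < 590)
        assert _rms(out.values[m]) >= 0.95 * _rms(x[m])

    def test_center_above_nyquist_rejected(self):
        tr = _trace(np.ones(100), fs=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            notch_filter(tr, 0.6, 0.01)

    def test_zero_phase_no_lag_on_broadband_noise(self):
        rng = np.random.default_rng(0)
        fs = 20.0
        x = rng.standard_normal(6000)
        out = notch_filter(_trace(x, fs), 0.04, 0.005).values
        xc = np.correlate(out - out.mean(), x - x.mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(x) - 1)
        assert lag == 0


class TestMotionNotch:
    def test_periodogram_power_reduced_20x(self):
        fs = 15.0
        t = np.arange(0, 600, 1 / fs)
        signal = 0.1 * np.sin(2 * np.pi * 0.5 * t)
        osc = 5.0 * np.sin(2 * np.pi * 0.04 * t)
        tr = _trace(100 + signal + osc, fs)
        out = remove_motion_oscillation(tr)
        band = lambda f: (f > 0.03) & (f < 0.05)
        f0, p0 = periodogram(tr.values - tr.values.mean(), fs=fs)
        f1, p1 = periodogram(out.values - out.values.mean(), fs=fs)
        assert p0[band(f0)].max() / p1[band(f1)].max() >= 20

    def test_flat_trace_stays_flat(self):
        tr = _trace(np.full(3000, 7.0), fs=15.0)
        np.testing.assert_allclose(remove_motion_oscillation(tr).values, 7.0,
                                   atol=1e-8)

    def test_near_idempotent(self):
        fs = 20.0
        t = np.arange(0, 600, 1 / fs)
        amp = 5.0
        tr = _trace(100 + amp * np.sin(2 * np.pi * 0.04 * t)
                    + np.sin(2 * np.pi * 0.5 * t), fs)
        one = remove_motion_oscillation(tr)
        two = remove_motion_oscillation(one)
        m = (t > 30) & (t < 570)
        # a second pass changes the interior by <1% of the oscillation
        assert np.abs(one.values[m] - two.values[m]).max() <= 0.01 * amp

    def test_advisory_flags_oscillating_recordings_only(self):
        fs = 15.0
        t = np.arange(0, 360, 1 / fs)
        rng = np.random.default_rng(0)
        quiet = _trace(100 + rng.standard_normal(t.size), fs)
        wobbly = _trace(100 + 5 * np.sin(2 * np.pi * 0.04 * t)
                        + rng.standard_normal(t.size), fs)
        assert not motion_oscillation_advisory(quiet)
        assert motion_oscillation_advisory(wobbly)


class TestStimulusBandNotch:
    def test_ramp_recovered_under_smooth_response_train(self):
        """The 0.2/0.4 Hz cascade recovers a slow basal trend (up to a
        constant) beneath a flash-response train whose power is
        concentrated below ~0.5 Hz."""
        fs = 27.0
        t = np.arange(0, 360, 1 / fs)
        amp = 1.0
        ramp = 0.5 * t / 360
        resp = np.zeros_like(t)
        for on in np.arange(3.0, 358, 5.0):
            resp += amp * np.exp(-0.5 * ((t - on - 2.5) / 0.8) ** 2)
        tr = _trace(100 + ramp + resp, fs)
        out = remove_stimulus_band(tr)
        m = (t > 25) & (t < 335)
        dev = out.values[m] - (100 + ramp[m])
        dev = dev - dev.mean()
        assert np.abs(dev).max() <= 0.10 * amp

    def test_constant_unchanged(self):
        tr = _trace(np.full(5000, 9.0), fs=27.0)
        np.testing.assert_allclose(remove_stimulus_band(tr).values, 9.0,
                                   atol=1e-8)

    def test_motion_band_passes_through(self):
        fs = 27.0
        t = np.arange(0, 600, 1 / fs)
        x = np.sin(2 * np.pi * 0.04 * t)
        out = remove_stimulus_band(_trace(100 + x, fs))
        m = (t > 30) & (t < 570)
        assert _rms(out.values[m] - 100) >= 0.95 * _rms(x[m])

    def test_low_frame_rate_rejected(self):
        with pytest.raises(ValueError):
            remove_stimulus_band(_trace(np.ones(100), fs=0.8))


class TestDffBath:
    def test_constant_trace_is_identically_zero(self):
        tr = _trace(np.full(1200, 100.0), fs=10.0)
        out = dff_bath(tr)
        assert out.f0 == 100.0
        np.testing.assert_array_equal(out.values, 0.0)

    def test_step_after_baseline(self):
        fs = 10.0
        vals = np.concatenate([np.full(600, 100.0), np.full(600, 150.0)])
        out = dff_bath(_trace(vals, fs))
        np.testing.assert_allclose(out.values[:600], 0.0)
        np.testing.assert_allclose(out.values[600:], 0.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            dff_bath(_trace(np.ones(100), fs=10.0))

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            dff_bath(_trace(np.zeros(1200), fs=10.0))


class TestDffVisual:
    def test_constant_trace_zero_for_any_protocol(self):
        prot = make_protocol(seed=0)
        fs = 10.0
        tr = _trace(np.full(int(366 * fs), 100.0), fs)
        out = dff_visual(tr, prot)
        assert out.f0 == 100.0
        np.testing.assert_array_equal(out.values, 0.0)

    def test_baseline_segments_exclude_post_flash_transients(self):
        prot = make_protocol(seed=1)
        fs = 20.0
        t = np.arange(0, 366, 1 / fs)
        vals = np.full(t.size, 100.0)
        for on in prot.flash_onsets_s:
            vals[(t >= on) & (t < on + 1.0)] = 200.0  # 1 s transient
        out = dff_visual(_trace(vals, fs), prot)
        assert out.f0 == 100.0

    def test_halving_baseline_total_leaves_f0_unchanged_on_noiseless(self):
        prot = make_protocol(seed=2)
        fs = 20.0
        tr = _trace(np.full(int(366 * fs), 123.0), fs)
        assert dff_visual(tr, prot, 30.0).f0 == dff_visual(tr, prot, 15.0).f0

    def test_segments_total_30s_nonconsecutive(self):
        prot = make_protocol(seed=3)
        segs = visual_baseline_segments(prot)
        assert len(segs) == 12
        total = sum(hi - lo for lo, hi in segs)
        assert total == pytest.approx(30.0)
        for (lo1, hi1), (lo2, _) in zip(segs, segs[1:]):
            assert hi1 < lo2  # non-consecutive

    def test_insufficient_gap_is_error(self):
        prot = StimulusProtocol(
            flash_onsets_s=np.array([1.0, 6.0]), polarities=["light", "dark"],
            n_epochs=1, epoch_length_s=60.0)
        tr = _trace(np.full(600, 100.0), fs=10.0)
        with pytest.raises(ValueError, match="insufficient"):
            dff_visual(tr, prot)


class TestEpochAverage:
    def _dff(self, values, fs):
        from lumapulse.timeseries import DffTrace
        return DffTrace(values=values, f0=100.0, baseline_rule="visual",
                        frame_rate_hz=fs)

    def _kernel_trace(self, prot, fs, offsets=None, epoch=1):
        t = np.arange(0, prot.n_epochs * 60 + 6, 1 / fs)
        vals = np.zeros(t.size)
        r = lambda tt: np.where(tt > 0, np.exp(-(tt - 0.3) ** 2 / 0.1), 0.0)
        idx = prot.epoch_flash_indices(epoch, "dark")
        for j, i in enumerate(idx):
            on = prot.flash_onsets_s[i]
            w = (t >= on - 2) & (t < on + 4.95)
            vals[w] += r(t[w] - on)
            if offsets is not None:
                vals[(t >= on - 2) & (t < on + 4.95)] += offsets[j]
        return self._dff(vals, fs), r

    def test_identical_responses_average_to_the_response(self):
        prot = make_protocol(seed=0, n_epochs=1)
        fs = 20.0
        dff, r = self._kernel_trace(prot, fs)
        resp = stimulus_locked_epoch_average(dff, prot, 1, "dark")
        assert resp.n_flashes == 6
        post = resp.times_s > 0
        np.testing.assert_allclose(resp.values[post], r(resp.times_s[post]),
                                   atol=1e-6)
        assert abs(resp.values[resp.times_s < 0].mean()) < 1e-12

    def test_per_flash_constant_offsets_removed(self):
        # alternate polarities so each dark window [-0.5, 4.9] s is isolated
        # and can carry its own additive constant
        prot = StimulusProtocol(
            flash_onsets_s=3.0 + 5.0 * np.arange(12),
            polarities=["dark", "light"] * 6, n_epochs=1)
        fs = 20.0
        t = np.arange(0, 66, 1 / fs)
        vals = np.zeros(t.size)
        r = lambda tt: np.where(tt > 0, np.exp(-(tt - 0.3) ** 2 / 0.1), 0.0)
        offsets = np.random.default_rng(4).uniform(-1, 1, 6)
        for j, i in enumerate(prot.epoch_flash_indices(1, "dark")):
            on = prot.flash_onsets_s[i]
            w = (t >= on - 0.5) & (t <= on + 4.91)
            vals[w] += r(t[w] - on) + offsets[j]
        dff = self._dff(vals, fs)
        resp = stimulus_locked_epoch_average(dff, prot, 1, "dark")
        post = resp.times_s > 0
        np.testing.assert_allclose(resp.values[post], r(resp.times_s[post]),
                                   atol=1e-6)

    def test_window_past_trace_end_drops_flash_with_warning(self):
        prot = make_protocol(seed=0, n_epochs=1)
        fs = 20.0
        dff, _ = self._kernel_trace(prot, fs)
        short = self._dff(dff.values[: int(56 * fs)], fs)  # cuts last flash
        with pytest.warns(UserWarning, match="dropped"):
            resp = stimulus_locked_epoch_average(short, prot, 1, "dark")
        assert resp.n_flashes == 5

    def test_no_usable_flashes_is_error(self):
        prot = make_protocol(seed=0, n_epochs=1)
        fs = 20.0
        dff = self._dff(np.zeros(int(2 * fs)), fs)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            stimulus_locked_epoch_average(dff, prot, 1, "dark")


class TestAverageAcrossRois:
    def _dff(self, values, fs=10.0):
        from lumapulse.timeseries import DffTrace
        return DffTrace(values=np.asarray(values, float), f0=100.0,
                        baseline_rule="visual", frame_rate_hz=fs)

    def test_identical_traces_unchanged(self):
        tr = self._dff(np.arange(10.0))
        out = average_across_rois([tr, tr, tr])
        np.testing.assert_array_equal(out.values, tr.values)

    def test_two_traces_mean(self):
        a = self._dff(np.arange(10.0))
        b = self._dff(np.arange(10.0) * 3)
        np.testing.assert_allclose(average_across_rois([a, b]).values,
                                   np.arange(10.0) * 2)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            average_across_rois([self._dff(np.zeros(5)),
                                 self._dff(np.zeros(6))])


class TestFilterDffInteraction:
    def test_notch_commutes_with_affine_dff(self):
        """dF/F is affine in F_t, so notching F then mapping with the same
        F0 equals mapping then notching, to numerical precision."""
        fs = 15.0
        t = np.arange(0, 360, 1 / fs)
        raw = _trace(100 + 5 * np.sin(2 * np.pi * 0.04 * t)
                     + 0.5 * np.sin(2 * np.pi * 0.3 * t), fs)
        dff = dff_bath(raw)
        f0 = dff.f0
        a = remove_motion_oscillation(dff).values
        b = (remove_motion_oscillation(raw).values - f0) / f0
        np.testing.assert_allclose(a, b, atol=1e-9)
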