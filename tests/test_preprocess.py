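import numpy as np
import pytest

from hbdot.preprocess import (ChannelTimeSeries, PreprocessConfig, bandpass,
                              butterworth_gain, channel_cv, detect_saturation,
                              preprocess_run, regress_scalp_global,
                              reject_bad_channels, remove_bad_timepoints,
                              to_optical_density)

FS = 18.5


def make_series(data, **kw):
    kw.setdefault("fs", FS)
    return ChannelTimeSeries(np.asarray(data, dtype=float), **kw)


class TestOpticalDensity:
    def test_constant_voltage_gives_zero_od(self):
        s = make_series(np.full((100, 2, 3), 1.3))
        od = to_optical_density(s)
        assert od.units == "OD"
        np.testing.assert_allclose(od.data, 0.0, atol=1e-15)

    def test_doubling_step_gives_log10_two(self):
        v = np.ones((100, 1, 1))
        v[50:] = 2.0
        s = make_series(v)
        od = to_optical_density(s)
        vbar = v.mean()
        expected = -np.log10(2.0 / vbar)
        np.testing.assert_allclose(od.data[50:, 0, 0], expected, rtol=1e-12)
        assert od.data[60, 0, 0] == pytest.approx(-0.30103 - np.log10(1 / vbar), abs=1e-5)

    def test_zero_sample_flags_channel_invalid(self):
        v = np.ones((50, 2, 3))
        v[10, 1, 0] = 0.0
        od = to_optical_density(make_series(v))
        assert not od.bad_channels[0]
        assert od.bad_channels[1]
        np.testing.assert_array_equal(od.data[:, 1, :], 0.0)


class TestChannelCV:
    def test_constant_signal_zero_cv(self):
        cv = channel_cv(make_series(np.full((64, 1, 3), 2.0)))
        np.testing.assert_allclose(cv, 0.0)

    def test_alternating_signal_cv_ten_percent(self):
        v = np.tile([[0.9], [1.1]], (50, 1))[:, :, None]
        cv = channel_cv(make_series(v))
        assert cv[0, 0] == pytest.approx(10.0, rel=1e-12)

    def test_zero_mean_reports_infinite(self):
        v = np.zeros((10, 1, 1))
        cv = channel_cv(make_series(v))
        assert np.isinf(cv[0, 0])


class TestChannelRejection:
    def test_exceeding_threshold_at_one_wavelength_rejects(self):
        cv = np.array([[14.0, 14.0, 16.0]])
        bad = reject_bad_channels(np.vstack([cv, [[1, 1, 1]]]),
                                  np.array([False, False]))
        assert bad.tolist() == [True, False]

    def test_threshold_is_strict(self):
        cv = np.array([[15.0, 15.0, 15.0], [1.0, 1.0, 1.0]])
        bad = reject_bad_channels(cv, np.array([False, False]))
        assert bad.tolist() == [False, False]

    def test_saturation_rejects_regardless_of_cv(self):
        cv = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        bad = reject_bad_channels(cv, np.array([True, False]))
        assert bad.tolist() == [True, False]

    def test_all_rejected_aborts(self):
        cv = np.full((3, 3), 99.0)
        with pytest.raises(RuntimeError):
            reject_bad_channels(cv, np.zeros(3, dtype=bool))

    def test_saturation_detector(self):
        v = np.ones((200, 2, 1))
        v[:3, 1, 0] = 5.0  # 1.5% of samples at ceiling
        sat = detect_saturation(make_series(v), ceiling=5.0, fraction=0.01)
        assert sat.tolist() == [False, True]


class TestBandpass:
    def test_dc_is_blocked(self):
        s = make_series(np.full((4000, 1, 1), 3.0), units="OD")
        out = bandpass(s)
        assert np.abs(out.data).max() < 1e-6 * 3.0

    @pytest.mark.parametrize("freq, rel_tol", [(0.04, 0.01), (0.2, 0.10)])
    def test_single_pass_gain_matches_analytic(self, freq, rel_tol):
        T = 40000
        t = np.arange(T) / FS
        x = np.sin(2 * np.pi * freq * t)[:, None, None]
        out = bandpass(make_series(x, units="OD"), mode="single_pass")
        measured = out.data[T // 2:, 0, 0].std() * np.sqrt(2)
        assert measured == pytest.approx(butterworth_gain(freq), rel=rel_tol)

    def test_stopband_attenuation_value(self):
        # closed-form low-pass magnitude at 0.2 Hz
        g = (1 + (0.2 / 0.08) ** 14) ** -0.5
        assert g == pytest.approx(1.6e-3, rel=0.05)

    def test_linearity(self, rng):
        x = rng.standard_normal((2000, 2, 1))
        y = rng.standard_normal((2000, 2, 1))
        a, b = 2.5, -1.25
        f = lambda d: bandpass(make_series(d, units="OD")).data
        np.testing.assert_allclose(f(a * x + b * y), a * f(x) + b * f(y),
                                   atol=1e-10 * np.abs(f(x)).max())

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            bandpass(make_series(np.ones((10, 1, 1)), units="OD"))


class TestScalpRegression:
    def test_channels_equal_to_global_mean_become_zero(self, rng):
        g = rng.standard_normal(500)
        data = np.tile(g[:, None, None], (1, 4, 1))
        s = make_series(data, units="OD",
                        channel_class=np.array(["short", "short", "long", "long"]))
        out = regress_scalp_global(s)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_orthogonal_channel_unchanged(self):
        t = np.arange(1000)
        g = np.sin(2 * np.pi * t / 100)
        y = np.cos(2 * np.pi * t / 100)  # orthogonal over full periods
        data = np.stack([g, y], axis=1)[:, :, None]
        s = make_series(data, units="OD",
                        channel_class=np.array(["short", "long"]))
        out = regress_scalp_global(s)
        np.testing.assert_allclose(out.data[:, 1, 0], y, atol=1e-12)

    def test_recovers_independent_component(self, rng):
        T = 5000
        g = rng.standard_normal(T)
        extra = rng.standard_normal(T)
        y = 2.0 * g + extra
        data = np.stack([g, y], axis=1)[:, :, None]
        s = make_series(data, units="OD",
                        channel_class=np.array(["short", "long"]))
        out = regress_scalp_global(s)
        r = np.corrcoef(out.data[:, 1, 0], extra)[0, 1]
        assert r > 0.99

    def test_idempotent(self, rng):
        data = rng.standard_normal((800, 6, 2))
        s = make_series(data, units="OD",
                        channel_class=np.array(["short"] * 3 + ["long"] * 3))
        once = regress_scalp_global(s)
        twice = regress_scalp_global(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_no_good_short_channels_raises(self, rng):
        s = make_series(rng.standard_normal((100, 2, 1)), units="OD",
                        channel_class=np.array(["long", "long"]))
        with pytest.raises(RuntimeError):
            regress_scalp_global(s)


class TestTimepointRemoval:
    def test_constant_signals_remove_nothing(self):
        s = make_series(np.ones((100, 2, 1)), units="OD",
                        channel_class=np.array(["short", "long"]))
        out, retained = remove_bad_timepoints(s)
        assert len(retained) == 100

    def test_injected_spike_removed_exactly(self):
        # bounded base signal, so only the injected spike crosses 3 SD
        t = np.arange(1000)
        data = np.stack([np.sin(t / 30.0), np.cos(t / 40.0)], axis=1)[:, :, None]
        sd = data[:, 0, 0].std()
        data[123, 0, 0] += 10 * sd
        s = make_series(data, units="OD",
                        channel_class=np.array(["short", "long"]))
        out, retained = remove_bad_timepoints(s)
        assert 123 not in retained
        assert out.removed_timepoints.tolist() == [123]

    def test_spike_in_long_channel_ignored(self, rng):
        data = rng.standard_normal((1000, 2, 1))
        # keep the short channel tame so only the long channel spikes
        data[:, 0, 0] = np.sin(np.arange(1000) / 50)
        data[500, 1, 0] += 50.0
        s = make_series(data, units="OD",
                        channel_class=np.array(["short", "long"]))
        out, retained = remove_bad_timepoints(s)
        assert len(retained) == 1000

    def test_metadata_preserved(self, rng):
        data = rng.standard_normal((300, 3, 2))
        s = make_series(data, units="OD",
                        channel_class=np.array(["short", "short", "long"]))
        out, retained = remove_bad_timepoints(s)
        assert out.n_channels == 3
        assert out.n_samples == len(retained)
        assert out.channel_class is s.channel_class


class TestFullChain:
    def test_mask_order_invariance(self, rng):
        """The global short mean over good channels equals the mean
        computed after discarding bad channels first."""
        data = np.abs(rng.standard_normal((500, 6, 3))) + 1.0
        cls = np.array(["short"] * 4 + ["long"] * 2)
        bad = np.array([False, True, False, False, False, False])
        good_short = cls == "short"
        g_masked = data[:, good_short & ~bad, :].mean(axis=1)
        pre = data[:, ~bad, :]
        g_pre = pre[:, (cls[~bad] == "short"), :].mean(axis=1)
        np.testing.assert_array_equal(g_masked, g_pre)

    def test_preprocess_run_outputs_consistent_branches(self, rng):
        T = 1200
        v = 1.0 + 0.01 * rng.standard_normal((T, 8, 3))
        s = make_series(np.abs(v),
                        channel_class=np.array(["short"] * 4 + ["long"] * 4))
        hb, mn, info = preprocess_run(s)
        assert hb.units == "OD" and mn.units == "OD"
        assert hb.n_samples == mn.n_samples
        np.testing.assert_array_equal(hb.bad_channels, mn.bad_channels)
        assert info["n_retained"] == hb.n_samples
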