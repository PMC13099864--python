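"""The SCAT receiver chain: filterbank, events, dechirp, delay, nulls."""

import numpy as np
import pytest

from batnav.acoustics import Waveform
from batnav.receiver import (FilterbankParams, NullPattern, dechirp,
                             default_threshold_levels, detect_events,
                             estimate_overall_delay, extract_nulls,
                             filterbank_spectrogram, transform_nulls_to_glint)


def analytic_null_freqs(dt, f_lo=20e3, f_hi=100e3):
    """Minima of |1 + exp(-i 2 pi f dt)|: f = (k + 1/2) / dt inside the band."""
    k = np.arange(0, int(f_hi * dt) + 2)
    f = (k + 0.5) / dt
    return f[(f >= f_lo) & (f <= f_hi)]


class TestFilterbank:
    def test_chirp_peak_times_follow_the_sweep(self, broadcast):
        env = filterbank_spectrogram(broadcast)
        peaks = env.times[np.argmax(env.envelope, axis=1)]
        # downward sweep: higher channels peak earlier (ties allowed on the
        # decimated envelope grid)
        assert np.all(np.diff(peaks) <= 0)
        # sweep law: channel fc is excited at t = (f0 - fc) / rate (edge
        # channels excluded: the amplitude taper pulls their peaks inward)
        expected = (100e3 - env.center_freqs) / 40e6
        assert np.max(np.abs(peaks - expected)[3:-3]) < 45e-6

    def test_ridge_width_matches_integration_time(self, broadcast):
        # width above half max ~ 350 us +- 20 % (mid-band channel)
        env = filterbank_spectrogram(broadcast)
        mid = env.envelope[40]
        width = np.sum(mid >= 0.5 * mid.max()) / env.sample_rate
        assert 280e-6 <= width <= 420e-6

    def test_two_glint_echo_shows_10khz_nulls(self, make_echo, receiver):
        env = receiver._envelopes_for(make_echo([6e-3, 6.1e-3]))
        amps = env.envelope.max(axis=1)
        ref = receiver.broadcast_events.channel_peak
        ratio = amps / ref
        # deep notches every ~10 kHz: channels at 25, 35, ... are minima
        null_idx = np.round((analytic_null_freqs(100e-6) - 20e3) / 1e3).astype(int)
        for i in null_idx:
            assert ratio[i] < 0.5 * ratio[i - 5:i + 6].max()

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            filterbank_spectrogram(Waveform(np.empty(0), 1e6))


class TestEvents:
    def test_silent_input_yields_all_absent(self):
        env = filterbank_spectrogram(Waveform(np.zeros(4096), 1e6))
        ev = detect_events(env)
        assert np.all(np.isnan(ev.event_time))

    def test_scaling_invariance_with_per_segment_reference(self, broadcast):
        # thresholds are fractions of the segment peak, so a scaled copy
        # produces identical event times
        env1 = filterbank_spectrogram(broadcast)
        scaled = Waveform(0.25 * broadcast.samples, broadcast.sample_rate)
        env2 = filterbank_spectrogram(scaled)
        t1 = detect_events(env1).event_time
        t2 = detect_events(env2).event_time
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_null_channels_are_retarded(self, make_echo, receiver):
        # amplitude-latency trading: events in attenuated (null) channels
        # occur later, forming the scalloped pattern
        env = receiver._envelopes_for(make_echo([6e-3, 6.1e-3]))
        ev = detect_events(env)
        d = dechirp(ev, receiver.broadcast_events)
        res = np.nanmean(d.residual_time, axis=1)
        null_idx = np.round((analytic_null_freqs(100e-6) - 20e3) / 1e3).astype(int)
        clear_idx = np.round((np.arange(20e3, 100e3, 10e3) + 0e3 - 20e3) / 1e3
                             ).astype(int)[1:]
        assert np.nanmean(res[null_idx]) > np.nanmean(res[clear_idx]) + 20e-6

    def test_nondecreasing_levels_required(self, broadcast):
        env = filterbank_spectrogram(broadcast)
        with pytest.raises(ValueError):
            detect_events(env, levels=np.array([0.5, 0.1]))


class TestDechirp:
    def test_broadcast_against_itself_is_zero(self, receiver):
        d = dechirp(receiver.broadcast_events, receiver.broadcast_events)
        cells = d.residual_time[np.isfinite(d.residual_time)]
        assert np.max(np.abs(cells)) < 1e-9

    def test_translation_equivariance(self, make_echo, receiver):
        e1 = receiver._envelopes_for(make_echo([6e-3]))
        e2 = receiver._envelopes_for(make_echo([7e-3]))
        d1 = dechirp(detect_events(e1), receiver.broadcast_events)
        d2 = dechirp(detect_events(e2), receiver.broadcast_events)
        diff = d2.residual_time - d1.residual_time
        np.testing.assert_allclose(diff[np.isfinite(diff)], 1e-3, atol=2e-6)

    def test_grid_mismatch_rejected(self, receiver, broadcast):
        env = filterbank_spectrogram(
            broadcast, FilterbankParams(center_freqs=np.arange(30e3, 90e3, 1e3)))
        with pytest.raises(ValueError):
            dechirp(detect_events(env), receiver.broadcast_events)


class TestOverallDelay:
    def test_identical_cells_give_that_value(self, receiver):
        d = dechirp(receiver.broadcast_events, receiver.broadcast_events)
        d.residual_time = np.full_like(d.residual_time, 4.2e-3)
        est = estimate_overall_delay(d)
        assert est is not None
        delay, conf = est
        assert delay == pytest.approx(4.2e-3)
        assert conf == 1.0

    def test_too_few_cells_reports_no_echo(self, receiver):
        d = dechirp(receiver.broadcast_events, receiver.broadcast_events)
        d.residual_time = np.full_like(d.residual_time, np.nan)
        d.residual_time[0, :5] = 1e-3
        assert estimate_overall_delay(d) is None

    @pytest.mark.parametrize("delay", [3e-3, 6e-3, 8.824e-3])
    def test_single_echo_delay_vs_matched_filter(self, delay, make_echo,
                                                 receiver):
        from scipy.signal import correlate

        echo = make_echo([delay], noise=0.01, seed=3)
        est = receiver.analyze(echo)
        mf = correlate(echo.samples, receiver.broadcast.samples, mode="full")
        mf_delay = (np.argmax(mf) - (len(receiver.broadcast.samples) - 1)) \
            / echo.sample_rate
        assert abs(est.overall_delay - mf_delay) <= 10e-6


class TestNulls:
    def test_one_glint_echo_has_no_nulls(self, make_echo, receiver):
        est = receiver.analyze(make_echo([6e-3], noise=0.01))
        assert len(est.null_freqs) == 0
        assert est.glint_dt is None

    @pytest.mark.parametrize("dt", [50e-6, 100e-6, 200e-6])
    def test_null_positions_match_analytic_minima(self, dt, make_echo,
                                                  receiver):
        est = receiver.analyze(make_echo([6e-3, 6e-3 + dt]))
        expected = analytic_null_freqs(dt)
        assert len(est.null_freqs) == len(expected)
        # within half the 1 kHz channel spacing of the analytic minima
        assert np.max(np.abs(np.sort(est.null_freqs) - expected)) <= 500.0

    def test_100us_pair_gives_10khz_spacing(self, make_echo, receiver):
        est = receiver.analyze(make_echo([6e-3, 6.1e-3]))
        spacing = np.diff(np.sort(est.null_freqs))
        assert np.mean(spacing) == pytest.approx(10e3, rel=0.02)

    def test_transform_arithmetic(self):
        p = NullPattern(np.array([25e3, 35e3, 45e3]), (20e3, 100e3))
        assert transform_nulls_to_glint(p) == pytest.approx(100e-6)
        assert transform_nulls_to_glint(
            NullPattern(np.array([40e3]), (20e3, 100e3))) is None

    def test_irregular_pattern_not_inverted(self):
        p = NullPattern(np.array([25e3, 30e3, 50e3, 55e3, 80e3]), (20e3, 100e3))
        assert transform_nulls_to_glint(p) is None


class TestFullChain:
    @pytest.mark.parametrize("dt", [50e-6, 80e-6, 100e-6, 150e-6, 200e-6,
                                    300e-6])
    def test_glint_delay_recovery(self, dt, make_echo, receiver):
        est = receiver.analyze(make_echo([6e-3, 6e-3 + dt], noise=0.01, seed=1))
        assert est.glint_dt is not None
        assert abs(est.glint_dt - dt) / dt <= 0.05

    def test_resolved_pair_reports_two_delays(self, make_echo, receiver):
        est = receiver.analyze(make_echo([6e-3, 7e-3], noise=0.01))
        assert est.glint_dt is None
        assert len(est.secondary_delays) == 2
        gap = est.secondary_delays[1] - est.secondary_delays[0]
        assert gap == pytest.approx(1e-3, abs=30e-6)

    def test_boundary_above_integration_time_is_not_single_mode(
            self, make_echo, receiver):
        # 400 us: beyond the ~350 us integration window, so the receiver
        # must not report a clean single-mode glint delay
        est = receiver.analyze(make_echo([6e-3, 6.4e-3], noise=0.01))
        assert est.glint_dt is None

    def test_amplitude_invariance(self, make_echo, receiver):
        a = receiver.analyze(make_echo([6e-3, 6.1e-3], amplitudes=[1, 1]))
        b = receiver.analyze(make_echo([6e-3, 6.1e-3], amplitudes=[0.1, 0.1]))
        assert abs(a.overall_delay - b.overall_delay) < 5e-6
        assert abs(a.glint_dt - b.glint_dt) / a.glint_dt < 0.02

    def test_no_echo_returns_none(self, receiver):
        silent = Waveform(np.zeros(8192), 1e6)
        assert receiver.analyze(silent) is None

    def test_envelope_hdf5_export(self, tmp_path, broadcast):
        import h5py
        from batnav.receiver import save_envelopes_h5

        env = filterbank_spectrogram(broadcast)
        path = tmp_path / "env.h5"
        save_envelopes_h5(path, env)
        with h5py.File(path) as fh:
            assert fh["envelope"].shape == env.envelope.shape
            assert fh.attrs["sample_rate"] == env.sample_rate

    def test_tracked_mode_selection(self, make_echo, receiver):
        # two well separated single-glint echoes: the gate picks the later
        echo = make_echo([4e-3, 9e-3], noise=0.01)
        est = receiver.analyze(echo, track_delay=9.1e-3, track_gate=1e-3)
        assert est.overall_delay == pytest.approx(9e-3, abs=20e-6)
        est2 = receiver.analyze(echo, track_delay=6.5e-3, track_gate=1e-3)
        assert est2 is None
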