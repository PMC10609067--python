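"""Recording chain: filtering, referencing, detection, artifact rejection,
sorting and the per-unit/per-electrode metrics."""

import numpy as np
import pytest

from meaperf import ephys
from meaperf.ephys import (
    SortedUnit,
    SpikeEvent,
    TimeSeriesRecording,
    amplitude_artifact_filter,
    bandpass,
    coincidence_artifact_filter,
    common_average_reference,
    detect_spikes,
    device_qc,
    electrode_noise,
    session_summary,
    sort_units,
    unit_metrics,
)
from meaperf.exceptions import InvalidParameterError, UndefinedMetricError

FS = 25000.0


def _sine(freq, duration=1.0, fs=FS, amp=10.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestDeviceQC:
    @pytest.mark.parametrize("ohm,expected", [
        (1.2e6, False),        # above 1 MOhm -> rejected
        (500e3, True),
        (100e3, True),         # boundary passes (exclusion rule is strict)
        (1e6, True),
        (99e3, False),
    ])
    def test_impedance_window(self, ohm, expected):
        assert device_qc(ohm) is expected

    def test_non_positive_impedance_rejected(self):
        with pytest.raises(InvalidParameterError):
            device_qc(0.0)


class TestBandpass:
    def test_dc_rejected(self):
        rec = TimeSeriesRecording(np.full((2, 25000), 10.0), FS)
        out = bandpass(rec)
        assert np.abs(out.signal).max() < 0.1

    def test_passband_tone_preserved(self):
        rec = TimeSeriesRecording(_sine(1000.0)[None, :], FS)
        out = bandpass(rec).signal[0][2500:-2500]   # ignore edges
        assert np.abs(out).max() == pytest.approx(10.0, rel=0.05)

    def test_stopband_tone_attenuated_20db(self):
        rec = TimeSeriesRecording(_sine(50.0, duration=2.0)[None, :], FS)
        out = bandpass(rec).signal[0][12500:-12500]
        assert np.abs(out).max() < 1.0   # >= 20 dB down from 10 uV

    def test_invalid_band_edges(self):
        rec = TimeSeriesRecording(np.zeros((1, 1000)), FS)
        with pytest.raises(InvalidParameterError):
            bandpass(rec, 3000.0, 300.0)
        with pytest.raises(InvalidParameterError):
            bandpass(rec, 300.0, 13000.0)   # above Nyquist


class TestCommonAverageReference:
    def test_identical_channels_cancel(self):
        sig = np.tile(_sine(700.0), (4, 1))
        out = common_average_reference(TimeSeriesRecording(sig, FS))
        assert np.allclose(out.signal, 0.0)

    def test_column_means_zero(self, rng):
        sig = rng.normal(size=(6, 5000))
        out = common_average_reference(TimeSeriesRecording(sig, FS))
        assert np.allclose(out.signal.mean(axis=0), 0.0, atol=1e-12)

    def test_single_channel_spike_scaled_15_16(self):
        sig = np.zeros((16, 100))
        sig[3, 50] = -80.0
        out = common_average_reference(TimeSeriesRecording(sig, FS)).signal
        assert out[3, 50] == pytest.approx(-80.0 * 15 / 16)
        assert out[0, 50] == pytest.approx(80.0 / 16)

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidParameterError):
            common_average_reference(TimeSeriesRecording(np.zeros((1, 100)), FS))

    def test_car_and_bandpass_commute(self, rng):
        # both operators are linear, so the order cannot matter
        rec = TimeSeriesRecording(rng.normal(size=(4, 25000)), FS)
        a = common_average_reference(bandpass(rec)).signal
        b = bandpass(common_average_reference(rec)).signal
        assert np.allclose(a, b, atol=1e-8)


class TestDetectSpikes:
    def test_strong_injected_spikes_all_detected(self, short_recording):
        rec, gt = short_recording
        filtered = common_average_reference(bandpass(rec))
        events = detect_spikes(filtered)
        from meaperf.synthetic import match_spike_times
        for times, ch in zip(gt.spike_times_s, gt.unit_channels):
            det = np.array([e.index / FS for e in events if e.channel == ch])
            assert match_spike_times(times, det) == len(times)

    def test_all_zero_trace_yields_no_events(self):
        rec = TimeSeriesRecording(np.zeros((2, 25000)), FS)
        assert detect_spikes(rec) == []

    def test_gaussian_crossing_rate_matches_oracle(self, rng):
        # independent oracle: count below-threshold runs separated by > 1 ms
        from scipy import signal as sps
        sos = sps.butter(4, (300, 3000), btype="bandpass", fs=FS, output="sos")
        n_rep, rates, oracle_rates = 8, [], []
        for _ in range(n_rep):
            x = sps.sosfiltfilt(sos, rng.standard_normal(int(30 * FS)))
            x /= x.std()
            rec = TimeSeriesRecording(x[None, :], FS)
            rates.append(len(detect_spikes(rec)) / 30.0)
            below = np.flatnonzero(x < x.mean() - 4 * x.std())
            runs = below[np.r_[True, np.diff(below) > 0.001 * FS]]
            oracle_rates.append(len(runs) / 30.0)
        se = np.std(oracle_rates, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(rates) - np.mean(oracle_rates)) <= 3 * se + 1e-9

    def test_too_short_recording_rejected(self):
        rec = TimeSeriesRecording(np.zeros((1, 10)), FS)
        with pytest.raises(InvalidParameterError):
            detect_spikes(rec)


def _event(channel=0, index=100, trough=-40.0, peak=10.0, n=35):
    snippet = np.zeros(n)
    snippet[10] = trough
    snippet[20] = peak
    return SpikeEvent(channel, index, snippet, trough)


class TestArtifactFilters:
    def test_amplitude_cutoff(self):
        events = [_event(trough=-350.0), _event(trough=-299.0),
                  _event(trough=-40.0, peak=301.0), _event(trough=-300.0)]
        kept = amplitude_artifact_filter(events)
        assert [e.trough_uV for e in kept] == [-299.0, -300.0]

    @pytest.mark.parametrize("channels,removed", [
        (range(3, 9), True),            # 6 consecutive -> removed
        (range(3, 8), False),           # 5 consecutive -> kept
        ((1, 3, 5, 7, 9, 11), False),   # 6 non-adjacent -> kept
    ])
    def test_consecutive_channel_rule(self, channels, removed):
        events = [_event(channel=c, index=1000 + i) for i, c in
                  enumerate(channels)]
        kept = coincidence_artifact_filter(events, FS)
        assert (len(kept) == 0) is removed

    def test_events_outside_window_not_grouped(self):
        # same 6 consecutive channels but spread over 50 ms: kept
        events = [_event(channel=c, index=1000 + 250 * i)
                  for i, c in enumerate(range(3, 9))]
        assert len(coincidence_artifact_filter(events, FS)) == 6

    def test_injected_artifacts_fully_removed(self, artifact_recording):
        from meaperf.synthetic import artifact_removal_report
        rec, gt = artifact_recording
        filtered = common_average_reference(bandpass(rec))
        events = detect_spikes(filtered)
        kept = coincidence_artifact_filter(
            amplitude_artifact_filter(events), FS, filtered.channel_order)
        report = artifact_removal_report(gt, events, kept, FS)
        assert report["artifact_removal_fraction"] == 1.0
        assert report["true_spike_loss_fraction"] < 0.01

    def test_filter_order_immaterial(self, artifact_recording):
        rec, _ = artifact_recording
        filtered = common_average_reference(bandpass(rec))
        events = detect_spikes(filtered)
        ab = coincidence_artifact_filter(amplitude_artifact_filter(events), FS)
        ba = amplitude_artifact_filter(coincidence_artifact_filter(events, FS))
        assert [(e.channel, e.index) for e in ab] == \
               [(e.channel, e.index) for e in ba]


class TestSortUnits:
    def test_two_distinct_units_separated(self, rng):
        from meaperf.synthetic import spike_template
        tpl_a, _ = spike_template(FS, 80.0)
        tpl_b, _ = spike_template(FS, 40.0)   # amplitude ratio 2
        n = 60
        snippets, labels = [], []
        for i in range(2 * n):
            tpl = tpl_a if i < n else tpl_b
            pad = np.zeros(35)
            pad[5:5 + len(tpl)] += tpl
            snippets.append(pad + rng.normal(0, 3.0, 35))
            labels.append(i < n)
        events = [SpikeEvent(0, 1000 * i, s, s.min())
                  for i, s in enumerate(snippets)]
        units = sort_units(events, FS, {0: 6.0})
        assert len(units) == 2
        # assignment accuracy against ground-truth labels
        best = 0.0
        for u in units:
            got = {e.index // 1000 for e in events} & \
                  set(int(i) for i in u.spike_indices // 1000)
            truth = {i for i, is_a in enumerate(labels) if is_a}
            acc = len(got & truth) / max(len(got), 1)
            best = max(best, acc)
        assert best >= 0.95

    def test_single_unit_not_split(self, short_recording):
        rec, gt = short_recording
        records, _, units = ephys.process_session(rec)
        for ch in gt.unit_channels:
            strong = [u for u in units
                      if u.channel == ch and u.n_spikes >= 30]
            assert len(strong) == 1

    def test_no_events_empty(self):
        assert sort_units([], FS) == []

    def test_below_min_spikes_yields_no_units(self):
        events = [_event(index=1000 * i) for i in range(5)]
        assert sort_units(events, FS, min_spikes=10) == []


class TestMetrics:
    def test_noise_matches_known_sigma(self, rng):
        trace = rng.normal(0, 6.0, int(10 * FS))
        assert electrode_noise(trace, [], FS) == pytest.approx(6.0, rel=0.05)

    def test_zero_trace_zero_noise(self):
        assert electrode_noise(np.zeros(1000), [], FS) == 0.0

    def test_excision_reduces_rms(self, short_recording):
        rec, _ = short_recording
        filtered = common_average_reference(bandpass(rec))
        events = detect_spikes(filtered)
        ch = 1
        ch_events = [e for e in events if e.channel == ch]
        with_spikes = np.sqrt((filtered.signal[ch] ** 2).mean())
        excised = electrode_noise(filtered.signal[ch], ch_events, FS)
        assert excised < with_spikes

    def test_everything_excised_is_error(self):
        events = [_event(index=i) for i in range(0, 100, 10)]
        with pytest.raises(UndefinedMetricError):
            electrode_noise(np.zeros(100), events, FS)

    def test_unit_metric_definitions(self):
        wf = np.zeros(35)
        wf[10], wf[20] = -24.8, 20.0
        unit = SortedUnit(0, 0, np.arange(5) * int(0.5 * FS), wf)
        vpp, snr, rate = unit_metrics(unit, 6.0, FS)
        assert vpp == pytest.approx(44.8)
        assert snr == pytest.approx(44.8 / 6.0)
        assert rate == pytest.approx(2.0)    # ISIs all 0.5 s

    def test_snr_error_and_rate_nan(self):
        unit = SortedUnit(0, 0, np.array([100]), np.array([-30.0, 0.0]))
        with pytest.raises(UndefinedMetricError):
            unit_metrics(unit, 0.0, FS)
        _, _, rate = unit_metrics(unit, 6.0, FS)
        assert np.isnan(rate)

    def test_vpp_snr_definition_30_over_6(self):
        wf = np.array([0.0, -18.0, 12.0])
        unit = SortedUnit(0, 0, np.array([0, 100]), wf)
        vpp, snr, _ = unit_metrics(unit, 6.0, FS)
        assert (vpp, snr) == (30.0, 5.0)


class TestSessionSummary:
    def _unit(self, ch, vpp):
        wf = np.array([0.0, -0.6 * vpp, 0.4 * vpp])
        u = SortedUnit(ch, 0, np.arange(10) * 1000, wf)
        u.vpp_uV, u.snr, u.rate_hz = vpp, vpp / 6.0, 2.0
        return u

    def test_electrode_mean_vpp(self):
        units = [self._unit(0, 30.0), self._unit(0, 40.0)]
        records, _ = session_summary(units, {0: 6.0}, {}, n_electrodes=16)
        assert records[0].vpp_uV == pytest.approx(35.0)
        assert records[0].n_units == 2 and records[0].active

    def test_active_proportion_5_of_16(self):
        units = [self._unit(ch, 30.0) for ch in range(5)]
        _, means = session_summary(units, {}, {}, n_electrodes=16)
        assert means["active_proportion"] == pytest.approx(5 / 16)

    def test_zero_active_device_means_undefined(self):
        records, means = session_summary([], {}, {}, n_electrodes=16)
        assert means["n_active"] == 0
        assert np.isnan(means["vpp_uV"])
        assert sum(r.active for r in records) == 0
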