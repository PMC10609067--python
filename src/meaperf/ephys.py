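"""Extracellular recording processing and single-unit metrics.

The chain mirrors a standard awake-rodent intracortical workflow on a 16-channel
single-shank array sampled at 25 kHz:

    band-pass (300-3000 Hz, zero phase)
    -> common-average reference across electrodes
    -> threshold detection at mean - 4*SD per channel
    -> artifact rejection: |amplitude| > 300 uV, and events co-occurring on
       more than five consecutive electrodes (motion artifacts)
    -> k-means spike sorting into single units
    -> per-unit Vpp, SNR (Vpp / noise RMS), spike rate (1 / median ISI)
    -> per-electrode and per-device session summaries, with an electrode
       counted as *active* when it records at least one sorted unit.

Noise is the RMS of the trace after excising detected spike snippets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .exceptions import InvalidParameterError, UndefinedMetricError

DEVICE_QC_LOW_OHM = 100e3
DEVICE_QC_HIGH_OHM = 1e6


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class TimeSeriesRecording:
    """Multichannel extracellular trace in microvolts.

    ``signal`` is (n_channels, n_samples); ``channel_order`` gives the
    physical shank order of the rows (index order for the single-shank
    device used here).  ``session`` carries (animal, group, week) labels.
    """

    signal: np.ndarray
    fs_hz: float
    channel_order: Optional[np.ndarray] = None
    session: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise InvalidParameterError("signal must be (n_channels, n_samples)")
        if self.fs_hz <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if np.isnan(self.signal).any():
            raise InvalidParameterError("signal contains NaNs")
        if self.channel_order is None:
            self.channel_order = np.arange(self.signal.shape[0])
        self.channel_order = np.asarray(self.channel_order, dtype=int)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, signal: np.ndarray) -> "TimeSeriesRecording":
        return TimeSeriesRecording(signal, self.fs_hz,
                                   self.channel_order.copy(), dict(self.session))

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("signal", data=self.signal.astype(np.float32))
            dset.attrs["fs_hz"] = self.fs_hz
            dset.attrs["channel_order"] = self.channel_order
            dset.attrs["session"] = json.dumps(self.session)

    @classmethod
    def load_h5(cls, path) -> "TimeSeriesRecording":
        with h5py.File(path, "r") as fh:
            dset = fh["signal"]
            return cls(dset[()], float(dset.attrs["fs_hz"]),
                       np.asarray(dset.attrs["channel_order"]),
                       json.loads(dset.attrs.get("session", "{}")))

    @classmethod
    def load_csv(cls, path, fs_hz: float) -> "TimeSeriesRecording":
        """Plain channel x sample CSV matrix (tiny fixtures)."""
        return cls(np.loadtxt(path, delimiter=","), fs_hz)


@dataclass
class SpikeEvent:
    channel: int
    index: int              # trough sample index within the recording
    snippet: np.ndarray     # uV, window around the trough
    trough_uV: float


@dataclass
class SortedUnit:
    channel: int
    unit_id: int
    spike_indices: np.ndarray
    waveform: np.ndarray    # ensemble (mean) waveform, uV
    vpp_uV: float = np.nan
    snr: float = np.nan
    rate_hz: float = np.nan

    @property
    def n_spikes(self) -> int:
        return len(self.spike_indices)


@dataclass
class ElectrodeWeekRecord:
    animal: str
    group: str
    week: int
    electrode: int
    n_units: int
    active: bool
    vpp_uV: float = np.nan
    noise_uV: float = np.nan
    snr: float = np.nan
    rate_hz: float = np.nan


def records_to_frame(records: Sequence[ElectrodeWeekRecord]) -> pd.DataFrame:
    cols = ["animal", "group", "week", "electrode", "n_units", "active",
            "vpp_uV", "noise_uV", "snr", "rate_hz"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


# --------------------------------------------------------------------------- #
# device QC
# --------------------------------------------------------------------------- #

def device_qc(impedance_1khz_ohm: float) -> bool:
    """Pre-implant pass/fail from the 1 kHz impedance.

    Devices above 1 MOhm or below 100 kOhm are rejected; the boundaries
    themselves pass (the exclusion rule is strict).
    """
    if impedance_1khz_ohm <= 0:
        raise InvalidParameterError("impedance must be positive")
    return DEVICE_QC_LOW_OHM <= impedance_1khz_ohm <= DEVICE_QC_HIGH_OHM


# --------------------------------------------------------------------------- #
# filtering and referencing
# --------------------------------------------------------------------------- #

def bandpass(recording: TimeSeriesRecording, low_hz: float = 300.0,
             high_hz: float = 3000.0, order: int = 4) -> TimeSeriesRecording:
    """Zero-phase Butterworth band-pass per channel (forward-backward)."""
    if not (0 < low_hz < high_hz):
        raise InvalidParameterError("band edges must satisfy 0 < low < high")
    if high_hz >= recording.fs_hz / 2:
        raise InvalidParameterError("upper band edge must be below Nyquist")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=recording.fs_hz, output="sos")
    return recording.copy_with(sps.sosfiltfilt(sos, recording.signal, axis=1))


def common_average_reference(recording: TimeSeriesRecording) -> TimeSeriesRecording:
    """Subtract the per-sample mean across electrodes from every channel."""
    if recording.n_channels < 2:
        raise InvalidParameterError("CAR requires at least 2 channels")
    car = recording.signal.mean(axis=0, keepdims=True)
    return recording.copy_with(recording.signal - car)


# --------------------------------------------------------------------------- #
# detection
# --------------------------------------------------------------------------- #

def _channel_threshold(trace: np.ndarray, sigma_mult: float, robust: bool) -> float:
    if robust:
        center = np.median(trace)
        sd = 1.4826 * np.median(np.abs(trace - center))
    else:
        center = trace.mean()
        sd = trace.std()
    return center - sigma_mult * sd


def detect_spikes(recording: TimeSeriesRecording, sigma_mult: float = 4.0,
                  robust: bool = False, pre_ms: float = 0.4,
                  post_ms: float = 1.0, refractory_ms: float = 1.0
                  ) -> List[SpikeEvent]:
    """Negative threshold-crossing detection at ``mean - sigma_mult * SD``.

    One event per crossing: the trough within the refractory window after the
    crossing is taken as the event time, and a lockout of ``refractory_ms``
    suppresses re-triggering.  Snippets span ``pre_ms`` before to ``post_ms``
    after the trough and must lie fully inside the recording.
    """
    fs = recording.fs_hz
    pre = int(round(pre_ms * 1e-3 * fs))
    post = int(round(post_ms * 1e-3 * fs))
    lockout = max(1, int(round(refractory_ms * 1e-3 * fs)))
    if recording.n_samples < pre + post:
        raise InvalidParameterError("recording shorter than the snippet window")

    events: List[SpikeEvent] = []
    for ch in range(recording.n_channels):
        trace = recording.signal[ch]
        thr = _channel_threshold(trace, sigma_mult, robust)
        below = trace < thr
        if not below.any():
            continue
        starts = np.flatnonzero(below & ~np.r_[False, below[:-1]])
        last_accepted = -np.inf
        for s in starts:
            if s - last_accepted < lockout:
                continue
            trough = s + int(np.argmin(trace[s:s + lockout]))
            last_accepted = trough
            if trough - pre < 0 or trough + post > len(trace):
                continue
            snippet = trace[trough - pre:trough + post]
            events.append(SpikeEvent(ch, trough, snippet.copy(), trace[trough]))
    return events


# --------------------------------------------------------------------------- #
# artifact rejection
# --------------------------------------------------------------------------- #

def amplitude_artifact_filter(events: Sequence[SpikeEvent],
                              cutoff_uV: float = 300.0) -> List[SpikeEvent]:
    """Drop events whose snippet exceeds +cutoff or falls below -cutoff."""
    return [ev for ev in events
            if ev.snippet.max() <= cutoff_uV and ev.snippet.min() >= -cutoff_uV]


def coincidence_artifact_filter(events: Sequence[SpikeEvent],
                                fs_hz: float,
                                channel_order: Optional[np.ndarray] = None,
                                window_ms: float = 0.5,
                                max_consecutive: int = 5) -> List[SpikeEvent]:
    """Remove co-occurring events spanning more than ``max_consecutive``
    consecutive electrodes (motion artifacts).

    Events are clustered in time (gaps <= the coincidence window merge); within
    a cluster the longest run of contiguous shank positions is found, and if
    it exceeds ``max_consecutive`` every event sitting on that run is removed.
    """
    if not events:
        return []
    order = np.asarray(channel_order) if channel_order is not None else None
    window = int(round(window_ms * 1e-3 * fs_hz))

    idx = np.argsort([ev.index for ev in events])
    sorted_events = [events[i] for i in idx]
    clusters: List[List[SpikeEvent]] = [[sorted_events[0]]]
    for ev in sorted_events[1:]:
        if ev.index - clusters[-1][-1].index <= window:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])

    def shank_pos(ch: int) -> int:
        if order is None:
            return ch
        return int(np.flatnonzero(order == ch)[0])

    keep: List[SpikeEvent] = []
    for cluster in clusters:
        positions = sorted({shank_pos(ev.channel) for ev in cluster})
        bad_positions: set = set()
        run = [positions[0]]
        for p in positions[1:] + [None]:
            if p is not None and p == run[-1] + 1:
                run.append(p)
            else:
                if len(run) > max_consecutive:
                    bad_positions.update(run)
                run = [p]
        for ev in cluster:
            if shank_pos(ev.channel) not in bad_positions:
                keep.append(ev)
    keep.sort(key=lambda ev: (ev.channel, ev.index))
    return keep


# --------------------------------------------------------------------------- #
# sorting
# --------------------------------------------------------------------------- #

def _cluster_snippets(snippets: np.ndarray, k_max: int,
                      silhouette_threshold: float, random_state: int
                      ) -> np.ndarray:
    """k-means over waveform PCA features; k chosen by silhouette score.

    k = 1 is used when no k >= 2 reaches the silhouette threshold (a single
    Gaussian cluster split in two scores well below 0.5).  Ties break toward
    smaller k.
    """
    n = len(snippets)
    n_comp = min(3, n - 1, snippets.shape[1])
    if n_comp < 1:
        return np.zeros(n, dtype=int)
    feats = PCA(n_components=n_comp, random_state=random_state).fit_transform(snippets)
    best_k, best_score, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
    for k in range(2, min(k_max, n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        labels = km.fit_predict(feats)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(feats, labels)
        if score > best_score + 1e-12:  # strict: ties keep smaller k
            best_k, best_score, best_labels = k, score, labels
    if best_k == 1 or best_score < silhouette_threshold:
        return np.zeros(n, dtype=int)
    return best_labels


def sort_units(events: Sequence[SpikeEvent], fs_hz: float,
               noise_uV: Optional[dict] = None, min_spikes: int = 10,
               k_max: int = 5, silhouette_threshold: float = 0.5,
               random_state: int = 0) -> List[SortedUnit]:
    """Cluster surviving events per channel into single units.

    Clusters with fewer than ``min_spikes`` spikes are discarded (not an
    error).  Unit metrics are filled when the channel's noise estimate is
    supplied via ``noise_uV`` (channel -> uV).
    """
    units: List[SortedUnit] = []
    by_channel: dict = {}
    for ev in events:
        by_channel.setdefault(ev.channel, []).append(ev)

    for ch in sorted(by_channel):
        evs = sorted(by_channel[ch], key=lambda e: e.index)
        if len(evs) < min_spikes:
            continue
        snippets = np.stack([ev.snippet for ev in evs])
        labels = _cluster_snippets(snippets, k_max, silhouette_threshold,
                                   random_state)
        for uid in np.unique(labels):
            sel = labels == uid
            if sel.sum() < min_spikes:
                continue
            indices = np.array([ev.index for ev, s in zip(evs, sel) if s])
            waveform = snippets[sel].mean(axis=0)
            unit = SortedUnit(ch, len(units), indices, waveform)
            noise = None if noise_uV is None else noise_uV.get(ch)
            if noise is not None:
                unit.vpp_uV, unit.snr, unit.rate_hz = unit_metrics(
                    unit, noise, fs_hz)
            else:
                unit.vpp_uV = waveform.max() - waveform.min()
            units.append(unit)
    return units


# --------------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------------- #

def electrode_noise(trace: np.ndarray, events: Sequence[SpikeEvent] = (),
                    fs_hz: float = 25000.0, pre_ms: float = 0.4,
                    post_ms: float = 1.0) -> float:
    """RMS of the channel trace after excising detected spike snippets."""
    trace = np.asarray(trace, dtype=float)
    keep = np.ones(len(trace), dtype=bool)
    pre = int(round(pre_ms * 1e-3 * fs_hz))
    post = int(round(post_ms * 1e-3 * fs_hz))
    for ev in events:
        keep[max(0, ev.index - pre):ev.index + post] = False
    if not keep.any():
        raise UndefinedMetricError("all samples excised; noise undefined")
    return float(np.sqrt(np.mean(trace[keep] ** 2)))


def unit_metrics(unit: SortedUnit, noise_uV: float, fs_hz: float):
    """(Vpp, SNR, spike rate) for one sorted unit.

    Vpp = max - min of the ensemble waveform; SNR = Vpp / noise RMS;
    spike rate = 1 / median inter-spike interval (s).  Rate is NaN with
    fewer than 2 spikes; zero noise raises.
    """
    if noise_uV <= 0:
        raise UndefinedMetricError("SNR undefined for non-positive noise")
    vpp = float(unit.waveform.max() - unit.waveform.min())
    snr = vpp / noise_uV
    if unit.n_spikes >= 2:
        isi_s = np.diff(np.sort(unit.spike_indices)) / fs_hz
        rate = float(1.0 / np.median(isi_s))
    else:
        rate = np.nan
    return vpp, snr, rate


def session_summary(units: Sequence[SortedUnit], noise_uV: dict,
                    session: dict, n_electrodes: int = 16):
    """Per-electrode records plus device-level means over active electrodes.

    An electrode is active when it carries at least one sorted unit; its
    metric values are means over its units.  Device means average the active
    electrodes ("devices that registered multiple active electrodes were
    averaged together"); with no active electrode they are NaN.
    """
    animal = session.get("animal", "")
    group = session.get("group", "")
    week = int(session.get("week", 0))
    by_electrode: dict = {}
    for u in units:
        by_electrode.setdefault(u.channel, []).append(u)

    records = []
    for el in range(n_electrodes):
        el_units = by_electrode.get(el, [])
        rec = ElectrodeWeekRecord(
            animal=animal, group=group, week=week, electrode=el + 1,
            n_units=len(el_units), active=len(el_units) >= 1,
            noise_uV=float(noise_uV.get(el, np.nan)))
        if el_units:
            rec.vpp_uV = float(np.mean([u.vpp_uV for u in el_units]))
            rec.snr = float(np.mean([u.snr for u in el_units]))
            rates = [u.rate_hz for u in el_units if np.isfinite(u.rate_hz)]
            rec.rate_hz = float(np.mean(rates)) if rates else np.nan
        records.append(rec)

    active = [r for r in records if r.active]
    device_means = {
        "n_active": len(active),
        "active_proportion": len(active) / n_electrodes,
    }
    for metric in ("vpp_uV", "noise_uV", "snr", "rate_hz"):
        vals = [getattr(r, metric) for r in active
                if np.isfinite(getattr(r, metric))]
        device_means[metric] = float(np.mean(vals)) if vals else np.nan
    return records, device_means


# --------------------------------------------------------------------------- #
# full per-session chain
# --------------------------------------------------------------------------- #

def process_session(recording: TimeSeriesRecording, config=None):
    """Run the full chain on one session; returns (records, device_means, units)."""
    from .config import PipelineConfig
    cfg = config or PipelineConfig()
    rec = bandpass(recording, *cfg.band_hz)
    if rec.n_channels >= 2:
        rec = common_average_reference(rec)
    events = detect_spikes(rec, cfg.detection_sigma, cfg.robust_sigma,
                           cfg.snippet_pre_ms, cfg.snippet_post_ms,
                           cfg.refractory_ms)
    events = amplitude_artifact_filter(events, cfg.amplitude_cutoff_uV)
    events = coincidence_artifact_filter(
        events, rec.fs_hz, rec.channel_order, cfg.coincidence_window_ms,
        cfg.consecutive_channel_limit)
    noise = {}
    for ch in range(rec.n_channels):
        ch_events = [ev for ev in events if ev.channel == ch]
        noise[ch] = electrode_noise(rec.signal[ch], ch_events, rec.fs_hz,
                                    cfg.snippet_pre_ms, cfg.snippet_post_ms)
    units = sort_units(events, rec.fs_hz, noise, cfg.min_spikes, cfg.k_max)
    records, device_means = session_summary(units, noise, rec.session,
                                            rec.n_channels)
    return records, device_means, units
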