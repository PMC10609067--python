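"""Seeded ground-truth generators for every pipeline stage.

Three families of inputs are emulated:

* extracellular recordings — band-limited (300-3000 Hz) Gaussian noise with a
  calibrated per-channel RMS, embedded biphasic spike units firing as Poisson
  processes, plus two artifact classes: large-amplitude events (> 300 uV on a
  single channel) and motion-like coincident events spanning >= 6 adjacent
  electrodes within 0.2 ms;
* implant-site fluorescence images — radially decaying marker intensity
  ``background + amplitude * exp(-d / length_const)`` around a hole polygon,
  with uniformly placed nuclei outside a neuron-depleted zone;
* nCounter-style count matrices — negative-binomial endogenous genes with
  known fold changes, housekeeping genes sharing group means, a 4x geometric
  positive-control series, and low-level negative controls.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy import signal as sps

from .ephys import ElectrodeWeekRecord, TimeSeriesRecording
from .exceptions import InvalidParameterError

# --------------------------------------------------------------------------- #
# recordings
# --------------------------------------------------------------------------- #


@dataclass
class UnitSpec:
    """One ground-truth unit: channel, mean firing rate, true Vpp."""
    channel: int
    rate_hz: float = 3.0
    vpp_uV: float = 40.0


@dataclass
class ArtifactSpec:
    n_amplitude: int = 0          # single-channel > 300 uV events
    n_coincident: int = 0         # motion-like events on adjacent channels
    amplitude_uV: float = 600.0
    coincident_uV: float = 150.0
    coincident_span: int = 6      # adjacent channels covered (>= 6)
    coincident_jitter_ms: float = 0.2


@dataclass
class RecordingGroundTruth:
    spike_times_s: List[np.ndarray]      # per unit, trough times, increasing
    unit_channels: List[int]
    unit_vpp_uV: List[float]
    noise_rms_uV: np.ndarray             # per channel
    artifacts: List[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        data = {
            "spike_times_s": [t.tolist() for t in self.spike_times_s],
            "unit_channels": list(map(int, self.unit_channels)),
            "unit_vpp_uV": list(map(float, self.unit_vpp_uV)),
            "noise_rms_uV": self.noise_rms_uV.tolist(),
            "artifacts": self.artifacts,
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path) -> "RecordingGroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls([np.asarray(t) for t in d["spike_times_s"]],
                   d["unit_channels"], d["unit_vpp_uV"],
                   np.asarray(d["noise_rms_uV"]), d["artifacts"])


def spike_template(fs_hz: float, vpp_uV: float, neg_ms: float = 0.4,
                   pos_ms: float = 0.6, trough_frac: float = 0.6) -> Tuple[np.ndarray, int]:
    """Biphasic template (negative phase then repolarization), scaled to Vpp.

    Returns (template, trough_offset_samples).  The trough carries
    ``trough_frac`` of the peak-to-peak range, the repolarization peak the
    remainder.
    """
    n_neg = max(2, int(round(neg_ms * 1e-3 * fs_hz)))
    n_pos = max(2, int(round(pos_ms * 1e-3 * fs_hz)))
    neg = np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = np.sin(np.pi * np.arange(n_pos) / n_pos)
    neg = -trough_frac * vpp_uV * neg / neg.max()
    pos = (1 - trough_frac) * vpp_uV * pos / pos.max()
    template = np.concatenate([neg, pos])
    return template, int(np.argmin(template))


def _poisson_train(rng: np.random.Generator, rate_hz: float, duration_s: float,
                   refractory_s: float = 1e-3) -> np.ndarray:
    """Homogeneous Poisson spike times with a hard refractory period."""
    if rate_hz <= 0:
        return np.empty(0)
    t, out = 0.0, []
    while True:
        t += rng.exponential(1.0 / rate_hz) + refractory_s
        if t >= duration_s:
            break
        out.append(t)
    return np.asarray(out)


def gen_recording(duration_s: float, n_channels: int = 16,
                  fs_hz: float = 25000.0,
                  unit_spec: Sequence[UnitSpec] = (),
                  noise_rms_uV: float = 6.0,
                  artifact_spec: Optional[ArtifactSpec] = None,
                  seed: int = 0, band_hz: Tuple[float, float] = (300.0, 3000.0)
                  ) -> Tuple[TimeSeriesRecording, RecordingGroundTruth]:
    """Synthesize a multichannel recording with known ground truth."""
    if duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    if fs_hz <= 0 or fs_hz < 2 * band_hz[1]:
        raise InvalidParameterError("sampling rate must be >= 2x the upper band edge")
    if noise_rms_uV <= 0:
        raise InvalidParameterError("noise RMS must be positive")
    if n_channels < 1:
        raise InvalidParameterError("need at least one channel")

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs_hz))

    # band-limited noise, exactly calibrated per channel
    white = rng.standard_normal((n_channels, n_samples))
    sos = sps.butter(4, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    noise = sps.sosfiltfilt(sos, white, axis=1)
    noise *= noise_rms_uV / np.sqrt(np.mean(noise ** 2, axis=1, keepdims=True))
    signal = noise

    # units
    spike_times, unit_channels, unit_vpps = [], [], []
    for spec in unit_spec:
        if not 0 <= spec.channel < n_channels:
            raise InvalidParameterError(f"unit channel {spec.channel} out of range")
        template, trough_off = spike_template(fs_hz, spec.vpp_uV)
        times = _poisson_train(rng, spec.rate_hz, duration_s)
        kept = []
        for t in times:
            start = int(round(t * fs_hz)) - trough_off
            if start < 0 or start + len(template) > n_samples:
                continue
            signal[spec.channel, start:start + len(template)] += template
            kept.append((start + trough_off) / fs_hz)
        spike_times.append(np.asarray(kept))
        unit_channels.append(spec.channel)
        unit_vpps.append(spec.vpp_uV)

    # artifacts: monophasic negative deflections (motion/electrical transients)
    artifacts: List[dict] = []
    spec = artifact_spec or ArtifactSpec()
    margin = 0.05

    def _pulse(depth_uV: float, width_ms: float):
        n = max(4, int(round(width_ms * 1e-3 * fs_hz)))
        shape = np.sin(np.pi * np.arange(n) / n)
        return -depth_uV * shape / shape.max(), n // 2

    for _ in range(spec.n_amplitude):
        t = rng.uniform(margin, duration_s - margin)
        ch = int(rng.integers(n_channels))
        pulse, trough_off = _pulse(spec.amplitude_uV, 0.5)
        start = int(round(t * fs_hz)) - trough_off
        signal[ch, start:start + len(pulse)] += pulse
        artifacts.append({"type": "amplitude", "channels": [ch],
                          "time_s": (start + trough_off) / fs_hz})
    for _ in range(spec.n_coincident):
        span = max(6, spec.coincident_span)
        if span > n_channels:
            raise InvalidParameterError("coincident span exceeds channel count")
        t = rng.uniform(margin, duration_s - margin)
        base = int(rng.integers(n_channels - span + 1))
        chans = list(range(base, base + span))
        pulse, trough_off = _pulse(spec.coincident_uV, 0.5)
        jitter_max = int(round(spec.coincident_jitter_ms * 1e-3 * fs_hz))
        times = []
        for ch in chans:
            start = (int(round(t * fs_hz)) - trough_off
                     + int(rng.integers(jitter_max + 1)))
            signal[ch, start:start + len(pulse)] += pulse
            times.append((start + trough_off) / fs_hz)
        artifacts.append({"type": "coincident", "channels": chans,
                          "time_s": float(np.mean(times))})

    rec = TimeSeriesRecording(signal, fs_hz)
    gt = RecordingGroundTruth(spike_times, unit_channels, unit_vpps,
                              np.full(n_channels, float(noise_rms_uV)),
                              artifacts)
    return rec, gt


def write_recording(rec: TimeSeriesRecording, gt: RecordingGroundTruth,
                    h5_path, json_path=None) -> None:
    rec.save_h5(h5_path)
    if json_path is not None:
        gt.to_json(json_path)


# --------------------------------------------------------------------------- #
# ground-truth evaluation
# --------------------------------------------------------------------------- #


def match_spike_times(true_times_s: np.ndarray, detected_times_s: np.ndarray,
                      tol_s: float = 0.5e-3) -> int:
    """Number of true spikes matched one-to-one by detections within tol."""
    true_times = np.sort(np.asarray(true_times_s))
    det = np.sort(np.asarray(detected_times_s))
    i = j = matched = 0
    while i < len(true_times) and j < len(det):
        dt = det[j] - true_times[i]
        if abs(dt) <= tol_s:
            matched += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    return matched


def evaluate_sorting(gt: RecordingGroundTruth, units, fs_hz: float,
                     tol_s: float = 0.5e-3) -> pd.DataFrame:
    """Per-true-unit recall/precision against the best-matching sorted unit.

    For each ground-truth unit the sorted unit on the same channel with the
    most matched spikes is taken; recall = matched / n_true and
    precision = matched / n_detected for that unit.
    """
    rows = []
    for times, ch, vpp in zip(gt.spike_times_s, gt.unit_channels,
                              gt.unit_vpp_uV):
        best = {"matched": 0, "n_detected": 0}
        for u in units:
            if u.channel != ch:
                continue
            det_times = np.asarray(u.spike_indices) / fs_hz
            matched = match_spike_times(times, det_times, tol_s)
            if matched > best["matched"]:
                best = {"matched": matched, "n_detected": len(det_times)}
        n_true = len(times)
        rows.append({
            "channel": ch, "true_vpp_uV": vpp, "n_true": n_true,
            "n_matched": best["matched"], "n_detected": best["n_detected"],
            "recall": best["matched"] / n_true if n_true else np.nan,
            "precision": best["matched"] / best["n_detected"]
            if best["n_detected"] else np.nan,
        })
    return pd.DataFrame(rows)


def artifact_removal_report(gt: RecordingGroundTruth, events_before,
                            events_after, fs_hz: float,
                            tol_s: float = 1e-3) -> dict:
    """Fractions of injected artifacts removed and of true spikes lost.

    An artifact counts as removed when none of the surviving events on its
    channels falls within ``tol_s`` of its time; true-spike loss compares the
    number of matched true spikes before vs after the artifact filters.
    """
    def surviving(events, channels):
        return np.array([ev.index / fs_hz for ev in events
                         if ev.channel in channels])

    n_removed = 0
    for art in gt.artifacts:
        times = surviving(events_after, set(art["channels"]))
        if not len(times) or np.min(np.abs(times - art["time_s"])) > tol_s:
            n_removed += 1
    matched_before = matched_after = n_true = 0
    for times, ch in zip(gt.spike_times_s, gt.unit_channels):
        n_true += len(times)
        matched_before += match_spike_times(times, surviving(events_before, {ch}))
        matched_after += match_spike_times(times, surviving(events_after, {ch}))
    return {
        "n_artifacts": len(gt.artifacts),
        "n_artifacts_removed": n_removed,
        "artifact_removal_fraction": n_removed / len(gt.artifacts)
        if gt.artifacts else np.nan,
        "true_spike_loss_fraction": (matched_before - matched_after)
        / matched_before if matched_before else np.nan,
    }


# --------------------------------------------------------------------------- #
# cohorts of electrode-week sessions
# --------------------------------------------------------------------------- #


@dataclass
class CohortDesign:
    """Two-group longitudinal design: 11 animals x 16 electrodes x weeks 1-16.

    ``active_prob`` maps group -> phase -> probability that an electrode-week
    carries at least one unit.
    """
    groups: Tuple[str, str] = ("treatment", "control")
    animals_per_group: int = 11
    electrodes_per_device: int = 16
    weeks: Tuple[int, ...] = tuple(range(1, 17))
    active_prob: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        "treatment": {"acute": 0.32, "sub-chronic": 0.42, "chronic": 0.37},
        "control": {"acute": 0.31, "sub-chronic": 0.35, "chronic": 0.41},
    })

    def validate(self, phase_ranges: Optional[dict] = None) -> None:
        from .phases import DEFAULT_PHASE_RANGES, assign_phase
        ranges = phase_ranges or DEFAULT_PHASE_RANGES
        for g in self.groups:
            for phase, p in self.active_prob[g].items():
                if not 0 <= p <= 1:
                    raise InvalidParameterError(
                        f"active probability {p} for {g}/{phase} outside [0,1]")
        for w in self.weeks:
            assign_phase(w, ranges)  # raises if a week falls outside all phases


def gen_cohort_sessions(design: CohortDesign, seed: int = 0,
                        phase_ranges: Optional[dict] = None
                        ) -> Tuple[pd.DataFrame, Dict[str, Dict[str, float]]]:
    """Electrode-week records for a full cohort, plus the true AEY per phase.

    Each electrode-week is independently active with its group x phase
    probability; active records get plausible Vpp/noise/SNR/rate draws.
    """
    from .phases import DEFAULT_PHASE_RANGES, assign_phase
    ranges = phase_ranges or DEFAULT_PHASE_RANGES
    design.validate(ranges)
    rng = np.random.default_rng(seed)
    rows: List[ElectrodeWeekRecord] = []
    for group in design.groups:
        for a in range(design.animals_per_group):
            animal = f"{group[:3]}-{a + 1:02d}"
            for week in design.weeks:
                phase = assign_phase(week, ranges)
                p_active = design.active_prob[group][phase]
                for el in range(1, design.electrodes_per_device + 1):
                    active = bool(rng.random() < p_active)
                    noise = float(np.clip(rng.normal(6.5, 1.2), 3.0, None))
                    rec = ElectrodeWeekRecord(
                        animal=animal, group=group, week=week, electrode=el,
                        n_units=0, active=active, noise_uV=noise)
                    if active:
                        rec.n_units = 1 + int(rng.random() < 0.3)
                        rec.vpp_uV = float(np.clip(rng.normal(38.0, 8.0), 15.0, None))
                        rec.snr = rec.vpp_uV / noise
                        rec.rate_hz = float(np.exp(rng.normal(np.log(2.0), 0.4)))
                    rows.append(rec)
    from .ephys import records_to_frame
    frame = records_to_frame(rows)
    true_props = {g: dict(design.active_prob[g]) for g in design.groups}
    return frame, true_props


# --------------------------------------------------------------------------- #
# implant-site images
# --------------------------------------------------------------------------- #


@dataclass
class ImageGroundTruth:
    """Radial-decay parameters for one synthetic marker image."""
    hole_polygon_px: np.ndarray          # (N, 2) as (row, col) vertices
    um_per_px: float = 1.0
    amplitude: float = 4000.0
    length_const_um: float = 100.0
    background: float = 1000.0
    noise_sd: float = 0.0
    nuclei_density_per_um2: float = 0.0
    depletion_radius_um: float = 0.0

    def validate(self) -> None:
        poly = np.asarray(self.hole_polygon_px, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3:
            raise InvalidParameterError("hole polygon needs >= 3 vertices")
        if self.length_const_um <= 0:
            raise InvalidParameterError("length constant must be positive")
        if self.um_per_px <= 0:
            raise InvalidParameterError("pixel scale must be positive")
        if self.amplitude < 0 or self.background < 0 or self.noise_sd < 0:
            raise InvalidParameterError("intensity parameters must be >= 0")


def circle_polygon(center_rc: Tuple[float, float], radius_px: float,
                   n_vertices: int = 64) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([center_rc[0] + radius_px * np.sin(theta),
                            center_rc[1] + radius_px * np.cos(theta)])


def gen_ihc_image(truth: ImageGroundTruth, size_px: Tuple[int, int] = (1024, 1024),
                  seed: int = 0) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(16-bit image, hole polygon, nuclei centroids) with radial structure.

    Expected intensity at distance d from the hole boundary is
    ``background + amplitude * exp(-d / length_const)``; Gaussian noise of
    ``noise_sd`` is added on top.  Nuclei are uniform outside the depletion
    radius (and the hole).
    """
    truth.validate()
    poly = np.asarray(truth.hole_polygon_px, dtype=float)
    if (poly < 0).any() or (poly[:, 0] >= size_px[0]).any() \
            or (poly[:, 1] >= size_px[1]).any():
        raise InvalidParameterError("hole polygon lies outside the image")
    from .ihc import hole_distance_um
    rng = np.random.default_rng(seed)
    hole_mask, dist_um = hole_distance_um(poly, size_px, truth.um_per_px)
    image = truth.background + truth.amplitude * np.exp(
        -np.where(hole_mask, 0.0, dist_um) / truth.length_const_um)
    image[hole_mask] = 0.0
    if truth.noise_sd > 0:
        image = image + rng.normal(0.0, truth.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 65535).astype(np.uint16)

    centroids = np.empty((0, 2))
    if truth.nuclei_density_per_um2 > 0:
        eligible = ~hole_mask & (dist_um > truth.depletion_radius_um)
        area_um2 = eligible.sum() * truth.um_per_px ** 2
        n = rng.poisson(truth.nuclei_density_per_um2 * area_um2)
        pts = []
        while len(pts) < n:
            r = rng.uniform(0, size_px[0])
            c = rng.uniform(0, size_px[1])
            if eligible[int(r), int(c)]:
                pts.append((r, c))
        centroids = np.asarray(pts) if pts else np.empty((0, 2))
    return image, poly, centroids


def write_ihc_image(image: np.ndarray, polygon: np.ndarray,
                    centroids: np.ndarray, tiff_path, json_path) -> None:
    tifffile.imwrite(tiff_path, image)
    with open(json_path, "w") as fh:
        json.dump({"hole_polygon_px": polygon.tolist(),
                   "nuclei_centroids_px": centroids.tolist()}, fh)


# --------------------------------------------------------------------------- #
# count matrices
# --------------------------------------------------------------------------- #


@dataclass
class CountsGroundTruth:
    """Generative description of a 152-probe nCounter-style panel."""
    base_means: np.ndarray               # endogenous per-gene control-group mean
    fold_change: np.ndarray              # endogenous true treated/control ratio
    dispersion: float = 0.05
    hk_means: np.ndarray = field(default_factory=lambda: np.array(
        [800.0, 1200.0, 2000.0, 600.0, 400.0, 1500.0]))
    pos_series: np.ndarray = field(default_factory=lambda: np.array(
        [32768.0, 8192.0, 2048.0, 512.0, 128.0, 32.0]))  # 4x geometric
    neg_mean: float = 5.0
    sample_efficiency_sd: float = 0.1    # lognormal SD of per-sample assay efficiency
    sample_content_sd: float = 0.1       # lognormal SD of per-sample RNA content

    def validate(self) -> None:
        if len(self.base_means) != len(self.fold_change):
            raise InvalidParameterError("base_means and fold_change lengths differ")
        if (self.fold_change <= 0).any() or (self.base_means <= 0).any():
            raise InvalidParameterError("means and fold changes must be positive")
        if self.dispersion < 0:
            raise InvalidParameterError("dispersion must be >= 0")
        if not (np.diff(self.pos_series) < 0).all():
            raise InvalidParameterError("positive-control series must decrease")


def default_counts_truth(n_endogenous: int = 132, frac_changed: float = 0.0,
                         fold: float = 4.0, dispersion: float = 0.05,
                         seed: int = 0) -> CountsGroundTruth:
    """Panel totalling 152 probes (132 endogenous + 6 housekeeping +
    6 positive + 8 negative) with an optional fraction of truly changed genes."""
    rng = np.random.default_rng(seed)
    base = np.exp(rng.uniform(np.log(50.0), np.log(2000.0), n_endogenous))
    fc = np.ones(n_endogenous)
    n_changed = int(round(frac_changed * n_endogenous))
    if n_changed:
        idx = rng.choice(n_endogenous, n_changed, replace=False)
        up = rng.random(n_changed) < 0.5
        fc[idx] = np.where(up, fold, 1.0 / fold)
    return CountsGroundTruth(base_means=base, fold_change=fc,
                             dispersion=dispersion)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, dispersion): var = mean + dispersion * mean^2; dispersion 0
    degenerates to the rounded mean."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.round(mean).astype(int)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gen_count_matrix(truth: CountsGroundTruth, n_per_group=(6, 7),
                     seed: int = 0):
    """CountMatrix for a treatment-vs-control panel; columns are samples.

    ``n_per_group`` is (n_treatment, n_control) or a single int for both.
    Per-sample assay-efficiency factors multiply every probe (corrected by
    positive-control normalization); per-sample RNA-content factors multiply
    endogenous and housekeeping probes (corrected by housekeeping
    normalization).
    """
    from .genes import CountMatrix
    truth.validate()
    if isinstance(n_per_group, int):
        n_per_group = (n_per_group, n_per_group)
    if min(n_per_group) < 2:
        raise InvalidParameterError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)

    n_t, n_c = n_per_group
    samples = [f"treat_{i+1}" for i in range(n_t)] + \
              [f"ctrl_{i+1}" for i in range(n_c)]
    groups = pd.Series(["treatment"] * n_t + ["control"] * n_c, index=samples)

    n_endo = len(truth.base_means)
    genes = ([f"gene_{i+1:03d}" for i in range(n_endo)]
             + [f"hk_{i+1}" for i in range(len(truth.hk_means))]
             + [f"pos_{chr(65+i)}" for i in range(len(truth.pos_series))]
             + [f"neg_{chr(65+i)}" for i in range(8)])
    gene_class = pd.Series(["endogenous"] * n_endo
                           + ["housekeeping"] * len(truth.hk_means)
                           + ["positive"] * len(truth.pos_series)
                           + ["negative"] * 8, index=genes)

    eff = np.exp(rng.normal(0.0, truth.sample_efficiency_sd, len(samples)))
    content = np.exp(rng.normal(0.0, truth.sample_content_sd, len(samples)))

    counts = np.zeros((len(genes), len(samples)))
    for j, s in enumerate(samples):
        fc = truth.fold_change if groups[s] == "treatment" else 1.0
        endo_mean = truth.base_means * fc * eff[j] * content[j]
        hk_mean = truth.hk_means * eff[j] * content[j]
        pos_mean = truth.pos_series * eff[j]
        neg_mean = np.full(8, truth.neg_mean * eff[j])
        counts[:n_endo, j] = _nb_draw(rng, endo_mean, truth.dispersion)
        counts[n_endo:n_endo + len(hk_mean), j] = _nb_draw(
            rng, hk_mean, truth.dispersion)
        off = n_endo + len(hk_mean)
        counts[off:off + len(pos_mean), j] = _nb_draw(rng, pos_mean,
                                                      truth.dispersion)
        if truth.dispersion == 0:
            counts[off + len(pos_mean):, j] = np.round(neg_mean)
        else:
            counts[off + len(pos_mean):, j] = rng.poisson(neg_mean)

    frame = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(counts=frame, gene_class=gene_class, groups=groups)
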