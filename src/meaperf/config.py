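"""Pipeline configuration.

All defaults mirror the study protocol: a 300-3000 Hz band, a -4 sigma
detection threshold, +/-300 uV amplitude cutoffs, removal of events spanning
more than five consecutive electrodes, 50 um radial bins (intensity to 700 um,
neuron density to 500 um), and FDR level q = 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml


@dataclass
class PipelineConfig:
    # phase binning (weeks, inclusive ranges; None drops a phase entirely)
    acute_weeks: Optional[Tuple[int, int]] = (1, 5)
    subchronic_weeks: Optional[Tuple[int, int]] = (6, 11)
    chronic_weeks: Optional[Tuple[int, int]] = (12, 16)
    # recording processing
    band_hz: Tuple[float, float] = (300.0, 3000.0)
    detection_sigma: float = 4.0
    robust_sigma: bool = False
    amplitude_cutoff_uV: float = 300.0
    consecutive_channel_limit: int = 5
    snippet_pre_ms: float = 0.4
    snippet_post_ms: float = 1.0
    refractory_ms: float = 1.0
    coincidence_window_ms: float = 0.5
    min_spikes: int = 10
    k_max: int = 5
    # cohort design
    animals_per_group: int = 11
    electrodes_per_device: int = 16
    # radial quantification
    bin_width_um: float = 50.0
    intensity_max_um: float = 700.0
    density_max_um: float = 500.0
    # statistics
    q: float = 0.05
    mad_k: float = 3.0
    seed: int = 0

    def phase_ranges(self) -> dict:
        ranges = {
            "acute": self.acute_weeks,
            "sub-chronic": self.subchronic_weeks,
            "chronic": self.chronic_weeks,
        }
        return {name: r for name, r in ranges.items() if r is not None}

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in fields:
                raise KeyError(f"unknown config key: {key}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


def validate_config(config: PipelineConfig) -> list:
    """Range/consistency checks; returns a list of error strings (empty = ok)."""
    errors = []
    ranges = list(config.phase_ranges().items())
    for name, (lo, hi) in ranges:
        if lo > hi or lo < 0:
            errors.append(f"{name} week range {lo}-{hi} is invalid")
    for (na, ra), (nb, rb) in zip(ranges, ranges[1:]):
        if rb[0] <= ra[1]:
            errors.append(f"phase ranges {na} {ra} and {nb} {rb} overlap")
    low, high = config.band_hz
    if not (0 < low < high):
        errors.append(f"band edges {config.band_hz} invalid")
    if config.detection_sigma <= 0:
        errors.append("detection multiplier must be positive")
    if config.amplitude_cutoff_uV <= 0:
        errors.append("amplitude cutoff must be positive")
    if config.consecutive_channel_limit < 1:
        errors.append("consecutive-channel limit must be >= 1")
    if config.bin_width_um <= 0:
        errors.append("bin width must be positive")
    if not (0 < config.q < 1):
        errors.append("q must be in (0, 1)")
    if config.mad_k <= 0:
        errors.append("MAD multiplier must be positive")
    return errors
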