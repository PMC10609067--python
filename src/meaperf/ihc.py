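"""Radial quantification of marker intensity and neuron density around an
implant hole.

Pixels are binned by Euclidean distance from the hole boundary in 50 um
intervals: fluorescence intensity (GFAP, CD68, IgG) out to 700 um, neuron
density out to 500 um.  The outermost intensity bin (650-700 um) defines the
background: GFAP profiles are divided by it (background bin -> 1), while
CD68/IgG — absent in healthy tissue — are background-subtracted folds
((raw - bg) / bg, background bin -> 0).  Neuron density is normalized to the
400-450 um bin.  Group differences are per-bin two-sample Student t-tests;
reporting is limited to 0-350 um (the full range is retained in outputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.draw import polygon2mask
from skimage.measure import label as sk_label, regionprops

from .exceptions import InvalidParameterError, NormalizationError

MARKER_CONVENTIONS = {
    "GFAP": "divide",          # background bin -> 1
    "CD68": "subtract_fold",   # background bin -> 0
    "IgG": "subtract_fold",
    "NeuN-density": "divide",
}

INTENSITY_MAX_UM = 700.0
DENSITY_MAX_UM = 500.0
BIN_WIDTH_UM = 50.0
REPORT_MAX_UM = 350.0


@dataclass
class MaskedImage:
    """16-bit marker image with a hole outline and an artifact mask."""
    image: np.ndarray
    hole_polygon_px: np.ndarray          # (N, 2) (row, col)
    um_per_px: float
    artifact_mask: Optional[np.ndarray] = None   # True = excluded

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.um_per_px <= 0:
            raise InvalidParameterError("pixel scale must be positive")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.image.shape, dtype=bool)


@dataclass
class RadialProfile:
    marker: str
    bin_edges_um: np.ndarray             # len = n_bins + 1, contiguous from 0
    counts: np.ndarray                   # pixels (or cells) per bin
    raw: np.ndarray                      # mean intensity or density per um^2
    normalized: Optional[np.ndarray] = None
    undefined: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def __post_init__(self):
        if self.undefined.size == 0:
            self.undefined = ~np.isfinite(self.raw)

    @property
    def n_bins(self) -> int:
        return len(self.raw)

    def bin_index(self, lo_um: float, hi_um: float) -> int:
        for i in range(self.n_bins):
            if np.isclose(self.bin_edges_um[i], lo_um) and \
                    np.isclose(self.bin_edges_um[i + 1], hi_um):
                return i
        raise KeyError(f"no bin {lo_um}-{hi_um} um")

    def to_frame(self, report_max_um: Optional[float] = None) -> pd.DataFrame:
        frame = pd.DataFrame({
            "marker": self.marker,
            "bin_lo_um": self.bin_edges_um[:-1],
            "bin_hi_um": self.bin_edges_um[1:],
            "n_pixels": self.counts,
            "raw_mean": self.raw,
            "normalized": self.normalized
            if self.normalized is not None else np.nan,
        })
        if report_max_um is not None:
            frame["reported"] = frame["bin_hi_um"] <= report_max_um
        return frame


# --------------------------------------------------------------------------- #
# distance map
# --------------------------------------------------------------------------- #

def hole_distance_um(polygon_px: np.ndarray, shape: Tuple[int, int],
                     um_per_px: float) -> Tuple[np.ndarray, np.ndarray]:
    """(hole mask, per-pixel distance in um from the hole boundary).

    The Euclidean distance transform measures pixel-center to nearest
    hole-pixel-center; half a pixel is subtracted so the distance refers to
    the hole boundary itself.
    """
    poly = np.asarray(polygon_px, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise InvalidParameterError("polygon needs >= 3 vertices")
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0:
        raise InvalidParameterError("degenerate polygon: zero area")
    hole = polygon2mask(shape, poly)
    if not hole.any():
        raise InvalidParameterError("degenerate polygon: empty hole mask")
    dist_px = ndimage.distance_transform_edt(~hole)
    dist_um = np.maximum(dist_px - 0.5, 0.0) * um_per_px
    return hole, dist_um


def distance_map(masked: MaskedImage) -> np.ndarray:
    """Per-pixel distance (um) from the hole boundary; NaN inside the hole."""
    hole, dist_um = hole_distance_um(masked.hole_polygon_px,
                                     masked.image.shape, masked.um_per_px)
    out = dist_um.copy()
    out[hole] = np.nan
    return out


# --------------------------------------------------------------------------- #
# profiles
# --------------------------------------------------------------------------- #

def _bin_edges(max_um: float, bin_width_um: float) -> np.ndarray:
    n_bins = int(round(max_um / bin_width_um))
    return np.linspace(0.0, n_bins * bin_width_um, n_bins + 1)


def intensity_profile(masked: MaskedImage, dist_um: Optional[np.ndarray] = None,
                      marker: str = "", max_um: float = INTENSITY_MAX_UM,
                      bin_width_um: float = BIN_WIDTH_UM) -> RadialProfile:
    """Mean unmasked intensity per 50 um distance bin out to ``max_um``."""
    if dist_um is None:
        dist_um = distance_map(masked)
    if dist_um.shape != masked.image.shape:
        raise InvalidParameterError("distance map shape mismatch")
    edges = _bin_edges(max_um, bin_width_um)
    valid = np.isfinite(dist_um) & ~masked.artifact_mask & (dist_um < max_um)
    idx = np.minimum((dist_um[valid] / bin_width_um).astype(int),
                     len(edges) - 2)
    vals = masked.image[valid]
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    sums = np.bincount(idx, weights=vals, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(marker or "intensity", edges, counts, means,
                         undefined=counts == 0)


def normalize_profile(profile: RadialProfile, marker: Optional[str] = None,
                      mode: Optional[str] = None) -> RadialProfile:
    """Normalize to the outermost (background) bin.

    ``mode`` overrides the marker convention: 'divide' (raw/bg),
    'subtract_fold' ((raw-bg)/bg) or 'subtract' (raw-bg).
    """
    marker = marker or profile.marker
    mode = mode or MARKER_CONVENTIONS.get(marker, "divide")
    bg = profile.raw[-1]
    if not np.isfinite(bg) or bg <= 0:
        raise NormalizationError("background bin undefined or non-positive")
    if mode == "divide":
        norm = profile.raw / bg
    elif mode == "subtract_fold":
        norm = (profile.raw - bg) / bg
    elif mode == "subtract":
        norm = profile.raw - bg
    else:
        raise InvalidParameterError(f"unknown normalization mode {mode!r}")
    return replace(profile, marker=marker, normalized=norm)


def density_profile(centroids_px: np.ndarray, masked: MaskedImage,
                    dist_um: Optional[np.ndarray] = None,
                    max_um: float = DENSITY_MAX_UM,
                    bin_width_um: float = BIN_WIDTH_UM,
                    baseline_bin_um: Tuple[float, float] = (400.0, 450.0),
                    normalize: bool = True) -> RadialProfile:
    """Cell density (per um^2) per 50 um bin, normalized to the baseline bin.

    Counts per bin are divided by the unmasked bin area; centroids on masked
    or in-hole pixels are ignored.
    """
    if dist_um is None:
        dist_um = distance_map(masked)
    edges = _bin_edges(max_um, bin_width_um)
    n_bins = len(edges) - 1

    valid_px = np.isfinite(dist_um) & ~masked.artifact_mask & (dist_um < max_um)
    px_idx = (dist_um[valid_px] / bin_width_um).astype(int)
    px_idx = np.minimum(px_idx, n_bins - 1)
    area_um2 = np.bincount(px_idx, minlength=n_bins) * masked.um_per_px ** 2

    counts = np.zeros(n_bins)
    pts = np.asarray(centroids_px, dtype=float).reshape(-1, 2)
    for r, c in pts:
        ri, ci = int(r), int(c)
        if not (0 <= ri < dist_um.shape[0] and 0 <= ci < dist_um.shape[1]):
            continue
        d = dist_um[ri, ci]
        if not np.isfinite(d) or masked.artifact_mask[ri, ci] or d >= max_um:
            continue
        counts[int(min(d // bin_width_um, n_bins - 1))] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(area_um2 > 0, counts / np.maximum(area_um2, 1e-300),
                           np.nan)
    profile = RadialProfile("NeuN-density", edges, counts, density,
                            undefined=area_um2 == 0)
    if normalize:
        base = density[profile.bin_index(*baseline_bin_um)]
        if not np.isfinite(base) or base <= 0:
            raise NormalizationError("baseline density bin is zero or undefined")
        profile.normalized = density / base
    return profile


# --------------------------------------------------------------------------- #
# per-bin group comparison
# --------------------------------------------------------------------------- #

def per_bin_ttest(profiles_a: Sequence[RadialProfile],
                  profiles_b: Sequence[RadialProfile],
                  report_max_um: float = REPORT_MAX_UM) -> List["TestResult"]:
    """Equal-variance two-sample t-test on normalized values, bin by bin.

    Bins with fewer than 2 defined values in either group are skipped
    (NaN result).  Results beyond ``report_max_um`` are still computed but
    flagged unreported via the label suffix in the output frame.
    """
    from .phases import TestResult
    if not profiles_a or not profiles_b:
        raise InvalidParameterError("need profiles in both groups")
    edges = profiles_a[0].bin_edges_um
    results = []
    for i in range(len(edges) - 1):
        a = np.asarray([p.normalized[i] for p in profiles_a], dtype=float)
        b = np.asarray([p.normalized[i] for p in profiles_b], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        label = f"{edges[i]:.0f}-{edges[i + 1]:.0f}um"
        if len(a) < 2 or len(b) < 2:
            results.append(TestResult(label, np.nan, np.nan))
            continue
        if np.all(np.r_[a, b] == a[0]):
            results.append(TestResult(label, 0.0, 1.0))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        res = TestResult(label, float(t), float(p))
        res.rejected = bool(p < 0.05) if np.isfinite(p) else None
        results.append(res)
    return results


def bin_test_frame(results, report_max_um: float = REPORT_MAX_UM) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.label.replace("um", "").split("-")
        rows.append({"bin_lo_um": float(lo), "bin_hi_um": float(hi),
                     "t": r.statistic, "p": r.pvalue,
                     "significant": r.rejected,
                     "reported": float(hi) <= report_max_um})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# synthetic-fixture blob segmentation
# --------------------------------------------------------------------------- #

def blob_centroids(image: np.ndarray, threshold: Optional[float] = None
                   ) -> np.ndarray:
    """Threshold + connected-components centroid finder.

    A deliberately simple segmenter for synthetic nuclei images only; real
    tissue requires a trained cell segmenter, whose centroid output this
    module consumes directly.
    """
    img = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = img.mean() + 2 * img.std()
    labels = sk_label(img > threshold)
    return np.asarray([p.centroid for p in regionprops(labels)])
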