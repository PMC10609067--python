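"""Phase binning and the study-level statistics on electrode-week records.

Weeks are grouped into the three neuroinflammatory phases (acute 1-5,
sub-chronic 6-11, chronic 12-16).  Active electrode yield (AEY) per
group x phase is the number of active electrode-weeks over the total
electrode-weeks (animals x 16 electrodes x weeks in phase).  Group
differences in AEY use a pooled one-tailed two-proportion z-test; recording
metrics use Kruskal-Wallis followed by pairwise rank tests corrected with the
two-stage Benjamini-Krieger-Yekutieli (BKY) adaptive FDR procedure.
Outliers are removed at 3 median absolute deviations from the median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateTestError, InvalidParameterError

DEFAULT_PHASE_RANGES: Dict[str, Tuple[int, int]] = {
    "acute": (1, 5),
    "sub-chronic": (6, 11),
    "chronic": (12, 16),
}

METRICS = ("vpp_uV", "noise_uV", "snr", "rate_hz")


@dataclass
class TestResult:
    label: str
    statistic: float
    pvalue: float
    tail: str = "two-sided"
    adjusted_p: Optional[float] = None
    rejected: Optional[bool] = None


@dataclass
class PhaseSummary:
    group: str
    phase: str
    aey_numerator: int
    aey_denominator: int
    electrode_means: pd.DataFrame          # per (animal, electrode) phase means
    units_per_active_electrode: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    @property
    def aey(self) -> float:
        return self.aey_numerator / self.aey_denominator


# --------------------------------------------------------------------------- #
# phase binning and aggregation
# --------------------------------------------------------------------------- #

def assign_phase(week: int, phase_ranges: Optional[dict] = None) -> str:
    """Map a study week to its phase; weeks outside every range raise."""
    if week < 0:
        raise InvalidParameterError("week must be >= 0")
    ranges = phase_ranges or DEFAULT_PHASE_RANGES
    for phase, (lo, hi) in ranges.items():
        if lo <= week <= hi:
            return phase
    raise InvalidParameterError(f"week {week} outside the study phase ranges")


def weeks_in_phase(phase: str, phase_ranges: Optional[dict] = None) -> int:
    lo, hi = (phase_ranges or DEFAULT_PHASE_RANGES)[phase]
    return hi - lo + 1


def aggregate_phase(records: pd.DataFrame, group: str, phase: str,
                    phase_ranges: Optional[dict] = None) -> PhaseSummary:
    """Collapse electrode-week records to one group x phase summary.

    * AEY numerator / denominator are tallied over every electrode-week.
    * Metrics are averaged per (animal, electrode) across the phase weeks
      (active weeks contribute; an electrode never active has no mean).
    * units-per-active-electrode = per-electrode unit sum across the phase
      divided by the number of weeks in the phase, for electrodes active at
      least once.
    """
    ranges = phase_ranges or DEFAULT_PHASE_RANGES
    sel = records[(records["group"] == group)
                  & (records["week"].apply(lambda w: assign_phase(w, ranges))
                     == phase)]
    n_weeks = weeks_in_phase(phase, ranges)
    numerator = int(sel["active"].sum())
    denominator = int(len(sel))

    active = sel[sel["active"]]
    if len(active):
        electrode_means = (active.groupby(["animal", "electrode"])[list(METRICS)]
                           .mean().reset_index())
        upae = (sel.groupby(["animal", "electrode"])["n_units"].sum() / n_weeks)
        ever_active = sel.groupby(["animal", "electrode"])["active"].any()
        upae = upae[ever_active].to_numpy(dtype=float)
    else:
        electrode_means = pd.DataFrame(columns=["animal", "electrode", *METRICS])
        upae = np.empty(0)
    return PhaseSummary(group, phase, numerator, denominator,
                        electrode_means, upae)


def units_per_active_electrode(unit_counts: Sequence[float],
                               n_weeks: int) -> float:
    """Per-electrode phase value: summed units over the phase / weeks in phase."""
    if n_weeks <= 0:
        raise InvalidParameterError("weeks in phase must be positive")
    return float(np.sum(unit_counts) / n_weeks)


# --------------------------------------------------------------------------- #
# outlier removal
# --------------------------------------------------------------------------- #

def mad_outlier_filter(values: Sequence[float], k: float = 3.0,
                       consistency: float = 1.0) -> np.ndarray:
    """Remove values more than ``k`` median absolute deviations from the median.

    The MAD is used plainly (no 1.4826 normal-consistency factor) by default;
    pass ``consistency=1.4826`` for the scaled variant.  A zero MAD removes
    nothing and warns.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise InvalidParameterError("need at least 3 values")
    med = np.median(x)
    mad = consistency * np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers removed", RuntimeWarning)
        return x
    return x[np.abs(x - med) <= k * mad]


# --------------------------------------------------------------------------- #
# tests
# --------------------------------------------------------------------------- #

def two_proportion_ztest(p1: float, n1: int, p2: float, n2: int,
                         tail: str = "greater", label: str = "") -> TestResult:
    """Pooled two-proportion z-test, no continuity correction.

    z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)) with
    pbar = (n1 p1 + n2 p2) / (n1 + n2).  ``tail='greater'`` takes the upper
    normal tail (tests p1 > p2); 'less' and 'two-sided' are available.
    Proportions may be passed as rates so printed rounded percentages can be
    used directly.
    """
    if n1 <= 0 or n2 <= 0:
        raise InvalidParameterError("sample sizes must be positive")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise InvalidParameterError("proportions must lie in [0, 1]")
    pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateTestError("pooled proportion of 0 or 1")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    if tail == "greater":
        p = stats.norm.sf(z)
    elif tail == "less":
        p = stats.norm.cdf(z)
    elif tail == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    else:
        raise InvalidParameterError(f"unknown tail {tail!r}")
    return TestResult(label or "two-proportion z", float(z), float(p), tail)


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   label: str = "") -> TestResult:
    """Kruskal-Wallis H with tie correction; all-identical data give H=0, p=1."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise InvalidParameterError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return TestResult(label or "kruskal-wallis", 0.0, 1.0)
    h, p = stats.kruskal(*groups)
    return TestResult(label or "kruskal-wallis", float(h), float(p))


# --------------------------------------------------------------------------- #
# two-stage BKY FDR
# --------------------------------------------------------------------------- #

def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejection flags."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(m, dtype=bool)
    if len(passed):
        reject[order[:passed[-1] + 1]] = True
    return reject


def bky_fdr(p_values: Sequence[float], q: float = 0.05
            ) -> Tuple[np.ndarray, np.ndarray]:
    """Two-stage Benjamini-Krieger-Yekutieli adaptive linear step-up.

    Stage 1 runs BH at q' = q / (1 + q); the number of stage-1 rejections r1
    estimates the number of true nulls as m0 = m - r1.  Stage 2 reruns the
    step-up with thresholds i * q' / m0.  Returns (rejection flags,
    adjusted values such that ``adjusted <= q`` reproduces the flags).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = len(p)
    q_prime = q / (1.0 + q)
    stage1 = _bh_reject(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        reject = np.zeros(m, dtype=bool)
        m0 = m
    elif r1 == m:
        reject = np.ones(m, dtype=bool)
        m0 = 1
    else:
        m0 = m - r1
        reject = _bh_reject(p * m0 / m, q_prime)  # thresholds i*q'/m0

    # step-up adjusted values: min_{j >= i} m0 (1+q) p_(j) / j, capped at 1
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m0 * (1.0 + q) / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    if r1 == m:
        adjusted = np.minimum(adjusted, q)
    return reject, adjusted


# --------------------------------------------------------------------------- #
# comparison families
# --------------------------------------------------------------------------- #

def allowed_contrasts(groups: Sequence[str], phases: Sequence[str]
                      ) -> List[Tuple[Tuple[str, str], Tuple[str, str]]]:
    """Within-phase between-group and within-group across-phase contrasts only.

    Cross-group cross-phase cells (e.g. acute control vs chronic treatment)
    carry no information about efficacy and are excluded by design.
    """
    contrasts = []
    for ph in phases:
        for ga, gb in combinations(groups, 2):
            contrasts.append(((ga, ph), (gb, ph)))
    for g in groups:
        for pa, pb in combinations(phases, 2):
            contrasts.append(((g, pa), (g, pb)))
    return contrasts


def check_contrast(cell_a: Tuple[str, str], cell_b: Tuple[str, str]) -> None:
    if cell_a[0] != cell_b[0] and cell_a[1] != cell_b[1]:
        raise InvalidParameterError(
            "cross-group cross-phase comparisons are not permitted")


def _dunn_z(values: dict, cell_a, cell_b) -> Tuple[float, float]:
    """Dunn's post-hoc z on pooled ranks across all cells (two-sided)."""
    cells = list(values)
    pooled = np.concatenate([np.asarray(values[c], dtype=float) for c in cells])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    offsets, pos = {}, 0
    for c in cells:
        offsets[c] = slice(pos, pos + len(values[c]))
        pos += len(values[c])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    na, nb = len(values[cell_a]), len(values[cell_b])
    mean_a = ranks[offsets[cell_a]].mean()
    mean_b = ranks[offsets[cell_b]].mean()
    se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / na + 1 / nb))
    z = (mean_a - mean_b) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def pairwise_phase_comparisons(values: Dict[Tuple[str, str], Sequence[float]],
                               q: float = 0.05, method: str = "mannwhitney",
                               gate_on_kw: bool = False) -> List[TestResult]:
    """Pairwise rank tests over the allowed contrast family, BKY-corrected.

    ``values`` maps (group, phase) -> metric values.  Pairwise statistics are
    Mann-Whitney rank-sum tests by default (``method='dunn'`` for Dunn's
    pooled-rank z).  With ``gate_on_kw`` the family is only tested when the
    omnibus Kruskal-Wallis across cells is significant at ``q``.
    """
    groups = sorted({g for g, _ in values})
    phase_order = list(DEFAULT_PHASE_RANGES)
    phases = sorted({p for _, p in values},
                    key=lambda p: phase_order.index(p)
                    if p in phase_order else len(phase_order))
    contrasts = [c for c in allowed_contrasts(groups, phases)
                 if c[0] in values and c[1] in values]

    if gate_on_kw:
        kw = kruskal_wallis([values[c] for c in values])
        if kw.pvalue >= q:
            return [TestResult(f"{a[0]}/{a[1]} vs {b[0]}/{b[1]}", np.nan,
                               np.nan, adjusted_p=np.nan, rejected=False)
                    for a, b in contrasts]

    results = []
    for cell_a, cell_b in contrasts:
        check_contrast(cell_a, cell_b)
        a = np.asarray(values[cell_a], dtype=float)
        b = np.asarray(values[cell_b], dtype=float)
        label = f"{cell_a[0]}/{cell_a[1]} vs {cell_b[0]}/{cell_b[1]}"
        if np.all(np.concatenate([a, b]) == a[0] if len(a) else True):
            stat, p = 0.0, 1.0
        elif method == "mannwhitney":
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        elif method == "dunn":
            stat, p = _dunn_z(values, cell_a, cell_b)
        else:
            raise InvalidParameterError(f"unknown method {method!r}")
        results.append(TestResult(label, float(stat), float(p)))

    reject, adjusted = bky_fdr([r.pvalue for r in results], q)
    for r, rej, adj in zip(results, reject, adjusted):
        r.adjusted_p = float(adj)
        r.rejected = bool(rej)
    return results


def phase_summary_frame(summaries: Sequence[PhaseSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.group, "phase": s.phase,
        "aey_numerator": s.aey_numerator,
        "aey_denominator": s.aey_denominator,
        "aey": s.aey,
        "mean_units_per_active_electrode":
            float(np.mean(s.units_per_active_electrode))
            if len(s.units_per_active_electrode) else np.nan,
    } for s in summaries])


def test_results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "comparison": r.label, "statistic": r.statistic, "tail": r.tail,
        "p": r.pvalue, "adjusted_p": r.adjusted_p, "rejected": r.rejected,
    } for r in results])
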