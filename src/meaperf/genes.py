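"""nCounter-style count normalization and differential expression.

The chain follows digital-counting convention: per-sample scale factors from
the positive-control probes (assay efficiency), a negative-control background
level (mean + 2 SD per sample, used only to flag genes), per-sample factors
from the housekeeping genes (RNA content), removal of genes with fewer than
20 counts in at least 85% of samples, then per-gene Welch t-tests on
log2(normalized + 1) with Benjamini-Hochberg correction at FDR 0.05.
Log2FoldChange is the log2 ratio of normalized group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidParameterError, NormalizationError

GENE_CLASSES = ("endogenous", "housekeeping", "positive", "negative")


@dataclass
class CountMatrix:
    """Gene x sample counts with per-gene classes and per-sample groups."""
    counts: pd.DataFrame                 # genes x samples
    gene_class: pd.Series                # gene -> class
    groups: pd.Series                    # sample -> group label
    background_flags: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        unknown = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if unknown:
            raise InvalidParameterError(f"unknown gene classes: {unknown}")
        if self.groups.nunique() < 1 or self.groups.value_counts().min() < 1:
            raise InvalidParameterError("groups must be non-empty")

    def genes_of(self, cls: str) -> pd.Index:
        return self.gene_class.index[self.gene_class == cls]

    def to_csv(self, counts_path, groups_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_class", self.gene_class)
        out.to_csv(counts_path, index_label="gene")
        if groups_path is not None:
            self.groups.rename("group").to_csv(groups_path, index_label="sample")

    @classmethod
    def from_csv(cls, counts_path, groups_path) -> "CountMatrix":
        table = pd.read_csv(counts_path, index_col="gene")
        gene_class = table.pop("gene_class")
        groups = pd.read_csv(groups_path, index_col="sample")["group"]
        return cls(table, gene_class, groups)


@dataclass
class DEResult:
    table: pd.DataFrame     # gene, class, kept, log2fc, p, q, significant

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"].fillna(False)]


# --------------------------------------------------------------------------- #
# normalization
# --------------------------------------------------------------------------- #

def _geomean(frame: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of the rows (zeros propagate to zero)."""
    vals = frame.to_numpy(dtype=float)
    if (vals <= 0).any():
        if (vals == 0).all(axis=0).any():
            return pd.Series(0.0, index=frame.columns)
        vals = np.where(vals > 0, vals, np.nan)
        out = np.exp(np.nanmean(np.log(vals), axis=0))
        out[np.isnan(out)] = 0.0
        return pd.Series(out, index=frame.columns)
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=frame.columns)


def _scale_factors(cm: CountMatrix, cls: str, agg: str) -> pd.Series:
    rows = cm.genes_of(cls)
    if len(rows) == 0:
        raise NormalizationError(f"no {cls} genes present")
    geo = _geomean(cm.counts.loc[rows])
    if (geo <= 0).any():
        raise NormalizationError(f"zero {cls} geometric mean in some sample")
    if agg == "geometric":
        reference = float(np.exp(np.log(geo).mean()))
    elif agg == "arithmetic":
        reference = float(geo.mean())
    else:
        raise InvalidParameterError(f"unknown aggregation {agg!r}")
    return reference / geo


def positive_control_normalize(cm: CountMatrix, agg: str = "geometric"
                               ) -> Tuple[CountMatrix, pd.Series]:
    """Scale every sample by reference / (its positive-control geometric mean).

    With the default geometric reference the factors' geometric mean is 1 by
    construction.  All probe classes are rescaled (assay efficiency affects
    every probe).
    """
    factors = _scale_factors(cm, "positive", agg)
    return replace(cm, counts=cm.counts * factors), factors


def housekeeping_normalize(cm: CountMatrix, agg: str = "geometric"
                           ) -> Tuple[CountMatrix, pd.Series]:
    """Scale endogenous + housekeeping probes by housekeeping-derived factors
    (RNA content per sample); control probes are left untouched."""
    factors = _scale_factors(cm, "housekeeping", agg)
    counts = cm.counts.copy()
    rows = cm.gene_class.isin(["endogenous", "housekeeping"])
    counts.loc[rows] = counts.loc[rows] * factors
    return replace(cm, counts=counts), factors


def background_threshold(cm: CountMatrix, n_sd: float = 2.0
                         ) -> Tuple[pd.Series, pd.DataFrame]:
    """Per-sample background = mean + n_sd * SD of the negative controls.

    Endogenous counts at or below their sample's background are flagged
    (inclusive boundary); flagged genes are reported, not altered.  SD uses
    ddof=1.  Returns (background per sample, boolean flag frame).
    """
    negatives = cm.genes_of("negative")
    if len(negatives) == 0:
        import warnings
        warnings.warn("no negative controls; background flagging skipped",
                      RuntimeWarning)
        empty = pd.DataFrame(False, index=cm.genes_of("endogenous"),
                             columns=cm.counts.columns)
        return pd.Series(np.nan, index=cm.counts.columns), empty
    neg = cm.counts.loc[negatives]
    background = neg.mean(axis=0) + n_sd * neg.std(axis=0, ddof=1)
    background = background.fillna(neg.mean(axis=0))
    endo = cm.counts.loc[cm.genes_of("endogenous")]
    flags = endo.le(background, axis=1)
    return background, flags


# --------------------------------------------------------------------------- #
# filtering
# --------------------------------------------------------------------------- #

def low_count_filter(cm: CountMatrix, threshold: float = 20.0,
                     fraction: float = 0.85, rule: str = "remove_if_low"
                     ) -> Tuple[CountMatrix, list]:
    """Remove endogenous genes with fewer than ``threshold`` counts in at
    least ``fraction`` of the samples.

    ``rule='keep_if_high'`` applies the complementary reading (kept only when
    >= fraction of samples reach the threshold).  Control and housekeeping
    probes are never removed here.  Returns (filtered matrix, removed genes).
    """
    endo = cm.genes_of("endogenous")
    low_frac = (cm.counts.loc[endo] < threshold).mean(axis=1)
    if rule == "remove_if_low":
        removed = endo[low_frac >= fraction].tolist()
    elif rule == "keep_if_high":
        removed = endo[(1 - low_frac) < fraction].tolist()
    else:
        raise InvalidParameterError(f"unknown rule {rule!r}")
    keep = cm.counts.index.difference(removed, sort=False)
    filtered = replace(cm, counts=cm.counts.loc[keep],
                       gene_class=cm.gene_class.loc[keep])
    return filtered, removed


# --------------------------------------------------------------------------- #
# differential expression
# --------------------------------------------------------------------------- #

def log2_fold_change(cm: CountMatrix, treatment: str = "treatment",
                     control: str = "control") -> pd.Series:
    """Per-gene log2(treated mean / control mean) on normalized counts;
    a zero group mean gives NaN (flagged downstream)."""
    t_cols = cm.groups.index[cm.groups == treatment]
    c_cols = cm.groups.index[cm.groups == control]
    if len(t_cols) == 0 or len(c_cols) == 0:
        raise InvalidParameterError("both groups must be present")
    mt = cm.counts[t_cols].mean(axis=1)
    mc = cm.counts[c_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mt / mc)
    lfc[(mt <= 0) | (mc <= 0)] = np.nan
    return lfc


def de_test(cm: CountMatrix, treatment: str = "treatment",
            control: str = "control", q: float = 0.05,
            log_transform: bool = True) -> DEResult:
    """Welch t-test per kept endogenous gene, BH-corrected at FDR ``q``.

    Tests run on log2(normalized + 1) by default (raw scale optional).
    Zero variance in both groups with equal means yields p = 1.
    """
    endo = cm.genes_of("endogenous")
    t_cols = cm.groups.index[cm.groups == treatment]
    c_cols = cm.groups.index[cm.groups == control]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise InvalidParameterError("need >= 2 samples per group")

    data = cm.counts.loc[endo]
    lfc = log2_fold_change(cm, treatment, control).loc[endo]
    x = np.log2(data[t_cols].to_numpy(dtype=float) + 1) if log_transform \
        else data[t_cols].to_numpy(dtype=float)
    y = np.log2(data[c_cols].to_numpy(dtype=float) + 1) if log_transform \
        else data[c_cols].to_numpy(dtype=float)

    pvals = np.empty(len(endo))
    tstats = np.empty(len(endo))
    for i in range(len(endo)):
        a, b = x[i], y[i]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            tstats[i], pvals[i] = (0.0, 1.0) if a.mean() == b.mean() \
                else (np.inf, 0.0)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        tstats[i], pvals[i] = t, p

    reject, qvals, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    table = pd.DataFrame({
        "gene_class": "endogenous",
        "kept": True,
        "log2fc": lfc,
        "t": tstats,
        "p": pvals,
        "q": qvals,
        "significant": reject,
    }, index=endo)
    return DEResult(table)


def de_pipeline(cm: CountMatrix, q: float = 0.05, threshold: float = 20.0,
                fraction: float = 0.85, agg: str = "geometric",
                log_transform: bool = True,
                treatment: str = "treatment", control: str = "control"
                ) -> Tuple[DEResult, dict]:
    """Full chain: positive-control normalization -> background flagging ->
    housekeeping normalization -> low-count filter -> Welch/BH DE.

    The low-count filter operates on normalized counts.  Returns the DE
    result (with removed genes recorded as kept=False) and a dict of
    intermediates (factors, background, flags, removed).
    """
    normed, pos_factors = positive_control_normalize(cm, agg)
    background, flags = background_threshold(normed)
    normed, hk_factors = housekeeping_normalize(normed, agg)
    filtered, removed = low_count_filter(normed, threshold, fraction)
    result = de_test(filtered, treatment, control, q, log_transform)
    if removed:
        dropped = pd.DataFrame({
            "gene_class": "endogenous", "kept": False, "log2fc": np.nan,
            "t": np.nan, "p": np.nan, "q": np.nan, "significant": False,
        }, index=pd.Index(removed, name=result.table.index.name))
        result = DEResult(pd.concat([result.table, dropped]))
    extras = {"positive_factors": pos_factors, "hk_factors": hk_factors,
              "background": background, "background_flags": flags,
              "removed": removed, "normalized": filtered}
    return result, extras
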