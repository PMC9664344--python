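"""Normalization and cell-type composition scoring.

Counts are normalized by median-of-ratios size factors (the default DESeq2
normalization): each sample's factor is the median, over genes with a
positive geometric mean across samples, of the ratio of its count to that
per-gene geometric-mean reference.  A sample's cell-type abundance is then
scored as the geometric mean of normalized counts over a marker panel, and
groups are compared with the exact two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import EXACT_CAP, wilcoxon_exact
from .types import CountMatrix, GroupComparison, MarkerPanel

logger = logging.getLogger(__name__)

__all__ = [
    "MedianOfRatiosNormalizer",
    "GeometricMarkerScorer",
    "size_factors",
    "normalize",
    "marker_score",
    "compare_groups",
    "proportions",
]


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return pd.DataFrame(counts)


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios (DESeq2-style) count normalization.

    The transformer operates on genes x samples DataFrames (the container
    orientation of this package, not the scikit-learn samples x features
    convention).  ``fit`` estimates per-sample size factors against the
    per-gene geometric-mean reference; genes with any zero count (zero
    geometric mean) are excluded from the median.  ``transform`` divides
    each sample's counts by its factor.

    Attributes
    ----------
    size_factors_ : pd.Series
        Positive per-sample scale factors.
    n_reference_genes_ : int
        Number of genes entering the median (non-zero in every sample).
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        values = X.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        nonzero = (values > 0).all(axis=1)
        if not nonzero.any():
            raise ValueError(
                "size factors undefined: no gene has non-zero counts in every sample"
            )
        logref = np.log(values[nonzero]).mean(axis=1, keepdims=True)
        ratios = np.log(values[nonzero]) - logref
        factors = np.exp(np.median(ratios, axis=0))
        self.size_factors_ = pd.Series(factors, index=X.columns, name="size_factor")
        self.n_reference_genes_ = int(nonzero.sum())
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        missing = X.columns.difference(self.size_factors_.index)
        if len(missing):
            raise ValueError(f"no size factor for samples: {missing.tolist()}")
        return X / self.size_factors_[X.columns]


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors for a genes x samples count matrix."""
    return MedianOfRatiosNormalizer().fit(counts).size_factors_


def normalize(counts, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    X = _as_frame(counts)
    factors = pd.Series(factors)
    missing = X.columns.difference(factors.index)
    if len(missing):
        raise ValueError(f"no size factor for samples: {missing.tolist()}")
    if (factors <= 0).any():
        raise ValueError("size factors must be > 0")
    return X / factors[X.columns]


class GeometricMarkerScorer(BaseEstimator, TransformerMixin):
    """Geometric-mean marker score per sample for one or more panels.

    ``transform`` maps a normalized genes x samples matrix to a tidy frame
    of per-sample scores: the geometric mean of ``normalized + pseudocount``
    over the panel genes, computed in log space so large panels neither
    overflow nor underflow.  With ``pseudocount=0`` a single zero count
    zeroes the score.

    Panel genes absent from the matrix are dropped with a logged warning;
    a panel with no genes present raises.
    """

    def __init__(self, panels: list[MarkerPanel] | MarkerPanel = (), pseudocount: float = 0.0):
        self.panels = panels
        self.pseudocount = pseudocount

    def _panel_list(self) -> list[MarkerPanel]:
        if isinstance(self.panels, MarkerPanel):
            return [self.panels]
        return list(self.panels)

    def fit(self, X, y=None):
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not self._panel_list():
            raise ValueError("at least one marker panel is required")
        return self

    def transform(self, X) -> pd.DataFrame:
        self.fit(X)
        X = _as_frame(X)
        rows = []
        self.dropped_genes_: dict[str, list[str]] = {}
        for panel in self._panel_list():
            present = [g for g in panel.genes if g in X.index]
            absent = [g for g in panel.genes if g not in X.index]
            if absent:
                logger.warning(
                    "panel %r: dropping %d genes absent from the matrix: %s",
                    panel.cell_type, len(absent), absent,
                )
            self.dropped_genes_[panel.cell_type] = absent
            if not present:
                raise ValueError(
                    f"no gene of panel {panel.cell_type!r} is present in the matrix"
                )
            vals = X.loc[present].to_numpy(dtype=float) + self.pseudocount
            with np.errstate(divide="ignore"):
                logvals = np.log(vals)
            scores = np.exp(logvals.mean(axis=0))
            scores[np.isneginf(logvals).any(axis=0)] = 0.0
            for sample, score in zip(X.columns, scores):
                rows.append(
                    {
                        "sample": sample,
                        "cell_type": panel.cell_type,
                        "score": float(score),
                        "n_markers": len(present),
                    }
                )
        return pd.DataFrame(rows)


def marker_score(normalized, panel: MarkerPanel, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-sample geometric-mean score of a marker panel.

    Returns a tidy DataFrame with columns (sample, cell_type, score,
    n_markers).
    """
    return GeometricMarkerScorer(panel, pseudocount).fit(normalized).transform(normalized)


def compare_groups(scores, groups, exact_cap: int = EXACT_CAP) -> GroupComparison:
    """Compare per-sample scores between exactly two groups.

    Delegates to the exact two-sided Wilcoxon rank-sum test; returns the
    test result together with per-group medians.  Group order follows
    first appearance in ``groups``.
    """
    scores = pd.Series(np.asarray(scores, dtype=float))
    groups = pd.Series(list(groups))
    if len(scores) != len(groups):
        raise ValueError("scores and groups must have equal length")
    names = list(dict.fromkeys(groups))
    if len(names) != 2:
        raise ValueError(f"exactly two groups are required, got {names}")
    x = scores[groups.values == names[0]].to_numpy()
    y = scores[groups.values == names[1]].to_numpy()
    result = wilcoxon_exact(x, y, exact_cap=exact_cap)
    medians = {names[0]: float(np.median(x)), names[1]: float(np.median(y))}
    return GroupComparison(result, (names[0], names[1]), medians)


def proportions(count_table: pd.DataFrame) -> pd.DataFrame:
    """Per-donor marker-positive cell proportions.

    ``count_table`` needs columns ``positive`` and ``total`` (plus any
    identifier columns such as donor, group, marker, which are passed
    through).  Returns the table with a ``proportion`` column appended.
    """
    t = pd.DataFrame(count_table).copy()
    for col in ("positive", "total"):
        if col not in t.columns:
            raise ValueError(f"count table missing column {col!r}")
    if (t["total"] <= 0).any():
        raise ValueError("total cell counts must be > 0")
    if (t["positive"] < 0).any():
        raise ValueError("positive cell counts must be >= 0")
    bad = t["positive"] > t["total"]
    if bad.any():
        raise ValueError(
            f"positive exceeds total in rows: {t.index[bad].tolist()}"
        )
    t["proportion"] = t["positive"] / t["total"]
    return t
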