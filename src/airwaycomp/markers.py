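"""Consensus cell-type marker discovery from correlation structure.

The pipeline assumes that genes consistently associated with a cell type
co-correlate across bulk samples, because samples are mixtures of cell
types in varying proportions.  Discovery proceeds in three stages:

1. *candidate selection* — genes significantly over-expressed in the
   target cell type in a cell-labelled matrix (one-vs-rest rank-sum test,
   Benjamini-Hochberg FDR < 0.01, and higher mean in the target);
2. *main co-correlating cluster* — per cohort, average-linkage
   hierarchical clustering of the candidate-gene similarity matrix
   (Pearson correlation of log2(normalized count + 1)) cut at correlation
   distance 1 - min_mean_r; the largest qualifying cluster is kept;
3. *consensus* — the intersection of the main clusters across all
   age-stratified cohorts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator

from .composition import MedianOfRatiosNormalizer
from .stats import benjamini_hochberg
from .types import CountMatrix, MarkerPanel, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RankSumMarkerSelector",
    "ConsensusMarkerFinder",
    "select_candidates",
    "similarity_matrix",
    "main_cluster",
    "consensus_markers",
]

NO_CLUSTER_STATUS = "no co-correlating cluster"


class RankSumMarkerSelector(BaseEstimator):
    """One-vs-rest over-expression screen for candidate cell-type markers.

    Fit on a cells x genes matrix ``X`` with cell-type labels ``y``.  For
    every gene a two-sided Wilcoxon rank-sum test compares the target cells
    against all others (tie-corrected normal approximation, appropriate at
    cell-level sample sizes); p-values are Benjamini-Hochberg adjusted
    across genes, and a gene is retained iff its q-value is below
    ``fdr_threshold`` *and* its mean library-size-normalized expression is
    higher in the target cells (over-expressed, not merely different).

    Parameters
    ----------
    cell_type : str
        Target label in ``y``.
    fdr_threshold : float, default 0.01
        BH q-value cutoff.
    library_size_normalize : bool, default True
        Scale each cell by (total counts / median total counts) before
        testing and computing means.  Median-of-ratios normalization is
        undefined at cell level (few genes are non-zero in every cell).

    Attributes
    ----------
    pvalues_, qvalues_ : np.ndarray per gene
    overexpressed_ : boolean array, mean higher in target
    support_ : boolean array, retained genes
    markers_ : list of retained gene names (input order)
    """

    def __init__(self, cell_type: str, fdr_threshold: float = 0.01,
                 library_size_normalize: bool = True):
        self.cell_type = cell_type
        self.fdr_threshold = fdr_threshold
        self.library_size_normalize = library_size_normalize

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("labels must match the number of cells (rows)")
        labels = set(y)
        if len(labels) < 2:
            raise ValueError("at least two cell-type labels are required")
        if self.cell_type not in labels:
            raise ValueError(f"target label {self.cell_type!r} not present in labels")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must lie in (0, 1]")

        values = X.to_numpy(dtype=float)
        if self.library_size_normalize:
            libsize = values.sum(axis=1)
            if (libsize <= 0).any():
                raise ValueError("every cell must have positive total counts")
            values = values / (libsize / np.median(libsize))[:, None]

        target = values[y == self.cell_type]
        rest = values[y != self.cell_type]
        res = mannwhitneyu(
            target, rest, axis=0, alternative="two-sided", method="asymptotic"
        )
        pvals = np.clip(res.pvalue, np.finfo(float).tiny, 1.0)
        self.pvalues_ = pvals
        self.qvalues_ = benjamini_hochberg(pvals)
        self.overexpressed_ = target.mean(axis=0) > rest.mean(axis=0)
        self.support_ = (self.qvalues_ < self.fdr_threshold) & self.overexpressed_
        self.feature_names_in_ = np.asarray(X.columns)
        self.markers_ = [g for g, keep in zip(X.columns, self.support_) if keep]
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def to_panel(self) -> MarkerPanel:
        return MarkerPanel(self.cell_type, self.markers_, stage="candidate")


def select_candidates(
    cells: CountMatrix,
    cell_type: str,
    fdr_threshold: float = 0.01,
    label_column: str = "label",
    exclude_genes=(),
) -> MarkerPanel:
    """Candidate markers of ``cell_type`` from a cell-labelled count matrix.

    ``exclude_genes`` supports pre-filters such as removing sex-chromosome
    genes (see :func:`sex_chromosome_genes`).
    """
    labels = cells.labels(label_column)
    counts = cells.counts
    if exclude_genes:
        counts = counts.drop(index=[g for g in exclude_genes if g in counts.index])
    selector = RankSumMarkerSelector(cell_type, fdr_threshold)
    selector.fit(counts.T, labels.to_numpy())
    return selector.to_panel()


def sex_chromosome_genes(chromosome_map: pd.DataFrame,
                         chromosomes=("X", "Y", "chrX", "chrY")) -> list[str]:
    """Genes on the given chromosomes, from a (gene, chromosome) table.

    Used to exclude sex-linked genes before candidate selection so sex
    imbalance between groups does not masquerade as cell-type signal.
    """
    m = pd.DataFrame(chromosome_map)
    if not {"gene", "chromosome"} <= set(m.columns):
        raise ValueError("chromosome map needs columns 'gene' and 'chromosome'")
    return m.loc[m["chromosome"].isin(chromosomes), "gene"].tolist()


def similarity_matrix(counts: CountMatrix, genes) -> SimilarityMatrix:
    """Pairwise Pearson correlation of log2(normalized count + 1).

    Counts are size-factor normalized first, so the similarity is invariant
    to per-sample sequencing depth.  Genes with zero variance across
    samples get correlation 0 to all others and are flagged.
    """
    genes = list(genes)
    frame = counts.counts if isinstance(counts, CountMatrix) else pd.DataFrame(counts)
    if frame.shape[1] < 3:
        raise ValueError("at least 3 samples are required for a similarity matrix")
    missing = [g for g in genes if g not in frame.index]
    if missing:
        raise KeyError(f"genes absent from the count matrix: {missing}")
    if len(set(genes)) != len(genes):
        raise ValueError("requested gene list contains duplicates")

    norm = MedianOfRatiosNormalizer().fit_transform(frame)
    logexpr = np.log2(norm.loc[genes].to_numpy(dtype=float) + 1.0)

    sd = logexpr.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(logexpr)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0

    values = pd.DataFrame(r, index=genes, columns=genes)
    return SimilarityMatrix(genes, values, [g for g, f in zip(genes, flat) if f])


def main_cluster(
    sim: SimilarityMatrix,
    linkage: str = "average",
    min_mean_r: float = 0.5,
    cell_type: str = "cell_type",
) -> MarkerPanel:
    """Extract the main co-correlating cluster from a similarity matrix.

    Agglomerative clustering on distance 1 - r, tree cut at distance
    1 - ``min_mean_r``.  Among clusters with at least two members and mean
    pairwise correlation >= ``min_mean_r``, the largest is returned; ties
    break toward higher mean correlation, then the lexicographically first
    member.  If no cluster qualifies an empty panel is returned with
    status ``"no co-correlating cluster"`` rather than an exception.
    """
    genes = list(sim.genes)
    if len(genes) < 2:
        raise ValueError("at least two genes are required for clustering")
    r = sim.values.to_numpy(dtype=float)
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = scipy_linkage(squareform(dist, checks=False), method=linkage)
    assignments = fcluster(Z, t=1.0 - min_mean_r, criterion="distance")

    best: tuple[int, float, str] | None = None
    best_members: list[str] = []
    for cid in np.unique(assignments):
        members_idx = np.flatnonzero(assignments == cid)
        if members_idx.size < 2:
            continue
        sub = r[np.ix_(members_idx, members_idx)]
        mean_r = sub[np.triu_indices_from(sub, k=1)].mean()
        if mean_r < min_mean_r:
            continue
        members = [genes[i] for i in members_idx]
        # rank: larger cluster, then higher mean r, then earliest first member
        key = (members_idx.size, mean_r, min(members))
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
        ):
            best = key
            best_members = members
    if best is None:
        return MarkerPanel(cell_type, [], stage="main_cluster", status=NO_CLUSTER_STATUS)
    return MarkerPanel(cell_type, best_members, stage="main_cluster")


class ConsensusMarkerFinder(BaseEstimator):
    """Consensus markers: genes in the main co-correlating cluster of every cohort.

    ``fit`` takes a list of cohort :class:`CountMatrix` objects and a
    candidate :class:`MarkerPanel`; it runs the similarity matrix and
    main-cluster extraction per cohort and intersects the results, reported
    in candidate order.

    Attributes
    ----------
    consensus_ : MarkerPanel (stage ``consensus``)
    cohort_panels_ : list of per-cohort main-cluster panels (diagnostics)
    dropped_genes_ : candidate genes missing from at least one cohort
    """

    def __init__(self, linkage: str = "average", min_mean_r: float = 0.5):
        self.linkage = linkage
        self.min_mean_r = min_mean_r

    def fit(self, cohorts: list[CountMatrix], candidates: MarkerPanel):
        if len(cohorts) < 2:
            raise ValueError("at least two cohorts are required for a consensus")
        if not candidates.genes:
            raise ValueError("candidate panel is empty")

        present = list(candidates.genes)
        dropped: list[str] = []
        for cm in cohorts:
            frame = cm.counts if isinstance(cm, CountMatrix) else pd.DataFrame(cm)
            here = set(frame.index)
            lost = [g for g in present if g not in here]
            if lost:
                dropped.extend(lost)
                present = [g for g in present if g in here]
        if dropped:
            logger.warning("dropping candidate genes missing from some cohort: %s",
                           sorted(set(dropped)))
        if not present:
            raise ValueError("no candidate gene is present in every cohort")
        self.dropped_genes_ = sorted(set(dropped))

        self.cohort_panels_ = []
        kept: set[str] | None = None
        for cm in cohorts:
            sim = similarity_matrix(cm, present)
            panel = main_cluster(sim, linkage=self.linkage,
                                 min_mean_r=self.min_mean_r,
                                 cell_type=candidates.cell_type)
            self.cohort_panels_.append(panel)
            members = set(panel.genes)
            kept = members if kept is None else kept & members

        consensus = [g for g in candidates.genes if g in (kept or set())]
        status = "ok"
        if not consensus:
            empty = [i for i, p in enumerate(self.cohort_panels_) if not p.genes]
            status = (
                f"empty consensus; cohorts with no co-correlating cluster: {empty}"
                if empty else "empty consensus: main clusters do not intersect"
            )
        self.consensus_ = MarkerPanel(candidates.cell_type, consensus,
                                      stage="consensus", status=status)
        return self


def consensus_markers(
    cohorts: list[CountMatrix],
    candidates: MarkerPanel,
    linkage: str = "average",
    min_mean_r: float = 0.5,
) -> MarkerPanel:
    """Intersection of per-cohort main co-correlating clusters (candidate order)."""
    finder = ConsensusMarkerFinder(linkage=linkage, min_mean_r=min_mean_r)
    finder.fit(cohorts, candidates)
    return finder.consensus_
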