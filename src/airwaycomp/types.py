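"""Core value containers shared across the pipeline.

The central container is :class:`CountMatrix`, a genes-by-samples (or
genes-by-cells) non-negative count table with optional per-sample metadata.
Marker panels, statistical test results, and competitive co-culture records
are small validated dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "MarkerPanel",
    "TestResult",
    "GroupComparison",
    "SimilarityMatrix",
    "CellTypeProfile",
    "MixtureSample",
    "MixtureDesign",
    "CoculturePar",
    "CocultureObservation",
    "DoublingCurve",
    "GrowthAdvantageResult",
    "PANEL_STAGES",
]

PANEL_STAGES = ("candidate", "main_cluster", "consensus")

#: orientation values: which fluorescent color the focal population carries
ORIENTATIONS = ("color1", "color2")


@dataclass
class CountMatrix:
    """Genes x samples count table with optional sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene name, one column per sample (or cell).
        Values must be non-negative and finite.
    metadata
        Optional DataFrame indexed by sample name.  Typical columns:
        ``cohort`` (age-stratified dataset label), ``donor``, ``label``
        (cell-type label for cell-level matrices), ``depth``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene names: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample names: {dups}")
        values = self.counts.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("counts contain non-finite values")
        if (values < 0).any():
            bad = self.counts.columns[(values < 0).any(axis=0)].tolist()
            raise ValueError(f"negative counts in samples: {bad}")
        if self.metadata is not None:
            missing = self.counts.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(
                    f"metadata missing for samples: {missing.tolist()}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def labels(self, column: str = "label") -> pd.Series:
        if self.metadata is None or column not in self.metadata.columns:
            raise ValueError(f"metadata column {column!r} not present")
        return self.metadata.loc[self.counts.columns, column]


@dataclass
class MarkerPanel:
    """Ordered marker-gene list for one cell type.

    ``stage`` records provenance: ``candidate`` (over-expression screen),
    ``main_cluster`` (dominant co-correlating cluster in one cohort) or
    ``consensus`` (intersection of main clusters across cohorts).
    """

    cell_type: str
    genes: list[str]
    stage: str
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.stage not in PANEL_STAGES:
            raise ValueError(f"stage must be one of {PANEL_STAGES}, got {self.stage!r}")
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dups = [g for g in self.genes if g in seen or seen.add(g)]  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate genes in panel {self.cell_type!r}: {dups}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class TestResult:
    """Two-sample rank-sum test outcome.

    ``statistic`` is the Mann-Whitney U of the first group;
    ``method`` flags whether the p-value came from exact enumeration of the
    U null distribution or from the tie-corrected normal approximation.
    """

    statistic: float
    p_two_sided: float
    method: str  # "exact" | "tie_corrected_normal"
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p_two_sided}")
        if not (0.0 <= self.statistic <= self.n1 * self.n2):
            raise ValueError("U statistic outside [0, n1*n2]")


@dataclass
class GroupComparison:
    """A :class:`TestResult` together with per-group medians."""

    result: TestResult
    groups: tuple[str, str]
    medians: dict[str, float]


@dataclass
class SimilarityMatrix:
    """Gene-by-gene Pearson correlation of log2(normalized count + 1).

    ``zero_variance`` flags genes with constant expression; their rows and
    columns are set to correlation 0 (diagonal stays 1).
    """

    genes: list[str]
    values: pd.DataFrame
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        if np.abs(v).max() > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class CellTypeProfile:
    """Mean relative expression of one cell type over the gene universe.

    ``expression`` is a non-negative Series over genes summing to 1.
    """

    cell_type: str
    expression: pd.Series

    def __post_init__(self) -> None:
        expr = pd.Series(self.expression, dtype=float)
        if (expr < 0).any():
            raise ValueError(f"negative expression in profile {self.cell_type!r}")
        total = float(expr.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"profile {self.cell_type!r} must sum to 1 (got {total!r}); "
                "use CellTypeProfile.from_weights to normalize"
            )
        self.expression = expr

    @classmethod
    def from_weights(cls, cell_type: str, weights: pd.Series | Mapping | np.ndarray,
                     genes: Sequence[str] | None = None) -> "CellTypeProfile":
        w = pd.Series(weights, index=genes, dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        return cls(cell_type, w / total)


@dataclass
class MixtureSample:
    """One bulk sample: a mixture of cell types at fractions summing to 1."""

    sample_id: str
    cohort: str
    fractions: Mapping[str, float]
    depth: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be > 0 for sample {self.sample_id!r}")
        fr = dict(self.fractions)
        if any(v < 0 for v in fr.values()):
            raise ValueError(f"negative fraction in sample {self.sample_id!r}")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"fractions must sum to 1 in sample {self.sample_id!r} "
                f"(got {sum(fr.values())!r})"
            )
        self.fractions = fr


@dataclass
class MixtureDesign:
    """Sample sheet plus the negative-binomial dispersion for simulation.

    ``dispersion`` is the NB over-dispersion alpha in Var = mu + alpha*mu^2;
    either a scalar applied to all genes or a per-gene Series.
    """

    samples: list[MixtureSample]
    dispersion: float | pd.Series = 0.05

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("design must contain at least one sample")
        disp = self.dispersion
        if np.isscalar(disp):
            if disp < 0:  # type: ignore[operator]
                raise ValueError("dispersion must be >= 0")
        else:
            if (pd.Series(disp) < 0).any():
                raise ValueError("dispersion must be >= 0")


@dataclass
class CoculturePar:
    """Parameters of a two-population exponential co-culture.

    Population A is the focal population (e.g. the pediatric donor) and B
    the reference.  ``events`` is the number of flow-cytometry events
    sampled per timepoint; ``None`` selects analytic mode (exact expected
    percentages, no sampling noise).
    """

    td_a: float
    td_b: float
    n0_ratio: float = 1.0
    feeder_fraction: float = 0.0
    duration_days: float = 7.0
    events: int | None = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.td_a <= 0 or self.td_b <= 0:
            raise ValueError("doubling times must be > 0")
        if not (0.0 <= self.feeder_fraction < 1.0):
            raise ValueError("feeder_fraction must lie in [0, 1)")
        if self.n0_ratio <= 0:
            raise ValueError("n0_ratio must be > 0")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")
        if self.events is not None and self.events < 1:
            raise ValueError("events must be >= 1 (or None for analytic mode)")


@dataclass
class CocultureObservation:
    """One well's two-color percentages at t0 and tX.

    ``orientation`` records which color the focal population carries
    (``"color1"`` or ``"color2"``), the dye-swap control of the assay.
    Percentages are on the 0-100 scale and include the unlabeled feeder
    population, so the three percentages sum to ~100 at each timepoint.
    """

    well: str
    orientation: str
    t0_days: float
    tx_days: float
    pct_color1_t0: float
    pct_color2_t0: float
    pct_unlabeled_t0: float
    pct_color1_tx: float
    pct_color2_tx: float
    pct_unlabeled_tx: float
    replicate: int = 1
    pair: str = ""
    focal_donor: str = ""
    ref_donor: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.tx_days <= self.t0_days:
            raise ValueError("tx_days must exceed t0_days")
        for tp, vals in (
            ("t0", (self.pct_color1_t0, self.pct_color2_t0, self.pct_unlabeled_t0)),
            ("tX", (self.pct_color1_tx, self.pct_color2_tx, self.pct_unlabeled_tx)),
        ):
            if any(v < 0 for v in vals):
                raise ValueError(f"negative percentage at {tp} in well {self.well!r}")
            if sum(vals) > 100.0 + 1e-6:
                raise ValueError(
                    f"percentages at {tp} sum to {sum(vals)!r} > 100 in well {self.well!r}"
                )


@dataclass
class DoublingCurve:
    """Serial-passage growth table: (passage, cumulative days, seeded, harvested)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"passage", "days", "seeded", "harvested"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"doubling curve missing columns: {sorted(missing)}")
        t = self.table
        if (t["seeded"] <= 0).any():
            raise ValueError("seeded cell numbers must be > 0")
        if (t["harvested"] < 0).any():
            raise ValueError("harvested cell numbers must be >= 0")
        days = t["days"].to_numpy()
        if not np.all(np.diff(days) > 0):
            raise ValueError("cumulative days must be strictly increasing")


@dataclass
class GrowthAdvantageResult:
    """Per-pair growth-advantage summary of a dye-swapped co-culture set.

    ``ga_percent`` is the mean of the two orientation means; negative values
    mean the focal population doubles *faster* than the reference (the sign
    convention of G_a = (T_focal - T_ref)/T_ref x 100).
    """

    pair: str
    ga_percent: float
    per_orientation: dict[str, float]
    per_well: pd.DataFrame
    td_ref: float
    n_wells: int
    excluded_wells: list[str] = field(default_factory=list)
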