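"""Synthetic data generators for every pipeline input.

The generators reproduce the statistical structure the downstream methods
assume:

* bulk cohorts are negative-binomial counts over mixtures of cell-type
  expression profiles, so markers of the same cell type co-correlate
  across samples because the cell type's fraction varies between samples;
* cell-level matrices carry per-cell type labels for the over-expression
  screen;
* competitive co-cultures are two exponentially growing populations plus
  an unlabeled feeder population, observed through finite multinomial
  flow-event sampling (or exactly, in analytic mode);
* doubling curves are serial passages with exponential growth and
  log-normal harvest noise.

All generators take explicit integer seeds and never touch global RNG
state.  Column ``i`` of a mixture matrix is drawn from the substream
keyed by ``(seed, i)``, so a sample's counts depend only on the seed, its
own parameters, and its position in the design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    CellTypeProfile,
    CocultureObservation,
    CoculturePar,
    CountMatrix,
    DoublingCurve,
    MarkerPanel,
    MixtureDesign,
    MixtureSample,
)

__all__ = [
    "simulate_mixture_counts",
    "simulate_labeled_cells",
    "simulate_coculture",
    "simulate_doubling_curve",
    "make_marker_discovery_scenario",
]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2.

    Implemented as a gamma-Poisson mixture; dispersion 0 is the Poisson
    limit.  ``dispersion`` may be scalar or per-gene.
    """
    mu = np.asarray(mu, dtype=float)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pois = disp == 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    od = ~pois
    if od.any():
        shape = 1.0 / disp[od]
        lam = rng.gamma(shape, mu[od] * disp[od])
        out[od] = rng.poisson(lam)
    return out


def _check_gene_universe(profiles: list[CellTypeProfile]) -> pd.Index:
    if not profiles:
        raise ValueError("at least one cell-type profile is required")
    genes = profiles[0].expression.index
    for p in profiles[1:]:
        if not genes.equals(p.expression.index):
            raise ValueError(
                f"profile {p.cell_type!r} has a different gene universe "
                f"than {profiles[0].cell_type!r}"
            )
    return genes


def simulate_mixture_counts(
    profiles: list[CellTypeProfile],
    design: MixtureDesign,
    seed: int,
) -> CountMatrix:
    """Simulate bulk counts from mixtures of cell-type profiles.

    Each sample's expected count is
    ``mu[g, s] = depth_s * sum_c f[c, s] * pi[g, c]`` and counts are
    negative-binomial with the design's dispersion.  Samples are drawn from
    independent substreams keyed by ``(seed, column index)``, so two designs
    sharing a sample at the same position produce identical columns.
    """
    genes = _check_gene_universe(profiles)
    pi = pd.DataFrame({p.cell_type: p.expression for p in profiles})
    disp = design.dispersion
    if not np.isscalar(disp):
        disp = pd.Series(disp).reindex(genes)
        if disp.isna().any():
            raise ValueError("per-gene dispersion does not cover the gene universe")
        disp = disp.to_numpy()

    cols = {}
    meta_rows = []
    for idx, s in enumerate(design.samples):
        unknown = set(s.fractions) - set(pi.columns)
        if unknown:
            raise ValueError(f"sample {s.sample_id!r} references unknown cell types {sorted(unknown)}")
        f = pd.Series(s.fractions).reindex(pi.columns).fillna(0.0)
        mu = s.depth * (pi.to_numpy() @ f.to_numpy())
        rng = np.random.default_rng([seed, idx])
        cols[s.sample_id] = _nb_draw(rng, mu, disp)
        meta_rows.append({"sample": s.sample_id, "cohort": s.cohort, "depth": s.depth})

    counts = pd.DataFrame(cols, index=genes)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(counts, metadata)


def simulate_labeled_cells(
    profiles: list[CellTypeProfile],
    cells_per_type: int,
    depth: float,
    seed: int,
    dispersion: float = 0.0,
) -> CountMatrix:
    """Simulate a cell-labelled count matrix for candidate marker selection.

    Every cell of type ``c`` has expected counts ``depth * pi[:, c]``; the
    metadata ``label`` column carries the cell-type labels.  At least two
    cell types are required (one-vs-rest selection is undefined otherwise).
    """
    if len(profiles) < 2:
        raise ValueError("at least two cell types are required for one-vs-rest selection")
    if cells_per_type < 2:
        raise ValueError("cells_per_type must be >= 2")
    genes = _check_gene_universe(profiles)
    rng = np.random.default_rng(seed)

    blocks = []
    labels = []
    names = []
    for p in profiles:
        mu = np.broadcast_to(
            (depth * p.expression.to_numpy())[:, None], (len(genes), cells_per_type)
        )
        blocks.append(_nb_draw(rng, mu, dispersion))
        labels.extend([p.cell_type] * cells_per_type)
        names.extend(f"{p.cell_type}_{i}" for i in range(cells_per_type))

    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=names)
    metadata = pd.DataFrame({"label": labels}, index=names)
    return CountMatrix(counts, metadata)


def _coculture_percentages(par: CoculturePar, t: float) -> tuple[float, float, float]:
    wa = par.n0_ratio * 2.0 ** (t / par.td_a)
    wb = 2.0 ** (t / par.td_b)
    labeled = 100.0 * (1.0 - par.feeder_fraction)
    pa = labeled * wa / (wa + wb)
    pb = labeled * wb / (wa + wb)
    return pa, pb, 100.0 * par.feeder_fraction


def simulate_coculture(
    par: CoculturePar,
    well: str = "well1",
    replicate: int = 1,
    orientation: str = "color1",
    pair: str = "",
    focal_donor: str = "",
    ref_donor: str = "",
) -> CocultureObservation:
    """Simulate one co-culture well under exponential growth.

    Population sizes follow ``N_i(t) = N_i(0) * 2**(t / td_i)``.  With
    ``par.events`` set, the reported percentages at each timepoint are a
    multinomial sample of that many flow events over (A, B, feeder); with
    ``par.events = None`` (analytic mode) the exact expected percentages
    are reported, which makes forward-inverse identities exact.

    ``orientation`` states which color population A (the focal population)
    carries; with ``orientation="color2"`` the color columns are swapped,
    emulating the dye-swap control.
    """
    rng = np.random.default_rng(par.seed)
    out = {}
    for label, t in (("t0", 0.0), ("tx", par.duration_days)):
        pa, pb, pu = _coculture_percentages(par, t)
        if par.events is not None:
            draw = rng.multinomial(par.events, [pa / 100, pb / 100, pu / 100])
            pa, pb, pu = 100.0 * draw / par.events
        if orientation == "color1":
            out[label] = (pa, pb, pu)
        else:
            out[label] = (pb, pa, pu)

    return CocultureObservation(
        well=well,
        orientation=orientation,
        t0_days=0.0,
        tx_days=par.duration_days,
        pct_color1_t0=out["t0"][0],
        pct_color2_t0=out["t0"][1],
        pct_unlabeled_t0=out["t0"][2],
        pct_color1_tx=out["tx"][0],
        pct_color2_tx=out["tx"][1],
        pct_unlabeled_tx=out["tx"][2],
        replicate=replicate,
        pair=pair,
        focal_donor=focal_donor,
        ref_donor=ref_donor,
    )


def simulate_doubling_curve(
    td: float,
    passages: int,
    days_per_passage: float,
    seed_cells: float,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DoublingCurve:
    """Simulate a serial-passage population doubling curve.

    Each passage seeds ``seed_cells`` cells and harvests
    ``seed_cells * 2**(days_per_passage / td)`` multiplied by mean-one
    log-normal noise with coefficient of variation ``noise_cv``.
    """
    if td <= 0:
        raise ValueError("doubling time must be > 0")
    if passages < 1:
        raise ValueError("passages must be >= 1")
    if seed_cells <= 0:
        raise ValueError("seed_cells must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    rng = np.random.default_rng(seed)
    growth = 2.0 ** (days_per_passage / td)
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), passages)
    else:
        noise = np.ones(passages)

    rows = []
    for p in range(1, passages + 1):
        rows.append(
            {
                "passage": p,
                "days": p * days_per_passage,
                "seeded": seed_cells,
                "harvested": seed_cells * growth * noise[p - 1],
            }
        )
    return DoublingCurve(pd.DataFrame(rows))


def make_marker_discovery_scenario(
    n_cohorts: int = 3,
    n_samples: int = 60,
    n_markers: int = 10,
    n_decoys: int = 200,
    dispersion: float = 0.05,
    depth_range: tuple[float, float] = (5e4, 1.5e5),
    fraction_range: tuple[float, float] = (0.1, 0.6),
    seed: int = 0,
) -> tuple[list[CountMatrix], MarkerPanel, list[str]]:
    """Build age-stratified cohorts with a planted consensus marker block.

    Two cell types mix in every sample: the target type, whose fraction
    varies uniformly over ``fraction_range`` (driving co-correlation of its
    markers), and a background type.  The candidate panel holds the
    ``n_markers`` true markers (expressed only by the target type) plus
    ``n_decoys`` decoy genes expressed equally by both types, so decoys
    carry no compositional signal.  A mirror block expressed only by the
    background type keeps both profiles summing to 1; it is not part of
    the candidate panel, as a real over-expression screen would not have
    selected it.

    Returns the cohorts, the candidate panel, and the planted marker names.
    """
    markers = [f"MRK{i:03d}" for i in range(n_markers)]
    fillers = [f"BGD{i:03d}" for i in range(n_markers)]
    decoys = [f"DCY{i:03d}" for i in range(n_decoys)]
    genes = pd.Index(markers + fillers + decoys)

    block_share = 0.5  # markers carry half the target type's expression
    w_target = pd.Series(0.0, index=genes)
    w_target[markers] = block_share / n_markers
    w_target[decoys] = (1 - block_share) / n_decoys
    w_bg = pd.Series(0.0, index=genes)
    w_bg[fillers] = block_share / n_markers
    w_bg[decoys] = (1 - block_share) / n_decoys

    profiles = [
        CellTypeProfile("target", w_target),
        CellTypeProfile("background", w_bg),
    ]

    cohort_names = [f"cohort{i + 1}" for i in range(n_cohorts)]
    cohorts = []
    for ci, cohort in enumerate(cohort_names):
        rng = np.random.default_rng([seed, 1000 + ci])
        samples = []
        for si in range(n_samples):
            f = rng.uniform(*fraction_range)
            depth = rng.uniform(*depth_range)
            samples.append(
                MixtureSample(
                    sample_id=f"{cohort}_s{si:02d}",
                    cohort=cohort,
                    fractions={"target": f, "background": 1.0 - f},
                    depth=depth,
                )
            )
        design = MixtureDesign(samples, dispersion=dispersion)
        cohorts.append(simulate_mixture_counts(profiles, design, seed=seed + 7919 * (ci + 1)))

    candidates = MarkerPanel("target", markers + decoys, stage="candidate")
    return cohorts, candidates, markers
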