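"""Growth-advantage inference from two-color competitive co-cultures.

Two labeled populations grow exponentially, N_i(t) = N_i(0) * 2**(t/td_i),
so the fold change of their flow-cytometry ratio over X days,

    Y = (%color1 / %color2 at X) / (%color1 / %color2 at 0),

determines the focal population's doubling time given the reference's.
The growth advantage is

    G_a = (T_focal - T_ref)/T_ref * 100
        = -T_ref * log2(Y) / (X + T_ref * log2(Y)) * 100,

negative when the focal population doubles faster.  Unlabeled feeder
events are excluded by construction (the labeled ratio is unchanged by
renormalization over labeled events).  The module also provides the
doubling-time, viral-titre and colony-forming-efficiency calculators the
assay depends on.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import CocultureObservation, DoublingCurve, GrowthAdvantageResult

logger = logging.getLogger(__name__)

__all__ = [
    "ratio_change",
    "doubling_time",
    "growth_advantage",
    "summarize_pair",
    "viral_titre",
    "colony_forming_efficiency",
]


def _check_percent_scale(obs: CocultureObservation, allow_fraction_scale: bool) -> None:
    # Guard against silently passing 0-1 fractions where 0-100 percentages
    # are expected; a labeled+unlabeled total <= 1.5 at both timepoints is
    # taken as fraction-scale input.
    tot0 = obs.pct_color1_t0 + obs.pct_color2_t0 + obs.pct_unlabeled_t0
    totx = obs.pct_color1_tx + obs.pct_color2_tx + obs.pct_unlabeled_tx
    if not allow_fraction_scale and max(tot0, totx) <= 1.5:
        raise ValueError(
            f"well {obs.well!r}: percentages sum to {tot0:.3g}/{totx:.3g}; inputs "
            "look like 0-1 fractions — pass allow_fraction_scale=True if intended"
        )


def ratio_change(obs: CocultureObservation, allow_fraction_scale: bool = False) -> float:
    """Fold change Y of the color1:color2 ratio between t0 and tX.

    Feeder (unlabeled) events are excluded by renormalizing over labeled
    events; since both colors are scaled identically this equals the raw
    percentage ratio.  A color at 0% at either timepoint is rejected
    ("population extinct or unlabeled") because Y is undefined.
    """
    _check_percent_scale(obs, allow_fraction_scale)
    for tp, (p1, p2) in (
        ("t0", (obs.pct_color1_t0, obs.pct_color2_t0)),
        ("tX", (obs.pct_color1_tx, obs.pct_color2_tx)),
    ):
        if p1 <= 0 or p2 <= 0:
            raise ValueError(
                f"well {obs.well!r}: population extinct or unlabeled at {tp} "
                f"(color1={p1}%, color2={p2}%)"
            )
    labeled0 = obs.pct_color1_t0 + obs.pct_color2_t0
    labeledx = obs.pct_color1_tx + obs.pct_color2_tx
    r0 = (obs.pct_color1_t0 / labeled0) / (obs.pct_color2_t0 / labeled0)
    rx = (obs.pct_color1_tx / labeledx) / (obs.pct_color2_tx / labeledx)
    return rx / r0


def doubling_time(curve: DoublingCurve, mode: str = "regression") -> float:
    """Doubling time (days) from a serial-passage growth table.

    Per-passage population doublings PD = log2(harvested/seeded) are
    accumulated; ``mode="regression"`` fits cumulative PD on cumulative
    days by least squares through the origin (td = 1/slope), using every
    passage; ``mode="endpoint"`` uses total days / total PD.
    """
    t = curve.table
    if (t["harvested"] <= 0).any():
        raise ValueError("harvested cell numbers must be > 0 to compute doublings")
    pd_per_passage = np.log2(t["harvested"].to_numpy() / t["seeded"].to_numpy())
    cum_pd = np.cumsum(pd_per_passage)
    days = t["days"].to_numpy(dtype=float)
    if cum_pd[-1] <= 0:
        raise ValueError("total population doublings must be positive")
    if mode == "regression":
        slope = float(days @ cum_pd) / float(days @ days)
    elif mode == "endpoint":
        slope = cum_pd[-1] / days[-1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if slope <= 0:
        raise ValueError("fitted growth rate is non-positive")
    return 1.0 / slope


def growth_advantage(Y: float, X: float, td_ref: float) -> float:
    """Growth advantage G_a (percent) of the focal vs reference population.

    ``Y`` is the fold change of the focal:reference ratio over ``X`` days
    and ``td_ref`` the reference population's doubling time in days.
    Negative G_a means the focal population doubles faster.  The implied
    focal doubling time X*td_ref/(X + td_ref*log2(Y)) must be positive.
    """
    if Y <= 0:
        raise ValueError("Y must be > 0")
    if X <= 0 or td_ref <= 0:
        raise ValueError("X and td_ref must be > 0")
    denom = X + td_ref * np.log2(Y)
    if denom <= 0:
        raise ValueError(
            f"implied non-positive doubling time: X + td_ref*log2(Y) = {denom:.4g} <= 0"
        )
    return float(-td_ref * np.log2(Y) / denom * 100.0)


def summarize_pair(
    observations: list[CocultureObservation],
    td_ref: float,
    pair: str | None = None,
    allow_fraction_scale: bool = False,
) -> GrowthAdvantageResult:
    """Per-pair growth advantage of the focal donor, dye-swap averaged.

    G_a is computed per well with the reference (adult) donor's doubling
    time ``td_ref``; ``Y`` is oriented so it always tracks focal/reference
    (inverted for wells where the focal donor carries color2).  Means are
    reported separately per orientation and averaged into ``ga_percent``.
    Wells with an extinct color are excluded and listed in
    ``excluded_wells``; every orientation present in the input must retain
    at least one usable well.
    """
    if not observations:
        raise ValueError("at least one observation is required")
    if td_ref <= 0:
        raise ValueError("reference doubling time must be > 0")
    if pair is None:
        pair = observations[0].pair or "pair"

    rows = []
    excluded = []
    for obs in observations:
        try:
            y = ratio_change(obs, allow_fraction_scale=allow_fraction_scale)
        except ValueError as err:
            logger.warning("excluding well %r: %s", obs.well, err)
            excluded.append(obs.well)
            continue
        if obs.orientation == "color2":
            y = 1.0 / y
        ga = growth_advantage(y, obs.tx_days - obs.t0_days, td_ref)
        rows.append(
            {
                "well": obs.well,
                "orientation": obs.orientation,
                "replicate": obs.replicate,
                "Y_focal": y,
                "X_days": obs.tx_days - obs.t0_days,
                "ga_percent": ga,
            }
        )

    orientations_in = {obs.orientation for obs in observations}
    per_well = pd.DataFrame(rows)
    kept_orientations = set(per_well["orientation"]) if len(per_well) else set()
    missing = orientations_in - kept_orientations
    if missing:
        raise ValueError(
            f"pair {pair!r}: no usable replicate for orientation(s) {sorted(missing)}"
        )

    per_orientation = {
        o: float(g["ga_percent"].mean()) for o, g in per_well.groupby("orientation")
    }
    ga = float(np.mean(list(per_orientation.values())))
    return GrowthAdvantageResult(
        pair=pair,
        ga_percent=ga,
        per_orientation=per_orientation,
        per_well=per_well,
        td_ref=td_ref,
        n_wells=len(per_well),
        excluded_wells=excluded,
    )


def viral_titre(pct_positive: float, volume_ml: float, cells_plated: float = 50_000) -> float:
    """Lentiviral titre (particles/mL) from a transduction assay.

    titre = (%positive / 100 * cells_plated) / volume_ml; the percentage is
    on the 0-100 scale and converted to a fraction of plated cells.
    """
    if not (0.0 <= pct_positive <= 100.0):
        raise ValueError("pct_positive must lie in [0, 100]")
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    if cells_plated <= 0:
        raise ValueError("cells_plated must be > 0")
    return pct_positive / 100.0 * cells_plated / volume_ml


def colony_forming_efficiency(colonies: float, seeded: float) -> float:
    """Colony-forming efficiency (%) = colonies formed / cells seeded * 100."""
    if seeded <= 0:
        raise ValueError("seeded must be > 0")
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    if colonies > seeded:
        raise ValueError("colonies cannot exceed seeded cells")
    return colonies / seeded * 100.0
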