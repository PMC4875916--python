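"""Per-tree biomass increments and plot-level aboveground wood production.

Each stem's growth over one year is converted to a biomass increment by
evaluating the allometric biomass equation at its initial diameter and
at the diameter projected one year ahead, with heights taken from the
height-diameter curve.  Plot AWP (MgC/ha/yr) sums these increments over
all stems recorded at the first census, weighted by each stem's
per-hectare expansion factor, and converts to carbon.

Two variants are produced: the headline *model* estimate, in which every
increment — including those of stems that died and of stems screened
out as gross measurement errors — is predicted from the fitted growth
model, and a *field* cross-check in which surviving stems that passed
screening keep their measured increments while the rest are gap-filled
with the median measured growth of surviving same-stratum plot members
(a simplified gap-filling rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allometry import (AllometryError, AllometryParams, WoodDensityTable,
                        agb, predict_height, to_carbon)
from .growth import GrowthParams, competition_index, predict_diameter_t1
from .inventory import PlotRecord, ScreeningReport, TreeRecord, ValidationError


class PlotExcludedError(ValueError):
    """The plot was excluded by screening and has no AWP."""


@dataclass
class TreeIncrement:
    tree_id: str
    AGB_t: float       # kg at first measurement
    AGB_t1: float      # kg one year later
    delta_AGB: float   # kg/yr
    method: str        # "model" | "field"
    expansion: float   # per-ha weight


def tree_increment(tree: TreeRecord, D_t1: float,
                   allom: AllometryParams, wd: float,
                   method: str = "model") -> TreeIncrement:
    """Annual biomass increment of one stem from its initial and
    one-year-ahead diameters."""
    d_ref = tree.D2 if tree.status == "recruit" else tree.D1
    if d_ref is None or D_t1 is None:
        raise ValidationError(f"tree {tree.tree_id}: missing diameter")
    if wd is None or wd <= 0:
        raise AllometryError(f"tree {tree.tree_id}: no wood density")
    agb_t = agb(d_ref, predict_height(d_ref, allom), wd, allom)
    agb_t1 = agb(D_t1, predict_height(D_t1, allom), wd, allom)
    return TreeIncrement(tree_id=tree.tree_id, AGB_t=agb_t, AGB_t1=agb_t1,
                         delta_AGB=agb_t1 - agb_t, method=method,
                         expansion=tree.expansion)


def _wd_for(tree: TreeRecord, wd_table: WoodDensityTable) -> float:
    return wd_table.lookup(tree.genus, tree.species)[0]


def _sum_to_awp(increments: list[TreeIncrement]) -> float:
    total_kg = sum(inc.delta_AGB * inc.expansion for inc in increments)
    return to_carbon(total_kg)


def plot_awp_model(plot_trees: list[TreeRecord], plot: PlotRecord,
                   growth: GrowthParams, allom: AllometryParams,
                   wd_table: WoodDensityTable,
                   excluded_plots: set[str] | None = None,
                   include_recruits: bool = False,
                   ) -> tuple[float, list[TreeIncrement]]:
    """Model-based plot AWP in MgC/ha/yr.

    All census-1 stems contribute a model-predicted increment, including
    stems that died between censuses (their growth is imputed from size
    and competitive status).  Recruits were not present at the first
    census and are excluded from the sum unless ``include_recruits``.
    """
    if excluded_plots and plot.plot_id in excluded_plots:
        raise PlotExcludedError(
            f"plot {plot.plot_id} was excluded by screening")
    increments = []
    for t in plot_trees:
        if t.status == "recruit" and not include_recruits:
            continue
        census = 2 if t.status == "recruit" else 1
        bl = competition_index(t, plot_trees, plot, census=census)
        d1 = predict_diameter_t1(t, bl, growth)
        increments.append(
            tree_increment(t, d1, allom, _wd_for(t, wd_table), "model"))
    return _sum_to_awp(increments), increments


def plot_awp_field(plot_trees: list[TreeRecord], plot: PlotRecord,
                   allom: AllometryParams, wd_table: WoodDensityTable,
                   tree_report: ScreeningReport,
                   excluded_plots: set[str] | None = None,
                   ) -> tuple[float, list[TreeIncrement]]:
    """Field-measurement-based plot AWP in MgC/ha/yr.

    Surviving stems that passed screening use their measured annualized
    growth; screened-out and dead stems are gap-filled with the median
    measured growth of surviving same-stratum stems in the plot (plot
    median across strata when the stratum has no survivors, zero when
    the plot has none).  Recruits are excluded as in the model variant.
    """
    if excluded_plots and plot.plot_id in excluded_plots:
        raise PlotExcludedError(
            f"plot {plot.plot_id} was excluded by screening")
    bad = tree_report.excluded_tree_ids
    measured: dict[str, list[float]] = {"outer": [], "inner": []}
    for t in plot_trees:
        if (t.status == "alive" and t.tree_id not in bad
                and t.D1 is not None and t.D2 is not None):
            measured[t.stratum].append((t.D2 - t.D1) / t.delta_t)
    all_g = measured["outer"] + measured["inner"]

    def fill_g(stratum: str) -> float:
        if measured[stratum]:
            return float(np.median(measured[stratum]))
        if all_g:
            return float(np.median(all_g))
        return 0.0

    increments = []
    for t in plot_trees:
        if t.status == "recruit":
            continue
        if (t.status == "alive" and t.tree_id not in bad
                and t.D2 is not None):
            g = (t.D2 - t.D1) / t.delta_t
        else:
            g = fill_g(t.stratum)
        increments.append(tree_increment(t, t.D1 + g, allom,
                                         _wd_for(t, wd_table), "field"))
    return _sum_to_awp(increments), increments
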