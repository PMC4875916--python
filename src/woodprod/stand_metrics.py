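"""Plot-level stand structure and diversity metrics.

Basal area (BA, m^2/ha) factors exactly into a size and a frequency
component,

    BA = pi/4 * (QMD/100)^2 * n_stems,

where QMD is the quadratic mean stem diameter (cm) and n_stems the stem
density per hectare.  Computing QMD with the same expansion weights as
BA and n_stems keeps the identity exact, which is what lets BA enter the
structural-equation model as a fixed-weight composite of its two parts.

Diversity is the effective number of species — the exponential of the
Shannon-Wiener index on basal-area shares — which equals species
richness when shares are equal and discounts rare species otherwise.
It is computed on unexpanded plot-level basal area because diversity
does not scale linearly with area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .inventory import PlotRecord, TreeRecord, ValidationError


@dataclass
class StandSummary:
    """One plot's structure, diversity and production — the SEM input row."""

    plot_id: str
    BA: float           # m^2/ha
    QMD: float          # cm
    n_stems: float      # stems/ha
    eff_species: float
    AWP: float | None = None   # MgC/ha/yr
    soilP_class: int | None = None
    logged: bool | None = None
    slope: float | None = None


def _census1(plot_trees: list[TreeRecord]) -> list[TreeRecord]:
    return [t for t in plot_trees if t.status != "recruit" and t.D1 is not None]


def stand_structure(plot_trees: list[TreeRecord], plot: PlotRecord,
                    expansion_weighted: bool = True,
                    ) -> tuple[float, float, float]:
    """(BA, QMD, n_stems) from census-1 stems.

    Expansion weighting (default) scales each stem by the reciprocal of
    its stratum's sampled area so all three quantities are per-hectare
    and the BA = pi/4 (QMD/100)^2 n_stems identity holds exactly; the
    unweighted option treats every stem equally (raw plot sums).
    """
    stems = _census1(plot_trees)
    if not stems:
        raise ValidationError(f"plot {plot.plot_id}: no census-1 stems")
    d = np.array([t.D1 for t in stems])
    if expansion_weighted:
        w = np.array([t.expansion for t in stems])
    else:
        w = np.ones(len(stems))
    n_stems = float(w.sum())
    ba = float(np.sum(math.pi / 4.0 * (d / 100.0) ** 2 * w))
    qmd = float(np.sqrt(np.sum(d ** 2 * w) / n_stems))
    return ba, qmd, n_stems


def effective_species(plot_trees: list[TreeRecord]) -> float:
    """exp(Shannon-Wiener index) on basal-area shares of census-1 stems.

    Species shares use unexpanded basal area (plot-level, not per
    hectare); unidentified stems (blank species) are excluded and the
    shares renormalized.  Single species -> 1; S species with equal
    shares -> S.
    """
    ba_by_species: dict[tuple[str, str], float] = {}
    for t in _census1(plot_trees):
        if not t.species:
            continue
        key = (t.genus, t.species)
        ba_by_species[key] = (ba_by_species.get(key, 0.0)
                              + math.pi / 4.0 * (t.D1 / 100.0) ** 2)
    total = sum(ba_by_species.values())
    if total <= 0:
        raise ValidationError("no identified stems: diversity undefined")
    p = np.array(list(ba_by_species.values())) / total
    return float(np.exp(-np.sum(p * np.log(p))))


def summarize_stand(plot_trees: list[TreeRecord], plot: PlotRecord,
                    awp: float | None = None) -> StandSummary:
    ba, qmd, n = stand_structure(plot_trees, plot)
    return StandSummary(plot_id=plot.plot_id, BA=ba, QMD=qmd, n_stems=n,
                        eff_species=effective_species(plot_trees), AWP=awp,
                        soilP_class=plot.soilP_class, logged=plot.logged,
                        slope=plot.slope)


def self_thinning_curve(summaries: list[StandSummary],
                        tau: float = 0.99) -> tuple[float, float]:
    """Upper-boundary (self-thinning) line on log-log axes.

    Fits log(QMD) on log(n_stems) at the ``tau`` quantile by minimizing
    the pinball loss, tracing the trade-off between how many stems a
    stand holds and how large they can be.  Returns (intercept, slope).
    """
    if len(summaries) < 20:
        raise ValidationError("need at least 20 plots for the quantile fit")
    x = np.log([s.n_stems for s in summaries])
    y = np.log([s.QMD for s in summaries])
    if np.std(x) < 1e-12:
        raise ValidationError("degenerate stem densities: no x variance")
    X = sm.add_constant(x)
    res = sm.QuantReg(y, X).fit(q=tau, max_iter=5000)
    return float(res.params[0]), float(res.params[1])
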