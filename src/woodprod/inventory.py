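"""Census data model, delimited-text I/O, and outlier screening.

A repeat forest census records each stem twice: its diameter at plot
establishment (``D1``) and at the recensus (``D2``), separated by
``delta_t`` years.  Plots are circular, with two nested strata: every
stem >= 30 cm diameter is measured over the full plot (0.125 ha by
default) while stems >= 10 cm are measured only in a small central
subplot (0.0125 ha).  Screening removes gross measurement errors from
the growth-model fitting set and drops plots devastated by mortality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd

#: diameter threshold (cm) for the full-plot stratum
OUTER_MIN_D = 30.0
#: diameter threshold (cm) for the central-subplot stratum
INNER_MIN_D = 10.0
#: default sampled areas (ha) per stratum
AREA_OUTER = 0.125
AREA_INNER = 0.0125

STATUSES = ("alive", "died", "recruit")
STRATA = ("outer", "inner")

TREE_COLUMNS = [
    "tree_id", "plot_id", "genus", "species", "D1", "D2",
    "status", "delta_t", "stratum",
]
PLOT_COLUMNS = [
    "plot_id", "transect_id", "logged", "slope", "elevation",
    "dist_stream", "soilP_measured", "soilP_class",
    "area_outer", "area_inner",
]


class CensusFormatError(ValueError):
    """A census or plot file is structurally unreadable (e.g. missing column)."""


class ValidationError(ValueError):
    """A record violates a type invariant."""


@dataclass
class TreeRecord:
    """One stem's two-census measurements.

    ``D1`` is None for recruits (not present at census 1); ``D2`` is None
    for stems that died between censuses.
    """

    tree_id: str
    plot_id: str
    genus: str
    species: str
    D1: float | None
    D2: float | None
    status: str
    delta_t: float
    stratum: str

    def validate(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(
                f"tree {self.tree_id}: status {self.status!r} not in {STATUSES}")
        if self.stratum not in STRATA:
            raise ValidationError(
                f"tree {self.tree_id}: stratum {self.stratum!r} not in {STRATA}")
        if not (self.delta_t > 0):
            raise ValidationError(f"tree {self.tree_id}: delta_t must be > 0")
        if self.status == "died" and self.D2 is not None:
            raise ValidationError(f"tree {self.tree_id}: died but D2 present")
        if self.status == "recruit":
            if self.D1 is not None:
                raise ValidationError(
                    f"tree {self.tree_id}: recruit but D1 present")
        else:
            if self.D1 is None:
                raise ValidationError(f"tree {self.tree_id}: missing D1")
            min_d = OUTER_MIN_D if self.stratum == "outer" else INNER_MIN_D
            if self.D1 < min_d:
                raise ValidationError(
                    f"tree {self.tree_id}: D1={self.D1} below the "
                    f"{min_d:g} cm threshold for stratum {self.stratum!r}")

    @property
    def expansion(self) -> float:
        """Per-hectare weight of this stem (reciprocal of sampled area)."""
        return 1.0 / (AREA_OUTER if self.stratum == "outer" else AREA_INNER)


@dataclass
class PlotRecord:
    """Plot-level covariates and sampling geometry."""

    plot_id: str
    transect_id: str
    logged: bool
    slope: float
    elevation: float
    dist_stream: float
    soilP_measured: float | None = None
    soilP_class: int | None = None
    area_outer: float = AREA_OUTER
    area_inner: float = AREA_INNER

    def validate(self) -> None:
        if self.area_outer <= 0 or self.area_inner <= 0:
            raise ValidationError(f"plot {self.plot_id}: non-positive area")
        if self.soilP_measured is not None and self.soilP_measured < 0:
            raise ValidationError(
                f"plot {self.plot_id}: negative measured soil P")
        if self.soilP_class is not None and self.soilP_class not in (1, 2, 3):
            raise ValidationError(
                f"plot {self.plot_id}: soilP_class must be 1, 2 or 3")


@dataclass
class ScreeningReport:
    """Outcome of a screening pass; every exclusion carries one reason code."""

    excluded_trees: list[tuple[str, str]] = field(default_factory=list)
    excluded_plots: list[tuple[str, str]] = field(default_factory=list)
    retained: dict[str, int] = field(default_factory=dict)

    @property
    def excluded_tree_ids(self) -> set[str]:
        return {t for t, _ in self.excluded_trees}

    @property
    def excluded_plot_ids(self) -> set[str]:
        return {p for p, _ in self.excluded_plots}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "tree", "id": i, "reason": r}
                for i, r in self.excluded_trees]
        rows += [{"kind": "plot", "id": i, "reason": r}
                 for i, r in self.excluded_plots]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


# ---------------------------------------------------------------------------
# I/O

def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_census(tree_path, plot_path) -> tuple[list[TreeRecord], list[PlotRecord]]:
    """Read tree and plot CSV tables and validate every record.

    Raises :class:`CensusFormatError` when a required column is missing and
    :class:`ValidationError` (with the offending row number) when a record
    breaks an invariant.
    """
    trees_df = pd.read_csv(tree_path, dtype={"tree_id": str, "plot_id": str})
    plots_df = pd.read_csv(plot_path, dtype={"plot_id": str, "transect_id": str})
    for col in TREE_COLUMNS:
        if col not in trees_df.columns:
            raise CensusFormatError(f"census table missing column {col!r}")
    for col in PLOT_COLUMNS:
        if col not in plots_df.columns:
            raise CensusFormatError(f"plot table missing column {col!r}")

    trees: list[TreeRecord] = []
    for i, row in enumerate(trees_df.itertuples(index=False), start=2):
        rec = TreeRecord(
            tree_id=str(row.tree_id), plot_id=str(row.plot_id),
            genus="" if pd.isna(row.genus) else str(row.genus),
            species="" if pd.isna(row.species) else str(row.species),
            D1=_opt_float(row.D1), D2=_opt_float(row.D2),
            status=str(row.status), delta_t=float(row.delta_t),
            stratum=str(row.stratum))
        try:
            rec.validate()
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
        trees.append(rec)

    plots: list[PlotRecord] = []
    for i, row in enumerate(plots_df.itertuples(index=False), start=2):
        cls = _opt_float(row.soilP_class)
        rec = PlotRecord(
            plot_id=str(row.plot_id), transect_id=str(row.transect_id),
            logged=bool(int(row.logged)), slope=float(row.slope),
            elevation=float(row.elevation), dist_stream=float(row.dist_stream),
            soilP_measured=_opt_float(row.soilP_measured),
            soilP_class=None if cls is None else int(cls),
            area_outer=float(row.area_outer), area_inner=float(row.area_inner))
        try:
            rec.validate()
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
        plots.append(rec)
    return trees, plots


def trees_to_frame(trees: Iterable[TreeRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in trees], columns=TREE_COLUMNS)


def plots_to_frame(plots: Iterable[PlotRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(p) for p in plots], columns=PLOT_COLUMNS)
    df["logged"] = df["logged"].astype(int)
    return df


def write_census(trees: Sequence[TreeRecord], plots: Sequence[PlotRecord],
                 tree_path, plot_path) -> None:
    """Inverse of :func:`read_census`; blank cells encode missing values."""
    trees_to_frame(trees).to_csv(tree_path, index=False)
    plots_to_frame(plots).to_csv(plot_path, index=False)


# ---------------------------------------------------------------------------
# Screening

def annual_growth(D1: float | None, D2: float | None,
                  delta_t: float) -> float | None:
    """Annualized diameter increment (D2 - D1) / delta_t in cm/yr.

    Negative values are legitimate (stem shrinkage).  Returns None — an
    explicit undefined-growth signal, never zero — when either diameter
    is missing.
    """
    if delta_t <= 0:
        raise ValidationError("delta_t must be > 0")
    if D1 is None or D2 is None:
        return None
    return (D2 - D1) / delta_t


def screen_trees(trees: Sequence[TreeRecord], g_max: float = 4.0,
                 shrink_max: float = 0.5) -> ScreeningReport:
    """Flag gross measurement errors for exclusion from growth fitting.

    A stem is flagged when its annualized growth is >= ``g_max`` cm/yr
    (threshold inclusive) or its diameter decreased by strictly more than
    ``shrink_max`` cm between censuses.  Small shrinkage is retained:
    stems can genuinely contract under drought-induced low hydrostatic
    pressure.  Flagged stems stay in the dataset — their growth is later
    model-imputed rather than measured — so this is report-only.
    """
    report = ScreeningReport()
    n_checked = 0
    for t in trees:
        g = annual_growth(t.D1, t.D2, t.delta_t)
        if g is None:
            continue
        n_checked += 1
        if g >= g_max:
            report.excluded_trees.append((t.tree_id, "extreme_growth"))
        elif (t.D2 - t.D1) < -shrink_max:
            report.excluded_trees.append((t.tree_id, "excess_shrinkage"))
    report.retained["trees_for_fitting"] = n_checked - len(report.excluded_trees)
    report.retained["trees_checked"] = n_checked
    return report


def screen_plots(trees: Sequence[TreeRecord], plots: Sequence[PlotRecord],
                 mortality_frac: float = 0.5) -> ScreeningReport:
    """Exclude plots that lost strictly more than ``mortality_frac`` of
    their census-1 stems; such plots are dropped from all downstream
    analyses (mass mortality, not steady-state dynamics)."""
    report = ScreeningReport()
    by_plot: dict[str, list[TreeRecord]] = {}
    for t in trees:
        by_plot.setdefault(t.plot_id, []).append(t)
    for p in plots:
        stems = [t for t in by_plot.get(p.plot_id, []) if t.status != "recruit"]
        if not stems:
            raise ValidationError(f"plot {p.plot_id}: no census-1 stems")
        died = sum(1 for t in stems if t.status == "died")
        if died / len(stems) > mortality_frac:
            report.excluded_plots.append((p.plot_id, "high_mortality"))
    report.retained["plots"] = len(plots) - len(report.excluded_plots)
    return report


def fitting_subset(trees: Sequence[TreeRecord],
                   tree_report: ScreeningReport,
                   plot_report: ScreeningReport) -> list[TreeRecord]:
    """Stems whose measured growth may enter model fitting: alive at both
    censuses, not flagged, and not on an excluded plot."""
    bad_trees = tree_report.excluded_tree_ids
    bad_plots = plot_report.excluded_plot_ids
    return [t for t in trees
            if t.status == "alive" and t.D1 is not None and t.D2 is not None
            and t.tree_id not in bad_trees and t.plot_id not in bad_plots]
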