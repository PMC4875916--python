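"""Tree allometry: height from diameter, biomass, wood density, carbon.

Height follows a three-parameter Weibull curve saturating at an
asymptote; aboveground biomass (AGB, kg) uses the pan-tropical power law
AGB = 0.0673 * (D^2 * H * WD)^0.976 with D in cm, H in m and wood
density WD in g/cm^3.  Woody tissue is assumed to be 47% carbon.

Wood density is looked up by taxon with hierarchical fallback
(species -> genus mean -> family mean -> dataset mean), mirroring how
global wood-density compilations are applied to inventories in which
not every stem is resolved to species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CARBON_FRACTION = 0.47


class AllometryError(RuntimeError):
    pass


@dataclass
class AllometryParams:
    """Height-curve and biomass-equation constants.

    Height defaults were fitted to 336 height-diameter pairs from the
    study region; the biomass coefficients are the moist-forest
    pan-tropical values.
    """

    h_asym: float = 79.9     # asymptotic height, m
    h_rate: float = 0.011
    h_shape: float = 0.74
    agb_coef: float = 0.0673
    agb_exp: float = 0.976
    carbon_frac: float = CARBON_FRACTION

    def __post_init__(self):
        if min(self.h_asym, self.h_rate, self.h_shape,
               self.agb_coef, self.agb_exp) <= 0:
            raise AllometryError("allometry parameters must be positive")
        if not 0 < self.carbon_frac < 1:
            raise AllometryError("carbon fraction must lie in (0, 1)")


def predict_height(D, params: AllometryParams | None = None):
    """Weibull height-diameter curve H = a * (1 - exp(-b * D^c)), metres.

    Strictly increasing in D, H(0) = 0, bounded above by ``h_asym``.
    """
    p = params or AllometryParams()
    D = np.asarray(D, dtype=float)
    H = p.h_asym * (1.0 - np.exp(-p.h_rate * D ** p.h_shape))
    return float(H) if H.ndim == 0 else H


def fit_height_curve(D, H, params: AllometryParams | None = None
                     ) -> tuple[AllometryParams, float]:
    """Nonlinear least-squares fit of the Weibull height curve.

    Returns the fitted parameters (biomass constants carried over
    unchanged) and the residual standard error.  Falls back to a grid of
    starting values before declaring non-convergence.
    """
    D = np.asarray(D, dtype=float)
    H = np.asarray(H, dtype=float)
    if len(D) < 10:
        raise AllometryError("need at least 10 height-diameter pairs")
    if np.any(D <= 0) or np.any(H <= 0):
        raise AllometryError("diameters and heights must be positive")
    if np.std(H) < 1e-10:
        raise AllometryError("degenerate data: heights are constant")

    def f(d, a, b, c):
        return a * (1.0 - np.exp(-b * d ** c))

    base = params or AllometryParams()
    starts = [(base.h_asym, base.h_rate, base.h_shape)]
    starts += [(a0, b0, c0)
               for a0 in (40.0, 80.0, 120.0)
               for b0 in (0.005, 0.02, 0.08)
               for c0 in (0.5, 0.8, 1.2)]
    last_err: Exception | None = None
    for a0, b0, c0 in starts:
        try:
            popt, _ = curve_fit(
                f, D, H, p0=(a0, b0, c0),
                bounds=([1e-3, 1e-6, 1e-3], [500.0, 5.0, 3.0]),
                maxfev=20000)
        except RuntimeError as e:  # pragma: no cover - depends on data
            last_err = e
            continue
        resid = H - f(D, *popt)
        dof = max(len(D) - 3, 1)
        rse = float(np.sqrt(np.sum(resid ** 2) / dof))
        fitted = AllometryParams(
            h_asym=float(popt[0]), h_rate=float(popt[1]),
            h_shape=float(popt[2]), agb_coef=base.agb_coef,
            agb_exp=base.agb_exp, carbon_frac=base.carbon_frac)
        return fitted, rse
    raise AllometryError(f"height-curve fit did not converge: {last_err}")


def agb(D, H, WD, params: AllometryParams | None = None):
    """Aboveground biomass (kg) from diameter (cm), height (m) and wood
    density (g/cm^3)."""
    p = params or AllometryParams()
    D = np.asarray(D, dtype=float)
    out = p.agb_coef * (D ** 2 * np.asarray(H) * np.asarray(WD)) ** p.agb_exp
    return float(out) if out.ndim == 0 else out


def to_carbon(mass_kg):
    """Woody biomass (kg) to carbon (Mg C) at 47% carbon concentration."""
    out = np.asarray(mass_kg, dtype=float) * CARBON_FRACTION / 1000.0
    return float(out) if out.ndim == 0 else out


class WoodDensityTable:
    """Taxon-keyed wood-density reference with hierarchical fallback.

    Lookup resolves to the most specific taxonomic level available:
    exact species value, else the genus mean, else the family mean, else
    the overall dataset mean.  The resolution level used is reported with
    each lookup.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"family", "genus", "species", "wd"}
        missing = required - set(df.columns)
        if missing:
            raise AllometryError(f"wood-density table missing {sorted(missing)}")
        if df.empty:
            raise AllometryError("wood-density table is empty")
        if (df["wd"] <= 0).any():
            raise AllometryError("wood densities must be positive")
        self._df = df.reset_index(drop=True)
        self._species = df.groupby(["genus", "species"])["wd"].mean().to_dict()
        self._genus = df.groupby("genus")["wd"].mean().to_dict()
        self._family = df.groupby("family")["wd"].mean().to_dict()
        self._dataset_mean = float(df["wd"].mean())

    @classmethod
    def from_csv(cls, path) -> "WoodDensityTable":
        return cls(pd.read_csv(path))

    def lookup(self, genus: str, species: str = "",
               family: str = "") -> tuple[float, str]:
        """Wood density (g/cm^3) and the taxonomic level that supplied it."""
        if species and (genus, species) in self._species:
            return float(self._species[(genus, species)]), "species"
        if genus and genus in self._genus:
            return float(self._genus[genus]), "genus"
        if family and family in self._family:
            return float(self._family[family]), "family"
        return self._dataset_mean, "dataset"


def lookup_wd(genus: str, species: str, family: str,
              table: WoodDensityTable) -> tuple[float, str]:
    """Functional wrapper around :meth:`WoodDensityTable.lookup`."""
    return table.lookup(genus, species, family)
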