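"""Soil-phosphorus prediction and classification.

Only a subset of plots has laboratory-measured total soil P, so P for
the rest is predicted from terrain covariates — distance to the nearest
stream, slope and elevation — with a random intercept for the transect
each plot belongs to (plots on a transect share parent material and
drainage).  Predicted or measured P is then binned into three ordinal
classes: low (<300 mg/kg), medium (300-500, bounds included) and high
(>500), which is how soil fertility enters the structural-equation
model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .inventory import PlotRecord, ValidationError

logger = logging.getLogger(__name__)

COVARIATES = ("dist_stream", "slope", "elevation")
LOW_MAX = 300.0    # mg/kg; values below are class 1
HIGH_MIN = 500.0   # mg/kg; values above are class 3


@dataclass
class SoilModel:
    """Random-intercept linear model for total soil P (mg/kg)."""

    coef: dict[str, float]               # original-scale fixed effects
    coef_se: dict[str, float]            # standard errors, original scale
    transect_sd: float
    resid_sd: float
    transect_intercepts: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"coef": self.coef, "coef_se": self.coef_se,
                       "transect_sd": self.transect_sd,
                       "resid_sd": self.resid_sd,
                       "transect_intercepts": self.transect_intercepts,
                       "meta": self.meta}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SoilModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_soil_model(plots: list[PlotRecord]) -> SoilModel:
    """Fit the soil-P mixed model by REML on plots with measured P.

    Covariates are standardized internally for conditioning; reported
    coefficients are back-transformed to original units (mg/kg per m,
    per degree).  A singular random-intercept fit falls back to ordinary
    least squares with a logged warning (transect SD reported as 0).
    """
    rows = [p for p in plots if p.soilP_measured is not None]
    counts: dict[str, int] = {}
    for p in rows:
        counts[p.transect_id] = counts.get(p.transect_id, 0) + 1
    if sum(1 for n in counts.values() if n >= 2) < 2:
        raise ValidationError(
            "need >= 2 transects with >= 2 measured plots each")
    df = pd.DataFrame({
        "soilP": [p.soilP_measured for p in rows],
        "transect": [p.transect_id for p in rows],
        **{c: [getattr(p, c) for p in rows] for c in COVARIATES},
    })
    means = {c: float(df[c].mean()) for c in COVARIATES}
    sds = {}
    unidentifiable = []
    for c in COVARIATES:
        sd = float(df[c].std())
        if sd < 1e-12:
            unidentifiable.append(c)
            sd = 1.0
        sds[c] = sd
        df[c + "_z"] = (df[c] - means[c]) / sd
    if unidentifiable:
        logger.warning("constant covariates, coefficients unidentifiable: %s",
                       unidentifiable)

    formula = "soilP ~ " + " + ".join(c + "_z" for c in COVARIATES)
    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.mixedlm(formula, df, groups=df["transect"]).fit(reml=True)
            tvar = float(res.cov_re.iloc[0, 0])
            singular = not np.isfinite(tvar) or tvar < 1e-10
        except Exception:
            singular = True
    if singular:
        logger.warning("singular mixed fit; falling back to OLS")
        ols = smf.ols(formula, df).fit()
        params, bse = ols.params, ols.bse
        transect_sd, resid_sd = 0.0, float(np.sqrt(ols.mse_resid))
        re_map: dict[str, float] = {}
    else:
        params, bse = res.fe_params, res.bse_fe
        transect_sd = float(np.sqrt(tvar))
        resid_sd = float(np.sqrt(res.scale))
        re_map = {k: float(v.iloc[0]) for k, v in res.random_effects.items()}

    coef = {c: float(params[c + "_z"]) / sds[c] for c in COVARIATES}
    coef_se = {c: float(bse[c + "_z"]) / sds[c] for c in COVARIATES}
    for c in unidentifiable:
        coef[c] = 0.0
        coef_se[c] = float("nan")
    intercept = float(params["Intercept"]) - sum(
        coef[c] * means[c] for c in COVARIATES)
    return SoilModel(coef={"intercept": intercept, **coef},
                     coef_se={"intercept": float(bse["Intercept"]), **coef_se},
                     transect_sd=transect_sd, resid_sd=resid_sd,
                     transect_intercepts=re_map,
                     meta={"n_plots": len(rows), "n_transects": len(counts),
                           "singular_fallback": singular,
                           "unidentifiable": unidentifiable})


def predict_soilP(plot: PlotRecord, model: SoilModel) -> float:
    """Predicted soil P (mg/kg): fixed effects plus the plot's transect
    intercept when that transect was in the training data."""
    for c in COVARIATES:
        if getattr(plot, c) is None:
            raise ValidationError(f"plot {plot.plot_id}: missing {c}")
    y = model.coef["intercept"] + sum(
        model.coef[c] * getattr(plot, c) for c in COVARIATES)
    y += model.transect_intercepts.get(plot.transect_id, 0.0)
    return float(y)


def classify_soilP(value: float) -> int:
    """Three-class ordinal soil P: <300 -> 1, 300-500 (inclusive) -> 2,
    >500 -> 3 (mg/kg)."""
    if value < 0:
        raise ValidationError("soil P cannot be negative")
    if value < LOW_MAX:
        return 1
    if value <= HIGH_MIN:
        return 2
    return 3


def assign_soil_classes(plots: list[PlotRecord],
                        model: SoilModel) -> list[PlotRecord]:
    """Fill in soilP_class for every plot: measured P keeps its measured
    class (prediction never overrides measurement); unmeasured plots get
    the class of their model prediction.  Returns the same records,
    mutated in place."""
    for p in plots:
        if p.soilP_measured is not None:
            p.soilP_class = classify_soilP(p.soilP_measured)
        elif p.soilP_class is None:
            p.soilP_class = classify_soilP(max(predict_soilP(p, model), 0.0))
    return plots
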