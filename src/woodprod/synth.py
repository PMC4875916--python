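"""Synthetic plot-network generator with known ground truth.

Emulates a nested circular-plot census of tropical moist forest: stems
>= 30 cm measured over the full 0.125-ha plot, stems >= 10 cm in a
0.0125-ha central subplot; species drawn from a log-series pool and
grouped into genera; second-census diameters generated from the
asymmetric-competition growth function with log-normal genus deviations
and Gaussian measurement noise over a 5-7 year interval; background
mortality (default 1.2%/yr) and recruitment; selective logging
implemented as size-biased removal of large stems calibrated by
bisection to a target quadratic-mean-diameter deficit (default 5 cm);
and a soil-phosphorus gradient structured by stream distance, slope and
elevation with transect-level intercepts.

Plot-level modifiers let tree diversity and soil P boost the growth
scale, so the drivers the structural-equation analysis looks for are
present by construction.  Everything is reproducible from the seed, and
the generator returns the exact latent quantities used (GroundTruth)
for recovery testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .growth import GrowthParams, competition_indices, growth_function
from .inventory import (AREA_INNER, AREA_OUTER, INNER_MIN_D, OUTER_MIN_D,
                        PlotRecord, TreeRecord, write_census)
from .stand_metrics import effective_species


class SynthesisError(RuntimeError):
    pass


@dataclass
class SynthConfig:
    """Generator settings; the defaults describe the emulated study design."""

    seed: int
    n_plots: int = 140
    n_transects: int = 14
    fraction_logged: float = 88 / 142
    # growth-function truth
    growth: GrowthParams = field(default_factory=lambda: GrowthParams(
        rho0=0.35, rho1=0.4, rho2=-0.008, rho3=1.2, rho4=0.04,
        sigma_genus=0.2, sigma_resid=0.08))
    # community structure
    n_species: int = 167
    n_genera: int = 60
    logseries_x: float = 0.985
    id_frac_species: float = 0.90   # fraction of stems identified to species
    id_frac_genus: float = 0.94
    # stand structure
    stems_outer_mean: float = 12.0   # >=30 cm stems per 0.125-ha plot
    stems_inner_mean: float = 4.6    # 10-30 cm stems per 0.0125-ha subplot
    outer_tail_scale: float = 11.0   # cm, exponential tail above 30 cm
    inner_tail_scale: float = 8.0    # cm, truncated tail above 10 cm
    d_max: float = 180.0
    # dynamics
    mortality_rate: float = 0.012        # /yr
    recruitment_rate: float = 0.018      # per stem-year
    delta_t_range: tuple[float, float] = (5.0, 7.0)
    n_mass_mortality_plots: int = 2      # plots with catastrophic mortality
    mass_mortality_frac: float = 0.85
    # logging signature
    logging_qmd_deficit: float = 5.0     # cm
    logging_d_scale: float = 8.0         # cm, removal-probability width
    # plot-level growth modifiers (drivers the SEM should recover)
    diversity_effect: float = 0.10       # on log growth scale, per SD
    soilp_effect: float = 0.10
    # soil model truth
    soil_coefs: dict = field(default_factory=lambda: {
        "intercept": 455.0, "dist_stream": 0.4, "slope": -4.0,
        "elevation": -0.3})
    soil_transect_sd: float = 60.0
    soil_resid_sd: float = 80.0
    n_soil_sampled: int = 48
    # measurement pathology
    gross_error_frac: float = 0.01
    round_dp: int | None = 1             # diameters recorded to 0.1 cm
    # wood density population
    wd_genus_mean: float = 0.60
    wd_genus_sd: float = 0.08
    wd_species_sd: float = 0.04

    def validate(self) -> None:
        for r in (self.fraction_logged, self.mortality_rate,
                  self.recruitment_rate, self.gross_error_frac):
            if not 0 <= r <= 1:
                raise SynthesisError(f"rate {r} outside [0, 1]")
        if self.seed is None:
            raise SynthesisError("seed is mandatory")


def _rnd(cfg: SynthConfig, v: float) -> float:
    return round(v, cfg.round_dp) if cfg.round_dp is not None else v


@dataclass
class GroundTruth:
    """Latent quantities behind one generated dataset."""

    config: SynthConfig
    growth: GrowthParams                 # incl. realized genus deviations
    species_genus: dict[str, str]
    plot_soilP: dict[str, float]
    plot_growth_multiplier: dict[str, float]
    tree_latent_growth: dict[str, float]   # cm/yr before noise
    error_tree_ids: list[str]
    logging_removal_midpoint: float  # cm, calibrated sigmoid midpoint

    def to_json(self, path) -> None:
        d = {
            "growth": {k: v for k, v in asdict(self.growth).items()
                       if k != "meta"},
            "species_genus": self.species_genus,
            "plot_soilP": self.plot_soilP,
            "plot_growth_multiplier": self.plot_growth_multiplier,
            "tree_latent_growth": self.tree_latent_growth,
            "error_tree_ids": self.error_tree_ids,
            "logging_removal_midpoint": self.logging_removal_midpoint,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


# ---------------------------------------------------------------------------
# helpers

def _logseries_abundances(n_species: int, x: float,
                          rng: np.random.Generator) -> np.ndarray:
    k = np.arange(1, n_species + 1)
    w = x ** k / k
    rng.shuffle(w)
    return w / w.sum()


def _draw_outer_d(n: int, cfg: SynthConfig, rng) -> np.ndarray:
    d = OUTER_MIN_D + rng.exponential(cfg.outer_tail_scale, size=n)
    return np.minimum(d, cfg.d_max)


def _draw_inner_d(n: int, cfg: SynthConfig, rng) -> np.ndarray:
    span = OUTER_MIN_D - INNER_MIN_D
    d = rng.exponential(cfg.inner_tail_scale, size=n) % span
    return INNER_MIN_D + d


def _removal_prob(d: np.ndarray, d_mid: float, cfg: SynthConfig
                  ) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(d - d_mid) / cfg.logging_d_scale))


def _expected_qmd(d_outer, d_inner, keep_outer=None) -> float:
    """Expansion-weighted pooled QMD of a stem population."""
    w_out = np.full(len(d_outer), 1 / AREA_OUTER)
    if keep_outer is not None:
        w_out = w_out * keep_outer
    w_in = np.full(len(d_inner), 1 / AREA_INNER)
    num = float(np.sum(d_outer ** 2 * w_out) + np.sum(d_inner ** 2 * w_in))
    den = float(w_out.sum() + w_in.sum())
    return math.sqrt(num / den)


def _calibrate_logging(cfg: SynthConfig, rng: np.random.Generator) -> float:
    """Bisect the size midpoint of the removal-probability sigmoid so the
    expected QMD deficit matches the configured target.

    Lower midpoints remove smaller (hence more) stems; the probability of
    removal always rises with diameter, so removal stays size-biased."""
    n_mc = 40000
    d_out = _draw_outer_d(n_mc, cfg, rng)
    n_in = int(n_mc * cfg.stems_inner_mean / cfg.stems_outer_mean)
    d_in = _draw_inner_d(n_in, cfg, rng)
    base = _expected_qmd(d_out, d_in)

    def deficit(d_mid: float) -> float:
        keep = 1.0 - _removal_prob(d_out, d_mid, cfg)
        return base - _expected_qmd(d_out, d_in, keep_outer=keep)

    lo_mid, hi_mid = INNER_MIN_D, 250.0
    hi = deficit(lo_mid)
    if hi < cfg.logging_qmd_deficit:
        raise SynthesisError(
            f"QMD deficit target {cfg.logging_qmd_deficit} cm unachievable: "
            f"even removing every large stem yields only {hi:.2f} cm")
    for _ in range(60):
        mid = (lo_mid + hi_mid) / 2
        # deficit decreases as the midpoint rises
        if deficit(mid) > cfg.logging_qmd_deficit:
            lo_mid = mid
        else:
            hi_mid = mid
    return (lo_mid + hi_mid) / 2


# ---------------------------------------------------------------------------
# main generator

def generate(cfg: SynthConfig
             ) -> tuple[list[TreeRecord], list[PlotRecord], GroundTruth]:
    """Generate one plot network; byte-identical for identical configs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # taxon pool
    abund = _logseries_abundances(cfg.n_species, cfg.logseries_x, rng)
    species = [f"sp{i:03d}" for i in range(cfg.n_species)]
    genera = [f"gen{i:03d}" for i in range(cfg.n_genera)]
    species_genus = {s: genera[i % cfg.n_genera]
                     for i, s in enumerate(species)}
    g_dev = rng.normal(0.0, cfg.growth.sigma_genus, size=cfg.n_genera)
    g_dev -= g_dev.mean()
    genus_effects = {g: math.exp(d) for g, d in zip(genera, g_dev)}
    truth_growth = GrowthParams(
        rho0=cfg.growth.rho0, rho1=cfg.growth.rho1, rho2=cfg.growth.rho2,
        rho3=cfg.growth.rho3, rho4=cfg.growth.rho4,
        genus_effects=genus_effects, sigma_genus=cfg.growth.sigma_genus,
        sigma_resid=cfg.growth.sigma_resid)

    logging_midpoint = (_calibrate_logging(cfg, np.random.default_rng(
        rng.integers(2 ** 31))) if cfg.fraction_logged > 0 else float("inf"))

    # plots, terrain, soil
    n_logged = int(round(cfg.n_plots * cfg.fraction_logged))
    logged_flags = np.array([True] * n_logged
                            + [False] * (cfg.n_plots - n_logged))
    rng.shuffle(logged_flags)
    transect_of = np.arange(cfg.n_plots) % cfg.n_transects
    transect_elev = rng.normal(250.0, 70.0, size=cfg.n_transects)
    transect_icpt = rng.normal(0.0, cfg.soil_transect_sd,
                               size=cfg.n_transects)
    plots: list[PlotRecord] = []
    soilP_latent: dict[str, float] = {}
    sampled = set(rng.choice(cfg.n_plots,
                             size=min(cfg.n_soil_sampled, cfg.n_plots),
                             replace=False).tolist())
    for i in range(cfg.n_plots):
        pid = f"P{i:03d}"
        t = int(transect_of[i])
        slope = float(rng.gamma(2.0, 5.0))
        elev = float(transect_elev[t] + rng.normal(0.0, 30.0))
        dist = float(rng.exponential(200.0))
        c = cfg.soil_coefs
        p_latent = (c["intercept"] + c["dist_stream"] * dist
                    + c["slope"] * slope + c["elevation"] * elev
                    + transect_icpt[t]
                    + rng.normal(0.0, cfg.soil_resid_sd))
        p_latent = max(p_latent, 5.0)
        soilP_latent[pid] = p_latent
        plots.append(PlotRecord(
            plot_id=pid, transect_id=f"T{t:02d}", logged=bool(logged_flags[i]),
            slope=slope, elevation=elev, dist_stream=dist,
            soilP_measured=p_latent if i in sampled else None))

    # census-1 stems
    trees: list[TreeRecord] = []
    tid = 0
    for i, plot in enumerate(plots):
        n_out = max(int(rng.poisson(cfg.stems_outer_mean)), 1)
        n_in = int(rng.poisson(cfg.stems_inner_mean))
        d_out = _draw_outer_d(n_out, cfg, rng)
        if plot.logged:
            keep = rng.random(n_out) >= _removal_prob(
                d_out, logging_midpoint, cfg)
            if not keep.any():
                keep[int(np.argmin(d_out))] = True
            d_out = d_out[keep]
        d_in = _draw_inner_d(n_in, cfg, rng)
        delta_t = float(rng.uniform(*cfg.delta_t_range))
        for d, stratum in [(x, "outer") for x in d_out] + \
                          [(x, "inner") for x in d_in]:
            sp_i = int(rng.choice(cfg.n_species, p=abund))
            sp = species[sp_i]
            gen = species_genus[sp]
            u = rng.random()
            if u > cfg.id_frac_genus:
                sp_lbl, gen_lbl = "", ""
            elif u > cfg.id_frac_species:
                sp_lbl, gen_lbl = "", gen
            else:
                sp_lbl, gen_lbl = sp, gen
            trees.append(TreeRecord(
                tree_id=f"t{tid:05d}", plot_id=plot.plot_id,
                genus=gen_lbl, species=sp_lbl,
                D1=_rnd(cfg, float(d)), D2=None, status="alive",
                delta_t=round(delta_t, 2), stratum=stratum))
            tid += 1

    by_plot: dict[str, list[TreeRecord]] = {}
    for t in trees:
        by_plot.setdefault(t.plot_id, []).append(t)

    # plot-level growth multipliers from diversity and soil P (z-scored
    # within the generated network)
    eff = {}
    for pid, members in by_plot.items():
        try:
            eff[pid] = effective_species(members)
        except Exception:
            eff[pid] = 1.0
    eff_v = np.array([eff[p.plot_id] for p in plots])
    soil_v = np.array([soilP_latent[p.plot_id] for p in plots])
    z_eff = (eff_v - eff_v.mean()) / max(eff_v.std(), 1e-9)
    z_soil = (soil_v - soil_v.mean()) / max(soil_v.std(), 1e-9)
    plot_mult = {p.plot_id: math.exp(cfg.diversity_effect * ze
                                     + cfg.soilp_effect * zs)
                 for p, ze, zs in zip(plots, z_eff, z_soil)}

    # growth, mortality, recruitment
    bl = competition_indices(trees, plots)
    latent_growth: dict[str, float] = {}
    mass_mort = set(rng.choice(cfg.n_plots,
                               size=min(cfg.n_mass_mortality_plots,
                                        cfg.n_plots), replace=False).tolist())
    mass_mort_ids = {plots[i].plot_id for i in mass_mort}
    for t in trees:
        g_latent = (growth_function(t.D1, bl[t.tree_id], truth_growth,
                                    t.genus or None)
                    * plot_mult[t.plot_id])
        latent_growth[t.tree_id] = float(g_latent)
        p_die = (cfg.mass_mortality_frac if t.plot_id in mass_mort_ids
                 else 1.0 - (1.0 - cfg.mortality_rate) ** t.delta_t)
        if rng.random() < p_die:
            t.status = "died"
            t.D2 = None
        else:
            g_obs = g_latent + rng.normal(0.0, cfg.growth.sigma_resid)
            t.D2 = _rnd(cfg, max(t.D1 + g_obs * t.delta_t, 1.0))

    for plot in plots:
        members = by_plot[plot.plot_id]
        delta_t = members[0].delta_t if members else 6.0
        lam = cfg.recruitment_rate * len(members) * delta_t
        for _ in range(int(rng.poisson(lam))):
            stratum = "inner" if rng.random() < 0.7 else "outer"
            base = INNER_MIN_D if stratum == "inner" else OUTER_MIN_D
            sp_i = int(rng.choice(cfg.n_species, p=abund))
            sp = species[sp_i]
            rec = TreeRecord(
                tree_id=f"t{tid:05d}", plot_id=plot.plot_id,
                genus=species_genus[sp], species=sp, D1=None,
                D2=_rnd(cfg, base + float(rng.exponential(2.0))),
                status="recruit", delta_t=delta_t, stratum=stratum)
            trees.append(rec)
            by_plot[plot.plot_id].append(rec)
            tid += 1

    # inject gross measurement errors to exercise screening
    error_ids: list[str] = []
    if cfg.gross_error_frac > 0:
        alive = [t for t in trees if t.status == "alive" and t.D2 is not None]
        n_err = int(rng.binomial(len(alive), cfg.gross_error_frac))
        for t in rng.choice(len(alive), size=n_err, replace=False):
            tr = alive[int(t)]
            if rng.random() < 0.5:
                tr.D2 = _rnd(cfg, tr.D1 + (4.0 + rng.exponential(1.0))
                             * tr.delta_t)
            else:
                tr.D2 = _rnd(cfg, max(tr.D1 - 0.6 - rng.exponential(0.5),
                                      0.5))
            error_ids.append(tr.tree_id)

    truth = GroundTruth(
        config=cfg, growth=truth_growth, species_genus=species_genus,
        plot_soilP=soilP_latent, plot_growth_multiplier=plot_mult,
        tree_latent_growth=latent_growth, error_tree_ids=error_ids,
        logging_removal_midpoint=logging_midpoint)
    return trees, plots, truth


def make_wd_table(truth: GroundTruth, seed: int) -> pd.DataFrame:
    """Wood-density reference (synthetic) matching the generated taxa:
    genus-level means with species-level scatter."""
    cfg = truth.config
    rng = np.random.default_rng(seed)
    genera = sorted(set(truth.species_genus.values()))
    g_wd = {g: float(np.clip(rng.normal(cfg.wd_genus_mean, cfg.wd_genus_sd),
                             0.2, 1.1)) for g in genera}
    rows = []
    for sp, gen in sorted(truth.species_genus.items()):
        wd = float(np.clip(g_wd[gen] + rng.normal(0, cfg.wd_species_sd),
                           0.15, 1.2))
        family = f"fam{int(gen[3:]) % 20:02d}"
        rows.append({"family": family, "genus": gen, "species": sp, "wd": wd})
    return pd.DataFrame(rows)


def end_to_end_fixture(scale: str, outdir, seed: int = 20160518) -> dict:
    """Write a complete pipeline input set (census, plots, wood density,
    ground truth) to ``outdir`` and return the file paths.

    ``small`` (30 plots) runs the whole pipeline in well under two
    minutes; ``full`` matches the emulated study layout (140 plots,
    median about 17 stems per plot).
    """
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scale == "small":
        cfg = SynthConfig(seed=seed, n_plots=30, n_transects=6,
                          n_soil_sampled=18, n_mass_mortality_plots=1)
    elif scale == "full":
        cfg = SynthConfig(seed=seed)
    else:
        raise SynthesisError(f"unknown scale {scale!r}")
    trees, plots, truth = generate(cfg)
    paths = {
        "census": outdir / "census.csv",
        "plots": outdir / "plots.csv",
        "wd": outdir / "wood_density.csv",
        "truth": outdir / "ground_truth.json",
    }
    write_census(trees, plots, paths["census"], paths["plots"])
    make_wd_table(truth, seed=seed + 1).to_csv(paths["wd"], index=False)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def recovery_config(seed: int, n_plots: int = 420, n_genera: int = 30,
                    noiseless: bool = False) -> SynthConfig:
    """A generator configuration for growth-model parameter recovery:
    plot network sized to about 5000 stems over ``n_genera`` genera, with
    mortality, recruitment, gross errors and plot-level growth modifiers
    switched off so the measured increments follow the growth function
    plus (optionally zero) residual noise exactly."""
    cfg = SynthConfig(seed=seed, n_plots=n_plots, n_transects=20,
                      n_genera=n_genera, n_mass_mortality_plots=0,
                      gross_error_frac=0.0, mortality_rate=0.0,
                      recruitment_rate=0.0, diversity_effect=0.0,
                      soilp_effect=0.0)
    if noiseless:
        cfg.growth.sigma_resid = 0.0
        cfg.growth.sigma_genus = 1e-12
        cfg.round_dp = None
    return cfg
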