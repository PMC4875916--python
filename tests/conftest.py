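import numpy as np
import pytest

import woodprod as wp
from woodprod.synth import recovery_config


def make_tree(tree_id="t1", plot_id="P1", genus="Gilbertiodendron",
              species="preussii", D1=40.0, D2=43.0, status="alive",
              delta_t=6.0, stratum="outer"):
    return wp.TreeRecord(tree_id=tree_id, plot_id=plot_id, genus=genus,
                         species=species, D1=D1, D2=D2, status=status,
                         delta_t=delta_t, stratum=stratum)


def make_plot(plot_id="P1", transect_id="T1", logged=False, slope=10.0,
              elevation=200.0, dist_stream=150.0, **kw):
    return wp.PlotRecord(plot_id=plot_id, transect_id=transect_id,
                         logged=logged, slope=slope, elevation=elevation,
                         dist_stream=dist_stream, **kw)


@pytest.fixture(scope="session")
def small_network():
    """A 30-plot synthetic network with default dynamics."""
    cfg = wp.SynthConfig(seed=1234, n_plots=30, n_transects=6,
                         n_soil_sampled=18, n_mass_mortality_plots=1)
    return wp.generate(cfg)


@pytest.fixture(scope="session")
def clean_network():
    """Noise-free network: no deaths, recruits, errors or rounding, so
    measured growth equals the growth function exactly."""
    cfg = recovery_config(777, n_plots=40, noiseless=True)
    return wp.generate(cfg)


#: true parameters of the default drivers-of-AWP path model used in the
#: SEM simulation tests (transformed scale)
SEM_TRUTH = {
    "BA->AWP": 0.55, "diversity->AWP": 0.02, "soilP->AWP": 0.08,
    "n_stems->diversity": 2.5, "soilP->diversity": 0.5,
    "logged->diversity": -0.3,
    "logged->QMD": -0.18, "slope->QMD": -0.002,
    "var(AWP)": 0.03, "var(QMD)": 0.02, "var(n_stems)": 0.16,
    "var(diversity)": 4.0, "var(soilP)": 0.55, "var(logged)": 0.24,
    "var(slope)": 50.0,
    "cov(n_stems,QMD)": -0.02,
}


@pytest.fixture(scope="session")
def sem_truth():
    return dict(SEM_TRUTH)


@pytest.fixture(scope="session")
def sem_dataset(sem_truth):
    spec = wp.build_default_spec()
    rng = np.random.default_rng(20160518)
    return spec, wp.simulate_from_spec(spec, sem_truth, 500, rng)
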