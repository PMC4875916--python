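"""Structural-equation engine: specification, ML estimation, fit indices.

The estimation checks compare against an oracle coded independently in
this file: it assembles the implied covariance directly from explicit
structural equations (not via the engine's parameter map) and minimizes
the same Wishart discrepancy with a generic simplex search.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import woodprod as wp
from woodprod.sem import SEMError, _ParamMap, apply_transforms


def _cov_frame(df, spec):
    table = apply_transforms(df, spec)
    return np.cov(table.to_numpy(), rowvar=False, ddof=1)


class TestSpec:
    def test_default_spec_shape(self):
        spec = wp.build_default_spec()
        spec.validate()
        assert len(spec.variables) == 7
        assert set(spec.composites) == {"BA"}
        assert not spec.composites["BA"].free_loadings
        assert spec.composites["BA"].weights == {"QMD": 2.0, "n_stems": 1.0}

    def test_composite_weights_are_not_free_parameters(self):
        pm = _ParamMap(wp.build_default_spec())
        assert not any(n.startswith("BA=") for n in pm.names)
        pm_free = _ParamMap(wp.build_default_spec(free_loadings=True))
        assert "BA=n_stems" in pm_free.names

    def test_removing_composite_path_increases_df(self):
        spec = wp.build_default_spec()
        df_full = _ParamMap(spec).df
        spec2 = wp.build_default_spec()
        spec2.paths = [p for p in spec2.paths if p.src != "BA"]
        assert _ParamMap(spec2).df == df_full + 1

    def test_cycle_rejected(self):
        spec = wp.SEMSpec(variables=["x", "y"],
                          paths=[wp.Path("x", "y"), wp.Path("y", "x")])
        with pytest.raises(SEMError, match="cycle"):
            spec.validate()

    def test_undeclared_variable_rejected(self):
        spec = wp.SEMSpec(variables=["x"], paths=[wp.Path("x", "z")])
        with pytest.raises(SEMError):
            spec.validate()


class TestFitBasics:
    def test_saturated_model_has_zero_discrepancy(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=200),
                           "y": rng.normal(size=200)})
        df["y"] += 0.5 * df["x"]
        spec = wp.SEMSpec(variables=["x", "y"], paths=[wp.Path("x", "y")])
        fit = wp.fit_ml(df, spec)
        assert fit.df == 0
        assert fit.F_min == pytest.approx(0.0, abs=1e-10)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-7)
        assert fit.rmsea == 0.0
        assert fit.cfi == 1.0
        assert fit.srmr == pytest.approx(0.0, abs=1e-6)

    def test_single_edge_standardized_equals_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = 0.7 * x + rng.normal(size=300)
        df = pd.DataFrame({"x": x, "y": y})
        spec = wp.SEMSpec(variables=["x", "y"], paths=[wp.Path("x", "y")])
        fit = wp.fit_ml(df, spec)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.std_paths["x->y"] == pytest.approx(r, abs=1e-6)
        # one-predictor R^2 is the squared standardized coefficient
        assert fit.r2["y"] == pytest.approx(r ** 2, abs=1e-6)

    def test_singular_sample_covariance_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        spec = wp.SEMSpec(variables=["x", "y"], paths=[wp.Path("x", "y")])
        with pytest.raises(SEMError, match="positive definite"):
            wp.fit_ml(df, spec)

    def test_affine_rescaling_leaves_standardized_solution(self, sem_dataset):
        spec, df = sem_dataset
        fit1 = wp.fit_ml(df, spec, compute_se=False)
        df2 = df.copy()
        df2["slope"] = 3.0 * df2["slope"] + 11.0
        df2["diversity"] = 0.1 * df2["diversity"]
        fit2 = wp.fit_ml(df2, spec, compute_se=False)
        for k in fit1.std_paths:
            assert fit2.std_paths[k] == pytest.approx(fit1.std_paths[k],
                                                      abs=1e-5), k
        assert fit2.F_min == pytest.approx(fit1.F_min, abs=1e-8)

    def test_freeing_a_parameter_never_worsens_fit(self, sem_dataset):
        spec, df = sem_dataset
        fit = wp.fit_ml(df, spec, compute_se=False)
        spec2 = wp.build_default_spec()
        spec2.paths.append(wp.Path("slope", "AWP"))
        fit2 = wp.fit_ml(df, spec2, compute_se=False)
        assert fit2.F_min <= fit.F_min + 1e-9
        assert fit2.df == fit.df - 1

    def test_standardizing_twice_is_idempotent(self, sem_dataset):
        spec, df = sem_dataset
        fit = wp.fit_ml(df, spec, compute_se=False)
        first = dict(fit.std_paths)
        wp.standardize_and_r2(fit)
        assert fit.std_paths == first


class TestIndices:
    def test_chi2_below_df_gives_zero_rmsea(self):
        fit = wp.SEMFit(
            spec=wp.SEMSpec(variables=["x"]), param_names=[],
            estimates=np.array([]), se=None, S=np.eye(2), Sigma=np.eye(2),
            N=100, F_min=0.01, chi2=1.0, df=5, p_value=0.9,
            chi2_baseline=50.0, df_baseline=1)
        rmsea, cfi, srmr = wp.fit_indices(fit)
        assert rmsea == 0.0
        assert cfi == 1.0

    def test_perfect_fit_identities(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        fit = wp.SEMFit(
            spec=wp.SEMSpec(variables=["x"]), param_names=[],
            estimates=np.array([]), se=None, S=S, Sigma=S.copy(),
            N=100, F_min=0.0, chi2=0.0, df=1, p_value=1.0,
            chi2_baseline=9.3, df_baseline=1)
        rmsea, cfi, srmr = wp.fit_indices(fit)
        assert (rmsea, cfi, srmr) == (0.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# oracle comparison on a 5-variable path model

ORACLE_TRUTH = {
    "x1->y1": 0.8, "x2->y1": -0.4, "y1->y2": 0.6, "x3->y2": 0.3,
    "var(x1)": 1.0, "var(x2)": 2.0, "var(x3)": 1.5,
    "var(y1)": 0.5, "var(y2)": 0.7,
    "cov(x1,x2)": 0.3, "cov(x1,x3)": -0.2, "cov(x2,x3)": 0.4,
}


def _oracle_spec():
    return wp.SEMSpec(
        variables=["x1", "x2", "x3", "y1", "y2"],
        paths=[wp.Path("x1", "y1"), wp.Path("x2", "y1"),
               wp.Path("y1", "y2"), wp.Path("x3", "y2")])


def _oracle_sigma(theta):
    """Implied covariance written out longhand from the equations
    y1 = b1 x1 + b2 x2 + e1;  y2 = b3 y1 + b4 x3 + e2."""
    b1, b2, b3, b4, v1, v2, v3, p1, p2, c12, c13, c23 = theta
    Sx = np.array([[v1, c12, c13], [c12, v2, c23], [c13, c23, v3]])
    # moments of y1
    w1 = np.array([b1, b2, 0.0])
    var_y1 = w1 @ Sx @ w1 + p1
    cov_x_y1 = Sx @ w1
    # y2 = b3*y1 + b4*x3 + e2
    var_y2 = b3 ** 2 * var_y1 + b4 ** 2 * v3 + 2 * b3 * b4 * cov_x_y1[2] + p2
    cov_x_y2 = b3 * cov_x_y1 + b4 * Sx[:, 2]
    cov_y1_y2 = b3 * var_y1 + b4 * cov_x_y1[2]
    S = np.zeros((5, 5))
    S[:3, :3] = Sx
    S[:3, 3] = S[3, :3] = cov_x_y1
    S[:3, 4] = S[4, :3] = cov_x_y2
    S[3, 3] = var_y1
    S[4, 4] = var_y2
    S[3, 4] = S[4, 3] = cov_y1_y2
    return S


def _oracle_minimize(S):
    sign, logdet_S = np.linalg.slogdet(S)

    def F(theta):
        Sig = _oracle_sigma(theta)
        s2, ld = np.linalg.slogdet(Sig)
        if s2 <= 0:
            return 1e9
        return ld + np.trace(np.linalg.solve(Sig, S)) - logdet_S - 5

    x0 = np.array([0.5, -0.5, 0.5, 0.5, 1, 1, 1, 1, 1, 0, 0, 0], float)
    res = optimize.minimize(F, x0, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14,
                                     "maxiter": 60000, "maxfev": 60000})
    res = optimize.minimize(F, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-13, "fatol": 1e-15,
                                     "maxiter": 60000, "maxfev": 60000})
    return res


@pytest.fixture(scope="module")
def oracle_data():
    spec = _oracle_spec()
    rng = np.random.default_rng(55)
    df = wp.simulate_from_spec(spec, ORACLE_TRUTH, 500, rng)
    return spec, df


class TestOracleEquivalence:
    def test_discrepancy_and_estimates_match_oracle(self, oracle_data):
        spec, df = oracle_data
        fit = wp.fit_ml(df, spec, compute_se=False)
        S = _cov_frame(df, spec)
        res = _oracle_minimize(S)
        assert fit.F_min == pytest.approx(res.fun, abs=1e-6)
        oracle_names = ["x1->y1", "x2->y1", "y1->y2", "x3->y2"]
        for i, name in enumerate(oracle_names):
            assert fit.estimate(name) == pytest.approx(res.x[i],
                                                       abs=1e-4), name

    def test_estimates_within_2se_of_truth(self, oracle_data):
        spec, df = oracle_data
        fit = wp.fit_ml(df, spec)
        for name in ("x1->y1", "x2->y1", "y1->y2", "x3->y2"):
            err = abs(fit.estimate(name) - ORACLE_TRUTH[name])
            assert err < 2.5 * fit.std_error(name), name

    def test_fit_indices_match_independent_formulas(self, oracle_data):
        spec, df = oracle_data
        fit = wp.fit_ml(df, spec, compute_se=False)
        N, chi2, dof = fit.N, fit.chi2, fit.df
        rmsea = math.sqrt(max(chi2 - dof, 0) / (dof * (N - 1)))
        denom = max(fit.chi2_baseline - fit.df_baseline, chi2 - dof, 0)
        cfi = 1 - max(chi2 - dof, 0) / denom
        assert fit.rmsea == pytest.approx(rmsea, abs=1e-10)
        assert fit.cfi == pytest.approx(cfi, abs=1e-10)
        # SRMR recomputed from the residual correlation matrix
        ds = np.sqrt(np.diag(fit.S))
        dm = np.sqrt(np.diag(fit.Sigma))
        resid = fit.S / np.outer(ds, ds) - fit.Sigma / np.outer(dm, dm)
        terms = [resid[i, j] ** 2 for i in range(5) for j in range(i, 5)]
        assert fit.srmr == pytest.approx(math.sqrt(np.mean(terms)),
                                         abs=1e-10)


class TestDefaultModelRecovery:
    def test_ba_path_dominates_and_truth_recovered(self, sem_dataset,
                                                   sem_truth):
        spec, df = sem_dataset
        fit = wp.fit_ml(df, spec)
        directed = {k: abs(v) for k, v in fit.std_paths.items()
                    if "->BA" not in k}
        assert max(directed, key=directed.get) == "BA->AWP"
        for name in ("BA->AWP", "n_stems->diversity", "logged->QMD"):
            assert abs(fit.estimate(name) - sem_truth[name]) \
                < 3 * fit.std_error(name), name

    def test_r2_in_unit_interval(self, sem_dataset):
        spec, df = sem_dataset
        fit = wp.fit_ml(df, spec, compute_se=False)
        for v, r2 in fit.r2.items():
            assert 0.0 <= r2 <= 1.0, v

    def test_free_loading_composite_fits_no_worse(self, sem_dataset):
        spec, df = sem_dataset
        fit_fixed = wp.fit_ml(df, spec, compute_se=False)
        fit_free = wp.fit_ml(df, wp.build_default_spec(free_loadings=True),
                             compute_se=False)
        assert fit_free.df == fit_fixed.df - 1
        assert fit_free.F_min <= fit_fixed.F_min + 1e-8
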