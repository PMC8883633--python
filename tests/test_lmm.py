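"""Mixed-model engine: likelihood correctness, Wald tests, diagnostics.

Two independent oracles check the fitter: a dense multivariate-normal
evaluation of the marginal likelihood on small data, and statsmodels
MixedLM (ML) on a moderate dataset.
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from hcpmediate import MixedModelSpec, fit_lmm, generate_trial, wald_test
from hcpmediate.data import ConfigError, TrialDataset, center_within_cluster
from hcpmediate.lmm import RankDeficiencyError, build_design
from hcpmediate.simulate import scenario_individual_paradox, scenario_s0


def dense_loglik(fit, df, spec):
    """Stacked multivariate-normal log-density at the fitted parameters."""
    y, X, Z, codes = build_design(df, spec)
    beta = np.array([fit.estimate(t) for t in spec.fixed_names])
    vc = fit.variance_components
    q = spec.n_random
    G = np.zeros((q, q))
    G[0, 0] = vc["var_intercept"]
    if q == 2:
        G[1, 1] = vc["var_slope"]
        if spec.slope_cov:
            G[0, 1] = G[1, 0] = vc["cov_intercept_slope"]
    V = vc["var_residual"] * np.eye(len(y))
    for j in np.unique(codes):
        idx = np.where(codes == j)[0]
        V[np.ix_(idx, idx)] += Z[idx] @ G @ Z[idx].T
    return multivariate_normal.logpdf(y, X @ beta, V)


@pytest.fixture(scope="module")
def tiny_frame():
    rng = np.random.default_rng(7)
    J, n = 5, 5
    cl = np.repeat(np.arange(J), n)
    T = (np.arange(J) % 2)[cl]
    x = rng.normal(size=J * n)
    slope = 0.3 + 0.25 * rng.normal(size=J)
    y = (
        1.0
        + 0.5 * T
        + slope[cl] * x
        + rng.normal(0, 0.6, J)[cl]
        + rng.normal(size=J * n)
    )
    return pd.DataFrame({"cluster": cl, "treatment": T, "x": x, "outcome": y})


SPECS = [
    MixedModelSpec("outcome", ("treatment", "x")),
    MixedModelSpec("outcome", ("treatment", "x"), random_slope="x"),
    MixedModelSpec("outcome", ("treatment", "x"), random_slope="x", slope_cov=False),
]


@pytest.mark.parametrize("spec", SPECS, ids=["intercept", "slope+cov", "slope"])
def test_loglik_matches_dense_mvn_oracle(tiny_frame, spec):
    fit = fit_lmm(spec, tiny_frame)
    assert fit.loglik == pytest.approx(dense_loglik(fit, tiny_frame, spec), abs=1e-6)


def test_matches_statsmodels_mixedlm():
    import statsmodels.formula.api as smf

    scn = dataclasses.replace(
        scenario_individual_paradox(), J=30, n_per_cluster=40
    )
    work = center_within_cluster(generate_trial(scn, 5))
    spec = MixedModelSpec(
        "outcome",
        ("treatment", "mediator_dev", "mediator_cluster_mean",
         "treatment:mediator_dev"),
        random_slope="mediator_dev",
    )
    fit = fit_lmm(spec, work)
    wdf = work.df.assign(txdev=work.df.treatment * work.df.mediator_dev)
    sm = smf.mixedlm(
        "outcome ~ treatment + mediator_dev + mediator_cluster_mean + txdev",
        wdf,
        groups=wdf.cluster,
        re_formula="~mediator_dev",
    ).fit(reml=False)
    assert fit.loglik >= sm.llf - 1e-4  # our optimum at least as good
    assert fit.estimate("treatment") == pytest.approx(
        sm.fe_params["treatment"], abs=1e-3
    )
    assert fit.estimate("treatment:mediator_dev") == pytest.approx(
        sm.fe_params["txdev"], abs=1e-3
    )
    assert fit.se("treatment:mediator_dev") == pytest.approx(
        sm.bse_fe["txdev"], rel=1e-2
    )
    vc = fit.variance_components
    assert vc["var_residual"] == pytest.approx(sm.scale, rel=1e-3)
    assert vc["var_intercept"] == pytest.approx(sm.cov_re.iloc[0, 0], rel=1e-2)


def test_singleton_clusters_reduce_to_ols(tiny_frame):
    df = tiny_frame.copy()
    df["cluster"] = np.arange(len(df))  # every row its own cluster
    spec = MixedModelSpec("outcome", ("treatment", "x"))
    with pytest.warns(UserWarning, match="unidentified"):
        fit = fit_lmm(spec, df)
    X = np.column_stack([np.ones(len(df)), df.treatment, df.x])
    beta_ols = np.linalg.lstsq(X, df.outcome, rcond=None)[0]
    assert np.allclose(
        [fit.estimate(t) for t in spec.fixed_names], beta_ols, atol=1e-6
    )
    assert fit.at_boundary


def test_estimates_invariant_under_within_cluster_permutation(s0_dataset):
    spec = MixedModelSpec("outcome", ("treatment", "mediator"))
    fit1 = fit_lmm(spec, s0_dataset)
    rng = np.random.default_rng(0)
    order = np.concatenate(
        [
            rng.permutation(ix)
            for ix in s0_dataset.df.groupby("cluster", sort=False).indices.values()
        ]
    )
    fit2 = fit_lmm(
        spec, TrialDataset(df=s0_dataset.df.iloc[order].reset_index(drop=True))
    )
    assert np.allclose(fit1.estimates, fit2.estimates, atol=1e-6)


def test_deterministic_refit(s0_dataset):
    spec = MixedModelSpec("outcome", ("treatment", "mediator"))
    fit1 = fit_lmm(spec, s0_dataset)
    fit2 = fit_lmm(spec, s0_dataset)
    assert np.array_equal(fit1.estimates, fit2.estimates)
    assert fit1.loglik == fit2.loglik


def test_monotone_likelihood_in_nesting(s0_dataset):
    work = center_within_cluster(s0_dataset)
    small = fit_lmm(MixedModelSpec("outcome", ("treatment",)), work)
    mid = fit_lmm(MixedModelSpec("outcome", ("treatment", "mediator_dev")), work)
    big = fit_lmm(
        MixedModelSpec(
            "outcome", ("treatment", "mediator_dev"), random_slope="mediator_dev"
        ),
        work,
    )
    tol = 1e-6
    assert mid.loglik >= small.loglik - tol
    assert big.loglik >= mid.loglik - tol


def test_rank_deficiency_names_collinear_term(tiny_frame):
    df = tiny_frame.assign(x_copy=tiny_frame.x)
    with pytest.raises(RankDeficiencyError, match="x_copy"):
        fit_lmm(MixedModelSpec("outcome", ("treatment", "x", "x_copy")), df)


def test_unknown_term_is_config_error(tiny_frame):
    with pytest.raises(ConfigError, match="nope"):
        fit_lmm(MixedModelSpec("outcome", ("nope",)), tiny_frame)


def test_parameter_covariance_symmetric_psd(s0_dataset):
    fit = fit_lmm(MixedModelSpec("outcome", ("treatment", "mediator")), s0_dataset)
    C = fit.parameter_covariance
    assert np.allclose(C, C.T)
    eigs = np.linalg.eigvalsh(C)
    assert eigs.min() > -1e-8 * max(eigs.max(), 1.0)
    assert np.isfinite(fit.loglik)


class TestWald:
    def test_zero_estimate_gives_zero_statistic(self, tiny_frame):
        spec = MixedModelSpec("outcome", ("treatment", "x"))
        fit = fit_lmm(spec, tiny_frame)
        forced = dataclasses.replace(
            fit,
            estimates=np.where(
                np.array(fit.param_names) == "treatment", 0.0, fit.estimates
            ),
        )
        res = wald_test(forced, ["treatment"])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_closed_form_single_constraint(self, tiny_frame):
        spec = MixedModelSpec("outcome", ("treatment", "x"))
        fit = fit_lmm(spec, tiny_frame)
        i = fit.param_names.index("treatment")
        est = np.array(fit.estimates)
        est[i] = 2.0
        cov = np.array(fit.parameter_covariance)
        cov[i, i] = 1.0
        forced = dataclasses.replace(
            fit, estimates=est, parameter_covariance=cov
        )
        res = wald_test(forced, ["treatment"])
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_df_equals_constraint_count(self, s0_dataset):
        work = center_within_cluster(s0_dataset)
        fit = fit_lmm(
            MixedModelSpec(
                "outcome",
                ("treatment", "mediator_dev", "treatment:mediator_dev"),
                random_slope="mediator_dev",
            ),
            work,
        )
        res = wald_test(
            fit, ["treatment:mediator_dev", "var_slope", "cov_intercept_slope"]
        )
        assert res.df == 3
        assert res.statistic >= 0
        assert 0 <= res.p_value <= 1

    def test_single_constraint_matches_z_squared(self, s0_dataset):
        fit = fit_lmm(
            MixedModelSpec("outcome", ("treatment", "mediator")), s0_dataset
        )
        res = wald_test(fit, ["mediator"])
        z = fit.estimate("mediator") / fit.se("mediator")
        assert res.statistic == pytest.approx(z**2, rel=1e-10)
        assert res.p_value == pytest.approx(fit.z_p_value("mediator"), rel=1e-9)

    def test_empty_constraint_rejected(self, tiny_frame):
        fit = fit_lmm(MixedModelSpec("outcome", ("treatment", "x")), tiny_frame)
        with pytest.raises(ValueError):
            wald_test(fit, [])


def test_json_serialisation_round_trips(tiny_frame):
    import json

    fit = fit_lmm(MixedModelSpec("outcome", ("treatment", "x")), tiny_frame)
    payload = json.loads(fit.to_json())
    assert payload["loglik"] == pytest.approx(fit.loglik)
    assert payload["convergence"]["converged"] is True
    assert set(payload["fixed_effects"]) == {"Intercept", "treatment", "x"}
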