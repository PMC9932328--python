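"""Mixed-model engine against independent oracles.

The linear REML path is checked against statsmodels MixedLM (same variance
components and fixed effects), ordinary least squares in the
no-random-effect limit, and a dense GLS solve at known variance components.
The beta path is checked against a logit-scale linear mixed fit in the
small-dispersion limit, where the two families coincide.
"""

import numpy as np
import pandas as pd
import pytest

from cfqct.cohort import CohortTruth, simulate_cohort
from cfqct.mixed import (
    fit_beta_mixed,
    fit_linear_mixed,
    gls_known_variance,
    shrink_to_open_unit,
)


def _design(df):
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(df)),
            "age": df.age_years.to_numpy(),
            "A3": df.A3.to_numpy(),
        },
        index=df.index,
    )
    for t in (3, 12, 24):
        X[f"t{t}"] = (df.timepoint_months == t).astype(float)
    return X


@pytest.fixture(scope="module")
def sim():
    df = simulate_cohort(CohortTruth(seed=3))
    return df, _design(df)


class TestLinearREML:
    def test_matches_statsmodels_mixedlm(self, sim):
        df, X = sim
        fit = fit_linear_mixed(df.BEI, X, df.subject, df.region)

        import statsmodels.formula.api as smf

        d = df.rename(columns={"age_years": "age"}).copy()
        for t in (3, 12, 24):
            d[f"t{t}"] = (d.timepoint_months == t).astype(float)
        ref = smf.mixedlm(
            "BEI ~ age + A3 + t3 + t12 + t24", d, groups=d.subject,
            re_formula="1", vc_formula={"region": "0 + C(region)"},
        ).fit(reml=True)
        ours = fit.params["estimate"].to_numpy()
        theirs = ref.params.iloc[: len(ours)].to_numpy()
        np.testing.assert_allclose(ours, theirs, rtol=2e-3, atol=2e-4)
        assert fit.variance_components["sd_patient"] == pytest.approx(
            float(np.sqrt(ref.cov_re.iloc[0, 0])), rel=2e-2)
        assert fit.variance_components["sd_residual"] == pytest.approx(
            float(np.sqrt(ref.scale)), rel=2e-2)

    def test_no_random_effect_limit_equals_ols(self):
        truth = CohortTruth(seed=8).with_endpoint("BEI", sd_patient=0.0, sd_region=0.0)
        df = simulate_cohort(truth)
        X = _design(df)
        fit = fit_linear_mixed(df.BEI, X, df.subject, df.region)
        beta_ols = np.linalg.lstsq(X.to_numpy(), df.BEI.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.params["estimate"], beta_ols, atol=1e-6)

    def test_gls_with_known_components_matches_dense_oracle(self):
        truth = CohortTruth(n_subjects=8, seed=4)
        df = simulate_cohort(truth)
        X = _design(df)
        ep = truth.endpoints["BEI"]
        beta = gls_known_variance(df.BEI, X, df.subject, df.region,
                                  ep.sd_patient, ep.sd_region, ep.sd_resid)
        # dense-matrix GLS oracle built from scratch
        n = len(df)
        V = np.zeros((n, n))
        subj = df.subject.to_numpy()
        reg = df.region.to_numpy()
        same_subj = subj[:, None] == subj[None, :]
        same_cell = same_subj & (reg[:, None] == reg[None, :])
        V += ep.sd_patient**2 * same_subj
        V += ep.sd_region**2 * same_cell
        V[np.diag_indices(n)] += ep.sd_resid**2
        Vi = np.linalg.inv(V)
        A = X.to_numpy()
        ref = np.linalg.solve(A.T @ Vi @ A, A.T @ Vi @ df.BEI.to_numpy())
        np.testing.assert_allclose(beta.to_numpy(), ref, atol=1e-8)

    def test_zero_variance_endpoint_rejected(self, sim):
        df, X = sim
        with pytest.raises(ValueError):
            fit_linear_mixed(np.ones(len(df)), X, df.subject, df.region)

    def test_robust_downweights_contamination(self, sim):
        df, X = sim
        y = df.BEI.to_numpy().copy()
        idx = np.arange(0, len(y), 97)
        y_cont = y.copy()
        y_cont[idx] += 5.0   # gross outliers
        plain = fit_linear_mixed(y_cont, X, df.subject, df.region)
        robust = fit_linear_mixed(y_cont, X, df.subject, df.region, robust=True)
        clean = fit_linear_mixed(y, X, df.subject, df.region)
        err_plain = abs(plain.estimate("age") - clean.estimate("age"))
        err_robust = abs(robust.estimate("age") - clean.estimate("age"))
        assert err_robust < err_plain

    def test_zero_region_variance_recovered_as_near_zero(self):
        truth = CohortTruth(seed=12).with_endpoint("BEI", sd_region=0.0)
        df = simulate_cohort(truth)
        fit = fit_linear_mixed(df.BEI, _design(df), df.subject, df.region)
        assert fit.variance_components["sd_region_within_patient"] < 0.02
        assert fit.variance_components["sd_patient"] == pytest.approx(0.15, rel=0.5)

    def test_exact_deterministic_response_flags_boundary(self):
        truth = CohortTruth(seed=14)
        for name in truth.endpoints:
            truth = truth.with_endpoint(name, sd_patient=0.0, sd_region=0.0, sd_resid=0.0)
        df = simulate_cohort(truth)
        fit = fit_linear_mixed(df.BEI, _design(df), df.subject, df.region)
        # residual variance collapses onto the search floor and must be flagged
        # (between-subject fixed effects are not identifiable in this limit,
        # so no assertion is made on them)
        assert "sd_residual" in fit.boundary


class TestBetaLaplace:
    def test_small_dispersion_agrees_with_logit_lmm(self):
        rng = np.random.default_rng(0)
        truth = CohortTruth(seed=21).with_endpoint(
            "WP_5_10", sd_resid=0.02, sd_patient=0.1, sd_region=0.05)
        df = simulate_cohort(truth)
        X = _design(df)
        y01 = shrink_to_open_unit(df.WP_5_10.to_numpy() / 100.0)
        bfit = fit_beta_mixed(y01, X, df.subject, df.region)
        lfit = fit_linear_mixed(np.log(y01 / (1 - y01)), X, df.subject, df.region)
        b, l = bfit.params["estimate"], lfit.params["estimate"]
        for term in ("age", "A3"):
            assert b[term] == pytest.approx(l[term], rel=0.05, abs=5e-4)

    def test_out_of_unit_interval_rejected(self, sim):
        df, X = sim
        with pytest.raises(ValueError):
            fit_beta_mixed(df.WP_5_10, X, df.subject, df.region)  # percentages, not (0,1)

    def test_wald_table_shape_and_ci_contains_estimate(self, sim):
        df, X = sim
        y01 = shrink_to_open_unit(df.WP_5_10.to_numpy() / 100.0)
        fit = fit_beta_mixed(y01, X, df.subject, df.region)
        assert list(fit.params.index) == list(X.columns)
        assert (fit.params.ci_low <= fit.params.estimate).all()
        assert (fit.params.estimate <= fit.params.ci_high).all()
        assert (fit.params.se > 0).all()
        assert fit.variance_components["dispersion_phi"] > 0
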