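"""The two lobar mixed-model analyses of airway structure vs air trapping.

*Cross-sectional*: with all visits stacked, each airway endpoint (BEI,
LA_5-10, WP_5-10) is regressed on age, severe air trapping A3 and visit
dummies, with random intercepts for patient and region-within-patient.
WP, a percentage bounded in (0, 100), uses the beta family on the
proportion scale (logit link); BEI and LA use the linear family. Fits are
robust (Huber-weighted) by default.

*Longitudinal*: for a visit interval (t0, t1), the endpoint at t1 is
regressed on age, A3 and the endpoint itself at t0 over subject x region
rows, with the same random intercepts. The baseline-endpoint coefficient
measures tracking: 1 means perfect persistence of regional values. For the
WP endpoint the baseline covariate enters on the logit scale, matching the
response link.

Every report echoes its model formula and coefficient scale; P-values are
Wald-based and descriptive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixed import MixedModelFit, fit_beta_mixed, fit_linear_mixed, shrink_to_open_unit

#: Endpoints analysed on the proportion scale with the beta family.
BETA_ENDPOINTS = ("WP_5_10",)
TIMEPOINT_DUMMIES = (3, 12, 24)


def _logit(p):
    return np.log(p / (1.0 - p))


def _check_cohort(data: pd.DataFrame, endpoint: str) -> None:
    required = {"subject", "timepoint_months", "age_years", "region", "A3", endpoint}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    if data[endpoint].std() == 0:
        raise ValueError(f"endpoint {endpoint} has zero variance")


def crosssectional_model(
    data: pd.DataFrame,
    endpoint: str,
    robust: bool = True,
    family: str | None = None,
    theta_start=None,
) -> MixedModelFit:
    """Endpoint ~ age + A3 + visit dummies + (1|patient) + (1|patient:region)."""
    _check_cohort(data, endpoint)
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(data)),
            "age": data["age_years"].to_numpy(float),
            "A3": data["A3"].to_numpy(float),
        },
        index=data.index,
    )
    present = sorted(set(data["timepoint_months"]) - {min(data["timepoint_months"])})
    for t in present:
        X[f"t{t}"] = (data["timepoint_months"] == t).astype(float)
    dummies = " + ".join(f"t{t}" for t in present)
    formula = (f"{endpoint} ~ age + A3 + {dummies} "
               "+ (1|patient) + (1|patient:region)")
    family = family or ("beta" if endpoint in BETA_ENDPOINTS else "linear")
    if family == "beta":
        y01 = shrink_to_open_unit(data[endpoint].to_numpy(float) / 100.0)
        return fit_beta_mixed(y01, X, data["subject"], data["region"],
                              robust=robust, formula=formula, theta_start=theta_start)
    return fit_linear_mixed(data[endpoint], X, data["subject"], data["region"],
                            robust=robust, formula=formula, theta_start=theta_start)


def longitudinal_model(
    data: pd.DataFrame,
    endpoint: str,
    interval: tuple[int, int] = (0, 24),
    robust: bool = True,
    family: str | None = None,
    theta_start=None,
) -> MixedModelFit:
    """endpoint@t1 ~ age@t0 + A3@t0 + endpoint@t0 + random intercepts.

    Subjects missing either visit of the interval are dropped (complete-case;
    the count is recorded in the scale note). Raises when the interval
    leaves no overlapping subject x region rows.
    """
    _check_cohort(data, endpoint)
    t0, t1 = interval
    base = data[data["timepoint_months"] == t0]
    follow = data[data["timepoint_months"] == t1]
    if base.empty or follow.empty:
        raise ValueError(f"no rows at one of the interval visits {interval}")
    cols0 = base[["subject", "region", "age_years", "A3", endpoint]].rename(
        columns={"age_years": "age0", "A3": "A3_0", endpoint: "y0"}
    )
    cols1 = follow[["subject", "region", endpoint]].rename(columns={endpoint: "y1"})
    merged = cols0.merge(cols1, on=["subject", "region"], how="inner")
    if merged.empty:
        raise ValueError(f"no subject has both visits of interval {interval}")
    n_dropped = base["subject"].nunique() - merged["subject"].nunique()

    family = family or ("beta" if endpoint in BETA_ENDPOINTS else "linear")
    baseline = merged["y0"].to_numpy(float)
    if family == "beta":
        baseline = _logit(shrink_to_open_unit(baseline / 100.0))
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(merged)),
            "age": merged["age0"].to_numpy(float),
            "A3": merged["A3_0"].to_numpy(float),
            "baseline": baseline,
        },
        index=merged.index,
    )
    formula = (f"{endpoint}@{t1}m ~ age@{t0}m + A3@{t0}m + {endpoint}@{t0}m "
               "+ (1|patient) + (1|patient:region)")
    note = f"{n_dropped} subjects without both visits dropped"
    if family == "beta":
        y01 = shrink_to_open_unit(merged["y1"].to_numpy(float) / 100.0)
        fit = fit_beta_mixed(y01, X, merged["subject"], merged["region"],
                             robust=robust, formula=formula, theta_start=theta_start)
    else:
        fit = fit_linear_mixed(merged["y1"], X, merged["subject"], merged["region"],
                               robust=robust, formula=formula, theta_start=theta_start)
    fit.scale_note = (fit.scale_note + "; " if fit.scale_note else "") + note
    return fit


def model_report_frame(fits: dict[str, MixedModelFit]) -> pd.DataFrame:
    """Stack fixed-effect tables of several fits into one tidy report."""
    rows = []
    for label, fit in fits.items():
        for term, row in fit.params.iterrows():
            rows.append(
                {
                    "model": label,
                    "term": term,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                    "family": fit.family,
                    "robust": fit.robust,
                    "formula": fit.formula,
                }
            )
    return pd.DataFrame(rows)
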