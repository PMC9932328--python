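"""Simulated longitudinal lobar cohorts with known generative parameters.

The simulator mirrors the generative form of the lobar mixed models this
package fits: for each subject, lung region and visit,

    endpoint = intercept + b_age*age + b_A3*A3 + b_t[visit]
               + u_patient + u_region(patient) + eps

with independent Gaussian random intercepts for patient and for
region-within-patient, Gaussian residuals, and the visit schedule
0 / 3 / 12 / 24 months (ages advance by 0, 0.25, 1 and 2 years). Baseline
age is Uniform(8, 16) years, matching a school-age cohort with median age
around 12. The severe air-trapping covariate A3 (% of parenchyma) is drawn
from a configurable log-normal — positive and right-skewed, the shape such
scores show in practice; its default median ~2.3% matches mild disease.

The wall-percentage endpoint lives in (0, 100)%; it is simulated on the
latent logit scale (random effects and residuals added there) and mapped
through 100*sigmoid, which keeps it inside its range and matches the beta
mixed model used to analyse it.

Every latent draw (random intercepts, residuals, linear predictor) is
recorded in the output table so tests can introspect the generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGIONS = ("RUL", "RML", "RLL", "LUL", "LLi", "LLL")
TIMEPOINTS = (0, 3, 12, 24)
#: Years added to baseline age at each visit.
AGE_OFFSETS = {0: 0.0, 3: 0.25, 12: 1.0, 24: 2.0}

COHORT_CSV_COLUMNS = ["subject", "timepoint_months", "age_years", "region",
                      "BEI", "LA_5_10", "WP_5_10", "A3"]


@dataclass
class EndpointTruth:
    """Fixed effects and variance components for one simulated endpoint."""

    intercept: float
    beta_age: float
    beta_a3: float
    beta_t: dict[int, float]          # visit (months) → additive shift; 0 for baseline
    sd_patient: float
    sd_region: float
    sd_resid: float
    link: str = "identity"            # "identity" or "logit100" (0–100% endpoints)

    def __post_init__(self) -> None:
        for name in ("sd_patient", "sd_region", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.link not in ("identity", "logit100"):
            raise ValueError(f"unknown link {self.link!r}")


def _default_endpoints() -> dict[str, EndpointTruth]:
    # Coefficient scales follow the fitted cross-sectional lobar models:
    # age→BEI 0.046, A3→WP(logit) 0.004, age→LA 0.598 etc.; intercepts chosen
    # so endpoint levels land at the study's medians (BEI ~0.4, LA ~10 mm²,
    # WP ~49%) at the median age of 12 y.
    return {
        "BEI": EndpointTruth(-0.16, 0.046, 0.003, {0: 0.0, 3: 0.019, 12: 0.015, 24: 0.006},
                             sd_patient=0.15, sd_region=0.10, sd_resid=0.10),
        "LA_5_10": EndpointTruth(2.8, 0.598, -0.006, {0: 0.0, 3: 0.112, 12: -0.016, 24: -0.035},
                                 sd_patient=1.2, sd_region=0.8, sd_resid=0.8),
        "WP_5_10": EndpointTruth(0.47, -0.042, 0.004, {0: 0.0, 3: -0.025, 12: 0.04, 24: 0.086},
                                 sd_patient=0.15, sd_region=0.10, sd_resid=0.10,
                                 link="logit100"),
    }


@dataclass
class CohortTruth:
    """Complete generative description of a balanced longitudinal cohort."""

    endpoints: dict[str, EndpointTruth] = field(default_factory=_default_endpoints)
    n_subjects: int = 36
    timepoints: tuple[int, ...] = TIMEPOINTS
    regions: tuple[str, ...] = REGIONS
    age_range: tuple[float, float] = (8.0, 16.0)
    a3_meanlog: float = 0.8           # log-normal A3: median exp(0.8) ≈ 2.2%
    a3_sdlog: float = 0.9
    seed: int = 0

    def with_endpoint(self, name: str, **changes) -> "CohortTruth":
        eps = dict(self.endpoints)
        eps[name] = replace(eps[name], **changes)
        return replace(self, endpoints=eps)


def simulate_cohort(truth: CohortTruth) -> pd.DataFrame:
    """Simulate a balanced subject x visit x region table (tidy, one row each).

    Returns the endpoint columns plus, for every endpoint ``E``, the latent
    columns ``linpred_E`` (fixed-effect part), ``u_patient_E``,
    ``u_region_E`` and ``eps_E`` for test introspection. A3 is truncated at
    100 (it is a percentage).
    """
    rng = np.random.default_rng(truth.seed)
    n, T, R = truth.n_subjects, list(truth.timepoints), list(truth.regions)
    rows = n * len(T) * len(R)

    subj = np.repeat(np.arange(1, n + 1), len(T) * len(R))
    tp = np.tile(np.repeat(T, len(R)), n)
    region = np.tile(R, n * len(T))

    age0 = rng.uniform(*truth.age_range, size=n)
    age = age0[subj - 1] + np.vectorize(AGE_OFFSETS.get)(tp)
    a3 = np.minimum(rng.lognormal(truth.a3_meanlog, truth.a3_sdlog, size=rows), 100.0)

    df = pd.DataFrame(
        {"subject": subj, "timepoint_months": tp, "age_years": age, "region": region, "A3": a3}
    )

    region_codes = pd.Categorical(region, categories=R).codes
    for name, ep in truth.endpoints.items():
        u_p = rng.normal(0.0, ep.sd_patient, size=n) if ep.sd_patient > 0 else np.zeros(n)
        u_r = (rng.normal(0.0, ep.sd_region, size=(n, len(R)))
               if ep.sd_region > 0 else np.zeros((n, len(R))))
        eps = rng.normal(0.0, ep.sd_resid, size=rows) if ep.sd_resid > 0 else np.zeros(rows)
        beta_t = np.array([ep.beta_t.get(int(t), 0.0) for t in tp])
        lin = ep.intercept + ep.beta_age * age + ep.beta_a3 * a3 + beta_t
        latent = lin + u_p[subj - 1] + u_r[subj - 1, region_codes] + eps
        if ep.link == "logit100":
            value = 100.0 / (1.0 + np.exp(-latent))
        else:
            value = latent
        df[name] = value
        df[f"linpred_{name}"] = lin
        df[f"u_patient_{name}"] = u_p[subj - 1]
        df[f"u_region_{name}"] = u_r[subj - 1, region_codes]
        df[f"eps_{name}"] = eps
    return df


def write_cohort_csv(df: pd.DataFrame, path: str) -> None:
    """Write the canonical cohort schema (drops latent introspection columns)."""
    cols = [c for c in COHORT_CSV_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_CSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing required columns: {sorted(missing)}")
    return df
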