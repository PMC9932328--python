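"""Simulation harnesses that exercise the pipeline against known truth.

Each function builds its own inputs (phantoms or simulated cohorts) from an
explicit seed, runs the corresponding package operation, and returns the
measured quantities next to the generative truth. The test suite asserts on
these results; the acceptance script reports them.
"""

from __future__ import annotations

import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .airway import MeasureParams, compute_bei, measure_cross_section, measure_tree
from .cohort import REGIONS, CohortTruth, simulate_cohort
from .mixed import fit_linear_mixed
from .models import crosssectional_model, longitudinal_model
from .phantoms import (
    TrappingSpec,
    make_airway_phantom,
    make_lobe_mask,
    make_paired_lung_phantom,
    single_tube_spec,
    six_lobe_tree_spec,
)
from .pipeline import load_config, run
from .trapping import analyse_pair, compute_ei_mla, compute_rvc

WALL_HU = 0.0
LUMEN_HU = -1000.0
BACKGROUND_HU = -850.0


# ---------------------------------------------------------------------------
# Airway geometry recovery (noise-free cylinder sweep)
# ---------------------------------------------------------------------------

def tube_recovery_sweep(
    lumens=(2.0, 3.0, 4.0, 6.0, 8.0),
    walls=(0.5, 1.0, 1.5),
    spacings=(0.5, 0.6),
    params: MeasureParams | None = None,
) -> pd.DataFrame:
    """Measure noise-free cylinders; one row per case with LD/WT errors (mm)."""
    params = params or MeasureParams(wall_hu=WALL_HU)
    rows = []
    for lumen in lumens:
        for wall in walls:
            for sp in spacings:
                spec = single_tube_spec(lumen, wall, length=20.0,
                                        lumen_hu=LUMEN_HU, wall_hu=WALL_HU,
                                        background_hu=BACKGROUND_HU)
                grid, _ = make_airway_phantom(spec, sp)
                m = measure_cross_section(grid, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0), params)
                ld = 2.0 * float(np.sqrt(m.LA / np.pi)) if m.valid else np.nan
                rows.append(
                    {
                        "lumen_mm": lumen,
                        "wall_mm": wall,
                        "spacing_mm": sp,
                        "valid": m.valid,
                        "ld_error_mm": ld - lumen if m.valid else np.nan,
                        "wt_error_mm": (m.WT - wall) if m.valid else np.nan,
                        "la_rel_error": (m.LA / (np.pi * (lumen / 2) ** 2) - 1.0)
                        if m.valid else np.nan,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bronchiectasis-index contract
# ---------------------------------------------------------------------------

def _measured_tree(dilations, spacing=0.6, taper=0.8, seed=0):
    spec = six_lobe_tree_spec(taper=taper, dilations=dilations,
                              lumen_hu=LUMEN_HU, wall_hu=WALL_HU,
                              background_hu=BACKGROUND_HU)
    grid, truth = make_airway_phantom(spec, spacing, seed=seed)
    measure_tree(grid, truth, MeasureParams(wall_hu=WALL_HU))
    return truth


def bei_contract_checks(spacing: float = 0.6, taper: float = 0.8) -> dict:
    """Tapering-tree zero, single 1.5x dilation, and additivity of the BEI.

    The dilation factor is chosen so the dilated child's lumen is exactly
    1.5x its parent's, i.e. a single tapering violation of size 0.5.
    Ground-truth BEI values are exact; measured BEI values carry the
    cross-section measurement error.
    """
    f = 1.5 / taper
    site_a, site_b = ("RML", 5), ("LLL", 4)

    taper_tree = _measured_tree({}, spacing, taper)
    one = _measured_tree({site_a: f}, spacing, taper)
    other = _measured_tree({site_b: f}, spacing, taper)
    both = _measured_tree({site_a: f, site_b: f}, spacing, taper)

    out = {
        "tapering_bei_truth": compute_bei(taper_tree, use_truth=True).bei,
        "tapering_bei_measured": compute_bei(taper_tree).bei,
        "single_dilation_lobar_bei_truth": compute_bei(one, region=site_a[0], use_truth=True).bei,
        "single_dilation_lobar_bei_measured": compute_bei(one, region=site_a[0]).bei,
        "additivity_sum_truth": compute_bei(one, use_truth=True).bei
        + compute_bei(other, use_truth=True).bei,
        "additivity_both_truth": compute_bei(both, use_truth=True).bei,
        "additivity_sum_measured": compute_bei(one).bei + compute_bei(other).bei,
        "additivity_both_measured": compute_bei(both).bei,
    }
    return out


# ---------------------------------------------------------------------------
# Air trapping: nesting, planted-defect recovery, Gaussian RVC, E/I MLA
# ---------------------------------------------------------------------------

def trapping_nesting_sweep(n_phantoms: int = 100, seed: int = 0) -> dict:
    """A1 >= A2 >= A3 on randomly parameterized paired phantoms."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_phantoms):
        mask = make_lobe_mask((36, 27, 18), (2.0, 2.0, 2.0))
        fracs = {lobe: float(rng.uniform(0.0, 0.2)) for lobe in REGIONS}
        spec = TrappingSpec(
            defect_fractions=fracs,
            insp=(float(rng.uniform(-900, -820)), float(rng.uniform(30, 70))),
            exp_normal=(float(rng.uniform(-700, -600)), float(rng.uniform(30, 70))),
            defect=(float(rng.uniform(-920, -850)), float(rng.uniform(15, 40))),
            blob_radius_mm=4.0,
            seed=int(rng.integers(2**31)),
        )
        ph = make_paired_lung_phantom(mask, spec)
        for region in ("total", *REGIONS):
            r = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, region)
            if not (r.A1 >= r.A2 >= r.A3 >= 0.0 and r.A1 <= 100.0):
                violations += 1
    return {"n_phantoms": n_phantoms, "nesting_violations": violations}


def defect_recovery_check(target: float = 0.10, seed: int = 0) -> dict:
    """Plant ``target`` defect fraction in the RML and recover it as A3."""
    mask = make_lobe_mask()
    spec = TrappingSpec(defect_fractions={"RML": target}, seed=seed)
    ph = make_paired_lung_phantom(mask, spec)
    res = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, "RML")
    return {
        "target_pct": 100.0 * target,
        "realized_pct": 100.0 * ph.realized_fractions["RML"],
        "a3_pct": res.A3,
        "a3_error_pp": res.A3 - 100.0 * target,
    }


def _gauss_band_prob(mu, sd, lo, hi):
    return sps.norm.cdf(hi, mu, sd) - sps.norm.cdf(lo, mu, sd)


def rvc_gaussian_check(seed: int = 0,
                       insp=(-850.0, 50.0), exp=(-650.0, 50.0)) -> dict:
    """RVC on two-Gaussian phantoms vs the closed-form normal-CDF answer."""
    mask = make_lobe_mask()
    spec = TrappingSpec(defect_fractions={}, insp=insp, exp_normal=exp, seed=seed)
    ph = make_paired_lung_phantom(mask, spec)
    measured = compute_rvc(ph.insp, ph.mask, ph.exp, ph.mask, "total")

    def rv(mu, sd):
        band = _gauss_band_prob(mu, sd, -950.0, -856.0)
        keep = 1.0 - sps.norm.cdf(-950.0, mu, sd)
        return band / keep

    analytic = rv(*exp) - rv(*insp)
    n = int((ph.mask.labels > 0).sum())
    # binomial SEM of each relative volume, combined in quadrature
    sems = []
    for mu, sd in (exp, insp):
        p = rv(mu, sd)
        keep = 1.0 - sps.norm.cdf(-950.0, mu, sd)
        sems.append(np.sqrt(p * (1 - p) / (n * keep)))
    sem = float(np.hypot(*sems))
    return {"measured": measured, "analytic": float(analytic), "sem": sem,
            "abs_error": abs(measured - analytic)}


def ei_mla_checks(seed: int = 0) -> dict:
    """E/I MLA identity (exp = insp) and the cohort-scale 0.64 phantom.

    The second phantom draws inspiratory attenuation around -850 HU and
    expiratory around -544 HU, the population means whose ratio matches the
    study cohort's median E/I MLA of 0.64.
    """
    mask = make_lobe_mask()
    spec = TrappingSpec(defect_fractions={}, insp=(-850.0, 50.0),
                        exp_normal=(-544.0, 50.0), seed=seed)
    ph = make_paired_lung_phantom(mask, spec)
    ratio = compute_ei_mla(ph.insp, ph.mask, ph.exp, ph.mask, "total")
    identity = compute_ei_mla(ph.insp, ph.mask, ph.insp, ph.mask, "total")
    n = int((ph.mask.labels > 0).sum())
    sem = float(np.hypot(50.0 / 850.0, 50.0 * 544.0 / 850.0**2) / np.sqrt(n))
    return {"identity": identity, "ratio": ratio, "expected": 544.0 / 850.0, "sem": sem}


# ---------------------------------------------------------------------------
# Mixed-model parameter recovery
# ---------------------------------------------------------------------------

def lmm_age_recovery(n_reps: int = 100, seed: int = 0, robust: bool = False) -> dict:
    """Simulate Table-3-scale cohorts; count CIs covering the true age->BEI slope."""
    truth_template = CohortTruth()
    beta_true = truth_template.endpoints["BEI"].beta_age
    seq = np.random.SeedSequence(seed).generate_state(n_reps)
    cover = 0
    ests = []
    theta = None
    for s in seq:
        df = simulate_cohort(CohortTruth(seed=int(s % 2**31)))
        fit = crosssectional_model(df, "BEI", robust=robust, theta_start=theta)
        theta = fit.theta
        lo, hi = fit.ci("age")
        cover += int(lo <= beta_true <= hi)
        ests.append(fit.estimate("age"))
    return {"n_reps": n_reps, "beta_true": beta_true, "covered": cover,
            "mean_estimate": float(np.mean(ests))}


def beta_a3_recovery(n_reps: int = 100, seed: int = 0) -> dict:
    """Coverage of the true A3->WP (logit-scale) slope by the beta mixed model."""
    truth_template = CohortTruth()
    beta_true = truth_template.endpoints["WP_5_10"].beta_a3
    seq = np.random.SeedSequence(seed).generate_state(n_reps)
    cover = 0
    ests = []
    theta = None
    for s in seq:
        df = simulate_cohort(CohortTruth(seed=int(s % 2**31)))
        fit = crosssectional_model(df, "WP_5_10", robust=False, theta_start=theta)
        theta = fit.theta
        lo, hi = fit.ci("A3")
        cover += int(lo <= beta_true <= hi)
        ests.append(fit.estimate("A3"))
    return {"n_reps": n_reps, "beta_true": beta_true, "covered": cover,
            "mean_estimate": float(np.mean(ests))}


def zero_coefficient_coverage(n_reps: int = 100, seed: int = 0) -> dict:
    """With a zero A3->BEI truth, the A3 CI should cover 0 ~95% of the time."""
    seq = np.random.SeedSequence(seed).generate_state(n_reps)
    cover = 0
    theta = None
    for s in seq:
        truth = CohortTruth(seed=int(s % 2**31)).with_endpoint("BEI", beta_a3=0.0)
        df = simulate_cohort(truth)
        fit = crosssectional_model(df, "BEI", robust=False, theta_start=theta)
        theta = fit.theta
        lo, hi = fit.ci("A3")
        cover += int(lo <= 0.0 <= hi)
    return {"n_reps": n_reps, "covered": cover}


# ---------------------------------------------------------------------------
# Longitudinal contract
# ---------------------------------------------------------------------------

def pure_tracking_check(seed: int = 0) -> dict:
    """endpoint@t1 == endpoint@t0 exactly: baseline coefficient must be ~1."""
    df = simulate_cohort(CohortTruth(seed=seed, timepoints=(0, 3)))
    base = df[df.timepoint_months == 0]
    track = df.copy()
    track.loc[track.timepoint_months == 3, "BEI"] = base["BEI"].to_numpy()
    fit = longitudinal_model(track, "BEI", (0, 3), robust=False)
    others = {}
    for term in ("age", "A3"):
        lo, hi = fit.ci(term)
        others[term] = {"estimate": fit.estimate(term), "covers_zero": lo <= 0.0 <= hi}
    return {
        "baseline_coefficient": fit.estimate("baseline"),
        "baseline_bias": fit.estimate("baseline") - 1.0,
        "others": others,
        "boundary_flags": fit.boundary,
    }


def _simulate_carryover(seed: int, beta_a3_3m: float = 0.017, beta_a3_24m: float = 0.0):
    """Longitudinal cohort with an A3->BEI carry-over only at 3 months.

    Generative form mirrors the longitudinal model: endpoint at follow-up =
    intercept + b_age*age0 + b_A3*A3_0 + b_base*endpoint_0 + u_patient +
    u_region(patient) + eps, with coefficient scales from the fitted
    longitudinal models (3 months: age 0.043, baseline 0.403; 24 months:
    age 0.023, baseline 0.983).
    """
    rng = np.random.default_rng(seed)
    n, R = 36, list(REGIONS)
    rows = []
    age0 = rng.uniform(8, 16, size=n)
    for si in range(n):
        u_p3, u_p24 = rng.normal(0, 0.05, size=2)
        for region in R:
            a3 = min(float(rng.lognormal(0.8, 0.9)), 100.0)
            y0 = max(0.0, 0.05 + 0.03 * age0[si] + rng.normal(0, 0.2))
            u_r3, u_r24 = rng.normal(0, 0.05, size=2)
            y3 = (0.02 + 0.043 * age0[si] + beta_a3_3m * a3 + 0.403 * y0
                  + u_p3 + u_r3 + rng.normal(0, 0.1))
            y24 = (0.02 + 0.023 * age0[si] + beta_a3_24m * a3 + 0.983 * y0
                   + u_p24 + u_r24 + rng.normal(0, 0.1))
            for tp, y in ((0, y0), (3, y3), (24, y24)):
                rows.append({"subject": si + 1, "timepoint_months": tp,
                             "age_years": age0[si] + {0: 0.0, 3: 0.25, 24: 2.0}[tp],
                             "region": region, "A3": a3, "BEI": y})
    return pd.DataFrame(rows)


def carryover_pattern_rate(n_reps: int = 100, seed: int = 0) -> dict:
    """How often the fits show a positive 3-month A3 effect and a null 24-month one."""
    seq = np.random.SeedSequence(seed).generate_state(n_reps)
    hits = 0
    th3 = th24 = None
    for s in seq:
        df = _simulate_carryover(int(s % 2**31))
        f3 = longitudinal_model(df, "BEI", (0, 3), robust=False, theta_start=th3)
        f24 = longitudinal_model(df, "BEI", (0, 24), robust=False, theta_start=th24)
        th3, th24 = f3.theta, f24.theta
        lo3, _ = f3.ci("A3")
        lo24, hi24 = f24.ci("A3")
        if lo3 > 0.0 and lo24 <= 0.0 <= hi24:
            hits += 1
    return {"n_reps": n_reps, "pattern_hits": hits}


# ---------------------------------------------------------------------------
# Pipeline determinism
# ---------------------------------------------------------------------------

def pipeline_determinism_check(workdir: str, seed: int = 20260929,
                               overrides: dict | None = None) -> dict:
    """Run the bundled demo config twice; compare manifests and outputs."""
    base = Path(workdir)
    cfg = load_config(None, {"seed": int(seed), **(overrides or {})})
    m1 = run(cfg, str(base / "run1"))
    m2 = run(cfg, str(base / "run2"))
    identical_manifest = json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)
    mismatches = []
    for rel in m1["outputs"]:
        f1, f2 = base / "run1" / rel, base / "run2" / rel
        if not filecmp.cmp(f1, f2, shallow=False):
            mismatches.append(rel)
    return {
        "identical_manifest": identical_manifest,
        "n_outputs": len(m1["outputs"]),
        "mismatched_files": mismatches,
    }
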