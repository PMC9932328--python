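"""Config-driven pipeline: phantom cohort → QCT measurement → statistics.

A run generates a synthetic cohort of subjects, each with paired
inspiratory/expiratory lung phantoms and an airway-tree phantom per visit,
measures airway geometry and air trapping, assembles the tidy cohort table,
applies the breath-hold volume QC gate, and fits the descriptive statistics
and lobar mixed models. Every stage writes its outputs under the run
directory together with a manifest (config, seed, software version, output
checksums) that makes a re-run byte-for-byte verifiable.

All randomness derives from the single config seed through spawned
`numpy` seed sequences, so the same config reproduces all CSV/JSON outputs
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .airway import MeasureParams, aggregate_region, compute_bei, measure_tree, sections_table
from .cohort import AGE_OFFSETS, COHORT_CSV_COLUMNS, REGIONS
from .models import crosssectional_model, longitudinal_model, model_report_frame
from .phantoms import (
    TrappingSpec,
    make_airway_phantom,
    make_lobe_mask,
    make_paired_lung_phantom,
    six_lobe_tree_spec,
)
from .stats import correlation_map, friedman_test, summarize
from .trapping import analyse_pair, results_table
from .volume_io import check_volume_consistency, write_mask, write_volume

log = logging.getLogger("cfqct.pipeline")

STAGES = ("phantom", "measure", "trap", "stats")


class ConfigError(ValueError):
    """Invalid run configuration (detected before any compute)."""


class PipelineError(RuntimeError):
    """A stage failed at run time."""


DEFAULT_CONFIG: dict = {
    "seed": 20260929,
    "stages": list(STAGES),
    "save_volumes": False,
    "volume_format": "nii",
    "n_subjects": 8,
    "visits": [0, 3, 12, 24],
    "phantom": {
        "spacing_mm": 0.6,
        "noise_sd_hu": 10.0,
        "trachea_lumen_mm": 8.0,
        "taper": 0.8,
        "max_generation": 6,
        "branch_length_mm": 8.0,
        "wall_fraction": 0.18,
        "dilation_probability": 0.3,
        "dilation_factor_range": [1.35, 1.9],
        "lung_shape": [60, 44, 30],
        "lung_spacing_mm": [1.5, 1.5, 1.5],
        "growth_per_visit": 0.012,
        "defect_fraction_range": [0.01, 0.15],
        "blob_radius_mm": 3.0,
        "insp_hu": [-850.0, 50.0],
        "exp_normal_hu": [-650.0, 50.0],
        "defect_hu": [-880.0, 30.0],
    },
    "measure": {
        "n_rays": 64,
        "plane_resolution_mm": 0.25,
        "section_step_mm": 1.0,
        "exclusion_mm": 2.0,
        "bei_kappa": 1.0,
        "wall_hu_calibration": 0.0,
        "generation_range": [5, 10],
    },
    "trapping": {"threshold_fractions": [0.75, 0.5, 0.25]},
    "qc": {"tlv_threshold": 0.05},
    "stats": {
        "robust": True,
        "endpoints": ["BEI", "LA_5_10", "WP_5_10"],
        "longitudinal_intervals": [[0, 3], [0, 24]],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config merged over the bundled defaults, then validate."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a YAML mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; valid: {STAGES}")
    f1, f2, f3 = cfg["trapping"]["threshold_fractions"]
    if not (f1 > f2 > f3):
        raise ConfigError("trapping threshold fractions must be strictly decreasing")
    if cfg["n_subjects"] < 1:
        raise ConfigError("need at least one subject")
    if cfg["qc"]["tlv_threshold"] <= 0:
        raise ConfigError("QC threshold must be positive")
    lo, hi = cfg["phantom"]["defect_fraction_range"]
    if not (0 <= lo <= hi <= 1):
        raise ConfigError("defect fraction range must satisfy 0 <= lo <= hi <= 1")
    if int(cfg["seed"]) < 0:
        raise ConfigError("seed must be non-negative")


def dump_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _measure_params(cfg: dict) -> MeasureParams:
    m = cfg["measure"]
    return MeasureParams(
        n_rays=int(m["n_rays"]),
        radial_step_mm=float(m["plane_resolution_mm"]),
        section_step_mm=float(m["section_step_mm"]),
        exclusion_mm=float(m["exclusion_mm"]),
        bei_kappa=float(m["bei_kappa"]),
        wall_hu=m["wall_hu_calibration"],
    )


# ---------------------------------------------------------------------------
# Per-subject phantom generation
# ---------------------------------------------------------------------------

def _subject_plan(cfg: dict, rng: np.random.Generator, subject: int) -> dict:
    """Draw one subject's time-stable characteristics."""
    ph = cfg["phantom"]
    lobes = list(REGIONS)
    sites = []
    for lobe in lobes:
        if rng.random() < ph["dilation_probability"]:
            gen = int(rng.integers(4, ph["max_generation"] + 1))
            f0 = rng.uniform(*ph["dilation_factor_range"])
            sites.append((lobe, gen, f0))
    return {
        "subject": subject,
        "age0": float(rng.uniform(8.0, 16.0)),
        "taper": float(ph["taper"] * rng.uniform(0.97, 1.03)),
        "wall_fraction": float(ph["wall_fraction"] * rng.uniform(0.9, 1.1)),
        "dilation_sites": sites,
        "defect_base": {
            lobe: float(rng.uniform(*ph["defect_fraction_range"])) for lobe in lobes
        },
    }


def _visit_phantoms(cfg: dict, plan: dict, visit_idx: int, visit: int, seed: int):
    """Build the airway phantom and the paired lung phantom for one visit."""
    ph = cfg["phantom"]
    rng = np.random.default_rng(seed)
    # bronchiectatic dilations persist and progress slightly
    dil = {
        (lobe, gen): f0 * (1.0 + 0.03 * visit_idx)
        for lobe, gen, f0 in plan["dilation_sites"]
    }
    spec = six_lobe_tree_spec(
        trachea_lumen=ph["trachea_lumen_mm"],
        taper=plan["taper"],
        max_generation=int(ph["max_generation"]),
        branch_length=float(ph["branch_length_mm"]),
        wall_fraction=plan["wall_fraction"],
        dilations=dil,
    )
    grid, truth = make_airway_phantom(
        spec, ph["spacing_mm"], noise_sd=float(ph["noise_sd_hu"]),
        seed=int(rng.integers(2**31)),
    )
    # lung grows a little between visits: inflate the voxel size
    growth = (1.0 + ph["growth_per_visit"]) ** visit_idx
    spacing = tuple(float(s) * growth for s in ph["lung_spacing_mm"])
    mask = make_lobe_mask(tuple(ph["lung_shape"]), spacing)
    fractions = {
        lobe: min(1.0, f * float(rng.uniform(0.7, 1.3)))
        for lobe, f in plan["defect_base"].items()
    }
    tspec = TrappingSpec(
        defect_fractions=fractions,
        insp=tuple(ph["insp_hu"]),
        exp_normal=tuple(ph["exp_normal_hu"]),
        defect=tuple(ph["defect_hu"]),
        blob_radius_mm=float(ph["blob_radius_mm"]),
        seed=int(rng.integers(2**31)),
    )
    lung = make_paired_lung_phantom(mask, tspec)
    return grid, truth, lung


# ---------------------------------------------------------------------------
# The run driver
# ---------------------------------------------------------------------------

def run(cfg: dict, out_dir: str) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    validate_config(cfg)
    out = Path(out_dir)
    for sub in ("phantoms", "measures", "trapping", "stats", "qc"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    try:
        manifest = _run_stages(cfg, out)
    except (ConfigError, PipelineError):
        raise
    except Exception as exc:  # annotate unexpected stage failures with the log path
        raise PipelineError(f"stage failure: {exc}; see {out/'run.log'}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return manifest


def _run_stages(cfg: dict, out: Path) -> dict:
    stages = list(cfg["stages"])
    root_seq = np.random.SeedSequence(int(cfg["seed"]))
    subj_seqs = root_seq.spawn(cfg["n_subjects"])
    params = _measure_params(cfg)
    visits = [int(v) for v in cfg["visits"]]
    gagg = tuple(cfg["measure"]["generation_range"])
    timings: dict[str, float] = {}
    outputs: list[Path] = []

    need_phantom = any(s in stages for s in ("phantom", "measure", "trap", "stats"))
    if not need_phantom:
        raise ConfigError("no stages requested")
    for s in ("measure", "trap"):
        if s in stages and "phantom" not in stages:
            raise PipelineError(f"stage '{s}' requires the phantom stage in the same run")
    if "stats" in stages and not {"measure", "trap"} <= set(stages):
        raise PipelineError("stage 'stats' requires measure and trap stages")

    cohort_rows = []
    qc_reports = {}
    section_lines_all = []
    trap_lines_all = []

    t0 = time.time()
    for si, seq in enumerate(subj_seqs):
        rng = np.random.default_rng(seq)
        plan = _subject_plan(cfg, rng, subject=si + 1)
        tlv_series = []
        for vi, visit in enumerate(visits):
            vseed = int(rng.integers(2**31))
            grid, truth, lung = _visit_phantoms(cfg, plan, vi, visit, vseed)
            log.info("subject %d visit %dm: phantoms built", si + 1, visit)
            if cfg["save_volumes"]:
                ext = "." + cfg["volume_format"].lstrip(".")
                base = out / "phantoms" / f"s{si+1:02d}_v{visit:02d}"
                write_volume(grid, f"{base}_airway{ext}")
                write_volume(lung.insp, f"{base}_insp{ext}")
                write_volume(lung.exp, f"{base}_exp{ext}")
                write_mask(lung.mask, f"{base}_lobes{ext}")
            truth_path = out / "phantoms" / f"s{si+1:02d}_v{visit:02d}_tree.json"
            truth_path.write_text(truth.to_json())
            outputs.append(truth_path)

            row_base = {
                "subject": si + 1,
                "timepoint_months": visit,
                "age_years": round(plan["age0"] + AGE_OFFSETS.get(visit, visit / 12.0), 4),
            }
            if "measure" in stages:
                measure_tree(grid, truth, params)
                section_lines_all.extend(
                    f"{si+1},{visit}," + ln
                    for ln in sections_table(truth)[1:]
                )
            if "trap" in stages:
                results = [
                    analyse_pair(lung.insp, lung.mask, lung.exp, lung.mask, region=r,
                                 fractions=tuple(cfg["trapping"]["threshold_fractions"]))
                    for r in ["total", *REGIONS]
                ]
                trap_lines_all.extend(
                    f"{si+1},{visit}," + ln for ln in results_table(results)[1:]
                )
                total_res = results[0]
                tlv_series.append(total_res.TLV_cm3)
                lobe_res = {r.region: r for r in results[1:]}
            if {"measure", "trap"} <= set(stages):
                for region in REGIONS:
                    agg = aggregate_region(truth, gagg, region, params.exclusion_mm)
                    bei = compute_bei(truth, region, kappa=params.bei_kappa)
                    cohort_rows.append(
                        {
                            **row_base,
                            "region": region,
                            "BEI": round(bei.bei, 6),
                            "LA_5_10": None if agg.LA is None else round(agg.LA, 4),
                            "WP_5_10": None if agg.WP is None else round(agg.WP, 4),
                            "A3": round(lobe_res[region].A3, 4),
                        }
                    )
        if tlv_series:
            qc_reports[f"subject_{si+1}"] = check_volume_consistency(
                tlv_series, threshold=float(cfg["qc"]["tlv_threshold"])
            )
    timings["phantom+measure+trap"] = round(time.time() - t0, 2)

    if section_lines_all:
        p = out / "measures" / "sections.csv"
        header = "subject,timepoint_months,branch_id,generation,lobe,pos_mm,LA,WA,TD,WT,WP,valid,reason"
        p.write_text("\n".join([header, *section_lines_all]) + "\n")
        outputs.append(p)
    if trap_lines_all:
        p = out / "trapping" / "trapping.csv"
        header = ("subject,timepoint_months,region,TLV_cm3,RLV_cm3,MLA_I,MLA_E,RVC,EI_MLA,"
                  "T1,T2,T3,A1,A2,A3")
        p.write_text("\n".join([header, *trap_lines_all]) + "\n")
        outputs.append(p)
    if qc_reports:
        p = out / "qc" / "qc.json"
        p.write_text(json.dumps(qc_reports, indent=1, sort_keys=True))
        outputs.append(p)

    cohort = None
    if cohort_rows:
        cohort = pd.DataFrame(cohort_rows)[COHORT_CSV_COLUMNS]
        p = out / "measures" / "cohort.csv"
        cohort.to_csv(p, index=False, float_format="%.6g")
        outputs.append(p)

    if "stats" in stages:
        t0 = time.time()
        _stats_stage(cfg, cohort, out, outputs)
        timings["stats"] = round(time.time() - t0, 2)

    manifest = {
        "software": {"package": "cfqct", "version": __version__},
        "seed": int(cfg["seed"]),
        "config": cfg,
        "stages": stages,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("run complete: %s", timings)
    return manifest


def _stats_stage(cfg: dict, cohort: pd.DataFrame, out: Path, outputs: list) -> None:
    if cohort is None or cohort.empty:
        raise PipelineError("stats stage has no cohort table")
    scfg = cfg["stats"]
    endpoints = list(scfg["endpoints"])

    # Table-2-shaped descriptives: per visit medians/IQRs of total-lung means
    desc_rows = []
    for ep in [*endpoints, "A3"]:
        for visit, sub in cohort.groupby("timepoint_months"):
            per_subject = sub.groupby("subject")[ep].median()
            s = summarize(per_subject)
            desc_rows.append({"endpoint": ep, "timepoint_months": visit, **s})
        wide = cohort.pivot_table(index="subject", columns="timepoint_months",
                                  values=ep, aggfunc="median")
        try:
            fr = friedman_test(wide.to_numpy())
            desc_rows.append({"endpoint": ep, "timepoint_months": "friedman",
                              "statistic": fr.statistic, "p": fr.p, "n": fr.n})
        except ValueError as exc:   # e.g. too few subjects or visits for the test
            log.warning("friedman test skipped for %s: %s", ep, exc)
    p = out / "stats" / "descriptives.csv"
    pd.DataFrame(desc_rows).to_csv(p, index=False, float_format="%.6g")
    outputs.append(p)

    cm = correlation_map(cohort, ["age_years", *endpoints, "A3"])
    p = out / "stats" / "correlations.csv"
    cm.to_csv(p, index=False, float_format="%.6g")
    outputs.append(p)

    fits = {}
    data = cohort.dropna(subset=endpoints)
    for ep in endpoints:
        fits[f"crosssectional_{ep}"] = crosssectional_model(
            data, ep, robust=bool(scfg["robust"]))
    present = set(cohort["timepoint_months"])
    for t0v, t1v in scfg["longitudinal_intervals"]:
        if not {int(t0v), int(t1v)} <= present:
            log.warning("longitudinal interval (%s, %s) skipped: visits absent", t0v, t1v)
            continue
        for ep in endpoints:
            fits[f"longitudinal_{ep}_{t0v}_{t1v}"] = longitudinal_model(
                data, ep, (int(t0v), int(t1v)), robust=bool(scfg["robust"]))
    frame = model_report_frame(fits)
    p = out / "stats" / "models.csv"
    frame.to_csv(p, index=False, float_format="%.6g")
    outputs.append(p)
    p = out / "stats" / "models.json"
    p.write_text(json.dumps({k: f.to_report() for k, f in fits.items()},
                            indent=1, sort_keys=True))
    outputs.append(p)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
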