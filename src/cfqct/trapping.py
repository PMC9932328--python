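"""Air-trapping metrics from paired inspiratory/expiratory CT.

All quantities are pure histogram statistics over a masked lung region:

* **TLV / RLV** — inspiratory / expiratory region volume (voxel count times
  voxel volume), cm^3.
* **RVC856–950** — change, expiration minus inspiration, of the relative
  volume of voxels with attenuation in [−950, −856] HU among
  non-emphysematous lung (voxels above −950 HU on the same scan). Ranges −1
  to 0; values closer to 0 mean more trapping.
* **E/I MLA** — expiratory-to-inspiratory ratio of mean lung attenuation;
  0 to 1, higher means more trapping.
* **A1/A2/A3** — percentages of analysed expiratory parenchyma below three
  nested patient-specific thresholds interpolated between the two mean lung
  attenuations, liberal (A1) to stringent (A3); A1 ⊇ A2 ⊇ A3 by
  construction.

No inspiratory–expiratory registration is performed: lobar masks are taken
as given per scan, and every metric here depends only on the within-region
attenuation histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import RegionMask, VolumeGrid, validate_alignment

#: HU band of the relative-volume-change metric (inclusive edges).
RVC_BAND = (-950.0, -856.0)
#: Emphysema-exclusion cutoff: voxels at or below this HU are excluded.
EMPHYSEMA_HU = -950.0
#: Default interpolation fractions of the three trapping thresholds.
DEFAULT_THRESHOLD_FRACTIONS = (0.75, 0.50, 0.25)


class RegionError(ValueError):
    """Empty region or unusable attenuation pair."""


@dataclass
class AirTrappingResult:
    region: str
    TLV_cm3: float
    RLV_cm3: float
    MLA_I: float
    MLA_E: float
    RVC: float
    EI_MLA: float
    T1: float
    T2: float
    T3: float
    A1: float
    A2: float
    A3: float


def _region_values(grid: VolumeGrid, mask: RegionMask, region: str) -> np.ndarray:
    validate_alignment(grid, mask)
    sel = mask.region_indices(region)
    vals = grid.data[sel]
    if vals.size == 0:
        raise RegionError(f"region {region!r} selects no voxels")
    return vals


def region_volume(grid: VolumeGrid, mask: RegionMask, region: str) -> float:
    """Region volume in cm^3: voxel count x voxel volume / 1000."""
    n = int(_region_values(grid, mask, region).size)
    return n * grid.voxel_volume_mm3 / 1000.0


def compute_rvc(
    insp: VolumeGrid, insp_mask: RegionMask,
    exp: VolumeGrid, exp_mask: RegionMask,
    region: str = "total",
) -> float:
    """RVC856–950: expiratory minus inspiratory relative band volume.

    Each scan's denominator is its own non-emphysematous lung (HU above
    −950); the band [−950, −856] has inclusive edges.
    """
    out = []
    for grid, mask in ((exp, exp_mask), (insp, insp_mask)):
        vals = _region_values(grid, mask, region)
        denom = int((vals > EMPHYSEMA_HU).sum())
        if denom == 0:
            raise RegionError(f"region {region!r}: no voxels above {EMPHYSEMA_HU} HU")
        band = int(((vals >= RVC_BAND[0]) & (vals <= RVC_BAND[1])).sum())
        out.append(band / denom)
    return out[0] - out[1]


def mean_lung_attenuation(grid: VolumeGrid, mask: RegionMask, region: str = "total") -> float:
    return float(_region_values(grid, mask, region).mean())


def compute_ei_mla(
    insp: VolumeGrid, insp_mask: RegionMask,
    exp: VolumeGrid, exp_mask: RegionMask,
    region: str = "total",
) -> float:
    mla_i = mean_lung_attenuation(insp, insp_mask, region)
    mla_e = mean_lung_attenuation(exp, exp_mask, region)
    if mla_i == 0:
        raise RegionError("inspiratory MLA is zero; ratio undefined")
    return mla_e / mla_i


def derive_at_thresholds(
    mla_i: float,
    mla_e: float,
    fractions: tuple[float, float, float] = DEFAULT_THRESHOLD_FRACTIONS,
) -> tuple[float, float, float]:
    """Patient-specific trapping thresholds between the two MLAs.

    T_k = MLA_I + f_k * (MLA_E - MLA_I) with f1 > f2 > f3, so T1 > T2 > T3 on
    the HU scale: the stringent threshold T3 sits closest to the (darker)
    inspiratory attenuation. Anchoring the thresholds to the subject's own
    attenuation pair keeps them valid across the growth-related density
    drift that breaks fixed-HU cutoffs in children.
    """
    if mla_e <= mla_i:
        raise RegionError(
            f"non-physiological MLA pair: expiratory {mla_e} must exceed inspiratory {mla_i}"
        )
    f1, f2, f3 = fractions
    if not (f1 >= f2 >= f3):
        raise ValueError(f"threshold fractions must be non-increasing, got {fractions}")
    return tuple(mla_i + f * (mla_e - mla_i) for f in (f1, f2, f3))


def compute_defects(
    exp: VolumeGrid,
    exp_mask: RegionMask,
    thresholds: tuple[float, float, float],
    region: str = "total",
) -> tuple[float, float, float]:
    """A1–A3: % of analysed expiratory parenchyma at or below each threshold."""
    t1, t2, t3 = thresholds
    if not (t1 >= t2 >= t3):
        raise ValueError(f"thresholds must satisfy T1 >= T2 >= T3, got {thresholds}")
    vals = _region_values(exp, exp_mask, region)
    return tuple(100.0 * float((vals <= t).sum()) / vals.size for t in (t1, t2, t3))


def analyse_pair(
    insp: VolumeGrid, insp_mask: RegionMask,
    exp: VolumeGrid, exp_mask: RegionMask,
    region: str = "total",
    fractions: tuple[float, float, float] = DEFAULT_THRESHOLD_FRACTIONS,
) -> AirTrappingResult:
    """All air-trapping endpoints for one region of one insp/exp pair.

    The A1–A3 thresholds are patient-specific: they are derived from the
    *total-lung* MLA pair and then applied per region, so lobar defect
    percentages of one subject share one threshold triple.
    """
    mla_i_total = mean_lung_attenuation(insp, insp_mask, "total")
    mla_e_total = mean_lung_attenuation(exp, exp_mask, "total")
    thresholds = derive_at_thresholds(mla_i_total, mla_e_total, fractions)
    a1, a2, a3 = compute_defects(exp, exp_mask, thresholds, region)
    return AirTrappingResult(
        region=region,
        TLV_cm3=region_volume(insp, insp_mask, region),
        RLV_cm3=region_volume(exp, exp_mask, region),
        MLA_I=mean_lung_attenuation(insp, insp_mask, region),
        MLA_E=mean_lung_attenuation(exp, exp_mask, region),
        RVC=compute_rvc(insp, insp_mask, exp, exp_mask, region),
        EI_MLA=compute_ei_mla(insp, insp_mask, exp, exp_mask, region),
        T1=thresholds[0], T2=thresholds[1], T3=thresholds[2],
        A1=a1, A2=a2, A3=a3,
    )


RESULT_CSV_HEADER = "region,TLV_cm3,RLV_cm3,MLA_I,MLA_E,RVC,EI_MLA,T1,T2,T3,A1,A2,A3"


def results_table(results: list[AirTrappingResult]) -> list[str]:
    lines = [RESULT_CSV_HEADER]
    for r in results:
        lines.append(
            f"{r.region},{r.TLV_cm3:.6g},{r.RLV_cm3:.6g},{r.MLA_I:.6g},{r.MLA_E:.6g},"
            f"{r.RVC:.6g},{r.EI_MLA:.6g},{r.T1:.6g},{r.T2:.6g},{r.T3:.6g},"
            f"{r.A1:.6g},{r.A2:.6g},{r.A3:.6g}"
        )
    return lines
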