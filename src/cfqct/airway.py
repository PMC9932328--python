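"""Airway geometry from orthogonal cross-sections, G5–10 aggregation, and
the tapering-based bronchiectasis index (BEI).

Measurement model
-----------------
At a centerline position, the attenuation volume is resampled on radial
spokes in the plane orthogonal to the local tangent (trilinear
interpolation, 0.25 mm radial step by default, 64 spokes). Along each spoke
the wall appears as a bright bump between the dark lumen and the parenchyma
plateau. Borders are located by full-width-half-maximum (FWHM):

* inner border — the half-rise position between the lumen level and the
  wall-peak level;
* outer border — the half-fall position between the wall peak and the outer
  plateau, estimated in a short window beyond the peak.

Crossings are refined by linear sub-sample interpolation. Spokes with no
prominent wall peak or no plateau within the search radius are discarded;
the whole section is invalid when more than 25% of spokes fail. Lumen area
LA and the outer area are the shoelace areas of the polygons through the
retained border points; WA is their difference, and

    WP = 100*WA/(LA+WA),  TD = 2*sqrt((LA+WA)/pi),  WT = (TD - 2*sqrt(LA/pi))/2

follow exactly from the two areas (equivalent-circle convention).

The bronchiectasis index sums normalized tapering violations: for each
measured parent→child pair with child generation >= 3, the error
max(0, (LD_child - k*LD_parent)/(k*LD_parent)) with k = 1 by default, summed
per lobe or over the whole lung. A healthy, strictly tapering tree scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .tree import AirwayTreeModel, Branch
from .volume_io import VolumeGrid

LOBE_SET = {"RUL", "RML", "RLL", "LUL", "LLi", "LLL"}


class MeasurementError(ValueError):
    pass


@dataclass
class MeasureParams:
    """Tunable knobs of the cross-section measurement."""

    n_rays: int = 64                  # radial spokes per section
    radial_step_mm: float = 0.25      # in-plane resampling resolution
    max_radius_mm: float = 12.0       # spoke length
    interp_order: int = 3             # 3 = cubic-spline resampling, 1 = trilinear
    lumen_window_mm: float = 0.3      # radius over which the lumen level is read
    peak_prominence_hu: float = 75.0  # minimum wall-peak prominence over its surround
    plateau_offset_mm: float = 2.0    # start of the outer-plateau window past the peak
    plateau_window_mm: float = 1.5    # width of the plateau window
    max_invalid_fraction: float = 0.25
    section_step_mm: float = 1.0      # centerline sampling distance
    exclusion_mm: float = 2.0         # skip sections this close to either endpoint
    bei_kappa: float = 1.0            # tapering-reserve factor of the BEI
    wall_hu: float | None = None      # calibrated wall attenuation → integral correction
    integral_margin_mm: float = 1.2   # integration margin past the FWHM borders


@dataclass
class CrossSectionMeasure:
    """Geometry of one orthogonal airway cross-section."""

    position_mm: np.ndarray
    pos_along_branch_mm: float
    LA: float | None = None       # lumen area, mm^2
    WA: float | None = None       # wall area, mm^2
    TD: float | None = None       # total (outer) diameter, mm
    WT: float | None = None       # wall thickness, mm
    WP: float | None = None       # wall percentage, %
    valid: bool = False
    reason: str | None = None
    n_rays_used: int = 0


@dataclass
class RegionAirwaySummary:
    region: str
    generation_range: tuple[int, int]
    TD: float | None
    WT: float | None
    LA: float | None
    WP: float | None
    n_sections: int
    n_branches: int


@dataclass
class BEIResult:
    region: str
    bei: float
    n_pairs: int
    violations: list = field(default_factory=list)   # (parent_id, child_id, error)


# ---------------------------------------------------------------------------
# Cross-section measurement
# ---------------------------------------------------------------------------

def _orthonormal_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(tangent, dtype=float)
    nrm = np.linalg.norm(t)
    if nrm < 1e-12:
        raise MeasurementError("degenerate tangent vector")
    t = t / nrm
    helper = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def _interp_source(grid: VolumeGrid, order: int):
    """Interpolation source array; spline coefficients cached per grid."""
    if order <= 1:
        return grid.data, True
    cache = getattr(grid, "_spline_cache", None)
    if cache is None or cache[0] != order:
        coeffs = ndimage.spline_filter(grid.data, order=order, output=np.float64,
                                       mode="nearest")
        grid._spline_cache = (order, coeffs)
    return grid._spline_cache[1], False


def _sample_profiles(grid: VolumeGrid, point, u, v, params: MeasureParams) -> np.ndarray:
    """(n_rays, n_radii) HU profiles along radial spokes."""
    radii = np.arange(0.0, params.max_radius_mm + 1e-9, params.radial_step_mm)
    theta = 2.0 * np.pi * np.arange(params.n_rays) / params.n_rays
    dirs = np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)  # (n_rays, 3)
    pts = np.asarray(point)[None, None, :] + dirs[:, None, :] * radii[None, :, None]
    idx = grid.physical_to_index(pts.reshape(-1, 3))
    source, prefilter = _interp_source(grid, params.interp_order)
    vals = ndimage.map_coordinates(source, idx.T, order=params.interp_order,
                                   mode="nearest", prefilter=prefilter)
    return vals.reshape(len(theta), len(radii))


def _fwhm_borders(profile: np.ndarray, params: MeasureParams):
    """Return (r_inner, r_outer) in mm for one spoke, or None when it fails."""
    step = params.radial_step_mm
    k_lum = max(1, int(round(params.lumen_window_mm / step)) + 1)
    lumen_level = float(np.median(profile[:k_lum]))

    peaks, _ = find_peaks(profile, prominence=params.peak_prominence_hu)
    # the boundary sample can be a maximum without being a find_peaks "peak"
    if len(peaks) == 0:
        return None
    p = int(peaks[0])
    peak_level = float(profile[p])
    if peak_level - lumen_level < params.peak_prominence_hu:
        return None

    # inner border: half-rise between lumen and peak, nearest crossing below the peak
    h_in = 0.5 * (lumen_level + peak_level)
    i = p
    while i > 0 and profile[i - 1] > h_in:
        i -= 1
    if i == 0:
        return None
    lo, hi = profile[i - 1], profile[i]
    frac = 0.0 if hi == lo else (h_in - lo) / (hi - lo)
    r_inner = (i - 1 + frac) * step

    # outer plateau level in a fixed window beyond the peak
    w0 = p + int(round(params.plateau_offset_mm / step))
    w1 = w0 + max(1, int(round(params.plateau_window_mm / step)))
    if w1 > len(profile):
        return None
    plateau = float(np.median(profile[w0:w1]))
    if peak_level - plateau < params.peak_prominence_hu:
        return None

    h_out = 0.5 * (peak_level + plateau)
    j = p
    while j < w1 - 1 and profile[j + 1] > h_out:
        j += 1
    if j >= w1 - 1:
        return None
    lo, hi = profile[j], profile[j + 1]
    frac = 0.0 if hi == lo else (lo - h_out) / (lo - hi)  # falling edge
    r_outer = (j + frac) * step
    if r_outer <= r_inner:
        return None
    if params.wall_hu is not None:
        corrected = _integral_correction(
            profile, r_inner, r_outer, lumen_level, plateau, params
        )
        if corrected is not None:
            return corrected
    return r_inner, r_outer


def _integral_correction(profile, r_in, r_out, lumen_level, plateau, params: MeasureParams):
    """Area-preserving thin-wall refinement of the FWHM borders.

    Sub-voxel walls blur into bumps wider and flatter than the wall itself,
    which drags the FWHM inner border into the lumen and inflates the wall
    thickness. Convolutional blur preserves two quantities: the midpoint of
    the two half-crossings (the wall centre, for a near-symmetric kernel) and
    the integral of the profile over a window bracketing the wall. With the
    wall material attenuation W calibrated (``params.wall_hu``), the true
    width w follows in closed form from the window integral I over
    [r0, r3] with lumen level L and outer plateau B:

        I - (L - B)(rc - r0) = w * (W - (L + B)/2)

    The corrected borders are rc -/+ w/2. Falls back to the plain FWHM
    borders when the geometry leaves no room for the integration window or
    the calibration is inconsistent (denominator <= 0).
    """
    step = params.radial_step_mm
    W = params.wall_hu
    den = W - 0.5 * (lumen_level + plateau)
    if den <= 0:
        return None
    rc = 0.5 * (r_in + r_out)
    r0 = max(0.0, r_in - params.integral_margin_mm)  # small lumens: window hits the centre
    r3 = r_out + params.integral_margin_mm
    i0, i3 = int(np.ceil(r0 / step)), int(np.floor(r3 / step))
    if i3 >= len(profile) or i3 - i0 < 3:
        return None
    r0, r3 = i0 * step, i3 * step
    integral = float(np.trapezoid(profile[i0 : i3 + 1] - plateau, dx=step))
    w = (integral - (lumen_level - plateau) * (rc - r0)) / den
    if w <= 0 or w > (r_out - r_in) * 2:
        return None
    return rc - 0.5 * w, rc + 0.5 * w


def _polygon_area(radii: np.ndarray, theta: np.ndarray) -> float:
    x, y = radii * np.cos(theta), radii * np.sin(theta)
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def measure_cross_section(
    grid: VolumeGrid,
    point,
    tangent,
    params: MeasureParams | None = None,
    pos_along_branch_mm: float = 0.0,
) -> CrossSectionMeasure:
    """Measure LA/WA/TD/WT/WP on the plane orthogonal to ``tangent`` at ``point``."""
    params = params or MeasureParams()
    point = np.asarray(point, dtype=float)
    idx = grid.physical_to_index(point)
    if np.any(idx < 0) or np.any(idx > np.asarray(grid.shape) - 1):
        raise MeasurementError(f"section point {point} lies outside the grid")
    u, v = _orthonormal_basis(tangent)

    profiles = _sample_profiles(grid, point, u, v, params)
    theta = 2.0 * np.pi * np.arange(params.n_rays) / params.n_rays
    inner, outer, kept = [], [], []
    for j in range(params.n_rays):
        res = _fwhm_borders(profiles[j], params)
        if res is not None:
            inner.append(res[0])
            outer.append(res[1])
            kept.append(theta[j])

    m = CrossSectionMeasure(position_mm=point, pos_along_branch_mm=pos_along_branch_mm,
                            n_rays_used=len(kept))
    discarded = 1.0 - len(kept) / params.n_rays
    if discarded > params.max_invalid_fraction:
        m.reason = f"{discarded:.0%} of rays failed to find a wall"
        return m

    kept = np.asarray(kept)
    la = _polygon_area(np.asarray(inner), kept)
    outer_area = _polygon_area(np.asarray(outer), kept)
    wa = outer_area - la
    if la <= 0 or wa <= 0:
        m.reason = "degenerate border polygons"
        return m
    m.LA, m.WA = la, wa
    m.TD = 2.0 * float(np.sqrt((la + wa) / np.pi))
    m.WT = (m.TD - 2.0 * float(np.sqrt(la / np.pi))) / 2.0
    m.WP = 100.0 * wa / (la + wa)
    m.valid = True
    return m


# ---------------------------------------------------------------------------
# Branch and tree measurement
# ---------------------------------------------------------------------------

def _resample_centerline(cl: np.ndarray, step: float):
    """Arc-length positions, points and tangents every ``step`` mm."""
    seg = np.diff(cl, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = float(seglen.sum())
    if total <= 0:
        return np.array([]), np.zeros((0, 3)), np.zeros((0, 3)), 0.0
    s = np.arange(step * 0.5, total, step)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    pts, tans = [], []
    for si in s:
        k = int(np.searchsorted(cum, si, side="right") - 1)
        k = min(k, len(seg) - 1)
        frac = (si - cum[k]) / seglen[k]
        pts.append(cl[k] + frac * seg[k])
        tans.append(seg[k] / seglen[k])
    return s, np.asarray(pts), np.asarray(tans), total


def measure_branch(grid: VolumeGrid, branch: Branch, params: MeasureParams) -> list[CrossSectionMeasure]:
    s, pts, tans, _total = _resample_centerline(branch.centerline, params.section_step_mm)
    sections = []
    for si, p, t in zip(s, pts, tans):
        try:
            sections.append(measure_cross_section(grid, p, t, params, pos_along_branch_mm=float(si)))
        except MeasurementError as exc:
            bad = CrossSectionMeasure(position_mm=p, pos_along_branch_mm=float(si))
            bad.reason = str(exc)
            sections.append(bad)
    return sections


def summarize_branch(
    sections: list[CrossSectionMeasure],
    branch_length_mm: float,
    exclusion_mm: float = 2.0,
) -> dict | None:
    """Per-branch TD/WT/LA/WP as medians over valid interior sections.

    Sections closer than ``exclusion_mm`` to either branch endpoint are
    dropped first: cross-sections at bifurcations cut through two lumens and
    are not representative. Returns None when nothing survives.
    """
    interior = [
        s for s in sections
        if s.valid
        and s.pos_along_branch_mm >= exclusion_mm
        and branch_length_mm - s.pos_along_branch_mm >= exclusion_mm
    ]
    if not interior:
        return None
    return {
        key: float(np.median([getattr(s, key) for s in interior]))
        for key in ("TD", "WT", "LA", "WA", "WP")
    }


def measure_tree(grid: VolumeGrid, tree: AirwayTreeModel, params: MeasureParams | None = None) -> AirwayTreeModel:
    """Measure every branch of ``tree`` in place and summarize its geometry."""
    params = params or MeasureParams()
    for branch in tree:
        branch.sections = measure_branch(grid, branch, params)
        geom = summarize_branch(branch.sections, branch.length_mm, params.exclusion_mm)
        if geom is None:
            branch.geometry = {}
            branch.excluded_reason = branch.excluded_reason or "no valid interior sections"
        else:
            branch.geometry = geom
    return tree


# ---------------------------------------------------------------------------
# Aggregation and the bronchiectasis index
# ---------------------------------------------------------------------------

def _branch_in_region(branch: Branch, region: str) -> bool:
    if region == "total":
        return branch.lobe in LOBE_SET
    return branch.lobe == region


def aggregate_region(
    tree: AirwayTreeModel,
    generation_range: tuple[int, int] = (5, 10),
    region: str = "total",
    exclusion_mm: float = 2.0,
) -> RegionAirwaySummary:
    """Section-weighted median geometry over branches of a generation range.

    All valid interior cross-sections of the selected branches are pooled and
    the median taken per parameter, so branches contribute in proportion to
    their section counts. An empty selection yields missing (None)
    aggregates, never zeros.
    """
    g0, g1 = generation_range
    pool: list[CrossSectionMeasure] = []
    n_branches = 0
    for b in tree:
        if b.generation is None or not g0 <= b.generation <= g1:
            continue
        if not _branch_in_region(b, region):
            continue
        secs = [
            s for s in b.sections
            if s.valid
            and s.pos_along_branch_mm >= exclusion_mm
            and b.length_mm - s.pos_along_branch_mm >= exclusion_mm
        ]
        if secs:
            n_branches += 1
            pool.extend(secs)
    if not pool:
        return RegionAirwaySummary(region, (g0, g1), None, None, None, None, 0, 0)
    agg = {k: float(np.median([getattr(s, k) for s in pool])) for k in ("TD", "WT", "LA", "WP")}
    return RegionAirwaySummary(region, (g0, g1), agg["TD"], agg["WT"], agg["LA"], agg["WP"],
                               len(pool), n_branches)


def _lumen_diameter(branch: Branch, use_truth: bool) -> float | None:
    if use_truth:
        return branch.lumen_diameter
    return branch.measured_lumen_diameter


def compute_bei(
    tree: AirwayTreeModel,
    region: str = "total",
    kappa: float = 1.0,
    use_truth: bool = False,
) -> BEIResult:
    """Sum tapering-violation errors over parent→child pairs of a region.

    For each pair with both lumen diameters available and child generation
    >= 3, the error is max(0, (LD_child - kappa*LD_parent)/(kappa*LD_parent));
    kappa = 1 demands strict non-increase. Pairs are attributed to the
    child's lobe. ``use_truth`` evaluates the generator's exact dimensions
    instead of measured ones.
    """
    total = 0.0
    n_pairs = 0
    violations = []
    any_measured = False
    for parent, child in tree.parent_child_pairs():
        ld_p, ld_c = _lumen_diameter(parent, use_truth), _lumen_diameter(child, use_truth)
        if ld_p is not None or ld_c is not None:
            any_measured = True
        if ld_p is None or ld_c is None:
            continue
        if child.generation is None or child.generation < 3:
            continue
        if not _branch_in_region(child, region):
            continue
        n_pairs += 1
        err = max(0.0, (ld_c - kappa * ld_p) / (kappa * ld_p))
        if err > 0:
            violations.append((parent.id, child.id, err))
        total += err
    if not any_measured:
        raise MeasurementError("tree carries no lumen diameters; measure it first")
    return BEIResult(region=region, bei=total, n_pairs=n_pairs, violations=violations)


# ---------------------------------------------------------------------------
# Section table export and a phantom-grade airway segmenter
# ---------------------------------------------------------------------------

SECTION_CSV_HEADER = "branch_id,generation,lobe,pos_mm,LA,WA,TD,WT,WP,valid,reason"


def sections_table(tree: AirwayTreeModel) -> list[str]:
    """CSV lines (with header) of every measured cross-section."""
    lines = [SECTION_CSV_HEADER]
    for b in sorted(tree.branches.values(), key=lambda b: b.id):
        for s in b.sections:
            vals = ",".join(
                "" if getattr(s, k) is None else f"{getattr(s, k):.6g}"
                for k in ("LA", "WA", "TD", "WT", "WP")
            )
            lines.append(
                f"{b.id},{b.generation},{b.lobe or ''},{s.pos_along_branch_mm:.3f},"
                f"{vals},{int(s.valid)},{s.reason or ''}"
            )
    return lines


def segment_airways(
    grid: VolumeGrid,
    seed_point_mm,
    threshold_hu: float = -900.0,
    leak_fraction: float = 0.2,
) -> np.ndarray:
    """Simple HU-threshold region growing with a gross leak check.

    Grows the connected low-attenuation component containing the seed. If the
    component swallows more than ``leak_fraction`` of the volume the grow has
    leaked into parenchyma and a :class:`MeasurementError` is raised. Suited
    to phantom volumes only; clinical-grade airway segmentation is out of
    scope for this package.
    """
    idx = tuple(np.round(grid.physical_to_index(np.asarray(seed_point_mm))).astype(int))
    if any(i < 0 or i >= s for i, s in zip(idx, grid.shape)):
        raise MeasurementError("seed point outside the grid")
    air = grid.data <= threshold_hu
    if not air[idx]:
        raise MeasurementError(f"seed voxel HU {grid.data[idx]:.0f} above threshold {threshold_hu}")
    labels, _ = ndimage.label(air)
    comp = labels == labels[idx]
    if comp.mean() > leak_fraction:
        raise MeasurementError("airway region grow leaked into the background")
    return comp
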