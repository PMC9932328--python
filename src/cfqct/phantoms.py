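"""Digital CT phantoms with exact ground truth.

Two families of phantom are generated:

* **Airway phantoms** — trees of cylindrical tubes (air-filled lumen, dense
  wall annulus, parenchyma-like background) rasterized into an HU lattice
  with partial-volume averaging, plus the exact
  :class:`~cfqct.tree.AirwayTreeModel` that produced them. These exercise the
  cross-section measurement, the G5–10 aggregation and the bronchiectasis
  index with known dimensions.
* **Paired inspiratory/expiratory lung phantoms** — six disjoint ellipsoidal
  "lobes" filled from Gaussian attenuation distributions, with contiguous
  low-attenuation defect blobs planted at a known volume fraction in the
  expiratory scan. These exercise the air-trapping metrics
  (RVC856–950, E/I MLA, A1–A3) against analytically known answers.

Partial-volume handling: a voxel's HU is the volume-weighted mix of
lumen/wall/background material obtained by 3x3x3 subsampling of the voxel.
A sharp binary edge would make any half-maximum edge detector degenerate;
the subsampled mix reproduces the ramped edges real CT reconstruction shows.

All randomness flows from explicit integer seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tree import AirwayTreeModel, Branch, assign_lobes, label_generations
from .volume_io import HU_MAX, HU_MIN, LOBE_LABELS, RegionMask, VolumeGrid


class SpatialBoundsError(ValueError):
    """A branch tube does not fit inside the requested grid."""


class GenerationError(RuntimeError):
    """A phantom target (e.g. defect fraction) could not be realized."""


# ---------------------------------------------------------------------------
# Airway tree phantoms
# ---------------------------------------------------------------------------

@dataclass
class BranchSpec:
    """Geometric description of one tube: a straight segment in mm."""

    id: int
    parent_id: int | None
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    lumen_diameter: float
    wall_thickness: float
    lobe: str | None = None

    def __post_init__(self) -> None:
        if self.lumen_diameter <= 0:
            raise ValueError(f"branch {self.id}: lumen_diameter must be > 0")
        if self.wall_thickness <= 0:
            raise ValueError(f"branch {self.id}: wall_thickness must be > 0")


@dataclass
class AirwayTreeSpec:
    """A full tree of tube specs plus the three material HU values."""

    branches: list[BranchSpec]
    lumen_hu: float = -1000.0
    wall_hu: float = 0.0
    background_hu: float = -850.0


_SUB = None  # cached 3x3x3 unit-cube subsample offsets


def _sub_offsets() -> np.ndarray:
    global _SUB
    if _SUB is None:
        g = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
        _SUB = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    return _SUB


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to the finite segment a→b (flat tube, no caps)."""
    d = b - a
    L2 = float(d @ d)
    t = (points - a) @ d / L2
    radial = np.linalg.norm(points - (a + np.clip(t, 0.0, 1.0)[:, None] * d), axis=1)
    inside = (t >= 0.0) & (t <= 1.0)
    return np.where(inside, radial, np.inf)


def make_airway_phantom(
    spec: AirwayTreeSpec,
    spacing: float | tuple[float, float, float],
    noise_sd: float = 0.0,
    shape: tuple[int, int, int] | None = None,
    origin: tuple[float, float, float] | None = None,
    seed: int = 0,
    margin_voxels: int = 4,
) -> tuple[VolumeGrid, AirwayTreeModel]:
    """Rasterize a tube tree into an HU volume and return it with its truth tree.

    When ``shape`` is omitted the grid is sized to enclose every tube with
    ``margin_voxels`` of background on all sides. When a shape/origin is
    requested, every tube must fit with at least 2 voxels of margin or a
    :class:`SpatialBoundsError` is raised. Gaussian noise of standard
    deviation ``noise_sd`` HU is added when positive, driven by ``seed``.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    if not spec.branches:
        raise ValueError("tree spec has no branches")

    sp = np.asarray(spacing)
    outer_r = {b.id: b.lumen_diameter / 2 + b.wall_thickness for b in spec.branches}
    lo = np.min([np.minimum(b.start, b.end) - outer_r[b.id] for b in spec.branches], axis=0)
    hi = np.max([np.maximum(b.start, b.end) + outer_r[b.id] for b in spec.branches], axis=0)

    if shape is None:
        origin_arr = lo - margin_voxels * sp
        shape = tuple(int(np.ceil((hi[i] - origin_arr[i]) / sp[i])) + margin_voxels + 1 for i in range(3))
    else:
        origin_arr = np.asarray(origin if origin is not None else (0.0, 0.0, 0.0), dtype=float)
        top = origin_arr + (np.asarray(shape) - 1) * sp
        if np.any(lo < origin_arr + 2 * sp) or np.any(hi > top - 2 * sp):
            raise SpatialBoundsError(
                f"tree extent [{lo}, {hi}] does not fit grid [{origin_arr}, {top}] "
                "with a 2-voxel margin"
            )
    origin_arr = np.asarray(origin_arr, dtype=float)
    shape = tuple(int(s) for s in shape)

    weights = (np.uint32(1) << np.arange(27, dtype=np.uint32))
    lumen_bits = np.zeros(shape, dtype=np.uint32)
    wall_bits = np.zeros(shape, dtype=np.uint32)
    offs = _sub_offsets() * sp  # (27, 3) physical offsets inside one voxel

    for b in spec.branches:
        a, e = np.asarray(b.start, float), np.asarray(b.end, float)
        r_l, r_o = b.lumen_diameter / 2.0, outer_r[b.id]
        blo = np.minimum(a, e) - r_o - sp
        bhi = np.maximum(a, e) + r_o + sp
        i0 = np.maximum(np.floor((blo - origin_arr) / sp).astype(int), 0)
        i1 = np.minimum(np.ceil((bhi - origin_arr) / sp).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        ix, iy, iz = [np.arange(i0[k], i1[k]) for k in range(3)]
        grid_idx = np.stack(np.meshgrid(ix, iy, iz, indexing="ij"), axis=-1).reshape(-1, 3)
        centers = grid_idx * sp + origin_arr
        # (n_voxels, 27) distances of subsample points to the tube axis
        pts = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        dist = _segment_distance(pts, a, e).reshape(-1, 27)
        lum_mask = dist <= r_l
        wall_mask = (dist > r_l) & (dist <= r_o)
        lum_pack = (lum_mask.astype(np.uint32) * weights).sum(axis=1, dtype=np.uint64).astype(np.uint32)
        wall_pack = (wall_mask.astype(np.uint32) * weights).sum(axis=1, dtype=np.uint64).astype(np.uint32)
        sel = (slice(i0[0], i1[0]), slice(i0[1], i1[1]), slice(i0[2], i1[2]))
        lumen_bits[sel] |= lum_pack.reshape(i1[0] - i0[0], i1[1] - i0[1], i1[2] - i0[2])
        wall_bits[sel] |= wall_pack.reshape(i1[0] - i0[0], i1[1] - i0[1], i1[2] - i0[2])

    n_lumen = _popcount27(lumen_bits)
    n_wall = _popcount27(wall_bits & ~lumen_bits)
    data = (
        n_lumen * spec.lumen_hu
        + n_wall * spec.wall_hu
        + (27 - n_lumen - n_wall) * spec.background_hu
    ) / 27.0

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    data = np.clip(data, HU_MIN, HU_MAX)

    grid = VolumeGrid(data.astype(np.float32), spacing, tuple(origin_arr))

    branches = [
        Branch(
            id=b.id,
            parent_id=b.parent_id,
            centerline=np.stack([np.asarray(b.start, float), np.asarray(b.end, float)]),
            lumen_diameter=b.lumen_diameter,
            wall_thickness=b.wall_thickness,
            lobe=b.lobe,
        )
        for b in spec.branches
    ]
    truth = AirwayTreeModel(branches)
    label_generations(truth)
    entries = {
        b.id: b.lobe
        for b in truth
        if b.lobe in LOBE_LABELS
        and (b.parent_id is None or truth.branches[b.parent_id].lobe not in LOBE_LABELS)
    }
    assign_lobes(truth, entries)
    return grid, truth


def _popcount27(bits: np.ndarray) -> np.ndarray:
    """Per-element population count of the 27 low bits of a uint32 array."""
    b = bits.view(np.uint8).reshape(bits.shape + (4,))
    return np.unpackbits(b, axis=-1).sum(axis=-1).astype(np.float64)


# -- convenience tree builders ---------------------------------------------

def single_tube_spec(
    lumen_diameter: float,
    wall_thickness: float,
    length: float = 20.0,
    direction=(0.0, 0.0, 1.0),
    lobe: str | None = None,
    **hu,
) -> AirwayTreeSpec:
    """One straight tube centred on the origin, for measurement tests."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    half = d * length / 2.0
    return AirwayTreeSpec(
        branches=[
            BranchSpec(
                id=0,
                parent_id=None,
                start=tuple(-half),
                end=tuple(half),
                lumen_diameter=lumen_diameter,
                wall_thickness=wall_thickness,
                lobe=lobe,
            )
        ],
        **hu,
    )


#: Unit directions used to fan the six lobar subtrees apart.
_LOBE_DIRECTIONS = {
    "RUL": (0.55, 0.45, 0.45),
    "RML": (0.85, -0.35, -0.10),
    "RLL": (0.45, 0.35, -0.75),
    "LUL": (-0.55, -0.45, 0.45),
    "LLi": (-0.85, 0.35, -0.10),
    "LLL": (-0.45, -0.35, -0.75),
}


def six_lobe_tree_spec(
    trachea_lumen: float = 8.0,
    taper: float = 0.8,
    max_generation: int = 6,
    branch_length: float = 9.0,
    wall_fraction: float = 0.18,
    min_wall: float = 0.6,
    dilations: dict[tuple[str, int], float] | None = None,
    **hu,
) -> AirwayTreeSpec:
    """A compact six-lobe tree: trachea, two mains, one chain per lobe.

    Lumens taper geometrically (child = ``taper`` x parent). ``dilations``
    maps (lobe, generation) to a multiplicative factor on that branch's
    lumen, used to plant bronchiectatic tapering violations with known
    magnitude. Wall thickness tracks the lumen (``wall_fraction`` of the
    lumen diameter, floored at ``min_wall`` mm).
    """
    dilations = dilations or {}

    def wall(lumen: float) -> float:
        return max(min_wall, wall_fraction * lumen)

    branches: list[BranchSpec] = []
    top = np.array([0.0, 0.0, branch_length * 1.6])
    carina = np.array([0.0, 0.0, 0.0])
    branches.append(BranchSpec(0, None, tuple(top), tuple(carina),
                               trachea_lumen, wall(trachea_lumen)))
    main_lumen = trachea_lumen * taper
    next_id = 1
    main_ends = {}
    for sign, name in ((1.0, "right"), (-1.0, "left")):
        d = np.array([0.75 * sign, 0.0, -0.66])
        d /= np.linalg.norm(d)
        end = carina + d * branch_length * 1.2
        branches.append(BranchSpec(next_id, 0, tuple(carina), tuple(end),
                                   main_lumen, wall(main_lumen)))
        main_ends[name] = (next_id, end)
        next_id += 1

    for lobe, direction in _LOBE_DIRECTIONS.items():
        side = "right" if lobe.startswith("R") else "left"
        parent_id, start = main_ends[side]
        d = np.asarray(direction, float)
        d /= np.linalg.norm(d)
        lumen = main_lumen * taper
        pid, pos = parent_id, start
        for gen in range(3, max_generation + 1):
            lum = lumen * dilations.get((lobe, gen), 1.0)
            length = branch_length * (0.92 ** (gen - 3))
            end = pos + d * length
            branches.append(BranchSpec(next_id, pid, tuple(pos), tuple(end), lum, wall(lum), lobe))
            pid, pos = next_id, end
            next_id += 1
            lumen *= taper
            # bend the chain slightly so deep branches stay compact
            rot = np.array([d[0] * 0.92, d[1] * 0.92, d[2] * 0.92 - 0.12])
            d = rot / np.linalg.norm(rot)
    return AirwayTreeSpec(branches=branches, **hu)


# ---------------------------------------------------------------------------
# Paired inspiratory/expiratory lung phantoms
# ---------------------------------------------------------------------------

@dataclass
class TrappingSpec:
    """Attenuation model for one paired insp/exp phantom.

    Inspiratory lung voxels are drawn from ``insp``; expiratory voxels from
    ``exp_normal`` except inside planted defect blobs, which use ``defect``.
    Lungs densify on expiration, so the expiratory normal mean must sit above
    the inspiratory mean, and trapped (defect) tissue stays darker than
    normal expiratory tissue.
    """

    defect_fractions: dict[str, float] = field(default_factory=dict)  # lobe → [0,1]
    insp: tuple[float, float] = (-850.0, 50.0)        # (mean HU, sd)
    exp_normal: tuple[float, float] = (-650.0, 50.0)
    defect: tuple[float, float] = (-880.0, 30.0)
    blob_radius_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lobe, f in self.defect_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"defect fraction for {lobe} must be in [0,1], got {f}")
        if self.exp_normal[0] <= self.insp[0]:
            raise ValueError("expiratory normal mean HU must exceed inspiratory mean "
                             "(lung densifies on expiration)")
        if self.defect[0] >= self.exp_normal[0]:
            raise ValueError("defect mean HU must lie below the expiratory normal mean")


@dataclass
class PairedLungPhantom:
    insp: VolumeGrid
    exp: VolumeGrid
    mask: RegionMask
    defect_mask: np.ndarray                    # bool lattice of planted voxels
    realized_fractions: dict[str, float]       # lobe → planted voxels / lobe voxels
    planted_voxels: dict[str, int]


def make_lobe_mask(
    shape: tuple[int, int, int] = (60, 44, 30),
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
    kind: str = "ellipsoid",
) -> RegionMask:
    """Six disjoint lobe regions (ellipsoids or boxes) in a 2x3 layout."""
    labels = np.zeros(shape, dtype=np.uint8)
    nx, ny, nz = shape
    order = ["RUL", "RML", "RLL", "LUL", "LLi", "LLL"]
    cell = (nx // 2, ny // 3)
    for i, name in enumerate(order):
        cx, cy = divmod(i, 3)
        x0, y0 = cx * cell[0], cy * cell[1]
        # leave a 2-voxel gap between cells so regions are unambiguous
        xs, ys, zs = slice(x0 + 2, x0 + cell[0] - 2), slice(y0 + 2, y0 + cell[1] - 2), slice(2, nz - 2)
        if kind == "box":
            labels[xs, ys, zs] = LOBE_LABELS[name]
        elif kind == "ellipsoid":
            ax = (xs.stop - xs.start) / 2.0
            ay = (ys.stop - ys.start) / 2.0
            az = (zs.stop - zs.start) / 2.0
            ccx, ccy, ccz = xs.start + ax - 0.5, ys.start + ay - 0.5, zs.start + az - 0.5
            X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
            inside = ((X - ccx) / ax) ** 2 + ((Y - ccy) / ay) ** 2 + ((Z - ccz) / az) ** 2 <= 1.0
            labels[inside] = LOBE_LABELS[name]
        else:
            raise ValueError(f"unknown lobe geometry kind {kind!r}")
    return RegionMask(labels, spacing)


def ellipsoid_volume_cm3(mask_shape_cell, spacing) -> float:
    """Analytic 4/3*pi*a*b*c volume (cm^3) of one lobe cell's ellipsoid."""
    a, b, c = (s / 2.0 for s in mask_shape_cell)
    sx, sy, sz = spacing
    return 4.0 / 3.0 * np.pi * a * sx * b * sy * c * sz / 1000.0


def make_paired_lung_phantom(lobe_mask: RegionMask, spec: TrappingSpec) -> PairedLungPhantom:
    """Draw paired insp/exp volumes and plant expiratory defect blobs.

    Defects are contiguous quasi-spherical blobs placed by rejection sampling
    entirely inside their lobe (blobs never straddle a lobe border). The blob
    count and a final voxel-growth step hit the target voxel count exactly,
    so the realized fraction recorded here is also what voxel counting
    recovers.
    """
    rng = np.random.default_rng(spec.seed)
    labels = lobe_mask.labels
    lung = labels > 0

    insp = rng.normal(spec.insp[0], spec.insp[1], size=labels.shape)
    exp = rng.normal(spec.exp_normal[0], spec.exp_normal[1], size=labels.shape)
    body_hu = 40.0  # soft tissue outside the lung
    insp[~lung] = body_hu
    exp[~lung] = body_hu

    defect = np.zeros(labels.shape, dtype=bool)
    realized, planted_n = {}, {}
    r_vox = max(1, int(round(spec.blob_radius_mm / min(lobe_mask.spacing))))
    ball = _ball_offsets(r_vox)
    for lobe, frac in spec.defect_fractions.items():
        sel = labels == lobe_mask.label_map[lobe]
        n_lobe = int(sel.sum())
        if n_lobe == 0:
            raise GenerationError(f"lobe {lobe} is empty in the mask")
        target = int(round(frac * n_lobe))
        planted = _plant_blobs(rng, sel, target, ball, lobe)
        defect |= planted
        planted_n[lobe] = int(planted.sum())
        realized[lobe] = planted_n[lobe] / n_lobe
    for lobe in lobe_mask.label_map:
        realized.setdefault(lobe, 0.0)
        planted_n.setdefault(lobe, 0)

    n_def = int(defect.sum())
    if n_def:
        exp[defect] = rng.normal(spec.defect[0], spec.defect[1], size=n_def)

    insp = np.clip(insp, HU_MIN, HU_MAX).astype(np.float32)
    exp = np.clip(exp, HU_MIN, HU_MAX).astype(np.float32)
    return PairedLungPhantom(
        insp=VolumeGrid(insp, lobe_mask.spacing, lobe_mask.origin),
        exp=VolumeGrid(exp, lobe_mask.spacing, lobe_mask.origin),
        mask=lobe_mask,
        defect_mask=defect,
        realized_fractions=realized,
        planted_voxels=planted_n,
    )


def _ball_offsets(r: int) -> np.ndarray:
    g = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    inside = X**2 + Y**2 + Z**2 <= r**2
    return np.stack([X[inside], Y[inside], Z[inside]], axis=1)


def _plant_blobs(rng, lobe_sel: np.ndarray, target: int, ball: np.ndarray, lobe: str) -> np.ndarray:
    planted = np.zeros(lobe_sel.shape, dtype=bool)
    if target == 0:
        return planted
    if len(ball) > int(lobe_sel.sum()):
        raise GenerationError(
            f"requested blob ({len(ball)} voxels) exceeds lobe {lobe} "
            f"({int(lobe_sel.sum())} voxels)"
        )
    coords = np.argwhere(lobe_sel)
    shape = np.asarray(lobe_sel.shape)
    n_ball = len(ball)
    attempts = 0
    while target - planted.sum() >= n_ball:
        if attempts > 5000:
            raise GenerationError(
                f"could not reach defect fraction in {lobe} with the requested blob size"
            )
        c = coords[rng.integers(len(coords))]
        vox = c + ball
        if np.any(vox < 0) or np.any(vox >= shape):
            attempts += 1
            continue
        idx = tuple(vox.T)
        if not lobe_sel[idx].all() or planted[idx].any():
            attempts += 1
            continue
        planted[idx] = True
    # grow the planted set voxel-by-voxel inside the lobe to hit the target exactly
    remaining = target - int(planted.sum())
    guard = 0
    while remaining > 0:
        if planted.any():
            frontier = ndimage.binary_dilation(planted) & lobe_sel & ~planted
        else:
            frontier = np.zeros_like(planted)
        cand = np.argwhere(frontier) if frontier.any() else coords[~planted[tuple(coords.T)]]
        if len(cand) == 0:
            raise GenerationError(f"lobe {lobe} saturated before reaching the defect target")
        take = cand[rng.permutation(len(cand))[: min(remaining, len(cand))]]
        planted[tuple(take.T)] = True
        remaining = target - int(planted.sum())
        guard += 1
        if guard > 10 * target + 100:
            raise GenerationError(f"defect growth failed to converge in {lobe}")
    return planted
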