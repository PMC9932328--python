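import numpy as np
import pytest

from cfqct.phantoms import (
    GenerationError,
    SpatialBoundsError,
    TrappingSpec,
    make_airway_phantom,
    make_lobe_mask,
    make_paired_lung_phantom,
    single_tube_spec,
)
from cfqct.trapping import region_volume
from cfqct.volume_io import LOBE_LABELS


class TestAirwayPhantom:
    def test_rasterized_lumen_volume_converges_to_cylinder(self):
        # lumen fraction per voxel is recoverable when wall HU = background HU
        lumen_d, length = 4.0, 16.0
        spec = single_tube_spec(lumen_d, 1.0, length=length,
                                lumen_hu=-1000.0, wall_hu=-850.0, background_hu=-850.0)
        spacing = lumen_d / 2.0 / 4.0  # radius / 4
        grid, _ = make_airway_phantom(spec, spacing)
        frac = (-850.0 - grid.data) / (-850.0 - (-1000.0))
        measured = float(frac.sum()) * grid.voxel_volume_mm3
        expected = np.pi * (lumen_d / 2.0) ** 2 * length
        assert abs(measured / expected - 1.0) < 0.05

    def test_same_seed_bit_identical(self):
        spec = single_tube_spec(4.0, 1.0)
        g1, _ = make_airway_phantom(spec, 0.5, noise_sd=20.0, seed=9)
        g2, _ = make_airway_phantom(spec, 0.5, noise_sd=20.0, seed=9)
        np.testing.assert_array_equal(g1.data, g2.data)
        g3, _ = make_airway_phantom(spec, 0.5, noise_sd=20.0, seed=10)
        assert not np.array_equal(g1.data, g3.data)

    def test_tube_outside_requested_grid_rejected(self):
        spec = single_tube_spec(4.0, 1.0, length=40.0)
        with pytest.raises(SpatialBoundsError):
            make_airway_phantom(spec, 0.5, shape=(32, 32, 32), origin=(-8.0, -8.0, -8.0))

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            make_airway_phantom(single_tube_spec(4.0, 1.0), 0.0)

    def test_truth_tree_carries_dimensions_and_generations(self):
        grid, truth = make_airway_phantom(single_tube_spec(4.0, 1.0), 0.6)
        b = truth.branches[0]
        assert b.lumen_diameter == 4.0 and b.wall_thickness == 1.0
        assert b.generation == 1


class TestLobeMask:
    def test_six_disjoint_lobes(self):
        mask = make_lobe_mask()
        present = set(np.unique(mask.labels)) - {0}
        assert present == set(LOBE_LABELS.values())

    def test_ellipsoid_volume_close_to_analytic(self):
        shape, spacing = (60, 44, 30), (1.5, 1.5, 1.5)
        mask = make_lobe_mask(shape, spacing)
        # one lobe cell is (shape[0]//2 - 4) x (shape[1]//3 - 4) x (shape[2] - 4)
        a, b, c = (shape[0] // 2 - 4) / 2, (shape[1] // 3 - 4) / 2, (shape[2] - 4) / 2
        analytic = 4.0 / 3.0 * np.pi * a * b * c * np.prod(spacing) / 1000.0
        n = int((mask.labels == LOBE_LABELS["RUL"]).sum())
        measured = n * np.prod(spacing) / 1000.0
        # voxelization error bounded by one voxel shell on the surface
        shell = 4.0 * np.pi * max(a, b, c) ** 2 * np.prod(spacing) / 1000.0
        assert abs(measured - analytic) < shell


class TestPairedLungPhantom:
    def test_zero_defect_fraction_plants_nothing(self):
        mask = make_lobe_mask((36, 27, 18), (2.0, 2.0, 2.0))
        ph = make_paired_lung_phantom(mask, TrappingSpec(defect_fractions={}, seed=1))
        assert ph.defect_mask.sum() == 0

    def test_planted_fraction_recovered_exactly_by_counting(self):
        mask = make_lobe_mask()
        ph = make_paired_lung_phantom(
            mask, TrappingSpec(defect_fractions={"RML": 0.10}, seed=3))
        sel = mask.labels == LOBE_LABELS["RML"]
        counted = (ph.defect_mask & sel).sum() / sel.sum()
        assert counted == ph.realized_fractions["RML"]
        assert abs(ph.realized_fractions["RML"] - 0.10) <= 0.01

    def test_defects_confined_to_their_lobe(self):
        mask = make_lobe_mask()
        ph = make_paired_lung_phantom(
            mask, TrappingSpec(defect_fractions={"RML": 0.08}, seed=5))
        outside = ph.defect_mask & (mask.labels != LOBE_LABELS["RML"])
        assert outside.sum() == 0

    def test_same_seed_bit_identical(self):
        mask = make_lobe_mask((36, 27, 18), (2.0, 2.0, 2.0))
        spec = TrappingSpec(defect_fractions={"RUL": 0.05}, seed=8)
        p1 = make_paired_lung_phantom(mask, spec)
        p2 = make_paired_lung_phantom(mask, spec)
        np.testing.assert_array_equal(p1.insp.data, p2.insp.data)
        np.testing.assert_array_equal(p1.exp.data, p2.exp.data)

    def test_unreachable_target_raises(self):
        mask = make_lobe_mask((20, 15, 10), (2.0, 2.0, 2.0))
        spec = TrappingSpec(defect_fractions={"RUL": 0.5}, blob_radius_mm=20.0, seed=1)
        with pytest.raises(GenerationError):
            make_paired_lung_phantom(mask, spec)

    def test_physiology_validation(self):
        with pytest.raises(ValueError):
            TrappingSpec(insp=(-650.0, 50.0), exp_normal=(-850.0, 50.0))
        with pytest.raises(ValueError):
            TrappingSpec(defect=(-600.0, 30.0))
        with pytest.raises(ValueError):
            TrappingSpec(defect_fractions={"RUL": 1.5})

    def test_lobar_volumes_sum_to_total(self, paired_phantom):
        ph = paired_phantom
        total = region_volume(ph.insp, ph.mask, "total")
        lobes = sum(region_volume(ph.insp, ph.mask, r) for r in LOBE_LABELS)
        assert total == pytest.approx(lobes, rel=1e-12)
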