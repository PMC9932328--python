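import numpy as np
import pytest

from cfqct.phantoms import TrappingSpec, make_lobe_mask, make_paired_lung_phantom
from cfqct.trapping import (
    RegionError,
    analyse_pair,
    compute_defects,
    compute_ei_mla,
    compute_rvc,
    derive_at_thresholds,
    region_volume,
)
from cfqct.volume_io import LOBE_LABELS, RegionMask, VolumeGrid


def _uniform_pair(insp_hu, exp_hu, shape=(12, 12, 12)):
    labels = np.zeros(shape, dtype=np.uint8)
    labels[1:-1, 1:-1, 1:-1] = LOBE_LABELS["RUL"]
    mask = RegionMask(labels, (1.0, 1.0, 1.0))
    insp = VolumeGrid(np.full(shape, float(insp_hu)), (1.0, 1.0, 1.0))
    exp = VolumeGrid(np.full(shape, float(exp_hu)), (1.0, 1.0, 1.0))
    return insp, exp, mask


class TestRegionVolume:
    def test_thousand_unit_voxels_is_one_cm3(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels.ravel()[:1000] = 1
        mask = RegionMask(labels, (1.0, 1.0, 1.0))
        grid = VolumeGrid(np.full((10, 10, 10), -800.0), (1.0, 1.0, 1.0))
        assert region_volume(grid, mask, "RUL") == pytest.approx(1.0)

    def test_empty_region_rejected(self):
        insp, _, mask = _uniform_pair(-850, -650)
        with pytest.raises(RegionError):
            region_volume(insp, mask, "LLL")


class TestRVC:
    def test_identical_volumes_give_zero(self):
        insp, _, mask = _uniform_pair(-900, -900)
        assert compute_rvc(insp, mask, insp, mask, "RUL") == 0.0

    def test_extreme_band_shift_reaches_minus_one(self):
        # inspiration entirely inside [-950, -856], expiration entirely above
        insp, exp, mask = _uniform_pair(-900, -700)
        assert compute_rvc(insp, mask, exp, mask, "RUL") == pytest.approx(-1.0)

    def test_range_bounds(self, paired_phantom):
        ph = paired_phantom
        rvc = compute_rvc(ph.insp, ph.mask, ph.exp, ph.mask, "total")
        assert -1.0 <= rvc <= 1.0


class TestEIMLA:
    def test_identity(self, paired_phantom):
        ph = paired_phantom
        assert compute_ei_mla(ph.insp, ph.mask, ph.insp, ph.mask, "total") == 1.0

    def test_uniform_ratio(self):
        insp, exp, mask = _uniform_pair(-850, -544)
        assert compute_ei_mla(insp, mask, exp, mask, "RUL") == pytest.approx(544 / 850)


class TestThresholds:
    def test_interpolation_arithmetic(self):
        assert derive_at_thresholds(-850.0, -650.0) == pytest.approx((-700.0, -750.0, -800.0))

    def test_equal_fractions_degenerate(self):
        t = derive_at_thresholds(-850.0, -650.0, (0.5, 0.5, 0.5))
        assert t[0] == t[1] == t[2]

    def test_affine_equivariance(self):
        base = derive_at_thresholds(-850.0, -650.0)
        shifted = derive_at_thresholds(-850.0 + 30.0, -650.0 + 30.0)
        assert np.allclose(np.asarray(shifted) - np.asarray(base), 30.0)

    def test_inverted_mla_pair_rejected(self):
        with pytest.raises(RegionError):
            derive_at_thresholds(-650.0, -850.0)


class TestDefects:
    def test_no_voxels_below_liberal_threshold(self):
        _, exp, mask = _uniform_pair(-850, -600)
        assert compute_defects(exp, mask, (-700.0, -750.0, -800.0), "RUL") == (0.0, 0.0, 0.0)

    def test_saturation(self):
        _, exp, mask = _uniform_pair(-850, -999)
        assert compute_defects(exp, mask, (-700.0, -750.0, -800.0), "RUL") == (100.0, 100.0, 100.0)

    def test_planted_fraction_recovered(self, paired_phantom):
        ph = paired_phantom
        res = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, "RML")
        assert res.A3 == pytest.approx(10.0, abs=1.0)

    def test_nesting_on_every_region(self, paired_phantom):
        ph = paired_phantom
        for region in ("total", *LOBE_LABELS):
            r = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, region)
            assert r.A1 >= r.A2 >= r.A3 >= 0.0
            assert r.A1 <= 100.0


class TestHistogramInvariances:
    def test_voxel_shuffle_invariance(self, paired_phantom):
        ph = paired_phantom
        rvc0 = compute_rvc(ph.insp, ph.mask, ph.exp, ph.mask, "total")
        rng = np.random.default_rng(0)
        sel = ph.mask.labels > 0
        exp2 = ph.exp.data.copy()
        vals = exp2[sel]
        exp2[sel] = rng.permutation(vals)
        shuffled = VolumeGrid(exp2, ph.exp.spacing)
        assert compute_rvc(ph.insp, ph.mask, shuffled, ph.mask, "total") == pytest.approx(rvc0)
        a0 = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, "total")
        a1 = analyse_pair(ph.insp, ph.mask, shuffled, ph.mask, "total")
        assert (a1.A1, a1.A2, a1.A3) == pytest.approx((a0.A1, a0.A2, a0.A3))

    def test_total_equals_volume_weighted_lobar_mean(self, paired_phantom):
        ph = paired_phantom
        total = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, "total")
        acc = np.zeros(3)
        n_total = 0
        for region in LOBE_LABELS:
            r = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, region)
            n = int((ph.mask.labels == LOBE_LABELS[region]).sum())
            acc += n * np.array([r.A1, r.A2, r.A3])
            n_total += n
        pooled = acc / n_total
        assert (total.A1, total.A2, total.A3) == pytest.approx(tuple(pooled))

    def test_enlarging_defect_never_decreases_metrics(self):
        mask = make_lobe_mask((36, 27, 18), (2.0, 2.0, 2.0))
        prev_a3, prev_rvc = -1.0, -2.0
        for frac in (0.02, 0.08, 0.16):
            ph = make_paired_lung_phantom(
                mask, TrappingSpec(defect_fractions={"RLL": frac}, seed=13))
            r = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, "RLL")
            rvc = r.RVC
            assert r.A3 >= prev_a3
            assert rvc >= prev_rvc - 1e-9
            prev_a3, prev_rvc = r.A3, rvc
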