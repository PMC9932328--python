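import numpy as np
import pytest

from cfqct.airway import (
    CrossSectionMeasure,
    MeasureParams,
    MeasurementError,
    aggregate_region,
    measure_cross_section,
    segment_airways,
    summarize_branch,
)
from cfqct.phantoms import make_airway_phantom, single_tube_spec
from cfqct.tree import AirwayTreeModel, Branch

PARAMS = MeasureParams(wall_hu=0.0)


class TestCrossSection:
    def test_cylinder_geometry_recovered(self, tube_4_1):
        grid, _ = tube_4_1
        m = measure_cross_section(grid, (0, 0, 0), (0, 0, 1), PARAMS)
        assert m.valid
        assert m.LA == pytest.approx(np.pi * 2.0**2, rel=0.05)
        assert m.WT == pytest.approx(1.0, abs=0.25)

    def test_two_mm_lumen_resolvable_at_coarse_spacing(self):
        # the resolvability bound: airways down to ~2 mm internal diameter
        spec = single_tube_spec(2.0, 1.0)
        grid, _ = make_airway_phantom(spec, 0.6)
        m = measure_cross_section(grid, (0, 0, 0), (0, 0, 1), PARAMS)
        assert m.valid
        ld = 2.0 * np.sqrt(m.LA / np.pi)
        assert abs(ld - 2.0) <= 0.3

    @pytest.mark.parametrize("direction", [(0.5, 0, 0.866), (0.866, 0, 0.5), (0.5, 0.5, 0.707)])
    def test_rotation_invariance(self, direction):
        spec = single_tube_spec(4.0, 1.0, direction=direction)
        grid, _ = make_airway_phantom(spec, 0.5)
        m = measure_cross_section(grid, (0, 0, 0), direction, PARAMS)
        assert m.valid
        ref = np.pi * 2.0**2
        assert m.LA == pytest.approx(ref, rel=0.02 + 0.03)  # 2% + discretization share

    def test_point_outside_grid_rejected(self, tube_4_1):
        grid, _ = tube_4_1
        with pytest.raises(MeasurementError):
            measure_cross_section(grid, (500.0, 0, 0), (0, 0, 1), PARAMS)

    def test_degenerate_tangent_rejected(self, tube_4_1):
        grid, _ = tube_4_1
        with pytest.raises(MeasurementError):
            measure_cross_section(grid, (0, 0, 0), (0, 0, 0), PARAMS)

    def test_section_in_pure_background_invalid_not_crash(self, tube_4_1):
        grid, _ = tube_4_1
        corner = grid.index_to_physical(np.asarray(grid.shape) - 2.0)
        m = measure_cross_section(grid, corner, (0, 0, 1), PARAMS)
        assert not m.valid and m.reason


def _section(la, wa, pos=5.0, valid=True):
    m = CrossSectionMeasure(position_mm=np.zeros(3), pos_along_branch_mm=pos)
    if valid:
        m.LA, m.WA = la, wa
        m.TD = 2 * np.sqrt((la + wa) / np.pi)
        m.WT = (m.TD - 2 * np.sqrt(la / np.pi)) / 2
        m.WP = 100 * wa / (la + wa)
        m.valid = True
    return m


class TestSummarizeBranch:
    def test_median_over_interior_sections(self):
        secs = [_section(la, 5.0, pos) for la, pos in [(10, 3), (11, 5), (12, 7)]]
        geom = summarize_branch(secs, branch_length_mm=10.0)
        assert geom["LA"] == 11.0

    def test_single_valid_section_passes_through(self):
        geom = summarize_branch([_section(9.0, 4.0, 5.0)], branch_length_mm=10.0)
        assert geom["LA"] == 9.0 and geom["WA"] == 4.0

    def test_bifurcation_sections_excluded(self):
        secs = [_section(10, 5, pos=0.5), _section(12, 5, pos=9.7)]
        assert summarize_branch(secs, branch_length_mm=10.0) is None


def _toy_measured_tree(section_counts):
    """Chain tree RUL: branch i has G=i+5 and section_counts[i] sections."""
    rng = np.random.default_rng(0)
    branches = []
    for i, n_sec in enumerate(section_counts):
        b = Branch(i, i - 1 if i else None,
                   np.array([[0, 0, 10.0 * i], [0, 0, 10.0 * (i + 1)]]), lobe="RUL")
        b.generation = 5 + i
        b.sections = [_section(10 + rng.normal(), 5 + 0.2 * rng.normal(), pos)
                      for pos in np.linspace(2.5, 7.5, n_sec)]
        b.geometry = {"LA": 10.0}
        branches.append(b)
    return AirwayTreeModel(branches)


class TestAggregateRegion:
    def test_identical_geometry_everywhere(self, ):
        tree = _toy_measured_tree([3])
        for s in tree.branches[0].sections:
            s.LA, s.WP, s.TD, s.WT = 10.0, 40.0, 5.0, 0.8
        agg = aggregate_region(tree, (5, 10), "RUL")
        assert (agg.LA, agg.WP, agg.TD, agg.WT) == (10.0, 40.0, 5.0, 0.8)
        total = aggregate_region(tree, (5, 10), "total")
        assert total.LA == 10.0

    def test_generation_range_boundary_excludes(self):
        tree = _toy_measured_tree([3, 3])
        tree.branches[0].generation = 4     # now outside (5, 10)
        agg = aggregate_region(tree, (5, 10), "RUL")
        assert agg.n_branches == 1

    def test_empty_selection_reports_missing_not_zero(self):
        tree = _toy_measured_tree([3])
        agg = aggregate_region(tree, (5, 10), "LLL")
        assert agg.LA is None and agg.n_sections == 0

    def test_section_weighted_median_matches_bruteforce_pooling(self):
        counts = [2, 5, 9]
        tree = _toy_measured_tree(counts)
        agg = aggregate_region(tree, (5, 10), "RUL")
        pooled = [s.LA for b in tree for s in b.sections]
        assert agg.LA == pytest.approx(np.median(pooled))
        # unweighted per-branch median differs when counts are unequal
        unweighted = np.median([np.median([s.LA for s in b.sections]) for b in tree])
        assert agg.LA != pytest.approx(unweighted, abs=1e-12)


class TestFormulasOnEmittedMeasures:
    def test_wp_fifty_when_la_equals_wa(self):
        m = _section(7.0, 7.0)
        assert m.WP == 50.0

    def test_formula_identities_machine_precision(self, measured_six_lobe):
        _, tree = measured_six_lobe
        n_checked = 0
        for b in tree:
            for s in b.sections:
                if not s.valid:
                    continue
                assert s.WP == pytest.approx(100.0 * s.WA / (s.LA + s.WA), abs=1e-12)
                assert s.TD == pytest.approx(2 * np.sqrt((s.LA + s.WA) / np.pi), abs=1e-12)
                assert s.WT == pytest.approx(
                    (s.TD - 2 * np.sqrt(s.LA / np.pi)) / 2, abs=1e-12)
                assert 0.0 < s.WP < 100.0
                n_checked += 1
        assert n_checked > 50


class TestSegmentation:
    def test_region_grow_recovers_lumen(self, tube_4_1):
        grid, _ = tube_4_1
        comp = segment_airways(grid, (0.0, 0.0, 0.0))
        frac = comp.sum() * grid.voxel_volume_mm3 / (np.pi * 4.0 * 20.0)
        assert 0.7 < frac < 1.2

    def test_seed_in_background_rejected(self, tube_4_1):
        grid, _ = tube_4_1
        with pytest.raises(MeasurementError):
            segment_airways(grid, (8.0, 8.0, 0.0))
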