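"""Bronchiectasis-index contract on ground-truth trees.

The BEI sums normalized tapering violations over parent→child pairs, so it
must be zero on a strictly tapering tree, equal a single violation's size
when only one child dilates, add across independent dilations, and never
decrease when any single child lumen grows.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfqct.airway import MeasurementError, compute_bei
from cfqct.tree import AirwayTreeModel, Branch, label_generations


def _truth_tree(lumens_by_id, parents):
    branches = []
    for bid, parent in parents.items():
        b = Branch(bid, parent, np.array([[0, 0, 5.0 * bid], [0, 0, 5.0 * bid + 5]]),
                   lobe="RUL" if bid >= 2 else None,
                   lumen_diameter=lumens_by_id[bid], wall_thickness=1.0)
        branches.append(b)
    return label_generations(AirwayTreeModel(branches))


CHAIN = {0: None, 1: 0, 2: 1, 3: 2, 4: 3}   # G1..G5 chain, lobe from G3


def test_strict_tapering_gives_zero():
    lumens = {i: 8.0 * 0.8**i for i in CHAIN}
    res = compute_bei(_truth_tree(lumens, CHAIN), use_truth=True)
    assert res.bei == 0.0
    assert res.n_pairs == 3  # children at G3, G4, G5


def test_single_dilation_equals_its_relative_excess():
    lumens = {0: 8.0, 1: 6.4, 2: 5.12, 3: 5.12 * 1.5, 4: 3.0}
    res = compute_bei(_truth_tree(lumens, CHAIN), region="RUL", use_truth=True)
    assert res.bei == pytest.approx(0.5)
    assert len(res.violations) == 1


def test_additivity_over_independent_dilations():
    base = {i: 8.0 * 0.8**i for i in CHAIN}
    one = dict(base); one[3] = base[2] * 1.5
    other = dict(base); other[4] = base[3] * 1.2
    both = dict(base); both[3] = base[2] * 1.5; both[4] = base[3] * 1.2
    # 'both' dilates child 4 relative to the *undilated* parent lumen of 'other'
    b_one = compute_bei(_truth_tree(one, CHAIN), use_truth=True).bei
    b_other = compute_bei(_truth_tree(other, CHAIN), use_truth=True).bei
    lumens_both = dict(both)
    b_both = compute_bei(_truth_tree(lumens_both, CHAIN), use_truth=True).bei
    # violations: one -> 0.5; other -> 0.2; both -> 0.5 + (4.8*1.2/ (5.12*1.5) ...)
    assert b_one == pytest.approx(0.5)
    assert b_other == pytest.approx(0.2)
    # with both dilations the second violation is measured against the dilated parent
    expected_second = max(0.0, (base[3] * 1.2) / (base[2] * 1.5) - 1.0)
    assert b_both == pytest.approx(0.5 + expected_second)


def test_pairs_below_generation_three_ignored():
    lumens = {0: 4.0, 1: 8.0, 2: 4.0, 3: 3.0, 4: 2.0}   # G2 child wider than trachea
    res = compute_bei(_truth_tree(lumens, CHAIN), use_truth=True)
    assert res.bei == 0.0


def test_unmeasured_tree_rejected():
    tree = _truth_tree({i: 5.0 for i in CHAIN}, CHAIN)
    for b in tree:
        b.lumen_diameter = None
    with pytest.raises(MeasurementError):
        compute_bei(tree)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(factor=st.floats(min_value=1.0, max_value=3.0),
       bigger=st.floats(min_value=0.01, max_value=1.0))
def test_monotonicity_in_single_child_lumen(factor, bigger):
    base = {i: 8.0 * 0.8**i for i in CHAIN}
    lo = dict(base); lo[3] = base[3] * factor
    hi = dict(base); hi[3] = base[3] * (factor + bigger)
    b_lo = compute_bei(_truth_tree(lo, CHAIN), use_truth=True).bei
    b_hi = compute_bei(_truth_tree(hi, CHAIN), use_truth=True).bei
    assert b_hi >= b_lo


def test_kappa_reserve_tolerates_mild_excess():
    lumens = {0: 8.0, 1: 6.4, 2: 5.12, 3: 5.12 * 1.1, 4: 3.0}
    strict = compute_bei(_truth_tree(lumens, CHAIN), use_truth=True, kappa=1.0)
    relaxed = compute_bei(_truth_tree(lumens, CHAIN), use_truth=True, kappa=1.2)
    assert strict.bei > 0.0
    assert relaxed.bei == 0.0
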