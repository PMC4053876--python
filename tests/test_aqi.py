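"""Breakpoint indexes and the composite PAQI weighting scheme."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paqikit import (
    BreakpointTable,
    classify,
    default_breakpoints,
    default_scheme,
    iaqi,
    modify_weights,
    paqi,
    paqi_grid,
    raw_weights,
)

TABLES = default_breakpoints()


@pytest.mark.parametrize("pollutant", ["PM2.5", "PM10"])
def test_iaqi_breakpoint_nodes_map_exactly(pollutant):
    table = TABLES[pollutant]
    for c, i in table.pairs:
        assert iaqi(c, table) == pytest.approx(i, abs=1e-12)
    assert iaqi(0.0, table) == 0.0


@pytest.mark.parametrize("pollutant", ["PM2.5", "PM10"])
def test_iaqi_segment_midpoints_are_endpoint_means(pollutant):
    table = TABLES[pollutant]
    for (c0, i0), (c1, i1) in zip(table.pairs, table.pairs[1:]):
        assert iaqi((c0 + c1) / 2, table) == pytest.approx((i0 + i1) / 2, abs=1e-12)


def test_iaqi_caps_above_last_breakpoint_and_rejects_negative():
    table = TABLES["PM2.5"]
    assert iaqi(1e4, table) == table.cap_index
    with pytest.raises(ValueError):
        iaqi(-1.0, table)


def test_iaqi_integer_flag_ceils():
    table = TABLES["PM2.5"]
    c = 17.3  # inside first segment, non-integer index
    assert iaqi(c, table, integer=True) == np.ceil(iaqi(c, table))


def test_iaqi_continuous_nondecreasing_dense_scan():
    for table in TABLES.values():
        c = np.arange(0, table.concentrations[-1] + 0.1, 0.1)
        vals = iaqi(c, table)
        assert (np.diff(vals) >= -1e-12).all()
        assert np.max(np.abs(np.diff(vals))) < 1.0  # no jumps at 0.1 resolution


def test_breakpoint_table_validation():
    with pytest.raises(ValueError):
        BreakpointTable("x", ((0.0, 0.0),))
    with pytest.raises(ValueError):
        BreakpointTable("x", ((5.0, 0.0), (10.0, 50.0)))  # first pair not (0,0)
    with pytest.raises(ValueError):
        BreakpointTable("x", ((0.0, 0.0), (10.0, 50.0), (10.0, 100.0)))


def test_raw_weights_examples():
    assert np.allclose(raw_weights([100, 100]), [0.5, 0.5])
    assert np.allclose(raw_weights([300, 100]), [0.75, 0.25])
    assert np.allclose(raw_weights([100, 0]), [1.0, 0.0])
    with pytest.raises(ValueError):
        raw_weights([0.0, 0.0])


def test_modify_weights_rules():
    P, s, t = modify_weights([0.5, 0.5])
    assert np.allclose(P, [0.5, 0.5]) and (s, t) == (0, 0)
    P, s, t = modify_weights([0.96, 0.04])
    assert np.allclose(P, [1.0, 0.0]) and (s, t) == (1, 1)
    # a large weight alone (no small one) leaves weights unchanged
    P, s, t = modify_weights([0.7, 0.3])
    assert np.allclose(P, [0.7, 0.3]) and (s, t) == (0, 1)
    with pytest.raises(ValueError):
        modify_weights([0.4, 0.4])


def test_modify_weights_idempotent():
    rng = np.random.default_rng(0)
    for _ in range(200):
        I = rng.uniform(0, 500, size=rng.integers(2, 5))
        if I.sum() == 0:
            continue
        P, _, _ = modify_weights(I / I.sum())
        P2, _, _ = modify_weights(P)
        assert np.allclose(P, P2, atol=1e-12)


def test_paqi_hand_examples():
    assert paqi([150, 150]).value == pytest.approx(150)
    assert paqi([300, 100]).value == pytest.approx(250)
    bundle = paqi([480, 20])
    assert np.allclose(bundle.raw, [0.96, 0.04])
    assert (bundle.s, bundle.t) == (1, 1)
    assert bundle.value == pytest.approx(480, abs=1e-12)


@settings(derandomize=True, max_examples=300)
@given(
    st.lists(st.floats(min_value=0.01, max_value=500.0), min_size=2, max_size=4)
)
def test_paqi_bounded_by_component_indexes(indexes):
    bundle = paqi(indexes)
    assert min(indexes) - 1e-9 <= bundle.value <= max(indexes) + 1e-9
    assert bundle.modified.sum() == pytest.approx(1.0, abs=1e-9)


def test_paqi_permutation_invariant():
    rng = np.random.default_rng(1)
    for _ in range(100):
        I = rng.uniform(0, 500, size=3)
        if I.sum() == 0:
            continue
        v = paqi(I).value
        perm = rng.permutation(3)
        assert paqi(I[perm]).value == pytest.approx(v, abs=1e-9)


def test_unmodified_paqi_equals_index_weighted_mean_identity():
    # with P = Q, PAQI = sum I^2 / sum I >= mean(I)
    rng = np.random.default_rng(2)
    for _ in range(200):
        I = rng.uniform(50, 400, size=3)
        bundle = paqi(I)
        if bundle.s == 0 or bundle.t == 0:  # no modification triggered
            assert bundle.value == pytest.approx((I**2).sum() / I.sum(), abs=1e-9)
            assert bundle.value >= I.mean() - 1e-9


def test_paqi_grid_matches_scalar_loop_oracle(grid_factory):
    rng = np.random.default_rng(3)
    a = rng.uniform(0, 500, size=(10, 10))
    b = rng.uniform(0, 500, size=(10, 10))
    mask = np.ones((10, 10), bool)
    mask[2, 3] = False
    out = paqi_grid(
        {"PM10": grid_factory(a, name="PM10"), "PM2.5": grid_factory(b, mask, name="PM2.5")}
    )
    assert not out.mask[2, 3]
    for i in range(10):
        for j in range(10):
            if out.mask[i, j]:
                assert out.values[i, j] == pytest.approx(
                    paqi([a[i, j], b[i, j]]).value, abs=1e-9
                )


def test_paqi_grid_constant_inputs(grid_factory):
    c = grid_factory(np.full((5, 5), 150.0), name="a")
    d = grid_factory(np.full((5, 5), 150.0), name="b")
    out = paqi_grid({"a": c, "b": d})
    assert np.allclose(out.values, 150.0)


def test_classify_bounds_and_monotone_severity():
    scheme = default_scheme()
    labels = [lab for _, lab in scheme]
    assert classify(0) == labels[0]
    # a value exactly on a bound takes the upper category
    assert classify(150) == "moderately polluted"
    assert classify(200) == "heavily polluted"
    severity = {lab: k for k, lab in enumerate(labels)}
    ranks = [severity[classify(v)] for v in range(0, 501)]
    assert all(b >= a for a, b in zip(ranks, ranks[1:]))
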