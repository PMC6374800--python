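import numpy as np
import pytest

from urseg.dptrace import (
    SegmentConfig,
    TracedPath,
    assemble_contours,
    backtrack,
    cumulative_cost,
    rasterize_closed_polygon,
    segment_image,
    trace_diaphysis_edge,
    trace_joint_segment,
)
from urseg.errors import ContourAssemblyError, TracingError
from urseg.metrics import confusion, dsc
from urseg.transform import StandardizationTransform


def enumerate_paths(costmap, seed_row, start_col, stop_col):
    """Brute-force oracle: all 3-connected paths, returns (best_cost, best_path).

    Ties are resolved to the minimum cost only; used for cost equality checks.
    """
    h = costmap.shape[0]
    best = [np.inf, None]

    def walk(row, col, cost, path):
        if cost >= best[0]:
            return
        if col == stop_col:
            best[0], best[1] = cost, list(path)
            return
        for dr in (-1, 0, 1):
            r = row + dr
            if 0 <= r < h:
                walk(r, col + 1, cost + costmap[r, col + 1], path + [(r, col + 1)])

    walk(seed_row, start_col, costmap[seed_row, start_col], [(seed_row, start_col)])
    return best[0], best[1]


def identity_transform(shape):
    return StandardizationTransform(
        crop_box=(0, 0, shape[0], shape[1]), scale=(1.0, 1.0),
        rot_k_cw=0, scaled_shape=shape,
    )


# ---------------------------------------------------------------- DP core


def test_three_by_four_example():
    m = np.array([
        [0.1, 0.9, 0.9, 0.9],
        [0.9, 0.1, 0.9, 0.1],
        [0.9, 0.9, 0.1, 0.9],
    ])
    cum = cumulative_cost(m, (0, 0), axis=1, direction=1, stop=3)
    path = backtrack(cum)
    assert path.total_cost == pytest.approx(0.4)
    np.testing.assert_array_equal(path.points, [[0, 0], [1, 1], [2, 2], [1, 3]])
    oracle_cost, _ = enumerate_paths(m, 0, 0, 3)
    assert path.total_cost == pytest.approx(oracle_cost)


def test_zero_map_straight_path():
    m = np.zeros((7, 9))
    cum = cumulative_cost(m, (3, 0), axis=1, direction=1, stop=8)
    path = backtrack(cum)
    np.testing.assert_array_equal(path.points[:, 0], np.full(9, 3))


def test_single_slice():
    m = np.array([[0.5], [0.2], [0.9]])
    cum = cumulative_cost(m, (1, 0), axis=1, direction=1, stop=0)
    assert cum.c[1, 0] == pytest.approx(0.2)
    path = backtrack(cum)
    assert len(path) == 1 and path.total_cost == pytest.approx(0.2)


def test_seed_slice_equals_cost_map(rng):
    m = rng.random((6, 8))
    cum = cumulative_cost(m, (2, 3), axis=1, direction=1, stop=7)
    assert cum.c[2, 3] == pytest.approx(m[2, 3])


def test_cumulative_nondecreasing_along_direction(rng):
    m = rng.random((6, 10))
    cum = cumulative_cost(m, (3, 0), axis=1, direction=1, stop=9)
    finite = np.where(np.isfinite(cum.c), cum.c, np.nan)
    mins = np.nanmin(finite, axis=0)
    assert np.all(np.diff(mins) >= -1e-12)


def test_dp_equals_bruteforce_random(rng):
    for _ in range(30):
        h = int(rng.integers(2, 7))
        w = int(rng.integers(2, 9))
        m = rng.random((h, w))
        seed = (int(rng.integers(0, h)), 0)
        cum = cumulative_cost(m, seed, axis=1, direction=1, stop=w - 1)
        path = backtrack(cum)
        oracle_cost, _ = enumerate_paths(m, seed[0], 0, w - 1)
        assert path.total_cost == pytest.approx(oracle_cost, abs=1e-12)


def test_dp_leftward_direction(rng):
    m = rng.random((5, 7))
    cum = cumulative_cost(m, (2, 6), axis=1, direction=-1, stop=0)
    path = backtrack(cum)
    oracle_cost, _ = enumerate_paths(m[:, ::-1], 2, 0, 6)
    assert path.total_cost == pytest.approx(oracle_cost, abs=1e-12)
    assert path.points[0][1] == 6 and path.points[-1][1] == 0


def test_dp_along_rows(rng):
    m = rng.random((7, 5))
    cum = cumulative_cost(m, (0, 2), axis=0, direction=1, stop=6)
    path = backtrack(cum)
    oracle_cost, _ = enumerate_paths(m.T, 2, 0, 6)
    assert path.total_cost == pytest.approx(oracle_cost, abs=1e-12)


def test_total_cost_matches_recomputed(rng):
    m = rng.random((6, 9))
    cum = cumulative_cost(m, (1, 0), axis=1, direction=1, stop=8)
    path = backtrack(cum)
    assert path.total_cost == pytest.approx(path.cost_along(m), abs=1e-9)


def test_monotonicity_constant_shift(rng):
    m = rng.random((6, 9))
    cum1 = backtrack(cumulative_cost(m, (3, 0), stop=8))
    cum2 = backtrack(cumulative_cost(m + 5.0, (3, 0), stop=8))
    np.testing.assert_array_equal(cum1.points, cum2.points)
    assert cum2.total_cost == pytest.approx(cum1.total_cost + 5.0 * len(cum1))


def test_three_connectivity_enforced():
    with pytest.raises(TracingError):
        TracedPath(points=np.array([[0, 0], [3, 1]]), axis=1, total_cost=0.0)


def test_unreachable_stop_raises(rng):
    m = rng.random((5, 5))
    cum = cumulative_cost(m, (2, 3), axis=1, direction=1, stop=4)
    with pytest.raises(TracingError):
        backtrack(cum, end=(0, 4))  # |0-2| > 1 column step away


# ---------------------------------------------------------------- diaphysis


def test_window_covering_span_equals_single_trace(rng):
    m = rng.random((8, 30))
    seed = (4, 7)
    single = trace_diaphysis_edge(m, seed, +1, window_w=100, stop_col=29)
    windowed = trace_diaphysis_edge(m, seed, +1, window_w=100, stop_col=29)
    np.testing.assert_array_equal(single.points, windowed.points)


def test_dark_line_followed_exactly():
    m = np.ones((20, 40))
    rows = (10 + np.round(3 * np.sin(np.arange(40) / 6.0))).astype(int)
    m[rows, np.arange(40)] = 0.0
    path = trace_diaphysis_edge(m, (rows[8], 8), +1, window_w=16, stop_col=39)
    np.testing.assert_array_equal(path.points[:, 0], rows[8:])
    left = trace_diaphysis_edge(m, (rows[8], 8), -1, window_w=16, stop_col=0)
    np.testing.assert_array_equal(left.points[:, 0], rows[8::-1])


def test_windowed_vs_global_on_clean_line():
    m = np.ones((20, 60))
    m[7, :] = 0.0
    a = trace_diaphysis_edge(m, (7, 30), +1, window_w=10, stop_col=59)
    b = trace_diaphysis_edge(m, (7, 30), +1, window_w=200, stop_col=59)
    np.testing.assert_array_equal(a.points, b.points)


def test_phantom_diaphysis_accuracy(default_phantom):
    truth = default_phantom
    contours, inter = segment_image(truth.image, return_intermediate=True)
    pre = inter["pre"]
    upper = contours.components[0].points  # b1 upper, standardized coords
    pts = pre.transform.to_original(upper.astype(float))
    can = truth.to_canonical_points(pts)
    errs = []
    for r, c in can:
        cc = int(round(np.clip(c, truth.params.collimation, truth.wrist_column - 20)))
        errs.append(abs(r - truth.edge_rows(cc)[0]))
    # ignore distal tail (cap region) for a pure diaphysis assessment
    errs = np.array(errs[: int(0.9 * len(errs))])
    assert errs.mean() <= 2.0


# ---------------------------------------------------------------- joint


def test_joint_straight_vertical_line():
    m = np.ones((30, 40))
    m[:, 20] = 0.0
    path = trace_joint_segment(m, (5, 20), (25, 20), x0=20, n=40)
    np.testing.assert_array_equal(path.points[:, 1], np.full(21, 20))
    assert path.points[0][0] == 5 and path.points[-1][0] == 25


def test_joint_band_restriction(rng):
    m = rng.random((40, 100))
    x0, n = 50, 100
    path = trace_joint_segment(m, (5, 50), (30, 52), x0=x0, n=n)
    half = n // 10
    assert np.all(path.points[:, 1] >= x0 - half)
    assert np.all(path.points[:, 1] <= x0 + half)


def test_joint_band_widened_with_warning(rng, caplog):
    m = rng.random((40, 100))
    with caplog.at_level("WARNING"):
        path = trace_joint_segment(m, (5, 50), (30, 70), x0=50, n=100)
    assert "widening band" in caplog.text
    assert tuple(path.points[-1]) == (30, 70)


def test_joint_requires_top_to_bottom():
    m = np.ones((20, 20))
    with pytest.raises(TracingError):
        trace_joint_segment(m, (15, 10), (5, 10), x0=10, n=20)


def test_joint_unreachable_anchor():
    m = np.ones((20, 60))
    with pytest.raises(TracingError):
        trace_joint_segment(m, (5, 10), (7, 40), x0=25, n=60)


# ---------------------------------------------------------------- assembly


def rect_paths(r0=5, r1=15, c0=2, c1=22):
    top = TracedPath(
        points=np.stack([np.full(c1 - c0 + 1, r0), np.arange(c0, c1 + 1)], 1),
        axis=1, total_cost=0.0,
    )
    bottom = TracedPath(
        points=np.stack([np.full(c1 - c0 + 1, r1), np.arange(c0, c1 + 1)], 1),
        axis=1, total_cost=0.0,
    )
    side = TracedPath(
        points=np.stack([np.arange(r0, r1 + 1), np.full(r1 - r0 + 1, c1)], 1),
        axis=0, total_cost=0.0,
    )
    return top, side, bottom


def test_rectangle_assembly():
    top, side, bottom = rect_paths()
    top2, side2, bottom2 = rect_paths(r0=25, r1=35)
    shape = (50, 40)
    out = assemble_contours(
        [top, side, bottom, top2, side2, bottom2], identity_transform(shape), shape
    )
    # closed polygon, no duplicate junction vertices
    assert np.array_equal(out.bone1[0], out.bone1[-1])
    n_unique = len(out.bone1) - 1
    assert n_unique == 2 * (22 - 2 + 1) + 2 * (15 - 5 + 1) - 4
    assert out.masks[0].sum() == (15 - 5 + 1) * (22 - 2 + 1)


def test_crossing_paths_rejected():
    top, side, bottom = rect_paths(r0=5, r1=15)
    bad_bottom = TracedPath(
        points=np.stack([np.full(21, 3), np.arange(2, 23)], 1), axis=1, total_cost=0.0
    )  # "lower" path above the upper one
    side_bad = TracedPath(
        points=np.stack([np.arange(3, 6), np.full(3, 22)], 1), axis=0, total_cost=0.0
    )
    top2, side2, bottom2 = rect_paths(r0=25, r1=35)
    with pytest.raises(ContourAssemblyError):
        assemble_contours(
            [top, side_bad, bad_bottom, top2, side2, bottom2],
            identity_transform((50, 40)), (50, 40),
        )


def test_wrong_path_count():
    with pytest.raises(ContourAssemblyError):
        assemble_contours([], identity_transform((10, 10)), (10, 10))


def test_rasterize_includes_boundary():
    poly = np.array([[2.0, 2.0], [2.0, 8.0], [8.0, 8.0], [8.0, 2.0], [2.0, 2.0]])
    mask = rasterize_closed_polygon(poly, (12, 12))
    assert mask[2, 2] and mask[8, 8] and mask[5, 5]
    assert mask.sum() == 49


# ---------------------------------------------------------------- pipeline


def test_segment_image_deterministic(default_phantom):
    a = segment_image(default_phantom.image)
    b = segment_image(default_phantom.image)
    np.testing.assert_array_equal(a.bone1, b.bone1)
    np.testing.assert_array_equal(a.masks[1], b.masks[1])


def test_segment_image_phantom_dsc(default_phantom):
    contours = segment_image(default_phantom.image)
    for b in (0, 1):
        d = dsc(confusion(default_phantom.bone_masks[b], contours.masks[b]))
        assert d >= 0.92
    # bone1 above bone2 in the standardized frame
    assert contours.components[0].points[0][0] < contours.components[5].points[0][0]


def test_segment_rotated_phantom_consistent():
    from urseg.phantom import PhantomParams, generate_phantom

    tA = generate_phantom(PhantomParams(seed=7, orientation="left-right"))
    tB = generate_phantom(PhantomParams(seed=7, orientation="down"))
    cA = segment_image(tA.image)
    cB = segment_image(tB.image)
    for b in (0, 1):
        mB = np.rot90(cB.masks[b], tB.rot_k)  # back to canonical frame
        assert dsc(confusion(cA.masks[b], mB)) >= 0.98


def test_contours_serialization(tmp_path, default_phantom):
    contours = segment_image(default_phantom.image)
    contours.save(tmp_path)
    assert (tmp_path / "contours.json").exists()
    assert (tmp_path / "contour_bone1.csv").exists()
    assert (tmp_path / "mask_bone2.png").exists()


def test_every_component_three_connected(default_phantom):
    contours = segment_image(default_phantom.image)
    for path in contours.components:
        steps = np.diff(path.points, axis=0)
        assert np.all(np.abs(steps[:, path.axis]) == 1)
        assert np.all(np.abs(steps[:, 1 - path.axis]) <= 1)
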