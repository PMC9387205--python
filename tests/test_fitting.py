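"""Objective arithmetic, multi-start fitting, color encoding and fit reuse."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from chromacloud import (
    AxisWeights,
    FitConfig,
    FitResult,
    OutOfGamutError,
    PointCloud3,
    TransformParams,
    apply_transform,
    convex_hull,
    encode,
    fit_cloud,
    objective,
)
from chromacloud.geometry import transform_coords
from conftest import pairwise

FAST = FitConfig(n_starts=5, seed=7)


@pytest.fixture(scope="module")
def small_fit(gamut):
    """One shared 5-start fit of a seeded 60-point Gaussian cloud."""
    rng = np.random.default_rng(99)
    cloud = PointCloud3([f"p{i}" for i in range(60)], rng.normal(0, 1, (60, 3)))
    return cloud, fit_cloud(cloud, config=FAST, gamut=gamut)


class TestObjective:
    def test_single_point_at_interior_scores_zero(self, gamut):
        hull = PointCloud3(["o"], np.zeros((1, 3)))
        p = TransformParams(translation=gamut.interior_point, scale=5.0)
        assert objective(p, hull, AxisWeights(), FitConfig(), gamut) == pytest.approx(0.0)

    def test_two_point_segment_equal_weights(self, gamut):
        """Segment of extent 20 along L*, fully inside: (20+0+0)/3."""
        hull = PointCloud3(["a", "b"], np.array([[-1.0, 0, 0], [1.0, 0, 0]]))
        p = TransformParams(translation=gamut.interior_point, scale=10.0)
        t = transform_coords(hull.coords, p)
        assert np.all(gamut.contains(t))
        got = objective(p, hull, AxisWeights(), FitConfig(), gamut)
        assert got == pytest.approx(20.0 / 3.0, abs=1e-9)

    def test_penalty_equals_mean_vertex_overshoot(self, gamut):
        """Tetrahedron with one vertex pushed outside: size − λ·over/4,
        with size and overshoot recomputed independently."""
        hull = PointCloud3(
            list("abcd"),
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float) - 0.25,
        )
        cfg = FitConfig(penalty_lambda=10.0)
        p = TransformParams(translation=[50.0, 80.0, 0.0], scale=60.0)
        t = transform_coords(hull.coords, p)
        outside = ~np.atleast_1d(gamut.contains(t))
        assert outside.sum() >= 1
        extents = t.max(axis=0) - t.min(axis=0)
        size = extents.sum() / 3.0
        over = sum(gamut.overshoot(ti) for ti in t)
        expected = size - 10.0 * over / 4.0
        got = objective(p, hull, AxisWeights(), cfg, gamut)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_axis_weights_reweight_extents(self, gamut):
        hull = PointCloud3(["a", "b"], np.array([[-1.0, 0, 0], [1.0, 0, 0]]))
        p = TransformParams(translation=gamut.interior_point, scale=10.0)
        w = AxisWeights(wL=2.0, wa=1.0, wb=1.0)
        got = objective(p, hull, w, FitConfig(), gamut)
        assert got == pytest.approx(2 * 20.0 / 4.0, abs=1e-9)


class TestFitCloud:
    def test_single_point_cloud_fits_with_zero_objective(self, gamut):
        res = fit_cloud(PointCloud3(["only"], np.array([[3.0, 4.0, 5.0]])), config=FAST, gamut=gamut)
        assert res.objective == pytest.approx(0.0, abs=1e-6)
        point = transform_coords(res.normalize_coords(np.array([[3.0, 4.0, 5.0]])), res.best)
        assert gamut.overshoot(point[0]) == pytest.approx(0.0, abs=1e-6)

    def test_fit_contains_hull_and_reaches_useful_scale(self, small_fit, gamut):
        cloud, res = small_fit
        hull = convex_hull(PointCloud3(cloud.names, res.normalize_coords(cloud.coords)))
        over = gamut.overshoot(apply_transform(hull, res.best).coords)
        assert np.max(over) <= 0.1
        assert res.best.scale >= 30.0

    def test_multistart_bookkeeping(self, small_fit, gamut):
        cloud, res = small_fit
        assert len(res.alternatives) == FAST.n_starts
        objs = [o for _, o in res.alternatives]
        assert objs == sorted(objs, reverse=True)
        assert res.objective >= max(objs) - 1e-12
        assert res.alternatives[0][1] == res.objective
        assert np.allclose(res.alternatives[0][0].to_vector(), res.best.to_vector())

    def test_reported_objective_is_recomputable(self, small_fit, gamut):
        cloud, res = small_fit
        hull = convex_hull(PointCloud3(cloud.names, res.normalize_coords(cloud.coords)))
        again = objective(res.best, hull, AxisWeights(), FitConfig(), gamut)
        assert again == pytest.approx(res.objective, rel=1e-9)

    def test_deterministic_for_fixed_seed(self, gamut):
        rng = np.random.default_rng(4)
        cloud = PointCloud3([f"p{i}" for i in range(30)], rng.normal(0, 1, (30, 3)))
        cfg = FitConfig(n_starts=3, seed=11)
        a = fit_cloud(cloud, config=cfg, gamut=gamut)
        b = fit_cloud(cloud, config=cfg, gamut=gamut)
        assert np.array_equal(a.best.to_vector(), b.best.to_vector())
        assert a.objective == b.objective

    def test_stronger_penalty_shrinks_the_cloud(self, gamut):
        """Raising λ never increases the best scale or the overshoot penalty.

        The optimizer is stochastic, so each λ's solution is chosen from the
        pooled candidates of all three fits: on a shared finite candidate
        set the exchange argument makes the penalty term exactly monotone
        in λ, and the scale ordering follows.
        """
        rng = np.random.default_rng(12)
        cloud = PointCloud3([f"p{i}" for i in range(30)], rng.normal(0, 1, (30, 3)))
        lambdas = (1.0, 10.0, 100.0)
        pool = []
        for lam in lambdas:
            res = fit_cloud(
                cloud, config=FitConfig(n_starts=4, seed=5, penalty_lambda=lam), gamut=gamut
            )
            pool.extend(p for p, _ in res.alternatives)
        norm = PointCloud3(cloud.names, res.normalize_coords(cloud.coords))
        hull = convex_hull(norm)

        def mean_overshoot(p):
            from chromacloud.geometry import transform_coords

            return float(np.mean(gamut.overshoot(transform_coords(hull.coords, p))))

        picks = []
        for lam in lambdas:
            cfg = FitConfig(penalty_lambda=lam)
            picks.append(max(pool, key=lambda p: objective(p, hull, AxisWeights(), cfg, gamut)))
        overs = [mean_overshoot(p) for p in picks]
        scales = [p.scale for p in picks]
        assert overs[0] >= overs[1] >= overs[2]
        assert scales[0] >= scales[1] >= scales[2]

    def test_input_scale_does_not_change_colors(self, gamut):
        rng = np.random.default_rng(21)
        coords = rng.normal(0, 1, (25, 3))
        names = [f"p{i}" for i in range(25)]
        cfg = FitConfig(n_starts=3, seed=9)
        hex_a = encode(PointCloud3(names, coords), fit_cloud(PointCloud3(names, coords), config=cfg, gamut=gamut), gamut=gamut).hex
        cloud10 = PointCloud3(names, 10.0 * coords)
        hex_b = encode(cloud10, fit_cloud(cloud10, config=cfg, gamut=gamut), gamut=gamut).hex
        for ha, hb in zip(hex_a, hex_b):
            da = np.array([int(ha[i : i + 2], 16) for i in (1, 3, 5)])
            db = np.array([int(hb[i : i + 2], 16) for i in (1, 3, 5)])
            assert np.abs(da - db).max() <= 1


class TestEncode:
    def test_outputs_are_valid_and_order_preserving(self, small_fit, gamut):
        cloud, res = small_fit
        table = encode(cloud, res, gamut=gamut)
        assert table.names == cloud.names
        assert all(len(h) == 7 and h[0] == "#" for h in table.hex)
        assert np.max(gamut.overshoot(table.lab)) <= 0.1 + 1e-6

    def test_identical_points_get_identical_colors(self, gamut):
        rng = np.random.default_rng(31)
        coords = rng.normal(0, 1, (20, 3))
        coords[7] = coords[3]
        cloud = PointCloud3([f"p{i}" for i in range(20)], coords)
        res = fit_cloud(cloud, config=FAST, gamut=gamut)
        table = encode(cloud, res, gamut=gamut)
        assert table.hex[7] == table.hex[3]
        assert np.allclose(table.lab[7], table.lab[3])

    def test_lab_distances_are_exact_multiple_of_input(self, small_fit, gamut):
        cloud, res = small_fit
        table = encode(cloud, res, gamut=gamut)
        din = pairwise(cloud.coords)
        dout = pairwise(table.lab)
        factor = res.best.scale / res.normalization[1]
        assert np.allclose(dout, factor * din, rtol=1e-9)
        assert pearsonr(din, dout).statistic == pytest.approx(1.0, abs=1e-9)

    def test_new_points_reuse_the_stored_transform(self, small_fit, gamut):
        cloud, res = small_fit
        new = PointCloud3(["n1", "n2"], cloud.coords[:2] + 0.01)
        table = encode(new, res, gamut=gamut)
        assert len(table) == 2

    def test_no_clamp_raises_with_offender_names(self, small_fit, gamut):
        cloud, res = small_fit
        # a far-away "new" point is guaranteed out of gamut
        far = PointCloud3(["way_out"], np.array([[500.0, 500.0, 500.0]]))
        with pytest.raises(OutOfGamutError, match="way_out"):
            encode(far, res, gamut=gamut, clamp=False)
        table = encode(far, res, gamut=gamut, clamp=True)
        assert table.n_clamped == 1

    def test_unknown_format_rejected(self, small_fit, gamut):
        cloud, res = small_fit
        with pytest.raises(ValueError):
            encode(cloud, res, gamut=gamut, format="rgb")


class TestFitResultJSON:
    def test_round_trip(self, small_fit, tmp_path):
        _, res = small_fit
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = FitResult.from_json(path)
        assert np.allclose(back.best.to_vector(), res.best.to_vector())
        assert back.objective == pytest.approx(res.objective)
        assert np.allclose(back.normalization[0], res.normalization[0])
        assert back.normalization[1] == pytest.approx(res.normalization[1])
        assert len(back.alternatives) == len(res.alternatives)

    def test_round_trip_from_string(self, small_fit):
        _, res = small_fit
        back = FitResult.from_json(res.to_json())
        assert np.allclose(back.best.to_vector(), res.best.to_vector())


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw", [{"n_starts": 0}, {"penalty_lambda": 0.0}, {"xatol": 0.0}, {"fatol": -1.0}]
    )
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            FitConfig(**kw)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            AxisWeights(wL=-1.0)
        with pytest.raises(ValueError):
            AxisWeights(wL=0.0, wa=0.0, wb=0.0)
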