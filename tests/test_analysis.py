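from itertools import combinations

import numpy as np
import pytest

from flimphasor import PhasorField, PhasorROI, omega_rad_per_ns
from flimphasor import analysis
from flimphasor.model import LifetimeMaps


def _field(g, s, photons=None, valid=None):
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    return PhasorField(
        g=g,
        s=s,
        photons=np.full(g.shape, 50.0) if photons is None else np.asarray(photons),
        valid=np.ones(g.shape, dtype=bool) if valid is None else valid,
        harmonic=1,
        omega=omega_rad_per_ns(80.0),
    )


def _ray_cast(point, verts):
    """Brute-force even-odd point-in-polygon (boundary not handled)."""
    x, y = point
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestSelectByPhasorROI:
    def test_polygon_covering_everything_equals_valid(self, rng):
        g = rng.uniform(0.05, 0.95, size=(5, 5))
        s = rng.uniform(0.05, 0.55, size=(5, 5))
        valid = rng.random((5, 5)) > 0.2
        f = _field(g, s, valid=valid)
        roi = PhasorROI(
            kind="polygon", params=[(0, 0), (1, 0), (1, 0.6), (0, 0.6)]
        )
        np.testing.assert_array_equal(analysis.select_by_phasor_roi(f, roi), valid)

    def test_ellipse_isolates_one_population(self, rng):
        p1, p2 = (0.3, 0.42), (0.7, 0.4)
        labels = rng.random((8, 8)) > 0.5
        jitter = rng.normal(0, 0.01, size=(2, 8, 8))
        g = np.where(labels, p1[0], p2[0]) + jitter[0]
        s = np.where(labels, p1[1], p2[1]) + jitter[1]
        f = _field(g, s)
        roi = PhasorROI(kind="ellipse", params=[p1[0], p1[1], 0.1, 0.1, 0.0])
        np.testing.assert_array_equal(analysis.select_by_phasor_roi(f, roi), labels)

    def test_polygon_agrees_with_ray_casting_oracle(self, rng):
        verts = [(0.2, 0.1), (0.8, 0.15), (0.7, 0.5), (0.4, 0.55), (0.15, 0.3)]
        g = rng.uniform(0, 1, size=(1000, 1))
        s = rng.uniform(0, 0.6, size=(1000, 1))
        f = _field(g, s)
        mask = analysis.select_by_phasor_roi(
            f, PhasorROI(kind="polygon", params=verts)
        )
        for i in range(1000):
            assert mask[i, 0] == _ray_cast((g[i, 0], s[i, 0]), verts)

    def test_boundary_vertex_is_inclusive(self):
        verts = [(0.2, 0.2), (0.6, 0.2), (0.4, 0.5)]
        f = _field([[0.2, 0.4]], [[0.2, 0.2]])  # a vertex and an edge point
        mask = analysis.select_by_phasor_roi(
            f, PhasorROI(kind="polygon", params=verts)
        )
        assert mask.all()

    def test_degenerate_roi_warns_and_selects_nothing(self):
        f = _field([[0.4]], [[0.3]])
        roi = PhasorROI(kind="polygon", params=[(0, 0), (0.5, 0.5), (1, 1)])
        with pytest.warns(UserWarning, match="zero area"):
            mask = analysis.select_by_phasor_roi(f, roi)
        assert not mask.any()

    def test_invalid_pixels_never_selected(self):
        valid = np.array([[True, False]])
        f = _field([[0.4, 0.4]], [[0.3, 0.3]], valid=valid)
        roi = PhasorROI(kind="ellipse", params=[0.4, 0.3, 0.2, 0.2, 0.0])
        mask = analysis.select_by_phasor_roi(f, roi)
        assert mask[0, 0] and not mask[0, 1]


class TestExcludePixels:
    def test_empty_exclusion_is_identity(self, rng):
        mask = rng.random((6, 6)) > 0.5
        out = analysis.exclude_pixels(mask, np.zeros((6, 6), dtype=bool))
        np.testing.assert_array_equal(out, mask)

    def test_excluding_everything_selected_empties_mask(self, rng):
        mask = rng.random((6, 6)) > 0.5
        assert not analysis.exclude_pixels(mask, mask).any()

    def test_truth_table_on_random_masks(self, rng):
        a = rng.random((10, 10)) > 0.5
        b = rng.random((10, 10)) > 0.5
        out = analysis.exclude_pixels(a, b)
        for i in range(10):
            for j in range(10):
                assert out[i, j] == (a[i, j] and not b[i, j])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            analysis.exclude_pixels(
                np.ones((2, 2), dtype=bool), np.ones((3, 3), dtype=bool)
            )


def _uniform_maps(value, shape=(4, 4)):
    tau = np.full(shape, float(value))
    return LifetimeMaps(
        tau_phase=tau.copy(), tau_mod=tau.copy(), tau_avg=tau.copy(),
        valid=np.ones(shape, dtype=bool),
    )


class TestSummarize:
    def test_uniform_map(self):
        maps = _uniform_maps(2.5)
        f = _field(np.full((4, 4), 0.4), np.full((4, 4), 0.3))
        rec = analysis.summarize(maps, f, None, "s1", "ctrl")
        assert rec.mean_tau_phase == pytest.approx(2.5)
        assert rec.mean_tau_mod == pytest.approx(2.5)
        assert rec.mean_tau_avg == pytest.approx(2.5)
        assert rec.n_pixels == 16

    def test_two_halves_pixel_weighted_mean(self):
        """2 ns and 4 ns halves with equal pixel counts -> 3.0 even when the
        photon counts differ (pixel weighting, not photon weighting)."""
        tau = np.block([
            [np.full((2, 4), 2.0)], [np.full((2, 4), 4.0)]
        ])
        maps = LifetimeMaps(
            tau_phase=tau, tau_mod=tau, tau_avg=tau,
            valid=np.ones((4, 4), dtype=bool),
        )
        photons = np.block([
            [np.full((2, 4), 10.0)], [np.full((2, 4), 1000.0)]
        ])
        f = _field(np.full((4, 4), 0.4), np.full((4, 4), 0.3), photons=photons)
        rec = analysis.summarize(maps, f, None, "s1", "ctrl")
        assert rec.mean_tau_mod == pytest.approx(3.0)

    def test_random_map_against_brute_force(self, rng):
        vals = rng.uniform(1, 5, size=(5, 5))
        valid = rng.random((5, 5)) > 0.3
        maps = LifetimeMaps(
            tau_phase=vals, tau_mod=vals * 1.1, tau_avg=vals * 1.05, valid=valid
        )
        mask = rng.random((5, 5)) > 0.4
        f = _field(np.full((5, 5), 0.4), np.full((5, 5), 0.3), valid=valid)
        rec = analysis.summarize(maps, f, mask, "s", "c")
        sel = mask & valid
        if sel.any():
            assert rec.mean_tau_phase == pytest.approx(vals[sel].mean())
        else:
            assert rec.mean_tau_phase is None

    def test_empty_selection(self):
        maps = _uniform_maps(2.0)
        f = _field(np.full((4, 4), 0.4), np.full((4, 4), 0.3))
        rec = analysis.summarize(
            maps, f, np.zeros((4, 4), dtype=bool), "s1", "ctrl"
        )
        assert rec.n_pixels == 0
        assert rec.mean_tau_phase is None
        assert rec.n_photons == 0


class TestPoolCondition:
    def test_single_image_pool_is_its_points(self, rng):
        f = _field(rng.uniform(0, 1, (4, 4)), rng.uniform(0, 0.6, (4, 4)))
        mask = rng.random((4, 4)) > 0.5
        pool = analysis.pool_condition([f], [mask], "ctrl", ["s1"])
        np.testing.assert_allclose(
            np.column_stack([pool["g"], pool["s"]]), f.masked_points(mask)
        )

    def test_pool_size_is_sum_of_masked_counts(self, rng):
        f1 = _field(rng.uniform(0, 1, (4, 4)), rng.uniform(0, 0.6, (4, 4)))
        f2 = _field(rng.uniform(0, 1, (3, 3)), rng.uniform(0, 0.6, (3, 3)))
        m1 = rng.random((4, 4)) > 0.5
        m2 = rng.random((3, 3)) > 0.5
        pool = analysis.pool_condition([f1, f2], [m1, m2], "ctrl")
        assert len(pool) == m1.sum() + m2.sum()

    def test_pooled_mean_is_size_weighted_mean_of_image_means(self, rng):
        f1 = _field(rng.uniform(0, 1, (4, 4)), rng.uniform(0, 0.6, (4, 4)))
        f2 = _field(rng.uniform(0, 1, (5, 5)), rng.uniform(0, 0.6, (5, 5)))
        pool = analysis.pool_condition([f1, f2], [None, None], "c")
        n1, n2 = f1.g.size, f2.g.size
        expected = (f1.g.mean() * n1 + f2.g.mean() * n2) / (n1 + n2)
        assert pool["g"].mean() == pytest.approx(expected, rel=1e-12)

    def test_omega_mismatch_rejected(self):
        f1 = _field([[0.4]], [[0.3]])
        f2 = PhasorField(
            g=np.array([[0.4]]), s=np.array([[0.3]]),
            photons=np.array([[10.0]]), valid=np.ones((1, 1), dtype=bool),
            harmonic=2, omega=f1.omega * 2,
        )
        with pytest.raises(ValueError, match="omega"):
            analysis.pool_condition([f1, f2], [None, None], "c")

    def test_reselection_with_same_roi_is_idempotent(self, rng):
        f = _field(rng.uniform(0, 1, (6, 6)), rng.uniform(0, 0.6, (6, 6)))
        roi = PhasorROI(kind="ellipse", params=[0.5, 0.3, 0.25, 0.2, 0.1])
        m1 = analysis.select_by_phasor_roi(f, roi)
        m2 = analysis.select_by_phasor_roi(f, roi) & m1
        np.testing.assert_array_equal(m1, m2)


def _enumerate_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of group splits."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)
    mu = n * len(b) / 2

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = u_stat(a, b)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        u, p = analysis.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_triples(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 2/20 = 0.1."""
        u, p = analysis.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 4), (5, 6), (6, 6)])
    def test_agrees_with_enumeration_oracle(self, na, nb, rng):
        a = rng.normal(0, 1, na).tolist()
        b = rng.normal(0.8, 1, nb).tolist()
        _, p = analysis.mann_whitney(a, b)
        assert p == pytest.approx(_enumerate_exact_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            analysis.mann_whitney([], [1.0])


class TestMaskingOrderIndependence:
    def test_threshold_then_manual_equals_manual_then_threshold(self, rng):
        from flimphasor import DecayCube, apply_photon_threshold

        counts = rng.integers(0, 100, size=(6, 6, 16)).astype(np.uint32)
        cube = DecayCube(counts=counts, bin_width=0.05, rep_frequency=80.0)
        manual = rng.random((6, 6)) > 0.5
        t = apply_photon_threshold(cube, 200, 900)
        np.testing.assert_array_equal(t & manual, manual & t)


class TestLoadRois:
    def test_round_trip_json(self, tmp_path):
        import json

        spec = [
            {"kind": "polygon", "label": "blob",
             "vertices": [[0.1, 0.1], [0.5, 0.1], [0.3, 0.4]]},
            {"kind": "ellipse", "label": "low-tau",
             "center": [0.7, 0.35], "semi_axes": [0.05, 0.04], "angle": 0.2},
        ]
        p = tmp_path / "rois.json"
        p.write_text(json.dumps(spec))
        rois = analysis.load_rois(p)
        assert [r.kind for r in rois] == ["polygon", "ellipse"]
        assert rois[0].label == "blob"
        assert rois[1].params[0] == pytest.approx(0.7)
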