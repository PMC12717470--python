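"""CCO growth: domain sizing, threshold, sampling, candidate search,
bifurcation optimization, overlap rejection, and the growth loop."""

import numpy as np
import pytest
from scipy import stats

import vasctree as vt
from vasctree import generator, geometry


class TestMakeDomain:
    def test_unit_sphere(self):
        dom = vt.make_domain((1, 1, 1), 4.0 / 3.0 * np.pi)
        assert np.allclose(dom.semi_axes, 1.0)
        assert dom.volume == pytest.approx(4.0 / 3.0 * np.pi)

    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ((6, 5, 1), (9.765, 8.138, 1.628)),
            ((20, 5, 3), (15.109, 3.777, 2.266)),
        ],
    )
    def test_control_tissue_semi_axes(self, ratios, expected):
        # 301 terminals x 1.8 mm^3 per terminal = 541.8 mm^3 total
        dom = vt.make_domain(ratios, 301 * 1.8)
        assert np.allclose(dom.semi_axes, expected, atol=5e-4)
        assert dom.volume == pytest.approx(541.8)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            vt.make_domain((1, 0, 1), 1.0)
        with pytest.raises(ValueError):
            vt.make_domain((1, 1, 1), -1.0)


class TestDistanceThreshold:
    def test_closed_form_value(self):
        dom = vt.make_domain((6, 5, 1), 541.8)
        assert vt.distance_threshold(dom, 301) == pytest.approx(0.51666, abs=1e-4)

    def test_unit_convention(self):
        # sphere of radius 1: threshold = sqrt(pi r^2 / n) = 1 at n = pi
        dom = vt.make_domain((1, 1, 1), 4.0 / 3.0 * np.pi)
        assert vt.distance_threshold(dom, 1) == pytest.approx(np.sqrt(np.pi))

    def test_scaling_law(self):
        dom = vt.make_domain((2, 3, 4), 100.0)
        assert vt.distance_threshold(dom, 200) == pytest.approx(
            vt.distance_threshold(dom, 100) / np.sqrt(2)
        )


class TestInitRoot:
    def test_tip_anchor_and_interior_target(self):
        cfg = vt.GenerationConfig(n_bif=5, seed=7, inlet="tip-x")
        state = vt.init_root(cfg)
        a = state.domain.semi_axes
        assert np.allclose(state.prox[0], [a[0], 0, 0])
        assert geometry.in_ellipsoid(state.dist[0], a)[0]
        assert np.sum((state.dist[0] / np.array(a)) ** 2) < 1.0

    def test_deterministic_per_seed(self):
        roots = [vt.init_root(vt.GenerationConfig(n_bif=1, seed=3)).dist[0] for _ in range(2)]
        assert np.array_equal(roots[0], roots[1])
        other = vt.init_root(vt.GenerationConfig(n_bif=1, seed=4)).dist[0]
        assert not np.array_equal(roots[0], other)

    def test_side_anchor(self):
        cfg = vt.GenerationConfig(n_bif=1, seed=0, inlet="side-y")
        state = vt.init_root(cfg)
        a = state.domain.semi_axes
        assert np.allclose(state.prox[0], [0, a[1], 0])


class TestSamplePerfusionPoint:
    def test_point_inside_ellipsoid_and_clear_of_vessels(self):
        cfg = vt.GenerationConfig(n_bif=1, seed=11)
        state = vt.init_root(cfg)
        state.d_thresh = 0.05
        p = vt.sample_perfusion_point(state)
        assert geometry.in_ellipsoid(p, state.domain.semi_axes)[0]
        d = geometry.point_segment_distance(p, state.prox[:1], state.dist[:1])[0]
        assert d >= state.d_thresh

    def test_uniform_in_ball_marginal(self, rng):
        # with no distance constraint, radii^3 must be U(0,1) in a sphere
        pts = geometry.sample_in_ellipsoid(rng, (2.0, 2.0, 2.0), n=10_000)
        u = (np.linalg.norm(pts, axis=1) / 2.0) ** 3
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_relaxation_terminates_with_huge_threshold(self):
        cfg = vt.GenerationConfig(n_bif=1, seed=5)
        state = vt.init_root(cfg)
        state.d_thresh = 1e6  # unsatisfiable until relaxed
        p = vt.sample_perfusion_point(state)
        assert geometry.in_ellipsoid(p, state.domain.semi_axes)[0]
        assert state.d_thresh < 1e6  # relaxation actually triggered


class TestCandidateVessels:
    def test_single_segment(self):
        state = vt.init_root(vt.GenerationConfig(n_bif=1, seed=1))
        assert vt.candidate_vessels(state, [0.0, 0.0, 0.0], 12).tolist() == [0]

    def test_matches_brute_force(self, rng):
        cfg = vt.GenerationConfig(n_bif=25, seed=9)
        state = vt.init_root(cfg)
        for _ in range(25):
            vt.grow_step(state)
        point = geometry.sample_in_ellipsoid(rng, state.domain.semi_axes)
        got = vt.candidate_vessels(state, point, 12)
        dist = geometry.point_segment_distance(
            point, state.prox[: state.n], state.dist[: state.n]
        )
        brute = np.lexsort((np.arange(state.n), dist))[:12]
        assert got.tolist() == brute.tolist()


class TestOptimizeBifurcation:
    def _toy_state(self):
        cfg = vt.GenerationConfig(n_bif=3, seed=2)
        state = vt.init_root(cfg)
        vt.grow_step(state)
        return state

    def test_argmin_contract(self):
        state = self._toy_state()
        point = np.array([0.1, 0.1, 0.1])
        cand = vt.optimize_bifurcation(state, 0, point, check_overlap=False)
        ctx = generator._StepContext(state, state.n_term + 1)
        vols, _, _ = generator._score_target(ctx, 0, point)
        assert cand.valid
        assert cand.volume_mm3 <= np.min(vols[np.isfinite(vols)]) + 1e-15

    def test_symmetric_point_gives_midplane_node(self):
        # single straight segment along x; point mirror-symmetric about its
        # perpendicular bisector plane -> optimum on the symmetry plane
        cfg = vt.GenerationConfig(n_bif=1, seed=0, triangle_points=66)
        state = vt.init_root(cfg)
        state.prox[0] = np.array([-1.0, 0.0, 0.0])
        state.dist[0] = np.array([1.0, 0.0, 0.0])
        state.length[0] = 2.0
        point = np.array([0.0, 0.8, 0.0])
        cand = vt.optimize_bifurcation(state, 0, point, check_overlap=False)
        assert cand.valid
        assert abs(cand.bifurcation_point[0]) <= 2.0 / 10 + 1e-9  # within grid resolution

    def test_close_to_fine_grid_minimum(self):
        cfg = vt.GenerationConfig(n_bif=1, seed=0)
        state = vt.init_root(cfg)
        state.prox[0] = np.array([-1.0, 0.0, 0.0])
        state.dist[0] = np.array([1.0, 0.0, 0.0])
        state.length[0] = 2.0
        point = np.array([0.4, 0.9, 0.2])
        coarse = vt.optimize_bifurcation(state, 0, point, check_overlap=False)
        fine_cfg = vt.GenerationConfig(n_bif=1, seed=0, triangle_points=101 * 102 // 2)
        fine_state = vt.init_root(fine_cfg)
        fine_state.prox[0] = state.prox[0]
        fine_state.dist[0] = state.dist[0]
        fine_state.length[0] = 2.0
        fine = vt.optimize_bifurcation(fine_state, 0, point, check_overlap=False)
        assert coarse.volume_mm3 >= fine.volume_mm3 - 1e-15
        assert coarse.volume_mm3 <= fine.volume_mm3 * 1.02  # grid-resolution tolerance

    def test_degenerate_collinear_point_does_not_crash(self):
        state = vt.init_root(vt.GenerationConfig(n_bif=1, seed=0))
        state.prox[0] = np.array([-1.0, 0.0, 0.0])
        state.dist[0] = np.array([1.0, 0.0, 0.0])
        state.length[0] = 2.0
        cand = vt.optimize_bifurcation(state, 0, np.array([2.5, 0.0, 0.0]), check_overlap=False)
        assert cand.valid
        assert np.isfinite(cand.volume_mm3)


class TestDetectOverlap:
    def _net(self, rows, diameters):
        prox = np.array([r[0] for r in rows], dtype=float)
        dist = np.array([r[1] for r in rows], dtype=float)
        parent = np.array([r[2] for r in rows])
        net = vt.Network(prox, dist, parent, diameter_um=np.array(diameters, dtype=float))
        return net

    def test_far_apart_no_overlap(self):
        net = self._net([((0, 0, 0), (1, 0, 0), -1)], [100.0])
        assert not vt.detect_overlap(net, [((5, 0, 0), (6, 0, 0), 100.0)])

    def test_crossing_segments_overlap(self):
        net = self._net([((0, 0, 0), (1, 0, 0), -1)], [100.0])
        assert vt.detect_overlap(net, [((0.5, -0.5, 0), (0.5, 0.5, 0), 100.0)])

    def test_adjacent_segments_ignored(self):
        net = self._net([((0, 0, 0), (1, 0, 0), -1)], [100.0])
        # shares the distal node: adjacent, not an overlap
        assert not vt.detect_overlap(net, [((1, 0, 0), (2, 0, 0), 100.0)])

    def test_agrees_with_sampled_distance_oracle(self, rng):
        for _ in range(100):
            a0, a1 = rng.normal(size=(2, 3))
            b0, b1 = rng.normal(size=(2, 3))
            d = geometry.segment_segments_distance(a0, a1, b0[None], b1[None])[0]
            t = np.linspace(0, 1, 201)
            pa = a0 + t[:, None] * (a1 - a0)
            pb = b0 + t[:, None] * (b1 - b0)
            brute = np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2))
            assert d <= brute + 1e-12
            assert d >= brute - 2e-2  # dense-sampling resolution


class TestGrowth:
    def test_single_step_structure(self):
        state = vt.init_root(vt.GenerationConfig(n_bif=1, seed=13))
        vt.grow_step(state)
        assert state.n == 3
        assert state.n_term == 2
        assert state.nterm[0] == 2

    def test_domain_volume_bookkeeping(self):
        cfg = vt.GenerationConfig(n_bif=10, seed=21)
        state = vt.init_root(cfg)
        assert state.domain.volume == pytest.approx(cfg.v_perf)
        for t in range(1, 11):
            vt.grow_step(state)
            assert state.domain.volume == pytest.approx((t + 1) * cfg.v_perf)

    def test_deterministic_replay(self):
        nets = [vt.generate(vt.GenerationConfig(n_bif=20, seed=77)) for _ in range(2)]
        assert np.array_equal(nets[0].proximal, nets[1].proximal)
        assert np.array_equal(nets[0].distal, nets[1].distal)
        assert np.array_equal(nets[0].diameter_um, nets[1].diameter_um)

    def test_generate_small_network(self):
        cfg = vt.GenerationConfig(n_bif=5, seed=3)
        net = vt.generate(cfg)
        assert net.n_segments == 11
        assert net.n_terminals == 6
        assert net.semi_axes is not None
        dom = vt.make_domain(cfg.ratios, 6 * cfg.v_perf)
        assert np.allclose(net.semi_axes, dom.semi_axes)

    def test_different_seeds_differ(self):
        a = vt.generate(vt.GenerationConfig(n_bif=10, seed=1))
        b = vt.generate(vt.GenerationConfig(n_bif=10, seed=2))
        assert not np.array_equal(a.distal, b.distal)

    def test_no_overlaps_in_generated_network(self):
        net = vt.generate(vt.GenerationConfig(n_bif=40, seed=8))
        r = net.diameter_um * 0.5e-3
        for i in range(net.n_segments):
            dist = geometry.segment_segments_distance(
                net.proximal[i], net.distal[i], net.proximal, net.distal
            )
            adjacent = np.zeros(net.n_segments, dtype=bool)
            adjacent[i] = True
            for j in range(net.n_segments):
                shared = any(
                    np.allclose(ea, eb, atol=1e-12)
                    for ea in (net.proximal[i], net.distal[i])
                    for eb in (net.proximal[j], net.distal[j])
                )
                if shared:
                    adjacent[j] = True
            clearance = dist - (r + r[i])
            assert np.all(clearance[~adjacent] >= -1e-9)
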