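"""Flows, pressures, diameter convergence, rheology laws, hematocrit
propagation and perfusion heterogeneity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vasctree as vt
from vasctree.units import POISEUILLE_MMHG
from conftest import random_tree


def _three_terminal_tree():
    prox = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 1, 0], [2, 1, 0]], dtype=float)
    dist = np.array([[1, 0, 0], [2, 1, 0], [2, -1, 0], [3, 2, 0], [3, 1, 0]], dtype=float)
    parent = np.array([-1, 0, 0, 1, 1])
    return vt.Network(prox, dist, parent)


class TestTopologicalFlows:
    def test_three_terminal_root_flow(self):
        net = _three_terminal_tree()
        q = vt.assign_topological_flows(net, 0.12)
        assert q[0] == pytest.approx(0.36)
        assert q[2] == pytest.approx(0.12)

    def test_conservation_on_random_tree(self, rng):
        net = random_tree(rng, 19, with_hemo=False)
        q = vt.assign_topological_flows(net, 0.12)
        assert q[net.root] == pytest.approx(20 * 0.12)
        ch = net.children
        for i in range(net.n_segments):
            if ch[i, 0] >= 0:
                assert q[i] == pytest.approx(q[ch[i, 0]] + q[ch[i, 1]], rel=1e-12)


class TestPoiseuilleSolve:
    def test_single_tube_closed_form(self):
        net = vt.Network(
            np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]), np.array([-1])
        )
        net.diameter_um = np.array([10.0])
        mu = 3.0 * 1.2
        flows, p_in, p_out = vt.poiseuille_solve(net, 30.0, np.array([mu]))
        expected = 30.0 / (128 * mu * 1.0 / (np.pi * 10.0**4) * POISEUILLE_MMHG)
        assert flows[0] == pytest.approx(expected, rel=1e-12)
        assert p_in[0] - p_out[0] == pytest.approx(30.0)

    def test_symmetric_tree_equal_sibling_flows(self):
        net = _three_terminal_tree()
        # make daughters 3,4 geometrically identical in resistance
        net._lengths = None
        net.distal[3] = net.proximal[3] + [1, 1, 0]
        net.distal[4] = net.proximal[4] + [1, -1, 0]
        net.diameter_um = np.array([40.0, 25.0, 25.0, 12.0, 12.0])
        flows, _, _ = vt.poiseuille_solve(net, 30.0, np.full(5, 3.6))
        assert flows[3] == pytest.approx(flows[4], rel=1e-10)

    def test_two_terminal_tree_matches_hand_solution(self):
        prox = np.array([[0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]])
        dist = np.array([[1.0, 0, 0], [3.0, 0, 0], [1.5, 1, 0]])
        parent = np.array([-1, 0, 0])
        net = vt.Network(prox, dist, parent)
        net.diameter_um = np.array([20.0, 12.0, 9.0])
        mu = np.array([3.6, 3.6, 3.6])
        R = 128 * mu * net.lengths / (np.pi * net.diameter_um**4) * POISEUILLE_MMHG
        # independent 2-resistor solution: parallel daughters in series with root
        g = 1 / R[1] + 1 / R[2]
        q0 = 30.0 / (R[0] + 1 / g)
        flows, p_in, p_out = vt.poiseuille_solve(net, 30.0, mu)
        assert flows[0] == pytest.approx(q0, rel=1e-10)
        assert flows[1] == pytest.approx(q0 * (1 / R[1]) / g, rel=1e-10)
        assert flows[2] == pytest.approx(q0 * (1 / R[2]) / g, rel=1e-10)
        assert p_out[1] == pytest.approx(0.0, abs=1e-10)
        assert p_out[2] == pytest.approx(0.0, abs=1e-10)

    def test_zero_diameter_rejected(self):
        net = _three_terminal_tree()
        net.diameter_um = np.array([40.0, 0.0, 25.0, 12.0, 12.0])
        with pytest.raises(ValueError):
            vt.poiseuille_solve(net, 30.0, np.full(5, 3.6))


class TestConvergeDiameters:
    def test_single_tube_closed_form(self):
        net = vt.Network(
            np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]), np.array([-1])
        )
        hc = vt.HemodynamicConfig()
        info = vt.converge_diameters(net, hc)
        # diameter such that Q = q_perf at dP = dp_tot over 1 mm at mu_rel 3
        mu = hc.mu_rel_generation * hc.plasma_viscosity
        d = (128 * mu * 1.0 * hc.q_perf * POISEUILLE_MMHG / (np.pi * hc.dp_tot)) ** 0.25
        assert net.diameter_um[0] == pytest.approx(d, rel=1e-12)
        assert info["max_terminal_flow_error"] == 0.0
        assert info["sweeps"] <= 2

    def test_symmetric_bifurcation_murray_ratio(self):
        net = _three_terminal_tree()
        net.proximal[3:] = net.distal[1]
        net.distal[3] = net.distal[1] + [1, 1, 0]
        net.distal[4] = net.distal[1] + [1, -1, 0]
        net._lengths = None
        hc = vt.HemodynamicConfig(murray_gamma=2.63)
        vt.converge_diameters(net, hc)
        assert net.diameter_um[3] == pytest.approx(net.diameter_um[4])
        assert net.diameter_um[1] / net.diameter_um[3] == pytest.approx(
            2 ** (1 / 2.63), rel=1e-12
        )

    def test_terminal_flow_tolerance_on_generated(self, net200):
        hc = vt.HemodynamicConfig()
        term = net200.is_terminal
        err = np.max(np.abs(net200.flow_nl_s[term] - hc.q_perf) / hc.q_perf)
        assert err <= 0.01

    def test_murray_law_exact_across_segments(self, net200):
        # log Q vs log d is exactly linear with slope gamma
        slope, r2 = vt.murray_exponent_fit(net200.diameter_um, net200.flow_nl_s)
        assert slope == pytest.approx(2.63, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_parent_diameter_not_smaller_than_daughters(self, net200):
        ch = net200.children
        d = net200.diameter_um
        for i in range(net200.n_segments):
            for c in ch[i]:
                if c >= 0:
                    assert d[c] <= d[i] + 1e-12

    def test_pressure_monotone_and_mean_terminal_drop(self, net200):
        assert np.all(net200.p_in - net200.p_out > -1e-12)
        term = net200.is_terminal
        drop = net200.p_in[net200.root] - net200.p_out[term]
        assert np.mean(drop) == pytest.approx(30.0, rel=1e-9)


class TestViscosityLaw:
    def test_constant_mode(self):
        assert float(vt.relative_viscosity(10.0, 0.4, mode="constant")) == 3.0
        assert float(vt.relative_viscosity(500.0, 0.0, mode="constant")) == 3.0

    def test_plasma_limit(self):
        assert float(vt.relative_viscosity(10.0, 0.0)) == pytest.approx(1.0)
        assert float(vt.relative_viscosity(1000.0, 0.0)) == pytest.approx(1.0)

    def test_frozen_reference_value(self):
        # independent transcription of the in-vitro law at d=10 um, H_D=0.4
        assert float(vt.relative_viscosity(10.0, 0.4)) == pytest.approx(
            1.2666817091481672, rel=1e-12
        )

    def test_increases_with_hematocrit(self):
        d = 30.0
        values = [float(vt.relative_viscosity(d, h)) for h in (0.1, 0.3, 0.5)]
        assert values == sorted(values)


class TestPhaseSeparation:
    def test_symmetric_split_preserves_hematocrit(self):
        h1, h2 = vt.phase_separation((40.0, 0.4, 1.0), ((25.0, 0.5), (25.0, 0.5)))
        assert h1 == pytest.approx(0.4)
        assert h2 == pytest.approx(0.4)

    def test_below_cutoff_daughter_gets_plasma(self):
        # parent 100 um: cutoff X0 = 0.4/100 = 0.004 fractional flow
        q_small = 0.003
        h1, h2 = vt.phase_separation(
            (100.0, 0.4, 1.0), ((10.0, q_small), (95.0, 1.0 - q_small))
        )
        assert h1 == 0.0
        assert h2 == pytest.approx(0.4 / (1.0 - q_small))

    def test_rbc_flux_conservation_random(self, rng):
        for _ in range(100):
            dp = rng.uniform(15, 120)
            d1, d2 = rng.uniform(0.3, 0.95, size=2) * dp
            f = rng.uniform(0.02, 0.98)
            qp = rng.uniform(0.5, 5.0)
            hp = rng.uniform(0.2, 0.55)
            h1, h2 = vt.phase_separation((dp, hp, qp), ((d1, f * qp), (d2, (1 - f) * qp)))
            flux = h1 * f * qp + h2 * (1 - f) * qp
            assert flux == pytest.approx(qp * hp, rel=1e-10)
            assert 0.0 <= h1 <= 1.0 and 0.0 <= h2 <= 1.0

    def test_invalid_fractional_flow(self):
        with pytest.raises(ValueError):
            vt.phase_separation((40.0, 0.4, 1.0), ((25.0, 1.0), (25.0, 0.0)))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    dp=st.floats(12.0, 150.0),
    f=st.floats(0.02, 0.98),
    hp=st.floats(0.1, 0.6),
    r1=st.floats(0.2, 0.95),
    r2=st.floats(0.2, 0.95),
)
def test_phase_separation_conserves_rbc_flux_property(dp, f, hp, r1, r2):
    """RBC flux is conserved and daughter hematocrits stay in [0, 1] for
    any admissible bifurcation geometry and split."""
    qp = 1.0
    h1, h2 = vt.phase_separation((dp, hp, qp), ((r1 * dp, f), (r2 * dp, 1.0 - f)))
    assert 0.0 <= h1 <= 1.0 and 0.0 <= h2 <= 1.0
    assert h1 * f + h2 * (1.0 - f) == pytest.approx(hp, rel=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(hd=st.floats(0.0, 0.7), d=st.floats(3.0, 500.0))
def test_fahraeus_effect_property(hd, d):
    """Tube hematocrit never exceeds discharge hematocrit in the
    microvascular diameter range, and vanishes with it."""
    ht = float(vt.tube_hematocrit(hd, d))
    assert 0.0 <= ht <= hd + 1e-12


class TestTubeHematocrit:
    def test_zero_in_zero_out(self):
        assert float(vt.tube_hematocrit(0.0, 10.0)) == 0.0

    def test_macrovessel_limit(self):
        assert float(vt.tube_hematocrit(0.4, 1.0e4)) / 0.4 == pytest.approx(1.0, abs=1e-6)

    def test_frozen_reference_value(self):
        assert float(vt.tube_hematocrit(0.4, 10.0)) == pytest.approx(
            0.2774317664431206, rel=1e-12
        )

    def test_fahraeus_inequality(self):
        for d in (5.0, 10.0, 50.0, 200.0):
            assert float(vt.tube_hematocrit(0.4, d)) <= 0.4


class TestPropagateHematocrit:
    def test_symmetric_tree_uniform(self):
        # perfect depth-2 tree with mirrored geometry: every bifurcation is
        # an even split between identical daughters
        prox = np.array(
            [[0, 0, 0], [0, 0, 1], [0, 0, 1], [1, 0, 2], [1, 0, 2], [-1, 0, 2], [-1, 0, 2]],
            dtype=float,
        )
        dist = np.array(
            [[0, 0, 1], [1, 0, 2], [-1, 0, 2], [2, 1, 3], [2, -1, 3], [-2, 1, 3], [-2, -1, 3]],
            dtype=float,
        )
        parent = np.array([-1, 0, 0, 1, 1, 2, 2])
        net = vt.Network(prox, dist, parent)
        vt.converge_diameters(net, vt.HemodynamicConfig())
        hd, ht = vt.propagate_hematocrit(net, 0.4)
        assert np.allclose(hd, 0.4)
        assert np.all(ht <= hd)

    def test_rbc_flux_conserved_end_to_end(self, net200):
        term = net200.is_terminal
        influx = net200.flow_nl_s[net200.root] * 0.4
        outflux = np.sum(net200.flow_nl_s[term] * net200.hd[term])
        assert outflux == pytest.approx(influx, rel=1e-8)

    def test_terminal_hd_band(self, net200):
        # bulk of terminal discharge hematocrit near the inlet value
        hd = net200.hd[net200.is_terminal]
        assert 0.25 <= np.median(hd) <= 0.55


class TestPerfusionHeterogeneity:
    def test_three_to_one_split(self):
        net = _three_terminal_tree()
        net.flow_nl_s = np.array([0.48, 0.36, 0.12, 0.24, 0.12])
        g = vt.perfusion_heterogeneity(net)
        root_rows = g[g.parent_id == 0]
        assert sorted(root_rows.fraction.round(12).tolist()) == [0.25, 0.75]

    def test_mean_exactly_half(self, net200):
        g = vt.perfusion_heterogeneity(net200)
        assert g["fraction"].mean() == pytest.approx(0.5, abs=1e-12)
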