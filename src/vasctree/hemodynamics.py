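"""Flow, pressure, diameter, viscosity and hematocrit computation.

Construction-time hemodynamics
------------------------------
During network growth the tree is solved under three constraints that
together determine every diameter in closed form:

1. every terminal arteriole carries the same flow ``q_perf`` (so segment
   flow is the downstream terminal count times ``q_perf``, and Kirchhoff
   conservation holds exactly at every bifurcation);
2. Murray's law ``Q = q_perf * (d / d_ref)**gamma`` holds across all
   segments, which fixes relative diameters ``d_i = d_ref * N_i**(1/gamma)``
   where ``N_i`` is the downstream terminal count;
3. the mean inlet-to-terminal Poiseuille pressure drop equals ``dp_tot``,
   which fixes the terminal reference diameter ``d_ref`` (at constant
   relative viscosity the drop scales as ``d_ref**-4``, giving a one-line
   solution; with the empirical viscosity law a damped fixed point is
   used).

Note that these constraints cannot coexist with an *identical* outlet
pressure at every terminal: on an asymmetric tree, equal terminal pressures
plus Murray diameters force terminal flows to spread far beyond 1%.  The
mean-pressure-drop anchoring keeps terminal flows exactly at ``q_perf``
while matching the prescribed overall gradient.  A conventional Poiseuille
solver with Dirichlet pressure boundaries is provided separately for
analysis and cross-checks.

Post-hoc rheology
-----------------
After construction, hematocrit is propagated from the inlet (discharge
hematocrit 0.4) through every bifurcation with the empirical logit
phase-separation law, tube hematocrit follows the Fahraeus relation, and
per-vessel relative viscosity is evaluated with the in-vitro
diameter/hematocrit law.  Hematocrit does not feed back into the flow
solution (one-way coupling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import Network, as_network_and_mask
from .units import POISEUILLE_MMHG, poiseuille_resistance

__all__ = [
    "HemodynamicConfig",
    "BifurcationSplit",
    "assign_topological_flows",
    "poiseuille_solve",
    "converge_diameters",
    "relative_viscosity",
    "phase_separation",
    "tube_hematocrit",
    "propagate_hematocrit",
    "perfusion_heterogeneity",
]


@dataclass
class HemodynamicConfig:
    """Parameters of the hemodynamic solution.

    ``mu_rel_generation`` is the constant relative viscosity used while
    sizing vessels (the classical value 3); ``plasma_viscosity`` converts
    relative to absolute viscosity in mPa*s.  ``viscosity_mode`` selects the
    viscosity used when converging diameters: ``"constant"`` (default) or
    ``"empirical"`` (the in-vitro diameter/hematocrit law).
    """

    murray_gamma: float = 2.63
    q_perf: float = 0.12
    dp_tot: float = 30.0
    inlet_hd: float = 0.4
    mu_rel_generation: float = 3.0
    plasma_viscosity: float = 1.2
    terminal_tolerance: float = 0.01
    viscosity_mode: str = "constant"

    def __post_init__(self) -> None:
        if not (0.0 < self.inlet_hd < 1.0):
            raise ValueError("inlet_hd must lie in (0, 1)")
        if self.murray_gamma <= 0:
            raise ValueError("murray_gamma must be positive")
        if self.terminal_tolerance <= 0:
            raise ValueError("terminal_tolerance must be positive")
        if self.viscosity_mode not in ("constant", "empirical"):
            raise ValueError("viscosity_mode must be 'constant' or 'empirical'")


@dataclass
class BifurcationSplit:
    """Fractional blood and RBC flow of the two daughters of a bifurcation."""

    parent_id: int
    daughter_ids: Tuple[int, int]
    fractional_flows: Tuple[float, float]
    fractional_rbc_flows: Tuple[float, float]


# ---------------------------------------------------------------------------
# Flows and pressures
# ---------------------------------------------------------------------------


def assign_topological_flows(network: Network, q_perf: float) -> np.ndarray:
    """Segment flows when every terminal carries exactly ``q_perf`` nL/s.

    Returns flows in nL/s; conservation at every bifurcation is exact by
    construction (parent leaf-count = sum of daughter leaf-counts).
    """
    return network.downstream_terminal_counts().astype(float) * q_perf


def poiseuille_solve(
    network: Network,
    dp_tot: float,
    viscosities_mpas: np.ndarray,
    p_inlet: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-network solve with Dirichlet pressure boundaries.

    The inlet node is held at ``p_inlet`` (default ``dp_tot``) and every
    terminal outlet node at ``p_inlet - dp_tot``.  Segment resistances are
    ``128*mu*L/(pi*d^4)``.  Returns ``(flows, p_in, p_out)`` per segment.
    """
    if network.diameter_um is None:
        raise ValueError("poiseuille_solve requires diameters")
    d = network.diameter_um
    if np.any(d <= 0):
        raise ValueError("zero or negative diameter makes the system singular")
    mu = np.broadcast_to(np.asarray(viscosities_mpas, dtype=float), d.shape)
    n = network.n_segments
    res = poiseuille_resistance(mu, network.lengths, d)
    g = 1.0 / res

    if p_inlet is None:
        p_inlet = float(dp_tot)
    p_outlet = p_inlet - float(dp_tot)

    # Node numbering: node 0 = inlet (root proximal end); node i+1 = distal
    # end of segment i.  Segment i connects node (parent+1 or 0) -> node i+1.
    root = network.root
    up_node = np.where(network.parent >= 0, network.parent + 1, 0)
    dn_node = np.arange(n) + 1

    fixed = np.zeros(n + 1, dtype=bool)
    fixed_val = np.zeros(n + 1)
    fixed[0] = True
    fixed_val[0] = p_inlet
    term = network.is_terminal
    fixed[dn_node[term]] = True
    fixed_val[dn_node[term]] = p_outlet

    free = np.flatnonzero(~fixed)
    idx_of = -np.ones(n + 1, dtype=np.int64)
    idx_of[free] = np.arange(len(free))

    rows, cols, vals = [], [], []
    rhs = np.zeros(len(free))
    for i in range(n):
        u, v, gi = up_node[i], dn_node[i], g[i]
        for (x, y) in ((u, v), (v, u)):
            if fixed[x]:
                continue
            rows.append(idx_of[x]); cols.append(idx_of[x]); vals.append(gi)
            if fixed[y]:
                rhs[idx_of[x]] += gi * fixed_val[y]
            else:
                rows.append(idx_of[x]); cols.append(idx_of[y]); vals.append(-gi)

    p = fixed_val.copy()
    if len(free):
        A = sp.coo_matrix((vals, (rows, cols)), shape=(len(free), len(free))).tocsr()
        p[free] = spla.spsolve(A, rhs)

    p_in = p[up_node]
    p_out = p[dn_node]
    flows = g * (p_in - p_out)
    return flows, p_in, p_out


def _propagated_pressures(
    network: Network, flows: np.ndarray, resistances: np.ndarray, p_inlet: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Root-down pressure propagation consistent with ``dP_i = R_i * Q_i``."""
    n = network.n_segments
    p_in = np.empty(n)
    p_out = np.empty(n)
    for i in network.topological_order():
        par = network.parent[i]
        p_in[i] = p_inlet if par < 0 else p_out[par]
        p_out[i] = p_in[i] - resistances[i] * flows[i]
    return p_in, p_out


def converge_diameters(
    network: Network, hconfig: HemodynamicConfig, max_sweeps: int = 200
) -> dict:
    """Size all vessels under the Murray / equal-terminal-flow constraints.

    Mutates ``network`` in place (diameter, flow, pressures) and returns a
    summary dict with ``d_ref``, the sweep count, and the maximum relative
    terminal-flow error.  Raises ``RuntimeError`` if the empirical-viscosity
    fixed point fails to settle within ``max_sweeps``.
    """
    gamma = hconfig.murray_gamma
    q = hconfig.q_perf
    counts = network.downstream_terminal_counts().astype(float)
    n_term = network.n_terminals
    flows = counts * q
    shape = counts ** (1.0 / gamma)  # d_i / d_ref
    lengths = network.lengths

    # Mean inlet->terminal drop = sum_i N_i * w_i / n_term where w_i is the
    # per-segment drop; with Murray diameters this collapses to a single sum.
    def dref_for(mu: np.ndarray) -> float:
        drop_unit = (
            128.0 * mu * lengths * flows / (np.pi * shape**4) * POISEUILLE_MMHG
        )  # per-segment drop at d_ref = 1 um
        mean_drop = float(np.sum(counts * drop_unit)) / n_term
        return (mean_drop / hconfig.dp_tot) ** 0.25

    mu_const = np.full(network.n_segments, hconfig.mu_rel_generation * hconfig.plasma_viscosity)
    d_ref = dref_for(mu_const)
    sweeps = 1
    if hconfig.viscosity_mode == "empirical":
        for sweeps in range(2, max_sweeps + 2):
            network.diameter_um = d_ref * shape
            network.flow_nl_s = flows
            hd, _ = propagate_hematocrit(network, hconfig.inlet_hd)
            mu = relative_viscosity(network.diameter_um, hd) * hconfig.plasma_viscosity
            d_new = dref_for(mu)
            # damped log-scale update
            d_next = float(np.exp(0.5 * (np.log(d_ref) + np.log(d_new))))
            if abs(d_next - d_ref) / d_ref < 1.0e-12:
                d_ref = d_next
                break
            d_ref = d_next
        else:
            raise RuntimeError(
                f"diameter convergence did not settle in {max_sweeps} sweeps "
                f"(last relative step {abs(d_new - d_ref) / d_ref:.3e})"
            )

    network.diameter_um = d_ref * shape
    network.flow_nl_s = flows
    if hconfig.viscosity_mode == "constant":
        mu = mu_const
    else:
        hd, _ = propagate_hematocrit(network, hconfig.inlet_hd)
        mu = relative_viscosity(network.diameter_um, hd) * hconfig.plasma_viscosity
    res = poiseuille_resistance(mu, lengths, network.diameter_um)
    network.p_in, network.p_out = _propagated_pressures(
        network, flows, res, p_inlet=hconfig.dp_tot
    )

    term = network.is_terminal
    max_err = float(np.max(np.abs(flows[term] - q) / q))
    if max_err > hconfig.terminal_tolerance:
        raise RuntimeError(
            f"terminal flows off by {max_err:.3%} > tolerance "
            f"{hconfig.terminal_tolerance:.1%}"
        )
    return {"d_ref_um": d_ref, "sweeps": sweeps, "max_terminal_flow_error": max_err}


# ---------------------------------------------------------------------------
# Empirical rheology (in-vitro laws)
# ---------------------------------------------------------------------------


def relative_viscosity(diameter_um, h_d, mode: str = "empirical", mu_rel_constant: float = 3.0):
    """Relative apparent blood viscosity in tube flow.

    ``mode="empirical"`` evaluates the in-vitro diameter/hematocrit law
    (eta45 and shape exponent C as functions of diameter in um); at
    ``h_d = 0`` it returns 1 (plasma).  ``mode="constant"`` returns
    ``mu_rel_constant`` regardless of inputs.
    """
    d = np.asarray(diameter_um, dtype=float)
    h = np.asarray(h_d, dtype=float)
    if mode == "constant":
        return np.broadcast_to(np.float64(mu_rel_constant), np.broadcast(d, h).shape).copy()
    if mode != "empirical":
        raise ValueError("mode must be 'empirical' or 'constant'")
    eta45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    frac = 1.0 / (1.0 + 1.0e-11 * d**12)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + frac) + frac
    num = (1.0 - h) ** c - 1.0
    den = (1.0 - 0.45) ** c - 1.0
    return 1.0 + (eta45 - 1.0) * num / den


def tube_hematocrit(h_d, diameter_um):
    """Tube hematocrit H_T from discharge hematocrit H_D (Fahraeus effect).

    H_T/H_D = H_D + (1-H_D)*(1 + 1.7 exp(-0.415 d) - 0.6 exp(-0.011 d)),
    with d in um; the ratio tends to 1 for macrovessels and H_T <= H_D
    throughout the microvascular range.
    """
    h = np.asarray(h_d, dtype=float)
    d = np.asarray(diameter_um, dtype=float)
    ratio = h + (1.0 - h) * (1.0 + 1.7 * np.exp(-0.415 * d) - 0.6 * np.exp(-0.011 * d))
    return h * ratio


def _logit(x):
    return np.log(x / (1.0 - x))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _rbc_fraction(fqb: float, d_parent: float, d_a: float, d_b: float, h_d: float) -> float:
    """Fractional RBC flux into the daughter receiving blood fraction fqb."""
    x0 = 0.4 / d_parent
    if fqb <= x0:
        return 0.0
    if fqb >= 1.0 - x0:
        return 1.0
    a = -6.96 * np.log(d_a / d_b) / d_parent
    b = 1.0 + 6.98 * (1.0 - h_d) / d_parent
    return float(_logistic(a + b * _logit((fqb - x0) / (1.0 - 2.0 * x0))))


def phase_separation(parent, daughters):
    """Discharge hematocrit of the two daughters of a bifurcation.

    ``parent = (d_um, h_d, q)``; ``daughters = ((d_um, q), (d_um, q))``.
    The empirical logit law gives each daughter's fractional RBC flux, with
    plasma-skimming cutoffs at fractional flow 0.4/d_parent; fluxes are
    renormalised so RBC flux is conserved exactly, and capped so no
    daughter exceeds unit hematocrit.
    """
    d_p, h_p, q_p = parent
    (d1, q1), (d2, q2) = daughters
    if q_p <= 0 or abs(q1 + q2 - q_p) > 1.0e-8 * q_p:
        raise ValueError("daughter flows must sum to the parent flow")
    f1 = q1 / q_p
    f2 = q2 / q_p
    if not (0.0 < f1 < 1.0) or not (0.0 < f2 < 1.0):
        raise ValueError("fractional flows must lie in (0, 1)")

    e1 = _rbc_fraction(f1, d_p, d1, d2, h_p)
    e2 = _rbc_fraction(f2, d_p, d2, d1, h_p)
    total = e1 + e2
    if total <= 0.0:  # degenerate; split RBCs with blood flow
        e1, e2 = f1, f2
    else:
        e1, e2 = e1 / total, e2 / total

    flux = q_p * h_p
    flux1 = min(e1 * flux, q1)  # cap at packed (h_d = 1)
    flux2 = flux - flux1
    if flux2 > q2:
        flux2 = q2
        flux1 = flux - flux2
    return flux1 / q1, flux2 / q2


def propagate_hematocrit(
    network: Network, inlet_hd: float = 0.4
) -> Tuple[np.ndarray, np.ndarray]:
    """Discharge and tube hematocrit for every segment, root-down.

    Requires flows and diameters.  The root receives ``inlet_hd``; every
    bifurcation applies the phase-separation law; RBC flux is conserved
    end-to-end.  Results are stored on the network and returned.
    """
    if network.diameter_um is None or network.flow_nl_s is None:
        raise ValueError("propagate_hematocrit requires diameters and flows")
    n = network.n_segments
    hd = np.empty(n)
    d = network.diameter_um
    q = network.flow_nl_s
    ch = network.children
    hd[network.root] = inlet_hd
    for i in network.topological_order():
        c1, c2 = ch[i]
        if c1 < 0:
            continue
        h1, h2 = phase_separation(
            (d[i], hd[i], q[i]), ((d[c1], q[c1]), (d[c2], q[c2]))
        )
        hd[c1], hd[c2] = h1, h2
    ht = tube_hematocrit(hd, d)
    network.hd = hd
    network.ht = ht
    return hd, ht


def perfusion_heterogeneity(network) -> pd.DataFrame:
    """Fractional daughter flows at every bifurcation.

    Each bifurcation contributes two rows (fractions f and 1-f), so the
    distribution mean is exactly 0.5; deviation from 0.5 measures perfusion
    heterogeneity.  Columns: parent_id, daughter_id, parent_diameter_um,
    daughter_diameter_um, fraction.
    """
    net, mask = as_network_and_mask(network)
    if net.flow_nl_s is None:
        raise ValueError("perfusion_heterogeneity requires flows")
    rows = []
    ch = net.children
    q = net.flow_nl_s
    d = net.diameter_um
    for i in range(net.n_segments):
        c1, c2 = ch[i]
        if c1 < 0 or not mask[i] or not (mask[c1] and mask[c2]):
            continue
        for c in (c1, c2):
            rows.append(
                (
                    int(i),
                    int(c),
                    float(d[i]) if d is not None else np.nan,
                    float(d[c]) if d is not None else np.nan,
                    float(q[c] / q[i]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "parent_id",
            "daughter_id",
            "parent_diameter_um",
            "daughter_diameter_um",
            "fraction",
        ],
    )
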