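"""Staged constrained-constructive-optimization (CCO) growth of arteriolar
trees in ellipsoidal tissue volumes.

One terminal is added per iteration:

A. the tissue ellipsoid is inflated by ``v_perf`` (semi-axes rescaled about
   the origin; existing vessel coordinates are left untouched);
B. a perfusion point is drawn uniformly in the ellipsoid, at least
   ``d_thresh = sqrt(pi r^2 / n_term)`` away from every existing vessel
   (r = radius of the equal-volume sphere); the threshold is relaxed by
   10% after every 50 failed draws so sampling always terminates;
C. the ``candidate_count`` segments nearest the point are considered as
   connection targets;
D. for each target, the triangle spanned by its endpoints and the new
   point is discretised into a barycentric lattice (66 nodes by default);
   every lattice node is scored as a tentative bifurcation point by the
   total intravascular blood volume of the re-sized tree, and the
   non-overlapping candidate of minimal volume is adopted.

Scoring exploits the closed-form hemodynamics of the constant-viscosity
Murray tree: with downstream-terminal counts ``N_i`` the blood volume is
``(pi/4) d_ref^2 * sum(L_i N_i^(2/gamma))`` and the reference diameter
follows from the mean inlet-to-terminal pressure drop, so each candidate
is scored in O(1) after an O(n) per-step sweep (ancestor prefix sums).
Overlap testing is deferred: candidates are ranked by volume and only
inspected until the first collision-free one, which is the adopted
configuration either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import geometry
from .hemodynamics import HemodynamicConfig, converge_diameters, propagate_hematocrit, relative_viscosity
from .model import GenerationConfig, Network, TissueDomain
from .units import POISEUILLE_MMHG

__all__ = [
    "GrowthState",
    "CandidateConnection",
    "make_domain",
    "distance_threshold",
    "init_root",
    "sample_perfusion_point",
    "candidate_vessels",
    "optimize_bifurcation",
    "detect_overlap",
    "grow_step",
    "generate",
]

logger = logging.getLogger(__name__)

_MIN_LEN = 1.0e-9  # mm; shorter tentative segments are rejected


def make_domain(ratios, total_volume: float) -> TissueDomain:
    """Ellipsoid with semi-axes proportional to (Rx, Ry, Rz) and the given
    volume: (a,b,c) = k*(Rx,Ry,Rz), k = (3V / (4 pi Rx Ry Rz))^(1/3)."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0) or total_volume <= 0:
        raise ValueError("ratios and volume must be strictly positive")
    k = (3.0 * total_volume / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    return TissueDomain(semi_axes=tuple(k * ratios))


def distance_threshold(domain: TissueDomain, n_term: int) -> float:
    """Minimum vessel clearance for new perfusion points, in mm.

    ``sqrt(pi r^2 / n_term)`` with r the radius of the equal-volume sphere
    — the 2D supporting-circle form promoted to the equivalent sphere (the
    square root restores length units).
    """
    if n_term < 1:
        raise ValueError("n_term must be >= 1")
    r = (3.0 * domain.volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(np.sqrt(np.pi * r * r / n_term))


def _triangle_lattice(n_points: int) -> np.ndarray:
    """Barycentric weights (n_points, 3) of the triangular lattice with
    m nodes per edge, n_points = m(m+1)/2."""
    m = int(round((np.sqrt(8 * n_points + 1) - 1) / 2))
    w = []
    for i in range(m):
        for j in range(m - i):
            k = (m - 1) - i - j
            w.append((i, j, k))
    return np.asarray(w, dtype=float) / max(m - 1, 1)


@dataclass
class CandidateConnection:
    """Outcome of the bifurcation-point search for one target segment."""

    target_id: int
    bifurcation_point: Optional[np.ndarray]
    volume_mm3: float
    valid: bool
    node_index: int = -1
    d_ref_um: float = np.nan


class GrowthState:
    """Mutable state of a generation run.

    Segment arrays are pre-allocated for the final size (2*n_bif + 1); the
    growing tree occupies the first ``n`` rows.  ``nterm`` holds the
    downstream terminal count of each segment, from which flows and
    Murray diameters follow in closed form.
    """

    def __init__(self, config: GenerationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.hconfig = HemodynamicConfig(
            murray_gamma=config.murray_gamma,
            q_perf=config.q_perf,
            dp_tot=config.dp_tot,
            terminal_tolerance=config.terminal_tolerance,
        )
        cap = 2 * config.n_bif + 1
        self.prox = np.zeros((cap, 3))
        self.dist = np.zeros((cap, 3))
        self.parent = np.full(cap, -1, dtype=np.int64)
        self.children = np.full((cap, 2), -1, dtype=np.int64)
        self.nterm = np.zeros(cap, dtype=np.int64)
        self.length = np.zeros(cap)
        self.n = 0
        self.iteration = 0
        self.d_thresh = 0.0
        self.domain: TissueDomain = make_domain(config.ratios, config.v_perf)
        gamma = config.murray_gamma
        self._a_exp = 2.0 / gamma
        self._b_exp = 2.0 - 4.0 / gamma
        self._inv_gamma = 1.0 / gamma
        self._lattice = _triangle_lattice(config.triangle_points)

    # -- derived quantities ------------------------------------------------

    @property
    def n_term(self) -> int:
        return (self.n + 1) // 2

    @property
    def n_bif_done(self) -> int:
        return (self.n - 1) // 2

    def _kb(self, n_term: int) -> float:
        mu = self.hconfig.mu_rel_generation * self.hconfig.plasma_viscosity
        return (
            128.0
            * mu
            * self.hconfig.q_perf
            * POISEUILLE_MMHG
            / (np.pi * n_term * self.hconfig.dp_tot)
        )

    def d_ref(self, n_term: Optional[int] = None) -> float:
        """Terminal reference diameter (um) of the current tree."""
        s = slice(0, self.n)
        b_sum = float(np.sum(self.length[s] * self.nterm[s].astype(float) ** self._b_exp))
        return (self._kb(n_term or self.n_term) * b_sum) ** 0.25

    def diameters(self) -> np.ndarray:
        s = slice(0, self.n)
        return self.d_ref() * self.nterm[s].astype(float) ** self._inv_gamma

    def network(self, full_hemodynamics: bool = True) -> Network:
        """Snapshot of the current tree as a :class:`Network`."""
        s = slice(0, self.n)
        net = Network(
            self.prox[s].copy(),
            self.dist[s].copy(),
            self.parent[s].copy(),
            config=self.config,
            semi_axes=self.domain.semi_axes,
            validate=False,
        )
        if full_hemodynamics:
            converge_diameters(net, self.hconfig)
            propagate_hematocrit(net, self.hconfig.inlet_hd)
            net.mu_rel = relative_viscosity(net.diameter_um, net.hd)
        return net


def init_root(config: GenerationConfig, rng: Optional[np.random.Generator] = None) -> GrowthState:
    """Create the initial state: a single root arteriole from the inlet
    surface anchor to a uniformly sampled interior perfusion point, inside
    a domain sized for one terminal (volume ``v_perf``)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = GrowthState(config, rng)
    inlet = state.domain.surface_point(config.inlet_direction)
    while True:
        target = geometry.sample_in_ellipsoid(rng, state.domain.semi_axes)
        if np.linalg.norm(target - inlet) > _MIN_LEN:
            break
    state.prox[0] = inlet
    state.dist[0] = target
    state.parent[0] = -1
    state.nterm[0] = 1
    state.length[0] = float(np.linalg.norm(target - inlet))
    state.n = 1
    return state


def sample_perfusion_point(
    state: GrowthState, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Uniform point in the current domain, at least ``state.d_thresh`` from
    every existing segment.  After each block of 50 failed draws the
    threshold is relaxed to 90% of its value (stored back on the state), so
    the sampler always terminates; the accepted point is uniform in the
    ellipsoid marginally."""
    rng = rng or state.rng
    s = slice(0, state.n)
    while True:
        pts = geometry.sample_in_ellipsoid(rng, state.domain.semi_axes, n=50)
        dmin = geometry.points_segments_min_distance(pts, state.prox[s], state.dist[s])
        ok = np.flatnonzero(dmin >= state.d_thresh)
        if len(ok):
            return pts[ok[0]]
        state.d_thresh *= 0.9


def candidate_vessels(state_or_network, point, k: int) -> np.ndarray:
    """Ids of the ``min(k, n)`` segments nearest to ``point``, ascending by
    point-to-segment distance, ties broken by smaller id."""
    if isinstance(state_or_network, GrowthState):
        s = slice(0, state_or_network.n)
        p0, p1 = state_or_network.prox[s], state_or_network.dist[s]
    else:
        p0, p1 = state_or_network.proximal, state_or_network.distal
    dist = geometry.point_segment_distance(np.asarray(point, dtype=float), p0, p1)
    ids = np.arange(len(dist))
    order = np.lexsort((ids, dist))
    return order[: min(k, len(dist))]


# ---------------------------------------------------------------------------
# Candidate scoring
# ---------------------------------------------------------------------------


class _StepContext:
    """Per-iteration prefix sums enabling O(1) candidate scoring.

    For a tentative split of segment j at point x with a new terminal at p,
    the modified tree's sums  A = sum L_i N_i^(2/gamma)  and
    B = sum L_i N_i^(2-4/gamma)  are the base sums minus j's contribution,
    plus the ancestor increments (every strict ancestor of j gains one
    downstream terminal), plus the three new pieces.
    """

    def __init__(self, state: GrowthState, n_term_new: int):
        s = slice(0, state.n)
        self.state = state
        self.n_term_new = n_term_new
        nt = state.nterm[s].astype(float)
        L = state.length[s]
        a, b = state._a_exp, state._b_exp
        self.na = nt**a
        self.nb = nt**b
        self.a_base = float(np.sum(L * self.na))
        self.b_base = float(np.sum(L * self.nb))
        # ancestor prefix sums, root-down
        inc_a = L * ((nt + 1.0) ** a - self.na)
        inc_b = L * ((nt + 1.0) ** b - self.nb)
        self.anc_a = np.zeros(state.n)
        self.anc_b = np.zeros(state.n)
        order = _topo_order(state)
        for i in order:
            p = state.parent[i]
            if p >= 0:
                self.anc_a[i] = self.anc_a[p] + inc_a[p]
                self.anc_b[i] = self.anc_b[p] + inc_b[p]
        self.kb = state._kb(n_term_new)


def _topo_order(state: GrowthState) -> np.ndarray:
    order = np.empty(state.n, dtype=np.int64)
    order[0] = 0  # root is always segment 0
    head, tail = 0, 1
    while head < tail:
        i = order[head]
        head += 1
        for c in state.children[i]:
            if c >= 0:
                order[tail] = c
                tail += 1
    return order


def _grid_points(state: GrowthState, j: int, point: np.ndarray) -> np.ndarray:
    """Lattice of tentative bifurcation points over the triangle spanned by
    segment j's endpoints and the perfusion point.  A degenerate (collinear)
    triangle is widened by a small perpendicular offset of the apex so the
    lattice still spans a 2D search space."""
    a = state.prox[j]
    b = state.dist[j]
    c = np.asarray(point, dtype=float)
    ab = b - a
    ac = c - a
    cross = np.cross(ab, ac)
    area2 = np.linalg.norm(cross)
    if area2 < 1.0e-10 * max(np.linalg.norm(ab), 1.0e-30) * max(np.linalg.norm(ac), 1.0e-30):
        # build any unit vector perpendicular to ab
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ab[0]) > 0.9 * np.linalg.norm(ab):
            ref = np.array([0.0, 1.0, 0.0])
        perp = np.cross(ab, ref)
        perp /= max(np.linalg.norm(perp), 1.0e-30)
        c = c + 1.0e-3 * max(np.linalg.norm(ab), _MIN_LEN) * perp
    verts = np.stack([a, b, c])
    return state._lattice @ verts


def _score_target(
    ctx: _StepContext, j: int, point: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Blood volume (mm^3) and d_ref (um) at every lattice node for target
    segment j; invalid (degenerate-length) nodes score +inf."""
    state = ctx.state
    x = _grid_points(state, j, point)
    a_pt, b_pt = state.prox[j], state.dist[j]
    l_prox = np.linalg.norm(x - a_pt, axis=1)
    l_dist = np.linalg.norm(x - b_pt, axis=1)
    l_new = np.linalg.norm(x - np.asarray(point, dtype=float), axis=1)
    nj = float(state.nterm[j])
    a, b = state._a_exp, state._b_exp
    const_a = ctx.a_base - state.length[j] * ctx.na[j] + ctx.anc_a[j]
    const_b = ctx.b_base - state.length[j] * ctx.nb[j] + ctx.anc_b[j]
    a_cand = const_a + l_prox * (nj + 1.0) ** a + l_dist * nj**a + l_new
    b_cand = const_b + l_prox * (nj + 1.0) ** b + l_dist * nj**b + l_new
    d_ref = (ctx.kb * b_cand) ** 0.25
    vol = np.pi * 0.25 * 1.0e-6 * d_ref**2 * a_cand
    bad = (l_prox < _MIN_LEN) | (l_dist < _MIN_LEN) | (l_new < _MIN_LEN)
    vol = np.where(bad, np.inf, vol)
    return vol, d_ref, x


def optimize_bifurcation(
    state: GrowthState,
    target_segment: int,
    point,
    check_overlap: bool = True,
    ctx: Optional[_StepContext] = None,
) -> CandidateConnection:
    """Best bifurcation point on the lattice for one target segment.

    Every lattice node is scored by total network blood volume; the
    minimal-volume node that passes the overlap test (if requested) is
    returned.  ``valid=False`` when every node is degenerate or overlapping.
    """
    point = np.asarray(point, dtype=float)
    if ctx is None:
        ctx = _StepContext(state, state.n_term + 1)
    vol, d_ref, x = _score_target(ctx, int(target_segment), point)
    order = np.argsort(vol, kind="stable")
    for idx in order:
        if not np.isfinite(vol[idx]):
            break
        if not check_overlap or not _candidate_overlaps(
            state, int(target_segment), x[idx], point, float(d_ref[idx])
        ):
            return CandidateConnection(
                target_id=int(target_segment),
                bifurcation_point=x[idx].copy(),
                volume_mm3=float(vol[idx]),
                valid=True,
                node_index=int(idx),
                d_ref_um=float(d_ref[idx]),
            )
    return CandidateConnection(
        target_id=int(target_segment),
        bifurcation_point=None,
        volume_mm3=np.inf,
        valid=False,
    )


# ---------------------------------------------------------------------------
# Overlap detection
# ---------------------------------------------------------------------------


def _candidate_overlaps(
    state: GrowthState, j: int, x: np.ndarray, point: np.ndarray, d_ref: float
) -> bool:
    """Would adopting (target j, bifurcation x, terminal at ``point``)
    collide with the rest of the tree?

    The three tentative tubes (proximal piece, distal piece, new terminal)
    are tested against all existing segments except the target itself and
    tube-specific adjacent segments (those sharing a node).  Collision =
    axis distance below the sum of radii, using the re-scaled Murray
    diameters of the modified tree.
    """
    s = slice(0, state.n)
    n = state.n
    inv_gamma = state._inv_gamma
    nt = state.nterm[s].astype(float)

    # downstream-terminal counts of the modified tree (ancestors of j gain 1)
    anc = np.zeros(n, dtype=bool)
    p = state.parent[j]
    while p >= 0:
        anc[p] = True
        p = state.parent[p]
    radii = 0.5e-3 * d_ref * (nt + anc) ** inv_gamma  # mm

    nj = float(state.nterm[j])
    prox_piece = (state.prox[j], x, 0.5e-3 * d_ref * (nj + 1.0) ** inv_gamma)
    dist_piece = (x, state.dist[j], 0.5e-3 * d_ref * nj**inv_gamma)
    new_piece = (x, point, 0.5e-3 * d_ref)

    sib = -1
    par = state.parent[j]
    if par >= 0:
        c1, c2 = state.children[par]
        sib = c2 if c1 == j else c1
    excl_prox = {j, int(par), int(sib)}
    excl_dist = {j, int(state.children[j][0]), int(state.children[j][1])}
    excl_new = {j}

    for (p0, p1, r), excl in (
        (prox_piece, excl_prox),
        (dist_piece, excl_dist),
        (new_piece, excl_new),
    ):
        dist = geometry.segment_segments_distance(p0, p1, state.prox[s], state.dist[s])
        clearance = dist - (radii + r)
        mask = np.ones(n, dtype=bool)
        for e in excl:
            if 0 <= e < n:
                mask[e] = False
        if np.any(clearance[mask] < 0.0):
            return True
    return False


def detect_overlap(network: Network, proposed) -> bool:
    """True iff any proposed tube collides with a non-adjacent network
    segment or with another non-adjacent proposed tube.

    ``proposed`` is a sequence of ``(p0, p1, diameter_um)``; adjacency
    (sharing an endpoint within 1e-9 mm) is decided from coordinates.
    """
    if network.diameter_um is None:
        raise ValueError("detect_overlap requires network diameters")
    segs = [
        (network.proximal[i], network.distal[i], float(network.diameter_um[i]))
        for i in range(network.n_segments)
    ]
    prop = [(np.asarray(p0, float), np.asarray(p1, float), float(d)) for p0, p1, d in proposed]

    def _adjacent(a, b) -> bool:
        return any(
            np.linalg.norm(ea - eb) < 1.0e-9
            for ea in (a[0], a[1])
            for eb in (b[0], b[1])
        )

    everything = segs + prop
    for k, cand in enumerate(prop):
        for other in everything[: len(segs) + k]:
            if other is cand or _adjacent(cand, other):
                continue
            d = geometry.segment_segments_distance(
                cand[0], cand[1], other[0][None, :], other[1][None, :]
            )[0]
            if d < 0.5e-3 * (cand[2] + other[2]):
                return True
    return False


# ---------------------------------------------------------------------------
# Growth loop
# ---------------------------------------------------------------------------


def _adopt(state: GrowthState, j: int, x: np.ndarray, point: np.ndarray) -> None:
    """Split target j at x and attach a new terminal reaching ``point``.

    Index j becomes the proximal piece; the distal piece and the terminal
    take the next two ids.  Downstream-terminal counts of j and all its
    ancestors increase by one.
    """
    m = state.n
    t = m + 1
    # distal piece inherits j's daughters
    state.prox[m] = x
    state.dist[m] = state.dist[j]
    state.parent[m] = j
    state.children[m] = state.children[j]
    state.nterm[m] = state.nterm[j]
    for c in state.children[m]:
        if c >= 0:
            state.parent[c] = m
    # new terminal
    state.prox[t] = x
    state.dist[t] = point
    state.parent[t] = j
    state.children[t] = (-1, -1)
    state.nterm[t] = 1
    # j becomes the proximal piece
    state.dist[j] = x
    state.children[j] = (m, t)
    state.nterm[j] += 1
    state.n = m + 2
    # lengths
    for i in (j, m, t):
        state.length[i] = float(np.linalg.norm(state.dist[i] - state.prox[i]))
    # ancestors gain one terminal
    p = state.parent[j]
    while p >= 0:
        state.nterm[p] += 1
        p = state.parent[p]


def grow_step(state: GrowthState, max_point_resamples: int = 20) -> GrowthState:
    """One CCO iteration: inflate, sample, connect, adopt the volume-minimal
    valid candidate.  Mutates and returns ``state``."""
    cfg = state.config
    state.iteration += 1
    n_term_new = state.n_term + 1
    # Inflate the tissue by v_perf; the existing network stretches with it
    # (isotropic rescale about the origin), keeping the inlet on the tissue
    # surface and preserving the geometric self-similarity of the tree.
    scale = (n_term_new / state.n_term) ** (1.0 / 3.0)
    s = slice(0, state.n)
    state.prox[s] *= scale
    state.dist[s] *= scale
    state.length[s] *= scale
    state.domain = make_domain(cfg.ratios, n_term_new * cfg.v_perf)
    state.d_thresh = distance_threshold(state.domain, n_term_new)

    ctx = _StepContext(state, n_term_new)
    for _ in range(max_point_resamples):
        point = sample_perfusion_point(state)
        targets = candidate_vessels(state, point, cfg.candidate_count)

        vols = np.empty((len(targets), len(state._lattice)))
        drefs = np.empty_like(vols)
        grids = np.empty((len(targets), len(state._lattice), 3))
        for ti, j in enumerate(targets):
            vols[ti], drefs[ti], grids[ti] = _score_target(ctx, int(j), point)

        flat = vols.ravel()
        t_idx, n_idx = np.unravel_index(np.arange(flat.size), vols.shape)
        # global ranking: volume, then (target id, node index) for determinism
        order = np.lexsort((n_idx, targets[t_idx], flat))
        for k in order:
            if not np.isfinite(flat[k]):
                break
            ti, ni = t_idx[k], n_idx[k]
            j = int(targets[ti])
            x = grids[ti, ni]
            if not _candidate_overlaps(state, j, x, point, float(drefs[ti, ni])):
                _adopt(state, j, x, point)
                n = state.n
                assert n == 1 + 2 * state.n_bif_done and state.n_term == 1 + state.n_bif_done
                logger.debug(
                    "iter=%d n_term=%d domain_volume=%.6g adopted_volume=%.6g",
                    state.iteration,
                    state.n_term,
                    state.domain.volume,
                    float(flat[k]),
                )
                return state
        logger.debug("iter=%d: no valid candidate, resampling point", state.iteration)
    raise RuntimeError(
        f"growth stalled at iteration {state.iteration}: no non-overlapping "
        f"candidate found after {max_point_resamples} perfusion points"
    )


def generate(
    config: GenerationConfig, rng: Optional[np.random.Generator] = None
) -> Network:
    """Run the full CCO loop and return a finished, hemodynamically solved
    network with ``config.n_bif`` bifurcations."""
    state = init_root(config, rng)
    for _ in range(config.n_bif):
        grow_step(state)
    expected_volume = (config.n_bif + 1) * config.v_perf
    assert abs(state.domain.volume - expected_volume) < 1.0e-9 * expected_volume
    net = state.network(full_hemodynamics=True)
    return net
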