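"""Core data model for arteriolar networks.

A network is a rooted binary tree of *segments*: straight cylindrical tubes
between two 3D nodes.  Internal nodes always carry exactly two daughters
(arteriolar trees bifurcate; trifurcations are represented as two nearby
bifurcations), so a network with ``n_bif`` bifurcations has ``2*n_bif + 1``
segments and ``n_bif + 1`` terminals.

Maximal chains of consecutive segments sharing one order label form a
*vessel* (element); morphometric statistics are reported per element, which
is how vessels are delimited in intravital measurements.

The module also implements the ``expVal`` observability filter: daughters
thinner than a given percentage of their parent mimic vessels that escape
intravital imaging, and their entire downstream subtrees are hidden from
the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .units import cylinder_volume_mm3

__all__ = [
    "GenerationConfig",
    "TissueDomain",
    "Segment",
    "Network",
    "NetworkView",
    "Vessel",
    "build_network",
    "total_blood_volume",
    "apply_expval_filter",
    "element_partition",
    "INLET_PRESETS",
]

#: Named inlet anchors: unit directions from the ellipsoid centre.  The
#: surface point in that direction is where the feeding arteriole enters.
INLET_PRESETS = {
    "tip-x": (1.0, 0.0, 0.0),
    "tip": (1.0, 0.0, 0.0),
    "side-y": (0.0, 1.0, 0.0),
    "side": (0.0, 1.0, 0.0),
}


def _is_triangular(n: int) -> bool:
    m = int((np.sqrt(8 * n + 1) - 1) // 2)
    return m * (m + 1) // 2 == n


@dataclass
class GenerationConfig:
    """User-adjustable parameters of a generation run.

    Parameters
    ----------
    n_bif
        Number of bifurcations in the finished network (network density).
    q_perf
        Blood flow through every terminal arteriole, nL/s.
    dp_tot
        Pressure gradient from inlet to terminal arterioles, mmHg.
    v_perf
        Tissue volume perfused per terminal arteriole, mm^3 (inverse vessel
        density).
    ratios
        Width:length:height ratios (Rx, Ry, Rz) of the ellipsoidal tissue.
    murray_gamma
        Murray's-law exponent relating flow and diameter, Q ~ d**gamma.
    exp_val
        Observability threshold in percent: daughters thinner than
        ``exp_val/100`` of their parent are hidden from analyses.  0 = off.
    inlet
        Surface anchor for the feeding arteriole: a named preset
        (``"tip-x"``/``"side-y"``) or a 3-vector direction from the centre.
    seed
        Seed of the single pseudo-random generator used for all draws.
    candidate_count
        Number of nearest segments considered when connecting a new
        perfusion point.
    triangle_points
        Nodes of the barycentric lattice discretising the bifurcation
        triangle; must be a triangular number (66 = 11 nodes per edge).
    terminal_tolerance
        Relative tolerance on terminal flows after diameter convergence.
    """

    n_bif: int
    q_perf: float = 0.12
    dp_tot: float = 30.0
    v_perf: float = 1.8
    ratios: Tuple[float, float, float] = (6.0, 5.0, 1.0)
    murray_gamma: float = 2.63
    exp_val: float = 0.0
    inlet: Union[str, Tuple[float, float, float]] = "tip-x"
    seed: int = 0
    candidate_count: int = 12
    triangle_points: int = 66
    terminal_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.n_bif < 0:
            raise ValueError("n_bif must be non-negative")
        for name in ("q_perf", "dp_tot", "v_perf", "murray_gamma", "terminal_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        self.ratios = tuple(float(r) for r in self.ratios)
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three strictly positive numbers")
        if not (0.0 <= self.exp_val < 100.0):
            raise ValueError("exp_val must lie in [0, 100)")
        if self.candidate_count < 1:
            raise ValueError("candidate_count must be >= 1")
        if self.triangle_points < 3 or not _is_triangular(self.triangle_points):
            raise ValueError("triangle_points must be a triangular number >= 3")

    @property
    def inlet_direction(self) -> np.ndarray:
        """Unit direction from the tissue centre towards the inlet."""
        if isinstance(self.inlet, str):
            try:
                u = np.asarray(INLET_PRESETS[self.inlet], dtype=float)
            except KeyError:
                raise ValueError(
                    f"unknown inlet preset {self.inlet!r}; "
                    f"known: {sorted(set(INLET_PRESETS))}"
                ) from None
        else:
            u = np.asarray(self.inlet, dtype=float)
        n = np.linalg.norm(u)
        if n <= 0:
            raise ValueError("inlet direction must be non-zero")
        return u / n

    def to_dict(self) -> dict:
        d = {
            "n_bif": self.n_bif,
            "q_perf": self.q_perf,
            "dp_tot": self.dp_tot,
            "v_perf": self.v_perf,
            "ratios": list(self.ratios),
            "murray_gamma": self.murray_gamma,
            "exp_val": self.exp_val,
            "inlet": list(self.inlet) if not isinstance(self.inlet, str) else self.inlet,
            "seed": self.seed,
            "candidate_count": self.candidate_count,
            "triangle_points": self.triangle_points,
            "terminal_tolerance": self.terminal_tolerance,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerationConfig":
        kw = dict(d)
        if isinstance(kw.get("ratios"), list):
            kw["ratios"] = tuple(kw["ratios"])
        if isinstance(kw.get("inlet"), list):
            kw["inlet"] = tuple(kw["inlet"])
        return cls(**kw)


@dataclass(frozen=True)
class TissueDomain:
    """Axis-aligned ellipsoid centred at the origin.

    ``semi_axes`` (a, b, c) are in mm and proportional to (Rx, Ry, Rz);
    x is the tissue width axis, y the length axis, z the height axis.
    """

    semi_axes: Tuple[float, float, float]
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be strictly positive")

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def contains(self, points) -> np.ndarray:
        from .geometry import in_ellipsoid

        return in_ellipsoid(np.asarray(points) - np.asarray(self.center), self.semi_axes)

    def surface_point(self, direction) -> np.ndarray:
        from .geometry import ellipsoid_surface_point

        return ellipsoid_surface_point(self.semi_axes, direction) + np.asarray(self.center)


@dataclass
class Segment:
    """Read-only record view of one segment of a :class:`Network`."""

    id: int
    proximal_node: np.ndarray
    distal_node: np.ndarray
    length: float
    diameter: Optional[float] = None
    flow: Optional[float] = None
    p_in: Optional[float] = None
    p_out: Optional[float] = None
    h_d: Optional[float] = None
    h_t: Optional[float] = None
    mu_rel: Optional[float] = None
    strahler: Optional[int] = None
    centrifugal: Optional[int] = None
    parent: Optional[int] = None
    daughters: Tuple[int, ...] = ()


class Network:
    """Array-backed rooted binary tree of vessel segments.

    Per-segment attributes are stored as flat numpy arrays indexed by
    segment id (0..n-1); hemodynamic arrays may be ``None`` until assigned.
    """

    _OPTIONAL = ("diameter_um", "flow_nl_s", "p_in", "p_out", "hd", "ht", "mu_rel")

    def __init__(
        self,
        proximal: np.ndarray,
        distal: np.ndarray,
        parent: np.ndarray,
        *,
        diameter_um: Optional[np.ndarray] = None,
        flow_nl_s: Optional[np.ndarray] = None,
        p_in: Optional[np.ndarray] = None,
        p_out: Optional[np.ndarray] = None,
        hd: Optional[np.ndarray] = None,
        ht: Optional[np.ndarray] = None,
        mu_rel: Optional[np.ndarray] = None,
        config: Optional[GenerationConfig] = None,
        semi_axes: Optional[Tuple[float, float, float]] = None,
        validate: bool = True,
    ) -> None:
        self.proximal = np.asarray(proximal, dtype=float).reshape(-1, 3)
        self.distal = np.asarray(distal, dtype=float).reshape(-1, 3)
        self.parent = np.asarray(parent, dtype=np.int64).reshape(-1)
        n = len(self.parent)
        if self.proximal.shape != (n, 3) or self.distal.shape != (n, 3):
            raise ValueError("proximal/distal/parent arrays disagree in length")
        for name, arr in (
            ("diameter_um", diameter_um),
            ("flow_nl_s", flow_nl_s),
            ("p_in", p_in),
            ("p_out", p_out),
            ("hd", hd),
            ("ht", ht),
            ("mu_rel", mu_rel),
        ):
            a = None if arr is None else np.asarray(arr, dtype=float).reshape(-1)
            if a is not None and len(a) != n:
                raise ValueError(f"{name} has wrong length")
            setattr(self, name, a)
        self.config = config
        self.semi_axes = None if semi_axes is None else tuple(float(a) for a in semi_axes)
        self._children: Optional[np.ndarray] = None
        self._lengths: Optional[np.ndarray] = None
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"network must have exactly one root, found {len(roots)}")
        return int(roots[0])

    @property
    def children(self) -> np.ndarray:
        """(n, 2) daughter ids, -1 where absent."""
        if self._children is None:
            n = self.n_segments
            ch = np.full((n, 2), -1, dtype=np.int64)
            counts = np.zeros(n, dtype=np.int64)
            for i, p in enumerate(self.parent):
                if p >= 0:
                    if counts[p] < 2:
                        ch[p, counts[p]] = i
                    counts[p] += 1
            self._children = ch
        return self._children

    @property
    def lengths(self) -> np.ndarray:
        if self._lengths is None:
            self._lengths = np.linalg.norm(self.distal - self.proximal, axis=1)
        return self._lengths

    @property
    def is_terminal(self) -> np.ndarray:
        return self.children[:, 0] < 0

    @property
    def n_terminals(self) -> int:
        return int(np.count_nonzero(self.is_terminal))

    @property
    def n_bifurcations(self) -> int:
        return int(np.count_nonzero(~self.is_terminal))

    def topological_order(self) -> np.ndarray:
        """Segment ids in root-down (breadth-first) order."""
        order = np.empty(self.n_segments, dtype=np.int64)
        order[0] = self.root
        ch = self.children
        head, tail = 0, 1
        while head < tail:
            i = order[head]
            head += 1
            for c in ch[i]:
                if c >= 0:
                    order[tail] = c
                    tail += 1
        if tail != self.n_segments:
            raise ValueError("network is not connected")
        return order

    def downstream_terminal_counts(self) -> np.ndarray:
        """Number of terminals in each segment's subtree (leaf-count)."""
        counts = np.where(self.is_terminal, 1, 0).astype(np.int64)
        for i in self.topological_order()[::-1]:
            p = self.parent[i]
            if p >= 0:
                counts[p] += counts[i]
        return counts

    def subtree_ids(self, root_id: int) -> np.ndarray:
        """All segment ids in the subtree rooted at ``root_id`` (inclusive)."""
        ch = self.children
        out = [int(root_id)]
        stack = [int(root_id)]
        while stack:
            i = stack.pop()
            for c in ch[i]:
                if c >= 0:
                    out.append(int(c))
                    stack.append(int(c))
        return np.asarray(sorted(out), dtype=np.int64)

    def validate(self) -> None:
        n = self.n_segments
        if n == 0:
            raise ValueError("network has no segments")
        if np.any(self.parent >= n) or np.any(self.parent < -1):
            bad = int(np.flatnonzero((self.parent >= n) | (self.parent < -2))[0])
            raise ValueError(f"segment {bad} references a non-existent parent")
        _ = self.root  # exactly one root
        counts = np.bincount(self.parent[self.parent >= 0], minlength=n)
        bad = np.flatnonzero((counts != 0) & (counts != 2))
        if len(bad):
            raise ValueError(
                f"segment {int(bad[0])} has {int(counts[bad[0]])} daughter(s); "
                "internal segments must have exactly 2"
            )
        self._children = None
        self.topological_order()  # connectivity & acyclicity
        if np.any(self.lengths <= 0):
            bad = int(np.flatnonzero(self.lengths <= 0)[0])
            raise ValueError(f"segment {bad} has non-positive length")

    # -- accessors ---------------------------------------------------------

    def segment(self, i: int) -> Segment:
        def _get(name):
            arr = getattr(self, name)
            return None if arr is None else float(arr[i])

        daughters = tuple(int(c) for c in self.children[i] if c >= 0)
        return Segment(
            id=int(i),
            proximal_node=self.proximal[i].copy(),
            distal_node=self.distal[i].copy(),
            length=float(self.lengths[i]),
            diameter=_get("diameter_um"),
            flow=_get("flow_nl_s"),
            p_in=_get("p_in"),
            p_out=_get("p_out"),
            h_d=_get("hd"),
            h_t=_get("ht"),
            mu_rel=_get("mu_rel"),
            parent=(int(self.parent[i]) if self.parent[i] >= 0 else None),
            daughters=daughters,
        )

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_segments
        df = pd.DataFrame(
            {
                "id": np.arange(n, dtype=np.int64),
                "parent_id": self.parent,
                "x0": self.proximal[:, 0],
                "y0": self.proximal[:, 1],
                "z0": self.proximal[:, 2],
                "x1": self.distal[:, 0],
                "y1": self.distal[:, 1],
                "z1": self.distal[:, 2],
            }
        )
        for col, name in (
            ("diameter_um", "diameter_um"),
            ("flow_nl_s", "flow_nl_s"),
            ("hd", "hd"),
            ("ht", "ht"),
        ):
            arr = getattr(self, name)
            if arr is not None:
                df[col] = arr
        return df

    def copy(self) -> "Network":
        kwargs = {
            name: (None if getattr(self, name) is None else getattr(self, name).copy())
            for name in self._OPTIONAL
        }
        return Network(
            self.proximal.copy(),
            self.distal.copy(),
            self.parent.copy(),
            config=self.config,
            semi_axes=self.semi_axes,
            validate=False,
            **kwargs,
        )


@dataclass
class NetworkView:
    """A network together with an inclusion mask (the ``expVal`` filter).

    Metric operations accept either a bare :class:`Network` or a view; on a
    view only included segments take part, and terminals are segments with
    no *included* daughters.
    """

    network: Network
    included: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool).reshape(-1)
        if len(self.included) != self.network.n_segments:
            raise ValueError("mask length mismatch")

    @property
    def excluded_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.included)

    @property
    def n_segments(self) -> int:
        return int(np.count_nonzero(self.included))


def as_network_and_mask(obj) -> Tuple[Network, np.ndarray]:
    """Normalise a Network-or-NetworkView argument to (network, bool mask)."""
    if isinstance(obj, NetworkView):
        return obj.network, obj.included
    if isinstance(obj, Network):
        return obj, np.ones(obj.n_segments, dtype=bool)
    raise TypeError(f"expected Network or NetworkView, got {type(obj)!r}")


@dataclass
class Vessel:
    """Maximal chain of consecutive same-order segments (a vessel element)."""

    segment_ids: Tuple[int, ...]
    order: int
    scheme: str
    length: float
    diameter: Optional[float]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_network(table: Union[pd.DataFrame, Iterable[Mapping]], **kwargs) -> Network:
    """Construct a validated :class:`Network` from a segment table.

    The table needs columns ``id``, ``parent_id`` (empty/NaN/-1 for the
    root) and endpoint coordinates ``x0..z1``; ``diameter_um``,
    ``flow_nl_s``, ``hd``, ``ht`` are optional.  Ids may be arbitrary
    integers; they are re-indexed to 0..n-1 preserving input order.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(list(table))
    required = ["id", "parent_id", "x0", "y0", "z0", "x1", "y1", "z1"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"segment table is missing columns: {missing}")

    ids = table["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("segment ids are not unique")
    index = {int(v): i for i, v in enumerate(ids)}

    raw_parent = table["parent_id"].to_numpy()
    parent = np.empty(len(ids), dtype=np.int64)
    for i, p in enumerate(raw_parent):
        if p is None or (isinstance(p, float) and np.isnan(p)) or p == "" or (
            isinstance(p, (int, np.integer)) and int(p) < 0
        ):
            parent[i] = -1
        else:
            p = int(p)
            if p not in index:
                raise ValueError(f"segment {int(ids[i])} references unknown parent {p}")
            parent[i] = index[p]

    proximal = table[["x0", "y0", "z0"]].to_numpy(dtype=float)
    distal = table[["x1", "y1", "z1"]].to_numpy(dtype=float)
    optional = {}
    for col, name in (
        ("diameter_um", "diameter_um"),
        ("flow_nl_s", "flow_nl_s"),
        ("hd", "hd"),
        ("ht", "ht"),
    ):
        if col in table.columns and not table[col].isna().all():
            optional[name] = table[col].to_numpy(dtype=float)
    return Network(proximal, distal, parent, **optional, **kwargs)


def total_blood_volume(network, mask: Optional[np.ndarray] = None) -> float:
    """Total intravascular volume in mm^3 (the CCO objective)."""
    net, base = as_network_and_mask(network)
    if net.diameter_um is None:
        raise ValueError("total_blood_volume requires diameters to be assigned")
    m = base if mask is None else (base & np.asarray(mask, dtype=bool))
    return float(np.sum(cylinder_volume_mm3(net.diameter_um[m], net.lengths[m])))


def apply_expval_filter(network: Network, exp_val: float) -> NetworkView:
    """Hide daughters thinner than ``exp_val`` percent of their parent.

    The whole subtree below a hidden daughter is hidden as well: a vessel
    missed by intravital imaging implies its descendants are missed too.
    The excluded set is monotone in ``exp_val``.
    """
    if not (0.0 <= exp_val < 100.0):
        raise ValueError("exp_val must lie in [0, 100)")
    if network.diameter_um is None:
        raise ValueError("expVal filtering requires diameters to be assigned")
    frac = exp_val / 100.0
    included = np.ones(network.n_segments, dtype=bool)
    d = network.diameter_um
    for i in network.topological_order():
        p = network.parent[i]
        if p < 0:
            continue
        if not included[p] or d[i] < frac * d[p]:
            included[i] = False
    return NetworkView(network, included)


def element_partition(network, scheme: str = "strahler", orders=None) -> list:
    """Partition segments into maximal same-order chains (vessel elements).

    Every included segment belongs to exactly one element; a daughter joins
    its parent's element iff both carry the same order under ``scheme``.
    Representative element diameter is the length-weighted mean of member
    segments; element length is the sum of member lengths.
    """
    net, mask = as_network_and_mask(network)
    if orders is None:
        from . import metrics

        if scheme == "strahler":
            orders = metrics.strahler_orders(network)
        elif scheme == "centrifugal":
            orders = metrics.centrifugal_orders(network)
        else:
            raise ValueError(f"unknown ordering scheme {scheme!r}")
    orders = np.asarray(orders)
    if np.any(mask & (orders <= 0)):
        raise ValueError("orders missing for some included segments")

    element_of = np.full(net.n_segments, -1, dtype=np.int64)
    members: list = []
    tail: dict = {}  # element id -> current tail segment; elements are paths
    for i in net.topological_order():
        if not mask[i]:
            continue
        p = net.parent[i]
        if (
            p >= 0
            and mask[p]
            and orders[p] == orders[i]
            and element_of[p] >= 0
            and tail.get(int(element_of[p])) == int(p)
        ):
            e = int(element_of[p])
            members[e].append(int(i))
            element_of[i] = e
            tail[e] = int(i)
        else:
            e = len(members)
            element_of[i] = e
            members.append([int(i)])
            tail[e] = int(i)

    vessels = []
    lengths = net.lengths
    for chain in members:
        ids = tuple(chain)
        ltot = float(np.sum(lengths[list(ids)]))
        if net.diameter_um is not None:
            dia = float(
                np.sum(net.diameter_um[list(ids)] * lengths[list(ids)]) / ltot
            )
        else:
            dia = None
        vessels.append(
            Vessel(
                segment_ids=ids,
                order=int(orders[ids[0]]),
                scheme=scheme,
                length=ltot,
                diameter=dia,
            )
        )
    return vessels
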