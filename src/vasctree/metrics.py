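"""Morphometric and hemodynamic network analyses.

Implements the two ordering schemes used in microvascular morphometry
(Strahler leaf-up; centrifugal root-down), per-order element statistics,
Horton's law ratios by three literature methods, box-counting fractal
dimension over a cuboid hierarchy, the Murray-exponent fit, and subtree
sampling by inlet-diameter band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import Network, NetworkView, Vessel, as_network_and_mask, element_partition

__all__ = [
    "OrderStats",
    "HortonResult",
    "FractalResult",
    "SubtreeSample",
    "strahler_orders",
    "centrifugal_orders",
    "per_order_stats",
    "horton_ratios",
    "fractal_dimension",
    "murray_exponent_fit",
    "sample_subtrees",
]


# ---------------------------------------------------------------------------
# Ordering schemes
# ---------------------------------------------------------------------------


def strahler_orders(network) -> np.ndarray:
    """Strahler order per segment (excluded segments get 0).

    Terminals are order 1.  A parent whose two daughters share the same
    order takes the next higher order; otherwise it takes the higher of the
    two.  On a filtered view a parent with a single included daughter
    continues that daughter's order.
    """
    net, mask = as_network_and_mask(network)
    orders = np.zeros(net.n_segments, dtype=np.int64)
    ch = net.children
    for i in net.topological_order()[::-1]:
        if not mask[i]:
            continue
        kids = [c for c in ch[i] if c >= 0 and mask[c]]
        if not kids:
            orders[i] = 1
        elif len(kids) == 1:
            orders[i] = orders[kids[0]]
        else:
            o1, o2 = orders[kids[0]], orders[kids[1]]
            orders[i] = o1 + 1 if o1 == o2 else max(o1, o2)
    return orders


def centrifugal_orders(network) -> np.ndarray:
    """Centrifugal order per segment: the root chain is order 1 and the
    order increments by one across every (included) bifurcation."""
    net, mask = as_network_and_mask(network)
    orders = np.zeros(net.n_segments, dtype=np.int64)
    ch = net.children
    for i in net.topological_order():
        if not mask[i]:
            continue
        p = net.parent[i]
        if p < 0 or not mask[p]:
            orders[i] = 1
        else:
            kids_p = [c for c in ch[p] if c >= 0 and mask[c]]
            orders[i] = orders[p] + 1 if len(kids_p) == 2 else orders[p]
    return orders


def _orders_for(network, scheme: str) -> np.ndarray:
    if scheme == "strahler":
        return strahler_orders(network)
    if scheme == "centrifugal":
        return centrifugal_orders(network)
    raise ValueError(f"unknown ordering scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Per-order statistics
# ---------------------------------------------------------------------------


@dataclass
class OrderStats:
    """Element-level per-order summary table.

    ``table`` is indexed by order (1..max) with columns
    ``mean_diameter_um, sd_diameter_um, mean_length_mm, sd_length_mm,
    n_elements, n_bifurcations``.
    """

    scheme: str
    table: pd.DataFrame


def per_order_stats(network, scheme: str = "strahler") -> OrderStats:
    """Mean diameter, length and count of vessel elements per order.

    Statistics are taken over *elements* (maximal same-order chains):
    element length is the sum of member segment lengths and element
    diameter the length-weighted mean, matching how vessels are delimited
    in intravital measurements.  ``n_bifurcations`` counts bifurcations at
    the distal end of segments of each order.
    """
    net, mask = as_network_and_mask(network)
    orders = _orders_for(network, scheme)
    vessels = element_partition(network, scheme=scheme, orders=orders)
    omax = max(v.order for v in vessels)
    rows = []
    ch = net.children
    for o in range(1, omax + 1):
        group = [v for v in vessels if v.order == o]
        if not group:
            raise ValueError(f"orders are not contiguous: no elements of order {o}")
        dias = np.array([v.diameter for v in group], dtype=float)
        lens = np.array([v.length for v in group], dtype=float)
        segs_o = np.flatnonzero(mask & (orders == o))
        nbif = sum(
            1
            for i in segs_o
            if sum(1 for c in ch[i] if c >= 0 and mask[c]) == 2
        )
        rows.append(
            {
                "order": o,
                "mean_diameter_um": float(np.mean(dias)) if net.diameter_um is not None else np.nan,
                "sd_diameter_um": float(np.std(dias, ddof=0)) if net.diameter_um is not None else np.nan,
                "mean_length_mm": float(np.mean(lens)),
                "sd_length_mm": float(np.std(lens, ddof=0)),
                "n_elements": len(group),
                "n_bifurcations": int(nbif),
            }
        )
    table = pd.DataFrame(rows).set_index("order")
    return OrderStats(scheme=scheme, table=table)


# ---------------------------------------------------------------------------
# Horton's law
# ---------------------------------------------------------------------------


@dataclass
class HortonResult:
    """Horton ratios from one calculation method.

    Ratios are reported > 1: R_D and R_L as 10**slope of the
    increasing-with-order fits, R_B as 10**|slope| of the (decreasing)
    element-count fit.  ``r_squared`` maps quantity -> fit R^2.
    """

    method: int
    r_d: float
    r_l: float
    r_b: float
    r_squared: dict


_QUANTITIES = ("diameter", "length", "count")


def _order_table(network, scheme: str) -> pd.DataFrame:
    t = per_order_stats(network, scheme).table
    return pd.DataFrame(
        {
            "order": t.index.to_numpy(),
            "diameter": t["mean_diameter_um"].to_numpy(),
            "length": t["mean_length_mm"].to_numpy(),
            "count": t["n_elements"].to_numpy(dtype=float),
        }
    )


def _fit(orders: np.ndarray, values: np.ndarray) -> Tuple[float, float]:
    """Least-squares slope of log10(values) vs order, with R^2."""
    if len(np.unique(orders)) < 2:
        raise ValueError("Horton fits require at least two orders")
    res = stats.linregress(orders, np.log10(values))
    return float(res.slope), float(res.rvalue**2)


def horton_ratios(networks, scheme: str = "strahler", method: int = 1) -> HortonResult:
    """Horton ratios for one or more networks.

    Method 1 pools the per-network per-order means into a single fit;
    method 2 averages per-network slopes (R^2 reported as the mean);
    method 3 averages the per-order means across networks first and fits
    the averaged profile.
    """
    if isinstance(networks, (Network, NetworkView)):
        networks = [networks]
    tables = [_order_table(n, scheme) for n in networks]
    if method not in (1, 2, 3):
        raise ValueError("method must be 1, 2 or 3")

    slopes: dict = {}
    r2: dict = {}
    if method == 1:
        pooled = pd.concat(tables, ignore_index=True)
        for q in _QUANTITIES:
            slopes[q], r2[q] = _fit(pooled["order"].to_numpy(), pooled[q].to_numpy())
    elif method == 2:
        per = {q: [] for q in _QUANTITIES}
        per_r2 = {q: [] for q in _QUANTITIES}
        for t in tables:
            for q in _QUANTITIES:
                s, r = _fit(t["order"].to_numpy(), t[q].to_numpy())
                per[q].append(s)
                per_r2[q].append(r)
        for q in _QUANTITIES:
            slopes[q] = float(np.mean(per[q]))
            r2[q] = float(np.mean(per_r2[q]))
    else:
        pooled = pd.concat(tables, ignore_index=True)
        averaged = pooled.groupby("order", as_index=False).mean()
        for q in _QUANTITIES:
            slopes[q], r2[q] = _fit(averaged["order"].to_numpy(), averaged[q].to_numpy())

    return HortonResult(
        method=method,
        r_d=float(10.0 ** slopes["diameter"]),
        r_l=float(10.0 ** slopes["length"]),
        r_b=float(10.0 ** abs(slopes["count"])),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# Box-counting fractal dimension
# ---------------------------------------------------------------------------


@dataclass
class FractalResult:
    """Box-counting table and fitted fractal dimension.

    ``table`` has one row per scale s (0..max): scale factor sf = 2**s,
    occupied box count N, and the per-scale dimension log N / log sf (0 at
    s = 0 where the single bounding cuboid trivially contains everything).
    ``slope`` is the least-squares fit of log N vs log sf over s >= 1;
    ``best_scale`` flags the scale whose 3-point local fit is strongest
    (R^2 above ``best_r2_threshold``), the scale at which the per-scale
    dimension is most representative.
    """

    table: pd.DataFrame
    slope: float
    r_squared: float
    best_scale: int


def fractal_dimension(
    network, max_scale: int = 6, best_r2_threshold: float = 0.95
) -> FractalResult:
    """Box-counting dimension of the network centreline.

    The minimum axis-aligned bounding cuboid (edge lengths L0x, L0y, L0z)
    is subdivided at scale s into 2**s boxes per dimension (cuboids, not
    cubes); a box is occupied iff a segment centreline passes through it.
    Occupancy is exact: each centreline is cut at every grid-plane crossing
    and interval midpoints identify the traversed cells.
    """
    net, mask = as_network_and_mask(network)
    ids = np.flatnonzero(mask)
    if len(ids) == 0:
        raise ValueError("fractal_dimension requires at least one segment")
    pts = np.vstack([net.proximal[ids], net.distal[ids]])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    extent = np.maximum(hi - lo, 1.0e-9)

    rows = [{"scale": 0, "scale_factor": 1, "n_boxes": 1, "dimension": 0.0}]
    p0 = net.proximal[ids]
    p1 = net.distal[ids]
    for s in range(1, max_scale + 1):
        k = 2**s
        edge = extent / k
        occupied = set()
        planes = np.arange(1, k) / k  # interior grid planes, unit coords
        for i in range(len(ids)):
            a = (p0[i] - lo) / extent
            b = (p1[i] - lo) / extent
            cuts = [0.0, 1.0]
            for dim in range(3):
                da = b[dim] - a[dim]
                if abs(da) > 1.0e-15:
                    t = (planes - a[dim]) / da
                    cuts.extend(t[(t > 0.0) & (t < 1.0)].tolist())
            t = np.unique(np.asarray(cuts))
            mids = a[None, :] + (0.5 * (t[:-1] + t[1:]))[:, None] * (b - a)[None, :]
            cells = np.clip((mids * k).astype(np.int64), 0, k - 1)
            lin = (cells[:, 0] * k + cells[:, 1]) * k + cells[:, 2]
            occupied.update(np.unique(lin).tolist())
        n_boxes = len(occupied)
        rows.append(
            {
                "scale": s,
                "scale_factor": k,
                "n_boxes": n_boxes,
                "dimension": float(np.log(n_boxes) / np.log(k)) if n_boxes > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)

    log_sf = np.log10(table["scale_factor"].to_numpy(dtype=float)[1:])
    log_n = np.log10(table["n_boxes"].to_numpy(dtype=float)[1:])
    res = stats.linregress(log_sf, log_n)
    slope, r2 = float(res.slope), float(res.rvalue**2)

    # best scale: the finest interior scale whose 3-point local fit of
    # log N vs log sf still clears the R^2 threshold -- the most resolved
    # estimate before box counts saturate on the centreline
    sf_all = np.log10(table["scale_factor"].to_numpy(dtype=float))
    n_all = np.log10(np.maximum(table["n_boxes"].to_numpy(dtype=float), 1.0))
    window_r2 = {}
    for s in range(1, max_scale):
        w = stats.linregress(sf_all[s - 1 : s + 2], n_all[s - 1 : s + 2])
        window_r2[s] = float(w.rvalue**2)
    strong = [s for s, wr2 in window_r2.items() if wr2 >= best_r2_threshold]
    if strong:
        best_scale = max(strong)
    else:
        best_scale = max(window_r2, key=window_r2.get)
    return FractalResult(table=table, slope=slope, r_squared=r2, best_scale=int(best_scale))


# ---------------------------------------------------------------------------
# Murray exponent
# ---------------------------------------------------------------------------


def murray_exponent_fit(
    diameters_um, flows_nl_s, min_diameter_um: Optional[float] = None
) -> Tuple[float, float]:
    """Slope of log(flow) vs log(diameter) over vessel segments.

    Returns ``(slope, r_squared)``.  ``min_diameter_um`` optionally drops
    small vessels first (a 20 um cutoff mimics in-vivo measurement limits).
    """
    d = np.asarray(diameters_um, dtype=float)
    q = np.asarray(flows_nl_s, dtype=float)
    if np.any(d <= 0) or np.any(q <= 0):
        raise ValueError("diameters and flows must be strictly positive")
    if min_diameter_um is not None:
        keep = d >= min_diameter_um
        d, q = d[keep], q[keep]
    if len(d) < 2:
        raise ValueError("need at least two segments to fit the exponent")
    if len(d) == 2:
        slope = float(np.log(q[1] / q[0]) / np.log(d[1] / d[0]))
        return slope, 1.0
    res = stats.linregress(np.log10(d), np.log10(q))
    return float(res.slope), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# Subtree sampling
# ---------------------------------------------------------------------------


@dataclass
class SubtreeSample:
    """A complete downstream tree whose inlet diameter falls in a band."""

    root_id: int
    inlet_diameter_um: float
    member_ids: np.ndarray

    def view(self, network: Network) -> NetworkView:
        mask = np.zeros(network.n_segments, dtype=bool)
        mask[self.member_ids] = True
        sub = NetworkView(network, mask)
        return sub


def sample_subtrees(network: Network, diameter_band: Tuple[float, float]) -> List[SubtreeSample]:
    """All maximal subtrees whose inlet diameter lies in ``diameter_band``.

    A segment qualifies iff its own diameter is inside [lo, hi] and its
    parent's diameter is above the band (or it is the network root), so
    samples are mutually disjoint on trees with parent-to-daughter
    non-increasing diameters.  Overlapping nested picks are additionally
    skipped explicitly, keeping disjointness unconditional.
    """
    if network.diameter_um is None:
        raise ValueError("sample_subtrees requires diameters")
    lo, hi = diameter_band
    if not (0 < lo < hi):
        raise ValueError("diameter band must satisfy 0 < lo < hi")
    d = network.diameter_um
    taken = np.zeros(network.n_segments, dtype=bool)
    out: List[SubtreeSample] = []
    for i in network.topological_order():
        if taken[i]:
            continue
        p = network.parent[i]
        if lo <= d[i] <= hi and (p < 0 or d[p] > hi):
            members = network.subtree_ids(i)
            taken[members] = True
            out.append(
                SubtreeSample(
                    root_id=int(i), inlet_diameter_um=float(d[i]), member_ids=members
                )
            )
    return out
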