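"""Serialization: network JSON (lossless round-trip), segment-table CSV,
and legacy-ASCII VTK polydata export for 3D viewers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import GenerationConfig, Network, build_network

__all__ = ["write_network", "read_network", "write_csv", "read_csv", "export_vtk"]

_FORMAT = "vasctree-network"
_VERSION = 1

_FIELDS = ("diameter_um", "flow_nl_s", "p_in", "p_out", "hd", "ht", "mu_rel")

CSV_COLUMNS = [
    "id",
    "parent_id",
    "x0",
    "y0",
    "z0",
    "x1",
    "y1",
    "z1",
    "diameter_um",
    "flow_nl_s",
    "hd",
    "ht",
    "strahler",
    "centrifugal",
]


def write_network(path: Union[str, Path], network: Network) -> None:
    """Write a network as JSON; numeric fields survive bit-identically."""
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "config": None if network.config is None else network.config.to_dict(),
        "semi_axes": None if network.semi_axes is None else list(network.semi_axes),
        "segments": {
            "proximal": network.proximal.tolist(),
            "distal": network.distal.tolist(),
            "parent": network.parent.tolist(),
        },
    }
    for name in _FIELDS:
        arr = getattr(network, name)
        if arr is not None:
            doc["segments"][name] = arr.tolist()
    Path(path).write_text(json.dumps(doc))


def read_network(path: Union[str, Path]) -> Network:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed network JSON at line {exc.lineno}: {exc.msg}") from exc
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a {_FORMAT} document")
    seg = doc["segments"]
    kwargs = {name: np.asarray(seg[name]) for name in _FIELDS if name in seg}
    config = None if doc.get("config") is None else GenerationConfig.from_dict(doc["config"])
    return Network(
        np.asarray(seg["proximal"]),
        np.asarray(seg["distal"]),
        np.asarray(seg["parent"]),
        config=config,
        semi_axes=None if doc.get("semi_axes") is None else tuple(doc["semi_axes"]),
        **kwargs,
    )


def write_csv(path: Union[str, Path], network: Network) -> None:
    """Segment table CSV (root row has empty parent_id)."""
    from . import metrics

    df = network.to_dataframe()
    df["parent_id"] = df["parent_id"].astype(object)
    df.loc[df["parent_id"] == -1, "parent_id"] = ""
    try:
        df["strahler"] = metrics.strahler_orders(network)
        df["centrifugal"] = metrics.centrifugal_orders(network)
    except Exception:
        pass
    cols = [c for c in CSV_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_csv(path: Union[str, Path], **kwargs) -> Network:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    return build_network(df, **kwargs)


def export_vtk(network: Network, path: Union[str, Path], color_field: str = "diameter") -> None:
    """Legacy ASCII VTK polydata: one polyline cell per segment with a
    per-cell scalar array (``diameter``, ``hd``, ``flow``, ``strahler`` or
    ``centrifugal``) for color-mapping in standard viewers."""
    from . import metrics

    fields = {
        "diameter": lambda: network.diameter_um,
        "hd": lambda: network.hd,
        "ht": lambda: network.ht,
        "flow": lambda: network.flow_nl_s,
        "strahler": lambda: metrics.strahler_orders(network).astype(float),
        "centrifugal": lambda: metrics.centrifugal_orders(network).astype(float),
    }
    if color_field not in fields:
        raise ValueError(f"unknown color field {color_field!r}; choose from {sorted(fields)}")
    values = fields[color_field]()
    if values is None:
        raise ValueError(f"field {color_field!r} is not assigned on this network")

    n = network.n_segments
    lines = [
        "# vtk DataFile Version 3.0",
        "vasctree arteriolar network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {2 * n} float",
    ]
    for i in range(n):
        lines.append(" ".join(f"{v:.9g}" for v in network.proximal[i]))
        lines.append(" ".join(f"{v:.9g}" for v in network.distal[i]))
    lines.append(f"LINES {n} {3 * n}")
    for i in range(n):
        lines.append(f"2 {2 * i} {2 * i + 1}")
    lines.append(f"CELL_DATA {n}")
    lines.append(f"SCALARS {color_field} float 1")
    lines.append("LOOKUP_TABLE default")
    for v in values:
        lines.append(f"{float(v):.9g}")
    Path(path).write_text("\n".join(lines) + "\n")
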