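"""Packaged generation configurations and the shared illustration fixture.

The presets cover the rat-skeletal-muscle conditions the generator was
designed around:

* ``control`` / ``gluteus`` — gluteus-maximus-like wide flat tissue
  (Rx:Ry:Rz = 6:5:1), terminal flow 0.12 nL/s (terminal arterioles of
  ~9 um via the diameter-flow relation), 30 mmHg inlet-to-terminal
  gradient, 1.8 mm^3 perfused per terminal, Murray exponent 2.63,
  300 bifurcations.  The gluteus configuration derives from an inlet
  vessel diameter of ~130 um; that value is documentation, not an
  enforced constraint.
* ``tissueA`` / ``tissueB`` / ``tissueC`` — the three 700-bifurcation
  shape studies: wide/flat 6:5:1 with a tip inlet, narrow 20:5:3 with a
  tip inlet, and the same narrow shape fed from the side of the tissue.
* ``tissueI``..``tissueIV`` — size studies around the control tissue:
  larger perfused volume per terminal (5.3 mm^3), more bifurcations
  (900), and the extreme small/large volumes (Vperf 1.8e-3 and
  1.8e+6 mm^3).
* ``spinotrapezius`` — long narrow muscle, terminal flow 0.026 nL/s
  (terminal arterioles of ~5 um), 0.0036 mm^3 per terminal (190 um
  inter-arteriolar spacing).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict

import numpy as np

from .model import GenerationConfig, Network

__all__ = ["PRESETS", "get_preset", "demo_network"]


def _cfg(**kw) -> GenerationConfig:
    base = dict(
        n_bif=300,
        q_perf=0.12,
        dp_tot=30.0,
        v_perf=1.8,
        ratios=(6.0, 5.0, 1.0),
        murray_gamma=2.63,
        exp_val=0.0,
        inlet="tip-x",
        seed=0,
    )
    base.update(kw)
    return GenerationConfig(**base)


PRESETS: Dict[str, GenerationConfig] = {
    "control": _cfg(),
    "gluteus": _cfg(),
    "tissueA": _cfg(n_bif=700),
    "tissueB": _cfg(n_bif=700, ratios=(20.0, 5.0, 3.0)),
    "tissueC": _cfg(n_bif=700, ratios=(20.0, 5.0, 3.0), inlet="side-y"),
    "tissueI": _cfg(v_perf=5.3),
    "tissueII": _cfg(n_bif=900),
    "tissueIII": _cfg(v_perf=1.8e-3),
    "tissueIV": _cfg(v_perf=1.8e6),
    "spinotrapezius": _cfg(
        n_bif=700, q_perf=0.026, v_perf=0.0036, ratios=(20.0, 5.0, 3.0)
    ),
}


def get_preset(name: str, **overrides) -> GenerationConfig:
    """A copy of a named preset, with optional field overrides."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
    return replace(cfg, **overrides) if overrides else replace(cfg)


def demo_network() -> Network:
    """Deterministic 9-segment illustration tree used across the test suite.

    Hand-assigned Strahler orders cover 1, 2 and 3 and include a parent
    taking the higher of two unequal daughter orders (a (1,2) -> 2 case),
    so the order-2 parent chains with its order-2 daughter into one vessel
    element.

    Layout (zero-based ids)::

        0 root (order 3)
        +-- 1 (order 2) -- terminals 2, 3
        +-- 4 (order 2, unequal daughters) -- terminal 5
                                           -- 6 (order 2) -- terminals 7, 8
    """
    proximal = np.array(
        [
            [0.0, 0.0, 0.0],   # 0 root
            [1.0, 0.0, 0.0],   # 1
            [1.6, 0.5, 0.0],   # 2
            [1.6, 0.5, 0.0],   # 3
            [1.0, 0.0, 0.0],   # 4
            [1.8, -0.7, 0.0],  # 5
            [1.8, -0.7, 0.0],  # 6
            [2.6, -1.0, 0.0],  # 7
            [2.6, -1.0, 0.0],  # 8
        ]
    )
    distal = np.array(
        [
            [1.0, 0.0, 0.0],
            [1.6, 0.5, 0.0],
            [2.1, 1.1, 0.0],
            [2.2, 0.3, 0.0],
            [1.8, -0.7, 0.0],
            [2.2, -0.2, 0.0],
            [2.6, -1.0, 0.0],
            [3.3, -0.7, 0.0],
            [3.2, -1.5, 0.0],
        ]
    )
    parent = np.array([-1, 0, 1, 1, 0, 4, 4, 6, 6])
    diameter = np.array([60.0, 35.0, 18.0, 20.0, 42.0, 16.0, 34.0, 19.0, 17.0])
    flow = np.array([0.60, 0.24, 0.12, 0.12, 0.36, 0.12, 0.24, 0.12, 0.12])
    return Network(proximal, distal, parent, diameter_um=diameter, flow_nl_s=flow)
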