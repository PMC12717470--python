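# vasctree

Synthesis and morphometric analysis of three-dimensional branching
arteriolar networks in ellipsoidal tissue volumes.

Arterioles control where blood goes inside a tissue, but quantitative maps
of whole arteriolar trees are scarce: intravital microscopy covers small
windows and a narrow diameter range. `vasctree` grows *synthetic* arteriolar
trees that are statistically realistic for rodent skeletal muscle, so that
questions about how tissue shape and size sculpt the microcirculation can
be asked computationally. It is aimed at microcirculation researchers,
tissue engineers and modellers who need a full geometric + hemodynamic
description of an arteriolar bed (positions, diameters, flows, pressures,
hematocrits) down to terminal arterioles.

## The model

Networks are built by **constrained constructive optimization (CCO)**: one
terminal arteriole is added per iteration inside an axis-aligned ellipsoid
whose volume grows by `Vperf` (tissue volume perfused per terminal) each
step, with semi-axes in user ratios `Rx:Ry:Rz`. A perfusion point is drawn
uniformly in the tissue — at least `d_thresh = sqrt(pi r^2 / n_term)` from
existing vessels (`r` the equal-volume-sphere radius) — and connected to one
of its 12 nearest segments. The bifurcation position is optimized over a
66-node barycentric lattice spanning the triangle (segment endpoints, new
point), scoring every candidate by **total intravascular blood volume** and
rejecting geometries whose tubes collide. The cheapest valid candidate is
adopted.

Hemodynamics close the model. Every terminal carries the same flow
`Qperf`, so segment flow is `Q_i = N_i * Qperf` with `N_i` the downstream
terminal count. Murray's law `Q ∝ d^γ` (default γ = 2.63, rat gluteus
maximus) fixes relative diameters, `d_i = d_ref * N_i^(1/γ)`, and the
reference diameter follows from requiring the mean inlet-to-terminal
Poiseuille pressure drop to equal `dPtot` (default 30 mmHg, relative blood
viscosity 3 during construction). After construction, discharge hematocrit
is propagated from the inlet (H_D = 0.4) through every bifurcation with
the empirical logit phase-separation law, tube hematocrit follows the
Fahraeus relation, and apparent viscosity the in-vitro diameter/hematocrit
law.

The analysis suite implements the standard morphometry toolkit:
Strahler and centrifugal ordering with vessel *elements* (maximal
same-order chains), per-order statistics, Horton ratios (`R_D`, `R_L`,
`R_B`) by three literature methods, box-counting fractal dimension over a
cuboid hierarchy, Murray-exponent fitting, perfusion-heterogeneity
distributions (fractional daughter flows), subtree sampling by
inlet-diameter band, and an observability filter (`expVal`) that hides
daughters thinner than a percentage of their parent to mimic imaging
limits.

## Worked example

```python
import vasctree as vt

cfg = vt.get_preset("control", seed=1)   # gluteus-maximus-like tissue, 300 bifurcations
net = vt.generate(cfg)

print("segments:", net.n_segments, " terminals:", net.n_terminals)
print("diameters: %.1f-%.1f um" % (net.diameter_um.min(), net.diameter_um.max()))
print("blood volume: %.3f mm^3" % vt.total_blood_volume(net))
slope, r2 = vt.murray_exponent_fit(net.diameter_um, net.flow_nl_s)
print("Murray exponent: %.3f (R^2=%.3f)" % (slope, r2))
h = vt.horton_ratios([net], "strahler", method=1)
print("Horton ratios: R_D=%.2f R_L=%.2f R_B=%.2f" % (h.r_d, h.r_l, h.r_b))
```

prints

```
segments: 601  terminals: 301
diameters: 10.3-90.3 um
blood volume: 0.136 mm^3
Murray exponent: 2.630 (R^2=1.000)
Horton ratios: R_D=1.60 R_L=2.00 R_B=4.11
```

The 301 terminal arterioles (~10 um, each perfusing 1.8 mm^3) hang off a
90 um inlet vessel; the diameter-flow fit returns exactly the configured
Murray exponent, and successive Strahler orders are ~1.6x wider, ~2x
longer and ~4x less numerous — the geometric progressions (Horton's law)
reported for real arteriolar beds.

The same operations are available from a shell:

```sh
vasctree generate --preset tissueA --seed 1 --out netA.json
vasctree analyze --in netA.json --scheme strahler --report orders.csv
vasctree fractal --in netA.json --max-scale 6
vasctree subtrees --in netA.json --band 40,60
vasctree export-vtk --in netA.json --out netA.vtk --color-field hd
```

Presets cover the tissue shapes (`tissueA`/`tissueB`/`tissueC`), the
size-study conditions (`tissueI`–`tissueIV`) and the two validation
muscles (`gluteus`, `spinotrapezius`).

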