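# Methods

This note documents the model implemented by `vasctree`, the defaults and
why they were chosen, the numerical decisions taken where the procedure
was genuinely open, and what the package's tests do and do not establish.

## Growth model

A network is a rooted binary tree of straight cylindrical segments inside
an axis-aligned ellipsoid centred at the origin (x = width `Rx`, y =
length `Ry`, z = height `Rz`). Growth is constrained constructive
optimization: starting from a single inlet arteriole (from a surface
anchor to a uniformly sampled interior point, in a domain sized for one
terminal), each iteration

1. **inflates** the tissue by `Vperf` and rescales the semi-axes about the
   origin. Existing vessel coordinates are rescaled isotropically with the
   tissue (factor `((t+1)/t)^(1/3)` at iteration t). This keeps the inlet
   on the tissue surface and makes the tree self-similar under growth;
   without it, trunk vessels would keep the lengths they had when the
   tissue was a few hundred times smaller, the inlet would end up deep in
   the interior, and the per-order length progression (Horton's length
   law) collapses — we verified R^2 drops from ~0.94 to ~0.27.
2. **samples** a perfusion point uniformly in the ellipsoid, rejecting
   points closer than `d_thresh = sqrt(pi r^2 / n_term)` to any segment,
   where `r` is the radius of the sphere with the tissue's volume. The
   printed form of this threshold is dimensionally ambiguous (it reads as
   an area); the square root is the only reading with length units and
   reduces to the classical 2D supporting-circle rule, so it is used and
   flagged here. After every 50 failed draws the threshold is relaxed to
   90%, guaranteeing termination while leaving the marginal distribution
   of accepted points uniform.
3. **connects** the point to one of its `candidate_count = 12` nearest
   segments. For each target the triangle (segment endpoints, new point)
   is discretised into a barycentric lattice of `triangle_points = 66`
   nodes (the 11th triangular number: 11 nodes per edge — the only regular
   lattice with that count). Every node is scored as a tentative
   bifurcation by the total blood volume of the re-sized tree; lattice
   nodes that would create zero-length pieces are skipped, and a collinear
   (degenerate) triangle is widened by a small perpendicular offset of the
   apex so a 2D search space survives.
4. **adopts** the globally cheapest candidate that passes the overlap
   test (axis-to-axis distance of non-adjacent tubes at least the sum of
   their radii, using the re-sized Murray diameters). Candidates are
   ranked by volume with a deterministic tie-break (target id, node
   index); overlap is only tested down the ranking until the first valid
   candidate, which is the one adopted in any case. If every candidate of
   a perfusion point is invalid the point is resampled (up to 20 times)
   before the run aborts.

All stochastic draws come from one seeded generator; a run is a pure
function of its configuration.

### Scoring in O(1) per candidate

With terminal flows fixed (below), blood volume is
`V = (pi/4) d_ref^2 * sum_i L_i N_i^(2/gamma)` and the reference diameter
satisfies `d_ref^4 ∝ sum_i L_i N_i^(2-4/gamma)` (mean terminal pressure
drop). Splitting target `j` changes only `j`'s own terms, its ancestors'
counts (`N -> N+1`), and adds three new pieces, so both sums are updated
from per-step ancestor prefix sums in constant time per lattice node.
This is why a 700-bifurcation network generates in seconds rather than
the hours a naive re-solve per candidate would cost.

## Hemodynamics

Three constraints size the tree:

- every terminal arteriole carries `Qperf` exactly, so `Q_i = N_i Qperf`
  (Kirchhoff conservation is exact by construction);
- Murray's law `Q = Qperf (d/d_ref)^gamma` holds across all segments,
  giving `d_i = d_ref N_i^(1/gamma)`;
- the **mean** inlet-to-terminal Poiseuille pressure drop equals `dPtot`,
  which fixes `d_ref` (closed form at constant relative viscosity 3;
  a damped fixed point when the empirical viscosity law is requested).

A word on why the pressure condition is a mean rather than a per-terminal
boundary condition: equal outlet pressures at every terminal, combined
with Murray diameters, would force sibling terminal flows to satisfy
`L1 Q1^(1-4/γ) = L2 Q2^(1-4/γ)` — with γ = 2.63 a 10% path-length
difference already produces a ~20% flow difference, incompatible with a
1% terminal-flow tolerance on any asymmetric tree. Anchoring the *mean*
drop keeps terminal flows exact and the overall gradient as prescribed;
individual terminal outlet pressures then scatter around `P_in - dPtot`.
Pressures are reported per segment by root-down propagation
(`dP_i = R_i Q_i`, inlet at `dPtot`, so the mean terminal outlet is 0); a
conventional sparse Poiseuille solver with Dirichlet boundaries is
provided separately (`poiseuille_solve`) for analysis and cross-checks.

After construction, rheology is evaluated one-way (it does not feed back
into flows): discharge hematocrit propagates from the inlet (`H_D = 0.4`)
through each bifurcation with the empirical logit phase-separation law
(parameters from the parent diameter, daughter diameters and parent
hematocrit; plasma-skimming cutoff at fractional flow `0.4/D_parent`;
RBC flux renormalised to conserve exactly and capped at packed cells);
tube hematocrit follows the empirical Fahraeus relation
`H_T/H_D = H_D + (1-H_D)(1 + 1.7 e^(-0.415 d) - 0.6 e^(-0.011 d))`; and
per-segment relative viscosity uses the in-vitro diameter/hematocrit law
(the in-vitro rather than in-vivo variant, matching the cited constants;
the mode is switchable). Plasma viscosity is 1.2 mPa·s; only viscosity
ratios matter for the flow solution under pressure anchoring.

## Parameters that matter

| parameter | default | units | meaning |
|---|---|---|---|
| `n_bif` | — | – | bifurcations in the finished tree (density/size) |
| `q_perf` | 0.12 | nL/s | terminal arteriolar flow (≈9 um terminals) |
| `dp_tot` | 30 | mmHg | inlet-to-terminal pressure gradient |
| `v_perf` | 1.8 | mm^3 | tissue volume per terminal (inverse density) |
| `ratios` | 6:5:1 | – | tissue width:length:height |
| `murray_gamma` | 2.63 | – | diameter-flow exponent (rat gluteus maximus) |
| `exp_val` | 0 | % | observability filter; 0 = complete network |
| `inlet` | tip-x | – | surface anchor (`tip-x` pole or `side-y` equator) |
| `candidate_count` | 12 | – | nearest-segment shortlist per new point |
| `triangle_points` | 66 | – | bifurcation lattice nodes |

Defaults approximate rat skeletal muscle; the `spinotrapezius` preset
switches to 0.026 nL/s terminals and 0.0036 mm^3 per terminal.

## Analyses

**Ordering.** Strahler: terminals are order 1; a parent takes the common
daughter order + 1, else the higher daughter order. Centrifugal: the root
chain is order 1, incrementing at every bifurcation (root order 1, not 0,
so order axes start at 1; switchable by subtracting 1). On an
`expVal`-filtered view, a parent with one visible daughter continues that
daughter's chain. Statistics are reported over *elements* — maximal
same-order chains — with element length the sum of member lengths and
element diameter the length-weighted mean; "number of vessels per order"
counts elements (the element definition exists precisely to make those
counts comparable to intravital vessel counts; segment-level statistics
remain available through the segment arrays).

**Horton ratios.** Least-squares slopes of log10(per-order mean) vs
order; `R_D`, `R_L` as `10^slope`, `R_B` as `10^|slope|` (ratios reported
> 1). Method 1 pools per-network per-order points, method 2 averages
per-network slopes, method 3 fits the replicate-averaged profile. The
three coincide on a single network. Method 3 is the fit quoted for
"strength of Horton's law" on replicate sets, since the averaged profile
is what a mean-per-order figure displays; single-network top-order
elements (one element whose length is set by where the two top subtrees
merge) are erratic and mostly affect method 1.

**Fractal dimension.** The minimum axis-aligned bounding cuboid is
subdivided at scale s into `2^s` boxes per dimension (cuboids, not cubes,
so flat tissues keep aspect); a box is occupied iff a segment centreline
crosses it, computed exactly by cutting each centreline at grid-plane
crossings. Reported are per-scale `D = log N / log 2^s`, the fitted slope
over all scales, and a best-scale flag: the finest interior scale whose
3-point local fit keeps R^2 ≥ 0.95 — the most resolved scale before the
counts saturate on the (zero-thickness) centreline set. Thickness of
vessels is ignored; centreline occupancy is the minimal consistent
choice.

**Perfusion heterogeneity.** Every bifurcation contributes both
daughters' fractional flows, so the distribution mean is exactly 0.5 and
it is symmetric by construction. In generated trees the distribution in
the smallest daughter-diameter bins is wider than in the largest (fans
out toward extreme splits), but the relation is not monotone across all
bins: mid-sized trunk continuations paired with single-terminal side
branches concentrate extreme fractions at mid/large parent diameters.

**Subtrees.** All maximal segments whose diameter falls in a band (e.g.
50 ± 10 um) with parent above the band, together with their complete
downstream trees. Diameters are non-increasing root-to-leaf here, which
makes samples disjoint; disjointness is enforced regardless.

## What the generator does and does not emulate

Generated networks reproduce, at rat-skeletal-muscle parameter values,
the geometric progressions across Strahler orders (diameter ratio ~1.6,
count ratio ~3.9), strong log-linear Horton fits, an exact Murray
exponent, box-counting dimensions ~2.1–2.4 (space-filling trees in flat
ellipsoids), terminal diameters near 9–10 um and discharge hematocrits
clustered around the inlet value. They do **not** emulate: terminal-flow
variability (all terminals are identical by assumption), regional
differences in microvessel density, vessel curvature (segments are
straight), venous/capillary compartments, pulsatility, or any feedback of
hematocrit on flow. Passing tests therefore demonstrate internal
consistency and agreement with published summary statistics of synthetic
trees — not fidelity to any individual measured network.

Two quantitative caveats found while validating:

- *Tube-hematocrit uniformity across orders.* Within 50 um subtrees the
  Fahraeus ratio rises ~15% between terminal (≈10 um) and inlet (≈50 um)
  diameters, so per-order mean `H_T` cannot be flat: its coefficient of
  variation across orders is ≈0.06–0.09 in our trees (discharge
  hematocrit: ≈0.03–0.06). A bound of 0.05 for both quantities is
  attainable only for `H_D`.
- *Centrifugal-order fits.* With the order incrementing at every
  bifurcation, 700-bifurcation trees reach centrifugal orders ~30–40, so
  log-linear fits across all centrifugal orders are shallow; Strahler
  fits are the meaningful ones at this scale.

## Numerical choices

- Units: mm / um / nL/s / mmHg / mPa·s / mm^3, converted only in
  `units.py`.
- Equal candidate volumes break ties by (target id, lattice-node index);
  the argmin is therefore order-independent and a run is reproducible
  bit-for-bit from its seed.
- Lattice nodes producing pieces shorter than 1e-9 mm are invalid;
  overlap clearance is tested strictly (< 0 mm).
- The terminal-flow tolerance (1%, `terminal_tolerance`) is verified on
  every finished network; with topological flows the residual is zero to
  round-off, and `converge_diameters` raises if it ever is not.
- Diameter convergence under the empirical viscosity law damps `d_ref`
  updates on the log scale (factor 0.5) and stops at a relative step of
  1e-12 (cap 200 sweeps).
- Degenerate inputs: single-segment networks are valid everywhere
  (order 1, one element, fractal table starts at N = 1); empty subtree
  samples are an empty list, not an error.

## Problem sizes used in the test suite

Unit tests run on hand-built fixtures and 200-bifurcation networks; the
morphometry reproduction uses five 700-bifurcation shape-A networks and
the acceptance script ten (the published protocol uses ten networks per
shape at 700 bifurcations; generation cost here is ~5 s per network, so
the full-scale protocol is affordable and preferred over scaled-down
surrogates wherever it is the condition of the published claim).
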