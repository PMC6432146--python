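# Methods

## Model and units

The polymer is a bead-spring chain in reduced units: bead diameter σ is the
length unit, ε = k\_BT = 1 the energy unit. Interactions:

| term | form | parameters | default |
|------|------|------------|---------|
| excluded volume | WCA, all bead pairs | ε, cutoff 2^{1/6}σ | ε = 1 |
| bond | FENE | k (ε/σ²), R₀ (σ) | k = 30, R₀ = 1.5 |
| bending | (κ/2)(θ−π)² per interior angle | κ (k\_BT/rad²) | κ = 10 |
| walls | WCA in wall-normal distance, both walls | — | off |

Bonded neighbors also interact through WCA (the standard Kremer–Grest
convention; the k = 30, R₀ = 1.5 pair is chosen exactly so that the combined
bond and core potentials make strand crossing energetically impossible,
which is what lets topology act as a conserved quantity). The equilibrium
bond length of the combined FENE+WCA potential is ≈ 0.97σ; chains are
constructed at that spacing.

dsDNA mapping: σ = 5 nm (effective diameter at ~0.15 M NaCl), 0.33 nm/bp,
hence round(5/0.33) = 15 bp per bead; the discrete worm-like-chain relation
κ ≈ l\_p/σ (k\_BT = 1) gives κ = 10 for l\_p = 50 nm. The mapping lives only
at I/O and reporting boundaries; engines run in reduced units.

Grafted terminal beads sit exactly in the wall planes and are excluded from
the wall potential (they are immobile, so the choice only affects reported
energies).

## Sampling

**Free chains — Monte Carlo.** Move mix (defaults 70/15/15): capped local
displacement (≤ 0.15σ), pivot (rotate one tail about a uniformly chosen
interior bead, random axis, angle uniform in ±π), and a crankshaft-type
rotation of an interior subchain about the axis through its two endpoint
beads (angle uniform in ±π; the pure reflection is the angle-π member).
The crankshaft stands in for the generalized end-bridging moves of the
original protocol, whose exact form is not public; ergodicity is supplied by
pivot + local. Pair energies for global moves use a sorted cell-hash over the
static beads (cell width = WCA cutoff), verified in tests to reproduce the
brute-force energy exactly. Pivot-dominated mixes equilibrate N = 1000
chains from a rod start in ~10⁵ attempted moves.

Topology-restricted mode re-classifies the chain after every *accepted*
pivot/crankshaft and reverts the move if the Δ\_p band changed. Capped local
moves cannot carry a bead through a strand (0.15σ cap against a ~0.9σ core
clearance) and are not individually re-checked; per-frame Δ\_p constancy is
asserted in the test suite instead.

**Wall-grafted chains — Langevin dynamics.** Grønbech-Jensen/Farago
discretization with m = 1, γ = 1, Δt = 0.01; terminal beads immobile.
Temperature is measured with the half-step (2GJ) velocity estimator, which
is free of the leading-order time-step bias — the test suite holds the mean
kinetic temperature to within 3 standard errors of k\_BT. Nonbonded forces
use a Verlet pair list (skin 0.4σ) rebuilt on displacement. γ and m are
conventional reduced-unit choices; only equilibrium properties are analyzed,
and those are γ-independent.

Both engines are bit-deterministic for a fixed seed and protocol.

## Knot identification

Knots are defined on closed curves, so open chains are closed first:

- **Grafted chains**: a polygonal semicircular arc in the plane of the
  end-to-end vector and an outward lateral direction, with radius grown
  geometrically (clearance-checked against the chain) until the arc cannot
  thread the configuration. Closure is unambiguous because the ends are
  pinned to the walls.
- **Free chains**: each end is extended along its direction away from the
  center of mass to 3× the chain extent, and the two far points are joined
  through a still more distant waypoint. The three anchor points can be
  frozen and reused so that repeated analyses of reduced chains see the
  same closure.

The closed polygon is reduced by KMT-style vertex elision (a vertex is
removed only if its spanning triangle is crossed by no other segment;
degenerate contacts are treated conservatively as blocking), which
preserves Δ\_p exactly and cuts vertex counts by an order of magnitude. The
reduced polygon is jittered by 10⁻⁶σ (seeded) to break constructed
degeneracies, projected along a seeded random direction (with perturb-retry
on tangencies or matched crossing depths), and its crossing diagram is
converted to the Alexander matrix: underpasses numbered along the curve,
generator arcs between consecutive underpasses, one row per crossing with
entries {1, −1} (over-strand incident) or {1/−t, −t/1, t−1} by crossing
sign. |det| of the (n−1)×(n−1) minor evaluates |Δ(t)| up to ±t^k; the
reciprocal-point product Δ\_p = |Δ(−1.1)·Δ(−1/1.1)| cancels the t^k
ambiguity (the same matrix polynomial is evaluated at t and 1/t). Bands of
±10% around the closed-form references {1, 9.0546, 25.0910, 227.1896}
assign the label; anything else is "other".

*Caveat:* the Alexander polynomial cannot distinguish 3₁#4₁ from certain
prime knots (e.g. 8₂₁) with the same Δ\_p. The production protocol would
additionally filter with the HOMFLY polynomial; here such rare mimics are
accepted as composite, which is documented rather than silently ignored.

## Knot localization

Boundary scan: remove beads one at a time from one end, starting with the
second monomer and keeping the terminal bead (which anchors the closure);
bridge the gap with the direct segment; re-classify after every removal.
The first classification that is neither the knot under analysis nor the
composite marks the boundary (the bead removed last). Four scans per frame
(both knots × both ends). Size = end − start (monomeric distance); position
= the arithmetic mean of the boundaries; d = pos(3₁) − pos(4₁), negative
when the trefoil is nearer the chain start. The scan steps one monomer at a
time deliberately — the classification sequence is not monotone, so
bisection would be unsound.

Free-chain scans hold the closing-arc anchors fixed for the whole analysis
and use the tolerant criterion: any Δ\_p outside all reference bands counts
as "still composite" (closure fluctuations are larger without walls).
Grafted-chain scans use the strict criterion. Frames that fail localization
are flagged and excluded from distributions but counted in the QC report; a
flagged fraction above 10% raises a quality warning.

## Synthetic configurations

Knot templates: unknot = circle; 3₁ = the standard trigonometric trefoil;
4₁ = a braid-closure-style parametrization (chosen because, unlike the
torus-style form, it does not wind about an axis, so open sub-arcs of it
stay figure-eight-knotted under straight-line extension of their ends).
Open arcs are obtained by excising a sub-arc of the closed template and are
screened exhaustively: a candidate survives only if it keeps its knot type
both under direct chord closure and under chord-line extension + radial
closure (the situation after splicing onto a straight backbone); survivors
are ranked by how smoothly the chord continues the end tangents. Arcs are
spliced into a straight backbone at the requested center fractions (window
centers corrected for the contour the knot consumes) and the path is
resampled at uniform bead spacing by sphere-polyline stepping. Overlapping
window requests nest the smaller knot inside the larger arc — the
intertwined start. Every construction is self-verified by classification;
the recorded `knot_spec` carries the realized bead regions.

Wall grafting rebuilds the tied chain from its knot spec, tilts it so the
end-to-end vector spans exactly the wall separation (shrinking knot spans,
then stretching bonds uniformly up to 8%, if slack is short), verifies no
bead crosses a wall, and relaxes with capped Metropolis moves under
topology verification. Default knot spans are ~40–80 beads — loose knots,
matching the weakly stretched regime.

## Free-energy analysis

P(d) is accumulated per run, normalized per run, and averaged over runs
with equal weights (runs are the independent unit); bins are centered on
d = 0. The default bin width is 5 monomers at the N = 1000 production
scale. F(d) = −k\_BT ln P(d), shifted so F = 0 at the d = 0 bin; empty bins
are NaN, never ±∞ (if the d = 0 bin is empty the shift falls back to the
global minimum and the profile is flagged). MD time series are smoothed
with a centered moving average (window 100 snapshots) before histogramming;
MC ensembles are histogrammed raw (no time axis exists).

Barrier extraction: on the connected valid range containing d = 0
(optionally median-filtered over 3 bins), the intertwined minimum is the
local minimum nearest d = 0 (boundary bins count as extremum candidates);
per side, the first maximum beyond it and the lowest minimum beyond that
maximum give Δ₁→₃ = F(max) − F(min₁) and Δ₁→₂ = F(max) − F(min₂), reported
per side and side-averaged. Δ₁→₂ is implemented as the barrier seen from
the separated state (max minus separated minimum). Monotone profiles yield
zeros with a `no_barrier` flag.

Two documented options support sparsely sampled (desk-scale) profiles:

- `fill_empty` in `extract_barriers`: empty bins between populated ones get
  the free energy of half the smallest observed bin probability — a
  never-visited transition region is at least that unlikely. This turns an
  undefined barrier into a finite lower-confidence estimate; it can only
  underestimate a barrier, and preserves monotone trends across conditions
  sampled with the same protocol.
- `symmetrize` in `distance_distribution`: averages P(d) with P(−d).
  Neither knot has a preferred side, so the equilibrium distribution is
  exactly even in d; enforcing the symmetry removes the start-side bias
  that production-scale run averaging removes statistically.

Knot-size distributions are summarized by a two-state (small/grown) split
with an Otsu threshold, flagged `single_state` when the state means are not
separated beyond the pooled spread. Persistence length is fitted from
⟨cos θ(s)⟩ = exp(−s·b/l\_p) over s ∈ [1, 20] bonds (b = measured mean bond
length); end-to-end statistics carry block-averaged standard errors.

## What the desk-scale tests do and do not show

The test suite runs the full pipeline at reduced problem sizes: N = 400 for
the persistence-length fit, N = 1000 with ~5×10⁵ MC moves for chain
dimensions, N = 200–300 grafted chains with 3×10⁵–10⁶ MD steps, ensembles
of tens of frames. At these sizes the suite verifies exact properties
(invariants, conservation, localization fidelity, analysis-stage algebra)
and *structural* properties of the free-energy landscape: the barrier
Δ₁→₃ does not decrease when the wall distance grows, and free chains
started well separated migrate to and prefer the intertwined state
(global minimum of the symmetrized profile at d = 0, bin width 24 ≈ half a
knot core at N = 250). What it does not establish is the production-scale
quantitative landscape — converged barrier heights (of order < 3 k\_BT for
walls at Ree ≈ 600σ and < 1 k\_BT for free chains) require on the order of
100 independent runs of 3×10⁹ steps at N = 1000, a cluster-scale budget.
The desk-scale estimates are biased by limited transition sampling in a
direction the regularizations above make explicit.

The synthetic-configuration generator produces idealized loose knots on
otherwise straight or equilibrated backbones; it emulates prescribed knot
content and confinement geometry, not sequence effects, electrostatics
beyond the effective diameter, torsional stiffness, or hydrodynamics —
all deliberately outside the model.

## Numerical choices

- Classification bands: ±10% relative around the Δ\_p references; the bands
  are separated by factors ≳ 2.5, so misassignment requires a genuinely
  different diagram, not noise.
- Determinants in float with `slogdet`; diagrams after reduction are small
  (≲ 60 crossings), keeping |Δ| far from overflow.
- Projection degeneracies (grazing crossings, matched depths) trigger a
  seeded perturb-and-retry of the direction, 12 attempts.
- MC Metropolis uses a 1e30 sentinel for overstretched bonds (certain
  rejection) to avoid inf−inf; total-energy evaluation reports +∞.
- Neighbor-list capacity is fixed (128 pairs/bead) and overflow is an
  error, not a silent truncation.
- Relaxation caps displacements at 0.1σ and re-verifies topology before
  returning; a change aborts the construction rather than continuing.
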