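# knotswap

Two knots tied on the same polymer can sit apart, slide along the backbone,
pass through one another, or nest one inside the other. On double-stranded
DNA — which knots spontaneously at the lengths used in nanochannel and
optical-tweezers experiments — these intertwining/swapping events are thermal
and governed by a *topological* free-energy barrier. `knotswap` is a complete
simulation-and-analysis stack for this problem: it builds coarse-grained
dsDNA-like chains carrying a trefoil (3₁) and a figure-eight (4₁) knot,
samples them in two regimes (ends grafted to parallel walls, and free chains),
identifies and localizes the knots along the backbone, and converts the
statistics of their relative position into free-energy profiles and barrier
heights.

## Model

The chain is a Kremer–Grest-type bead-spring polymer in reduced units
(σ = ε = k\_BT = 1):

- **Excluded volume** between all bead pairs via the WCA potential
  U(r) = 4ε[(σ/r)¹² − (σ/r)⁶ + ¼] for r ≤ 2^{1/6}σ, zero beyond;
- **Bonds** via FENE springs, U(r) = −(kR₀²/2) ln(1 − r²/R₀²) with k = 30,
  R₀ = 1.5σ — stiff enough that strands cannot cross and topology is
  conserved;
- **Bending** via U(θ) = (κ/2)(θ − π)² on the angle between adjacent bonds;
- **Walls** (when present) acting on each bead through the same WCA form in
  the wall-normal distance.

The dsDNA mapping takes σ = 5 nm (effective diameter at physiological salt),
so one bead ≈ 15 bp, and the discrete worm-like-chain relation
κ ≈ l\_p k\_BT/σ fixes κ = 50 nm / 5 nm = 10 to reproduce the 50 nm
persistence length. A chain of N = 1000 beads models 15 kbp of DNA.

Free chains are sampled by Metropolis Monte Carlo (capped local moves, pivot
rotations, crankshaft rotations of interior subchains) with cell-list overlap
checks; wall-grafted chains by Langevin dynamics (Grønbech-Jensen/Farago
discretization, Δt = 0.01, γ = m = 1) with the terminal beads anchored.

Knot identification closes the open chain (a large lateral semicircular arc
for grafted chains; radial extension of the ends away from the center of mass
for free chains), reduces the polygon by topology-preserving vertex elision,
and evaluates the Alexander-polynomial product Δ\_p = |Δ(−1.1)·Δ(−1/1.1)|
from the crossing diagram — a normalization-free scalar that cleanly separates
the unknot (1), 3₁ (≈ 9.05), 4₁ (≈ 25.09) and their connected sum (≈ 227.19).
Knot boundaries come from the monomer-removal scan: delete beads one at a
time from one end, bridge the gap by a straight segment, and re-classify; the
first deletion that destroys the knot marks its boundary. The relative
position d = pos(3₁) − pos(4₁) is the order parameter; Boltzmann inversion
F(d) = −k\_BT ln P(d) gives the free-energy profile, from which the barrier
Δ₁→₃ between the intertwined minimum and its flanking maxima is extracted.

## Worked example

```python
from knotswap import tie_knots_on_chain, locate_both
from knotswap.topology import classify_chain

chain = tie_knots_on_chain(400, [("3_1", 0.3), ("4_1", 0.7)], seed=1)
kc = classify_chain(chain, seed=5)
print(f"knot class: {kc.label}  (Delta_p = {kc.delta_p:.4f})")
s31, s41, rel = locate_both(chain, closure_mode="free")
print(f"3_1 span: [{s31.start_monomer}, {s31.end_monomer}]  size {s31.size}")
print(f"4_1 span: [{s41.start_monomer}, {s41.end_monomer}]  size {s41.size}")
print(f"relative position d = {rel.d:.1f}")
```

prints

```
knot class: composite_31_41  (Delta_p = 227.1896)
3_1 span: [105, 138]  size 33
4_1 span: [260, 299]  size 39
relative position d = -158.0
```

The chain carries exactly one trefoil and one figure-eight knot (the Δ\_p
value is the product of the two closed-form references), the trefoil core
occupies ~33 monomers around bead 120 and the figure-eight ~39 monomers
around bead 280, and the negative d says the trefoil sits nearer the chain
start. A full pipeline — generate, simulate, localize per frame, histogram d,
invert to F(d) and extract barriers — is available both as a library
(`knotswap.io.run_study`) and a CLI:

```
knotswap run-study --config study.json --out artifacts/
knotswap generate --n-beads 400 --knot 3_1:0.3 --knot 4_1:0.7 --out start.xyz
```

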