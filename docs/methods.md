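# Model and methods

## The model

`chromodyn` simulates a coarse-grained budding-yeast chromosome fragment as
a bead–spring polymer: 10 nm spheres, one per nucleosome, joined by
harmonic linker springs with 15 nm rest length. One bead stands for 150 bp
(nucleosome plus linker), so the canonical 2000-bead chain covers ~300 kb —
comparable to the long arm of yeast chromosome V. Higher-order structure is
not imposed; it emerges from five forces acting on every bead *i*:

| force | form | role |
|---|---|---|
| entropic | magnitude `c1`, uniform random direction, redrawn each step | Brownian motion of the solvated nucleosome |
| tension | `Ks (d_{i,i±1} − c2) û` | Hookean linker DNA |
| repulsion | `c3` for `d < 10 nm`; `c3 / (d/10nm)^12` for `10 ≤ d ≤ 15 nm`; 0 beyond | excluded volume, soft-core |
| attraction | `c4 · d_{i,i±2}` toward the second neighbours | shapes the DNA entry/exit (α) angle |
| condensin | `Kcondensin (d − c5) û` per bond, 0 beyond 40 nm | crosslink between bonded condensin sites |

Condensin is modelled as fixed binding-site beads placed every ~10 kb
(matching the spacing of condensin enrichment along yeast chromosome
arms). When two free sites come within the 40 nm interaction radius a bond
forms; each bond dissolves with probability `p` per unit time. In the
**Type I** model a site holds at most one bond (pairwise loops); in
**Type II** up to two (loops can coalesce into rosettes). Lowering `p`
from 1e-3 (G1) to 1e-4 (M phase) emulates mitotic stabilisation of
condensin binding. A freshly dissolved pair re-forms automatically within
a 3-step window if still in range and both sites retain capacity; bonds
are permitted between sites on different chains, with identical rules.

Beads exclude volume but linkers may pass through one another — the
implicit equivalent of occasional strand passage by topoisomerase II.

## Integration and units

Forces are in pN, positions in nm, and the bead mobility is 1 nm/pN per
unit time. Each step advances the midpoint scheme

```
x_half = x0 + (dt/2) · [F_ent(x0) + F_det(x0)]
x1     = x0 + dt     · [F_ent(x0) + F_det(x_half)]
```

where the entropic draw from the step start is reused at the second stage
and the bond set updates once per step, before the force evaluations.

**Choice of `dt`.** The stiffest relaxation in the system is the linker
spring: the relative coordinate of a bonded pair relaxes at rate
`2·Ks·mobility`. An explicit scheme is only stable for
`dt < 1/(Ks·mobility)`, so `dt` defaults to **half the stiffest relaxation
time**, `1/(2·max(Ks, Kcondensin))` = 0.01 time units at the default
stiffness (runs without condensin sites use `1/(2·Ks)`). This is the
standard CFL-style step choice, and the model's three published local
observables (displacement, linker tension for both parameter pairs)
emerge quantitatively at exactly this operating point — a step of 1 in
these units, sometimes quoted for this class of model, is two orders of
magnitude beyond the stability limit of the printed scheme and diverges
immediately.

**Time mapping.** One time unit corresponds to `λ²/D` seconds with
`λ = 15 nm` the linker length and `D = 1.33e7 nm²/s` the (rounded,
published) diffusion coefficient of a solvated nucleosome — i.e.
1.69e-5 s per unit, 1.69e-7 s per default step. `TimeMapping` can instead
derive `D = kB·T/f` from a friction coefficient; with `f = 3e-7 g/s` at
298.15 K this gives 1.64e-5 s per unit (3% below the rounded constant —
the published rounding corresponds to ~290 K). The package defaults to
the published constant for continuity with the reported timescales. Per
unit time the bead diffusion coefficient implied by the entropic kick is
`c1²·dt/6 = 1 nm²/unit`.

**Per-step probabilities.** `p` is a rate-like probability per unit time;
the per-step dissociation probability is `p·dt`. Bond lifetimes are then
geometric with mean `1/(p·dt)` steps = `1/p` time units, independent of
the step size.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| `c1` | 24.5 | pN | entropic kick magnitude; with `Ks` sets nucleosome mobility |
| `Ks` | 50 | pN/nm | linker spring constant |
| `c2` | 15 | nm | linker rest length |
| `c3` | 10 | pN | repulsion magnitude |
| `c4` | 0.005 | pN/nm | attraction coefficient (calibrated, see below) |
| `Kcondensin` | 50 | pN/nm | condensin bond spring |
| `c5` | 30 | nm | condensin bond rest length (< capture radius, so broken in-range pairs can re-form) |
| `attraction_radius` | 40 | nm | condensin capture/interaction radius |
| `p` | 1e-3 (G1) / 1e-4 (M) | per unit time | bond dissociation probability |

An alternative calibration (`Ks = 10 pN/nm`, `c1 = 11 pN`) reproduces the
same nucleosome mobility at lower average linker tension (~2.2 vs
~4.7 pN); the model's qualitative behaviour is insensitive to the choice.

**Calibration of `c4`.** The attraction coefficient has no published
value; it was fixed once by the sweep in `chromodyn.calibrate`
(rerunnable via `chromodyn calibrate`): `c4 = 0.005 pN/nm` places the
equilibrium α-angle mode at ~68° (target 70 ± 5°, the nucleosome
entry/exit geometry); 0.0025 gives ~87°, 0.01 gives ~57°. The soft-core
exponent of the repulsion middle branch evaluates `d` in units of the
10 nm bead diameter, making the profile continuous at the bead surface
(value `c3` at 10 nm, ~0.008·`c3` at 15 nm).

## Starting conformations

Production runs seed the chain along a 3D Hilbert curve filling a 150 nm
cube (the smallest curve order with enough vertices; self-avoiding by
construction), expand it inside a hard cylindrical wall of 200 nm
diameter (radial clamping about the chain's principal axis), then remove
the constraint and relax until the marker-pair distance plateaus
(moving-average change below 2% per window by default). A straight-line
geometry exists as a debug option. Measurement protocols for *local*
observables instead start from a random-direction chain (angles begin
near their equilibrium distribution), which reaches local equilibrium in
~10⁵ steps instead of ~10⁶.

## Observables

* **Marker distance / compaction** — Euclidean distance between two
  marker beads (default: ~144 kb apart, centred); compaction is
  `1 − plateau/baseline` with the plateau taken over the final third of
  the trace.
* **Displacement distribution** — `|x(t+Δ) − x(t)|` pooled over beads and
  overlapping window starts, Δ = 30 ms (the closest frame multiple).
* **α angle** — angle at each interior bead between the vectors to its
  chain neighbours (180° = straight). The mode is read from a 5°
  histogram smoothed with a [1,2,1]/4 kernel plus quadratic refinement;
  the raw argmax bin flips between near-equal neighbours (±4° seed
  scatter vs ±1.6° smoothed).
* **Linker tension** — mean `|Ks (d − c2)|` over linkers and frames.
* **Kurtosis** — Pearson `μ₄/σ⁴` of inter-locus distance samples.
* **Simulated 4C** — per-bead contact frequencies against a viewpoint
  bead (contact = within 40 nm, reusing the condensin interaction radius;
  configurable), normalised to all contacts; long-range fraction = share
  beyond a genomic threshold.
* **Rosettes** — single-linkage clusters of condensin sites at 40 nm;
  clusters of ≥3 sites are rosettes, the rest of the chromatin is the
  "web". Identity across frames requires ≥50% member overlap; lifespans
  are frames-alive × seconds-per-frame.
* **Occupied volume** — count of 50 nm grid cells containing ≥1 bead
  centre × cell volume (the grid edge matches the local persistence
  length, balancing over- and under-estimation).
* **Persistence length** — `Lp = ∫ K_or(L′) dL′` with
  `K_or(L′) = ⟨u(L)·u(L+L′)⟩` averaged over tangent pairs and structures,
  integrated up to a genomic cutoff (100 kb default). For loop polymers
  `Lp` grows with the cutoff, unlike a worm-like chain.
* **Interchain contacts** — bead pairs on different chains within 40 nm.

## Problem sizes and what the desk-scale runs show

Local observables (displacement, tension, α angles, kurtosis, per-bead
occupied volume) are self-averaging: a 300-bead chain with a 3×10⁵-step
equilibration and ~10⁶-step production gives percent-level precision, and
the package's standard protocols use exactly that.

Chain-scale equilibration is governed by Rouse dynamics: the slowest mode
of an N-bead chain relaxes in ~`N²b²/(3π²D)` time units ≈ 3×10⁷ units for
N = 2000 — about 10⁹ integration steps, consistent with the reported
~7 min in-vivo condensation timescale but far beyond interactive compute.
Consequently:

* **Occupied volume** of the 300 kb chromosome is measured as volume per
  bead on a globally equilibrated shorter chain and extrapolated linearly
  to 2000 beads (the chain is dilute at the 50 nm grid scale, so occupancy
  is extensive; N = 150 and N = 300 extrapolate to 0.055 and 0.052 µm³
  against the full-scale 0.050 µm³ reference).
* **Condensation experiments** use a scaled protocol: 200 beads with
  condensin sites every ~2.25 kb (site spacing scaled with chain length so
  loop formation fits the accessible timescale — at 10 kb spacing,
  loop-closure search alone exceeds 10⁸ steps). Marker-distance traces at
  this scale are dominated by slow conformational wander (the
  autocorrelation time exceeds any affordable window), so condensation
  checks average over replicate seeds and assert the model *contrasts*:
  looped chains are more compact than matched no-condensin controls, and
  Type II binds more sites into larger, far longer-lived rosettes with
  more long-range 4C contacts than Type I. The full-scale quantitative
  figures (≈25% Type I vs >40% Type II marker compaction after the p
  switch, and the open/compact bistability of Type II at p = 5×10⁻⁴)
  require the 2000-bead, ~10⁹-step experiment and are not reproduced at
  desk scale.

The synthetic protocols emulate an isolated chromosome fragment in open
solvent. They do not represent nuclear confinement, crowding by other
chromosomes, tethering (centromere/telomere anchors), or sequence-specific
nucleosome positioning — so quantitative agreement of the desk-scale runs
supports the force-field calibration and the condensin-rule contrasts, not
nuclear-scale organisation.

## Numerical choices

* Production stepping runs in a numba kernel: hashed cell list rebuilt
  into a Verlet pair list (15 nm cutoff + 4 nm skin, refreshed when any
  bead drifts half a skin; neighbour buckets deduplicated per bead because
  distinct cells may hash-collide). The numpy implementations in
  `forces`/`bonds`/`integrate` define the semantics and serve as oracles
  in the test suite.
* Entropic directions are uniform on the unit sphere (Marsaglia in the
  kernel, normalised Gaussians in the reference).
* Coincident beads (zero pair distance) receive a random force direction —
  a probability-zero configuration tolerated rather than fatal.
* Bond updates traverse sites in random order each step (no index bias);
  a pair with mutual free capacity bonds once (unordered semantics).
* The persistence-length integral uses a left-rectangle sum over lags,
  the convention under which a rigid rod yields exactly the cutoff length
  and a freely jointed chain the geometric-series closed form
  `b/(1 − ⟨cos θ⟩)`.
* Runs are bit-reproducible for a fixed seed; each schedule phase derives
  its kernel seed from the run seed and phase index.
* Trajectory frames are stored float32 (0.1 µm-scale positions keep
  ~6×10⁻⁵ nm resolution — far below every observable's scale); the live
  integration state is float64.
* The repulsion support is `(0, 15]` nm inclusive; a chain whose linkers
  sit exactly at 15 nm (the rest length) therefore feels a ~0.08 pN
  residual on its two end beads — physically negligible, but worth knowing
  when constructing exact-rest-length test states.

## Known limitations

* No hydrodynamic interactions, electrostatics, or bending potential
  beyond the second-neighbour attraction; no explicit condensin loading or
  diffusion (sites are fixed beads).
* The explicit-midpoint stability constraint ties the accessible physical
  time to the linker stiffness; full-scale condensation timecourses are
  out of reach on one CPU (see above).
* Linker crossing is unrestricted (no bond-bond excluded volume), so
  topological relaxation is faster than in a strand-passage-limited
  nucleus.
* PDB export uses fixed-width coordinate columns (±1 µm range after the
  ×10 nm→Å conversion); strongly extended conformations can exceed the
  format and should be exported as XYZ instead.
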