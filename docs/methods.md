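# Methods

## The two routes to a monolayer's surface pressure

A surfactant monolayer at a solvent–air interface lowers the bare surface
tension γ_w to γ_m; the difference

    Π = γ_w − γ_m

is the surface pressure. `isopress` computes Π from particle simulations in
two independent ways.

**Tensor route** (`isopress.tensor`). For a slab with two interfaces normal
to z, the Kirkwood–Irving expression gives the tension from the diagonal
pressure-tensor anisotropy,

    γ = (L_z / 2) · ⟨P_zz − (P_xx + P_yy)/2⟩ ,

the 1/2 splitting the integrated anisotropy between the two interfaces.
Two simulations are needed (with and without the film), and the estimator
degrades at high packing where the film state is fragile.

**Osmotic route** (`isopress.osmotic`). Two virtual walls at x = ±x_wall
act as semipermeable membranes: solvent crosses freely, surfactant beads
beyond a wall feel a flat-bottom restoring force. The force law is
quadratic in the penetration depth d = |x| − x_wall,

    F(d) = k·d²  (k in kcal mol⁻¹ Å⁻³ in real units),

with a linear law (k in kcal mol⁻¹ Å⁻²) available as an option; the
estimator itself is agnostic to which law generated the data. The
time-averaged total restoring force is the osmotic force, and the ideal 2D
film pressure is

    Π_ideal = ⟨F_wall⟩ / (4·L_y) ,

the 4 counting the four wall–interface intersections (two walls × two
interfaces). The default force constant in reduced units is k = 50 ε/σ³,
which keeps mean penetrations near 0.2 σ — restrictive but not stiff, and
the measured pressure is insensitive to doubling it (this is verified by
the test suite).

**Semi-empirical correction** (`isopress.profiles`). Treating the film as a
surface solution of depth equal to the molecule length overestimates Π at
high packing. The correction

    Π_real = Π_ideal · ξ ,   ξ = L_z;int(dilute reference) / L_z;int(A) ,

uses the interfacial thickness L_z;int: the distance over which the solvent
density falls from 90% to 10% of its bulk value along the interface
normal. ξ ≈ 1 for a widely spread film and decreases as packing thickens
the inhomogeneous surface zone.

## Estimator details and numerical choices

* **Bulk reference density.** The "maximum" solvent density is
  operationalized as the mean over the central 50% (by bin index) of the
  slab region — the contiguous run of bins above half the maximum — not the
  single highest bin, which would bias the 90% crossing on noisy profiles.
* **Crossings.** Located by linear interpolation between adjacent bin
  centers. The profile is split at its densest bin; each half contributes
  one interface when it decays through both thresholds. With multiple
  crossings (non-monotonic tails) the outermost crossing is used and a
  warning is emitted. The two interfaces' thicknesses are averaged before
  forming ξ.
* **Slab recentring.** A Langevin-thermostatted slab performs a slow random
  walk along z; each frame is therefore recentred on the solvent's mean z
  (restricted to the analysis strip when one is set) before histogramming.
  Without this the time-averaged profile smears by the walk amplitude.
* **Fixed observation width.** The apparent time-averaged interface width
  contains a capillary-wave contribution that grows with the lateral area
  of the averaging window, so thicknesses measured over windows of
  different widths are not comparable. Inside an area sweep every state is
  therefore analysed over sub-strips of one fixed width — the film region
  of the narrowest state — tiled across its film region and averaged
  (`profiles.tiled_thickness`); the dilute reference is the same-width
  strip average over the clean slab (`profiles.strip_averaged_reference`,
  which also exploits the clean slab's homogeneity in x to cut the
  reference variance). The reference comes from a separate
  surfactant-free run under identical conditions (an extrapolated dilution
  series would serve as an alternative but is not the default);
  `reference_thickness` takes a `region` argument for one-off matched
  measurements.
* **Coverage factor in the same-run tensor route.** With walls at ±x_wall
  inside a box of length L_x the film covers only c = 2·x_wall/L_x of each
  interface; the rest is the mandated clean margin. The box-averaged
  tension is then γ_box = c·γ_strip + (1−c)·γ_w, so `analyze_run` recovers
  the film pressure as Π = (γ_w − γ_box)/c. For a wall-free full-coverage
  system c = 1 and the expression reduces to Π = γ_w − γ_m. This
  area-weighted decomposition was verified numerically on dilute toy runs.
* **Uncertainties.** Block averaging over 5 contiguous blocks (remainder
  frames dropped); Π uncertainties from the wall-force series, γ
  uncertainties from the instantaneous tension estimator, differences
  combined in quadrature. ξ's own statistical error is not propagated into
  Π_real (it is dominated by slow interface modes and would require far
  longer runs to estimate reliably; the replicate-sweep machinery below is
  the intended way to average it down).
* **Wall-force accumulation** is sequential in bead-index order, so the
  estimator is bit-for-bit reproducible against a naive double-loop
  reference.
* **Unit conversions.** 1 kcal mol⁻¹ Å⁻² = 694.77 mN/m and
  1 bar·Å = 0.01 mN/m, from SI first principles; reduced-unit runs report
  ε/σ².

## The toy simulator

`isopress.toysim` is a self-contained Langevin-dynamics model of a
solvent-slab + monolayer system. It is a generic coarse-grained toy — not a
parameterized lipid force field — because the pressure estimators under
test are force-field-agnostic; it exists to generate all test data and to
serve as a cross-method oracle.

* **Species and interactions.** Solvent W, head H, tail T; force-shifted
  Lennard-Jones pair potentials (so the virial is consistent with the
  truncated forces). In reduced units (ε = σ = m = k_B = 1):
  ε_WW = 1.0, ε_WH = 1.2 (σ 0.9), ε_WT = 0.25 (WCA, purely repulsive),
  ε_HH = 0.15 (σ 0.8), ε_HT = 0.15 (σ 0.9), ε_TT = 0.15; cutoff 2.5 σ.
  Surfactants are H–T–T chains with harmonic bonds (k = 100 ε/σ²,
  r₀ = 1 σ). The small, moderately hydrated head floats in the interfacial
  zone when dilute but is crowded into the near-surface water under
  compression, thickening the 90–10% zone; dry tails point into the
  vacuum; the weakly cohesive film stays a monolayer rather than
  collapsing. These couplings were chosen so the model reproduces the
  qualitative monolayer phenomenology the estimators assume (ξ ≈ 1 when
  spread out, thickening under compression) — they are study conditions,
  not fits.
* **State point.** T = 0.5 ε/k_B — well below the liquid–vapour critical
  point of the force-shifted fluid, giving a sharp (≈1.5 σ) bare interface,
  an equilibrium slab density ≈ 0.8 σ⁻³ and negligible vapour.
* **Geometry.** Box 33 × 10 × 28 σ, periodic in all directions with a
  vacuum region along z; 1480 solvent beads form a ≈5.6 σ slab; 15
  surfactants per leaflet sit on both interfaces between walls at
  ±x_wall; the default x_wall = 12 σ leaves a 4.5 σ clean-interface margin
  to the box edge (the 18 Å margin of a real setup at σ ≈ 4 Å) so solvent
  exchanges freely across the wall planes. Area per surfactant is
  A = 2·x_wall·L_y/n_leaflet, so the default is A = 16 σ² and the standard
  compression grid runs 16 → 10 → 6 → 4 σ² (walls ±12 → ±3 σ). Compression
  much beyond A ≈ 3 σ² buries the film irreversibly (heads solvated in
  bulk, near-zero wall force on re-expansion), so the study grid stays in
  the reversible monolayer regime.
* **Integrator.** BAOAB-splitting Langevin at dt = 0.005 τ, friction
  1 τ⁻¹; the whole run loop is one numba kernel seeded once (legacy numpy
  RNG), making runs bitwise reproducible. With friction → 0 the O-step
  vanishes and momentum is conserved to integrator precision.
* **Pressure log.** Instantaneous kinetic + virial tensor including pair,
  bond and wall (external, Σ x·F_x) terms over the full box volume.
* **Limitations.** No electrostatics, no angle potentials, no solvent
  hydrogen-bond structure: the bare interface is soft (width ≈ 1.5 σ
  against ≈ 0.1 of a molecular diameter for real water), so the film's
  relative perturbation of L_z;int is weaker and noisier than in atomistic
  systems. Slow capillary modes at the box scale dominate the run-to-run
  scatter of L_z;int (σ ≈ 0.05–0.1 σ per 40 k-step run); the sweep
  machinery therefore supports replicate seeds combined by inverse-variance
  weighting. Passing tests demonstrate estimator correctness and the
  qualitative monolayer phenomenology at toy scale — not quantitative
  agreement with any real lipid isotherm, which would require an external
  force field and far longer runs.

## Isotherm assembly

`isotherm.sweep` holds the surfactant count fixed and repositions the walls
(instantaneously, like trough barriers) over an ordered area grid. Right
after an inward jump some beads sit several σ beyond the new wall where
the quadratic restraint is violent, so each repositioning is followed by a
short discarded displacement-limited relaxation (velocity clamp) and a
discarded thermal re-equilibration segment; the first 20% of every sampled
segment is additionally discarded as burn-in, plus extra equilibration at
the first point. Each point
carries Π_ideal, ξ, Π_real and optionally the tensor-route Π from the same
run. A drift test (first vs second half of the retained wall-force series
differing by more than 3× their combined block SE) flags unequilibrated
points rather than silently dropping them. Replicate sweeps are combined
per area point by inverse-variance weighting. `plateau_detect` flags
near-flat stretches (centered difference |dΠ/dA| below a configurable
threshold, default 0.1 mN m⁻¹ Å⁻² in real units) as a phase-coexistence
diagnostic.

## Problem sizes

The test suite and the acceptance script run everything from scratch on one
CPU: single-state runs use 40 k steps (≈1600 beads), sweep points 22–25 k
steps, with three replicate compression sweeps (combined by
inverse-variance weighting) and one expansion sweep. These sizes put the
statistical checks at the edge of resolvability for the slow interface
modes (see Limitations) while keeping a full session in the tens of
minutes; all of them are set in one place (`tests/conftest.py`,
`scripts/acceptance.py`) and scale up trivially.
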