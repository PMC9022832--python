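# Methods

## Scope and model

The package implements a statistical-mechanics model of RNA packaging
selection during capsid nucleation.  Its moving parts are:

1. **Scaffold** (`polyhedra`).  The dodecahedral graph (20 vertices, 30
   edges, 12 pentagonal faces) with its full symmetry group of 120
   rotations and reflections, obtained as the graph automorphism group —
   for 3-connected planar graphs this equals the geometric symmetry group,
   so no coordinates are needed.  Tetrahedron and cube fixtures expose the
   same interface at exhaustively checkable scale.  Vertex labels follow
   `networkx.dodecahedral_graph`; all canonical forms are defined on this
   labelling, with edge subsets canonicalized to the numerically minimal
   edge-index bitmask over the orbit.

2. **ψ-sequence library** (`treelib`).  All 5,184,000 labeled spanning
   trees are enumerated by a depth-first include/exclude search with
   union-find cycle rejection and a connectivity prune (JIT-compiled;
   ~3 s), then reduced to 43,380 symmetry classes by vectorized orbit
   minimization.  Both counts are verified independently — the labeled
   total against the Kirchhoff matrix-tree determinant, the class count
   against a Burnside-lemma recount — at build time and in the test suite.
   Hamiltonian paths are counted as undirected edge subsets (1620 on the
   dodecahedron); this convention reproduces the reference count, so it is
   frozen in the API.

3. **Energetics** (`energetics`).  ΔE(n) = n₁ε₁ + n₂ε₂ − n₃ − μ₀n in E₀
   units.  ε₂ ≡ −1 + 2ε₁ is always derived (link–edge affinity is
   additive over the two pentamer edges meeting a shared link).  μ₀
   absorbs the non-specific electrostatic affinity; `mu0="equilibrium"`
   sets ΔE(12) = 0, i.e. μ₀ = (19ε₂ − 11)/12.  E₀ (k\_BT) enters only in
   Boltzmann/Arrhenius exponents −E₀·ΔE.

4. **Assembly networks** (`network`).  Per pentamer count *n* the level
   minimum is found by exhaustive search over all C(12, n) ≤ 924 face
   subsets — exact, no heuristics.  Nodes are the minimum-energy
   configurations, merged when related by a symmetry of the dodecahedron
   that maps the tree onto itself (the stabilizer subgroup; the full group
   would conflate physically distinct assemblies on the same molecule).
   Links join configurations differing by one pentamer.

5. **Kinetics** (`kinetics`).  Metropolis on-rates
   λ·c\_f·min(1, e^(−E₀ΔΔE)) and off-rates λ·min(1, e^(+E₀ΔΔE)) fixed by
   detailed balance, so the Boltzmann distribution
   P\_eq(n) ∝ exp(−E₀ΔE(n) + n ln c\_f) is the exact stationary state at
   clamped c\_f.  Mass conservation couples species through
   c\_f/c₀ = 1 − (D/(F·n\_species))·Σ n·P.  The resulting nonlinear ODE
   (dP/dt = (c\_f(P)·M\_on + M\_off)P with constant generator matrices) is
   integrated by BDF with the analytic Jacobian
   c\_f·M\_on + M\_off + (M\_on P)(∇c\_f)ᵀ, rtol 10⁻⁸ / atol 10⁻¹²,
   log-spaced output.  Networks have ≤ ~90 nodes, so runs to 10¹⁰ time
   units take well under a second.

6. **Observables** (`observables`).  Delay time by the maximum-slope
   tangent construction on a PCHIP-resampled assembly curve (raw log
   grids make naive differencing noisy); the estimator is stable to <2%
   under grid doubling.  Selectivity S per the peak-yield definition,
   clamped to zero when the competitor wins; S(E₀) scans rebuild nothing
   but the rate exponents, since the network geometry and the E₀-unit
   profile are E₀-independent.

## Parameter conventions and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| E₀ | pentamer–pentamer edge binding (k\_BT) | 4.0 | calibration from empty-capsid assembly data gives ≈4.7; 4.0 is the study's round value |
| ε₁ | −(link affinity)/E₀ | −0.5 | onset-concentration calibration gives −ε₁ ≈ 0.29; −0.5 is the study's convenient value |
| μ₀ | reference chemical potential (E₀ units) | −4.0 | near assembly equilibrium (−49/12 ≈ −4.083) |
| c₀ | total pentamer concentration (reference units) | 1.0 | reference concentration |
| D | mixing ratio 12·r\_t/c₀ | 0.5 | twice the pentamers needed (D=1 is stoichiometric) |
| λ | base rate | 1.0 | defines the time unit 1/λ; its microscopic (Smoluchowski) derivation is out of scope |

## Design choices where the source was ambiguous

* **Off-rate sign.**  The printed detailed-balance ratio conflicts in sign
  with the printed equilibrium distribution; we implement the convention
  (ratio = c\_f·e^(−E₀ΔΔE)) under which the equilibrium distribution is the
  exact stationary state.  ΔΔE = 0 ties take the unsuppressed branch on
  both sides, preserving detailed balance.
* **Equilibrium normalization** includes the pentamer-free n = 0 state —
  it is the source node of every assembly network.
* **Network membership.**  Levels hold exactly the global-minimum-energy
  configurations.  With this rule a level occasionally contains a node
  with no single-pentamer link to the neighbouring level (e.g. one
  level-10 node of the default (9,8) class).  Such nodes are kept — the
  master equation flows both ways, so they are metastable side states —
  and `AssemblyNetwork.connectivity_report()` lists them; only
  empty-to-complete reachability is enforced.  m₅ = 4 for the default
  (9,8) class, matching the reference value.
* **Class selection within a (MLD, N\_p) bucket.**  Profiles of same-index
  classes are similar but not identical (the (19,2) bucket spans barriers
  4.5–5.0 E₀).  `TreeLibrary.select` defaults to the member with the
  largest activation barrier (ties broken by canonical order), which
  reproduces the published reference profiles — 3.0 E₀ for (9,8), 5.0 E₀
  for (19,2); an explicit `class_id` overrides.  At ε₁ = −1.1 the (9,8)
  members place the incomplete-particle ground state at 9 or 10 pentamers
  depending on the member; the published example shows ten.
* **Initial condition**: all probability on n = 0 and c\_f(0) = c₀
  (unassembled RNA in fresh pentamer solution).

## Known discrepancies with the published values

Two published kinetic numbers are not reproduced by the model equations as
printed, and the package reports its own computed values rather than
fitting to them:

* **Long-time single-species packaged fraction.**  At E₀ = 4, ε₁ = −0.5,
  μ₀ = −4, c₀ = 1, D = 0.5 the published long-time fraction is ~66%.  The
  self-consistent equilibrium of the model is bounded by
  P₁₂ ≤ w/(1+w) with w = e⁴(1 − P₁₂/2)¹², whose fixed point is 0.55
  (intermediate states carry negligible Boltzmann weight); the computed
  value is 0.539, and the ODE and the Boltzmann distribution agree to
  solver tolerance.  No membership or normalization variant reaches 0.66.
* **Delay time.**  The tangent construction yields 10.1 time units for the
  default (9,8) class versus the published ~8.5.  The intercept is stable
  (±2% across tangent points and grids); across plausible network
  conventions the value spans 7.0–10.2.  Relatedly, published absolute
  thermalization times (~10³/10⁵) are shorter than computed (~10⁶/10⁸–10⁹),
  while the *ordering* and the ≥ 2-orders-of-magnitude separation — and all
  dimensionless yields and selectivities — are reproduced.

## What the tests do and do not show

The suite verifies exact combinatorics against independent oracles
(Cayley/Kirchhoff counts, Burnside recounts, brute-force orbit partitions,
permutation-based Hamiltonian-path counts), exhaustive-enumeration network
oracles on the cube, analytic stationary states on a 3-level toy ladder,
Gillespie-vs-ODE agreement at fixture scale, and the reference barriers,
multiplicities, yields and selectivities.  All inputs are generated by the
package itself; the model idealizes real assembly (single spanning-tree
geometry per molecule, level-uniform energies, well-mixed mean-field
kinetics, no elongation-stage effects, no maturation), so passing tests
validate the implementation of this model, not its biological fidelity.

Problem sizes used by the default suite and the acceptance script: the
full 5.18M-tree enumeration, exact C(12, n) level minimizations, and ODE
horizons of 10⁴–10¹⁰ time units (the dynamics at the reference parameters
plateau well before the horizon ends; longer horizons change nothing but
cost little, as the stiff solver takes geometric steps).
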