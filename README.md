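# capsid-contest

Kinetic selection of viral RNA by packaging signals, modelled as a
**packaging contest** between RNA species competing for capsid protein
during the nucleation stage of small ssRNA virus assembly.

## The model

The capsid is the dodecahedral (Zlotnick-type) model: twelve pentamers on
the faces of a dodecahedron.  The ψ sequence — the cluster of packaging
signals on the condensed RNA — is a **spanning tree** of the dodecahedral
graph: 19 links joining all 20 vertices, leaving 11 of the 30 edges bare.
Each of the 5,184,000 labeled spanning trees falls into one of 43,380
symmetry classes, indexed by two folding-geometry characteristics:

* **MLD** (maximum ladder distance) — the tree diameter in links
  (19 for the linear chain, 9 at minimum);
* **wrapping number** N\_p — the number of faces whose boundary carries the
  maximum of four tree links (2–4 for Hamiltonian paths, 8 at maximum).

A configuration of *n* pentamers on faces has assembly energy (in units of
the pentamer–pentamer binding scale E₀, itself in k\_BT)

    ΔE(n) = n₁ε₁ + n₂ε₂ − n₃ − μ₀n,        ε₂ = −1 + 2ε₁,

where n₁/n₂ count tree links under unshared/shared pentamer edges, n₃
counts bare shared edges, and μ₀ is the reference chemical potential.
Exhaustive minimization over face subsets gives the minimum-energy assembly
profile ΔE\_min(n); its maximum is the nucleation **activation barrier**.
The distinct minimum-energy intermediates (merged under the tree's
symmetry stabilizer) form a layered assembly network on which a master
equation with Metropolis on-rates, detailed-balance off-rates, and a shared
free-pentamer pool (mixing ratio D = 12·r\_t/c₀) describes packaging
competition between species.  Kinetic selectivity at the encoded species'
peak yield is

    S = [P₁₂⁽¹⁾(t_max) − P₁₂⁽²⁾(t_max)] / P₁₂⁽¹⁾(t_max).

## Worked example

```python
import capsid_contest as cc

graph = cc.build_dodecahedron()
library = cc.dodecahedron_library()           # ~15 s: 5.18M trees -> 43,380 classes
params = cc.EnergyParams(e0=4.0, eps1=-0.5, mu0=-4.0)

compact = library.select(9, 8, energy_params=params)    # MLD=9,  N_p=8
linear  = library.select(19, 2, energy_params=params)   # MLD=19, N_p=2
net1 = cc.build_network(compact, graph, params)
net2 = cc.build_network(linear, graph, params)
print(net1.profile.barrier, net2.profile.barrier)   # 3.0 5.0   (E0 units)
print(net1.multiplicities[5])                       # 4         (m_5)

# supersaturated stoichiometric competition: c0=4, D=2
traj = cc.integrate([net1, net2], cc.KineticsParams(c0=4.0, d_ratio=2.0), t_end=1e6)
sel = cc.selectivity(traj)
print(round(float(traj.packaged_fraction(0).max()), 3))  # 0.788
print(round(sel.s, 3))                                   # 0.991
```

The compact, maximally wrapped class has a 2 E₀ lower nucleation barrier
than the linear chain, so it assembles orders of magnitude faster; run at
the stoichiometric mixing ratio it drains the pentamer pool first and keeps
~99% selectivity over more than 2×10⁵ time units at ~79% yield.  Scanning
the energy scale (`cc.selectivity_scan`) shows an order–disorder
transition: below E₀ ≈ 1 k\_BT the linear chain's far larger number of
assembly pathways erases selectivity entirely.

A CLI mirrors the library: `capsid-contest enumerate|network|simulate|
compete|scan|fixtures` (see `--help`).

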