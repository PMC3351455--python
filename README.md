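# linfw — the linear framework for time-scale separation

Cellular sub-systems that equilibrate quickly — an enzyme cycling
through its bound states, transcription factors hopping on and off a
promoter, a substrate being pushed through its modification states —
can be *eliminated* from a model exactly, leaving rational algebraic
expressions in the slow variables.  The Michaelis-Menten rate law, the
Monod-Wyman-Changeux saturation curve and the thermodynamic formalism
of gene regulation are all instances of one calculation: steady states
of a **labelled directed graph** under linear (Laplacian) dynamics.

`linfw` implements that calculation symbolically and numerically, for
modellers in systems biology and quantitative biochemistry who want
exact eliminations without hand algebra.

## The core result

A graph `G` with positive edge labels (rate constants, possibly times
concentrations of *slow* species — the uncoupling condition) defines

    dx/dt = L(G)·x ,     L[i,j] = label(j→i),  columns sum to 0.

If `G` is strongly connected, `ker L(G)` is one-dimensional and spanned
by the **Matrix-Tree vector**

    ρ_i = Σ_{spanning trees T rooted at i}  Π_{edges of T} label ,

a positive polynomial in the labels.  Every steady state is `x = λρ`;
normalising by a reference vertex (`x_i/x_1 = ρ_i/ρ_1`) or by the total
(`x_i = x_tot·ρ_i/Σρ`) gives the rational expressions that appear in
every time-scale-separation formula.  For general graphs, `dim ker L`
equals the number of terminal strongly connected components, with one
MTT basis vector per terminal SCC.  At thermodynamic equilibrium,
detailed balance collapses the trees to single paths of equilibrium
constants `K_ij = a/b` (and `K_ij = exp(−ΔG/RT)` connects to free
energies).

On top of the core sit application builders: enzyme mechanisms →
symbolic rate laws (King-Altman), multisite modification → mod-form
distributions and multistability, ligand binding → saturation and
gene-regulation functions at or away from equilibrium, reaction
networks → the complex-graph decomposition `f = Y·L·Ψ`, and
synthesis/degradation → the augmented ∗-graph steady state.

## Worked example

A one-site kinase/phosphatase futile cycle, eliminated hierarchically
(`python examples/ptm_distribution.py`):

```
1-site mod-form distribution (rational in [K], [P] only):
  [S0]/S_tot = [P]*kcat_P_1_0*kon_P_1_0*(kcat_K_0_0 + koff_K_0_0)/([K]*kcat_K_0_0*kon_K_0_0*(kcat_P_1_0 + koff_P_1_0) + [P]*kcat_P_1_0*kon_P_1_0*(kcat_K_0_0 + koff_K_0_0))
  [S1]/S_tot = [K]*kcat_K_0_0*kon_K_0_0*(kcat_P_1_0 + koff_P_1_0)/([K]*kcat_K_0_0*kon_K_0_0*(kcat_P_1_0 + koff_P_1_0) + [P]*kcat_P_1_0*kon_P_1_0*(kcat_K_0_0 + koff_K_0_0))

Conservation solution (E_tot = {'K': 1.0, 'P': 1.2}, S_tot = 5.0):
  [S0] = 2.857703   full ODE: 2.857703
  [S1] = 1.143875   full ODE: 1.143875
free enzymes: {'K': 0.017717, 'P': 1.183861}

-- two-site distributive cycle, saturated-kinase regime --
3 coexisting steady states (free kinase values): [11.4, 18.65, 93.44]
```

(the suffix `_K_0_0` tags the kinase mechanism acting on site 0 of
mod-form `S0`; rate-constant names come from the fixture generator)

Reading the output: the steady-state fraction of modified substrate is
a ratio of two monomials in the free enzyme concentrations — the
effective catalytic efficiencies `kon·kcat/(koff + kcat)` of kinase
and phosphatase competing for the substrate.  Solving the enzyme and
substrate conservation laws pins the free concentrations down; the
values agree with brute-force integration of the full nonlinear
network (all enzyme-substrate complexes explicit) to machine
precision.  With two sites and a saturated kinase the conservation
equations acquire three positive roots — the bistability of the dual
modification cycle — of which the outer two are dynamically stable.

Other entry points, one script per capability, live in `examples/`:
`kernel_basics.py`, `enzyme_rate_law.py`, `detailed_balance.py`,
`gene_regulation.py`, `crnt_decomposition.py`,
`synthesis_degradation.py`.  A thin CLI mirrors the library:

```sh
linfw rho graph.json            # MTT kernel vector
linfw kernel graph.json         # basis for general graphs
linfw ssd graph.json --mode total
linfw check-db graph.json       # detailed balance / cycle condition
linfw enzyme mech.json --rate   # symbolic rate law
linfw syndeg pg.json            # open-system steady state
linfw gen strong --seed 1 -o g.json
```

## Layout

```
src/linfw/
  labels.py        edge-label algebra (rate/concentration symbols)
  graph.py         LinGraph, Laplacian, SCCs, uncoupling condition
  matrix_tree.py   spanning trees, ρ by trees and by minors, kernel basis
  steady_state.py  the two normalisations, numeric ODE steady state
  equilibrium.py   detailed balance, cycle condition, free energies
  enzymes.py       mechanism grammar, King-Altman rate laws
  ptm.py           mod-form graphs, distributions, conservation solving
  binding.py       microstates, saturation, gene-regulation functions
  crnt.py          complex graphs, f = Y·L·Ψ, complex balance
  syndeg.py        synthesis/degradation via the ∗-graph
  fixtures.py      seeded generators for every input family
  io.py, cli.py    JSON/TSV formats and the `linfw` command
```

`docs/methods.md` documents the model, conventions (Laplacian sign,
van't Hoff direction), numerical policies and known limitations.
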