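# Methods

## The model

`linfw` computes steady states of the *linear framework*: a labelled
directed graph `G` whose vertices are molecular components and whose
edges are first-order mass-action reactions, the label being the rate
constant.  The induced dynamics is linear,

    dx/dt = L(G) · x,

with the Laplacian convention `L[i,j] = label(j→i)` for `i ≠ j` and
`L[j,j] = −Σ labels leaving j`, so every **column** sums to zero and
`Σ x_i` is conserved.  Nonlinearity enters through the labels: a label
may be any rational expression in rate constants and concentrations of
*slow* species, subject to the **uncoupling condition** — no
concentration in a label may name a species that is itself a graph
vertex.  This is what lets a fully nonlinear biochemical sub-system be
eliminated exactly at steady state by linear algebra.

For a strongly connected graph `ker L` is one-dimensional and spanned
by the Matrix-Tree vector `ρ`: `ρ_i` is the sum over spanning trees
rooted at `i` of the product of tree-edge labels — a polynomial in the
labels with positive coefficients.  Steady states are `x = λρ`; the
free scalar is removed either by a reference vertex (`x_i/x_1 =
ρ_i/ρ_1`) or by the total (`x_i = x_tot · ρ_i/Σρ`).  For a general
graph, `dim ker L` equals the number of terminal strongly connected
components, and a basis is obtained by applying the MTT to each
terminal SCC in isolation and padding with zeros.

On this core sit five application layers:

* **enzymes** — mechanisms from a three-shape grammar (bind, release,
  interconvert) compile to a graph on enzyme states; MTT elimination is
  the King-Altman procedure and yields symbolic rate laws (the
  Michaelis-Menten law for the one-intermediate irreversible scheme,
  with `V_max = k3·E_tot`, `K_M = (k2+k3)/k1`).
* **ptm** — multisite modification: hierarchical elimination first
  removes enzyme intermediates (effective coefficients `c^E_ij`, so the
  mod-form graph edge `i→j` is labelled `Σ_E c^E_ij[E]`), then the
  mod-forms themselves.  The distribution is rational in the *p* free
  enzyme concentrations regardless of the number of sites; the free
  concentrations solve nonlinear conservation equations that may have
  several positive roots (multistability).
* **binding** — microstates are (conformation, occupancy-bitstring)
  pairs; edges either switch conformation (no bit changes) or flip one
  bit (binding `k_on[L]`, unbinding `k_off`).  At equilibrium,
  probabilities come from products of equilibrium constants along
  paths; away from equilibrium, from the MTT — strong connectivity is
  the only requirement.  Averages over the probabilities give
  fractional saturation and gene-regulation functions.
* **crnt** — reaction sides become "complexes"; the species-level
  mass-action field factors as `f = Y·L(G_N)·Ψ`, separating the
  nonlinearity (`Ψ`, monomials) from the network structure (`L`,
  linear).  Complex balance (`L·Ψ(x) = 0`) implies steadiness but not
  conversely.
* **syndeg** — zero-order synthesis and first-order degradation
  half-edges make the dynamics affine; a single auxiliary vertex `*`
  restores an ordinary graph, and when the augmented graph is strongly
  connected the unique steady state is `x_i = ρ*_i/ρ*_*`, automatically
  satisfying the overall balance `Σ s_i = Σ d_i x_i`.

## Conventions and parameters that matter

* **Symbol roles.**  Concentration symbols are bracketed (`[S]`), rate
  constants are bare names; both are declared positive.  The role is
  queryable from the name, which is what `validate_uncoupling` uses —
  no parsing heuristics.
* **Labels.**  Must evaluate strictly positive for positive symbol
  values; positivity is *sampled* at 10 log-uniform points in
  [1e-3, 1e3] rather than proven symbolically.  A zero label is
  rejected: "no edge" is the representation of a zero rate.  Parallel
  edges merge by summing labels (first-order fluxes are additive; the
  mod-form labels require this).
* **Free energies.**  `labels_from_energies` uses
  `K_ij = exp(−(G_j − G_i)/RT)` with the symmetric split
  `a = ω·√K`, `b = ω/√K` per reversible pair (`ω` the kinetic scale
  detailed balance leaves free).  The sign convention — lower energy,
  higher occupancy — is a documented package convention; it is
  self-consistent and round-trips through `energies_from_equilibrium`.
* **Context-dependent binding constants** are looked up by
  (conformation, site, occupancy-context) with fallback to
  (conformation, site) and then (site,), so cooperative systems stay
  expressible without exhaustive tables.
* **Vertex naming.**  User-facing vertices are strings (by convention
  `1…n`); `*` is reserved for the synthesis/degradation augmentation.

## Numerical choices

* **Two kernel routes, each the other's oracle.**  `rho_mtt` is
  exhaustive reverse-pruned backtracking over rooted spanning trees
  (deterministic order, configurable count cap, default 10^6;
  practical to ~12 vertices); `rho_minor` is the signed principal minor
  `(−1)^{n−1}·det`.  They are asserted identical symbolically.
* **Exact arithmetic where floating point is ill-posed.**  With labels
  spanning six decades, the alternating signs of a determinant cancel
  catastrophically: a float determinant can be off by 1e-7 relative
  while the all-positive tree sums are accurate to machine precision.
  `rho_minor` therefore lifts float labels to exact rationals (floats
  are binary fractions, so the lift is lossless) before taking the
  determinant.  For the same reason, rank/nullspace oracles in the test
  suite use exact rational linear algebra rather than SVD thresholds —
  a genuinely nonzero singular value of a badly conditioned Laplacian
  can sit at 5e-10 relative, below any safe threshold.
* **Symbolic equality** (`exprs_equal`) expands small differences to
  canonical polynomial form; above a ~2000-operation cap it switches to
  exact evaluation at random rational points (a nonzero rational
  function vanishes there with probability ≈ 0).  Mod-form
  distributions are deliberately left as uncancelled `ρ_i/Σρ`: forcing
  a common denominator across the per-mechanism rational labels blows
  up combinatorially and gains nothing.
* **ODE oracles.**  All "ground-truth" comparisons integrate the full
  nonlinear mass-action network (assembled reaction-by-reaction,
  independent of any Laplacian machinery) with LSODA at rtol 1e-10,
  in doubling time windows until `‖dx/dt‖∞ < tol·‖x‖∞`
  (default 1e-10).  Linear affine systems use a horizon of 40
  relaxation times of the slowest eigenmode.
* **Conservation solving** (PTM and ligand totals) runs damped
  root-finding (`scipy` hybr) in log-concentration coordinates — which
  enforces positivity — from a deterministic log-spaced grid in
  [1e-6, 1]·total per dimension plus a seeded random batch; roots are
  accepted at relative residual < 1e-10 and merged at relative distance
  1e-6.  The PTM conservation system is solved in `p + 1` unknowns
  (free enzymes plus free-substrate total): intermediates sequester
  substrate as well as enzyme, and including the substrate conservation
  law makes the framework solution agree with the full ODE to machine
  precision rather than to a sequestration-sized error.  The reported
  mod-form distribution is over free mod-forms; the ODE comparisons use
  the same quantity.
* **Cycle condition** is verified over a spanning-tree-induced
  fundamental cycle basis (sufficient, since every cycle composes from
  basis cycles; the small-n oracle enumerating all simple cycles agrees
  on fixtures).  Numeric ratio tolerance: relative 1e-9, configurable.
  The reported ratio for a failing cycle is orientation-dependent
  (ratio or its inverse).
* **Boundedness of open systems.**  Strong connectivity of the
  augmented graph is the sufficient condition used for the steady-state
  construction; `detect_unbounded` additionally applies a spectral
  check (max real eigenvalue of `L − Δ` restricted to the
  synthesis-reachable closed subsystem) for graphs that fail it.  The
  spectral branch is an extension beyond the strong-connectivity
  criterion and is labelled as such in its report.

## Synthetic data

The `fixtures` module generates every input family deterministically
from a seed (`SeedSequence` sub-streams per family, so adding a
generator never perturbs existing fixtures):

* random strongly connected graphs (random Hamiltonian cycle + extra
  edges at probability 0.35), random digraphs, and detailed-balanced
  graphs whose labels derive from a random vertex potential in
  [−3, 3] RT — the cycle condition then holds by construction;
* numeric labels are log-uniform over [1e-3, 1e3], the dynamic range a
  stiff biochemical network realistically spans;
* distributive kinase/phosphatase PTM systems on 1–4 binary sites, each
  single-bit conversion an irreversible one-intermediate mechanism with
  rate constants log-uniform in [10^-1.5, 10^1.5];
* the two-site sequential modification cycle ships with fixed default
  rate constants (nM, s^-1) in the literature-standard bistable regime
  of the dual futile cycle — fast second kinase step, kinase near
  saturation — where comparable enzyme totals give three coexisting
  conservation solutions;
* binding systems with one ligand per site and random constants, and
  random mass-action networks with ≤ 6 species/reactions and
  stoichiometries ≤ 2.

What the generators do *not* emulate: thermal noise and copy-number
stochasticity (all dynamics are deterministic mass-action), competing
ligands on one site, enzyme cascades where substrates are enzymes,
polypeptide modifiers with chain combinatorics, and regulated
(state-dependent) degradation.  Passing tests therefore demonstrate the
exactness of the eliminations for deterministic mass-action kinetics
under the uncoupling condition — not agreement with single-molecule
data or with systems violating those structural assumptions.

## Problem sizes

The test suite and the reproduction script use 200 random graphs
(n ≤ 7) for the kernel results, 100 detailed-balanced graphs, 100
open-system fixtures, 30 random reaction networks × 100 states, 1- and
2-site PTM systems checked end-to-end against the full ODE, and a 2×2
grid scan for multistability.  Symbolic identities are checked on
graphs of up to 5 vertices, where canonical expansion is cheap.  These
sizes keep every computation exact or at integrator precision while
exercising each code path at realistic connectivity.

## Known limitations

* Spanning-tree enumeration is exponential in general; beyond ~12
  vertices only the determinant route is practical, and beyond that
  symbolic determinants themselves grow quickly.  The framework's
  value is symbolic insight at moderate size, not large-scale numerics.
* `solve_conservation` finds roots by multi-start; completeness of the
  root set is heuristic (the starts are chosen to bracket the
  physically meaningful range, and all reported roots are
  residual-validated), not a certified enumeration.
* Non-strongly-connected augmented graphs have no steady-state recipe
  here: the module refuses rather than guessing.
* `check_complex_balanced` and `verify_decomposition` are numeric-first
  by design; symbolic CRNT identities are only exercised on small
  networks in tests.
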