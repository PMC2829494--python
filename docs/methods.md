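# Methods

## Scope and model

`glk` builds a parameterized genome-scale *linlog* kinetic model from a
stoichiometric reconstruction plus whatever kinetic data are available
(curated reference fluxes, reference concentrations, scaled elasticities),
and analyses the result with a metabolic control analysis (MCA) that remains
valid when the kinetic rank `rank(N·ε′)` falls below the stoichiometric rank
`rank(N)`.

The dynamical model is

    dx/dt = diag(c)⁻¹ · N · v(x),
    v_j(x) = v*_j · (1 + Σ_i ε_ij · ln(x_i / x*_i)),

with `N` the m×n stoichiometric matrix over internal (non-boundary)
metabolites, `c` the compartment volume of each metabolite, `(x*, v*)` a
reference steady state (mM, mM/s) and `ε_ij = ∂ln v_j / ∂ln x_i` the scaled
elasticities at the reference. Linlog kinetics is linear in the logarithms of
concentrations, so steady states and the Jacobian `diag(c)⁻¹·N·ε′` have
closed forms; the approximation is only trustworthy near the reference
state. Boundary (extracellular) species are held fixed and are not part of
the state vector.

## Network reduction

Compartmentalized reconstructions are reduced before parameterization:

* **Decompartmentalization** merges every intracellular compartment into
  one. Species are unified when they share a `(database, accession)`
  annotation pair; unannotated species fall back to case-insensitive name
  equality. Reactions whose stoichiometry cancels entirely (pure
  intracellular transport) are removed. The merged compartment's volume is
  the sum of the member volumes, conserving total intracellular volume.
  Membrane compartments count as intracellular unless reclassified in the
  input.
* **Isoenzyme lumping** collapses reactions with identical stoichiometry
  maps into one reaction carrying the union of catalysts; two reversible
  reactions that are global sign-flips of each other are also lumped.
  Reactions with identical maps but *different* reversibility flags are
  deliberately kept separate — merging them would silently change the
  feasible flux space. The survivor id is the lexicographically smallest,
  for determinism.
* **Biomass pseudo-reaction**: an irreversible sink consuming growth
  precursors in fixed proportions, flagged non-metabolic, used as the FBA
  objective when the reconstruction lacks one.

Both reductions are idempotent and can only shrink m, n and `rank(N)`.

## Unique reference flux

The reference flux `v*` is selected from the steady-state polytope
`{N v = 0, v_min ≤ v ≤ v_max}` by a lexicographic sequence of linear
programs (HiGHS throughout):

1. `Z*` — maximize the growth objective (skipped when no objective).
2. `D*` — minimize the L1 misfit `Σ_{j∈BM} |v_j − v_j^T|` to the known
   target fluxes, holding `f·v = Z*`. The ordering is configurable
   (`targets-first` drops growth optimality); lexicographic is the default.
3. `Z₁` — minimize total flux `Σ_j |v_j|` via the exact positive/negative
   split `v = v⁺ − v⁻`.
4. **Centering**: iterate — flux-variability bounds (2n LPs) under the
   accumulated constraints; centre = midpoint of each bound pair; impose
   the bound box; minimize `Σ_j |v_j − centre_j|`; retain the achieved
   distance `d_k` as the budget constraint `Σ|v_j − c_{k,j}| ≤ d_k(1+10⁻⁹)`.
   Stop when the widest bound interval is below the convergence tolerance
   (default 10⁻⁶ mM/s absolute, max 50 iterations).

Each stage optimum is frozen with a relative slack of 10⁻⁶ so solver
round-off cannot empty the polytope. The converged centre is unique by
construction even when intermediate LP witnesses are degenerate; bound
traces are nested and centre distances non-increasing. Default bounds are
±1000 mM/s (irreversible: [0, 1000]). All distances are L1 so every stage
stays a pure LP; an L2 target fit is available behind the
`distance_norm = l2` switch (smooth SLSQP solve, intended for small
problems).

## Parameter assignment and provenance

* **Concentrations**: known values (strictly positive) are taken as given;
  the remainder default to the *median of the known pool*
  (`default-median` provenance). When one parameter has several source
  records, they are median-aggregated first.
* **Elasticities** (tendency modelling): unknown `ε_ij` with `N_ij ≠ 0`
  default to `−N_ij` — reactant coefficients are negative, so substrates
  get positive elasticities — except products of irreversible reactions,
  which get exactly 0. These defaults equal the scaled elasticities of a
  mass-action rate law, which the test suite verifies by symbolic
  differentiation. Effector entries (`N_ij = 0`) enter only through the
  known-elasticity table.
* Every parameter carries exactly one provenance record
  (`organism-match`, `other-organism`, `default-median`,
  `tendency-estimate`, `user`) with an optional origin reference; the
  pipeline reports counts per class and the SBML export writes origins as
  MIRIAM-style urn annotations.

The packaged tables `yeast_targets.tsv` (21 curated fluxes, one of them
zero), `yeast_concentrations.tsv` (22 intracellular values; pool median
≈ 0.18 mM) and `yeast_extracellular.tsv` (28 footprinting-medium values)
reproduce the published yeast inputs. `biomass_synthetic.tsv` is a synthetic
demonstration composition, not a curated one.

## Control analysis under rank deficiency

The unscaled elasticity matrix is `ε′ = diag(v*)·εᵀ·diag(1/x*)` (n×m), so a
zero-flux reaction contributes an all-zero row. Consequently
`A = diag(c)⁻¹·N·ε′` can have rank `m₀ < rank(N)`: the number of
*kinetically* independent metabolites is smaller than stoichiometry alone
suggests. The link matrix is built directly from A:

    L = A · A_r⁺,   A_r = the first m₀ linearly independent rows of A,

with `⁺` the Moore–Penrose pseudoinverse; `A = L·A_r` and the rows of L at
the independent positions form the identity. Control coefficients follow as

    C^S′ = −L (N_r ε′ L)⁻¹ N_r,   C^J′ = I + ε′ C^S′,

from which the summation (`C^J′ v* = v*`, `C^S′ v* = 0`) and connectivity
(`C^J′ ε′ L = 0`, `C^S′ ε′ L = −L`) theorems follow algebraically;
`verify_theorems` checks all four to 10⁻⁶ relative (observed residuals on
the test fixtures are ≲10⁻¹²). When `rank(N ε′) = rank(N)` the construction
reduces to the classical one built from the independent rows of N;
`reder_equivalence_check` verifies the two routes agree and reports
not-applicable otherwise. Scaled flux control coefficients use
`C^J_ij = C^J′_ij · v*_j / v*_i`, masked (NaN plus an explicit boolean mask,
never silently zero) wherever a reference flux vanishes.

An independent perturbation oracle multiplies one reaction rate by
`(1 + δ)` (default δ = 10⁻⁶), solves the linearized system for the displaced
steady state and returns `Δx/(δ v*_j)` and `Δv/(δ v*_j)` as estimates of the
corresponding control-coefficient columns.

## Numerical choices

* **Numerical rank**: singular values below `rank_tolerance · σ_max` are
  zero; default `rank_tolerance = 10⁻⁹` (recommend 10⁻⁶ for sparse, badly
  scaled genome-scale data).
* **Independent rows**: greedy modified Gram–Schmidt in natural row order
  (first independent rows win), falling back to pivoted QR if the greedy
  sweep undershoots the SVD rank. The choice of r is not unique; the
  control coefficients are invariant to it (tested), only L's layout
  changes.
* Link reconstruction is required to satisfy `‖A − L·A_r‖∞ ≤ 10⁻⁸·‖A‖∞`;
  `(N_r ε′ L)` with condition number above 10¹² is rejected with advice to
  raise the rank tolerance.
* Steady-state feasibility `‖N v‖∞` is expected below 10⁻⁹ on desk-scale
  problems (HiGHS basis solutions), 10⁻⁶ at genome scale.
* Degenerate LP ties are left to the solver; only the converged centre is
  guaranteed deterministic.

## Fixtures: what they emulate and what they do not

The fixture generator provides a linear chain (pointlike flux polytope,
supply-controlled MCA hand solution), a symmetric diamond (centering must
return the 0.5/0.5 branch split), an ATP/ADP moiety cycle (conserved pair,
`m₀ = 1 < m = 2`) and seeded random sparse networks built on a cycle
backbone so that a nonzero steady-state flux is certified by construction.
Their "known answers" are hand- or closed-form-derived, never produced by
the package, so they act as independent oracles. Test problem sizes are
kept small (≤ 15 reactions, 20 random seeds) — large enough to exercise
rank deficiency and degeneracy, small enough that hand answers exist.
Passing them demonstrates algebraic and algorithmic correctness; it says
nothing about the biological fidelity of any particular reconstruction,
curation quality, or the accuracy of linlog kinetics far from the
reference state.

The genome-scale validation (published reduction counts 1059/956/820 and
rank figures 616/205) requires the deposited consensus yeast network, which
is far too large to ship inside the package; the corresponding test looks
for a user-supplied copy under `data/external/` and fails with instructions
otherwise.

## Known limitations

* Linlog rates are undefined at zero concentrations and unreliable far from
  the reference state; rates may legitimately go negative.
* No thermodynamic or loopless constraints in flux estimation; no
  gene–protein–reaction logic; no mass/charge balancing.
* The L2 distance option uses a dense smooth solver and does not scale.
* Co-transported species in merged compartments follow the
  empty-stoichiometry cancellation rule; protonation bookkeeping across
  merged compartments is not modelled.
* Scaled control coefficients adopt the standard normalization
  `v*_j / v*_i`; published tables computed under a different scaling
  convention may differ by per-row factors.
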