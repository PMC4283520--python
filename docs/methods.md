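# Methods

## Scope and model structure

`emforce` implements a hybrid kinetic–stoichiometric strain-design
computation for metabolic networks.  The network's reactions are split
into a kinetic subnetwork J_kin, described by elementary mass-action
kinetics and therefore carrying a (generally unique) steady-state flux,
and a stoichiometric remainder J_stoic constrained only by mass balance
and flux bounds.  Fluxes are expressed per 100 units of carbon-source
uptake (mmol gDW⁻¹ h⁻¹ on a −100 glucose basis, exchange reactions
written outward so uptake is negative); metabolite concentrations are
normalized to 1 at the reference steady state.

## Elementary kinetics and ensemble anchoring

Each enzymatic reaction is decomposed into a cycle of elementary steps —
ordered substrate binding, one catalytic step, ordered product release —
each step exchanging exactly one enzyme state for another, so total
enzyme is conserved by construction.  A uni-uni reaction therefore has
two steps (E + A ⇌ EA, EA ⇌ E + B); bi-bi ordered has four.  Substrate-
level regulation is restricted to competitive (dead-end) inhibition,
which adds a binding step from the free enzyme to an inactive state, and
simple activation, where the cycle turns over only from an
activator-bound enzyme state.  Richer rate laws (Hill, ping-pong with
more than two substrates) are out of scope; the mechanism kind is
declared per reaction (TSV: `reaction_id  kind  regulator:mode,...`).

A parameterization is not drawn in rate-constant space but in the
ensemble-modeling coordinates:

* step reversibilities R_l = v_b/v_f ∈ (0,1), sampled uniformly on
  [0.05, 0.95] by default (the truncation avoids near-singular rate
  constants as R → 1; the full interval is available via
  `SamplingConfig`);
* enzyme fractions e, uniform on the simplex (symmetric Dirichlet,
  concentration 1).

Given the reference net flux v_ref, the elementary fluxes follow from
v_f = v_ref/(1−R) and v_b = R·v_ref/(1−R), and rate constants are fixed
by requiring those fluxes at reference fractions and unit concentrations
("anchoring").  Every sampled member therefore reproduces the reference
flux distribution exactly (anchoring residual < 1e−9 is enforced at
construction and re-verified by simulation in the tests).  Special
cases, each a deliberate design choice:

* v_ref < 0: the mechanism is flipped so the anchored cycle runs
  net-forward internally; the sign is restored on output.
* v_ref = 0: the ratio form is undefined, so every step is anchored at
  equilibrium with a sampled exchange magnitude v_f = v_b uniform on
  (0, 1] (normalized flux units).  This keeps zero-flux reactions
  responsive to perturbations instead of freezing them.
* Regulator binding steps carry zero net flux at any steady state and are
  likewise anchored by a sampled exchange magnitude.
* Total enzyme e_tot is bounded (knockout 0, up to 10-fold
  up-regulation); the individual enzyme fractions are *not* separately
  bounded — they are simplex-constrained state variables that evolve
  under the ODEs, so bounding them independently of e_tot would be
  ill-posed.  Only e_tot is constrained.

## Steady-state simulation

The kinetic subnetwork is simulated as mass-action ODEs over the dynamic
metabolite concentrations and all enzyme-state amounts.  Boundary
treatment: the uptake exchange flux is clamped at the basis value (the
training data are normalized per uptake, so the model deliberately cannot
predict uptake changes), and metabolites shared with non-fixed
stoichiometric reactions are clamped at their reference concentration.
Fluxes of those stoichiometric reactions are completed from the kinetic
net fluxes by least squares on the clamped-metabolite balances (exactly
determined on the shipped fixtures).

The solver integrates with LSODA to t = 50, refines with a damped-Newton
root solve on a reduced state (one enzyme-state amount per reaction
eliminated by conservation, avoiding the conservation-law singularity of
the Jacobian), and falls back to integration to t = 1e3 (normalized time)
if the refinement fails.  Steady tolerance: max |dc/dt| < 1e−9.
Divergence or failure to settle returns a non-converged result rather
than raising.  Exact knockouts are snapped to zero enzyme so integrator
round-off can never leave residual flux in a deleted reaction.

## Mutant data and GA selection

The synthetic-data generator emulates the experimental setting the
method was built for: a wild-type strain plus single-gene-deletion
mutants, with measured fluxes for the kinetic reactions and exchanges,
normalized per 100 units of uptake.  Noise, when enabled, is
multiplicative Gaussian (default 5% relative — no noise model is
prescribed by the setting, so this is a documented choice), never applied
to the uptake flux (the normalization basis) and clipped so it cannot
flip a flux sign.  Non-converged strains are excluded with a warning in
the dataset metadata.

Fitness of a parameterization is the sum over strains and measured
reactions of squared scaled deviations, scale = reported SD if present,
else max(|v_meas|, one flux unit on the dataset basis); simulated fluxes
are converted to the dataset's uptake basis first, which makes the score
invariant under a common rescaling of measurements and basis.  A
non-converged strain contributes a fixed penalty (1e6, far above any
converged score).

The genetic algorithm works on genomes whose genes are whole per-reaction
parameter blocks: crossover swaps blocks between parents (anchoring is
preserved because blocks are swapped whole), mutation resamples one
reaction's block, selection is binary tournament, and elitism makes the
best score non-increasing.  Defaults: population 50, 200 generations,
crossover 0.9, mutation 0.05 per reaction, elitism 1; `fitness_tol`
enables early stopping once the target deviation is reached.  All
randomness flows from one seed; the pipeline derives per-stage seeds from
a master seed by fixed offsets (data +0, noise +1, ensemble +2, GA +3) so
stages can be rerun independently — and so the fitted ensemble never
accidentally contains the ground-truth member in recovery experiments.

An honest caveat established by the recovery experiments on the branched
fixture: with a fixed uptake basis, knockout steady-state fluxes in a
tree-shaped network are fully determined by stoichiometry, so knockout
training data discriminate parameterizations mainly through steady-state
*existence* (saturation limits), not flux values.  Held-out fold-change
predictions are correspondingly tighter near-linear regimes than a
genome-scale network would exhibit; passing the recovery test shows
consistency of the machinery, not identifiability of every kinetic
parameter.

## MUST classification

A reaction must increase (MUST^U) or decrease (MUST^L) when its flux
range in the overproduction space lies strictly above or below its range
in the reference space (margin ε = 1e−6 absorbs LP noise).  The reference
space honors kinetic uniqueness: kinetic reactions are pinned at their
reference flux (their reference range is a point), and stoichiometric
reactions get FVA ranges with those fluxes fixed and condition uptake
bounds applied.  The overproduction space is stoichiometric FVA under the
condition plus floors at 90% of the product's and 10% of the biomass's
theoretical maxima (both configurable); using a purely stoichiometric
overproduction side (kinetic fluxes free) is a documented choice — it
yields a superset of attainable states and therefore never misclassifies
a reaction as MUST.  Only single-reaction MUST sets are computed;
pairwise sets from the original bilevel formalism are out of scope.

## Two-step FORCE design

Step 1 (kinetic): for each subset of kinetic MUST reactions up to the
budget κ, a steady-state-constrained NLP maximizes the product flux over
e_tot of the selected reactions, all enzyme-state amounts, and dynamic
concentrations, subject to: mass-action stationarity as equality
constraints; enzyme totals equal to e_tot; concentrations within a
fivefold band of reference (default); biomass at or above its floor; and
the piecewise selection bounds on e_tot — unselected [1, 1], selected
down-regulation [0, 1] (removal is the 0 endpoint, e_tot continuous),
selected up-regulation [1, z] with z = 10 by default.  The NLP is solved
by multistart SLSQP (starts on an e_tot grid; feasible returned points
are accepted even when SLSQP reports a line-search exit, since
feasibility is re-checked explicitly), and every candidate optimum is
verified by ODE relaxation from the perturbed reference so that only
dynamically reachable steady states are reported.  Ties break toward
fewer interventions, then lexicographic order.

Step 2 (stoichiometric): with the kinetic fluxes fixed at the step-1
optimum, subsets of stoichiometric MUST reactions within the remaining
budget are enumerated; a selected MUST^U reaction has its lower bound
raised to its overproduction-space minimum, a MUST^L reaction its upper
bound lowered to the overproduction-space maximum.  The inner LP
minimizes the product flux over the remaining degrees of freedom
(worst case), and the reported value must satisfy strong duality against
the solver's dual objective within 1e−6.

Budget escalation runs κ = 1, 2, … and stops once the improvement in
achieved product flux, measured as a fraction of the new value, falls
below 1% (no threshold is canonical; 1% is the documented default — and
defining the fraction against the new value makes a threshold of 1 stop
after the first design).  Achieved flux is non-decreasing in κ; the
worst-case value never exceeds it.  Yields are reported as mol product
per mol carbon source = product flux / 100 on the per-100 basis.

The two-step split can in principle miss designs that jointly exploit
kinetic and stoichiometric manipulations; `enumerate_oracle` implements
the same split by an independent route — dense e_tot grids evaluated by
ODE relaxation, refined by Nelder-Mead, plus single LPs for the
stoichiometric step — and is used to validate the NLP path on small
instances (agreement within 1e−4 relative is asserted in the tests).

## Solvers and numerics

All LPs use scipy's HiGHS interface; feasibility tolerance 1e−9,
optimality 1e−8; dual objectives are reconstructed from solver marginals
for the duality checks.  No MINLP solver is required: at desk scale the
exhaustive-enumeration strategy is exact over the discrete choices and
multistart over the continuous ones.  The independent constraint-based
cross-check in the tests goes through cobrapy/GLPK so the two LP routes
share no code.

## Fixture and problem sizes

The canonical fixture is a branched toy: fixed 100-unit uptake, a
two-step backbone, and a branch point splitting 20/80 between a product
export and a waste export that doubles as the biomass proxy.  Its numbers
are chosen for closed-form checkability (theoretical product maximum 100;
with the 10% biomass floor, 90).  Random chain-and-branch toys (≤ 25
reactions) extend the MUST-oracle comparison.  Test problem sizes — 100
anchoring draws, a 50-member ensemble, 20 oracle networks, κ ≤ 3 — keep
the full suite at roughly two minutes while exercising every code path;
they are fixture-scale choices, and none of the toy results quantify
behavior on genome-scale networks.

## Known limitations

* Regulation is boolean at the condition level (repression/activation
  rules) and competitive/essential at the substrate level; graded
  transcriptional kinetics and toxicity effects are not modeled.
* The kinetic boundary treatment (clamped interface metabolites, fixed
  uptake) is one defensible convention; alternatives (dynamic drains)
  would change perturbed flux splits.
* Step-1 optimality is certified only against the enumeration oracle at
  desk scale; the NLP is nonconvex and multistart SLSQP carries no global
  guarantee at larger κ or network size.
* Pure-FBA degenerate mode (empty kinetic set) is supported by the data
  model, but the design step then reduces to bound manipulation only.
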