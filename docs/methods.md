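# Methods

## Model and assumptions

The package models de-novo riboflavin biosynthesis as an open, irreversible
reaction network in a single well-mixed volume.  Enzymatic steps follow
single-substrate Michaelis–Menten kinetics; lumazine synthase (LS) and
riboflavin kinase (RK) use the two-substrate form
`Vmax·A·B/(KmA·KmB + A·KmB + B·KmA + A·B)`, which factorises into the
product of the two saturation terms and reduces to the single-substrate law
when the co-substrate saturates.  No product inhibition, reversibility,
allosteric regulation or explicit compartment volumes are modelled: the
hypothesised plastid/cytosol translocations are plain transport steps in one
volume.

### Network composition

The canonical network has 12 metabolites and 14 reactions, external
transport included.  The reaction list is shipped as an editable record
table (`CANONICAL_TOPOLOGY`), so a transcribed literature table can replace
it without code changes.  Choices that were genuinely open:

* **Riboflavin synthase stoichiometry.**  RS is modelled as a dismutation,
  `2 DMRYL -> riboflavin + ARP`, with single-substrate kinetics in DMRYL.
  The recycled pyrimidine makes the overall pathway consume two Rub5P per
  GTP, the standard riboflavin-synthase chemistry.
* **LS coefficients.**  LS condenses ARP and DHB4P 1:1; no source states
  other coefficients.
* **The two ARP pools.**  The translocation of the pyrimidine (ARP) into
  the plastid is a real reaction of the network, so ARP is tracked as a
  cytosolic and a plastidial pool (the RS-recycled pyrimidine re-enters the
  plastidial pool directly).  FAD translocation to the cytosol and FAD
  export, by contrast, are modelled as two parallel sinks on a single FAD
  pool: the translocated cytosolic FAD lies outside the model boundary.
  This keeps the species count at 12 with both hypothesised translocations
  present, and it makes the flux-closure system exactly solvable (see
  below).  Splitting FAD instead would add a 13th species whose closure is
  generically only solvable in the least-squares sense.
* **RK's co-substrate.**  ATP is not one of the tracked species; it enters
  RK's two-substrate law as a clamped constant (default 3×10⁶ nM,
  configurable per parameter set).

### Units

Tabulated Vmax values are in nmol/(mg protein·min); the simulated state is
nM with time in seconds.  Because the effective enzyme abundance (mg protein
per litre) behind such tables is never known, a single configurable factor
`vmax_scale` converts tabulated Vmax to a volumetric nM/s rate.  The default
is 1/60 — i.e. one tabulated unit is read as 1 nmol/L/min of pathway
capacity — and should be recalibrated whenever a real abundance estimate is
available.  Riboflavin is reported in µmol/L (= nM/1000) at the reporting
layer only; internal state stays in nM.

## Boundary-flux prediction (stoichiometric closure)

Four reactions have no kinetic constants: GTP import, Rub5P import, FAD
synthetase and FAD export.  Their fluxes are predicted from the
stoichiometric sub-model: all kinetic fluxes are evaluated at a reference
state (by default the initial concentrations) and the unknown fluxes are
chosen so that `S·v = 0` holds on every metabolite balance that involves at
least one unknown (the *closure system*).  Balances composed purely of
kinetic fluxes cannot be influenced by the unknowns and are excluded; their
imbalance is what the simulation subsequently integrates.  For the canonical
network the closure system is triangular (GTP, Rub5P, FMN and FAD balances)
and exactly solvable; on other networks a least-squares solution is returned
with its residual.  FADS is the one *internal* reaction whose flux is
predicted this way, from the FMN balance.  Predicted fluxes are frozen as
zero-order boundary fluxes; an LP mode (`fba_fluxes`, HiGHS) is provided as
an alternative predictor for sensitivity analysis — the default predictor is
closure because no objective function is implied by the problem.

Zero-order sinks are depletion-guarded: a fixed flux consuming a tracked
species is scaled by `s/(s+ε)` with ε = 10⁻⁶ nM, so it switches off smoothly
at depletion instead of driving the pool negative.  At working
concentrations the correction is ≤ 10⁻⁸ relative.

## Simulation

The ODE system `dC/dt = S·v(C)` (boundary species clamped) is integrated
with LSODA via `scipy.integrate.solve_ivp`, rtol 10⁻⁶ and atol 10⁻⁹ nM
(common biochemical-simulator defaults; no tolerances are prescribed by the
problem).  Dense output decouples reported concentrations from the output
grid.  Tiny negative excursions beyond −10·atol are clipped with a warning.
The default horizon is 1500 s.  Plateau detection is an operational stand-in
for a visual judgement: the earliest `t` where the species changes by less
than `rel_tol` (default 10⁻³) relative over a window (default 150 s).
Steady-state search integrates in growing chunks until max|dC/dt| over
internal metabolites falls below a tolerance (default 10⁻⁶ nM/s) or `t_max`
is reached; the initial state counts, so a balanced model converges at t=0.

## Overexpression scan and control analysis

Overexpression multiplies an enzyme's Vmax by a fold factor; the
bifunctional RibA scales its GTPCHII and DHBPS activities together (one gene
dose).  The fold behind published "optimised enzyme" scenarios is typically
unstated; the default is 10, and `calibrate_fold` recovers a fold from a
reported baseline/scenario end-point pair by log-space bisection.

Each scenario **re-predicts** the closure-derived boundary fluxes at its own
initial state before simulating.  This is a deliberate design choice:
boundary transport is demand-driven, so an enzyme with higher capacity draws
proportionally more precursor.  With fluxes frozen at baseline values, every
scenario would be import-capped and the scan could not discriminate between
enzymes at all.  User-fixed boundary fluxes (as in the toy fixtures) are
never touched — only fluxes tagged as closure-predicted are re-derived.

The end-point metric is riboflavin at `t_end` (matching a time-course
read-out), not steady-state flux; scenarios need not have plateaued at
`t_end`.  Ranking is by end-point gain over baseline, ties broken
alphabetically and flagged.

Control coefficients are central finite differences of a steady-state
observable (a reaction flux or a species concentration) with respect to each
reaction's rate parameter, scaled to elasticities
`C_i = (p_i/O)·∂O/∂p_i` (default perturbation ±1%).  Flux-control
coefficients over a pathway flux sum to 1 (summation theorem) when *all*
reactions, boundary fluxes included, are perturbed.  Note a structural
caveat of frozen zero-order sinks: perturbing a supply step of a pool whose
only consumption is a frozen zero-order flux yields a system with no steady
state (the fixed sink can never rebalance), so control analysis of the
canonical model should either restrict the perturbed reaction set or clamp
the affected species; the toy chains have no such pool.

## Synthetic data

The generators emulate the *structure* of curated kinetic tables, not their
values: log-uniform Km on [10², 10⁶] nM, Vmax on [10⁻¹, 10²] nmol/mg/min,
initial concentrations on [10², 10⁵] nM (chosen to bracket typical
magnitudes for flavinogenesis enzymes), one entry per kinetic reaction, two
Km values for the two-substrate reactions, all bit-reproducible from a seed.
`perturb_parameters` builds robustness ensembles with mean-1 log-normal
factors of given CV.

The packaged "reference" fixture is hand-designed, not sampled: RibA's two
activities carry roughly an order of magnitude less capacity than every
downstream enzyme, making it the binding constraint by construction, and the
initial concentrations are computed analytically (by inverting each rate
law at the designed branch fluxes of 0.5 nM/s on the pyrimidine side and
1.0 nM/s on the butanone side) so that the baseline starts exactly at its
operating point.  The baseline time course is therefore flat — its plateau —
while overexpression scenarios depart from it, which is what the scan
measures.  What passing tests on this fixture show is that the *method*
(closure, integration, scan, ranking) behaves correctly and that the
rate-limiting-step identification is robust to parameter noise around a
known ground truth; they say nothing about the kinetics of any real plant,
for which a transcribed parameter table must be supplied.

## Numerical choices and limitations

* Closure residuals are reported; the closure system itself is solved to
  machine precision when full rank, and a rank-deficient system raises with
  the unconstrained fluxes named.
* The LP mode requires finite bounds and reports infeasibility and
  unboundedness explicitly.
* SBML export writes L3V1 with kinetic laws as MathML over local parameters
  named `vmax`/`km_a`/`km_b`/`clamp_b`/`flux`; the importer recovers the
  law kind from those names rather than re-parsing MathML symbolically, so
  only documents following this convention (including any hand-written
  ones) round-trip.  Unresolved boundary fluxes export as 0.
* Problem sizes used in the shipped checks — 1500 s horizons, 100-member
  ensembles, 200 random draws for the robustness contract, ≤6-reaction toys
  for vertex-enumeration cross-checks — keep the full suite under a minute
  on one CPU while exercising every code path; all are configurable.
* Not modelled: enzyme mechanism beyond MM (no inhibition or
  reversibility), thermodynamic constraints, compartment volumes,
  stochastic kinetics, knockouts, multi-gene combinatorial overexpression,
  and parameter fitting to data.
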