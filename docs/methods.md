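# Methods

This note records the modeling assumptions, numerical choices and limitations
behind `srcmkin`.  It documents what the code does and why; every number
quoted here is computed by the test suite or by `scripts/acceptance.py`.

## The compartmental model

The shipped network spans three unit-volume compartments — acidogen cytoplasm
(CAC), shared medium, methanogen cytoplasm (MAC) — so concentration balance
and amount balance coincide (fluxes are uniformly mmol/min/ml and the model
declares no volumes).  Mass balance is dx/dt = S·v over internal species
only.  Three species classes sit outside the balance:

* **Feed and off-gas boundary species** (medium glycine/alanine/proline,
  dissolved H₂ and CO₂, exported CH₄): clamped at their declared
  concentrations, implementing the input vector u(t) as constant clamps.
  A feed schedule can be emulated by re-applying a scenario between runs.
* **Cofactor pools** (NAD⁺/NADH, ATP/ADP/AMP, Pi/PPi, thioredoxin, PEP,
  sulfite): clamped as homeostatically buffered.  The pathway description
  provides no regeneration kinetics, and without buffering the glycine-only
  scenario stalls the moment the NADH pool is exhausted — a statement about
  missing reactions, not about the chemistry being modeled.
* **Enzyme pools**: modifier species with assigned initial concentrations.
  They enter rate laws only by scaling V_max (V_max = k_cat·[E], enzyme
  levels constant) and they count toward the compartment metabolite census,
  which is how the published counts (24 in CAC, 37 in MAC) are reached.

Reactions are irreversible by default (the pathway arrows are
unidirectional); reversibility is an explicit flag evaluated as a net
forward-minus-reverse mass-action law (used by the control-analysis toys).
Intracellular reactions use Michaelis–Menten kinetics — a product of
saturation factors over the declared driving substrates — and transport
reactions use generalized mass action, first-order by default.  Water and
protons are implicit.

### Transcription choices in the shipped network

The full reaction/species tables of the original reconstruction are not
publicly distributed, so `data/srcm_network.yaml` is a transcription from
the narrative pathway description; each entry is marked `transcribed` (stated
chemistry) or `inferred` (this package's reconstruction).  Decisions a
reviewer should know about:

* **Reaction ids.**  R1 (alanine dehydrogenase), R2 (glycine → acetate via
  L-amino-acid dehydrogenase), R3 (glycine reductase), R5/R6
  (phosphotransacetylase/acetate kinase), R8 (acetate activation), R9
  (CODH CO₂/CO interconversion), R11 (methyl transfer), R13 (methyl-CoM
  reductase), R14 (heterodisulfide reductase) and M15 (coenzyme M synthesis)
  follow the ids used in the source narrative; R4, R7, R10, R12 and M16–M18
  complete the census and are this package's assignment.
* **Glycine reductase stoichiometry** (not printed anywhere): glycine + Pi +
  2[H] → acetyl-phosphate + NH₃, with NADH as the lumped electron donor and
  the thioredoxin couple carried as modifiers.  Acetate kinase (R6) then
  yields acetate + ATP, so reduced thioredoxin and ATP appear exactly as the
  described end products.
* **R9 direction.**  The narrative ties R9 to "CO₂ from CO" without fixing a
  direction.  It is modeled reductively (CO₂ + H₂ → CO): a futile CODH branch
  that competes with heterodisulfide reduction for scarce reducing
  equivalents.  This gives the optimization result its mechanism (see below)
  and is flagged `inferred`.
* **Medium ownership.**  The six shared metabolites (formate, acetate,
  pyruvate, CO₂, NH₃, H₂) belong to the medium compartment and are excluded
  from the intracellular censuses.  Each membrane carries exactly 6 exchange
  reactions; a transporter is counted in both compartments it touches, so
  CAC and MAC each see 6 and the medium sees 12.
* **Dissolved H₂ is clamped at 1 µmol/ml** — low interspecies hydrogen is the
  hallmark of syntrophy, and it makes H₂ a genuinely contested resource
  between R9 and R14.
* **Proline** enters the medium from gelatin but has no consuming reaction
  (only glycine/alanine catabolism is modeled): a boundary dead end, as is
  the oxidized thioredoxin partner.
* **No CO₂ is produced by the methanogen** in this transcription (the
  carbonyl branch ends in CO); aceticlastic CH₃COOH → CH₄ + CO₂ is therefore
  not atom-complete here.  Atom/charge balancing of the real reactions is
  out of scope — charges are annotations, not constraints.

## Simulation

* **Deterministic**: LSODA (adaptive, stiffness-switching) with defaults
  rtol 1e-8, atol 1e-12, output every 1.0 min, and an internal-step budget
  of 10,000 — the batch-mode protocol of the source study.  The right-hand
  side evaluates rate laws at max(x, 0); outputs are projected to zero where
  the integrator undershoots and the count plus the raw minimum are recorded
  in `Trajectory.clipped_points` / `metadata["min_raw_concentration"]`.
  On toy systems at default tolerances the raw minimum stays above −atol
  (asserted in the suite).
* **Stochastic**: Gibson–Bruck next-reaction method with an indexed priority
  queue of putative firing times and a dependency graph for propensity
  updates; exact ties fire the lowest reaction index.  Copy numbers are
  round(c·ω); propensities are the macroscopic laws evaluated at n/ω and
  scaled by ω, which for saturating MM laws is the standard macroscopic
  approximation (documented, not exact).  One NumPy generator per run seeded
  from `settings.seed`; replicate r of a study uses seed + r, so runs are
  bit-reproducible.  At ω = 10⁵ the 100-replicate mean of a two-step chain
  stays within 2% of the ODE solution (acceptance suite).

## Control analysis

Steady states solve S·v = 0 by damped Newton (finite-difference Jacobian,
backtracking line search, non-negativity projection) with a long-time
integration fallback, residual tolerance 1e-9.  Stability is judged from the
eigenvalues of the internal-species Jacobian (central differences, step
max(1e-8, 1e-6·|xᵢ|)).

Elasticities are analytic: K_m/(K_m+S) per MM saturation factor, 1 for a
modifier (V_max ∝ [E]), the kinetic order for power laws.  A scaled
elasticity at xᵢ = 0 or vⱼ = 0 is reported as NaN and flagged — the scaling
xᵢ/vⱼ is degenerate there — never silently zeroed.

Flux control coefficients perturb each enzyme's activity (V_max or k, with a
reversible pair scaled together) by ±1% by default, re-solve the steady
state, and difference centrally.  The published description fixes no
perturbation size; 1% is this package's documented choice, and the
FCC-dependent claims in the suite are closed-form/property checks (two-step
pathway C₁ = k₂/(k₋₁+k₂), summation and connectivity theorems to 1e-3), not
value reproductions.

Local sensitivity is a central-difference derivative of whole trajectories
with a per-species |Δx| area-under-curve summary; a Richardson check in the
suite confirms second-order convergence.

## Optimization and fitting

Candidates are evaluated at the steady state when one is requested and
exists, otherwise at the end of the batch horizon (default here: 30 min —
the pre-steady-state protocol; with clamped feeds the drawn parameterizations
often have no finite steady state, since uptake can exceed saturable
capacity).  The scalarized objective is Σ w·J(maximize) − Σ w·J(minimize)
with shipped weights 1.0 and 0.1 and defaults maximize = {R13},
minimize = {R1, R2, R3}.  Decision variables default to the activities of
R3, R5, R9 and R11 within [0.2×, 5×] of baseline — the reactions the source
narrative singles out as falling (R3, R9) and rising (R5, R11) under
optimization.

The search is seeded differential evolution (bounded, derivative-free,
polish off) followed by a deterministic **parsimony refinement**: each
decision activity is dropped to its lower bound whenever that does not
reduce the objective.  Rationale: when methane flux is tiny the objective
gradient along a futile branch (lowering R9 frees H₂ worth ~1e-5 mmol/min/ml)
is far below DE's resolution at a few hundred evaluations; minimal enzyme
investment is the standard tie-break and makes the down-regulation of
non-contributing branches deterministic.  The reported optimum never falls
below the starting point.

With these fixed weights the catabolic penalty can dominate the (often ~30×
smaller) methane term, so a strict methane increase is the typical but not
universal outcome across parameter-table seeds; the canonical shipped
conditions (table seed 0) show methane rising while R3 and R9 fall.

Fitting is bounded trust-region least squares on concentration residuals,
optionally log-scaled — the statistically matched weighting for the
multiplicative noise model, and the difference between ~12% and ~4% median
K_m error in the recovery study.  Multistart draws log-uniform initial
points under the given seed; integrator failures return a large penalty
residual.

## Synthetic data

`generate_parameter_table` draws log-uniform kinetic constants — K_m in
[0.01, 10] mmol/ml, V_max in [0.1, 10] mmol/min/ml, transport k in
[0.01, 10] min⁻¹ — deterministically under a seed; kinetic orders default
to 1 and initial concentrations come from the structure file.  The table is
a labeled synthetic stand-in for a measured parameter supplement, emulating
its schema (reaction, enzyme, substrate, K_m, V_max, initial concentration).
Not every seed yields a model with a finite steady state (see above); the
analysis stack is built to tolerate that, and attainment is not hidden
behind seed selection.

Observation noise is multiplicative lognormal with mean 1 and coefficient of
variation exactly `noise_cv` (σ² = ln(1+cv²), mean-corrected), independent
per point and replicate, truncated at zero.  This emulates positive,
decade-spanning metabolomic time courses; it does not emulate real digester
error structure (autocorrelation, detection limits, gas–liquid partitioning
of CH₄/CO₂ are out of scope).  Consequently the recovery studies demonstrate
estimator correctness under the stated noise model, not field performance.

The designated identifiable subset for the end-to-end closure test is the
transport triplet {glycine uptake T2, acetate export T3, acetate uptake T7}
observed through gly_c, ac_c, ac_e and ac_m: first-order transport rates are
strongly identified by the pools on both sides, whereas far-downstream
V_max values (e.g. R13) are conditionally identifiable at best when the step
is not rate-limiting.

## Interchange

SBML Level 3 Version 1 was chosen over L2 for explicit unit support (mmol,
ml, min declared as unit definitions).  The writer emits canonical MathML
for the two law shapes with local parameters; metabolite charges and
transporter classes travel in a package annotation namespace (L3 core has no
charge attribute).  The reader accepts exactly those canonical shapes and
rejects anything else with a named-reaction message — it is a subset codec
for this package's models, not a general SBML consumer.  Round-trip identity
(census and rate evaluations to 1e-9 at random states) is asserted in the
suite.  CLI runs emit a JSON manifest (command, config hash, seeds, package
version, file digests); config files are YAML with CLI flags taking
precedence.

## Problem sizes

Default study sizes were chosen to characterize each method adequately:
stochastic agreement uses 100 replicates at ω = 10⁵ (≈1000 initial copies)
and 1000 replicates for the pure-death mean; recovery uses 50-point time
courses and 20 replicate fits; optimization uses ~400 objective evaluations
(DE popsize 6 × 12 generations over 4 parameters) at rtol 1e-6.

## Known limitations

* The synthetic parameter tables are stand-ins; absolute flux values
  (e.g. the optimized methane rates) are not comparable to measured ones,
  only the structural and qualitative results are.
* MM propensities in the stochastic simulator are a macroscopic
  approximation; exact SSA semantics hold only for elementary mass action.
* Clamped cofactor pools remove conservation constraints (energy/redox
  balance is not enforced).
* The SBML codec covers the package's law subset only.
* No thermodynamic (ΔG) feasibility checking; reversibility is structural.
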