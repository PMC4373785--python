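# Methods

## The linear inverse model

All three analyses operate on one constraint system over the flux vector
x (mmol/min, one component per reaction, in model order):

* **Equalities `E x = f`.** The upper rows of E are the stoichiometric
  matrix restricted to *internal* metabolites (boundary species — flagged
  in SBML or carrying the BiGG `_b` suffix — are exchanged with the
  environment and not balanced). Their right-hand side is 0: the
  steady-state assumption. Below them, one unit row per *fixed* flux pins
  a reaction to a known value.
* **Inequalities `G x ≥ h`.** One unit row per irreversible reaction, with
  h = 0. Reversible reactions carry no bounds at all: the only
  inequalities in the system are irreversibility constraints, so
  boundedness of any quantity is a property of the network, not of
  arbitrary ±1000 default bounds.
* **Approximate equalities `A x = b + ε`.** Measured fluxes with standard
  deviations. These never restrict the feasible set; they define the
  Gaussian likelihood used by the ensemble sampler.

Feasibility is enforced to an absolute tolerance of 1e-9; FVA ranges below
1e-6 mmol/min count as uniquely determined. Both tolerances sit far below
the two-decimal reporting precision of the fluxes.

## FBA and FVA

`solve_fba` passes the system to `scipy.optimize.linprog` (HiGHS).
Degenerate optima are resolved by whatever vertex the solver returns —
deterministically for a fixed input ordering — and non-uniqueness is
reported only through `flux_variability`, which re-solves 2n LPs with the
objective constrained to ≥ `optimum_fraction` × optimum. Infeasible
problems raise an error carrying the constraint rows with the largest
residual at a least-squares point (a starting point for diagnosis);
unbounded problems name a reaction that grows along an improving ray.

## Ensemble sampling (mirror Metropolis-Hastings)

The equality-feasible set is parameterized as x = x₀ + Z q with Z an
orthonormal null-space basis of the stacked equality system (SVD, rank
tolerance 1e-10) and x₀ a feasible point — by default the FBA solution, so
the chain starts at the optimum of the deterministic analysis. In the
reduced coordinates the polytope is `G Z q ≥ h − G x₀` and the likelihood
is Gaussian.

**Proposal.** Steps are `jump · L u` with u standard normal. L is built
from the eigendecomposition of the information matrix
`(A Z / sd)ᵀ (A Z / sd)`: along directions the likelihood constrains, the
scale is the likelihood standard deviation; along likelihood-flat
directions it is the feasible range of the polytope (two LPs per
direction), with 1.0 as last resort for doubly unbounded flat directions.
This is the package's definition of the "relative proposal step size"
`jump`: `jump = 0.1` takes steps of a tenth of the local posterior scale.
A likelihood-shaped proposal matters in practice: measured fluxes with
very different standard deviations (0.058 vs 0.004 in the brain data)
create narrow ridges that axis-aligned steps traverse extremely slowly.

**Mirror move.** A proposal outside the polytope is reflected across the
most-violated hyperplane, repeatedly, until feasible; reflection preserves
proposal symmetry, so the ordinary Metropolis ratio
`L(x′)/L(x)` applies. Reflections are capped at 1000 bounces per proposal
(orders of magnitude above observed counts); a proposal exceeding the cap
is rejected.

**Defaults.** Burn-in 10⁷ steps, 10⁷ sampling steps thinned by 100
(ensemble size 10⁵), jump 0.1, seed 1868 — the configuration of the brain
study the package reproduces. Tests and the acceptance script run
scaled-down chains (burn-in 10⁵, 10⁴ kept samples), which keeps the full
suite within minutes while leaving Monte-Carlo standard errors well below
the assertion tolerances. Identical seed + config + input gives a bitwise
identical ensemble. A chain with zero accepted proposals during burn-in
aborts with a diagnostics error suggesting a smaller jump.

**Correctness checks.** On 1-D and 2-D polytopes the sampler is compared
with closed-form truncated-normal moments (within 3 Monte-Carlo standard
errors at 10⁴ kept samples). During development the brain-polytope
posterior was additionally validated against direct rejection sampling
from the reduced Gaussian; the glucose-uptake marginal agreed to three
decimals in mean and sd.

## Lsei-FBA

Fold changes are converted to linear scale (`2^v` for log2 input) before
any use — multiplying a flux by a fold change is only meaningful in
linear space. Aggregation to reactions defaults to the arithmetic mean of
the linear fold changes of all associated genes; `minimum` and
`geometric_mean` are available, as is a structured policy (minimum over
AND-joined complex subunits, mean over OR-joined isoforms) that is off by
default. Reactions with no measured gene — including most transport and
exchange steps — are simply absent from A: they are determined by balance
and irreversibility alone. All rows of A are weighted equally (an
unweighted sum of squares).

The rough target is `b(r) = reference(r) × fc(r)` on the *signed*
reference value, so an expression increase on a release flux (negative
sign) predicts a larger release. Whether an increase should instead push a
negative flux toward zero is genuinely ambiguous; signed scaling is the
convention here and is applied uniformly. The disease projection imposes
*no* fixed exchange fluxes and drops the healthy-state PPP/GABA fraction
constraints: under the perturbed condition those quantities are unknown
and become outputs.

### The constrained least-squares solver

`solve_lsei` minimizes ‖Ax − b‖² subject to Ex = f, Gx ≥ h with a primal
active-set method: equalities are eliminated through the null-space basis,
the working set starts from the constraints active at an LP feasible
point, each iteration solves an equality-constrained least-squares
subproblem (minimum-norm via `lstsq`), performs a ratio test to add the
blocking constraint, and drops working-set constraints with negative
Lagrange multipliers at stationarity. Rank deficiency anywhere is handled
by minimum-norm least squares rather than errors. When the minimizer is
non-unique in null directions of A, the minimum-Euclidean-norm flux vector
among the minimizers (within the final active subspace, checked against
the inactive constraints) is returned, making the result deterministic.
The solver is verified against brute-force enumeration over all inequality
active sets on random 5-reaction problems, and the FBA solver against
polytope vertex enumeration on random 4–8 reaction networks.

## The brain fixture

`build_brain_model()` returns a 71-reaction, 89-metabolite core network of
brain energy metabolism in three compartments, transcribed with Recon-1
style identifiers and standard textbook stoichiometry: glycolysis, the
oxidative and non-oxidative pentose phosphate pathway, pyruvate transport
and the citric acid cycle, the malate-aspartate shuttle (with the
proton-coupled aspartate/glutamate exchanger), the glycerol-phosphate
shuttle, a cytosolic GABA shunt (glutamate decarboxylase, GABA
transaminase, succinate-semialdehyde dehydrogenase, with succinate
re-entering the matrix via a neutral dicarboxylate carrier and
α-ketoglutarate leaving via an irreversible oxoglutarate carrier), the
respiratory chain with explicit proton stoichiometry (4+4+2 protons
pumped per NADH through complexes I/III/IV, 4 protons per ATP through the
synthase/phosphate-carrier pair) and peripheral reactions of brain energy
metabolism (creatine kinase, adenylate kinase, carbonic anhydrase,
glycogen mobilization, malic enzymes, glutamine synthetase, glutamate
dehydrogenase, citrate/malate exchange) that carry no flux at the ATP
optimum but shape the feasible space.

Two modeling conventions matter:

* Extracellular species and the cytosolic currency pools (atp/adp/pi/h,
  nadp/nadph) are unbalanced externals. The cytosolic ATP surplus is
  exactly the net-ATP objective; NADPH consumption and ATP-consuming work
  are outside the network.
* The proton balance of the mitochondrial matrix is explicit, so the
  ATP yield per glucose is a consequence of carrier and pump
  stoichiometry. Where the compartmentation of the GABA-shunt arm and the
  proton coupling of the minor carriers admitted alternatives, the
  variant consistent with the published healthy-brain flux values
  (net ATP 8.49, ATP synthase 7.48 mmol/min at the stated constraints)
  was chosen; with it the model reproduces net ATP production
  8.498 mmol/min and ATP synthase flux 7.482 mmol/min, and FVA shows the
  optimum is unique to machine precision.

`BrainStudyData` carries the measured whole-brain exchange rates
(glucose 0.284±0.058, lactate −0.013±0.032, pyruvate −0.003±0.004
mmol/min; medians ± sd) and the pathway fractions (PPP 6.9% of
glycolysis, GABA shunt 32% of glucose oxidation). The fraction-derived
constraints are rounded to 3 decimals (0.020 and 0.091 mmol/min) *before*
being fixed, matching the printed values the reference fluxes were
computed with.

## The synthetic fold-change generator

`synthetic_fold_changes` emulates the one feature of microarray-derived
disease contrasts the projection algorithm relies on: many small, largely
congruent shifts within a pathway. Every gene of a listed pathway draws
log2 fc ~ Normal(effect_p, noise_sd); genes outside listed pathways draw
from Normal(0, noise_sd); a gene in several listed pathways gets the mean
effect. It does **not** emulate probe-level noise structure,
absent/present calls, correlation between genes of one complex, or any
relation between expression and protein activity — so passing tests show
that the *pipeline* behaves correctly (idempotence at unit fold changes,
directionally correct response, constraint satisfaction), not that
predictions from real expression data are accurate. The acceptance run
uses effects {oxphos −0.6, tca −0.6, glycolysis −0.3} with noise 0.1 as a
disease-like condition.

## Numerical choices and limitations

* LP backend: HiGHS via scipy; deterministic for fixed input ordering.
* Null-space rank tolerance 1e-10 (sampler and LSEI alike).
* Active-set iteration cap 50·(dof + constraints); mirror bounce cap 1000.
* The FVA uniqueness threshold (1e-6 mmol/min) and feasibility tolerance
  (1e-9) are fixed package constants, not tuned per model.
* The hypergraph renderer guarantees the semantic contract (widths,
  colors, direction, labels); layout coordinates are aesthetic. Layered
  layout follows the order of the metabolite list; `force` is a simple
  spring embedding for small sub-networks. Networks beyond ~100 reactions
  should be plotted as selected subsets.
* The ensemble sampler assumes the likelihood-relevant directions are
  either constrained by measurements or bounded by the polytope; a model
  with a likelihood-flat, doubly unbounded direction would random-walk
  there (scale 1.0) without converging — such a direction means the
  posterior itself is improper.
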