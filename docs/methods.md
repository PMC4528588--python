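# Methods

## Model class and assumptions

All networks are elementary mass-action systems over the species of a
microbial phosphorelay. A phosphorelay moves a phosphate group through
four stages (His -> Asp -> His -> Asp) that can live on separate proteins
(regular relay: HK, REC, Hpt, RR) or be partly fused into one receptor: a
*hybrid* HK carries an extra receiver (REC) domain and therefore has four
internal states OO, PO, OP, PP over its (His, Asp) sites, and an
*unorthodox* HK carries REC and Hpt domains, giving eight states over
three sites.

Modelling conventions:

- Phosphotransfer between two proteins is a bimolecular reaction;
  transitions among the internal states of a multi-domain HK
  (autophosphorylation, intramolecular transfer, hydrolysis) are first
  order. No enzyme-substrate complex intermediates are represented.
- Hydrolysis acts only on aspartate-phosphorylated sites (REC domains and
  RRs); histidine-phosphorylated species are stable. The one deliberate
  exception is the six-reaction core model, where a first-order sink from
  Hpt~P (`k6`) stands in for the removed downstream layer.
- ATP/ADP and the external signal are implicit. The signal enters only by
  scaling the autophosphorylation rate constants: the swept input is `k1`
  (autophosphorylation with the REC site empty) with `k3` (REC site
  occupied) slaved at a fixed ratio rho = k3/k1.
- Units are nondimensional (arbitrary concentration and time); all
  outputs are reported as phosphorylated fractions of a protein's total.

Every protein's total concentration is conserved; the builders expose the
conservation vectors, and the ODE right-hand side and analytic Jacobian
are generated directly from the reaction list.

## Steady states by elimination

For any architecture with a single Hpt protein through which all
bimolecular reactions run, the steady-state system collapses to one
univariate polynomial. Writing h for the free-Hpt concentration (so
[Hpt~P] = T - h with T the Hpt total), the steady-state equations of each
remaining protein are *linear* in that protein's own species once h is
fixed. Solving one small linear system per protein expresses every
concentration as a rational function of h; substituting into the Hpt~P
balance and clearing denominators gives the steady-state polynomial P(h).
Positive steady states correspond one-to-one to roots of P in (0, T),
and back-substitution reconstructs the full state vector from each root.

For the core model this gives a cubic; with all rates and totals set to 1
it is proportional to 2h^3 + h^2 - 1, with the unique positive root
h ~ 0.6573. For n hybrid HKs sharing one Hpt the degree is 2n+1: each HK
block contributes a quadratic denominator q_i(h), and the balance
k6 (T - h) prod q_i(h) = sum_i H_i k_{i,1} k_{i,2} k_{i,5} h (k_{i,3} +
k_{i,4} h) prod_{j != i} q_j(h) has degree 2n+1.

Two implementations exist behind one dispatcher:

- `derive_polynomial` performs the elimination symbolically (sympy),
  yielding exact coefficient expressions in the rates and totals; it
  covers the core and shared-Hpt systems and, as an extension, the full
  hybrid, yeast and single-module shared-RR systems.
- `numeric_elimination` carries out the same elimination in
  floating-point polynomial arithmetic at a fixed parameter set
  (per-protein Cramer solves with numpy polynomial determinants). It is
  orders of magnitude faster and is the route all sweeps take. Symbolic
  elimination of networks with many reverse-transfer reactions (e.g. the
  yeast model) suffers severe expression swell, which this path avoids.

Architectures outside this class (regular relay, unorthodox HK,
multi-module shared-RR) are handled by `find_steady_states_numeric`, a
multi-start Newton solver on the stoichiometric compatibility class:
starts are drawn uniformly on the product of per-protein simplices
(Dirichlet weights times totals, seeded), solutions are validated by
residual and non-negativity and deduplicated at relative tolerance 1e-5.
The same solver doubles as the independent oracle for the polynomial
route; the test suite checks state-by-state agreement at 1e-6 relative
tolerance on random parameter sets.

### Root handling and certification

Roots are computed by the companion-matrix method and polished by Newton
iteration; roots below 1e-9 are discarded and roots closer than a
relative 1e-7 are merged and flagged as fold candidates (root collisions
are exactly the saddle-node points). When requested -- always for
multistability witnesses -- the count is certified in exact arithmetic:
parameter floats are converted to rationals without rounding, and either
a Sturm-sequence count on (0, inf) or a sign-alternation certificate at
rational interleaving points is evaluated. The sign-alternation
certificate proves at least k roots; combined with the degree bound it
pins the count exactly whenever k equals the degree, which is the case
for every constructed witness.

### Stability

Stability is read from the Jacobian restricted to the compatibility
class: one species per conservation law (the fully unphosphorylated form
of each protein) is eliminated, removing the structural zero eigenvalues.
An eigenvalue counts as negative when Re(lambda) < -eps or
Re(lambda) < -rel |lambda| (eps = 1e-8 times the largest rate,
rel = 1e-6); the relative test keeps genuinely stable slow modes of
widely scaled systems out of the "marginal" bin, while near-zero
eigenvalues at folds still classify as marginal rather than being
coerced. For witness states whose decisive eigenvalue falls below the
double-precision noise floor (machine epsilon times the Jacobian norm),
classification is repeated end-to-end in 50-digit arithmetic
(`classify_stability_hp`): the root is re-polished on the exact
polynomial, back-substituted, and the reduced Jacobian eigen-decomposed
in mpmath. Along sorted roots the labels alternate
stable/unstable/.../stable in every certified witness.

## Witness construction

### 2n+1 states for n HKs sharing one Hpt

The construction works in flux space. At steady state the total HK->Hpt
phosphate flux F(h) = sum_i H_i f_i(h) must balance the hydrolysis line
L(h) = k6 (T - h); steady states are the crossings. A tuned single-HK
block has a non-monotone unit-flux curve f(h): it rises to a local peak M
and decays to a much lower plateau f_inf = 1/(1/k1 + 1/k2) (the
reference block has M/f_inf ~ 13). Dividing the bimolecular rates k4, k5
by s stretches the curve horizontally by exactly s, so n copies of the
block at scales s_i = sep^(i-1) produce n staggered rise/decay features.
Against a nearly flat line of height V, block i's rise gives an
up-crossing and its decay a down-crossing provided
(V - P_i)/M < H_i < (V - P_i)/f_inf, where P_i is the accumulated
plateau of the earlier blocks; the line's own fall to zero at h = T
supplies the final crossing, for 2n+1 in total. Defaults: H_i = (V -
P_i)/g with g the geometric mean of M and f_inf, sep = 2000 (the linear
small-h rise of each block, slope ~ k5/s, must not leak into the
previous window) and T = 2e4 s_n (the line must stay flat through the
last block's slow algebraic decay). The construction is deterministic;
seeded jitter is only used as a fallback if certification fails.
Certification is always by the exact sign-alternation count, never by
the geometry.

### prod(2n_i + 1) states for modules sharing one RR

Each module receives a certified shared-Hpt witness; the modules are
then coupled to the common RR weakly: the transfer rate kt_i is chosen
so that kt_i [RR] is 1e-4 of the module's hydrolysis rate k6_i, leaving
the per-module root structure intact. Steady states of the coupled
system are found by Newton refinement from every product combination of
per-module states (plus random multi-starts) and validated by residual,
conservation and pairwise-distinctness checks. For two single-HK modules
this yields 9 steady states, 4 of them stable (2 stable branches per
module, combinatorially).

## Bifurcation analysis

Sweeps enumerate all steady states per input (polynomial route where
available), classify them, and thread points into branches by optimal
nearest-neighbour assignment in output value; a branch that disappears
or is born mid-sweep records a fold at that input. Input grids are
logarithmic by default since folds span decades in rate space.
Hysteresis is the gap between the input where the low stable branch
disappears (up-switching threshold) and where the high branch disappears
(down-switching); it is cross-validated by quasi-static time-integration
sweeps that carry the state from one grid point to the next, whose
output jumps must land within one grid step of the polynomial folds.

Integration-to-steady-state uses LSODA with the analytic Jacobian
(rtol 1e-9, atol 1e-12) and stops when no phosphorylated-species
concentration changes by more than 1e-5 over a window of 10 time units.
The threshold is a modelling convention of the field; the window length
is this package's own choice (a fixed window makes the criterion
well-defined for slowly creeping trajectories).

## Logic gates

Two independently signalled HKs sharing one Hpt that feeds one RR can
implement an adder, a Boolean AND, or a Boolean OR. Response surfaces
report the RR~P fraction per signal-grid cell; bistable cells are
resolved to the branch reached by integration from the fully
unphosphorylated state ("signal on from rest"), with all coexisting
stable values retained in a multivalued mask. Classification is
corner-based with thresholds at 0.75/0.25 of the maximum achievable
output (gate surfaces in this regime are near-saturating, so relative
thresholds are the natural choice). ADDER requires non-Boolean corners
and an isotonic regression of output against s1+s2 with R^2 >= 0.95 --
summation is a qualitative claim, and isotonic R^2 measures exactly
"monotone function of the sum" without imposing a functional form.

The two Boolean gates share one kinetic base: the HK flux drives a
bistable Hpt switch, and the single-signal flux lies below the switch's
up-fold for the AND totals but above it for the OR totals. Only the
totals and the RR~P dephosphorylation rate differ between AND and OR
(`search_gate_params` enforces exactly this restriction), which is the
tuning freedom the architecture offers. The gate witnesses were found by
seeded randomized search followed by local refinement of the worst
classification margin, and are verified at two grid resolutions (8 and
16 points per axis).

## Case studies

The yeast osmosensing model is Sln1 (hybrid HK) -> Ypd1 (Hpt) -> Ssk1
and Skn7 (RRs), with reverse transfers at every protein-protein step and
aspartate hydrolyses; the output is the Ssk1~P fraction. No measured
parameter table ships with this package: the defaults are a
reconstructed biologically feasible set -- the Sln1 block realizes a
non-monotone Ypd-phosphorylation flux with k3 >> k1, transfers are order
1-20, hydrolyses order 0.01-0.05 -- and every rate carries a provenance
flag (`measured-in-cited-work` for the in-vitro-characterized
phosphotransfer steps, `assumed-feasible` otherwise) so measured values
can be substituted. Totals use round arbitrary units so the standard
total-concentration sweeps (Ypd 1, 2, 3; Skn7 0.5, 1.5, 2.5) are runnable
verbatim, and those sweeps are tested for distinctness and monotone fold
shift. Default behaviour: bistable
with hysteresis, robust to +-10 % perturbation of every rate. The
Ssk1 -> Ypd reverse transfer can be disabled by a builder flag.

The V. harveyi-like model is the two-HK shared-Hpt/shared-RR topology
with symmetric adder defaults; the natural three-HK variant is
`build_shared_rr([3])`.

## Parameter sampling

Random parameter sets draw rates log-uniformly from [1e-2, 1e2] and
totals from [0.1, 10], always from an explicit seed. The four-decade
rate range spans biologically plausible ratios without committing to
units; on this distribution roughly 0.2 % of core parameter sets are
bistable, enough for the implication audits to exercise real witnesses.

## Problem sizes in the shipped tests

The acceptance-level tests use 100 random parameter sets per
architecture for the polynomial-vs-oracle comparison (60 multi-starts,
escalated to 400 on count disagreement), 10^4 sets for the k3 > k1
audit, 10^3 sets for regular-relay monostability (12 starts each),
30-60 point sweep grids, and 8/16-point gate grids. These sizes keep the
full suite within a few minutes while leaving the statistical
conclusions unchanged at larger n (the audits are deterministic given
the seed).

## Known limitations

- No enzyme-substrate complexes, no thermodynamic (detailed-balance)
  constraints, no stochastic or spatial effects.
- Case-study and witness parameters are reconstructed regimes, not
  fitted values; passing tests demonstrate the dynamical repertoire of
  the architectures, not quantitative agreement with any measured
  dose-response curve.
- The multistability witnesses span many decades of concentration by
  construction; they demonstrate attainability of the 2n+1 bound, not a
  physiological operating point.
- Gate classification depends on the declared corner thresholds and the
  from-rest branch convention; other conventions (e.g. branch tracking
  from the high state) would relabel bistable surfaces.
- The numeric multi-start oracle can in principle miss steady states
  with very small basins; escalating the start budget is the only
  remedy used, and the polynomial route is exact wherever it applies.
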