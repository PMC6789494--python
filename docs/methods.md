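# Methods

## Model and scope

`chiralnet` analyzes deterministic mass-action reaction networks.  A
network is a finite list of irreversible reactions
c₁X₁+…+cₙXₙ → d₁X₁+…+dₙXₙ with nonnegative integer coefficients;
reversible reactions are split at parse time, so the reaction count `r`
always refers to the split set.  Species declared `constant` follow the
pool-chemical approximation: they multiply rate laws but have no
differential equation (their rows leave the stoichiometric matrix S and
their orders leave the order matrix R).  Inflows (∅ → A) are zero-order,
outflows first-order.  All quantities are dimensionless; no unit system
is imposed.

The chiral structure is declared, not inferred: `pair L:D` statements name
the enantiomeric pairs (L-form first), and `dual a~b` ties rate labels of
dual reactions that do not simply share one label.  Pseudochirality is
then *verified*: the species involution (swap every pair, fix achiral
species) must map the reaction multiset onto itself, each reaction landing
on a dual in the same rate-label class.  Pairs of pool species take part
in the involution but do not count toward the order k, which is the
number of dynamic pairs.  Mixed dynamic/constant pairs are rejected.
States are racemic when the enantiomeric gap Σᵢ|Lᵢ − Dᵢ| vanishes; the
absolute value makes "gap = 0" equivalent to the componentwise racemic
condition Lᵢ = Dᵢ, which a bare signed sum would not be.

Only mathematical steady states (all net production rates zero) are
treated; detailed-balance or other chemical-equilibrium refinements are
out of scope, as are thermodynamic feasibility constraints, stochastic
kinetics and non-mass-action rate laws.

## Decision procedure

The symmetry-breaking criterion is the instability of A − B, the
difference of the L→L and L→D blocks of the racemic Jacobian in canonical
species order (L-side, D-side, achiral).  Two independent code paths
decide it at a state: the k×k block spectrum, and an eigenvector search
on the full Jacobian (unstable eigenvalue with vᵢ ≠ v_{i+k}); they are
asserted to agree outside the marginal band, and the tests exercise that
assertion on random networks.

The search space is linearized with the convex-coordinate change of
variables: extreme currents of {v ≥ 0, S_ext·v = 0} are enumerated by
double description in exact integer arithmetic; the stability matrix
V = S·E(j)·R has entries linear in the coordinates j; the signed
characteristic-polynomial coefficients (−1)ⁱΩᵢ of its pair-block
difference (Ωᵢ = principal-minor sums) drive the sampler.  The extension
rows of S_ext force equal steady currents within every rate-label
equality class, one row per extra class member.  This generalizes
"one row per dual pair": the two coincide when classes are pairs, and the
generalization is what keeps unit-concentration back-mapping consistent
when classes merge (e.g. the APED model with all stereoselectivity
factors equal to 1).  A `paper` mode additionally skips classes that are
enantiomer-interconverting pairs (a racemization and its reverse),
matching the convention of published extended matrices; the default
`all` mode is sound because at racemic states every dual pair carries
equal current, and it prunes the cone harder.  V itself is always built
from the plain S: the appended rows only shape the cone, not the
Jacobian factorization.

A negative signed coefficient is necessary for a positive real root, and
sufficient only at i = k (negative constant term).  The sampler therefore
treats hits as *candidates*, and every reported state is post-verified
with the eigenvalue and eigenvector tests; candidates that fail remain
candidates.  Emptiness is certified soundly when all monomial
coefficients of (−1)ⁱΩᵢ are nonnegative (the polynomial is then
nonnegative on the orthant); the linear i = 1 case is decided exactly by
LP, which makes the order-1 pipeline complete: accept/reject, never
inconclusive.  For i ≥ 2 exhausted rejection sampling yields
"inconclusive", never "reject" — rejection sampling cannot prove
emptiness, and exact quantifier elimination over these semialgebraic sets
is deliberately out of scope.

Back-mapping picks, among the infinitely many steady states with
velocity Σ jₗvₗ, the one with every concentration equal to 1 and
k_q = w_q.  This choice makes the scaling matrix Δ = diag(1/Xᵢ) the
identity, so V(j) *is* the Jacobian at the sample and the linearized
verdict is exact there; it also makes the state exactly racemic with
exactly equal dual rate constants.  Coordinates whose composite current
vanishes on some reaction are rejected (the unit-concentration preimage
needs strictly positive currents), naming the dead reaction.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `seed` | required | all sampling randomness |
| `n_samples` | 10⁴ per i | sampling budget per coefficient index |
| `scale` | 2 | box bound for convex coordinates (dimensionless runs keep numbers in [0, 2]) |
| `i_max` | 5 | highest coefficient index searched (degree of minors) |
| `dual_mode` | `all` | extension-row selection (`paper` for published-matrix compatibility) |
| `max_confirm` | 200 | candidate states submitted to full confirmation |
| instability tol | 10⁻⁹ | Re λ above it counts unstable; \|Re λ\| within it is "marginal" and never confirmed |
| eigenvector tol | 10⁻⁷·‖v‖ | threshold for vᵢ ≠ v_{i+k} |
| steady-state tol | 10⁻⁸ (relative) | gap/residual bound for accepting a state as racemic steady |
| `epsilon` (SMSB) | 10⁻¹⁰ relative | perturbation of the first pair |
| ee threshold | 0.1 | final \|ee\| declaring symmetry broken |

The strict mathematical definitions ("Re λ > 0", "vᵢ ≠ v_{i+k}") need
numerical bands; the bands above are the package's choices, and states in
the marginal band are reported separately rather than decided.

## Simulation

The mass-action ODE is integrated with LSODA (analytic Jacobian
supplied); pool species are held fixed.  Integration proceeds in stages
and stops on steady state (‖dX/dt‖ < 10⁻¹²), runaway autocatalysis
(concentration above 10¹², by which point the enantiomeric excess is
saturated), saturation of ee, or the horizon t = 10⁶.  When the racemic
state has a known unstable rate λ the step size is capped at 0.5/λ: an
imbalance far below the local error tolerance is invisible to the step
controller, and an A-stable corrector taking large steps would otherwise
damp a growing mode it cannot see.  This matters when seeding ee at the
floating-point ulp scale (~10⁻¹⁶), where the growth of the asymmetric
mode must be resolved explicitly.  Small negative undershoots are clipped
and flagged.  Bifurcation scans re-equilibrate each grid point by
integrating from the previous racemic state and re-symmetrizing the pairs
(continuation), which is robust near folds where root-finding from
scratch is not; the scanned rate constant is changed together with its
whole dual label class so the network stays pseudochiral.

## Synthetic networks

`models.random_pseudochiral` draws random mass-action reactions
(coefficients ≤ 2) over k pairs plus achiral species and closes the set
under the involution with shared labels, so its outputs always pass the
pseudochirality check; with `reversible=True` every seed reaction gets a
reverse, guaranteeing a nontrivial steady-state cone so racemic steady
states can be constructed by back-mapping.  These networks emulate the
*structure* of homochirality models (dual pairing, label classes, small
stoichiometries) but not their chemistry: no conservation of mass is
imposed, no thermodynamic consistency, and the reaction sparsity is
arbitrary.  Passing property tests on them therefore validates the
algebra (block symmetry, dual-route agreement, factorizations) — not the
realism of any kinetic parameter.

The APED stereoselectivity factors α, β, γ enter the analysis through
label identification only: a factor equal to 1 collapses the primed rate
label onto its base class, constraining the cone; factors different
from 1 leave the primed labels free, and sampled states realize the
factors as rate-constant ratios.  Numeric factor values are therefore
simulation-configuration data, not network structure — the same
convention used for the replicator model's rate-constant equalities.

## Numerical choices and degenerate inputs

* Cone enumeration is exact (Python integers, gcd-normalized rays,
  combinatorial adjacency test); output is sorted in descending
  lexicographic order for reproducibility.  The brute-force support-subset
  enumeration used as the test oracle is exponential and only run at
  r ≤ 8.
* Ωᵢ via principal-minor enumeration is used up to 8×8; larger numeric
  matrices fall back to eigenvalue-product expansion.
* Convex coordinates are solved directly when the currents are linearly
  independent; otherwise a nonnegative least-squares solution is returned
  with a non-uniqueness flag (the coordinate tuple is only unique when
  the rays are independent, which can fail when s exceeds the cone
  dimension).  A residual above 10⁻⁸·‖w‖ means the velocity is not in the
  cone and the state is rejected as non-steady.
* The Routh table returns "undecidable" on zero pivots (spectra touching
  the imaginary axis) instead of applying epsilon heuristics; the root
  verdict then stands alone.
* Rate-label classes take the lexicographically smallest label as
  representative, making symbolic output deterministic.
* Networks with an empty current cone are rejected outright ("no positive
  steady-state currents"): they have no positive steady states to
  destabilize.

## Problem sizes

The bundled analyses run at the sizes shipped in the fixtures: up to 26
reactions and 29 extreme currents (imperfect-condition enzymatic model),
order up to 4 (APED), 10⁴ coordinate samples per coefficient index, and
a few hundred confirmed-state verifications per run.  The oracle suites
use 500 random matrices (≤ 6×6), 1000 random polynomials, ≥ 100 random
networks and 100 Clarke-factorization checks.

## Known limitations

* For i < k the negative-coefficient condition is heuristic; the sampler
  can miss symmetry-breaking regions whose instability is not reflected
  in a low-index coefficient (verdict "inconclusive", never a false
  "reject").  For k > 5 only coefficients up to i_max are examined.
* Rejection sampling density is uniform on the box; no claim is made
  about coverage of thin instability regions.  Bifurcation scans are the
  intended remedy around sampled points.
* The double-description implementation targets the small, heavily
  constrained cones of this problem class; it is not tuned for
  elementary-flux-mode-scale enumeration.
* Hopf-type marginal states (\|Re λ\| inside the band) are reported but
  not classified.
* Large perturbations of racemic states (beyond the linear regime probed
  here) can reach homochiral states by routes this analysis does not see.
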