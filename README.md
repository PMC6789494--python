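# chiralnet

Can a chemical reaction network spontaneously break mirror symmetry?

Biological homochirality — life's exclusive use of one enantiomer of each
chiral building block — is commonly explained by *absolute asymmetric
synthesis*: reaction mechanisms that, in an achiral environment, amplify a
negligible enantiomeric imbalance into a large, persistent one.  Ever
since Frank's 1953 autocatalysis model, such mechanisms have been proposed
as mass-action reaction networks, and the hard question for each new
proposal is the same: **does this network actually have racemic steady
states whose instability drives homochiral dynamics, and at which
parameter values?**

`chiralnet` answers that question algorithmically for *pseudochiral*
networks — networks invariant under swapping every L-species with its
D-partner, with dual reactions sharing rate constants.  It is aimed at
researchers building or auditing models of the emergence of
homochirality.

## Method

For a pseudochiral network of order *k* (number of dynamic enantiomeric
pairs, species ordered L₁…L_k, D₁…D_k, achiral), the Jacobian of the
mass-action ODE at a racemic steady state has a block symmetry.  Writing
*A* for the k×k block coupling L-species to L-species and *B* for the
L-to-D block, a racemic steady state is **symmetry-breaking** — able to
seed homochiral dynamics — iff the characteristic polynomial of *A − B*
has a root with positive real part.  An equivalent, and independently
checked, formulation asks for an unstable eigenvalue of the full Jacobian
whose eigenvector satisfies vᵢ ≠ v_{i+k} for some pair.

Searching for such states directly means sampling a highly nonlinear
semialgebraic set.  `chiralnet` linearizes it with Clarke's stoichiometric
network analysis:

1. the steady-state set maps onto the polyhedral cone
   C = {v ≥ 0 : S·v = 0} (S the stoichiometric matrix, extended with
   rows forcing equal currents through dual reactions — the racemic
   condition on the cone);
2. the extreme currents v₁…v_s of C (enumerated by exact integer double
   description) give convex coordinates j: every steady velocity is
   Σ jₗ vₗ;
3. the Jacobian factorizes as J = S·E·R·Δ with E = diag(Σₗ vₗᵢ jₗ), so
   stability analysis moves to V = S·E·R, whose entries are *linear* in j;
4. with AV, BV the pair blocks of V and
   p(λ) = λᵏ − Ω₁λᵏ⁻¹ + Ω₂λᵏ⁻² − … the characteristic polynomial of
   AV − BV (Ωᵢ = sum of i×i principal minors), a negative signed
   coefficient (−1)ⁱΩᵢ < 0 is necessary for a positive real root.  The
   sampler certifies each set {j ≥ 0 : (−1)ⁱΩᵢ < 0} empty when every
   monomial coefficient is nonnegative, decides the linear i = 1 case
   exactly by LP, and otherwise samples it (hit-and-run / rejection);
5. each sampled j is back-mapped to a racemic steady state (all
   concentrations 1, rate constants equal to the composite current, which
   makes Δ the identity and the linearized verdict exact there) and
   confirmed with the eigenvalue *and* eigenvector criteria, then
   optionally by stiff ODE simulation of the enantiomeric excess
   ee = (L − D)/(L + D).

The verdict is *accept* (confirmed symmetry-breaking states, with
samples), *reject* (certified impossible), or *inconclusive*.

## Worked example

Frank's model (`L + A → 2L`, `D + A → 2D`, `L + D → P`, feedstock A held
constant) is the minimal mechanism of absolute asymmetric synthesis:

```python
from chiralnet import models, sna_sampling, detect_smsb

net, chiral = models.fixture("frank")
report = sna_sampling(net, chiral, seed=1, n_samples=1000, max_confirm=5)
print("verdict:", report.verdict)
print("order:", report.order, "| extreme currents:", report.cone_size)
rec = report.records[0]
print("i=1 coefficient:", rec["polynomial"], "->", rec["verdict"])
state = report.confirmed[0].state
print("confirmed state:", state.concentrations, state.rate_constants)
broke, ee = detect_smsb(net, chiral, state)
print("SMSB in simulation:", broke, "| final ee:", ee)
```

prints

```
verdict: accept
order: 1 | extreme currents: 1
i=1 coefficient: -j1 -> found
confirmed state: {'L': 1.0, 'D': 1.0, 'A': 1.0, 'P': 1.0} {'k1': 1.8553, 'k2': 1.8553, 'k3': 1.8553}
SMSB in simulation: True | final ee: 1.0
```

The single extreme current (1, 1, 1) makes the i = 1 coefficient −j₁,
negative for every positive convex coordinate: *every* positive racemic
steady state of Frank's model is symmetry-breaking.  The back-mapped
state at j₁ ≈ 1.855 has all concentrations 1 and equal rate constants;
perturbing L against D by one part in 10¹⁰ and integrating drives the
enantiomeric excess to ±1 (complete homochirality).  The Calvin
mechanism, by contrast, is *rejected* with a certificate — its two signed
coefficients are nonnegative on the whole cone — reproducing the known
result that it cannot break mirror symmetry.

The same pipeline is available from the shell:

```sh
chiralnet analyze frank.crn --seed 1 --report report.json
chiralnet check replicator.crn
chiralnet bifurcate frank.crn --param k3 --seed 1 --from 0.5 --to 1.5
chiralnet fixtures
```

Bundled benchmarks (`chiralnet.models`): the toy two-species cone
example, Frank, Calvin, the open-flow replicator model, the APED
(activation-polymerization-epimerization-depolymerization) model, and
the enzymatic Iwamoto model under perfect and imperfect stereoselectivity.

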