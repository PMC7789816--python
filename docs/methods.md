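# Methods

## Scope and data model

`pedkin` analyses registry pedigrees of closed companion-animal populations.
A pedigree is a topologically ordered set of records (id, sire, dam, sex,
breed code, birth year).  Registry exports are chronically incomplete, so
unknown parents are modelled as absent links; a parent id that is referenced
but never defined materialises as a founder of breed `UNKNOWN` with sex
inferred from the slot it occupies.  Because generations overlap strongly in
cat breeding, a *population* is defined operationally as the parents of the
kittens born in two consecutive calendar years, and a two-year window is
used as the approximate generation interval throughout.

Two founder conventions coexist and are kept explicit in the API:

* *strict founders* (both parents unknown) anchor the kinship and breed-
  composition recursions;
* for the lastNative rule a founder is any individual with **at least one**
  unknown parent — a single unknown parent already breaks native
  traceability.

Individuals without a birth year pass no year-based filter and belong to no
cohort; the loader warns once.

## Kinship and diversity

Kinship `f_ij` is the probability that two alleles drawn at random, one from
i and one from j, are identical by descent.  It is computed by the tabular
method in one topological pass over the *full ancestry closure* of the
cohort: founders get `f_kk = 1/2` and zero cross-kinship, and

```
f_ij = (f_{s(i),j} + f_{d(i),j}) / 2          (j before i)
f_ii = (1 + f_{s(i),d(i)}) / 2
```

with an unknown parent contributing 0.  Fixed-depth (4–5 generation)
pedigrees systematically underestimate kinship in old closed breeds, which
is why the closure is never truncated.  The closure computation is O(n²) in
the closure size; cohorts of a few hundred animals with closures of a few
thousand ancestors take well under a second.

Derived statistics: `mk_i` (mean kinship of i with every member, itself
included), `mk̄` (mean over all N² ordered pairs **including** the
diagonal — some tools exclude self-pairs, which inflates FGE for small
cohorts), `GD = 1 − mk̄`, `FGE = 1/(2 mk̄)`, `F_i = 2 f_ii − 1`.  Nothing is
rounded before presentation.

## Native ancestry

Breed composition is the expected genomic contribution of each founder
breed: strict founders contribute unit mass to their own breed, everyone
else averages their parents, an unknown parent counting as `UNKNOWN`.  The
lastNative rule — founders of a breed born after a threshold year are
reassigned to `UNKNOWN` — is applied first whenever native traceability
matters, so late, undocumented entries do not count as native founders.

Kinship at native alleles extends the tabular recursion with two matrices:
`fN_ij` (alleles IBD *and* both native) and `Q_ij` (both alleles native),
with founder bases `fN_kk = δ_k/2`, `Q_kk = δ_k`, `Q_kl = δ_k δ_l`, and
diagonals `fN_ii = (n_i + fN_{s,d})/2`, `Q_ii = (n_i + Q_{s,d})/2` where
`n_i` is i's native contribution.  Diagonals use two-draws-with-replacement
semantics so the population means stay consistent with the all-ordered-pairs
convention above.  Then `condGD = 1 − mean(fN)/mean(Q)` and
`NGE = 1/(2(1 − condGD)) = mean(Q)/(2·mean(fN))`, both with uniform
population weights.  The deterministic recursion is the primary path; a
vectorised Mendelian gene-dropping simulator (unique labelled founder
alleles, native tags, one transmission draw per parent slot per replicate)
provides the independent Monte-Carlo estimate used in validation.  Its pair
estimates average the two independent allele draws per individual, so the
binomial standard error it reports is a conservative bound; validation
checks require ~99.5 % of entries within 3 SE and none beyond 5 SE, the
multiplicity-aware version of a per-entry 3σ band over tens of thousands of
entries.

## Optimal contribution selection

Contributions c (fractions of the next generation's genes) are constrained
to c ≥ 0 with male and female sums fixed at 0.5 each — the standard OCS
convention, consistent with the sex-ratio effective size
`N_e = 4 N_m N_f / (N_m + N_f)` used elsewhere.  Objectives:

* `min_pkin`: minimise `c'Mc`; potential diversity `N_oc = 1/(2 mk̄_min)`.
* `min_pkin_at_native`: minimise `(c'fN c)/(c'Q c)`, optionally under
  `c'Mc ≤ ub_mk` with `ub_mk = mk̄ + (1 − mk̄)·ΔF`, `ΔF = 1/(2 N_e L)`
  (generation interval L = 3.2 years by default), and under a native floor
  `Σ c_i n_i ≥ native_lb`.  The default floor is the current population's
  mean native contribution plus ε = 1e-6 ("at least as native as today").

Both are solved by SLSQP from eight deterministic starts (the uniform
sex-balanced point plus seven seeded Dirichlet-random feasible points);
single-start solvers stall on the fractional objective often enough that the
multi-start is not optional.  The fractional solution is refined by
Dinkelbach iterations — solve `min c'(fN − λQ)c`, update `λ` — and the
residual `|c'(fN − λ*Q)c|` at the end is reported as the optimality
certificate.  Infeasible constraint sets raise an error naming the binding
constraint; constraints are never silently relaxed.  Per-cluster tables
report `N_oc` from the unconstrained (no `ub_mk`) optimum — potential
diversity is a ceiling, while the bound describes one generation's
permissible step towards it; the full `OCSResult` carries both if needed.

## Subpopulation discovery

Features are the unscaled pairs `(mk_i, F_i)` — both already probabilities
on [0, 1], so no standardisation is applied.

**UPGMA route.**  Average-linkage agglomeration on Euclidean distances (the
linkage is prescribed by the method; Euclidean is the default metric of the
reference implementation and is logged).  For k = 1…k_max the tree is cut
and three criteria computed: pseudo-F (Calinski–Harabasz), pseudo-t²
(Duda–Hart statistic of the pair merged between k+1 and k), and the cubic
clustering criterion in the SAS formulation (observed R² against its
expectation under a uniform hyperbox aligned with the principal axes).  The
"largest discontinuity" rule is operationalised deterministically: reading
each trace from high k to low, CCC and pseudo-F nominate the k with the
largest rise relative to k+1, pseudo-t² nominates the partition just finer
than its largest peak; the final k is the modal nomination, ties going to
the smaller k.  The full criteria table is always emitted so a human can
override.

**Model-based route.**  Gaussian mixtures with the eigenvalue decomposition
`Σ_g = λ_g D_g A_g D_gᵀ` (volume, shape with det A = 1, orientation), each
factor Equal, Variable or spherical (I): families EII, VII, EEE, VEE, VVE,
EEV, VEV, VVV.  EM from a seeded k-means partition, convergence at relative
log-likelihood change < 1e-8 (max 500 iterations).  M-steps follow the
closed forms where they exist and small flip-flop iterations for the shared
factors (VEV shared shape, VEE shared matrix); the VVE shared orientation is
profiled exactly in 2-D as a 1-D search over the rotation angle (dense grid
plus bounded polish) — the feature space here is always 2-D, and the
orientation update raises for d > 2 rather than silently approximating.
Model and k maximise `BIC = 2 logL − m ln n`.  A component whose covariance
collapses numerically (e.g. onto duplicated feature rows — full sibs have
identical kinship rows, hence identical features) is ridge-regularised and
flagged, and flagged fits are excluded from BIC selection: an unbounded
likelihood spike on duplicated points is a degeneracy, not evidence of
structure.  This matches the reference implementation's behaviour of
reporting such cells as missing.  The EEE/VVV/VEV/VVE log-likelihoods are
cross-checked against the reference R implementation in the test suite.

Per-cluster tables recompute every statistic (N, mean ECG, N_e, mk̄, F̄,
FGE, N_oc, NGE, N_ocatN) on the cluster members alone by restricting the
cohort matrices (kinship is pairwise-intrinsic, so restriction is exact);
clusters below 4 members are flagged "nd" and excluded from statistics, and
a total row recomputes the whole population so cluster and module-level
numbers can be compared bitwise.

## The synthetic scenarios

The simulator emulates the structural features the analysis assumes:
overlapping generations (breeders stay candidates for 6 years by default),
regional subpopulations with migration, a founding/introgression event,
line-breeding vs outcrossing propensity, truncated-Poisson litters with mean
4.2, and ~9 % missing parentage — litter size and missingness matching the
registry statistics this package is built around.  Everything is
reproducible from one seed.  A truth sidecar records regions, true parents
and foreign-ancestry flags for supervised validation.

Presets:

* `thai_like` — four weakly connected regions (migration 0.02), outcrossing,
  a THA pool founded in 1995 that draws roughly half of its founding-phase
  matings from a separate SIA pool (fraction 0.5 over 1996–1999).  Final
  cohorts show low mk̄/F̄, a kinship histogram dominated by near-zero mass,
  and a sizeable SIA genomic contribution.
* `siamese_like` — one region, line-breeding propensity 0.8 (a mate with
  kinship ≥ 0.125 is chosen preferentially), producing the high-F̄, high-mk̄
  pattern of an old heavily line-bred breed.
* `flat` — a single-region random-mating control with full parentage
  recording, sized (60 founders, 40 recruits/year) so family structure stays
  weak.

What the simulator does **not** emulate: real litter-size and sex-ratio
heterogeneity between breeders, non-stationary popularity waves, pedigree
errors (wrong parents rather than missing ones), and registry-specific
coding quirks.  Passing tests therefore demonstrate correctness of the
estimators and the plumbing under realistic structure — not that any
particular real registry meets the model's assumptions.

A calibration check pins the simulator to theory: under discrete
generations, random mating and N = 100 (equal sexes), the final-cohort mean
inbreeding over 10 seeds matches Wright's accumulation
`1 − (1 − 1/(2N_e))^t` within sampling error.

One deliberate deviation from an obvious expectation is documented here:
model-based clustering does *not* reliably select k = 1 on the `flat`
control, because pedigree-derived features are never Gaussian — inbreeding
coefficients are skewed and quasi-discrete, and BIC honestly spends extra
components on that shape.  The k = 1 recovery property is therefore tested
on genuinely single-Gaussian data, and the control's role is comparative
(less structure, lower F̄ than the structured scenarios).

## Numerical choices

* Kinship accumulates in double precision; no rounding before presentation.
* Histogram bins are left-closed right-open, 0.001 wide on [0, 0.55], final
  bin closed; values above the top edge go to a flagged overflow bin.
* SLSQP: ftol 1e-10, 500 iterations, 8 starts; KKT/stationarity residuals
  reported; fixed seeds make every solve bit-reproducible.
* EM: relative tolerance 1e-8, max 500 iterations; covariance collapse
  threshold 1e-10 of the mean feature variance; ridge 1e-8 of that scale.
* ECG, completeness and AVK all index parents as generation 1.
* Topological sorting is Kahn's algorithm with a heap on input position:
  deterministic, and input row order never affects any statistic.

## Known limitations

* No genomic (marker-based) kinship; founders are assumed unrelated unless
  a future side-file supplies founder kinships.
* The native-kinship recursion treats `UNKNOWN` founders as non-native by
  construction; if a registry's unknowns are in fact native, NGE is a lower
  bound.
* OCS here is single-generation (no look-ahead, no litter-integer
  rounding).
* The VVE orientation update is 2-D only (exact there); all other families
  are dimension-general.
* CCC follows the SAS formulation; other implementations differ in the
  hyperbox estimate and can shift the nominated k on weakly structured
  data, which is why the criteria table is always emitted alongside the
  automatic choice.
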