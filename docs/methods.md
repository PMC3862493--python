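# Methods

This note documents the models, conventions, and numerical choices behind
strokenet, and what the synthetic cohorts do and do not establish about
real data.

## Connectivity mapping

A subject's network is built from labeled streamlines. A fiber belongs to
region pair {i, j} by its two **endpoint** labels only; fibers touching a
region mid-trajectory do not count, fibers with an unassigned endpoint or
both endpoints in one region are dropped (counts logged). The edge weight
is the fiber connection density

w_ij = (2 / (V_i + V_j)) · Σ_{f ∈ F_e} 1/l_f,

with region volumes V in mm³ and fiber trajectory lengths l in mm, so
weights carry units 1/(mm³·mm). The density is additive over fibers,
strictly decreasing in each fiber's length, and halves when both volumes
double. Voxel label lookup uses half-open boxes [lower, upper) per axis,
so a boundary point belongs to the voxel on its upper side — an arbitrary
but deterministic convention.

Volumes are the caller's responsibility: the bundled 90-region AAL table
ships *nominal synthetic* volumes on a realistic scale (4–25 cm³) purely
so that the pipeline runs out of the box; a real study must supply its
measured region table. Converting voxel counts to mm³ is likewise the
caller's job.

## Graph metrics

All metrics operate on symmetric, nonnegative, zero-diagonal matrices
(validated on load; asymmetry ≤ 1e-9 is averaged away, more is an error).

* **Weight → length.** Shortest paths use length = 1/w (absent edge =
  ∞). For density-like weights this is the standard choice; the map is
  isolated in one function so an alternative (e.g. −log w) is pluggable.
* **Clustering** is the Onnela coefficient with weights rescaled by the
  **per-subject** network maximum, so each subject's C_i ∈ [0, 1]
  independently of the cohort; C_i = 0 when degree < 2. On binary
  matrices it reduces to the unweighted clustering coefficient.
* **Betweenness** is the unnormalized sum over unordered pairs of
  shortest-path fractions (Brandes accumulation, exact tie
  multiplicities). Rankings and group contrasts are invariant to the
  omitted (n−1)(n−2) constant.
* **Efficiency** sums use 1/∞ = 0 for disconnected pairs rather than
  excluding them from the denominator, keeping global efficiency
  monotone under edge addition and bounded. Averages are over ordered
  pairs (identical to unordered for symmetric matrices).
* **Characteristic path length** is defined as 1/E_glob — the
  harmonic-mean convention — even when some pairs are disconnected; it is
  +∞ (with a warning) only for a completely disconnected network.
* **Vulnerability** recomputes efficiency on the n−1 remaining nodes;
  removing a peripheral node can raise efficiency, so values may be
  negative (a 4-node star's leaves sit at −1/12).

## Null models and small-worldness

Surrogates preserve node count, edge count, and the exact degree sequence
via double-edge swaps on the binary topology (default 10 accepted swaps
per edge, a conventional mixing burn-in; a bounded retry budget guards
pathological graphs, returning the partial randomization with a logged
swap count). The original weight multiset is then permuted uniformly onto
the rewired edges: total weight is preserved, the strength sequence is
not — the null scrambles *which* connections are strong while holding
topology-level structure fixed. Whether the original study shuffled or
regenerated surrogate weights is not recoverable; shuffling is our
convention.

σ = γ/λ uses the ensemble means of C and L over (by default) 100
surrogates, with per-surrogate seeds spawned deterministically from one
master seed. The ensemble evaluates only C and L (not the full metric
set) for speed.

## Hub identification

Metrics are computed per subject, then averaged across the group per node,
then ranked ("average-then-rank"; rank-then-average is a noted,
unimplemented alternative). Each criterion flags exactly
k = round(0.2·n) nodes (18 of 90); ties at the cutoff are broken by atlas
order with a logged warning — determinism beats silent ambiguity. The
fifth criterion ranks **nodal** vulnerability: ranking nodes by the
network-level maximum would be undefined. Hub score is the flag count
(0–5); score ≥ 2 defines a hub.

## Group statistics

Permutation tests pool both groups and redraw equal-size labelings. The
identity labeling is always among the n_perm assignments: its difference
ties the observed value and ties count as exceedances, so p ≥ 1/n_perm
and the test is exact (P(p ≤ α) ≤ α under exchangeability) at any
n_perm — including the scaled-down ensembles used in testing. No further
small-sample correction is applied. An `exact=True` mode enumerates all
C(n, n_a) assignments for small samples.

The test is one-tailed. Unless a direction is configured per metric, the
side follows the sign of the observed difference and is flagged as
post-hoc in the report — the original direction choices are not
recoverable, and a post-hoc side roughly doubles the effective level, so
configured directions are preferable for confirmatory use.

Nodal tests share one permutation set per metric (vectorized across
nodes) and enter Benjamini–Hochberg FDR together at q = 0.05; the
reported critical p is the largest rejected p value, 0 when nothing is
rejected. Global tests are flagged at p < 0.05 uncorrected.

Partial correlation residualizes both variables on covariates plus an
intercept by least squares; r is the residual Pearson correlation, p from
the t distribution with n − 2 − k degrees of freedom (two-sided — whether
the original reports were t-based or permutation-based is unstated;
t-based is implemented). Gender enters as a 0/1 indicator (results are
invariant to the coding); subjects missing a score are dropped listwise
per analysis with a logged count, never at load.

## Synthetic cohorts

The generator emulates the study design the pipeline targets:

| parameter | default | rationale |
|---|---|---|
| group sizes | 44 NC / 47 patients | the target two-group design |
| nodes | 90 | AAL non-cerebellar parcellation |
| topology | ring lattice k=6, rewiring p=0.1 | small-world regime (σ ≈ 7–8) |
| edge weights | lognormal(0, 0.5) | right-skewed, positive |
| subject noise | multiplicative lognormal, CV 0.15 | mean-1, preserves symmetry/positivity |
| lesion | 6 parietal-occipital nodes × 0.7 | localized 30% connectivity loss |
| NIHSS link | betweenness at PAL.R, coef 0.6, noise sd 0.65 | planted partial correlation ≈ 0.64 |
| ages | N(68, 8); 60% male | elderly stroke cohort |
| MMSE | NC 26–30, patients 18–30 | group-appropriate ranges |

NIHSS is `round(5 + 0.6·z + ε)` clipped at 0, where z is the target
metric standardized **across the patients' own lesioned, noisy matrices**
— so the planted correlation survives the full pipeline, not just the
template. Cohort generation is a pure function of the spec including the
master seed.

What the cohorts do **not** emulate: anatomically embedded geometry and
distance-dependent connection probability, realistic lesion shapes,
tractography noise (crossing fibers, gyral bias), hemispheric asymmetry,
or covariate–connectivity confounding beyond the planted link. Passing
tests therefore establish that the *machinery* is correct and calibrated
(metrics exact against brute-force oracles; type-I error and FDR
controlled on exchangeable nulls; planted effects of realistic size
recovered), not that any given real dataset satisfies the assumptions.

The streamline generator inverts the density formula per edge (1–3
fibers, random inverse-length shares) so a rebuilt matrix matches its
target to ~1e-15 relative; it exists to exercise the mapping stage, not
to mimic tract geometry.

## Numerical and scale choices

* Symmetry tolerance 1e-9 (then averaged); larger asymmetry errors out to
  catch transposition bugs.
* Matrix TSVs store 17 significant digits; write→read round trips are
  bit-identical (pandas `float_precision="round_trip"`).
* Per-stage RNG streams come from `SeedSequence` spawning, so stage
  outputs are independent of each other and reproducible bit for bit;
  the run manifest records every derived seed.
* Test-suite problem sizes: oracle checks use ≤ 12-node graphs (where
  exhaustive enumeration is feasible); calibration studies use 20–30-node
  cohorts with 200–1,000 permutations; planted-effect recovery runs at the
  full 90-node default. The acceptance script keeps the study-scale
  parameters (100 surrogates, 5,000 permutations).

## Known limitations

* Betweenness tie detection relies on exact floating-point equality
  inside Brandes' algorithm; ties between genuinely different weighted
  paths are only recovered when their lengths are bit-equal (as in
  unit-weight graphs). With continuous weights, exact ties have measure
  zero.
* The surrogate ensemble does not preserve the strength sequence;
  strength-preserving weighted rewiring is a future hook.
* One-tailed sides chosen post-hoc inflate the effective level (see
  above); the report marks them.
* The bundled atlas volumes are nominal; hub and density results on real
  data require measured volumes.
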