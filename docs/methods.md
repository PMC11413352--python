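# Methods

`eapnet` implements a two-track network analysis of eleven standardized
measures per subject — two auditory event-related potentials (MMN, P3a), two
continuous-performance attention tasks (DS-CPT, CPT-IP), and seven cognitive
scores (LNS-F, LNS-R, PWMT, CVLT, N-back, PFMT, VOLT) — compared between a
schizophrenia-like and a control-like group.

## Undirected track: Gaussian graphical models

Each group's variables are z-scored (sample SD, denominator n−1) after
listwise deletion. The GGM is the matrix of regularized partial correlations
r_p(i,j) = −Θ_ij / √(Θ_ii Θ_jj) obtained from the graphical-lasso estimate

  Θ̂(λ) = argmax_Θ  log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|,

with S the sample correlation matrix and the diagonal unpenalized
(penalizing it changes selected sparsity and is not the convention of the
implementation family this follows). The solver is a blockwise coordinate
descent (numba-compiled): each column update solves a lasso on the current
working covariance; convergence is certified by the per-entry KKT
stationarity residual, which the public solver drives below its tolerance
(default 1e-4; internal path fits reach ~1e-9) or raises.

λ is selected on a 100-point log-spaced path from λ_max (the largest
absolute off-diagonal correlation; the path's first element is pinned to
λ_max exactly because `logspace` round-trips the endpoint one ulp low) down
to 0.01·λ_max, minimizing the Extended BIC

  EBIC(λ) = −2L + E log n + 4 γ E log p,   L = (n/2)(log det Θ − tr(SΘ)),

with γ = 0.5 and E the number of off-diagonal entries whose magnitude
exceeds the sparsify tolerance (1e-7, numerical-noise level — sparsity comes
from the penalty, not this threshold). Final partial correlations below that
tolerance are set to exactly zero and excluded from the edge set.

Edge accuracy: a nonparametric bootstrap resamples whole subjects at the
original n, re-standardizes, refits the entire EBIC path, and reports
2.5%/97.5% quantile bounds per edge (B = 1000 by default). Regularization
means the full-sample point estimate can occasionally fall outside its own
bootstrap interval; this is recorded, not corrected.

Node predictability is the OLS R² of each node regressed on its selected
GGM neighbors (isolated nodes score 0). A nodewise-regularized variant
exists in the literature; the OLS-on-neighbors definition was chosen because
it is exactly reproducible from the fitted graph and oracle-checkable.

## Group comparison of GGMs

The network comparison test pools all subjects, repeatedly splits them at
random into groups of the original sizes, re-standardizes within each
permuted group, and refits both networks (2000 iterations by default).
Statistics: M = max_{ij} |edge_A − edge_B| (structure invariance) and
S = |Σ|edge_A| − Σ|edge_B|| over unordered pairs (global strength
invariance). p-values use the add-one convention
(#{perm ≥ obs} + 1)/(iterations + 1), avoiding zero p-values. The pooled
rows are sorted canonically and the larger group always takes the first
split, so p-values are exactly invariant to relabeling the groups.
Edge-wise permutation tests cover all pairs with a nonzero observed
estimate in either group and are Holm-Bonferroni adjusted (statsmodels).

## Directed track: Bayesian networks

Gaussian DAGs are scored with the decomposable BIC: node j with parent set
Pa contributes the maximized Gaussian log-likelihood of its least-squares
regression on Pa (ML residual variance, denominator n) minus (k/2) log n
with k = |Pa| + 2 (intercept, slopes, residual variance). This parameter
count preserves score equivalence — Markov-equivalent DAGs score
identically, which the tests verify — and matches the convention of the
standard implementation family for continuous networks.

Search is hill-climbing from the empty DAG over single-arc additions,
deletions and reversals that preserve acyclicity, applying the strictly
best-scoring move until none improves (minimum counted improvement
1e-9·n, guarding against floating-point cycling; exact ties break
lexicographically on (operation, parent, child) in the canonical column
order). Plain greedy search (restarts = 0) demonstrably terminates in local
optima on these structures: when several orientations of an early arc score
nearly identically, the first choice locks the search into an equivalence
class that can only represent the data with a compensating extra arc, and
no single move escapes. The default is therefore perturbation-based
restarts (restarts = 20, perturb = 5): each restart applies up to five
random acyclicity-preserving arc reversals/deletions/additions to the
incumbent best DAG and re-climbs, keeping the higher score. This routinely
reaches scores at or above the generating DAG's own BIC. `restarts=0`
recovers the plain climb.

Stability: B bootstrap resamples (whole subjects, original n) each yield
one learned DAG; every node pair is tallied by presence in either direction
(arc strength) and, conditional on presence, by orientation (arc
direction). The averaged network keeps pairs with strength ≥ 0.85 oriented
by the majority direction when it reaches ≥ 0.51; an exact 50/50 split
drops the pair, and a cyclic consensus raises an error with the offending
cycle (never silently repaired). Arc betas come from refitting each node of
the final averaged DAG on its parents by OLS on the full standardized
sample (the alternative — averaging bootstrap coefficients — was rejected
as less reproducible); the network BIC is reported for the same DAG.

## DAG comparison

Jaccard similarity = |skeleton intersection| / |skeleton union|
(direction-blind, consistent with arc strength being tallied "regardless of
direction"; 0 when the union is empty). Arc direction agreement = fraction
of skeleton-common pairs oriented identically (undefined without common
pairs). Because the literature also divides by one network's total arc
count, both alternative denominators are emitted alongside. The bootstrap
of these metrics resamples each group's subjects and learns one
hill-climbing DAG per group per iteration — a tractability trade-off
relative to nesting a full B-sample averaging run inside every iteration;
the point estimates still use the full averaged networks.

Cohen's d between groups is (mean_A − mean_B)/pooled SD with the usual
(n−1)-weighted pooled variance.

## Synthetic data generator

Because the study's subject-level data are not deposited, the generator
emulates the two reported group structures as linear-Gaussian SEMs over the
eleven measures: each node is Σ β·parent + Gaussian noise, sampled
ancestrally in topological order. Arc sets encode exactly the structures
named in the results narrative (e.g. the patient chain
MMN → P3a → DS-CPT → CPT-IP with MMN a common cause of both attention
tasks; the patient collider VOLT → N-back ← CVLT; the control chains
LNS-F → LNS-R → CVLT → VOLT and N-back → PFMT → VOLT with N-back a common
cause of PFMT, VOLT, PWMT and CVLT) — a partial reconstruction, since the
full fitted arc lists are not reproduced in the available text.

Path coefficients are synthetic stand-ins: 0.4 for every arc except
MMN → P3a = −0.5, whose negative sign mirrors the reported negative MMN–P3a
partial correlation (the strongest edge in both groups). Residual variances
are auto-calibrated in topological order so every marginal variance is
exactly 1 (calibration fails loudly if parents already explain ≥ 1). The
schizophrenia-like group carries a −1.32 SD mean offset on VOLT, matching
the reported direction of the largest between-group effect size; mean
offsets do not touch the covariance, so they affect only the effect-size
stage. Optional missingness (completely at random, default 0) exercises
listwise deletion. Default group sizes are 663 (patient-like) and 630
(control-like).

What the generator does not emulate: non-Gaussian margins, floor/ceiling
effects of real task scores, age or medication structure, missingness that
is not completely at random, and the study's actual fitted coefficients.
Passing tests therefore demonstrate the correctness and calibration of the
estimation machinery under the stated SEMs, not reproduction of the
clinical findings.

## Numerical and design choices

- Canonical variable order is the input column order; it drives all
  deterministic tie-breaking and table layouts.
- d-separation uses a reachability traversal over (node, entry-direction)
  states; tests check it against a moralization oracle, networkx, and the
  vanishing-partial-correlation criterion on exact SEM covariances.
- The pipeline derives every stage seed from one master seed via
  `SeedSequence`, making the full report a pure function of (data, config);
  reports contain no timestamps.
- Standardization happens within group, after listwise deletion, for both
  the observed fits and every permuted or resampled refit.
- Bootstrap resamples are re-standardized before refitting; for structure
  learning this is cosmetic (the Gaussian BIC is location/scale
  equivariant) but keeps every fit on the same scale as the observed one.
- Degenerate inputs: constant columns, collinear parents and noise-free
  regressions raise informative errors rather than returning infinities.

## Problem sizes in the test suite

The acceptance-style tests run at reduced but honest sizes chosen to keep
the full suite to minutes: exhaustive-search comparisons at 3–4 nodes
(25/543 DAGs), support recovery with 50 replicates at n=600, permutation
calibration with 200 replicates × 250 permutations at n=300 per group, and
averaged-network recovery with 20 networks at the study sample sizes with
B=200. The full-fidelity defaults (B=1000, 2000 permutations) remain the
package defaults.

## Known limitations

- Hill-climbing with restarts is still a heuristic; at n≈650 with several
  similarly-strong paths, the BIC-optimal equivalence class genuinely
  differs from the generating one in a sizeable fraction of samples, so
  bootstrap direction frequencies for such arcs hover near 0.5 and
  orientation recovery is data-limited, not search-limited.
- The NCT edge-wise family and the predictability definition are documented
  choices among published variants (see above), not uniquely determined.
- The generator's uniform betas make some orientations harder to identify
  than heterogeneous real-world coefficients would be.
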