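# Methods

This note records the model as implemented, the defaults and why they
are what they are, what the synthetic data does and does not emulate,
and the numerical choices a maintainer would otherwise have to reverse
engineer.

## Optimizer

One iteration processes the whole population vectorised: advance the
chaotic states, rank by fitness, move elites by cyclone foraging and the
rest by chain foraging, somersault everyone, and accept each candidate
only if it improves that individual (greedy selection). Elitism is
therefore structural: the best-so-far trace cannot increase, and the
restart step re-checks the incumbent after replacing the worst 35%.

* **Chaotic control.** Maps run in their fully chaotic parameterisations
  (circle with K = 0.5, logistic r = 4, tent μ = 2). Raw states are
  rescaled affinely to `C ∈ [0.1, 0.9]`. Seeds avoid known fixed points
  and dyadic collapse sets; if a trajectory still hits the boundary
  within 1e-6 it is reseeded from the run RNG. One state per individual,
  advanced once per iteration.
* **Lévy flights** use Mantegna's algorithm with stability index 1.5.
  Note the β = 2 endpoint of Mantegna's construction is *not* exactly
  Gaussian (the `1/|v|^{1/β}` factor keeps tail mass); tests check
  monotone tail lightening rather than a Gaussian limit.
* **Initialization** mixes LHS-with-scrambled-Sobol-offsets, Lévy steps
  around the domain midpoint (scale 10% of the range), and uniform
  draws, at (0.65, 0.225, 0.125) for most categories and (0.60, 0.35,
  0.05) for composition landscapes — midpoints of the intended ranges,
  with composition pushed to the Lévy-heavy end. Largest-remainder
  apportionment keeps the counts exact.
* **Memory** holds 5 + 5 + 5 entries. Quality banks accept when not full
  or on a ≥10% relative improvement over the bank's worst
  (`Δ = (f_worst − f_new)/(|f_worst| + 1e-12)`, scale-safe at zero and
  negative fitness); the short-term bank prefers evicting entries older
  than 50 iterations. The diversity bank requires the newcomer's nearest
  stored neighbour to sit beyond half the stored minimum pairwise
  distance, and evicts the most crowded member when full. Retrieval
  mixes banks 70/20/10 (short/long/diversity) with softmax-over-rank
  inside a bank. During cyclone and somersault moves at most five
  distinct memory samples are drawn per iteration and shared among the
  rows that reference memory — a performance choice with negligible
  distributional effect.
* **Local search** triggers every `F_local` iterations on the incumbent.
  On unimodal/multimodal categories it estimates a forward-difference
  gradient on a sampled coordinate subset (30% of dimensions early, 15%
  mid, 5% late, at least one), adds one backward probe per coordinate to
  estimate curvature, and takes a bias-corrected per-coordinate Newton
  step, probed at full/half/quarter length and accepted only on
  improvement. On hybrid/composition categories it uses random subspace
  directions or multi-scale Gaussian perturbations (scales h, 3h, 10h)
  instead — deliberately gradient-free on deceptive landscapes. A
  persistent pattern-search radius doubles on success (up to 64× the
  scheduled step, so far starts are reachable) and quarters on failure
  (down to 1e-14), which is what lets repeated calls refine a smooth
  basin to machine precision even though the scheduled step
  `h = 0.01·range·(1 − 0.7 r_t)` never falls below 0.3% of the range.
* **Restarts** fire after `T_restart` iterations without improvement
  beyond 1e-12 absolute. The worst ⌈0.35 N⌉ individuals are redrawn by
  memory perturbation (Gaussian, σ = 5% of range), Lévy steps around the
  midpoint, or uniform redraw; strategy weights (0.4, 0.3, 0.3) shift to
  (0.2, 0.4, 0.4) early (`r_t < 0.3`) or on deceptive problems. A
  normalised Shannon entropy of per-dimension occupancy histograms is
  logged, and an optional entropy floor can co-trigger restarts; the
  no-improvement counter is the primary trigger.
* **Schedules.** Per category (unimodal / multimodal / hybrid /
  composition), `P_cyclone` = 0.85 / 0.65 / 0.55 / 0.45, `S₀` = 1.2 /
  2.0 / 2.2 / 2.5, `F_local` = 3 / 6 / 7 / 8, `T_restart` = 20 / 15 /
  12 / 10; deceptive overrides 0.45–0.35, 2.8–3.5, 3, and 6–10. `CR₀`
  defaults to 0.9 (swept by the sensitivity harness). Boundary handling
  is clamping. The deceptive flag is supplied per problem; there is no
  landscape detection.
* **Budget.** Two batch evaluations per iteration (one candidate per
  individual per operator), plus ≤ 2k+4 evaluations per local-search
  call and one re-evaluation per restarted individual — `O(T_max·N·D)`
  overall, checked by an evaluation counter.

Reproducibility: each run derives four named substreams (init,
operators, restart, local) from a single `SeedSequence(seed)`; identical
(config, seed) pairs give bit-identical run records.

## Benchmarks and statistics

Instances are `f(x) = base(M(x − o)) + bias` with a seeded QR-orthogonal
rotation and a shift uniform in [−80, 80]^D on the [−100, 100]^D domain;
hybrid/composition exemplars are fixed-weight sums of three bases
sharing one optimum. These are category exemplars for exercising the
optimizer, not reproductions of any official competition data; official
shift/rotation arrays can be passed in where available. The baseline
optimizer is the original manta-ray algorithm with its canonical
coefficients and fixed somersault factor 2.

Friedman (average ranks, rank 1 = lowest mean error, χ² with k−1 df),
Nemenyi CD (`q_α√(k(k+1)/6n)`, studentized-range quantile at infinite
df over √2) and the Wilcoxon signed-rank test (W = smaller rank sum;
exact two-sided p by enumeration over sign assignments for ≤ 12 nonzero
pairs, tie-corrected continuity-corrected normal approximation beyond)
are implemented here and cross-checked against scipy in the tests.

## Feature selection

The wrapper searches the continuous relaxation `[0,1]^p`; binarization
at 0.5 happens only at evaluation, so the continuous dynamics are
untouched. The objective per mask is

```
mean 5-fold CV misclassification
  + 0.02 · (mean fraction of wrong tree votes)      # margin tie-break
  + 0.01 · k/p                                      # compactness
```

evaluated by a compiled CART forest (50 trees, depth 5, per-node
`sqrt(k)` feature subsampling — plain bagging via `max_features=None`).
Three choices matter and were made deliberately:

* **Frozen folds and bootstraps.** The stratified folds, bootstrap
  resamples and per-tree feature streams are fixed per selection run and
  shared by every mask, making the objective deterministic (hence
  cacheable — repeated masks cost a dictionary lookup) and making mask
  comparisons paired, so the search cannot chase resampling luck.
* **Feature subsampling.** With pure bagging, every tree splits on the
  same dominant gene and a mask's CV error does not reflect its weaker
  members; with `sqrt` subsampling the error genuinely degrades when
  uninformative genes are added. This is also the classic random-forest
  configuration for this kind of internal classifier.
* **Margin tie-break.** The misclassification rate moves in steps of one
  held-out sample and plateaus; the soft vote-margin term orders masks
  within a plateau (genuinely informative genes produce near-unanimous
  votes). Its weight (0.02) keeps it below one misclassified sample
  except on exact plateaus.

Binary-mode specifics: sparse warm-start positions (~5 bits, drawn with
probability ∝ 1/(1 + t-rank)² from the screening statistics), a
drop-one/add-one bit-neighbourhood local search (continuous probes
almost never cross the threshold), sparse restart draws (Lévy steps
around the box centre would binarize to ~p/2-bit masks), a hard cap of 8
selected features inside binarize (ultra-compact masks by construction;
dense somersault images compete on their best-supported coordinates),
Hamming distances in the memory banks, and a final stability/consensus
mask: bits present in ≥ 50% of the 30 best distinct masks evaluated.
Near-optimal masks disagree on genes that merely fit the particular
training draw but agree on consistently informative ones, so the
consensus is more stable than the single best mask.

The nested protocol refits variance filter → Welch-t top-100 screen →
wrapper selection inside each outer training partition only; outer folds
are stratified (the design is 47/25 imbalanced) and fold fingerprints
are recorded so leakage is checkable. Final learners (pluggable;
defaults: the internal forest and a linear-kernel SVM) are fitted on the
outer-train restricted to the selected genes and scored on the held-out
fold; weighted accuracy/precision/recall/F1 are aggregated as mean ± SD
with a summed confusion matrix and derived sensitivity/specificity.

## Synthetic expression data

The generator emulates a two-class high-dimensional low-sample-size
design: 72 samples split 47/25, unit-variance log-scale Gaussian noise
genes (optionally variance-calibrated Student-t for heavy tails), and k
informative genes shifted by `effect` within-class SDs in the minority
class, optionally sharing a latent factor (block correlation ρ). Presets:
easy (effect 3.0, ρ = 0), hard (effect 1.0, ρ = 0.6, t(3) noise). It does
*not* emulate probe-level artifacts, batch effects, gene–gene networks
beyond one block, or multi-class structure — so passing recovery tests
show the pipeline's mechanics and statistical behaviour at this
geometry, not performance on real microarrays.

## Known limitations

* **Wrapper selection bias bounds gene recovery.** At n ≈ 58 training
  samples and effect 2.0, the internal CV optimum frequently *excludes*
  1–2 informative genes: compact subsets that happen to separate the
  particular draw score several held-out samples better than the full
  informative set, and this persists under repeated CV partitions (it is
  in-draw redundancy, not partition noise). A plain top-5 |t| filter
  recovers all informative genes on the same folds. Consequently the
  honest wrapper recovers ≥ 4/5 informative genes in roughly 60% of
  outer folds at these conditions, and no amount of search effort raises
  that without anchoring selection to the filter statistic. Users who
  need maximal recovery at this sample size should treat the t-ranking
  as primary and the wrapper as a refinement.
* Final benchmark errors on smooth unimodal instances reach the
  floating-point floor (~1e-20 and below), which depends on the shift
  magnitude through cancellation in `x − o`.
* The ablation and sensitivity harnesses reproduce table mechanics and
  qualitative orderings; absolute fitness values depend on the problem
  supplied and are not comparable to any published magnitudes.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
package's own defaults for a single-CPU workflow: 30 optimizer runs for
success-rate and contrast measurements (budget ceiling 1500 iterations
for the contrast study), 10 runs × 2000 iterations for the
near-precision measurement, a reduced selector budget (N = 60, T = 60)
with 5 generator seeds × 5 outer folds for the gene-recovery protocol,
and 1e5-insertion stress tests for the memory contract.
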