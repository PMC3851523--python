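# Methods

## Problem and model

Affinity-purification mass spectrometry (AP-MS) studies report, for each
bait purification, a spectral count per identified prey protein — a
semi-quantitative abundance proxy spanning single digits to the thousands.
Most matrix-model scoring methods for protein–protein interaction (PPI)
inference consume only binary presence/absence data, so the usual practice
is to binarize: every positive count becomes a 1. That treats a
single-spectrum identification (very plausibly noise) the same as a
forty-spectrum one.

`specsample` instead represents the quantitative matrix by an ensemble of
binary matrices. A count *n* becomes the probability

    P(cell is a true observation) = 1 − (1 − p)^n

where *p* ∈ (0, 1] is the reliability of a single spectral count; the *n*
counts are treated as independent chances of one true observation. For each
of *T* trials, every cell is drawn as an independent Bernoulli variable at
its probability; the chosen binary scorer runs unmodified on each
realization; the final score of a pair is the arithmetic mean of its
per-realization scores. At *p* = 1 the ensemble degenerates exactly to the
direct binarization, which is also the comparator we report improvements
against.

### Aggregation details

- The candidate universe is fixed once, from the direct binarization: all
  pairs co-purifying at least once (plus observed bait–prey pairs for
  spoke-aware scorers). A universe pair absent from a realization's score
  table contributes 0 for that trial, so the mean is over a constant pair
  set. (The alternative — charging absent pairs the scorer's X = 0 value —
  was considered and rejected: for the null-model scorers that value is an
  artifact of the tail convention, not evidence.)
- The mean is computed as (first-trial score) + mean of deviations from it.
  Algebraically identical to the plain mean, this removes the common
  magnitude before summation and makes deterministic ensembles (*p* = 1)
  reproduce single-realization scores bit-for-bit.
- Scorers with unbounded negative scores would let one realization dominate
  a mean; per-realization scores can therefore be clamped from below before
  averaging. The default floor is 0 for the socio-affinity score and no
  clamping otherwise.

### Randomness contract

Trial *t* uses a Philox counter-based stream keyed by `(seed, t)`; the cell
at row *i*, column *j* consumes the draw at flat position `i·n_cols + j`.
Every draw is a pure function of (seed, trial, row, column), so results are
identical across runs, execution orders and degrees of parallelism.

## Scorers

All scorers operate on per-experiment presence sets. By default the bait is
added to its own experiment's set (a purification physically contains its
bait; configurable) and control columns are excluded (configurable). Columns
in the same replicate group are treated as independent experiments.
Scores are natural-log quantities; tail probabilities are floored at 1e−300
before the log so all scores are finite.

### Hart-style null-model scores

Under the null, partners co-purify at random in proportion to overall
participation. With `X_AB` = number of experiments in which A and B
co-purify, `N_A` = Σ over experiments containing A of (s_e − 1) (s_e =
proteins present in experiment e), and `N` = Σ_e C(s_e, 2) total
co-purifying pairs, the null expectation is λ_AB = N_A·N_B / N and

    score(A,B) = −log P[tail of X_AB under the null].

`hart_hypergeometric` draws N_B of N pair slots with N_A marked;
`hart_poisson` uses the Poisson(λ_AB) approximation, accurate for large
studies (the package's convergence tests bound the relative gap below 5% at
N = 1e5 for λ ≤ 6). The upper tail is strictly-greater-than (`tail="gt"`,
i.e. 1 − CDF(X)) by default, with `tail="ge"` available and applied
uniformly to both scorers. Degenerate nulls (λ = 0 or a zero marginal)
score 0. `cooccurrence_count` (score = X_AB) is included as a trivial
reference scorer.

### Socio-affinity (SAI) and purification enrichment (PE)

Both combine spoke evidence (bait retrieves prey) and matrix evidence (two
preys co-purify under third-party baits). The published descriptions of
these scores leave constants and edge conventions open, so the exact forms
here are this package's own, chosen to be finite on all inputs and verified
in the test suite against independently coded naive reference
implementations:

- SAI(i,j) = S(i|j) + S(j|i) + M(i,j), each term a log-ratio of observed to
  expected retrievals under independence (expected spoke: f_i · n_j;
  expected matrix: f_i · f_j · n_purif, with f the overall retrieval
  frequency). A term with zero observed events contributes 0, so a pair
  with no evidence scores exactly 0 and scores are finite but can be
  negative — hence the clamp at aggregation time.
- PE(i,j) accumulates log-likelihood ratios per purification with
  parameters r (probability of detecting a true association; default 0.3)
  and n_pseudo (pseudo-observations at the average retrieval rate added to
  each prey's frequency estimate; default 10). Observed spoke retrievals
  contribute log(r / f_i), misses log((1−r)/(1−f_i)); matrix co-retrievals
  contribute log(r·max(f_i,f_j)/(f_i·f_j)), and one-sided retrievals
  log((1−r)/(1−f_other)). Purifications containing neither protein are
  neutral. Note the LLR behaves correctly but perhaps unintuitively when a
  protein's frequency exceeds r: co-occurrence with a sufficiently sticky
  protein is weak or negative evidence.

### Spectral-count baseline

`spectral_sum_baseline` ranks each observed bait–prey pair by the prey's
summed counts over that bait's non-control columns (summation rather than
per-column maximum; replicates therefore accumulate evidence).

## Evaluation protocol

`evaluate_topk` counts how many of the top-K ranked pairs (descending
score, ties broken lexicographically) fall in the gold-standard subset with
at least k supporting sources; subsets nest by construction, and curves are
reported absolutely and relative to the spectral-count baseline.
`average_precision` uses the full-recall convention (normalized by the
number of gold pairs at the threshold). `sweep_p` reports the validated-
count gain of the ensemble over the direct binarization across a grid of
reliability values.

## Synthetic study generator

No public AP-MS study ships with ground truth, so the generator plants it:
disjoint complexes of known membership, bait purifications against them,
and a contaminant background. It reproduces two robust qualitative features
of real count matrices — positive contaminant counts concentrated at 1–2,
and an approximately rank-1 contaminant structure (each protein has a fixed
stickiness propensity applying across all purifications).

Default preset (the package's reference study conditions): 300 proteins, 40
complexes of 5 members (100 proteins background-only), 150 experiments,
3 baits per complex (the 120-bait pool is cycled, so 30 columns are
replicate purifications), true-prey detection probability 0.7, true counts
1 + Poisson(5) (mean 6), contaminants per experiment Poisson(8) drawn
without replacement in proportion to Dirichlet(0.5) stickiness weights,
contaminant counts Geometric(0.6) (mean 1.67, ~84% at 1–2). Baits receive
no count in their own row; bait presence travels through metadata. All
randomness flows from a single seed through named child streams.

What the generator does not emulate: peptide-level detectability (protein
length, ionization), MS1 intensities, control purifications, overlapping
complexes, and abundance-correlated true counts. Passing tests on this
model therefore demonstrate that the sampling machinery extracts the count
information the model encodes — not performance on any particular real
data set.

### Measured behavior on the default preset

The suite and `scripts/acceptance.py` recompute these from scratch; typical
values at the default preset: ensemble (hart_poisson, p = 0.3, 120 trials)
average precision ≈ 0.87 versus ≈ 0.61 for direct binarization, with the
top-K improvement positive across p ∈ [0.1, 0.7] in every replicate
examined. Disjoint-seed rank agreement between 120- and 480-trial ensembles
is Spearman ≈ 0.974 (≈ 0.994 between 480 and 1920 trials): at 150
experiments, 120 trials leaves visible Monte-Carlo rank noise among the
thousands of low-scoring contaminant pairs, so studies of this size that
care about deep ranking should consider larger ensembles — the cost is
linear and the computation embarrassingly parallel.

## Numerical and design choices

- Tail probabilities floored at 1e−300 before −log; scores finite always.
- Counts are validated as non-negative integers at parse time with
  cell-level error positions; zero is a stored value, not missing data.
- Protein identifiers are opaque case-sensitive strings; pairs are
  canonicalized to lexicographic order and self-pairs are rejected
  everywhere.
- Ranked output is byte-deterministic (stored order, `repr` floats, LF
  endings); ties break by pair identifier.
- `count_to_probability` is evaluated as `-expm1(n·log1p(-p))` to avoid
  cancellation at small p.
- Problem sizes in the test suite (small 30-protein studies for exactness
  checks, the 300-protein default preset for recovery and stability
  checks, 10 replicates for the superiority comparison) were chosen to make
  the statistical assertions decisive at desk scale.

## Known limitations

- SAI/PE constants are package-defined interpretations of the published
  score families; absolute values are not comparable to other
  implementations (rankings are the meaningful output).
- The count→probability map is the single-parameter geometric-tail form;
  saturating or abundance-normalized transforms are out of scope.
- Aggregation is mean-with-optional-clamp only; no other score transforms.
- Gold standards must already be pairwise; no expansion of complexes into
  pairs is performed.
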