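# Methods

`sccausal` infers gene–gene causal networks from single-cell expression
matrices with constraint-based structure learning, and wraps that core in the
practical machinery such an analysis needs: gene filtering, dependence-based
feature selection, reliability scoring, and a ground-truth simulator.  This
note records the statistical model behind each stage, the defaults and why
they were chosen, and what the synthetic benchmarks do and do not show.

## Data model and preprocessing

The substrate is a dense gene × cell matrix (genes are rows everywhere).
Raw values are non-negative; `log2` maps x ↦ log2(x+1) so zeros stay zeros,
and `zscore` standardizes each gene with the sample standard deviation
(constant genes map to all-zero rows rather than NaN).  Per-gene attributes
are the row mean, the fraction of cells with strictly positive signal, and
the sample variance.  Fold changes against a control are
log2((mean_case + 1)/(mean_ctrl + 1)); the pseudo-count of 1 keeps the value
defined and bounded at zero counts and makes the statistic monotone in the
case mean.  This is a deliberate self-contained convention, not a
reimplementation of any particular differential-expression tool, so fold
changes are comparable within a run but not across tools.

Filtering is a strict-inequality conjunction of up to five conditions (mean,
% expressing cells, variance, |log FC|, transcription-factor membership).
The packaged defaults — mean > 0.1, expressed in > 50 % of cells,
|log2 FC| > 0.3 — target the highly-and-differentially-expressed regime in
which downstream feature selection is reliable.  Candidate output is ordered
by a caller-chosen attribute, ties broken lexicographically, so runs are
reproducible.

Cell subsampling (without replacement, seeded) caps runtime; 300 cells for
plate-based data and 600 for droplet-based data are sensible defaults for
~50-gene inputs, with more cells needed for sparser genes or larger panels.

## Dependence statistics

The Hilbert–Schmidt independence criterion is estimated with the biased
V-statistic HSIC_b = trace(K H L H)/n² using Gaussian kernels and the
median-pairwise-distance bandwidth (subsampled to 1000 seeded pairs beyond
n ≈ 45; a zero median, from heavily tied data, falls back to bandwidth 1).
Squared distance covariance is mean(A ∘ B) over double-centered Euclidean
distance matrices; since dCov² is the same V-statistic evaluated on the
distance-induced kernel (Kc = −H D H / 2 up to a constant factor), one gamma
approximation serves both.

The gamma null fits a two-moment Gamma distribution to T = n·mean(Kc ∘ Lc)
under independence with the standard HSIC moment formulas: mean
tr(Kc)tr(Lc)/(n−1)² and variance 2(n−4)(n−5)/(n(n−1)(n−2)(n−3)) times the
off-diagonal mean of (Kc ∘ Lc)², scaled to T.  A non-positive fitted mean
(degenerate input) falls back to the permutation null with a warning.
Permutation p-values use the add-one estimator p = (1 + #{perm ≥ obs})/(1+B)
with B = 100 by default (minimum 19), so p is never zero and never smaller
than 1/(B+1).

## Conditional-independence tests

Seven tests share one interface (data, i, j, S) → statistic + p-value; all
standardize the columns they use.

- **gauss** — partial correlation via correlation-matrix inversion and the
  Fisher z transform, z = √(n−|S|−3)·atanh(r), two-sided normal p-value.
  Exact under joint Gaussianity and fast; blind to nonlinear dependence.
  Singular conditioning matrices are ridge-regularized and flagged.
- **hsic.gamma / hsic.perm, dcc.gamma / dcc.perm** — for S = ∅ the
  unconditional statistic above; for S ≠ ∅ each tested variable is replaced
  by its residual from a Gaussian-kernel ridge regression on the S columns
  (kernel Gram matrix + n·λ·I with λ = 1e−3, median-heuristic bandwidth)
  before the unconditional test.  Residualization-based conditional testing
  is approximate — it removes the conditional mean, not all higher-order
  dependence — but is deterministic, well calibrated in the linear-Gaussian
  null benchmarks, and retains power against nonlinear alternatives.
- **rcit / rcot** — random-Fourier-feature approximations of the kernel
  conditional-independence test.  Variables map to f_xy = 5 cosine features
  (f_z = 25 for the conditioning block) of Gaussian kernels with
  median-heuristic bandwidths; the S features are partialled out of the X
  and Y features by least squares (rcot residualizes both blocks; rcit
  builds its Y features on (Y, S) jointly, its published asymmetric scheme).
  The statistic is n‖cov(residual features)‖²_F and the null the weighted
  chi-square of the feature-product covariance spectrum, evaluated by
  Hall–Buckley–Eagleson three-cumulant matching.  With the standard feature
  counts the sampled spectrum concentrates below ~3 standard deviations of
  frequency, so very high-frequency signals (e.g. sin(4·) of a standardized
  variable) are outside the approximation's reach; power benchmarks
  therefore use the quadratic and moderate-frequency regimes these defaults
  resolve.

Symmetric tests canonicalize (i, j) internally so that p(i,j|S) ≡ p(j,i|S)
holds exactly, including for the seeded permutation stream; rcit is
asymmetric by construction.  Because the permutation resolution is 1/(B+1),
gamma and permutation variants agree in p-value rank order only where
p-values are resolvable; the packaged agreement check uses a dependence grid
in that regime.

## Structure learning

Skeleton estimation is PC-stable: starting from the complete graph, for
conditioning-set sizes ℓ = 0…max_cond_size (default 3) each surviving pair
is tested against all size-ℓ subsets of either endpoint's neighborhood as
frozen at the start of the level, removing the edge at the first p > α.
Freezing makes the result independent of variable order (verified by
permutation tests) and is the standard parallelizable variant.  The first
separating set found (smallest ℓ, lexicographic order) is recorded; for
surviving pairs the largest p seen becomes the edge's annotation (the
weakest evidence the edge survived), and the drawn edge weight is −log10 p.

Orientation finds unshielded colliders a→c←b (c absent from sepset(a,b)),
then propagates with Meek rules 1–4 to a fixpoint.  Conflicting collider
demands resolve to an undirected edge carrying a conflict flag, and flagged
edges are excluded from later Meek propagation — a conservative policy that
keeps the output order-independent.  Rule 4 is implemented in the sound
form (a—b oriented a→b when a—d, d→c, c→b with b,d non-adjacent); it cannot
fire without background knowledge but completes the stated rule set.  Edge
signs come from the Pearson correlation of the endpoints' expression
(positive = activation, negative = repression, undefined = 0 with warning).

Default α is 0.1, matching the workflow's recommended operating point for
~50-gene panels; smaller α prunes more aggressively (edge counts are
monotone in α on fixed data).

## Feature selection

BAHSIC ranks candidates by backward elimination: each round scores every
remaining gene by HSIC between that gene and the (possibly multivariate)
response and removes the lowest ⌈0.1 × remaining⌉.  Scoring each gene
against the fixed response — rather than the leave-one-out set statistic —
gives the same ranking for additive kernels at linear cost, and makes the
per-gene scores round-invariant, so they are computed once and the
elimination loop runs over the memoized order.  Ties break
lexicographically; the procedure is deterministic.  The ensemble-tree
alternative fits a random-forest regression of each response gene on the
candidates (seeded, impurity importances averaged over responses).  The
recommended joint use interleaves both top-k lists into a deduplicated union
capped at k_total; k defaults to 50, the usual feature-panel size.  Manual
add/remove after selection is a list merge.

## Reliability scoring

Networks from different CI tests (or repeated runs) are compared by
structural Hamming distance: one point per adjacency present in exactly one
graph, one point per shared adjacency with a different mark; a direction
flip costs 1.  Similarity = exp(−SHD/2σ²) with σ = 5.  Consensus membership
defaults to the largest average-linkage cluster of (1 − similarity) at a
configurable cut height — a reproducible stand-in for picking the most
mutually similar networks off a cluster map — and is overridable by explicit
labels.  The consensus keeps an adjacency iff every member has it, keeps a
direction iff unanimous, and a sign iff unanimous.  TPR of a network against
the consensus is overlap/(overlap + specific) on adjacencies; an empty
network scores 1 vacuously, with a warning.  Stability profiles count, for
the union of adjacencies over m runs, the fraction occurring in exactly k
and in ≥ k runs.  Adjacency (not direction) is the unit everywhere an
"interaction" is counted; direction enters only through unanimity and the
SHD mark term.

## Spike-in QC

A spike-in block of genes with known interactions is stacked under the case
matrix after equalizing cell counts (seeded subsampling of the larger) and
pairing spike-in cells to case cells by a seeded random permutation.  Random
pairing is the load-bearing choice: it guarantees the two blocks are
independent in the combined matrix, so any inferred cross-block edge is a
false positive of the chosen CI test, and the cross-edge fraction (flag
threshold 5 %, configurable) estimates its false-positive behavior on data
with the case's marginal distributions.  Spike-in gene ids are prefixed
(`SPIKE_`) to guarantee disjointness, and case values are never modified.

## Synthetic benchmarks

`random_dag` draws a topological order and includes each forward pair with
probability d/(p−1) (expected p·d/2 edges); weights are uniform on ±[0.5, 2]
so no edge is negligibly weak.  `simulate_sem` generates in topological
order — linear x_j = Σ w·x_i + ε, or nonlinear with per-edge mechanisms
drawn from {tanh, square, sine} applied to the parent before weighting —
with Gaussian noise, standardizing each column as it is generated so signal
does not compound along paths.  Dropout is uniform Bernoulli zeroing
(seeded, mask returned); an expression-dependent logistic variant would be
more faithful to capture chemistry but couples the missingness to the
signal, so the neutral model is the default.  Evaluation compares inferred
adjacencies to the DAG skeleton (precision/recall/F1), directed edges to the
DAG and to the true CPDAG (computed by collider detection + Meek closure on
the truth), and marks to the true CPDAG via SHD.

What the simulator does not emulate: counts are Gaussian-derived rather than
negative-binomial, there are no library-size or batch effects, no cell
subpopulations, and dropout is independent of expression.  Passing the
synthetic benchmarks therefore demonstrates correctness of the inference
machinery under its stated assumptions, not performance on any particular
tissue or platform.

## Problem sizes in the packaged checks

The packaged test suite and the acceptance script run entirely on synthetic
data at sizes chosen to exercise each claim meaningfully on a single CPU:
CI-test calibration uses 500 replicates at n = 300 with |S| = 2 (permutation
B = 100) against the exact binomial 99 % band; nonlinear power uses 100
replicates of y = x² + noise at n = 300; parameter recovery uses 10 seeds of
p = 10, expected degree 2, n = 600 nonlinear SEMs (median adjacency F1,
with and without 30 % dropout); oracle correctness enumerates the full
Markov-equivalence class of 50 random DAGs on ≤ 5 nodes; stability runs
five DCC.perm inferences on disjoint 300-cell subsamples.  Numbers reported
by `scripts/acceptance.py` are computed fresh from these runs at the given
seed.

## Known limitations

- Residualization-based conditioning (hsic/dcc) tests conditional
  uncorrelatedness in feature space after mean removal; pathological
  dependences carried purely by conditional variance can escape it.
- The gamma null is an approximation; p-values are accurate in the bulk but
  not in the extreme tail, where the permutation variants (with their
  1/(B+1) floor) are the safer choice.
- PC output is a Markov equivalence class: many edges remain undirected, and
  orientations rely on faithfulness, which dense or deterministic
  relationships can violate.
- Fold-change and bandwidth conventions are package-internal; numeric
  p-values are not expected to match other implementations bit-for-bit,
  though decisions at any reasonable α agree on well-separated signals.
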