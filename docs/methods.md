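# Methods

## Model

betadce scores a feature subset by how predictable each training
sample's class is from its nearest neighbors, measured on the subset's
Euclidean geometry. For a sample with $K_A$ class-A and $K_B$ class-B
neighbors among its $K = K_A + K_B$ nearest, the class probability
$P_A$ is modeled as $\mathrm{Beta}(K_A+1, K_B+1)$: the posterior of a
binomial proportion under a uniform prior, treating the neighbor labels
as $K$ Bernoulli observations of the local class balance. Its mean
$(K_A+1)/(K+2)$ is closed-form, so the objective needs no resampling.
The variance of the same posterior,
$(K_A+1)(K_B+1)\,/\,\big[(K+2)^2 (K+3)\big]$, is exposed as a
diagnostic: at a fixed $K_A\!:\!K_B$ ratio the mean of the majority
class rises and the variance falls as $K$ grows, which is exactly the
bias/variance trade-off the per-sample $K$ optimization navigates — a
small pure neighborhood is not trusted more than a larger, mildly
impure one.

Assumptions worth stating: the two classes are judged by *local*
neighborhood composition, so the method is nonparametric and handles
nonlinear structure (the XOR benchmark exists to demonstrate this), but
it inherits the usual nearest-neighbor caveats — all features in a
subset contribute equally to the distance, so features must be on
comparable scales (standardize first), and very small samples per class
limit the admissible $K$ range.

## Per-sample K and the objective

For each sample, $K$ is scanned over $1 \ldots k_{\max}$ and chosen to
maximize the expected probability of the sample's **true** class,
$E_{\text{true}}(K) = (K_c + 1)/(K + 2)$; ties go to the smallest $K$
(the least assumption about the extent of the local neighborhood). The
subset objective is the class-balanced cross-entropy
$H = -\tfrac{1}{n_A}\sum_{A}\ln E_i - \tfrac{1}{n_B}\sum_{B}\ln E_i$
in nats (natural logarithm). Using the true-class expectation makes
misclassified samples expensive ($E_i < 1/2 \Rightarrow -\ln E_i >
\ln 2$), which is what lets $H$ drive selection; a
``predicted-class`` switch is provided that instead scores each sample
by the winning class's expectation $\max(E[P_A], E[P_B])$ — the
winner-take-all reading — but that variant is blind to misclassified
samples and is offered for sensitivity analysis only, with the
per-sample $K$ still chosen by the true-class criterion so the two
modes differ only in the entropy summand.

$H$ is bounded below by
$-\ln\frac{n_A}{n_A+1} - \ln\frac{n_B}{n_B+1} > 0$ (each class term at
its best achievable $E$) and the implementation is checked against a
naive full-distance-matrix, exhaustive-scan reference to $10^{-12}$.

Determinism conventions: the query sample is excluded from its own
neighbor set (leave-one-out; including it would inflate every $E$
identically and mask errors); exact distance ties break toward the
lower sample index via a stable sort; identical inputs give bitwise
identical results for any worker count.

## Epoch search

Epoch $i$ evaluates every size-$i$ subset of the current candidate
pool, sorted ascending by $H$ with ties broken lexicographically by
feature names. Epoch 1 always scores all $p$ single features — the
budget governs later epochs only, since scanning every feature once is
both cheap and necessary to seed the pool fairly. The pool for epoch
$i{+}1$ is the first $m$ unique features encountered scanning the
sorted list, where $m = \max\{m : \binom{m}{i+1} \le N_e\}$, computed
with exact incremental integer binomials. The search stops when
$\min H(i) \ge 0.95 \cdot \min H(i-1)$ (the comparison is $\ge$, i.e.
continuing requires a strictly-more-than-5% relative improvement), when
the pool cannot supply $i+1$ features, or at `max_epochs`.

**Return policy.** The literal one-epoch-lookback rule ("stop and take
the current epoch's best") can return a *worse* subset than the
previous epoch's best: the stopping epoch is by construction the one
that failed to improve. The default `return_policy="global-best"`
therefore returns the lowest-$H$ subset seen in any epoch, which on the
XOR benchmark is the informative pair rather than pair-plus-noise; the
literal `current-epoch-best` behavior remains available.

**Defaults.** $N_e = 100{,}000$ per epoch, giving an epoch-2 pool of
447 features — comfortably above typical informative-feature counts for
omics panels while keeping an epoch under $10^5$ evaluations.
$k_{\max}$ defaults to $n-1$ (optimized values well above 10 do occur
in practice, so a tight default cap would bias the objective); it is
configurable for speed. `stop_ratio` and `max_epochs` (20) are
config-exposed.

## Prediction

A held-out sample is scored by the beta-posterior mean of $P_A$ given
the class counts among its $K_{\text{used}}$ nearest *training*
samples; the predicted class is A iff the score $\ge 0.5$ (the tie
resolves to A, documented and deterministic). $K_{\text{used}}$
defaults to the rounded median of the training samples' optimized $K$
on the selected subset — a robust summary of a typically right-skewed
distribution — with a fixed-$K$ override. Test data are standardized
with the training means/SDs, never their own, to avoid leakage. AUC is
computed by the rank (Mann–Whitney) formulation with mid-ranks, so tied
scores count one half.

## The XOR-like generator

The generator emulates the benchmark's study conditions: 280 samples,
140 per class, two real features, each class split equally (70/70) over
two diagonally opposed isotropic Gaussian clusters — class A at
$(-1,-1)$ and $(1,1)$, class B at $(-1,1)$ and $(1,-1)$ — with
per-cluster standard deviation $\sigma = 0.5$. Centers and $\sigma$
are the package's own choice of geometry: at $\sigma = 0.5$ the four
clusters visibly overlap at the midlines, the classes are not linearly
separable, and each feature's marginal is an uninformative bimodal
mixture — the XOR property the benchmark requires. All of it is
config-exposed.

The redundant feature appended in the permutation test is by default a
fresh independent standard-normal column per replicate; a
`permuted-copy` mode (random permutation of the first real feature,
preserving its marginal) is provided since either construction yields a
label-independent column. For the cross-entropy evaluator a replicate
counts as a false discovery under the default `slack-0.95` rule when
the 3-feature $H$ falls below $0.95 \times$ the 2-feature baseline —
the same retention condition the search itself applies — with a
`strict` ($H_3 < H_2$) variant for sensitivity analysis. Accuracy-type
baselines (KNN leave-one-out with $k$ tuned over $1\ldots30$; RBF-SVM
with stratified 5-fold CV over a $C \times \gamma$ log grid,
$C \in 10^{-2..3}$, $\gamma \in 10^{-3..1}$) count any strict accuracy
increase as a discovery, since no slack is natural on an accuracy
scale. Baseline grids are config-exposed; the reported baseline FDRs
depend on them and on the generator geometry, so only the
cross-entropy evaluator's zero-FDR behavior is treated as a
reproducible benchmark quantity.

What the generator does *not* emulate: real omics data have correlated
features, heavy-tailed noise, batch structure, and many weakly
informative features; passing the synthetic benchmark shows the
objective rejects label-independent features and recovers jointly
informative pairs under clean Gaussian geometry, not that it ranks
correlated biological signals correctly.

## Numerical and design choices

- Distances are squared-Euclidean for ordering (monotone equivalent,
  cheaper); sorting is a stable argsort after setting the self-distance
  to $+\infty$.
- Standardization uses the population (divide-by-$n$) SD; zero-variance
  features are dropped with a warning and recorded in the fitted
  parameters. Evaluating a subset containing a zero-variance feature
  raises a degenerate-feature error rather than silently treating it as
  a no-op dimension.
- The pool bound uses exact integer arithmetic, so no overflow for any
  budget.
- Parallelism (joblib threads) only partitions independent subset or
  replicate evaluations and merges in submission order; results are
  identical for any `--threads` value.
- Problem sizes used by the shipped checks: permutation test at 1,000
  replicates (binomial Monte-Carlo error ~0.3 pp at FDR 1%); selection
  recovery over 100 seeded generator draws with 8 appended noise
  features.

## Known limitations

- Binary classification only; no multiclass extension.
- Euclidean distance only (no Mahalanobis or kernelized metrics).
- The epoch search is greedy across epochs: a feature not reaching the
  pool at epoch $i$ can never re-enter, so with budgets far below
  $\binom{p}{2}$ the optimum is not guaranteed — the standard wrapper
  trade-off; raise $N_e$ to trade compute for coverage.
- The per-sample $K$ optimization maximizes a selection-biased quantity
  (a maximum over $K$), so single-feature $H$ on pure noise sits below
  the naive chance level; comparisons should always be between subsets
  under the same rule, as the search and permutation test do.
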