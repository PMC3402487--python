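# Methods

`netprog` implements a two-stage analysis: (1) derive a disease gene
signature by propagating heterogeneous seed evidence over a protein
interaction network and calling significance against permuted-seed nulls;
(2) evaluate the signature's clinical value with a kernel survival SVM,
concordance-driven model selection, risk stratification, and a stratified
treatment-benefit analysis. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic benchmark does
and does not establish.

## Network propagation

The interaction network is undirected, unweighted and simple (self-loops
and duplicate edges removed at load time; edge weights in input files are
ignored). Gene identifiers are case-sensitive strings, ordered
lexicographically so node indexing is reproducible. Isolated nodes are
removed before normalization — a degree-0 column cannot be made
stochastic — and seeds falling on removed nodes are reported as unmapped.

With `A` the adjacency matrix and `D` the degree diagonal, the transition
matrix is `W = A D^{-1}` (column `j` holds the uniform distribution over
`j`'s neighbors). The random walk with restart iterates

    p^{t+1} = (1 - r) W p^t + r p0

with restart probability `r = 0.5` by default. Because `W` is
column-stochastic, total probability is conserved at every step, and the
L1 residual contracts at least geometrically at rate `(1 - r)`, so r = 0.5
converges in a few tens of iterations. Convergence is declared when the
L1 change falls below `1e-6` (configurable; L1 was chosen as the
convention of the random-walk prioritization literature this follows —
whether per-gene or L-infinity tests behave differently is a
documented, configurable choice, not a result). A `max_iter = 10000`
guard catches misuse at r near 0.

The fixed point solves `(I - (1 - r) W) p = r p0`, a nonsingular system
for r > 0 since the spectral radius of `(1 - r) W` is at most `1 - r`.
`rwr_solve_exact` computes it by sparse LU; the permutation-null stage
factorizes the system once and solves all permuted start vectors as
batched right-hand sides. The two routes agree to better than `1e-8`
(tested on random graphs), so the choice is purely computational.

## Start probabilities

Two evidence channels seed the walk: `s_i`, the number of prognostic
expression signatures containing gene `i`, and `m_i`, the number of
distinct catalogued somatic variants of gene `i`. The integrated ("NEM")
start distribution gives the channels equal total weight and each gene
weight proportional to its evidence count within a channel:

    p0_i = 1/2 * s_i / sum_j s_j + 1/2 * m_i / sum_j m_j

with sums over genes that map onto the network (evidence genes absent
from the network are dropped before normalization and reported — the
walk cannot start off-network, and smearing their mass over the network
would dilute the channels). Single-channel runs ("NE", "NM") use one
term renormalized. The formula is the minimal one satisfying the design
constraints: equal channel totals, monotone in `s_i` and `m_i`,
scale-invariant within a channel, and summing to one; NEM is then
exactly the entrywise average of NE and NM when both channels are
non-empty. If a channel maps no genes in NEM mode its weight passes to
the other channel with a warning rather than failing the run.

## Permutation significance

The null model shuffles the entire start vector uniformly across nodes
(1000 permutations by default; unit and robustness tests use 100–200),
preserving the multiset of seed weights and hence the total mass and its
skew. Channel-wise permutation was rejected: the quantity being
significance-tested is the walk score under the integrated seeding, and
its null should permute that seeding as a whole. Each permutation draws
from its own RNG stream spawned from the stage seed, so results do not
depend on batching.

For each gene the real steady-state score is ranked against (a) its own
null scores — the *local* p-value, which absorbs topology effects such
as hubs scoring high under any seeding — and (b) the pooled null scores
of all genes — the *global* p-value, measuring absolute proximity to the
actual seeds. Both use the add-one estimator `p = (1 + #{null >= real})
/ (N + 1)` with ties counted conservatively; p-values are therefore
never zero and decrease monotonically in the score. A gene enters the
signature when both p-values fall below alpha (0.05 default); the
signature is split by provenance into seed-overlapping and
network-added genes. Robustness is probed by holding out each
expression signature in turn and reporting Dice overlap of the re-derived
set with the full-run set.

## Expression preparation

Probe-level matrices are collapsed to genes by discarding probes mapped
to more than one gene and keeping, per gene, the probe with the largest
interquartile range across samples (type-7 linear-interpolation
quartiles; IQR ties broken by lexicographic probe ID for determinism).
Gene rows are then Z-scored with the population SD (ddof = 0,
configurable; the choice only rescales rows and cannot change
rank-based downstream results). Constant genes are dropped with a
warning. Train and test cohorts are always standardized separately so
the test cohort never leaks into training statistics; Z-scoring is
applied after any cohort subsetting (e.g. stage restriction).

## Kernel survival SVM

The prognostic model is a ranking SVM on comparable pairs of censored
records: pair (i, j) is comparable when `t_i < t_j` and subject i's
event was observed. The score function lives in the span of Gaussian
kernel sections, `f(x) = sum_j alpha_j K(x_j, x)` with
`K(x, y) = exp(-||x - y||^2 / (2 sigma^2))`, and training minimizes

    1/2 alpha' K alpha + c * sum_{(i,j) in P} max(0, 1 - (f_i - f_j))^2.

Every comparable pair pushes the shorter-lived member a margin higher,
so higher score means higher predicted risk by construction. The
squared hinge keeps the problem smooth and convex in `alpha`; it is
solved in the n-dimensional primal by L-BFGS. Pair sets above 50,000
are subsampled with the run seed (inactive at the benchmark scale).
scikit-survival's kernel ranking SVM implements the same formulation
(their `alpha` equals `2c`) and serves as an independent cross-check in
the test suite; scores agree to correlation > 0.99.

Model selection follows the printed protocol: both `c` and `sigma` range
over {1e-5, …, 1e5} (11 x 11 = 121 cells), scored by the mean Harrell
C-index over 5-fold cross-validation repeated 5 times. Folds are
stratified by event status; the fold split is the only stochastic
element, so a fixed seed reproduces the selection exactly. Ties in the
mean C-index break toward the smallest `c`, then the smallest `sigma`
(prefer the simpler model, deterministically). Fold-level fits
warm-start along the ascending-c path and run under a capped solver
budget (they only rank cells); the final model is refit on the full
cohort to full tolerance. Folds whose training or validation split has
no comparable pair are skipped with a warning.

Test cohorts are aligned to the training gene order; genes missing from
the test matrix are imputed at 0 — the per-gene mean after Z-scoring —
with a warning. Patients are stratified at the median score (at-median
samples go to the low-risk group: deterministic, and conservative
toward treatment de-escalation); the split depends only on score ranks.

## Survival statistics

*C-index.* Harrell's convention: the fraction of comparable pairs in
which the shorter-lived member has the strictly higher score, with 0.5
credit for score ties; event-event time ties are excluded from the
comparable set. The implementation is tested for exact equality against
a brute-force double loop.

*Kaplan-Meier and log-rank.* Delegated to `lifelines`
(`KaplanMeierFitter`, two-group `logrank_test` with the hypergeometric
variance and a 1-df chi-square reference).

*Cox proportional hazards.* Fit in-package by Newton-Raphson with
step-halving on the partial likelihood, Breslow tie handling by default
(Efron available). Breslow is the default because it makes the
classical identity exact: for a binary group covariate at distinct
event times, the log-rank statistic equals the squared Cox score test
(the hypergeometric variance's tie factor (n - d)/(n - 1) is 1 without
ties) — this identity is asserted to 1e-6 in the tests. Hazard ratios
carry Wald 95% CIs on the log scale, matching the univariate and
multivariate tables the analysis produces; a likelihood-ratio p is also
reported. Monotone likelihoods (a covariate that strictly orders the
events) are detected by coefficient divergence (|beta| > 20) and raised
as separation rather than returned as a huge finite HR.

*Treatment-benefit analysis.* Restricted to stage III samples with a
recorded adjuvant-chemotherapy flag, split at the median risk score;
within each stratum treated vs untreated relapse-free survival is
compared by Kaplan-Meier, log-rank, and a univariate Cox HR for
treatment (HR < 1 = benefit). Strata in which the comparison is
impossible (an arm with fewer than two samples, a constant flag) are
skipped with a warning; strata with monotone likelihoods keep the
log-rank result and report the HR as unavailable.

Since the same comparison is reported with both a log-rank p and a Cox
Wald p (they answer the same question through different statistics),
outputs label both explicitly.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **Network** — a Barabasi-Albert preferential-attachment graph
  (2000 genes, 3 edges per new node) gives the heavy-tailed degree
  distribution of real interactomes; a random 80-gene "driver" module
  receives extra internal edges until its edge density reaches 0.10.
  2000 nodes is a deliberate scale-down of the ~11.5k-protein
  integrated interactome the analysis design targets.
* **Evidence** — eight signatures with unique sizes {8, 58, 26, 24, 19,
  22, 34, 21} (the per-signature sizes of the published collection being
  emulated) draw half their genes from the module plus its 1-hop
  neighborhood and the rest uniformly, so the evidence is *near* but not
  equal to the module and propagation has genuine work to do. The
  mutation catalog (150 genes, 40% from the module pool) carries
  Zipf(2) variant counts with the largest counts assigned to module-pool
  genes: driver genes accumulate many distinct variants while passengers
  carry the singleton tail, making the channel's mass — not merely its
  membership — module-enriched. A complementary-evidence variant feeds
  the signatures one half of the module and the mutations the other,
  isolating the value of integrating both channels.
* **Cohorts** — each sample carries a latent risk z ~ N(0, 1); module
  genes load on z with per-gene loadings uniform in ±[0.4, 1.0] that are
  shared between cohorts (the risk-to-expression mapping is the common
  biology; everything else is drawn independently per cohort).
  Non-module genes are pure noise. Relapse times are exponential with
  hazard 0.02 * exp(beta * z) per month (beta = 1 by default); uniform
  censoring is calibrated by root-finding so the expected event fraction
  matches the target 0.28, the recurrence fraction scale of the cohorts
  being emulated. Stage III probability rises with z (logistic, slope
  0.8); adjuvant chemotherapy is assigned at random and multiplies the
  hazard by 0.4 only for samples in the high-latent-risk half — the
  interaction the stratified analysis is asked to recover.

What passing the benchmark shows: the propagation machinery is exact,
the permutation null is calibrated, module-concentrated evidence is
recovered and integrating two weak complementary channels beats either
alone, the SVM finds transferable survival signal where it exists
(C-index ≈ 0.70–0.78 against an oracle ceiling of ≈ 0.72–0.80) and none
where it does not, and the treatment interaction is recovered at n =
300. What it does not show: anything about probe-level microarray
artifacts, batch effects, biological pathway structure, or the actual
effect sizes of any real cohort — non-module signature genes carry no
expression signal here, so the derived signature's test concordance
(≈ 0.6) sits between the random baseline (≈ 0.5) and the informative-
gene ceiling, and real-data performance cannot be inferred from it.

## Problem sizes and defaults

| Parameter | Default | Notes |
| --- | --- | --- |
| restart probability r | 0.5 | propagation vs seed fidelity trade-off |
| convergence tolerance | 1e-6 (L1) | configurable |
| permutations | 1000 | tests and robustness sweeps use 100–200 |
| significance alpha | 0.05 | dual local/global threshold |
| (c, sigma) grid | 10^-5 … 10^5 | 121 cells |
| cross-validation | 5-fold x 5 repeats | event-stratified |
| cohort size | 120 per cohort | 300 for the treatment analysis |
| pair cap | 50,000 | seeded subsample above this |

The acceptance script (`scripts/acceptance.py`) runs the full pipeline
at these defaults in both train/test directions, plus the hold-one-
signature-out robustness sweep, a 10-set random-gene baseline, and the
treatment-benefit stratification, and writes every number it computes
to JSON.
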