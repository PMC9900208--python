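# Methods

This note records the model, the choices behind every tunable parameter, what
the synthetic benchmark does and does not emulate, and the numerical corner
cases. It states no result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

The input is a set of genes believed to share a biological context, a
genome-scale undirected molecular network (protein–protein interactions,
co-expression, or any weighted edge list), and a gene set collection (GMT)
such as a process ontology or a disease catalogue. The method treats gene
discovery as binary classification: learn what distinguishes the input genes
from background genes *in terms of their network connectivity*, then score
every gene in the network.

## Gene identity

All computation happens on a dense internal index defined by the ID-mapping
table (one gene per row; internal id = row order). Four namespaces are
supported — Entrez, symbol, Ensembl gene, Ensembl protein — and the input
list's namespace is auto-detected as the one resolving the largest fraction
of IDs (ties break in that fixed order, so numeric IDs prefer Entrez). Symbol
matching is case-insensitive after whitespace stripping; Ensembl version
suffixes (`.N`) are stripped. When two rows of the ID table claim the same
external ID, the first-listed row wins; this synonym rule is this package's
own documented convention. Input genes that map to the index but have no
network edges are reported and excluded from training (features only exist
for network genes), yet still receive predictions.

## Network representations

**Adjacency.** Row $g$ of the symmetric weighted adjacency matrix, zero
diagonal. Duplicate edges merge by maximum weight — max is order-independent
and idempotent, so re-loading a written network is a fixed point.

**Influence.** $F = r\,(I - (1-r)W)^{-1}$ with $W$ the *column*-normalized
adjacency ($W_{uv}$ = probability of stepping to $u$ from $v$) and restart
probability $r \in (0,1)$, default **0.85**. Column $v$ of $F$ is the
expected visiting distribution of a walk restarting at $v$, so every column
sums to 1 (checked to 1e-8); the feature vector of gene $g$ is row $g$ of
$F$. The linear system is solved densely below 5 000 nodes and by sparse LU
above; the closed form is verified in the tests against an independent
truncated power-series oracle ($\sum_{k\le 200} r(1-r)^k W^k$, agreement
below 1e-6, in practice ~1e-15). Isolated nodes get an identity column (a
walk that never leaves its restart point), which keeps the operator
stochastic; they appear as zero rows in the adjacency representation.

**Embedding.** node2vec: biased second-order random walks (return parameter
$p$, in-out parameter $q$; $p=q=1$, the default, reduces to first-order
walks) followed by skip-gram with negative sampling. The walk generator and
the minibatched SGD trainer are implemented in numpy inside this package and
draw all randomness from one seeded generator in a single worker, so the
embedding is bitwise reproducible given the seed. Defaults: dimension 128,
walk length 80, 10 walks per node, window 10, 5 negative samples, 1 epoch,
initial learning rate 0.025 with linear decay, seed 42. These follow common
practice for this family of embedders; the method itself prescribes none of
them. Isolated nodes produce no walks and keep their small random
initialization (flagged in the log). Minibatch gradient application uses
unbuffered scatter-adds, accepting within-batch update collisions the way
asynchronous word2vec implementations do.

## Negative selection

Candidate negatives are the genes annotated to at least one term of the
background collection. A term is "sufficiently close" to the positives when
its one-sided hypergeometric overlap tail $P[X \ge \text{overlap}]$ is below
$\alpha$ (default **0.05**); members of close terms are excluded from the
negative pool. Choices made here, each configurable:

- **Statistic.** The hypergeometric tail is the standard overrepresentation
  test for set overlap; a Jaccard-threshold mode is available behind a flag.
- **Universe** = genes present in the network, not the collection's union or
  the genome: the classifier can only ever see network genes, so that is the
  population the draw models.
- **No multiple-testing correction**: the screen exists to *exclude* risky
  negatives, and over-exclusion is safer than training against unlabeled
  positives. Correction would make exclusion harder exactly when collections
  are large.
- Training requires at least 10 negatives; fewer is a hard error suggesting a
  larger collection or smaller $\alpha$.

Genes in no term remain unlabeled: never trained on, always scored.

## Classifier and evaluation

L2-regularized logistic regression (strength 1.0, i.e. C = 1), lbfgs, on
features standardized to mean 0 / variance 1 over the training rows only;
class imbalance is handled with inverse-frequency sample weights
(switchable). Ranks break probability ties by ascending internal id so
output tables are reproducible. Non-convergence retries once with a 10×
iteration cap before failing with diagnostics.

Cross-validation is stratified k-fold (default **k = 5**, reduced with a
warning if it exceeds the positive count), refitting the entire pipeline —
standardization included — inside each fold. The headline metric is
$\log_2(\mathrm{auPRC}/\mathrm{prior})$: auPRC has the fold's positive
fraction as its chance level, so the ratio is comparable across set sizes and
its log2 reads as doublings over chance. It is computed as
$\log_2(\mathrm{auPRC}) - \log_2(\mathrm{prior})$, which makes the ceiling
identity $\mathrm{auPRC}=1 \Rightarrow \log_2(1/\mathrm{prior})$ exact in
floating point. auROC and precision at the held-out positive count are
reported alongside.

## Interpretation

Every term of an interpretation collection is trained through the *identical*
pipeline (the term's members as positives; the term itself always treated as
close to its own positives). The user model is compared to the panel by
cosine similarity of intercept-free weight vectors (Pearson mode behind a
flag), with z-scores over the panel's similarity distribution. Because the
pipeline is deterministic, a panel term identical to the input set reproduces
the user model exactly and scores cosine 1 at rank 1 — the self-consistency
property the tests pin. Panels are cached keyed by a hash of the feature
parameters and collection contents; any parameter change invalidates the
cache. The connectivity view is the exact induced subgraph of the top-K
ranked genes (default **K = 50**).

## Synthetic benchmark

`make_benchmark` plants `m` modules of size `s` in an `n`-node
stochastic-block-model graph (within-module edge probability `p_in`,
background `p_out`), writes one GMT term per module plus random noise terms,
and hands the method a fraction `f` of one module. Standard conditions:
n = 500, m = 5, s = 20, p_in = 0.3, p_out = 0.01, f = 0.5, 10 noise terms,
seed 7 — module degree ≈ 6 against background degree ≈ 5, a realistic
signal-to-noise regime where recovery is high but not trivially perfect. All
randomness flows from a single integer seed through spawned child streams
(one per artifact), so regeneration is byte-identical.

What the benchmark does **not** emulate: scale-free degree distributions,
edge-weight heterogeneity, overlapping modules, annotation bias, or
incomplete/incorrect input sets beyond the held-out split. Passing tests
demonstrate that the machinery is correct and well-calibrated on clean
planted structure, not that any particular biological discovery will
replicate.

The permutation-null check shuffles a 50-positive label set over the
benchmark's annotated genes and averages cross-validated auROC over 20
shuffles. Fifty positives (10 per fold) keep the sampling error of that mean
near 0.01, so the ±0.05 calibration band is a ~4σ statement about bias rather
than a statement about auROC variance; shuffling the original 10-positive set
would leave 2 positives per fold and a standard error comparable to the band.

## Numerical and degenerate-input choices

- Influence solves assert finiteness and clip solver noise at zero; columns
  are validated to sum to 1 within 1e-8.
- Zero-variance features standardize with divisor 1 (constant columns carry
  no gradient either way).
- Probability ties rank by ascending internal id; similarity ties rank by
  term id.
- Zero-norm weight vectors define cosine 0 with a warning.
- Empty GMT files yield an empty collection with a warning; a term line with
  fewer than three fields, a non-positive or non-numeric edge weight, and an
  input list resolving in no namespace are hard errors naming the offending
  line or IDs.
- Multiplying all features by a constant leaves rankings essentially
  unchanged (rank correlation ≥ 0.99 in the guard test); exact probability
  invariance is not expected because standardization interacts with the fixed
  L2 penalty.

## Known limitations

- The influence formula and its restart default are this package's documented
  convention; other implementations normalize by rows or parameterize the
  restart differently, so numeric compatibility with externally distributed
  influence matrices is not claimed.
- Closeness is pure set overlap; no ontology-graph reasoning.
- No hyperparameter search, alternative classifiers, probability calibration,
  GPU training, or multi-network fusion.
- The embedding trainer is tuned for the desk scales used here (hundreds to a
  few thousand nodes); for very large networks a specialized embedding tool
  will be faster.
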