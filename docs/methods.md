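# Methods

This note records the model implemented by `oncovote`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Edge taxonomy and data model

The interactome is an undirected graph over opaque, case-sensitive
protein identifiers; no mapping between identifier namespaces (gene
symbol, UniProt accession, …) is attempted — callers must harmonise
identifiers upstream. A subset of nodes carries a cancer label; each edge
is then C–C, C–X or X–X. Duplicate edges collapse (interaction
multiplicity is not a feature), self-interactions are retained and
flagged, and homology-driven redundancy is handled by a user-supplied
edge-exclusion list rather than by any built-in sequence comparison: the
semantics of "drop these edges before anything else" is preserved without
tying the package to an external homology resource.

## The one-to-one domain-interaction model

Each annotated edge (P_i, P_j) distributes exactly unit mass over its
domain pairs: 1/(M·N) per ordered pair, with M and N the endpoints'
domain-instance counts (multiplicity included; a self-loop uses
S(P)×S(P)). Contributions are accumulated on **unordered** pair keys:
physical domain contact is symmetric, and ordered bookkeeping would
double-count pairs in the per-edge sum. Mass conservation (total mass =
number of contributing edges) holds exactly and is enforced by test.

The observed matrix is built from **C–C edges only** by default — the
interaction rules are meant to be cancer-specific — with `"all"`
available for comparison. The null ensemble permutes the global multiset
of domain-assignment instances across proteins, preserving each
protein's assignment count, with **B = 40** draws by default (estimates
stabilise by a few tens of draws; B is exposed as `--b-rand`). The ratio
R = I/⟨I^rand⟩ uses the strict inequality R > 1 in the edge score, as
defined.

Numerical edge cases:

* a pair observed but never drawn in the null ensemble would divide by
  zero; its null mean is floored at 1/(B · max_e M_e N_e), the smallest
  mean attainable by appearing once with minimal weight in one draw —
  finite, and monotone in evidence. The floor is configurable.
* edges with a domainless endpoint are excluded from accumulation and
  receive DDI = 0 downstream, with a logged count.
* pairs with zero observed mass have R = 0 regardless of the null.

## Domain-frequency and linker-degree features

C(α)/X(α) count domain **instances** across cancer/noncancer proteins
(a domain repeated within one protein counts each time): the scores are
meant as weighted frequencies, and occurrence counting is what makes a
heavily reused cancer domain weigh more. The denominator m + n (domain
types occurring on either side) is a global constant, so DFS is a scaled
sum — implemented as defined, even though any per-edge rescaling would
drop out after min–max normalization anyway.

CLD counts **distinct** proteins in the union of the two endpoints'
neighbourhoods, excluding the endpoints themselves; a shared neighbour
counts once. (Union-versus-sum is not determined by the defining
illustration; the union reading treats the neighbourhood as a set, which
matches how the score is described.) The endpoints' own labels do not
enter. A pair with no external neighbours scores 0, the conservative,
least cancer-like value, rather than NaN.

Min–max normalization is fitted per feature on training rows and applied
with clamping to evaluation rows; inside cross-validation it is refitted
per fold, so no evaluation information leaks into the scaling. A
degenerate feature (max = min) maps to 0. Global (fit-once) normalization
remains available for reproducing single-pass workflows.

## Dataset construction and the classifier bench

Positives are C–C edges; negatives pool C–X and X–X (an `"XX"`-only mode
exists for ablation). Edges lacking domain data are excluded *before*
balancing. Balanced 1:1 sampling keeps all positives and draws negatives
uniformly without replacement, deterministically under a seed.

The bench is a registry of 13 scikit-learn-backed classifiers spanning
six families — probabilistic (Gaussian/Bernoulli naive Bayes), function
fitters (logistic regression, linear SVM), discriminant analysis
(LDA/QDA), instance-based (1-NN, 5-NN), rules (a prior-rate baseline and
a one-feature stump) and trees (CART, a depth-limited tree, random
forest). The bench protocol — shared stratified folds, pooled confusion
counts, F1-ranked panels, majority and strict voting — is the method; no
attempt is made to reproduce any particular legacy implementation of the
individual learners. Every classifier must expose a continuous
positive-class score (probability or margin) so per-classifier AUCs and
vote-fraction AUCs are defined.

Metric conventions: the reported F1 is the harmonic mean of specificity
and sensitivity (a deliberate convention of this benchmark, distinct from
the precision/recall F-measure) and is reported as a fraction. MCC uses
the standard Matthews formula with the square-root denominator. Ratios
with zero denominators are reported as 0 and flagged as degenerate rather
than raised. Ranking ties break by accuracy, then name, so reports are
deterministic. Majority panels must be odd; the ensemble's continuous
score is its vote fraction.

## Protein-level inference

A candidate is treated as noncancer; its incident edges to known cancer
proteins (the C–X construction) are scored by a trained panel, strict
consensus by default, and the candidate is called cancer under the
`any` rule (one positive edge suffices) or the `majority` rule (more than
half). Both are exposed because edge-to-protein aggregation is not
uniquely determined by the problem; `any` is the default as the natural
reading of "one predicted C–C interaction re-labels X as C".
Candidates with no testable edges are unclassifiable: excluded from hit
counting, kept in the hit-ratio denominator, reported separately. The
case-study filter chain removes candidates already in the training labels
and those lacking PPI or domain data before prediction.

## The synthetic generator

The generator emulates the two structures the method needs: domain
propensity (pools of cancer-only / shared / noncancer-only domain types,
with class-dependent draw odds scaled by `enrichment`) and assortative
wiring (class-conditional Erdős–Rényi with p_cc, p_cx, p_xx). Domain
popularity is Zipf(1) within the universe — real domain-family sizes are
heavy-tailed — decoupled from pool membership; per-protein counts are
Poisson (mean 3, minimum 1), sampled with replacement.

Default (strong-signal) conditions: 300 cancer / 1200 noncancer proteins,
400 domain types, pool fractions 0.10 cancer-only / 0.21 shared (mirroring
the observed proportions of cancer-only and shared domain types in real
annotation universes), enrichment 4, p_cc = 0.02, p_cx = p_xx = 0.004.
This yields ≈5,000 edges, ≈900 of them C–C, and cleanly separable
classes. Benchmark studies hold out 20% of the cancer labels as an
independent all-positive test list.

The null condition (enrichment 1, all p equal) deserves its two odd-looking
numbers. Even with label-independent domain assignment the *method*
retains two finite-sample couplings: (i) an endpoint's own domain
instances are inside C(α), so DFS self-counts its edge — negligible only
when popularity variance dominates, which Zipf popularity provides at any
scale; (ii) a domain pair seen on a single C–C edge gets R ≫ 1 and
"remembers" its own training edge. The null therefore uses a small,
densely reused domain universe (8 types, so every pair's ratio
concentrates near 1) and a large network (3000 cancer / 6000 noncancer
proteins, p = 6.2·10⁻⁴ ≈ 2,800 C–C edges among ≈25,000), because the
variance of a rank AUC under the null is dominated by per-node
neighbourhood effects and scales like 1/√n_cancer. Under these
conditions all four feature AUCs sit within 0.5 ± 0.03 (measured on the
full edge set, ≥ 2,000 edges) and all classifier accuracies within
0.5 ± 0.05.

What passing on synthetic data does **not** show: the generator has no
degree heterogeneity (no hubs), no identifier noise, no incompleteness or
study bias in edge sampling, and its domain pools are cleanly partitioned
— real interactomes are messier on all four counts. Results on the
benchmark bound what the pipeline can do when its assumptions hold, not
what it will achieve on a real interactome.

## Problem sizes and runtime

The shipped study sizes — strong benchmark ≈1,800 balanced rows, null
≈5,500 balanced rows / 25,000 scored edges, B = 40 randomizations,
10-fold cross-validation of 13 classifiers — were chosen so a full
acceptance run completes in well under a minute on one CPU while keeping
every calibration band at ≥3σ of its estimator noise. All randomness
(generator, null ensemble, sampling, folds) fans out deterministically
from one master seed.

## Known limitations

* Feature computation for the frequency and linker-degree scores uses the
  training labels of the *whole* network; like the original formulation,
  scores of training edges are not label-blind (the hold-out study
  measures the effect honestly on unseen proteins, but edge-level CV
  metrics inherit it).
* The DDI ratio is undefined information-theoretically when the null
  floor engages; the floor keeps ordering sensible but its absolute scale
  is a convention.
* No identifier mapping, no live database access, no homology
  computation; these are inputs, not features, of the package.
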