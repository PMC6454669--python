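# Methods

This note records the model, the conventions chosen where the design was
genuinely open, what the synthetic benchmark does and does not emulate,
and the package's known limitations.

## Knowledge graph and PRA features

The KG is a set of deduplicated directed typed edges over opaque,
case-sensitive string entities.  Multi-edges collapse to one edge and
edges are unweighted: the one-step transition probability under a relation
is uniform over that relation's out-neighbours.  A node with no out-edge
of the requested relation is a dead end and contributes probability 0 —
walk mass is silently dropped rather than renormalised, so a path
distribution sums to at most 1.  This keeps "the walk cannot continue"
distinct from "the walk ends elsewhere", which the not-found conventions
downstream rely on.

Relation-path identity is by relation sequence only.  The canonical path
enumeration is length-major, then lexicographic by relation index in the
vocabulary order (first appearance in the edge file, or an explicit
sidecar).  Nothing in the model fixes a layout, but determinism is
required for a trained model to be reusable, so the layout is part of the
file contract.  Inverse relations are not added to the vocabulary: the
feature length identity L = Σ m^t assumes exactly the m declared relation
types.  Length-0 paths exist only as the recursion base case and are
never emitted as features.

`PathFeaturizer` caches all path distributions per source entity, which
makes candidate scoring (one drug against many targets) linear instead of
quadratic in practice; cached results are bit-identical to the direct
recursion, and both are checked against an independent walk-enumeration
oracle in the tests.

## The classifier

The concatenated feature vector (length 2L; 144 at the default synthetic
scale, 5512 at m = 52, l = 2) is treated as a single-channel 1-D signal.
Architecture and training settings:

| parameter | default | why |
|---|---|---|
| conv stages | 3 | reference configuration of the method |
| filters per stage | 128 | reference configuration |
| window size k | 3, stride 1, same padding | conventional; unspecified by the method |
| pooling | max, size 2, non-overlapping | conventional; "compresses" positions 2× per stage |
| attention units | 128 | reference configuration |
| dense units | 256 | reference configuration |
| batch size | 52 | reference configuration |
| max epochs | 12 | reference configuration; no early stopping |
| optimizer | Adam, lr 1e-3 | conventional default, exposed in config |
| loss | 2-way softmax cross-entropy | only gradient descent + backprop is prescribed |

The attention layer computes u_t = tanh(W_w h_t + b_w), weights
α_t ∝ exp(u_tᵀ u_s) and the summary s = Σ α_t h_t; u_s is a learned
vector, randomly initialised, since its origin is otherwise undefined.
α is a positive distribution, so s is always a coordinate-wise convex
combination of the pooled features — asserted in tests.  Setting
`use_attention=False` replaces α with uniform 1/T for the
attention-vs-averaging comparison.

Implementation is pure numpy: im2col convolutions as matrix products and
hand-derived backpropagation, verified against central-difference
numerical gradients at float64.  Everything stochastic (initialisation,
epoch shuffling) derives from the config seed; training is reproducible
bit for bit.

Numerical choices: He (fan-in, gain 2) normal initialisation for the
ReLU conv/dense layers — the PRA inputs are sparse probabilities with
mean ~3·10⁻³, and more conservative scales demonstrably leave the
network undertrained within the fixed 12-epoch budget; Xavier-scale
normals for the tanh attention and softmax head; logits computed in the
configured dtype but softmax/loss in float64; probabilities are clamped
only through the log's 1e-300 floor, and a non-finite loss aborts
training with the epoch index.  Inputs are used as-is: no rescaling or
standardisation precedes convolution.  Pooling truncates a trailing
remainder position; configurations whose pooling would leave zero
positions are rejected at construction with the offending stage named.

## Candidate scoring

Per candidate drug, cases with positive-class probability below 0.5 are
discarded first (the classifier judged them non-therapeutic); a drug with
no surviving case is *not found*, which is deliberately distinct from a
zero score.  The score is the arithmetic mean of the top ⌈η·n_kept⌉
surviving probabilities.  Reading the top-η selection as "mean over the
selected count" (rather than dividing by the fraction η itself) keeps the
score on the probability scale for every η; the alternative reading would
rescale scores by 1/η and change nothing about the induced ranking within
a fixed η.  η defaults to 0.2, the setting that performed best in the
method's sensitivity sweep; the sweep utility evaluates {5, 10, 20, 50,
100}%.  Ties receive fractional (mean-position) ranks, which makes mean
rank well defined and permutation invariant.

## Random-walk baseline

RW-k ignores relation types: P_ij = 1/d_i over relation-agnostic
out-neighbours, sink rows all zero (absorbing to nowhere, not self-loops,
so "not found" stays meaningful).  The t-step reach probability is
(P^t)_ij; the transfer rule is implemented in row convention, which is
what "probability that node i reaches node j in t steps" forces.  The
default drug score accumulates steps 1..k; per-step scoring is available
because step-wise values are sometimes reported.  The graph is used as
directed, without symmetrisation.  Matrix powers are checked against
brute-force walk enumeration and the Chapman–Kolmogorov identity.

## Evaluation protocols

Precision, recall and F-score follow the standard confusion-count
formulas; any 0/0 denominator yields 0 with a `degenerate` flag instead
of raising, so cross-validation aggregation never aborts.  Folds are
stratified (class proportions preserved) — plain random ten-way splits
can produce near-single-class folds at n = 400 — and seeded.  Rediscovery
reports mean rank and hit@10 (rank ≤ 10, fractional ties included) over
*found* known drugs only, with the not-found count reported separately;
when nothing is found both aggregates are flagged undefined rather than
zero.

The feature ablations replace nonzero entries with Uniform(0,1) draws
(seeded) or with 1, always preserving the zero pattern: they destroy the
walk-probability magnitudes while keeping the connectivity fingerprint.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical shape of a predication KG plus a
therapeutic gold standard: typed edges over drug / target / disease /
intermediate entities, treatment-indicative relation-path motifs, and
uniform background clutter.  For each planted positive (d, t, s) it
realises one signal path d→t (default motif R1,R2 through a random
intermediate) and one t→s (R3,R4); every planted edge independently
survives with probability 1 − noise (default noise 0.1).  Background
edges are uniform over (entity, relation, entity) at 8 expected edges per
entity.  Defaults: 120 drugs, 40 targets, 30 diseases, 100 intermediates,
m = 8 relation types, 200 positives, balanced negatives drawn uniformly
with rejection against the positives.  The rediscovery benchmark takes 10
diseases that have a planted drug, hides that drug among 99 decoy drugs
(100 candidates, matching the standard protocol) and provides a
candidate-target pool of 10 targets per disease containing the true ones.
120 drugs rather than a smaller pool is forced by the 100-candidate
protocol itself.

Deliberately not emulated: predicate semantics (relations are opaque
ids), entity-type constraints on background edges, degree heterogeneity
of real corpora, and textual ambiguity.  Background edges may complete a
signal path for a negative triplet probabilistically — that mirrors
real-KG label noise and is not prevented by construction.

**Consequences at desk scale.**  Because each length-2 leg consists of
two edges, a positive keeps both planted legs with probability
(1−0.1)⁴ ≈ 0.66 (≈ 0.74 after incidental rescue by background paths).
Positives that lost a leg are indistinguishable from negatives that
gained one, so no classifier can recover labels much beyond that bound:
classification F on the default bundle plateaus near 0.8, and rediscovery
hit@10 near 25–30% — which is in fact the regime corpus-scale studies of
this method report, not the near-perfect recovery a noise-free planted
benchmark would give.  Passing tests therefore demonstrate correct
mechanics and the right *relative* ordering (attention ≥ uniform
averaging, PRA ≥ randomised magnitudes, method ≥ random-walk baselines on
hit@10 and on mean rank for k ≥ 3), not corpus-scale absolute numbers.
Note one sharp edge of the found-only convention: RW-2 fails to find most
known drugs, and its mean rank — computed over the few easy cases it does
find — can look better than methods that find everything.

## Problem sizes used by the shipped checks

Oracle comparisons use 100 random graphs (≤ 50 edges, paths ≤ length 3;
≤ 30 edges, ≤ 4 steps for the walk baseline).  The ten-fold protocol runs
at full default scale (400 examples, full-size network).  The ablation
and attention-vs-averaging comparisons use stratified 2-fold splits per
seed across 5 seeds — with a from-scratch numpy network, 10-fold × modes ×
seeds would spend its runtime re-measuring the same direction — and the
rediscovery benchmark runs 5 seeds end to end.  These sizes are the
package's own choices and are printed by `scripts/acceptance.py` as the
`n` of each reported quantity.

## Known limitations

* PRA enumeration is exponential in path length; l > 3 on large
  vocabularies is impractical by design (no learned path pruning or
  bidirectional search is included).
* The classifier is CPU-bound numpy; it is sized for desk-scale feature
  lengths (≲ 10⁴), not corpus-scale embedding training.
* No per-path logistic-regression weighting from classic PRA, no
  restart-based heterogeneous-network walkers; those are different
  methods, cited as external comparisons only.
* Entity typing is carried by the triplet files, not enforced by the
  graph: a malformed gold standard (e.g. a disease used as a drug) is
  featurised without complaint.
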