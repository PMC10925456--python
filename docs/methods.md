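# Methods

`anchorscape` analyzes *anchor sets*: collections of evolved protein
genotypes with measured fitness, collected by segmented directed evolution
of a transcriptional repressor. The pipeline computes the assay statistics
that define fitness, quantifies epistasis among anchors, organizes them
into a relation graph, reconstructs the fitness landscape with a
rank-loss model, enumerates and ranks combinatorial designs, and reports
how strongly a handful of anchors compresses the theoretical design space.
A synthetic-data module simulates the whole data-generating process on
planted landscapes so every stage is testable end to end.

## Genotypes and fitness

Variants are site-consistent sets of amino-acid substitutions on a single
reference, written in the field's `S57R` notation (1-based residue sites;
no insertions or deletions). Fitness is fold repression: the ratio of
background-subtracted uninduced to induced fluorescence medians. All
assay statistics (`fold_repression`, `relative_expression`,
`circuit_score`, `resistance_index`, `fold_propagation`, the mammalian
mCherry:BFP ratio form) are deterministic arithmetic on medians; inputs
that would make a denominator nonpositive raise errors rather than being
clamped, because silent clamping hides gating problems upstream. The
"relative expression" statistic divides by the *raw* standard median
(no background subtraction) — a deliberate, slightly asymmetric reading
of the assay definition, flagged here because it is easy to "fix"
accidentally.

Replicate measurements of one genotype are combined by geometric mean:
fold changes are ratio-scaled, so averaging belongs on the log scale.
An arithmetic-mean option exists for sensitivity checks.

## Epistasis

For a background genotype g and disjoint mutation groups A and B,

    ε = f(g) + f(g∪A∪B) − f(g∪A) − f(g∪B)

computed on the raw fold-repression scale by default (a `log2` option
exists; on a planted additive+pairwise landscape the log2 scan returns
each planted interaction term exactly). Sign classification compares each
group's effect with and without the other: no sign change → *magnitude*
epistasis, one change → *sign*, both → *reciprocal sign*. Effects within
a caller-supplied absolute tolerance of zero count as sign-neutral, and
|ε| ≤ tolerance is classified as no epistasis; the default tolerance is 0,
appropriate for noiseless synthetic data — for measured data the caller
must supply a tolerance reflecting assay noise, since none is inherent in
the statistic. `enumerate_quadruples` automates query construction: it
emits every (g, A, B) decomposition whose four genotypes are all present
in the anchor set, deduplicated under A↔B exchange.

## Relation map

Distance between variants is the number of residues at which their full
sequences differ (equal to the Hamming distance of applied sequences for
substitution-only genotypes). The relation graph links genotypes at
distance 1..d; "fewer than 3 residues" is d = 2 and "fewer than 2" is
d = 1, the same code path. Evolution paths are simple paths with
non-decreasing mutation count (mutations accumulate under segmented
scanning; reversions are rare — the constraint is configurable off),
ordered by length then lexicographic label for determinism. Shared
high-fitness peaks are connected components of the subgraph above a
fitness threshold.

## Planted landscapes and the evolution simulator

`GroundTruthLandscape` assigns each genotype a log2 fold repression:
baseline b0 (default log2 5) plus additive per-mutation effects
(Normal(0.5, 0.3) log2 units by default) plus sparse pairwise interaction
terms. Interactions are planted on a Bernoulli(density) subset of
site-distinct candidate pairs; with probability `sign_flip_prob` a term
overrides the pair's additive sum (e = −(a_i+a_j) + |Normal(0, sd)|),
which produces sign and reciprocal-sign epistasis and — when both singles
are deleterious — crossable fitness valleys. The default structural scale
mirrors the benchmark anchor set: 8 segments, 39 sites, 52 candidate
substitutions on a ~220-residue reference.

The simulator is a Wright–Fisher-like loop per passage: a dilution
bottleneck (1:50 by default), Poisson mutation proposals on the surviving
lineages, then multinomial selection-resampling with weights
2^(β · min(L, b0+s)). Two deliberate departures from a bare resampling
model:

* **Selection strength β (default 4).** One passage is an overnight
  amplification — many phage generations — so per-passage selection is
  much sharper than a single generation of fitness-proportional sampling.
* **Selection saturation s (default 3 log2 units).** The transcriptional
  circuit coupling repressor function to phage propagation is monotone
  but bounded, so selection cannot distinguish variants above a ceiling;
  true fitness is unaffected, only the selection weights saturate.

The per-passage proposal rate defaults to 0.15 mutations/genome. This is
the mutation-limited regime consistent with the observed behaviour of
segmented scanning campaigns, where a dominant mutation emerges in a
minority of segment-passages rather than every passage; at rates near
0.5 the default 39-site landscape saturates within one campaign and any
scanning strategy trivially discovers nearly all sites. Plaque sampling
draws 2 random phage *individuals* per passage (duplicate genotypes
collapse), so rare transient mutants are observed in proportion to their
frequency, as plaque picking does.

Segmented scanning (`simulate_segment_scan`) restarts from wild type per
route and confines proposals to the route's active segment; the
global-competition baseline (`simulate_pance`) proposes over all
candidates in a single pool. The site-discovery contrast
(`site_discovery_contrast`) matches the two arms resource-for-resource:
8 routes × 500 phage × 8 passages versus one pool of 4000 phage × 8
passages with 16 plaque picks per passage — equal total population,
passages, proposals and observations, so the measured difference is
attributable to segmentation and parallelization alone. Under these
conditions the segmented arm discovers at least as many distinct mutated
sites in well over 80% of paired seeds (the paired-seed experiment in
`analysis/05_simulate_scanning.py` and the acceptance suite). The
mechanism: a single globally competing pool converges on the few
globally best mutations and then stops discovering (saturating
selection), while restarted segment-restricted routes keep every segment
in the selective sweep regime.

## The benchmark anchor set

`make_anchor_fixture` builds a deterministic 82-record anchor set with
exactly 52 distinct mutations at 39 sites and 68/82 (~83%) of variants
carrying more than 2 mutations. The reference sequence is synthetic: the
wild-type residue at every named site matches the letter implied by the
mutation label (D33, R43, S57, A75, I80, G83, C93, P94, D119, V188,
A199, G212), with remaining positions filled from a fixed seed. Fitness
values come from a small planted landscape whose interaction terms are
chosen so the qualitative sign relations hold on the raw fold-repression
scale: ε(D33E, S57R) < 0 in the wild-type background;
ε([S57R P94L], V188F) > 0; D33E × [P94L V188F] shows magnitude epistasis
and P94L × [G83V V188F A199S G212S] reciprocal-sign epistasis, both in
the S57R background; and every anchor is fitter than wild type
(fold repression 5). These values are synthetic stand-ins that encode the
benchmark's summary structure, not measured data. Wild type itself is not
an anchor; `fixture_with_wildtype` appends it for epistasis queries and
the relation map.

## Fitness model

Features are one-hot indicators over a candidate-mutation vocabulary
(`onehot`), optionally extended with one indicator per mutation *pair*
present (`onehot_pairs`) so pairwise epistasis is representable by a
linear scorer; an `external` mode accepts any provider mapping a variant
to a fixed-length embedding (for protein-language-model or structural
features — the repository ships no weights).

Training minimizes a soft rank loss — the mean pairwise logistic loss
over strictly-ordered target pairs,
L = mean log(1 + exp(−(s_i − s_j)/τ)) over pairs with t_i > t_j — with
full-batch Adam, exponential learning-rate decay, optional weight decay,
and best-validation-epoch selection. Targets are log2 fold repression;
because the loss depends only on score differences, shifting all targets
by a constant leaves the learned ranking unchanged (a tested invariant).
The default `ModelConfig` (one hidden layer of 32, lr 1e-3, decay
0.95/epoch, 50 epochs, τ = 1, fine-tune rates 1e-4 backbone / 5e-4 head)
is the standard recipe for an attached pre-trained backbone. For
desk-scale one-hot features on planted landscapes the package uses
`recovery_config`: a *linear* scoring head, τ = 0.02, weight decay 0.003
(raised to 0.03–0.1 for pair-augmented features, whose dimension exceeds
the sample count), lr 0.05 with 0.9995 decay, 3000 epochs. The sharp
temperature with light weight decay drives the pairwise logistic loss
toward its max-margin ranking limit, which is what noiseless linear
recoverability requires; the 50-epoch default underfits such features
badly and is not used for the recovery analyses.

Data splits follow a 59/7/16 train/validation/test partition of 82
records (rescaled proportionally for other set sizes).
`cross_validate` runs k-fold (default 10) selection over the 66-record
train+validation pool with the 16 test records excluded entirely — the
reconciliation of a fixed three-way split with k-fold hyperparameter
search. Evaluation is Spearman's ρ with average-rank ties (scipy).

Two experimental-design points, fixed before the fact by identifiability
arithmetic rather than tuned: (1) the pairs-vs-onehot comparison runs on
landscapes with 13 candidates at 11 sites, because with 82 anchors over
52 candidates a specific mutation pair appears in fewer than one training
anchor on average, so no estimator could learn pair terms at that scale;
(2) model comparisons are evaluated on a ~300-genotype fresh probe set
from the same landscape, because Spearman differences on a 16-item test
set are dominated by rank noise.

## Designs and compression

`enumerate_designs` traverses every combination of exactly k candidate
mutations with at most one per site (lexicographically ordered; wild
type appended when requested). For 13 candidates over 11 sites — two
sites carrying two alternatives — with k = 6 this yields 1092 variants,
1093 predictions with wild type. "Exactly k" rather than "up to k" is
the reading consistent with that count; so is the 2+2+9×1 site
multiplicity. `count_designs` cross-checks the enumeration with the
closed form: the coefficient of x^k in Π_s (1 + c_s x). Ranking uses the
trained model's scores, descending, ties broken lexicographically.

`compression_report` computes the theoretical design space
alphabet^sites in log10 (39 sites × log10 20 ≈ 50.7) and the ratio to
the anchor count (≈ 48.8 for 82 anchors), reporting floored exponents
(10^50, 10^48) to match order-of-magnitude conventions.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the real data — anchor
counts, mutation-number distribution, ratio-scaled fitness, sparse
pairwise epistasis with sign/reciprocal-sign cases, segment-restricted
route dynamics — but not its substance: real assay noise is not
lognormal-with-known-CV, real epistasis is not exactly pairwise, and the
published model's accuracy rests on pre-trained structural/language
embeddings that this package abstracts behind the provider interface.
Passing tests therefore certify that the pipeline's statistics,
enumerations and training recover planted truth under the stated
conditions; they do not certify performance on wet-lab data. Problem
sizes in the tests and acceptance analyses (82-anchor sets, 10–13
candidate vocabularies, 50 paired simulation seeds, 3000-epoch linear
trainings) were chosen so each experiment is decisive at desk scale.

## Known limitations

* No nucleotide-level representation: proposals act directly on amino
  acids, so codon accessibility and transition/transversion bias are out
  of scope.
* The simulator's selection model is phenomenological (β, saturation);
  it is calibrated to regime, not to titers.
* The rank-loss trainer is full-batch and CPU-bound; it is sized for
  10²–10³ anchors, not deep-mutational-scanning-scale data.
* Epistasis classification near the tolerance boundary is discontinuous
  by construction; callers comparing noisy replicates should pass an
  explicit tolerance.
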