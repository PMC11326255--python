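# Methods

## The prediction problem

Given a metabolite's chemical structure and a pathway's set of member
metabolites, decide whether the metabolite belongs to the pathway. The
package treats this as a single binary classification over *pairs*: the
Cartesian product of all metabolites with all pathways, labeled by
membership. The pairing serves two purposes: it multiplies the number of
positive examples (every pathway contributes its full member list), and it
lets one model score arbitrary new (metabolite, pathway) combinations
without retraining a per-pathway model zoo.

## Features

**Metabolite side — atom coloring.** A molfile (MDL V2000) is parsed into a
hydrogen-free element-labeled graph; bond orders 1/2/3 are kept verbatim and
aromatic bonds stay order 4 (no kekulization, so parsing needs no
aromaticity perception and is fully deterministic). Each atom then receives
one *color* per radius: at radius 0 the element symbol; at radius r the
element followed by the lexicographically sorted list of
`bond_order:neighbor-color-at-radius-(r−1)` terms. Sorting makes colors
canonical — featurization is invariant under any re-indexing of atoms, which
a property test checks with random permutations. An atom emits colors while
its bond-distance ball is still growing and stops when the ball saturates
(bounded by its component's diameter), so feature totals are finite and the
sum of radius-0 counts always equals the heavy-atom count. The feature
vector is the multiset of emitted colors; the corpus vocabulary maps each
color to a column, ordered lexicographically, with no frequency pruning.

**Pathway side.** A pathway's count vector is the element-wise sum of its
members' count vectors, with summed bond counts — the pathway is represented
by the pooled chemistry of its members. By default the sum includes every
member, including the query metabolite of a positive pair; see
*Limitations*.

**Normalization.** Entry-wise, each vector's non-zero counts are divided by
its bond count and passed through a softmax, so the non-zero outputs are in
(0, 1] and sum to one while zero entries stay zero (a dense softmax over the
full vocabulary would flatten all vectors toward uniform). The softmax is
computed with the standard max-shift for numerical stability; bond-less
single-atom entries use a divisor of 1. Feature-wise, min/max scaling maps
each training-split column onto [0, 1]; constant columns map to 0 and
out-of-range test values are clipped. Scaling is fit on the training rows of
each CV iteration only — fitting on everything would leak test statistics —
and the pipeline order is fixed: normalize entry-wise → cross join → split →
fit min/max on train → transform both halves.

## Model

One feed-forward network with ReLU hidden layers and a sigmoid output,
trained by seeded mini-batch Adam on binary cross-entropy over sparse
feature rows (single precision). Class imbalance is left to the cross-join
itself, which raises the positive rate to a workable level; no loss
re-weighting is applied by default. Defaults (desk scale, all overridable
via configuration or the seeded random hyperparameter search in
`pathpair.model.tune`):

| parameter | default | note |
| --- | --- | --- |
| hidden layers | (128,) | one layer suffices for the synthetic corpora |
| learning rate | 2·10⁻³ | Adam step size |
| batch size | 512 | larger batches amortize the dense gradient update |
| max epochs | 22 | past the observed convergence knee on the default corpus |
| early-stop patience | 0 (off) | see below |
| weight decay | 10⁻⁴ | L2 penalty |

Early stopping on validation MCC is implemented (patience > 0 holds out 10%
of the training rows, restores the best parameters, ties keep the latest
epoch) but disabled by default: on corpora of this size the validation MCC
estimate is noisy enough that restore-at-best systematically picks an
underfit epoch, while the fixed 22-epoch budget is both faster and more
reproducible. Training is deterministic given the seed; two runs with the
same configuration produce byte-identical predictions. Datasets larger than
memory stream from the HDF5 store in row blocks (blocks shuffled per epoch,
rows within a block in order).

## Evaluation protocol

Monte-Carlo cross-validation: each iteration draws a fresh stratified split
with 10% of the entries in the test set, stratum = (pathway, label) so each
pathway's positives and negatives are proportionally represented (a
label-only fallback exists for universes with tiny strata). Iteration *i*
uses seed `base_seed + i` for its split, scaling fit and model training.
Five metrics are recorded per iteration over all test entries — accuracy,
precision, recall, F1, MCC — plus the per-pathway confusion counts.
Zero-denominator MCC (and precision/recall/F1) is defined as 0, the
undefined-as-no-correlation convention, applied uniformly.

Per-pathway and per-level scores come from *summed* confusion matrices:
counts are added over all iterations (and over the pathways of a level)
before one MCC is computed. Summation avoids the per-iteration
division-by-zero that small pathways would otherwise cause; the price is
that summed scores have no standard deviation. The MCC numerator and
radicand are evaluated in exact integer arithmetic, so large summed
matrices cannot overflow.

Two size analyses quantify the size–performance relationship, with pathway
size measured both as member count and as total non-hydrogen atoms:
(1) correlation of overall pathway MCC with size — Spearman on the regular
scale and Pearson on log₁₀(size), asymptotic p-values, no multiple-testing
correction; (2) threshold curves — the overall MCC of the pathways at or
above each size threshold, either filtering only the MCC computation
(threshold 0 reproduces the global MCC) or, in the training sweep,
rebuilding the training universe itself and always scoring the same fixed
evaluation pathways so thresholds are comparable.

Results persist to a single SQLite file (tables `iteration_metrics`,
`pathway_counts`, `pathway_scores`, `correlations`, `threshold_curve`,
`sweep`, `provenance`), with TSV exports and PNG figures. Runs write a
manifest (config digest, seeds, package version) sufficient to reproduce
them exactly; dataset HDF5 files are written without timestamps so a
rebuild is byte-identical.

## Synthetic data

The generator emulates the statistical shape of a curated pathway
knowledgebase at desk scale. Molecules are random connected graphs: a
uniform spanning tree over 3–5 heavy atoms sampled from a weighted alphabet
(C 0.70, N 0.12, O 0.12, S 0.04, P 0.02), occasional extra edges
(probability 0.10 per atom), bond orders weighted 0.80/0.15/0.03/0.02 for
single/double/triple/aromatic. The 20 L3 pathways partition the 500
metabolites with truncated log-normal sizes (median parameter 25, σ 0.7,
minimum 3, rescaled to sum to the pool), and 4 L2 categories are disjoint
round-robin unions of L3 pathways whose members they inherit — mirroring a
category/pathway hierarchy. Molecule and pool sizes were chosen so the full
recovery experiment runs in minutes on one CPU; they sit at the small end of
real metabolite sizes.

The planted signal has two parts, both carried by a member metabolite with
probability `signal_strength`: a pathway-specific *motif* — a 3-atom
element-and-bond-order labeled path appended to the skeleton — and a
pathway-specific *composition bias* (a distinct ordered pair of elements
whose sampling weights are multiplied by 6 and 3). Motifs are chosen
rarest-first under the background distribution and deduplicated by their
canonical middle-atom color, so every pathway's motif is a substructure no
other pathway produces and background skeletons essentially never form.
The composition bias exists because a motif alone is a pure
feature-interaction signal (membership correlates with *metabolite-motif ×
pathway-identity*, with no marginal effect), which gradient descent
discovers very slowly; the bias mirrors how real pathway categories differ
in elemental makeup (nitrogen-rich nucleotide pathways, carbon-rich lipid
pathways) and gives the optimizer a dense first-order cue. With
`size_dependent_signal` the carry probability scales with pathway size rank
(0.1 to 1.0), reproducing the size–performance correlation qualitatively.
Generation is driven by one seeded generator: identical config and seed
give a byte-identical corpus.

What the generator does *not* emulate: chemical valence rules, realistic
ring systems, overlapping pathway membership (each synthetic metabolite
belongs to exactly one L3 pathway and its parent), or the true KEGG-scale
feature dimensionality (~14k metabolite columns). Passing the recovery
tests therefore shows the pipeline is correct and can learn planted
chemical structure; it does not certify real-data performance levels.

## Numerical and design choices

- Bond order 4 (aromatic) is a first-class order; no kekulization or
  aromaticity perception anywhere.
- Charges, isotopes and stereo flags in molfiles are ignored; disconnected
  components are kept as one graph; V3000 input is rejected explicitly.
- Size-threshold semantics are inclusive (≥ threshold).
- Softmax divide-then-normalize reading: counts are divided by the bond
  count *before* exponentiation; the function is isolated so the
  alternative reading could be swapped in one place.
- Ties in hyperparameter search resolve to the earliest trial; ties in
  early-stopping validation keep the latest parameters.
- The `fetch` CLI command only documents the external data contract (a
  molfile directory plus a pathway/level/metabolite TSV); no network code.

## Limitations

**The pathway features encode membership.** Because a pathway's vector is
the sum of its members' fingerprints, a classifier can notice that a
metabolite's own — often distinctive — colors are contained in a pathway's
vector, without using any shared chemistry. On a null corpus with zero
planted signal, the bare containment rule reaches AUC ≈ 0.9 at this scale
and the MLP attains held-out MCC ≈ 0.36; held-out scores of the default
pipeline are therefore optimistically biased wherever molecules are
distinctive, and a zero-signal control does **not** score near zero. The
leave-one-out variant (`build_dataset(exclude_query_metabolite=True)`)
subtracts the query metabolite from its positive pairs' pathway sums, but
the resulting per-pair perturbation is itself label-correlated and performs
equivalently; a fully leak-free protocol would have to rebuild pathway
vectors per CV split from training members only, which breaks the fixed
build-once pipeline order and is out of scope here. Interpret absolute
held-out scores accordingly; comparisons between configurations on the same
corpus remain meaningful.

**Other limitations.** The exact radius schedule of the circular
substructure features is this package's deterministic reading (per-atom
emission while the neighborhood ball grows); hyperparameters are desk-scale
defaults, not tuned replicas of any published configuration; stratified
splitting requires every (pathway, label) stratum to hold at least two
entries, so singleton strata need the label-only fallback.
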