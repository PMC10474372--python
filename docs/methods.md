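# Methods

## Model

The predictor is a two-branch network. The cell-line branch is a visible
neural network (VNN) whose topology is compiled from a gene-annotated
ontology: each term owns `k` neurons (default 6), genes feed only the terms
they are annotated to, and a term's neurons receive input only from its
children's neurons. Each layer computes `O(s) = tanh(W(s) I(s) + b(s))` with
`W(s)` stored in CSR form so that off-pattern weights are not parameters;
gradient masking therefore holds by construction rather than by post-hoc
zeroing. The drug branch is a dense tanh network over a hashed circular
(Morgan, radius 2) fingerprint of 2048 bits. The branch outputs are
concatenated, passed through one hidden fusion layer, and read out by a
single linear neuron predicting the normalized area under the dose-response
curve (AUDRC; 0 = complete death, 1 = no effect, > 1 = growth advantage).

Two published layer presets are preserved: the mutation preset (drug branch
100/50/6, VNN output 6, fusion 6) and the expression preset (drug branch
200/100/50, VNN output 30, fusion 40), both with `k = 6`.

Normalization comes in two variants. "post" places batch normalization after
each activation; "ic" places a batch-normalization + dropout block
(independent-component layer, dropout rate 0.15) before each weight layer.
Normalization statistics are per neuron over the batch; evaluation uses
running statistics. Virtual-node connections are ordinary trainable sparse
connections; an identity-freeze option exists for ablation.

## Ontology compilation

Pruning keeps a term only if it has at least `min_genes` (default 5)
annotated genes and, when it has children, at least
`min_distinct_from_children` (default 10) genes not annotated to any child;
the hierarchy is limited to `max_depth` (default 8) subsystem levels above
the bottom. A deleted term's genes and children are reassigned to *all* of
its parents (the ontology is a DAG; the deletion rule would otherwise be
ambiguous). Terms are evaluated bottom-up and the procedure iterates to a
fixpoint, because deletions push genes upward and can change a parent's
distinct-gene count; the depth limit is enforced with the same deletion
rule, deepest terms first. The root is never deleted, and pruning never
drops a gene (only reassigns it).

Layer assignment gives each term `1 +` the longest term-path to a bottom
term below it. An edge spanning `d > 1` layers receives `d − 1` pass-through
virtual nodes (chains are shared among parents of the same child); a gene
annotated to a term at layer `L > 1` is routed through `L − 1` gene-carrying
virtual nodes so the first-layer equation literally consumes the gene
vector. Node order is lexicographic with virtual nodes last, purely for
bit-identical reproducibility of the masks.

## Dose-response standardization

`audrc_trapezoid` (AUDRC1) integrates viability over log10 concentration
across the experiment's own range; `audrc_standardized` (AUDRC2) first fits
the four-parameter logistic `v(x) = lower + (upper − lower)/(1 + (x/EC50)^h)`
by bounded least squares in log-concentration space and then integrates the
fitted curve over a standardized 100 pM to 100 µM window by adaptive
quadrature. Both areas are divided by the log10 window width; that
normalization is what pins the scale anchors (flat control curve → exactly
1, flat zero-viability curve → exactly 0) and makes AUDRC2 independent of
the raw experiment's dose range. Integration over log concentration is the
dose-response convention; the anchors force the normalized reading.

Numerical choices: initialization takes the asymptotes from the extreme-dose
means, EC50 from the dose nearest half-range, slope 1; slope is bounded to
[−50, 50] and the asymptotes to the data range ± twice its span. Constant
viability, a single distinct dose after filtering, or optimizer failure
produce an explicit `fallback-constant` parameter set at the mean viability
rather than a spurious sigmoid. If the optimizer lands in the mirrored
parameterization (`upper < lower`) the curve is reparameterized by swapping
asymptotes and negating the slope, which leaves the function unchanged.
Viabilities are never clamped: values above 1 are biologically meaningful.

## Training

Loss is the mean squared error between measured and predicted AUDRC,
minimized by gradient descent with momentum 0.9. Published-scale defaults
are kept in `TrainConfig` (learning rate 0.1, weight decay 2e-3, 400 epochs,
batch 20 000); the batch size auto-clamps to the dataset. Weight decay is
applied to weight matrices only, not to biases or normalization parameters
(configurable). A validation subset (default 10% of the training pairs,
whole units under the unit-respecting fold schemes) is monitored each epoch
and the best-validation parameter state is restored. A NaN/inf loss aborts
with a diagnostic instead of silently continuing.

At package test scale (the planted cohort below) the training recipe is
scaled down accordingly: ~4.6k parameters (`k = 3`, drug branch (2,), VNN
output 6, fusion 8), 200 epochs of batch-128 SGD at learning rate 0.05 with
weight decay 2e-4. The smaller decay matters: at this parameter count the
published decay rate keeps the fusion layer in its near-linear regime, where
the optimizer settles for an additive cell + drug solution and never learns
the drug-specific routing that the attribution stage depends on.

## Attribution

DeepLIFT multipliers are backpropagated from the scalar output: the linear
rule through dense, sparse and evaluation-mode batch-normalization layers
(the latter folds to an affine map using running statistics), the Rescale
rule through tanh with a gradient fallback when the input difference is
below 1e-9 (avoiding 0/0), dropout inactive. The reference activation is the
per-gene median of the cell feature matrix and the fingerprint of glucose on
the drug side. Contributions satisfy summation-to-delta at every layer cut
(checked to 1e-6 in the tests), vanish identically when the input equals the
reference, and reduce exactly to gradient × (input − reference) for affine
networks. Drug-bit scores are computed and stored but not interpreted:
hashed fingerprint bits have no stable substructure meaning. For the
mutation modality the "median cell" reference is a modeling choice, not a
given; an all-zeros (wild-type) reference is equally defensible and both are
accepted.

## Mechanism-of-action classifiers

Per drug, neuron scores are summed over cell lines, giving `k` features per
term (6 under the default); each (term, neuron) column is divided by its
population standard deviation across drugs (zero-spread columns are left
unscaled and flagged). Labels come from a drug → term annotation table
closed upward (a drug annotated to a term is annotated to all ancestors);
drugs with no annotation are *unknown* and excluded from SVM training.
Virtual nodes contribute no features — they are bookkeeping, not terms.

For every term with at least 16 positively annotated drugs, RBF-kernel SVMs
are trained per fold of a 4-fold drug-level split on that term's own `k`
columns, with `C = 1`, `γ = 1/(n_features × variance)` (variance pooled over
the whole feature matrix by default; per-term recomputation is available)
and class weights inversely proportional to class frequencies. Probabilities
are Platt-scaled (sigmoid calibration fitted by internal cross-fitting on
the training fold, via scikit-learn's calibration wrapper). Annotated drugs
receive out-of-fold probabilities; unknown drugs receive the mean over the
fold models. A fold whose training labels contain a class with fewer than
two members is skipped and flagged. AUROC is reported per term (across
drugs) and per drug (across terms, with a confusion matrix at probability
0.5); it equals the Mann–Whitney pairwise concordance by definition, which
the tests verify by brute force. The logit-difference ranking
`logit(p) − logit(label)` clips labels to {1e-3, 1 − 1e-3} since the logit
of a hard 0/1 diverges; the default report keeps the top 30 terms.

## Synthetic fixtures

The generator emulates the *structure* of a pooled drug screen, not its
distributions. Ontologies are single-rooted trees of chosen depth and
branching; a configurable fraction of deep edges is rewired to a strictly
higher ancestor to exercise virtual-node insertion. Cell features are i.i.d.
Gamma(2, 1) per gene (nonnegative, expression-like). Fixture "fingerprints"
are unique random 2048-bit vectors: a drug-identity signal, deliberately not
chemistry, so recovery tests do not depend on RDKit hashing. Each responsive
drug acts through one planted causal term: its response is
`1 − effect × sigmoid(z)` plus Gaussian noise, where `z` is the
cohort-standardized mean feature of the causal term's genes — standardized
because the raw mean of nonnegative features sits in the sigmoid's saturated
tail and would carry no between-cell signal. Non-responsive pairs are
`1 + noise`, and responsive drugs are annotated to their causal term.

Default cohort conditions: 200 cell lines, 40 drugs of which 36 are
responsive through 2 causal terms (18 each, satisfying the ≥ 16-drug SVM
filter with both positive and negative labeled drugs per term), effect size
0.8, noise SD 0.05, over a depth-3, branching-2 ontology with 5 genes per
bottom term. Dose-response fixtures are sampled from known 4PL parameters
over 10 log-spaced doses in the standardized window, with the exact
ground-truth AUDRC2 recorded by quadrature.

What passing the planted-recovery tests shows: the full pipeline — sparse
compilation, masked training, attribution, per-term SVMs — can recover a
mechanism that is genuinely present in the data at realistic noise. What it
does not show: performance on real screens, where fingerprints carry shared
chemistry, expression is correlated across genes and pathways overlap, and
response heterogeneity is far richer than one sigmoid per drug.

## Known limitations

- Dense-matrix gradient accumulation inside the sparse layers (an
  `(out × in)` outer product restricted to the mask afterwards) is simple
  and exact but would be memory-hostile at genome scale; a production run at
  the published scale would accumulate per-nonzero products directly.
- Batch normalization uses running statistics during single-sample training
  batches, so a batch size of 1 trains without normalization updates.
- The 4PL fitter assumes a single sigmoidal transition; biphasic curves get
  the best single-sigmoid approximation, not a warning.
- `evaluation` reports the pooled correlation across test folds (per-fold
  values are also available); pooled and averaged per-fold values differ
  slightly whenever folds have unequal variance.
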