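# Methods

## Problem and sample formalism

A candidate 5mC site is a cytosine in a promoter sequence together with its
flanking context: the window `E₋δ … E₋₁ C E₊₁ … E₊δ` of length `L = 2δ+1`.
The default half-window δ = 20 gives 41-nt samples. Candidates reported on
the reverse strand appear as G in the forward reference; they are
reverse-complemented before encoding so that every sample is C-centred,
while coordinates in all outputs refer to the original input sequence
(0-based in the API and BED, with BED intervals half-open).

Edge candidates whose window would overhang the sequence are skipped by
default; an optional `pad_n` mode fills the overhang with N instead.
Windows containing N are excluded from training but scored at prediction
time (N encodes as all-zero one-hot and property bits) and flagged in the
TSV output, so prediction degrades gracefully on ambiguous sequence.

## Encodings

* **one-hot** — 4 indicator values per position, N → zeros.
* **dpf** — per position the chemical-property triple and the cumulative
  frequency: x_k = 1 iff the base is a purine (A/G), y_k = 1 iff it carries
  an amino group (A/C), z_k = 1 iff it pairs by two hydrogen bonds (A/T);
  λ_k is the count of the position's own base over the prefix 1..k divided
  by k (so λ_1 = 1 always, and λ_k·k is an exact integer count — the test
  suite checks this against brute force). The denominator is the position
  index k, not the full window length: λ is the running density of the base
  up to that position. N positions get properties (0,0,0) and λ counting
  literal N matches.
* **fused** — one-hot followed by dpf (8L values). The concatenation order
  is fixed for reproducibility.

No standardisation is applied; all features are already in [0, 1].

## Ensemble and fusion

With ≈11 negatives per positive, a single classifier trained on the raw
class ratio mostly learns the prior. Instead the negatives of the training
set are randomly partitioned into k groups of near-equal size (k defaults to
11, matching the imbalance ratio, and is configurable); each group is paired
with **all** positives, the larger side is down-sampled at random so the
subset is exactly 1:1, and one sub-model is trained per subset. Every
training negative is therefore seen by exactly one sub-model and every
positive by all of them.

Sub-models are scikit-learn `MLPClassifier` networks with hidden layers
64-128-256-128-64, ReLU activations and a logistic output whose activation
is the positive-class probability. A single logistic output unit is used
rather than a two-unit sigmoid head: for binary classification the two
parameterisations yield the same score, and the single-unit form is the
native one for the backend. Regularisation is an L2 penalty (alpha = 1e-4)
plus early stopping on an internal 10% validation split (patience 10
epochs); the `dropout_rate` config field (default 0.3) is recorded in model
manifests for provenance but the backend does not insert dropout layers.
Remaining optimisation choices, none of which are structural: Adam with
learning rate 1e-3, batch size 256 (clipped to the training-portion size on
small subsets), at most 50 epochs.

Decision fusion is **strict unanimity**: a site is called methylated only
if every sub-model's probability exceeds the threshold (default 0.5). The
fused positive set is the intersection of the sub-model positive sets, so
the fused specificity is provably at least every sub-model's specificity on
any fixed test set — the characteristic Sp gain of the design, asserted as
a property test. A majority rule is available as an alternative. For ROC
curves a continuous fused score is needed; the default is the **minimum**
of the k probabilities, chosen because thresholding the minimum at t is
exactly the unanimous decision at t (verified exhaustively in the tests).
The mean is available as an alternative score fusion.

All randomness — negative partition, down-sampling, weight initialisation,
shuffling, fold assignment — fans out from one master seed through
`numpy.random.SeedSequence`, so a fixed seed reproduces training and
evaluation bit-identically on one CPU. Prediction on the same batch is
bit-identical across runs; scores for the same window embedded in
differently ordered batches can differ at the last-ulp level from BLAS
accumulation order, so cross-batch comparisons are asserted at 1e-9.

## Evaluation

Confusion counts are kept in the (N⁺, N⁻, false-negatives, false-positives)
form, with Sn = 1 − FN/N⁺, Sp = 1 − FP/N⁻, Acc the complement of the
overall error rate, and MCC the standard Matthews correlation — equal to
the Pearson correlation of the binary label/prediction vectors, which the
tests use as an independent oracle. When the MCC denominator vanishes
(e.g. a constant prediction vector, which the unanimous rule produces under
the null model) MCC is defined as 0 with a warning. AUC is the trapezoidal
area under the ROC curve computed at every distinct score threshold; it
equals the Mann–Whitney pair statistic with ties counted ½ (also asserted
against exhaustive pair counting). Cross-validation reports macro-averages
over folds then over repeats; the counts in a CV report are pooled totals
over all evaluated folds.

Stratified splitting rounds each class's train count to the nearest integer
(`floor(f·n + 0.5)`); with an 80/20 split this reproduces the published
benchmark's class-wise split counts exactly.

## Synthetic data

The generator emulates the *shape* of an RRBS-derived promoter benchmark:
C-centred windows of length 2δ+1 at a configurable class ratio (defaults
target 1:11). Negatives are i.i.d. draws from a background with GC fraction
`gc_background` (default 0.5). Positives additionally draw the
`motif_width` positions straddling the centre (default 8, the centre itself
is never altered) from the mixture `(1−effect)·background + effect·consensus`,
where the consensus alternates G and C so that planted positives are
CpG-dense through the central cytosine — the dinucleotide-level signal
expected around methylated promoter CpGs. `effect = 0` makes the classes
exchangeable (a null model for calibration checks); `effect = 0.9` plants a
strongly learnable signal. Held-out AUC is non-decreasing in `effect`
(property-tested at 0, 0.3, 0.6, 0.9).

What the generator does **not** emulate: genomic positional structure,
CD-HIT-style sequence redundancy, methylation levels, read-level RRBS noise,
or promoter GC richness (unless configured). Tests passing on synthetic
data therefore demonstrate that the pipeline is correct and that the
ensemble learns a planted sequence signal at the stated imbalance — not
that any particular accuracy will transfer to a real benchmark.

## Problem sizes used in checks

The heavyweight checks run the full pipeline at n_pos = 500, n_neg = 5,500,
δ = 20, k = 11 with 5-fold cross-validation — large enough that per-fold
test sets hold 100 positives and the null-model AUC concentrates near 0.5,
while a full run completes in well under a minute. The reproducibility
check runs synth → train → evaluate twice at n_pos = 120, n_neg = 1,320 and
compares bytes.

## Known limitations

* Sub-models have no dropout; regularisation behaviour may differ from a
  dropout-trained network of the same architecture.
* Model bundles are joblib-serialised scikit-learn estimators: portable
  across runs of the same environment, not across major scikit-learn
  versions (the bundle manifest records versions and loading fails loudly).
* The scanner scores every eligible candidate independently; it does not
  aggregate evidence across neighbouring CpGs.
* Training on datasets approaching the published benchmark's size (~900k
  windows) is possible but memory- and time-intensive with the default
  dense encodings; the package is tuned for the 10³–10⁵ window range.
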