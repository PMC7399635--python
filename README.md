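# promoter5mc

Prediction of 5-methylcytosine (5mC) sites in promoter DNA sequences.

Promoter CpG-island hypermethylation silences tumor-suppressor genes, so
mapping which cytosines in a promoter are methylated is a recurring task in
cancer epigenomics. Assays such as RRBS label individual cytosines as
methylated or not, but genome-scale wet-lab profiling is expensive; this
package provides a sequence-based classifier that, given only the 41-nt
window around a candidate cytosine, predicts whether it is a 5mC site. It is
aimed at bioinformaticians who have (or can construct) a labeled table of
candidate windows and want a reproducible train/evaluate/scan pipeline.

## Method

Each candidate site is the window `E₋δ … E₋₁ C E₊₁ … E₊δ` of length
`L = 2δ + 1` (default δ = 20, L = 41) centred on a cytosine. Sites described
as G on the reverse strand are reverse-complemented first, so every window is
C-centred. Windows are encoded as:

- **one-hot** (4L values): A→[1,0,0,0], C→[0,1,0,0], G→[0,0,1,0], T→[0,0,0,1];
- **dpf** (4L values): per position the chemical-property triple
  (ring structure x_k = 1 for purines A/G; functional group y_k = 1 for the
  amino bases A/C; hydrogen bond z_k = 1 for the weakly paired A/T) plus the
  cumulative frequency λ_k = (count of the position's base in positions
  1..k)/k;
- **fused** (8L values): one-hot followed by dpf.

Methylation labels are heavily imbalanced (≈1 positive : 11 negatives), so
the classifier is a **down-sampling ensemble**: the negatives are randomly
partitioned into k = 11 equal groups, each group is combined with the
positives (the larger side down-sampled so the subset is exactly balanced),
and one fully connected neural network (hidden layers 64-128-256-128-64,
ReLU) is trained per subset. A query is called methylated only when **all
k sub-models** vote positive at the 0.5 threshold — a strict unanimity rule
that pushes specificity up at some cost in sensitivity. For ranking/ROC the
k probabilities are fused into one score, by default their minimum, which is
exactly threshold-equivalent to the unanimous rule. Performance is reported
as Sn, Sp, Acc, MCC and AUC under repeated stratified k-fold
cross-validation.

## Worked example

Everything is driven by one master seed, so each step below reproduces
byte-identically. Generate a synthetic benchmark (200 positives, 2,200
negatives, strong planted CpG-motif signal), train the 11-sub-model
ensemble on one-hot features, and evaluate it:

```sh
promoter5mc synth --n-pos 200 --n-neg 2200 --delta 20 --effect 0.9 --seed 7 --out data
promoter5mc train data/samples.tsv --encoding onehot --delta 20 --k 11 --seed 7 --out model
promoter5mc evaluate model data/samples.tsv --out report.json
```

The report's fused row (training-set evaluation of this small run):

```
fused: {'n_pos': 200, 'n_neg': 2200, 'false_neg': 12, 'false_pos': 2,
        'sn': 0.94, 'sp': 0.9991, 'acc': 0.9942, 'mcc': 0.9613, 'auc': 0.9993}
submodel Sp range: 0.8677 - 0.9773
```

Each sub-model alone has specificity 0.87–0.98; the unanimous fusion lifts
it to 0.999 because a false positive must fool all eleven sub-models at
once, while sensitivity drops only to 0.94. That specificity gain is the
point of the design: with 11 negatives per positive, false positives
dominate the error budget.

Scanning a promoter FASTA calls every eligible C (or G with `--strand -`):

```sh
promoter5mc predict model promoter.fa --strand + --out calls
head -3 calls/calls.tsv
```

```
sequence        position  strand  fused_score  call  contains_n
promoter_demo   22        +       0.000014     0     0
promoter_demo   23        +       0.000000     0     0
```

`calls/calls.bed` holds the same sites as BED6 with the fused score scaled
to 0–1000; coordinates always refer to the input sequence.

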