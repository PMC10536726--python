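# Methods

## Problem setting

An outpatient claim is one patient encounter: one to three ICD-10 diagnoses,
one or more CPT/HCPCS procedure lines, patient age and gender. Procedure-code
overutilization is the presence of procedures that do not belong with the
claim's diagnoses, other procedures, and demographics. No labels exist at
scale, so detection is framed as unsupervised anomaly detection over claims:
learn what normal procedure/diagnosis/demographic combinations look like and
flag claims containing procedures the model cannot reconcile with their
context. Provider identity, specialty, geography and billed amounts are
deliberately excluded from the feature set so the model generalizes across
providers rather than memorizing their habits.

## Feature encoding

Claims are encoded as fixed-length binary vectors with block layout
`[CPT | ICD category | age (5) | gender (3)]`:

- Diagnoses are truncated to the 3-character ICD-10 general category, which
  trims the sparsity of the diagnosis space while keeping clinical meaning.
- Age is bucketed into five bands — under 18, 18–38, 39–59, 60–80, 81+ —
  implemented as the half-open partition [0,18), [18,39), [39,60), [60,81),
  [81,∞), which is contiguous and exhaustive.
- Gender is one-hot over (male, female, other).
- CPT codes occurring in fewer than `min_claims` *distinct claims* (not claim
  lines) are dropped from the vocabulary, so a model can never flag a
  procedure merely for being rare. The reference value for 100k-claim-scale
  data is 100; desk-scale synthetic corpora use 5 by default, roughly
  preserving the filtered tail fraction.
- Codes are sorted lexicographically for deterministic dimension assignment,
  and the encoder spec (vocabulary lists, block layout, `min_claims`) is
  serialized to JSON so train-time and score-time encodings are bit-identical.
- Repeated units of one procedure collapse to a single active bit; unit
  counts are out of scope.

The vocabulary may also contain *reserved* codes exempt from the rarity
filter. They hold feature dimensions that remain all-zero through training —
the structural device that lets held-out test sets contain procedure codes
the model has never seen while keeping train and test vectors the same
length.

## Autoencoder and the feature-weighted loss

The network is a symmetric funnel with seven hidden layers: three ReLU
encoder layers, a ReLU bottleneck, three mirrored ReLU decoder layers, and a
sigmoid output at input width, so each output is the reconstruction
probability of one binary feature. Hidden widths follow a geometric taper:
the first layer is the largest power of two not exceeding half the input
width, halved twice more, with the bottleneck at min(128, half the innermost
encoder width). At input width 4835 this gives (2048, 1024, 512) with
bottleneck 128; at the desk-scale benchmark's input width (~450 after
filtering) it gives (128, 64, 32) with bottleneck 16.

Sparse multi-hot targets make plain BCE degenerate: with so few ones per
vector, always predicting zeros already yields a small loss. The
feature-weighted BCE down-weights the zero-target terms by w ∈ (0, 1]:

    fwBCE = -(1/N) Σ_i Σ_j [ y_ij log ŷ_ij + w (1 - y_ij) log(1 - ŷ_ij) ]

Two normalization details matter. The loss divides by the batch size N only —
the per-claim loss is a sum over all M feature dimensions, not a per-element
mean, so reported loss values scale with M. And probabilities are clipped to
[ε, 1−ε] with ε = 1e-7 inside the logs for numerical safety; the backward
pass zeroes the gradient where the clip is active, keeping the analytic
gradient consistent with the implemented loss (validated against central
finite differences in the tests; the check jitters biases off zero first so
no ReLU preactivation sits exactly on the kink).

The w sweep in the acceptance suite reproduces both failure modes at the
ends of the scale: at w = 1 (plain BCE) reconstructions collapse toward all
zeros — held-out mean reconstruction at active procedure dimensions falls
below 0.5 — while at w near 0 the zero-target dimensions drift high toward
all ones. Both means are monotone decreasing in w. The default w = 0.05 sits
in the healthy middle regime (active dimensions reconstruct high, inactive
low) and is the key tuning knob; it is exposed in every config surface.

Training uses Adam (lr 1e-3, β = 0.9/0.999), batch size 256, a 10%
validation split, early stopping on validation fwBCE with patience 10, and
restores the best-validation checkpoint. All stochastic stages (weight
initialization, shuffling, the split) are seeded. The implementation is
plain NumPy — forward pass, analytic backpropagation, Adam — which at these
problem sizes trains the full benchmark model in well under a minute on one
CPU.

## Scoring and evaluation

The model infers a probability per procedure code on a claim (the
reconstruction probability at that code's dimension; near one = fits the
context, near zero = outlier). Per-claim aggregation uses
`1 − min(per-code probability)` by default: the claim scores as its most
anomalous procedure, the natural reduction for "at least one code is an
outlier". `1 − mean` and `1 − product` are selectable for sensitivity
analysis, since the aggregation function is the one genuinely open design
point of the evaluation protocol.

Claim scores are binarized at each of the 21 thresholds 0.00–1.00 (step
0.05; score ≥ threshold → outlier), and precision, recall and F1 are
computed with outliers as the positive class. Metrics are reported at the
max-F1 threshold; ties break toward the lower threshold, privileging recall,
because in post-payment review a false negative is a missed overutilization
while a false positive only costs reviewer time. Zero denominators yield 0
with a flag rather than an error, keeping sweeps total.

Model pairs are compared with McNemar's test on the discordance table of
best-threshold predictions: b = claims model A gets right and B wrong, c the
reverse. The reported statistic is the continuity-corrected chi-square
(|b−c|−1)²/(b+c); the p-value uses the exact binomial distribution when
b + c < 25 and the chi-square reference otherwise.

### DBSCAN baseline

DBSCAN clusters the binary vectors; noise points (cluster label −1) are its
outlier predictions. On binary data the Euclidean metric is the square root
of the Hamming distance, making eps interpretable as bit-difference radius;
Jaccard is selectable. Since no reference hyper-parameters exist for this
data, (eps, min_samples) are grid-tuned on a labeled validation split
maximizing F1 — a deliberately generous treatment of the baseline. Per-code
attribution is not defined for DBSCAN; it scores whole claims only.

## Synthetic claims generator

The generator emulates the structure of outpatient claims data rather than
any real dataset:

- Each diagnosis category owns a pool of 8–16 procedure codes drawn
  Zipf-weighted from the non-reserved codes (popular codes recur across
  pools, as common procedures do across specialties).
- Diagnosis marginals and procedure weights follow a Zipf law with exponent
  1.1, giving the long-tailed code-frequency distribution of claims data.
- A claim draws 1–3 diagnoses, then 1–6 procedures Zipf-weighted from the
  union of its diagnoses' pools; age bucket and gender come from
  Dirichlet-drawn conditionals of the primary diagnosis, so demographics
  carry diagnosis information the model can exploit.
- Reserved codes (20 of 400 by default) belong to no pool and never appear
  in normal claims.

Test sets are built by injection: exactly round(fraction × n) claims receive
added codes (half one code, half two; an odd count gives the extra claim
one). `out_of_sample` mode injects reserved codes — outliers the training
data has literally never exhibited, at fraction 0.27 by default (0.20 being
the reference large-scale variant). `context_mismatch` mode injects
in-vocabulary codes foreign to all of the claim's own diagnosis pools, at
fraction 0.30 — a stand-in for human-annotated overutilization, which is
harder because the injected codes were seen during training, just never in
this context. Injection only ever adds codes; a claim is labeled an outlier
iff it was injected. Injected codes are drawn uniformly from the eligible
set without regard to demographic plausibility.

What passing on this generator does *not* show: real claims have correlated
comorbidities, provider-level coding habits, temporal drift, and annotator
judgment about unit counts and clinical necessity — none of which are
modeled. The out-of-sample benchmark in particular is an idealized setting
in which the detector's perfect recall is structurally forced (reserved
dimensions are all-zero in training, so their reconstruction probabilities
sit near zero and every injected claim scores near 1); results on
context-mismatch injections are the more informative indicator for
real-data behavior, and real annotated claims are harder still.

## Benchmark conditions

The reference out-of-sample benchmark (tests and `scripts/acceptance.py`)
uses: 40 diagnosis categories, 400 procedure codes with 20 reserved, pools
of 8–16, 20,000 training claims, `min_claims` 5, w = 0.05, 30 epochs, a
2,000-claim test set at outlier fraction 0.27, and a separate 1,000-claim
labeled validation set for DBSCAN tuning. These sizes keep a full run to a
few minutes on one CPU while leaving the filtered vocabulary, sparsity and
imbalance qualitatively comparable to the 100k-claim reference scale. The
acceptance suite asserts recall 1.0 at the max-F1 threshold, the autoencoder
strictly beating tuned DBSCAN on F1, and McNemar p < 0.05.

## Numerical and degenerate-input conventions

- Probability clip ε = 1e-7 in losses; reconstruction outputs additionally
  clipped to (1e-12, 1−1e-12) so downstream logs are safe.
- Claims whose procedures were all filtered from the vocabulary (or whose
  diagnosis categories are all unknown to the encoder) are skipped with a
  logged warning and excluded from training and scoring; skip counts are
  reported.
- Within-claim age or gender conflicts are hard validation errors — one
  patient per claim is an invariant, not something to resolve silently.
- Ages within a sampled bucket are uniform; the open-ended top bucket is
  capped at 100 for sampling purposes.
- DBSCAN border-point ties follow the scan-order rule of the underlying
  implementation (first-reached cluster wins); correctness tests compare the
  order-independent parts (noise set, core-point partition) against a
  brute-force density-reachability oracle.
- McNemar with b + c = 0 reports p = 1 (degenerate; the models are
  indistinguishable).

## Known limitations

- The generator's conditional independence (procedures given pools, no
  inter-procedure correlation beyond pool co-membership) is simpler than
  real claim structure; absolute metric values on synthetic data should not
  be read as real-data performance.
- DBSCAN at realistic dimensionality is handicapped by the curse of
  dimensionality; its role here is the same as in the original protocol — a
  density-based reference point, not a tuned competitor.
- Unit counts, billed amounts, provider features, code embeddings, and
  variational or regularized architectures are out of scope.
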