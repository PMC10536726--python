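# claimwatch

Unsupervised detection of **procedure-code overutilization** in outpatient
healthcare claims.

Overutilization — billing procedure codes (CPT/HCPCS) that are inappropriate
or unnecessary for a claim's diagnoses and patient profile — is the largest
component of waste in US healthcare spending. Labeled examples are scarce, so
this package detects it without labels: a deep autoencoder is trained to
reconstruct normal claims, and procedure codes it cannot reconstruct in
context are flagged as potential outliers for human review.

## The model

Each claim is encoded as a sparse binary vector

```
x = [ CPT multi-hot | ICD-10 category multi-hot | age bucket one-hot (5) | gender one-hot (3) ]
```

where diagnoses are reduced to their 3-character ICD-10 general categories and
CPT codes occurring in fewer than `min_claims` claims are dropped from the
vocabulary (so rarity alone can never flag a code). A symmetric
seven-hidden-layer autoencoder (three ReLU encoder layers, a low-dimensional
bottleneck, three ReLU decoder layers, sigmoid output) reconstructs per-dimension
probabilities ŷ. Because x is overwhelmingly zeros, plain binary cross-entropy
collapses the model onto predicting all zeros; training instead uses a
**feature-weighted BCE** that down-weights the zero-target terms by w ∈ (0, 1]:

```
fwBCE = -(1/N) Σᵢ Σⱼ [ yᵢⱼ log ŷᵢⱼ + w (1 − yᵢⱼ) log(1 − ŷᵢⱼ) ]
```

(N = batch size; the per-claim loss is a *sum* over the M feature dimensions,
not a mean). A claim's score is `1 − min(ŷ over its own CPT dimensions)` — a
claim is as suspicious as its least-reconstructable procedure. Scores are
binarized at thresholds 0.00–1.00 in 0.05 steps and models are reported at the
threshold maximizing F1 (outliers = positive class). A DBSCAN baseline, whose
unclustered "noise" claims are its outlier predictions, and McNemar's paired
test on the discordance table complete the evaluation harness.

Because real Medicare claims cannot be redistributed, the package includes a
synthetic-claims generator: diagnosis categories own procedure pools, code
frequencies are Zipf long-tailed, demographics are diagnosis-conditioned, and
a set of *reserved* procedure codes owns feature dimensions yet never appears
in normal claims — injecting them into held-out claims creates ground-truth
out-of-sample outliers, and injecting in-vocabulary codes from foreign
diagnosis pools creates the harder context-mismatch outliers.

## Worked example

```python
from claimwatch.benchmark import run_out_of_sample_benchmark, BenchmarkConfig
from claimwatch.autoencoder import TrainingConfig

config = BenchmarkConfig(n_train=4000, n_test=500, n_dbscan_val=300,
                         training=TrainingConfig(epochs=15))
result = run_out_of_sample_benchmark(seed=1, config=config)

best = result.report.sweep.best_row
print(f"autoencoder: precision {best.precision:.2f}, recall {best.recall:.2f}, "
      f"F1 {best.f1:.2f} at threshold {best.threshold:.2f}")
print(f"dbscan:      F1 {result.report.comparison_sweep.best_f1:.2f}")
mc = result.report.mcnemar
print(f"mcnemar:     statistic {mc.statistic:.1f}, p = {mc.p_value:.2e}")
```

prints

```
autoencoder: precision 0.88, recall 0.99, F1 0.93 at threshold 0.95
dbscan:      F1 0.49
mcnemar:     statistic 135.1, p = 3.12e-31
```

The autoencoder misses almost no injected outlier (recall 0.99 at this small
4,000-claim scale, 1.0 at the full benchmark scale below) because the
injected codes' feature dimensions were all-zero during training, so their
reconstruction probabilities stay near zero; DBSCAN cannot separate claims
differing in one or two bits of a several-hundred-dimensional binary space,
and the McNemar p-value shows the gap is far beyond chance.

The same pipeline is available from a shell:

```sh
claimwatch simulate --seed 1 --out runs/sim
claimwatch train    --seed 1 --data runs/sim --out runs/model
claimwatch evaluate --seed 1 --data runs/sim --model runs/model --out runs/eval
```

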