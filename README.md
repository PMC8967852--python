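# ictalfeat

Engineered and learned single-channel iEEG biomarkers for seizure
detection — a complete, desk-scale implementation of a
biomarker-engineering pipeline for intracranial EEG, testable end-to-end
on synthetic recordings.

The package is aimed at researchers in quantitative electrophysiology who
want interpretable seizure features: it computes 16 classical engineered
metrics per 1 s epoch, trains two small neural feature encoders whose
16-dimensional embeddings can be compared against those metrics,
characterizes every model by its narrowband frequency response, and ranks
all 48 features by random-forest Gini importance under leakage-proof
subject-wise cross-validation.

## The metrics and models

Every computation operates on 1 s, single-channel, 400-sample epochs,
labeled preictal (0) before seizure onset and ictal (1) at and after it.

**Engineered features (16).** Welch band powers in delta (2–4 Hz), theta
(4–8), alpha (8–12), beta (12–30), low gamma (30–80) and high gamma
(80–150 Hz), reported both relative to total power and as log10 absolute
powers; the energy ratio / epileptogenicity index

    ER = (P_β + P_γ + P_γ′) / (P_θ + P_α),      EI = ER / (N_d − N_0 + 1)

which reduces to ER on single 1 s epochs; phase-locked high gamma

    PLHG = | (1/n) Σ A_HFO · exp(i(Φ_LF − Φ_HFO)) |

with the low-frequency composite 4–30 Hz and the high-frequency composite
30–150 Hz from the analytic signal; and two Benford-conformity measures —
the Cho–Gaines distance

    D = sqrt(N · Σ_d (e_d − o_d)²),   with  P_d = log10((d+1)/d)

between the observed first-significant-digit distribution and the Benford
expectation, computed on the raw samples (TDCG) and on the FFT magnitude
spectrum (FDCG).

**Learned features (16 + 16).** A 1-D convolutional encoder on the raw
epoch (TDBB, features z0..z15) and a dense encoder on the 200-bin FFT
magnitude spectrum (FDBB, p0..p15), each followed by a shared dense
classifier (16→14→…→2→1); the classifier alone on the engineered features
is the EMC. The networks are implemented on numpy with hand-written
reverse-mode gradients and trained with Adam, early-stopped on the
validation loss, under leave-one-subject-out cross-validation with
subject-level train/validation/test partitions.

## Worked example

```python
import numpy as np
from ictalfeat import (SyntheticConfig, generate_dataset, build_epochset,
                       engineered_feature_table, run_loo)

config = SyntheticConfig(n_subjects=10, channels_per_subject=4, seed=1)
epochs = build_epochset(generate_dataset(config))
table = engineered_feature_table(epochs.X, epochs.sample_rate)
print(table.groupby(epochs.y)[["rel_low_gamma", "ei", "tdcg"]].mean().round(3))

folds = run_loo(epochs, "fdbb", n_val_subjects=3, seed=1,
                max_epochs=40, patience=10)
print("mean held-out AUC:", np.mean([f.metrics["auc"] for f in folds]))
```

prints

```
   rel_low_gamma     ei   tdcg
0          0.163  1.758  2.290
1          0.377  8.843  1.768
```

— preictal (row 0) versus ictal (row 1) epochs: the ictal half carries the
configured 8× low-gamma power gain, an energy ratio about five times
higher, and *better* Benford conformity (lower TDCG), because the gained
broadband activity spreads sample magnitudes over more orders of
magnitude — and

```
mean held-out AUC: 1.0
```

for the spectral encoder trained subject-wise on these clearly separable
synthetic seizures.

There is also a CLI mirroring the library stages:

```bash
ictalfeat synth --subjects 10 --channels 4 --seed 1 --out data/
ictalfeat features --data data/ --out features.csv
ictalfeat pretrain --model fdbb --data data/ --val-subjects 3 --out runs/
```

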