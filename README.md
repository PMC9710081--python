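# medadhere

Medication adherence analytics for long-term (lipid-lowering) therapy:
stockpile-aware adherence metrics computed from pharmacy dispensing
records, quarterly patient time-series assembly, and a head-to-head
comparison of temporal against non-temporal classifiers of future
adherence — exercisable end-to-end on a seeded synthetic cohort generator,
with no external data required.

## Who this is for

Pharmacoepidemiologists and clinical-ML researchers who work with
dispensing claims and want (a) carefully tested implementations of the
standard adherence measures, and (b) a reproducible benchmark showing how
much predictive signal lives in the *sequence* of a patient's recent
history rather than in its summary statistics.

## The measures and the model

Two standard dispensing-based adherence measures over a period of
*N* days:

- **MPR** (medication possession ratio)
  `MPR = 100 × (sum of days' supply dispensed in period) / N` —
  counts supply indiscriminately, so overlapping refills can drive it
  above 100%.
- **PDC** (proportion of days covered)
  `PDC = 100 × (days in period "covered") / N` —
  an early refill is *shifted* to start covering when the previous supply
  runs out, so surplus (stockpile) closes later gaps but never back-fills
  a gap that has already elapsed; PDC ≤ 100 always.

Switching within a therapeutic class (e.g. simvastatin → atorvastatin) is
handled by computing PDC per drug and, per 90-day quarter, summing across
the class with an upper bound of 100%. The resulting quarterly series
`LL_PDC` defines the prediction target: a patient is labelled **adherent
(1)** when mean `LL_PDC ≥ 80` over the 20-quarter (~5-year) prediction
window following their risk-assessment (index) date, and non-adherent (0)
otherwise.

Classifiers of that label from the 8-quarter observation window before
the index date:

- **LSTM** (forget-gate, many-to-one) and **simple RNN** — temporal models
  consuming the `patients × quarters × features` sequence;
- **MLP**, **ridge classifier** (±1 targets, CV over an L2 grid) and
  **logistic regression** — non-temporal models on flattened, aggregated
  (per-feature time means) or last-quarter inputs.

The networks are implemented in numpy with analytic backpropagation and
ADAM (α=0.001, β₁=0.9, β₂=0.999, ε=1e-7); gradients are verified against
finite differences in the test suite. Models are compared by test-set ROC
AUC with pairwise DeLong tests, Bonferroni adjustment and a
bootstrap-resampling sensitivity analysis (two-sample Kolmogorov–Smirnov
on the AUC distributions).

## Worked example

```python
from medadhere import (SimulationConfig, ModelSpec,
                       run_adherence_experiment)

spec = [ModelSpec("LSTM", "lstm", "sequential"),
        ModelSpec("Simple RNN", "rnn", "sequential"),
        ModelSpec("MLP", "mlp", "flattened"),
        ModelSpec("RC", "ridge", "flattened"),
        ModelSpec("RC (aggregated)", "ridge", "aggregated"),
        ModelSpec("LR", "logistic", "flattened")]
result = run_adherence_experiment(SimulationConfig(n_patients=2000),
                                  seed=1, models=spec)
for name, auc in result.report.auc.items():
    print(f"{name:18s} {auc:.3f}")
```

prints (seed 1, 2,000 simulated patients):

```
LSTM               0.881
Simple RNN         0.829
MLP                0.804
RC                 0.768
RC (aggregated)    0.756
LR                 0.793
```

The synthetic cohort plants genuinely temporal signal — a "declining"
discontinuer whose refill gaps escalate over the last observation quarters
has the same *average* coverage as a steady moderate user but a very
different future — so sequence-aware models (LSTM, simple RNN) beat the
linear models, and every model beats its aggregated variant.
`result.report` also carries the pairwise DeLong p-values and the
Bonferroni threshold (0.05/15 for 6 models).

The same pipeline is available from the shell:

```bash
medadhere simulate --n-patients 2000 --seed 7 --out cohort/
medadhere compute --cohort cohort/ --out pdc.csv
medadhere build --cohort cohort/ --out tensor/
medadhere evaluate --n-patients 2000 --seed 1 --out report.json
medadhere post-predict --lengths 4,8,12,16 --out windows.json
```

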