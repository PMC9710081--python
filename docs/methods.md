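# Methods

## Adherence measures

All intervals are half-open `[start, end)` in integer days from an
arbitrary epoch; quarters are fixed 90-day blocks, so no calendar
arithmetic exists anywhere in the package. A *d*-day supply dispensed on
day *t* covers `[t, t+d)` absent shifting.

**Coverage construction (PDC).** For one patient and one drug, events are
processed in date order against a supply frontier *F*: each dispense
starts covering at `max(dispense_date, F)` and runs for its days' supply,
after which *F* advances to that end. An early refill is thereby shifted
forward (stockpile), closing *later* gaps; days that elapsed uncovered
before a dispense stay uncovered. Stockpile carried into an analysis
window from earlier dispenses behaves like a virtual dispense at the first
event. The implementation is interval-based; the test suite proves it
equal, on tens of thousands of random patterns, to an independent
day-by-day pill-stock counter (increment by supply on the dispense day,
decrement on every day the stock is positive).

**MPR attribution.** A dispense belongs to the period containing its
dispense date; supply is not prorated across period boundaries. PDC, by
contrast, is computed on coverage intersected with the period, so it is
automatically prorated. Note that `MPR ≥ PDC` holds whenever the
evaluation period starts no later than the first dispense considered; if
coverage is allowed to *carry into* a period from dispenses before it, PDC
can exceed MPR (the stress tests therefore anchor periods at day 0, before
all dispenses).

**Switching.** PDC is computed per drug independently — shifting never
crosses drugs, since a patient who switches typically abandons the old
supply — and per-quarter class-level adherence is the sum of the drugs'
PDCs capped at 100%. The cap applies to the sum only; per-drug values are
already ≤ 100 by construction.

**Label.** Mean quarterly class-level PDC over the 20 prediction quarters,
with the historical threshold of ≥ 80% defining adherence (the boundary
value 80.0 counts as adherent).

**Carry-in flag.** Whether pre-window history should contribute stockpile
to window PDC is a modelling choice; both behaviours are supported
(`include_carry_in` in the tensor builder), with full-history carry-in the
default since it matches the stockpile semantics above.

## Study design

Each patient's risk-assessment date is the index date. Observation
quarter *q* ∈ 1..8 spans `[index − (9−q)·90, index − (8−q)·90)`;
prediction quarter *q* ∈ 1..20 spans `[index + (q−1)·90, index + q·90)`.
The index day itself belongs to prediction quarter 1 (the boundary must be
assigned to one side; this choice keeps the observation window strictly
historical). Inclusion requires, in order: an index date within the
configured range; all five cholesterol components (HDL, LDL, TRI, TCL,
TC/HDL) reported in both windows; at least one lipid-lowering dispense in
the observation window with a 2-week look-ahead past the index; feasible
data values (positive supplies, positive lipid values, plausible age);
age ≥ 18; and a non-excluded ethnicity label. The cascade reports
per-rule attrition in application order and is idempotent.

## Feature tensor

Features fall into 8 categories (Demographic; Lipids; Lipid-lowering
drugs; CVD drugs; Other drugs; Hospitalisation; HbA1c and eGFR;
risk-assessment fields), ~65 columns after one-hot encoding, assembled per
observation quarter:

- Lab values use last-observation-carried-forward after the first test and
  0 before any test; the paired TEST (tested this quarter) and TESTED
  (ever tested, monotone non-decreasing) flags disambiguate true zeros.
  LOCF is the minimal imputation consistent with those flags.
- Per-drug and class-level PDCs are bounded [0, 100].
- Hospitalisation contributes in-quarter day counts, an acute-admission
  flag and condition-category flags (history HX_* / outcome OUT_*).
- Static demographics and risk-assessment fields are broadcast to every
  quarter; AGE advances with the quarter axis and equals the recorded
  age at the final observation quarter. Categorical fields (ethnicity,
  smoking, diabetes, renal, genetic-lipid, atrial fibrillation) are
  one-hot; sex is a single binary.
- Continuous features are z-standardised with training-split statistics
  only (required for stable network optimisation); binary features are
  left untouched.

Model input variants: `sequential` (n × 8 × F) for the recurrent models;
`flattened` (concatenation over quarters); `aggregated` (means of
time-varying features, last-quarter values of static ones, AGE excepted —
its last-quarter value is used); `last_quarter`.

## Models and training

Logistic regression and the ridge classifier are the linear baselines.
The ridge classifier recodes labels to ±1, minimises squared error plus
`L2·‖β‖²` in closed form (intercept unpenalised), and chooses L2 from the
grid {1e-6 … 10} by 5-fold cross-validated squared error; its continuous
regression value is the ROC score, since the class sign alone would not
trace a curve. The logistic fit is delegated to scikit-learn; its
probability is the score.

The MLP is 3 dense layers (64/64/2 by default) with dropout after each
hidden layer (rates 0.2152 / 0.1758) and a 2-unit softmax output. The
simple RNN uses a sigmoid hidden update
`h_t = σ(W_hx x_t + W_hh h_{t−1} + b_h)`; the LSTM uses tanh input node
and state squashing with sigmoid input/forget/output gates,
`s_t = g⊙i + s_{t−1}⊙f`, `h_t = tanh(s_t)⊙o`. Both recurrent models read
the output only at the final time step (many-to-one) through a dense
softmax layer. Hidden and cell states start at zero.

Training uses categorical cross-entropy with ADAM at its published
defaults (α=1e-3, β₁=0.9, β₂=0.999, ε=1e-7), a fixed epoch budget (100
for the recurrent models, 50 for the MLP; no early stopping), and a
seeded shuffle each epoch. The single L2 strength quoted per recurrent
model (LSTM 9.261e-3, simple RNN 1.202e-2) is applied to the recurrent
layer's weight matrices (input and recurrent kernels, biases excluded) —
the minimal reading of a one-number-per-model specification. Weights are
initialised symmetric-uniform scaled by 1/√fan-in from the training seed;
identical seeds give bit-identical training runs. Reference batch sizes
(1024 / 4096 / 256) were tuned on a ~81,000-sample training set; at desk
scale the experiment layer shrinks them proportionally to the actual
training-set size with a floor of 32, preserving the update count per
epoch. Non-finite losses raise immediately rather than silently
continuing.

Data splitting holds out ~10.1% of patients as the test set and rotates
five 90/10 train/validation folds through the remainder; final models are
trained on the fold-1 training split. Hyperparameter selection minimises
mean validation loss across the five folds (loss, not accuracy — the
smoother criterion); grid entries whose fit raises are scored infinity
and thereby excluded.

## Synthetic cohort generator

The generator's defaults *are* the study conditions; it emulates the
structure of linked risk-assessment / dispensing / laboratory /
hospitalisation data without attempting demographic realism. Four latent
phenotypes drive dispensing: persistent (gap mean 2 d, early-refill
probability 0.25, per-quarter stopping hazard 0.004), discontinuer (two
sub-modes: *declining*, whose refill gaps escalate by 12 d/quarter over
the last four observation quarters and who stops with hazard 0.45/quarter
after the index and rarely restarts; and *steady*, constant 18 d gaps,
hazard 0.03, restart 0.5 — constructed so that average observation-window
coverage is similar but the future differs, placing real signal in the
sequence order), intermittent (on/off episodes, hazard 0.30, restart
0.45) and switcher (drug A until a random switch quarter, then drug B,
with a small rhythm disruption). The mixture defaults (0.28 / 0.44 /
0.20 / 0.08) were calibrated once against the simulator's own
ground-truth label tally to land near the 57.6% adherent prevalence
typical of large lipid-lowering cohorts, and then frozen. Demographics
mildly tilt the phenotype odds (age toward persistence; smoking and
deprivation away from it), giving non-temporal features genuine signal
too.

Refills are 90-day supplies; each patient starts during a 4-quarter
lead-in so carried-in stockpile is exercised. Cholesterol panels occur
per quarter with probability 0.316 (HbA1c 0.289, eGFR 0.372), with one
panel guaranteed in each window to satisfy inclusion (unless the patient
is deliberately excludable); lipid values drift down ~25% while on
treatment and regress off it. Background hospitalisations occur at
0.02/quarter; deaths at 0.0024/quarter from the index, truncating all
subsequent events. A `long_memory` flag plants, for half the patients, a
hospitalisation in prediction quarters 5–10 that triggers discontinuation
only from quarter 17 onward — information invisible to short observation
windows in the post-index experiment, used to test whether models exploit
distant history. Determinism is per-patient: patient *i* draws from a
generator seeded `[seed, i]`, so identical (config, seed) pairs are
byte-identical.

What the generator does **not** emulate: real-world seasonality, dose
titration, polypharmacy interactions, informative lab-testing (testing is
independent of health state given treatment), realistic ICD coding or
population demographics. Passing tests therefore demonstrate that the
pipeline recovers the kinds of signal it was built to represent — not
that the same AUC levels would be obtained on real linked data.

## Evaluation

ROC AUC is computed from midranks (ties credited ½). DeLong's test uses
the placement-value (structural components) covariance with midrank ties
and a two-sided normal p-value; the tests verify it against a grouped
delete-one jackknife oracle. Bonferroni thresholds are α divided by the
number of unordered model pairs; significance is reported at both the raw
and adjusted levels, the adjustment being conservative. Bootstrap
sensitivity analysis draws full-size resamples of the test set with
replacement (single-class resamples are redrawn, keeping the repeat count
exact; redraws are reported); AUC distributions are compared with the
asymptotic two-sample Kolmogorov–Smirnov test (an exact small-sample mode
is available behind a flag).

The post-index experiment re-anchors at the end of prediction quarter 16,
labels adherence over quarters 17–20, removes patients who died before
the new index (read as the *end* of quarter 16), and retrains each model
for observation windows of 4, 8, 12 and 16 quarters.

## Problem sizes and determinism

Default experiment scale is 5,000 simulated patients (the signal-recovery
checks average over 5 seeds); unit tests use 300–2,500. These sizes are
the package's chosen desk scale: large enough for stable AUC ordering,
small enough to iterate on quickly. All randomness flows from explicit
integer seeds (simulation, splitting, initialisation, shuffling, dropout,
bootstrap); two identical runs serialise to identical bytes.

## Known limitations

- The inpatient-stay correction to PDC (days hospitalised counted as
  covered) is deliberately out of scope.
- The logistic baseline inherits scikit-learn's default L2 prior
  (C = 1.0) rather than being unpenalised.
- The DeLong test is two-sided; one-sided variants are not exposed.
- The simulator's hazards are quarter-resolution, so discontinuation
  dates are uniform within a quarter rather than day-exact.
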