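# icisurv

Hybrid mechanistic + deep-learning survival prediction for cancer patients
under immune checkpoint inhibitor (ICI) therapy.

Only a minority of patients benefit from ICIs, and classical response
criteria (RECIST-style volume thresholds) are late and only loosely tied to
overall survival. This package implements a hybrid alternative: estimate
per-patient *mathematical biomarkers* from routine imaging via a mechanistic
tumor-burden model, combine them with standard clinical measures, and train
a discrete-time neural survival model that outputs an individual survival
curve — probability, not a binary response label — for each patient.

It is aimed at quantitative oncology / biostatistics researchers who want a
tested, reproducible reference implementation of the full pipeline, with a
synthetic-cohort generator standing in for (undeposited) trial data.

## The model in brief

**Mechanistic layer.** Normalized tumor burden ρ(t) (ρ(0)=1) follows the
logistic-form master equation

    dρ/dt = ρ(α0 − μ + Λμ) − ρ²·Λμ,

with α0 the intrinsic growth rate, μ the therapy-induced kill rate and Λ
the anti-tumor immune state. (μ, Λ) are fit per patient by least squares on
log burden; α1 = ln ρ(t1)/t1 is the effective growth rate at first
restaging, with α1 ≤ 0.002 day⁻¹ defining the prognostically favorable
group.

**Survival layer.** Time is cut into 20 equidistant bins and a one-hidden-
layer network maps the encoded features to a per-bin conditional event
probability (logistic hazard) h_j(x); the survival curve is
S(t_k|x) = Π_{j≤k}(1 − h_j(x)). Training minimizes the right-censored
discrete-time negative log-likelihood with Adam and early stopping.
Accuracy is scored by event-time concordance, the IPCW Brier score and the
IPCW negative binomial log-likelihood (censoring distribution estimated by
Kaplan–Meier on the flipped event indicator), and feature contributions are
quantified by integrated gradients, feature ablation and permutation
importance.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from icisurv.cohort import CohortSpec, generate_cohort
from icisurv.pipeline import RunConfig, run_experiment

config = RunConfig(cohort_spec=CohortSpec(n_patients=93, seed=42),
                   split_seed=42, net_seed=42)
result = run_experiment(config)
print(result["comparison"].round(3))
```

prints, for one 93-patient synthetic cohort (19-patient test set):

```
               c_index_td    ibs  inbll  n_test
feature_set
hybrid              0.853  0.120  0.376      19
clinical_only       0.713  0.196  0.576      19
mb_only             0.867  0.108  0.354      19
```

`c_index_td` is the probability that, of two comparable patients, the one
who died earlier was assigned the lower predicted survival at that time
(1.0 = perfect discrimination, 0.5 = chance); `ibs` and `inbll` are
time-averaged censoring-weighted error scores (lower is better). Single
19-patient splits are noisy — the mb-only arm happens to edge out the
hybrid here — so the headline comparison repeats this over 10 fresh
cohorts and takes seed medians (`analysis/03_train_and_compare.py`):

```
               c_index_td    ibs  inbll
feature_set
clinical_only       0.601  0.224  0.699
hybrid              0.712  0.168  0.506
mb_only             0.690  0.189  0.587
```

where the hybrid arm has the best (largest) median concordance and the
best (smallest) median error scores.

## Analysis scripts

The study is organised as numbered drivers over the library:

| script | what it does |
|---|---|
| `analysis/01_simulate_cohort.py` | draw the default 93-patient cohort + burden series; cohort-characteristics table |
| `analysis/02_fit_biomarkers.py` | fit (μ, Λ, α1) from burden series; recovery vs generator truth; prognostic groups |
| `analysis/03_train_and_compare.py` | train hybrid / clinical-only / biomarker-only arms on identical splits; seed-median comparison |
| `analysis/04_kfold_stability.py` | exhaustive 5-group (20-fold) validation-loss stability study |
| `analysis/05_feature_importance.py` | integrated gradients + ablation (training set), permutation importance (test set), cross-method ranks |

Each writes small tables under `results/`.

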