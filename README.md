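# spirokit

A desk-scale toolkit for computational spirometry: it takes raw forced
expiratory flow curves through to a drafted diagnostic report in five
testable stages — metric
extraction, cohort construction, neural curve encoding, multimodal prompt
assembly, and guideline-grounded report drafting — with an evaluation
harness for judged report quality and diagnostic accuracy.  Every stage
runs in seconds to minutes on one CPU against a built-in synthetic spirogram
generator, so the full pipeline is reproducible without access to any
restricted clinical cohort.  It is aimed at researchers prototyping
spirogram analysis methods and at anyone who needs transparent, tested
reference implementations of the standard spirometric computations.

## What it computes

**Spirometric indices.** From a uniformly sampled expiratory flow curve
f(t) (L/s) with cumulative volume V(t) = ∫f dt, the toolkit computes FVC
(total exhaled volume), FEV1 (volume at 1 s after time zero), PEF (max f),
FEF25–75 = 0.5·FVC / (t75 − t25), and FEF75 (instantaneous flow at 75% of
FVC exhaled).

**Reference equations.** Predicted values, z-scores, and the lower limit of
normal follow the LMS model used by modern multi-ethnic lung-function
references:

    M = exp(a0 + a1·ln h + a2·ln a + Mspline(a)),   S = exp(b0 + b1·ln a + Sspline(a))
    z = ((y/M)^L − 1) / (L·S),                      LLN = value at z = −1.645

Official reference coefficient tables are not redistributed; the loader
accepts their CSV schema and a calibrated synthetic table ships for the
synthetic world.

**Curve encoder.** A 1-D CNN (three conv–ReLU–pool blocks, total temporal
downsampling r = 8) followed by a bidirectional LSTM maps a length-T curve
to a feature matrix E ∈ R^(⌈T/r⌉×D_feat), with a masked-pooling logistic
head for the probability of obstructive disease and a class-activation
saliency map over the input timesteps.  The network core is pure NumPy with
hand-derived gradients, verified by finite-difference checks.

**Cross-modal projector.** P = Dropout(ReLU(E·W1 + b1))·W2 + b2 projects
encoder features into a language-model embedding width; a pre-training
stage fits the projector to target embedding sequences by mean-squared
alignment loss with the encoder frozen.

**Diagnosis and reports.** The rule-based report generator applies the
hierarchical logic used in obstructive lung disease: FEV1/FVC below its LLN
establishes obstruction *first*; only then is severity graded 1–4 by FEV1
percent predicted.  Reports combine PFT findings, a flow-volume morphology
description (concavity index of the descending limb), and BM25-retrieved
guideline snippets.  External LLM/VLM generators plug in as adapters.

**Evaluation.** A six-dimension judge (factual accuracy, completeness,
logic, terminology, safety, curve description; 1–5 raw, normalised to
0–100), diagnosis extraction with a valid-response rate, AUROC / AUPRC /
F1 / sensitivity / specificity with subject-level percentile bootstrap
intervals, and a paired input-masking robustness experiment.

## Worked example

```python
from spirokit.simulate import generate_cohort
from spirokit.reference import full_pft, synthetic_reference_table
from spirokit.report import (describe_morphology, default_knowledge_base,
                             generate_report, retrieve)

records = generate_cohort(10, prevalence=0.5, seed=42)
rec = next(r for r in records if r.label == 1)          # an obstructive case
pft = full_pft(rec.curves[0], rec.demographics, synthetic_reference_table())
for name in ("FVC", "FEV1", "FEV1_FVC", "PEF"):
    i = pft[name]
    print(f"{name}: measured {i.measured:.3f}  predicted {i.predicted:.3f}"
          f"  LLN {i.lln:.3f}  z {i.z_score:+.2f}")

morph = describe_morphology(rec.curves[0])
snips = retrieve("airflow obstruction severity treatment",
                 default_knowledge_base(), k=2)
print(generate_report(rec, pft, morph, snips).impression)
```

prints

```
FVC: measured 2.901  predicted 4.055  LLN 3.255  z -2.37
FEV1: measured 1.447  predicted 3.435  LLN 2.684  z -4.35
FEV1_FVC: measured 0.499  predicted 0.848  LLN 0.757  z -6.04
PEF: measured 3.561  predicted 7.922  LLN 5.798  z -3.38
Step 1 (primary criterion): measured FEV1/FVC 0.499 < LLN 0.757 -> airflow
obstruction present. Severity: grade 3 (severe). Structured diagnosis: 1.
Confidence: 1.00. Step 2 (severity): FEV1 42% of predicted -> grade 3.
```

The measured ratio of 0.499 sits far below its lower limit of normal
(0.757, the 5th centile of the reference distribution), so obstruction is
established at the primary step; FEV1 at 42% of predicted then grades it
severe.  The morphology description for the same curve reports a concavity
index of +0.43 — the "scooped" descending limb of airflow obstruction.

A command-line interface covers the same stages:

```
spirokit simulate --n 200 --prevalence 0.5 --seed 7 --out-dir cohort/
spirokit metrics --curve cohort/curves/S000000_b1.csv --demo demo.json --out pft.json
spirokit qc --manifest cohort/manifest.jsonl --out-dir qc/
spirokit run --out-dir run/ --n 200 --seed 7     # full end-to-end pipeline
```

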