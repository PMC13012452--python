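# Methods

This note documents the models, numerical choices, and open design
decisions behind spirokit, in the order data flows through the pipeline.

## Synthetic spirogram model

A forced expiratory maneuver is modelled in the volume domain by a
piecewise flow–volume relation: a linear rise from zero flow to the peak,

    Q(v) = PEF · v / v_peak,                        0 ≤ v < v_peak,

and a power-law descending limb,

    Q(v) = PEF · ((FVC − v) / (FVC − v_peak))^k,    v_peak ≤ v ≤ FVC,

with `v_peak = v_peak_frac · FVC`.  The exponent k is the single morphology
dial: k > 1 yields a concave ("scooped") limb — the flow–volume hallmark of
airflow obstruction — k = 1 a linear limb, k < 1 a convex one.  For this
family the descending-limb concavity index (one minus the ratio of the area
under the limb to the area under its chord) has the closed form
(k − 1)/(k + 1), which anchors the morphology tests.

**Time-domain synthesis.** The maneuver is the solution of dv/dt = Q(v).
Both limbs solve in closed form: the rising limb is exponential growth
v(t) = v₀·e^{λt} with λ = PEF/v_peak, and on the descending limb
u = FVC − v satisfies u^{1−k} linear in t (logarithmic for k = 1).  The
generator therefore evaluates the exact solution on the uniform sampling
grid rather than stepping the ODE numerically; sampling is the only
discretisation.  Because v = 0 is a fixed point of the rising-limb ODE, the
maneuver starts from a bootstrap volume v₀ = 10⁻³·FVC (≤ 0.1% of the
volume budget).  The maneuver ends where the noiseless flow falls below the
end-of-test threshold (default 0.025 L/s, mirroring standard end-of-test
flow criteria); concave limbs approach FVC asymptotically, so some
exhalable volume is always left behind — as in real obstructive spirometry.
Measurement noise is additive Gaussian flow noise per sample.

Defaults: dt = 0.01 s; v_peak_frac ∈ [0.07, 0.14] (peak flow occurs after
~10% of FVC is exhaled, matching the sharp early peak of adult maneuvers);
noise 0.05 L/s.

**Cohorts.** Subjects draw age ~ U(40, 70) years, sex-specific normal
heights, and a never/former/current smoking mix — a middle-aged volunteer
cohort of the kind spirometry biobanks enrol.  A subject's true FVC is its
demographic expectation times exp(0.13·z) with z ~ N(0, 1); PEF is 2.0 L/s
per litre of FVC with log-normal jitter.  Disease effects are
class-conditional: controls draw k ∈ [0.8, 1.4], cases k ∈ [2, 4] plus a
0.60× PEF depression, a 0.90× FVC reduction, and a −0.8 shift of the
volume z-score — jointly depressing FEV1 and FEV1/FVC, the physiological
signature of obstruction.  PEF is eased downward if needed so every
maneuver outlasts the 1-s FEV1 window.  Records carry ≥ 2 repeated blows
with multiplicative FVC jitter (3% log-sd) so the blow-consistency filter
is exercisable, diagnosis codes drawn consistently with the label, and an
optional label-noise fraction whose records receive physiology from the
*other* class (emulating diagnosis-code noise; this is what the
label-consistency screen is meant to catch).

**What the generator does not emulate:** cough and glottic-closure
artifacts, submaximal effort, the inspiratory limb, bronchodilator
response, and real demographic confounding between covariates and disease.
Passing tests therefore demonstrate correctness of the computations and
the qualitative robustness properties on clean morphology, not clinical
performance on real spirograms.

## Metric engine

Volume is the cumulative trapezoidal integral of flow.  Time zero defaults
to the first sample whose flow reaches 5% of PEF; the standard
back-extrapolation construction is available behind a flag.  FEV1 is the
volume linearly interpolated 1 s after time zero (flagged missing for
maneuvers shorter than 1 s); t25/t75 are interpolated on the running
maximum of the volume trace so that measurement noise cannot break
monotonicity; FEF75 interpolates instantaneous flow at 75% of FVC exhaled
(the standard reading of that index); PEF is the raw — not smoothed —
maximum flow.  Degenerate inputs (non-positive exhaled volume, or
back-flow exceeding 5% of exhaled volume) raise a validity error rather
than returning numbers.

The engine is tested against an independent oracle that integrates the
same flow–volume ODE with an adaptive high-order stepper (rtol 1e-10) and
reads all indices off the continuous solution: at dt = 0.001 s the worst
disagreement across 100 random parameter draws is ~0.5% (tolerance 1%).

## LMS reference equations

Predicted medians and coefficients of variation follow the LMS form with
age-spline offsets linearly interpolated from a lookup table; z-scores use
the standard ((y/M)^L − 1)/(L·S) with the log-limit when |L| < 1e-6, and
the LLN is the 5th centile (z = −1.645).  The bundled table is synthetic:
its coefficients were calibrated once against the generator's healthy
population (geometric-mean ratio and log-spread of each measured index
over 800 simulated controls), so that control z-scores are approximately
standard normal and ~5% of controls fall below the LLN — making the
synthetic world self-consistent.  It reproduces no published table; users
supply real tables via the CSV schema
`sex,index,a0,a1,a2,b0,b1,L` + `sex,index,age,m_spline,s_spline`.

## Cohort construction

The pipeline order is fixed: case-definition labelling (ICD-10 prefixes
J43/J44 plus self-report codes) → percentile outlier trimming (default
0.5% per tail on FVC, FEV1, PEF; linear-interpolation percentiles) →
blow-consistency filtering (|FVC_a − FVC_b| / max(FVC_a, FVC_b) > 10%
between the two best blows excludes the record; the max denominator is the
symmetric, conservative choice) → control downsampling to 1:1 →
label-consistency screening → stratified 8:1:1 splitting.  Every exclusion
carries a machine-readable (stage, reason) pair and each stage conserves
records (in = out + excluded).

The label screen is a pluggable checker; the default deterministic rule
flags a case with FEV1/FVC z ≥ +1 or a control with z ≤ −3 — a documented
stand-in for an external consistency checker, not a claim about any
specific one.  Held-out split sizes use per-stratum ceilings
(val = test = ⌈0.1·n_class⌉): this is the unique simple rounding convention
under which an 8,245 / 10,171 cohort yields 14,730 / 1,843 / 1,843.

## Curve encoder

Three 1-D convolution blocks (default channels 32/64/64, kernels 7/5/3,
each followed by ReLU and stride-2 average pooling ⇒ temporal reduction
r = 8) feed a bidirectional LSTM (hidden 64 ⇒ D_feat = 128), giving a
feature matrix of shape ⌈T/r⌉ × D_feat per curve.  Input is the per-curve
PEF-normalised flow plus a constant sampling-interval channel.  The
disease head is masked mean pooling over valid timesteps, a linear layer,
and a logistic output trained by binary cross-entropy (Adam, early
stopping on validation loss).

The network core is NumPy with hand-derived reverse-mode gradients;
finite-difference checks in the test suite pin every layer's backward pass
to ~1e-7 relative error.  Padding is handled so that no information leaks
across sequence boundaries: activations beyond each curve's valid length
are zeroed after every convolution, pooling windows are anchored at the
time origin (an odd tail element averages against an implicit zero), and
the reverse LSTM direction runs over each sequence's own valid length.
Identical curves embedded under different batch paddings agree exactly.

**Saliency.** The exported map weights each final-layer feature row by its
positive contribution to the disease logit through the pooling head (a
class-activation map), linearly upsampled to input length and min-max
normalised.  A plain activation-norm map is also available, but it proved
training-seed fragile: across retrainings of the separable benchmark the
norm map concentrated on the descending limb in only ~3 of 5 seeds (it can
lock onto the flow peak instead), whereas the class-activation map did so
in 5 of 5 — hence the default.  On trained models, mean saliency over the
descending limb exceeds the rising limb in ≥ 80% (empirically 100%) of
noiseless obstructive curves.

**Benchmark sizes.** The classifier-recovery benchmark uses n = 400
noiseless curves at dt = 0.02 s (k = 0.8 vs k = 3), 260/40/100
train/val/test, and a reduced configuration (channels 16/32/32, hidden 32):
it trains in well under a minute on one CPU and reaches held-out AUROC 1.0.

## Projector and prompts

The projector applies P = Dropout(ReLU(E·W1 + b1))·W2 + b2 row-wise;
dropout is active only in training mode, so evaluation is deterministic
and equals the two-line matrix-algebra oracle to machine precision.
Pre-training minimises mean-squared error against target embedding
sequences from a pluggable text-embedding function with the encoder
frozen; MSE is the natural choice where only "semantic alignment" is
specified.  The planted-linear-map recovery test (targets E·A) reaches a
final loss < 1% of initial.  D_LLM defaults to 256 (64 in tests) — the
target width is a free parameter; correctness does not depend on matching
any particular language model.

Prompts carry three blocks — demographics; the PFT quadruple
(measured/predicted/LLN/z) for FEV1, FVC, FEV1/FVC, PEF, FEF25–75; and the
encoder probability — plus an embedding placeholder span when projected
features are attached.  Masking replaces every numeric token inside the
PFT block while preserving headers; it is idempotent, and masked prompts
contain no digit inside the PFT block.  The prompt template is original.

## Reports and retrieval

Retrieval is lexical BM25 (k1 = 1.5, b = 0.75, ties broken by snippet id):
deterministic, dependency-free, and adequate for a small guideline
knowledge base.  The bundled knowledge base contains short original
paraphrases of obstructive-disease guidance; a JSONL loader accepts user
bases.  The diagnostic hierarchy is strict: obstruction iff measured
FEV1/FVC < LLN (ties are non-obstructed); severity grades 1–4 at FEV1
percent-predicted cut-points 80/50/30; a missing LLN yields an
inconclusive result, never a guess.  Confidence is a logistic function of
how far the ratio z-score sits below the 5th-centile point.  Report
templates deliberately avoid "non-fully reversible" phrasing, which is not
defensible without bronchodilator reversibility data.

## Evaluation harness

Judge scores are six 1–5 integers normalised to 0–100 by (raw − 1)/4·100.
The deterministic rubric fallback scores: fraction of gold-report numbers
present in the candidate (factual accuracy), section coverage
(completeness), LLN-citation plus diagnosis agreement (logic), a
terminology checklist, diagnosis contradiction (safety), and
morphology-keyword agreement (curve description).  Adapter judges must
return the six raw scores; one retry, then the fallback.

Classification metrics operate on extracted (decision, confidence) pairs;
unparseable reports are invalid and only lower the valid-response rate.
AUROC (tie-corrected rank statistic) and AUPRC (precision–recall step
area) come from scikit-learn and are pinned exactly, for every input of
size ≤ 8, to brute-force pairwise/threshold-enumeration oracles in the
test suite.  Decisions are used as-is for F1/sensitivity/specificity — no
confidence thresholding.

Bootstrap intervals are percentile intervals over subject-level resampling
(n = 10,000 by convention; smaller in tests for speed), seeded and
deterministic; resamples on which a metric is undefined are redrawn up to
a cap, then dropped with a log entry, and an interval with > 50% drops is
flagged unreliable.  Percentile intervals for a normal mean at n = 60
cover at ~93–95%, within the ±4-point acceptance band.

The masking experiment runs the prompt → report → extraction → metrics
chain twice over the identical record order, unmasked and masked.  Two
fallback pipelines are provided: a text-only pipeline whose generator
re-parses the PFT block from the rendered prompt (under masking it loses
its evidence, the diagnosis is inconclusive, and the valid-response rate
collapses to 0), and a curve-aware pipeline that falls back to the
morphology/encoder channel and keeps a 100% valid-response rate under
masking — the qualitative robustness contrast between single- and
multi-channel designs.

## Reproducibility

All randomness flows from one root seed through per-stage derived seeds
(CRC32 of the stage name XOR root, kept below 2³¹), so each stage is
independently reproducible; identical configuration and seed give
byte-identical artifacts.  Checkpoints are single-file archives of config
plus weights.

## Known limitations

- The curve family has no inspiratory limb and one shape parameter; it
  cannot represent mixed or restrictive patterns.
- The synthetic reference table is only valid inside the synthetic world.
- The rule-based judge and report generator are deterministic proxies;
  scores are not comparable to human or LLM judging on real reports.
- The encoder core is CPU-bound NumPy: adequate at cohort sizes of
  hundreds to a few thousand curves, not for biobank-scale training.
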