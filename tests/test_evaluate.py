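"""Evaluation harness: judge rubric, metric oracles, bootstrap, masking."""

import itertools

import numpy as np
import pytest

from spirokit.evaluate import (
    DiagnosisExtraction,
    JudgeScores,
    bootstrap_ci,
    classification_metrics,
    extract_diagnosis,
    judge_report,
    masking_experiment,
    multimodal_pipeline,
    normalize_score,
    parse_pft_block,
    text_only_pipeline,
)
from spirokit.projector import build_prompt
from spirokit.reference import full_pft, synthetic_reference_table
from spirokit.report import Report
from spirokit.simulate import generate_cohort, EffectConfig


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def auroc_bruteforce(labels, confs):
    """Exhaustive pairwise concordance with half-credit for ties."""
    pos = [c for c, y in zip(confs, labels) if y == 1]
    neg = [c for c, y in zip(confs, labels) if y == 0]
    total = len(pos) * len(neg)
    s = sum(1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg)
    return s / total


def auprc_bruteforce(labels, confs):
    """Threshold enumeration of the precision-recall step curve."""
    order = sorted(set(confs), reverse=True)
    n_pos = sum(labels)
    ap, prev_recall = 0.0, 0.0
    for thr in order:
        sel = [y for y, c in zip(labels, confs) if c >= thr]
        tp = sum(sel)
        precision = tp / len(sel)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def make_extractions(decisions=None, confs=None, n=None):
    n = n or (len(decisions) if decisions is not None else len(confs))
    out = []
    for i in range(n):
        d = decisions[i] if decisions is not None else 1
        c = confs[i] if confs is not None else None
        out.append(DiagnosisExtraction(d, c))
    return out


class TestNormalizeScore:
    @pytest.mark.parametrize("raw,expected", [(1, 0), (2, 25), (3, 50),
                                              (4, 75), (5, 100)])
    def test_affine_anchor_points(self, raw, expected):
        assert normalize_score(raw) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            normalize_score(0)
        with pytest.raises(ValueError):
            normalize_score(6)

    def test_monotone(self):
        vals = [normalize_score(r) for r in (1, 2, 3, 4, 5)]
        assert vals == sorted(vals)


class TestJudgeFallback:
    def gold(self):
        return Report(
            findings="- FEV1: 2.10, predicted 3.80, LLN 3.00, z -2.50",
            morphology="The descending limb is concave (scooped).",
            impression="Airflow obstruction: FEV1/FVC below LLN. "
                       "Structured diagnosis: 1. Confidence: 0.90.",
            recommendations="- stop smoking",
            diagnosis=1, confidence=0.9,
        )

    def test_identical_report_scores_five(self):
        g = self.gold()
        scores = judge_report(g, g)
        assert scores.raw["factual_accuracy"] == 5
        assert scores.raw["completeness"] == 5

    def test_empty_morphology_scores_low(self):
        rep = self.gold()
        rep.morphology = ""
        scores = judge_report(rep, self.gold())
        assert scores.raw["curve_description"] <= 2

    def test_contradictory_diagnosis_fails_safety(self):
        rep = self.gold()
        rep.diagnosis = 0
        scores = judge_report(rep, self.gold())
        assert scores.raw["safety"] == 1

    def test_deterministic(self):
        a = judge_report(self.gold(), self.gold())
        b = judge_report(self.gold(), self.gold())
        assert a.raw == b.raw

    def test_adapter_retry_then_fallback(self):
        calls = []

        def flaky(rep, gold):
            calls.append(1)
            raise ValueError("unparseable")

        scores = judge_report(self.gold(), self.gold(), judge=flaky)
        assert len(calls) == 2  # one retry
        assert scores.raw["factual_accuracy"] == 5

    def test_normalized_property(self):
        scores = JudgeScores(raw={d: 3 for d in (
            "factual_accuracy", "completeness", "logic_evidence",
            "terminology", "safety", "curve_description")})
        assert all(v == 50.0 for v in scores.normalized.values())


class TestExtractDiagnosis:
    def test_structured_report(self):
        rep = Report("f", "m", "i", "r", diagnosis=1, confidence=0.9)
        ext = extract_diagnosis(rep)
        assert (ext.decision, ext.confidence) == (1, 0.9)

    def test_template_text(self):
        text = "... Structured diagnosis: 0. Confidence: 0.85."
        ext = extract_diagnosis(text)
        assert (ext.decision, ext.confidence) == (0, 0.85)

    def test_gibberish_invalid(self):
        assert not extract_diagnosis("lorem ipsum dolor").valid

    def test_refusal_lowers_valid_rate(self):
        extractions = [extract_diagnosis("Structured diagnosis: 1. "
                                         "Confidence: 0.8"),
                       extract_diagnosis("I cannot assess this input.")]
        summary = classification_metrics(extractions, [1, 0])
        assert summary.valid_response_rate == 0.5


class TestClassificationMetrics:
    def test_perfect_ranking(self):
        ext = make_extractions(decisions=[0, 1], confs=[0.2, 0.8])
        s = classification_metrics(ext, [0, 1])
        assert s.auroc == 1.0

    def test_half_auroc_example(self):
        ext = make_extractions(decisions=[0, 1, 1, 0],
                               confs=[0.1, 0.4, 0.35, 0.8])
        s = classification_metrics(ext, [0, 1, 1, 0])
        assert s.auroc == 0.5

    def test_f1_worked_example(self):
        ext = make_extractions(decisions=[1, 1, 0])
        s = classification_metrics(ext, [1, 0, 0])
        assert s.f1 == pytest.approx(2 / 3)
        assert s.sensitivity == 1.0
        assert s.specificity == 0.5

    def test_single_class_flags_rank_metrics(self):
        ext = make_extractions(decisions=[1, 1], confs=[0.6, 0.7])
        s = classification_metrics(ext, [1, 1])
        assert s.auroc is None and s.flags

    def test_matches_bruteforce_on_all_small_instances(self):
        """AUROC/AUPRC equal exhaustive enumeration for every labelling of
        n <= 8 with random (sometimes tied) confidences."""
        rng = np.random.default_rng(0)
        for n in range(2, 9):
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                confs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
                ext = make_extractions(decisions=list(labels),
                                       confs=list(confs))
                s = classification_metrics(ext, list(labels))
                assert s.auroc == pytest.approx(
                    auroc_bruteforce(labels, confs), abs=1e-12
                )
                assert s.auprc == pytest.approx(
                    auprc_bruteforce(labels, confs), abs=1e-12
                )

    def test_confusion_counts_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = rng.integers(4, 30)
            labels = rng.integers(0, 2, n)
            if len(set(labels.tolist())) < 2:
                continue
            decisions = rng.integers(0, 2, n)
            ext = make_extractions(decisions=list(decisions))
            s = classification_metrics(ext, labels)
            tp = np.sum((decisions == 1) & (labels == 1))
            fp = np.sum((decisions == 1) & (labels == 0))
            fn = np.sum((decisions == 0) & (labels == 1))
            tn = np.sum((decisions == 0) & (labels == 0))
            if 2 * tp + fp + fn:
                assert s.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
            if tp + fn:
                assert s.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert s.specificity == pytest.approx(tn / (tn + fp))


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        ci = bootstrap_ci(lambda d: 1.0, np.arange(20), n_resamples=100, seed=0)
        assert ci.lower == ci.upper == 1.0

    def test_seed_determinism(self):
        data = np.random.default_rng(2).normal(size=40)
        a = bootstrap_ci(np.mean, data, n_resamples=200, seed=5)
        b = bootstrap_ci(np.mean, data, n_resamples=200, seed=5)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_interval_widens_with_smaller_sample(self):
        rng = np.random.default_rng(3)
        small = rng.normal(size=50)
        large = rng.normal(size=500)
        w_small = np.mean([
            (lambda c: c.upper - c.lower)(
                bootstrap_ci(np.mean, small, n_resamples=300, seed=s))
            for s in range(5)
        ])
        w_large = np.mean([
            (lambda c: c.upper - c.lower)(
                bootstrap_ci(np.mean, large, n_resamples=300, seed=s))
            for s in range(5)
        ])
        assert w_small > w_large

    def test_coverage_near_nominal(self):
        """Percentile interval covers the true normal mean ~95% of the time
        (tolerance +/- 4 points over 200 trials)."""
        rng = np.random.default_rng(4)
        mu = 1.7
        covered = 0
        trials = 200
        for t in range(trials):
            data = rng.normal(mu, 1.0, size=60)
            ci = bootstrap_ci(np.mean, data, n_resamples=500, seed=t)
            covered += ci.lower <= mu <= ci.upper
        assert abs(covered / trials - 0.95) <= 0.04

    def test_always_undefined_metric_raises(self):
        def never(d):
            raise ValueError("always undefined")

        with pytest.raises(ValueError):
            bootstrap_ci(never, np.arange(5), n_resamples=20, seed=0)


@pytest.fixture(scope="module")
def cohort():
    records = generate_cohort(
        40, 0.5, effect_config=EffectConfig(noise_sd=0.02), seed=21
    )
    coeffs = synthetic_reference_table()
    for r in records:
        r.pft = full_pft(r.curves[0], r.demographics, coeffs)
    return records


class TestMaskingExperiment:
    def test_prompt_parse_roundtrip(self, cohort):
        r = cohort[0]
        bundle = build_prompt(r, r.pft)
        parsed = parse_pft_block(bundle.text)
        assert parsed["FEV1_FVC"].lln == pytest.approx(
            r.pft["FEV1_FVC"].lln, abs=5e-3
        )

    def test_text_pipeline_collapses_under_masking(self, cohort):
        """The PFT-text-only pipeline keeps a 100% valid-response rate
        unmasked and loses parseable decisions when the numbers are
        withheld."""
        result = masking_experiment(cohort, pipeline=text_only_pipeline)
        assert result["unmasked"]["metrics"].valid_response_rate == 1.0
        assert result["masked"]["metrics"].valid_response_rate == 0.0
        assert result["deltas"]["valid_response_rate"] == -1.0

    def test_curve_channel_survives_masking(self, cohort):
        result = masking_experiment(cohort, pipeline=multimodal_pipeline)
        assert result["masked"]["metrics"].valid_response_rate == 1.0
        assert result["masked"]["metrics"].auroc >= 0.8

    def test_pairing_contract_identical_order(self, cohort):
        """Masked and unmasked arms traverse the same records: subject
        findings sections pair one-to-one."""
        reports_a = [text_only_pipeline(r, mask_pft=False) for r in cohort]
        result = masking_experiment(cohort, pipeline=text_only_pipeline)
        reports_b = [text_only_pipeline(r, mask_pft=False) for r in cohort]
        assert [r.findings for r in reports_a] == [r.findings for r in reports_b]
        assert result["unmasked"]["metrics"].valid_response_rate == 1.0
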