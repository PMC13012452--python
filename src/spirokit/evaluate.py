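"""Evaluation protocol: six-dimension judged report quality, score
normalisation, diagnosis extraction, classification metrics with bootstrap
confidence intervals, and the input-masking robustness experiment.

Raw judge scores live on a 1-5 scale per dimension and are normalised to
0-100 by the affine map (raw - 1)/4 * 100 (1 -> 0, 5 -> 100).  Diagnostic
accuracy uses the extracted binary decision for F1 / sensitivity /
specificity and the extracted confidence for AUROC / AUPRC; reports from
which no decision can be parsed count as invalid and lower the
valid-response rate.  Confidence intervals are subject-level percentile
bootstrap intervals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .metrics import PFTIndex, PFTResult
from .projector import build_prompt
from .report import (
    MorphologyDescription,
    Report,
    default_knowledge_base,
    describe_morphology,
    generate_report,
    retrieve,
)

__all__ = [
    "JudgeScores",
    "DiagnosisExtraction",
    "MetricsSummary",
    "BootstrapCI",
    "JUDGE_DIMENSIONS",
    "normalize_score",
    "judge_report",
    "extract_diagnosis",
    "classification_metrics",
    "bootstrap_ci",
    "masking_experiment",
    "parse_pft_block",
    "text_only_pipeline",
    "multimodal_pipeline",
]

logger = logging.getLogger(__name__)

JUDGE_DIMENSIONS = (
    "factual_accuracy",
    "completeness",
    "logic_evidence",
    "terminology",
    "safety",
    "curve_description",
)


def normalize_score(raw: float) -> float:
    """Map a 1-5 raw judge score onto 0-100: (raw - 1)/4 * 100."""
    if not 1 <= raw <= 5:
        raise ValueError(f"raw score must lie in [1, 5], got {raw}")
    return (raw - 1.0) / 4.0 * 100.0


@dataclass
class JudgeScores:
    """Six per-dimension raw scores in {1..5} with 0-100 normalisation."""

    raw: dict  # dimension -> int in 1..5

    def __post_init__(self) -> None:
        missing = set(JUDGE_DIMENSIONS) - set(self.raw)
        if missing:
            raise ValueError(f"missing judge dimensions: {sorted(missing)}")
        for dim, v in self.raw.items():
            if not 1 <= v <= 5:
                raise ValueError(f"{dim} score {v} outside 1..5")

    @property
    def normalized(self) -> dict:
        return {d: normalize_score(v) for d, v in self.raw.items()}


@dataclass(frozen=True)
class DiagnosisExtraction:
    decision: int | None  # 0, 1, or None for invalid
    confidence: float | None = None

    @property
    def valid(self) -> bool:
        return self.decision in (0, 1)


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    level: float
    n_resamples: int
    seed: int | None
    unreliable: bool = False


@dataclass
class MetricsSummary:
    auroc: float | None
    auprc: float | None
    f1: float | None
    sensitivity: float | None
    specificity: float | None
    valid_response_rate: float
    flags: list = field(default_factory=list)
    ci: dict = field(default_factory=dict)  # metric name -> BootstrapCI

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "auroc", "auprc", "f1", "sensitivity", "specificity",
                "valid_response_rate",
            )
        }
        d["flags"] = list(self.flags)
        return d


# ---------------------------------------------------------------------------
# rubric-fallback judge
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"[-+]?\d+\.\d+|[-+]?\d+")
_TERM_CHECKLIST = (
    "fev1", "fvc", "lln", "predicted", "z", "airflow", "obstruction",
)
_MORPH_TERMS = ("concave", "scooped", "linear", "convex")


def _numbers(text: str) -> list:
    return [float(x) for x in _NUM_RE.findall(text)]


def _to_report(obj) -> Report:
    if isinstance(obj, Report):
        return obj
    # free text: best-effort sectioning
    return Report(
        findings=str(obj), morphology="", impression=str(obj),
        recommendations="", diagnosis=None, confidence=None,
    )


def _band(frac: float) -> int:
    """Map a [0, 1] proxy onto the 1-5 scale."""
    return 1 + int(round(4 * min(max(frac, 0.0), 1.0)))


def judge_report(report, gold, judge=None) -> JudgeScores:
    """Score a generated report against its gold reference.

    The pluggable ``judge`` adapter must return a dict of six raw 1-5
    scores; a parse failure is retried once, then the report is scored by
    the deterministic rubric fallback.  The fallback computes proxies:
    numeric agreement with the gold report (factual accuracy), section
    coverage (completeness), ordered-rationale and diagnosis agreement
    (logic), a terminology checklist, contradiction flags (safety), and
    morphology-keyword agreement (curve description).
    """
    if judge is not None:
        for _ in range(2):  # one retry on parse failure
            try:
                raw = judge(report, gold)
                return JudgeScores(raw=dict(raw))
            except Exception as exc:
                err = exc
        logger.warning("judge adapter failed twice (%s); using rubric", err)

    rep, ref = _to_report(report), _to_report(gold)

    ref_nums = _numbers(ref.findings + " " + ref.impression)
    rep_nums = set(_numbers(rep.findings + " " + rep.impression))
    if ref_nums:
        hits = sum(
            any(abs(a - b) <= 1e-6 + 0.005 * abs(b) for b in rep_nums)
            for a in ref_nums
        )
        factual = _band(hits / len(ref_nums))
    else:
        factual = 3

    sections = [rep.findings, rep.morphology, rep.impression, rep.recommendations]
    completeness = _band(sum(bool(s.strip()) for s in sections) / 4.0)

    logic = 1
    imp = rep.impression.lower()
    if "lln" in imp or "limit of normal" in imp:
        logic += 2
    if rep.diagnosis is not None and rep.diagnosis == ref.diagnosis:
        logic += 2
    logic = min(logic, 5)

    text_all = " ".join(sections).lower()
    term_hits = sum(t in text_all for t in _TERM_CHECKLIST)
    terminology = _band(term_hits / len(_TERM_CHECKLIST))

    if rep.diagnosis is not None and ref.diagnosis is not None:
        safety = 5 if rep.diagnosis == ref.diagnosis else 1
    else:
        safety = 2  # no committed decision: cautious but uninformative

    morph = rep.morphology.lower()
    if not morph.strip():
        curve = 1
    else:
        rep_terms = {t for t in _MORPH_TERMS if t in morph}
        ref_terms = {t for t in _MORPH_TERMS if t in ref.morphology.lower()}
        if ref_terms:
            curve = _band(len(rep_terms & ref_terms) / len(ref_terms))
        else:
            curve = 2 if not rep_terms else 3

    return JudgeScores(
        raw={
            "factual_accuracy": factual,
            "completeness": completeness,
            "logic_evidence": logic,
            "terminology": terminology,
            "safety": safety,
            "curve_description": curve,
        }
    )


# ---------------------------------------------------------------------------
# diagnosis extraction
# ---------------------------------------------------------------------------

_DX_RE = re.compile(r"structured diagnosis:\s*([01])", re.IGNORECASE)
_CONF_RE = re.compile(r"confidence:\s*([01](?:\.\d+)?)", re.IGNORECASE)


def extract_diagnosis(report, extractor=None) -> DiagnosisExtraction:
    """Parse the (binary decision, confidence) pair from a report.

    Structured :class:`Report` objects expose the fields directly; free text
    is parsed from the impression template.  Unparseable reports yield the
    ``invalid`` value (decision None), which counts against the
    valid-response rate.
    """
    if extractor is not None:
        try:
            decision, confidence = extractor(report)
            return DiagnosisExtraction(decision, confidence)
        except Exception as exc:
            logger.warning("extractor adapter failed (%s); using rules", exc)
    if isinstance(report, Report):
        if report.diagnosis in (0, 1):
            return DiagnosisExtraction(report.diagnosis, report.confidence)
        return DiagnosisExtraction(None, None)
    text = str(report)
    m = _DX_RE.search(text)
    if not m:
        return DiagnosisExtraction(None, None)
    c = _CONF_RE.search(text)
    return DiagnosisExtraction(int(m.group(1)), float(c.group(1)) if c else None)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------


def _confusion(decisions, labels) -> tuple:
    tp = int(np.sum((decisions == 1) & (labels == 1)))
    fp = int(np.sum((decisions == 1) & (labels == 0)))
    tn = int(np.sum((decisions == 0) & (labels == 0)))
    fn = int(np.sum((decisions == 0) & (labels == 1)))
    return tp, fp, tn, fn


def classification_metrics(extractions: list, labels) -> MetricsSummary:
    """Point metrics over valid extractions.

    AUROC is the tie-corrected Mann-Whitney statistic of the confidences,
    AUPRC the precision-recall step-curve area; F1, sensitivity, and
    specificity come from the binary decisions.  Single-class label sets
    leave the rank metrics undefined and flagged.
    """
    labels = np.asarray(labels, dtype=int)
    if len(extractions) != labels.size:
        raise ValueError("extractions and labels must align")
    valid = np.array([e.valid for e in extractions], dtype=bool)
    if not valid.any():
        raise ValueError("no valid extractions")
    rate = float(valid.mean())
    v_labels = labels[valid]
    decisions = np.array([e.decision for e, ok in zip(extractions, valid) if ok])
    flags = []

    tp, fp, tn, fn = _confusion(decisions, v_labels)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else None
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None

    confs = np.array(
        [e.confidence for e, ok in zip(extractions, valid) if ok], dtype=float
    )
    auroc = auprc = None
    if np.unique(v_labels).size < 2:
        flags.append("single-class labels: rank metrics undefined")
    elif np.any(np.isnan(confs)) or any(
        e.confidence is None for e, ok in zip(extractions, valid) if ok
    ):
        flags.append("missing confidences: rank metrics undefined")
    else:
        auroc = float(roc_auc_score(v_labels, confs))
        auprc = float(average_precision_score(v_labels, confs))
    return MetricsSummary(
        auroc=auroc, auprc=auprc, f1=f1, sensitivity=sens,
        specificity=spec, valid_response_rate=rate, flags=flags,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    metric_fn,
    data,
    n_resamples: int = 10000,
    level: float = 0.95,
    seed=None,
    max_redraws: int = 5,
) -> BootstrapCI:
    """Subject-level percentile bootstrap interval for ``metric_fn(data)``.

    ``data`` is indexable along its first axis; each resample draws subjects
    with replacement.  Resamples on which the metric is undefined (raises or
    returns None/NaN) are redrawn up to ``max_redraws`` times, else dropped
    with a log entry; an interval with more than half of its resamples
    dropped is flagged unreliable.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    data = np.asarray(data)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    values, dropped = [], 0
    for _ in range(n_resamples):
        val = None
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            try:
                val = metric_fn(data[idx])
            except Exception:
                val = None
            if val is not None and np.isfinite(val):
                break
            val = None
        if val is None:
            dropped += 1
        else:
            values.append(float(val))
    if dropped:
        logger.warning("%d bootstrap resamples dropped as undefined", dropped)
    if not values:
        raise ValueError("metric undefined on every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        lower=float(lo), upper=float(hi), level=level,
        n_resamples=n_resamples, seed=seed,
        unreliable=dropped > 0.5 * n_resamples,
    )


# ---------------------------------------------------------------------------
# fallback report pipelines and the masking experiment
# ---------------------------------------------------------------------------

_PFT_LINE_RE = re.compile(
    r"-\s*(?P<label>[\w/2575-]+):\s*measured\s+(?P<measured>[-+]?\d+\.?\d*)"
    r".*?predicted\s+(?P<predicted>[-+]?\d+\.?\d*)"
    r".*?LLN\s+(?P<lln>[-+]?\d+\.?\d*)"
    r".*?z-score\s+(?P<z>[-+]?\d+\.?\d*)",
)
_LABEL_TO_NAME = {
    "FEV1": "FEV1", "FVC": "FVC", "FEV1/FVC": "FEV1_FVC",
    "PEF": "PEF", "FEF25-75": "FEF25_75",
}


def parse_pft_block(prompt_text: str) -> PFTResult:
    """Recover a numeric PFT result from rendered prompt text.

    Masked prompts carry no numeric PFT tokens, so parsing yields an empty
    result — which is exactly how a prompt-driven report generator loses
    access to the primary diagnostic evidence under masking.
    """
    result = PFTResult()
    for m in _PFT_LINE_RE.finditer(prompt_text):
        name = _LABEL_TO_NAME.get(m.group("label"))
        if name is None:
            continue
        result.indices[name] = PFTIndex(
            name,
            measured=float(m.group("measured")),
            predicted=float(m.group("predicted")),
            lln=float(m.group("lln")),
            z_score=float(m.group("z")),
        )
    return result


def text_only_pipeline(record, mask_pft: bool = False, kb=None) -> Report:
    """PFT-text-driven report pipeline with no curve channel.

    The generator sees only the rendered prompt: it re-parses the PFT block
    and drafts the report from those numbers.  Under masking the parsed
    block is empty, the hierarchical diagnosis is inconclusive, and the
    report carries no extractable decision.
    """
    bundle = build_prompt(record, record.pft, copd_prob=None, mask_pft=mask_pft)
    parsed = parse_pft_block(bundle.text)
    kb = kb or default_knowledge_base()
    snippets = retrieve("airflow obstruction diagnosis severity", kb, k=2)
    morph = MorphologyDescription(0.0, "rounded", "")
    return generate_report(record, parsed, morph, snippets)


def multimodal_pipeline(
    record, mask_pft: bool = False, kb=None, model=None
) -> Report:
    """Curve-aware report pipeline: morphology and the encoder probability
    provide a parallel information channel, so a committed decision survives
    PFT masking."""
    from .encoder import classify

    bundle = build_prompt(record, record.pft, copd_prob=None, mask_pft=mask_pft)
    parsed = parse_pft_block(bundle.text)
    kb = kb or default_knowledge_base()
    snippets = retrieve("airflow obstruction diagnosis severity", kb, k=2)
    morph = describe_morphology(record.curves[0])
    rep = generate_report(record, parsed, morph, snippets)
    if rep.diagnosis is None:
        # masked text channel: fall back to the curve channel
        if model is not None:
            prob = float(classify(record.curves[0], model))
        else:
            prob = 1.0 / (1.0 + np.exp(-8.0 * morph.concavity_index))
        decision = int(prob > 0.5)
        rep = Report(
            findings=rep.findings,
            morphology=rep.morphology,
            impression=(
                "Quantitative PFT values were withheld; assessment relies on "
                f"the flow-volume curve channel. {morph.text} "
                f"Structured diagnosis: {decision}. Confidence: {prob:.2f}."
            ),
            recommendations=rep.recommendations,
            diagnosis=decision,
            confidence=prob,
        )
    return rep


def masking_experiment(
    records: list,
    pipeline=text_only_pipeline,
    gold_reports: list | None = None,
    judge=None,
) -> dict:
    """Run the prompt -> report -> judge -> metrics chain with and without
    PFT masking over the identical record order.

    Returns masked and unmasked :class:`MetricsSummary` objects, their
    paired deltas, and mean normalised judge scores per dimension (gold
    references default to the unmasked outputs).
    """
    labels = [r.label for r in records]
    unmasked = [pipeline(r, mask_pft=False) for r in records]
    masked = [pipeline(r, mask_pft=True) for r in records]
    gold = gold_reports if gold_reports is not None else unmasked

    out = {}
    for key, reports in (("unmasked", unmasked), ("masked", masked)):
        extractions = [extract_diagnosis(rep) for rep in reports]
        try:
            summary = classification_metrics(extractions, labels)
        except ValueError:
            summary = MetricsSummary(
                auroc=None, auprc=None, f1=None, sensitivity=None,
                specificity=None, valid_response_rate=0.0,
                flags=["no valid extractions"],
            )
        scores = [judge_report(rep, g, judge=judge) for rep, g in zip(reports, gold)]
        mean_scores = {
            dim: float(np.mean([s.normalized[dim] for s in scores]))
            for dim in JUDGE_DIMENSIONS
        }
        out[key] = {"metrics": summary, "judge": mean_scores}

    deltas = {}
    for name in ("auroc", "auprc", "f1", "valid_response_rate"):
        a = getattr(out["unmasked"]["metrics"], name)
        b = getattr(out["masked"]["metrics"], name)
        deltas[name] = None if a is None or b is None else b - a
    out["deltas"] = deltas
    return out
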