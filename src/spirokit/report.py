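"""Guideline-grounded diagnostic report drafting.

The pipeline mirrors how a gold-standard report is assembled: a
morphological description of the flow-volume curve, lexical retrieval of
guideline knowledge snippets, and a report synthesiser.  External LLM/VLM
generators plug in through simple callable adapters; a deterministic
rule-based fallback implements the hierarchical diagnostic logic —
airflow obstruction is established by FEV1/FVC against its LLN *first*,
and only then graded by FEV1 percent-predicted (grades 1-4).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .metrics import PFTResult, compute_volume
from .simulate import SpiroCurve

__all__ = [
    "MorphologyDescription",
    "KnowledgeSnippet",
    "Diagnosis",
    "Report",
    "concavity_index",
    "describe_morphology",
    "retrieve",
    "diagnose",
    "generate_report",
    "default_knowledge_base",
    "load_knowledge_base",
    "CONCAVITY_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: |concavity_index| below this is reported as a linear descending limb
CONCAVITY_THRESHOLD = 0.08


@dataclass
class MorphologyDescription:
    concavity_index: float
    pef_sharpness: str  # "sharp" | "rounded"
    text: str


@dataclass(frozen=True)
class KnowledgeSnippet:
    id: str
    text: str
    tags: tuple = ()
    source: str = "local"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("snippet text must be non-empty")


@dataclass
class Diagnosis:
    decision: int | None  # 1 obstruction, 0 none, None inconclusive
    grade: int | None  # 1..4 when obstructed
    confidence: float | None
    rationale: list = field(default_factory=list)


@dataclass
class Report:
    findings: str
    morphology: str
    impression: str
    recommendations: str
    diagnosis: int | None
    confidence: float | None

    def to_markdown(self) -> str:
        return (
            "# Spirometry report\n\n"
            f"## Findings\n{self.findings}\n\n"
            f"## Curve morphology\n{self.morphology}\n\n"
            f"## Impression\n{self.impression}\n\n"
            f"## Recommendations\n{self.recommendations}\n"
        )

    def to_dict(self) -> dict:
        return {
            "findings": self.findings,
            "morphology": self.morphology,
            "impression": self.impression,
            "recommendations": self.recommendations,
            "diagnosis": self.diagnosis,
            "confidence": self.confidence,
        }


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def concavity_index(curve: SpiroCurve) -> float:
    """Concavity of the descending limb on the flow-volume plane.

    1 - (area under the descending limb) / (area under the chord from
    (v_peak, PEF) to (FVC, 0)); positive for a concave ("scooped") limb,
    zero for a linear one, negative for convex.  For the power-law limb
    family with exponent k the closed form is (k-1)/(k+1).
    """
    flow = curve.flow
    volume = compute_volume(curve)
    i_pef = int(np.argmax(flow))
    if i_pef >= flow.size - 1:
        raise ValueError("peak flow at the final sample: no descending limb")
    pef = float(flow[i_pef])
    v_peak = float(volume[i_pef])
    v_end = float(volume[-1])
    if v_end <= v_peak:
        raise ValueError("no volume excursion after peak flow")
    limb_area = float(np.trapezoid(flow[i_pef:], volume[i_pef:]))
    chord_area = 0.5 * pef * (v_end - v_peak)
    return 1.0 - limb_area / chord_area


def describe_morphology(
    curve: SpiroCurve, describer=None
) -> MorphologyDescription:
    """Templated curve-morphology description (rule fallback), or a pluggable
    visual describer receiving the flow-volume data.  Adapter failures fall
    back to the rules with a log entry."""
    if describer is not None:
        try:
            text = describer(curve)
            ci = concavity_index(curve)
            return MorphologyDescription(ci, _pef_sharpness(curve), text)
        except Exception as exc:
            logger.warning("morphology adapter failed (%s); using rules", exc)
    ci = concavity_index(curve)
    sharp = _pef_sharpness(curve)
    if ci > CONCAVITY_THRESHOLD:
        limb = (
            "The descending limb is concave, showing the 'scooped' pattern "
            "after peak flow that accompanies airflow obstruction."
        )
    elif ci < -CONCAVITY_THRESHOLD:
        limb = "The descending limb is convex relative to the chord."
    else:
        limb = "The descending limb is essentially linear."
    peak_txt = (
        "a sharp, early peak" if sharp == "sharp" else "a rounded, later peak"
    )
    text = (
        f"The flow-volume curve rises to {peak_txt} "
        f"(concavity index {ci:+.2f}). {limb}"
    )
    return MorphologyDescription(ci, sharp, text)


def _pef_sharpness(curve: SpiroCurve) -> str:
    volume = compute_volume(curve)
    i_pef = int(np.argmax(curve.flow))
    frac = volume[i_pef] / volume[-1] if volume[-1] > 0 else 1.0
    return "sharp" if frac <= 0.2 else "rounded"


# ---------------------------------------------------------------------------
# retrieval
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokens(text: str) -> list:
    return _TOKEN_RE.findall(text.lower())


def retrieve(query: str, kb: list, k: int = 3) -> list:
    """Top-k snippets by BM25 lexical relevance (k1=1.5, b=0.75).

    Returns (snippet, score) pairs in descending score order, ties broken by
    snippet id; an empty query yields an empty result with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not kb:
        raise ValueError("knowledge base is empty")
    q_tokens = _tokens(query)
    if not q_tokens:
        logger.warning("empty retrieval query")
        return []
    k1, b = 1.5, 0.75
    docs = [_tokens(s.text + " " + " ".join(s.tags)) for s in kb]
    n = len(docs)
    avgdl = sum(len(d) for d in docs) / n
    scores = []
    for snippet, doc in zip(kb, docs):
        counts = {}
        for t in doc:
            counts[t] = counts.get(t, 0) + 1
        score = 0.0
        for term in set(q_tokens):
            df = sum(1 for d in docs if term in d)
            if df == 0:
                continue
            idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
            tf = counts.get(term, 0)
            score += idf * tf * (k1 + 1) / (
                tf + k1 * (1 - b + b * len(doc) / avgdl)
            )
        scores.append((snippet, score))
    scores.sort(key=lambda p: (-p[1], p[0].id))
    return scores[: min(k, len(scores))]


def default_knowledge_base() -> list:
    """Short original paraphrase snippets of obstructive-disease guidance
    (diagnostic criteria, severity grading, treatment); a loader accepts
    user-supplied snippet files for richer bases."""
    return [
        KnowledgeSnippet(
            "kb-dx-lln",
            "Airflow obstruction is established when the measured FEV1/FVC "
            "ratio falls below its lower limit of normal; a ratio at or "
            "above the LLN argues against obstruction.",
            ("diagnosis",),
        ),
        KnowledgeSnippet(
            "kb-severity",
            "Once airflow obstruction is present, severity is graded by FEV1 "
            "percent predicted: grade 1 mild at 80% or above, grade 2 "
            "moderate 50-79%, grade 3 severe 30-49%, grade 4 very severe "
            "below 30%.",
            ("severity",),
        ),
        KnowledgeSnippet(
            "kb-morph",
            "A concave, scooped descending limb of the flow-volume curve "
            "reflects small-airway airflow limitation; a linear or convex "
            "limb is the usual normal appearance.",
            ("diagnosis", "morphology"),
        ),
        KnowledgeSnippet(
            "kb-treat-mild",
            "For mild to moderate obstruction, smoking cessation, "
            "bronchodilator therapy, and vaccination are first-line "
            "management; reassess lung function over time.",
            ("treatment",),
        ),
        KnowledgeSnippet(
            "kb-treat-severe",
            "Severe or very severe obstruction warrants combination inhaled "
            "therapy, pulmonary rehabilitation, and specialist review for "
            "exacerbation prevention.",
            ("treatment", "severity"),
        ),
        KnowledgeSnippet(
            "kb-normal",
            "When spirometry is within normal limits, no airflow limitation "
            "is demonstrated; clinical follow-up depends on symptoms and "
            "exposure history.",
            ("diagnosis",),
        ),
    ]


def load_knowledge_base(path) -> list:
    """Load snippets from a JSONL file with fields id, text, tags, source."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(
                KnowledgeSnippet(
                    d["id"], d["text"], tuple(d.get("tags", ())),
                    d.get("source", "file"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# hierarchical diagnosis
# ---------------------------------------------------------------------------


def diagnose(pft: PFTResult) -> Diagnosis:
    """Hierarchical diagnostic logic: the FEV1/FVC-vs-LLN check comes first.

    Step 1 establishes obstruction iff measured FEV1/FVC < its LLN (strict).
    Step 2, only when obstructed, grades severity by FEV1 percent predicted:
    >=80 grade 1, 50-79 grade 2, 30-49 grade 3, <30 grade 4.  A missing LLN
    yields an inconclusive result, never a guess.  Confidence is a logistic
    function of how far the ratio z-score sits below the 5th-centile point.
    """
    ratio = pft.indices.get("FEV1_FVC")
    if ratio is None or ratio.measured is None or ratio.lln is None:
        return Diagnosis(
            None, None, None,
            ["FEV1/FVC ratio or its LLN unavailable: inconclusive"],
        )
    rationale = []
    obstructed = ratio.measured < ratio.lln
    rationale.append(
        f"Step 1 (primary criterion): measured FEV1/FVC {ratio.measured:.3f} "
        f"{'<' if obstructed else '>='} LLN {ratio.lln:.3f} -> "
        f"{'airflow obstruction present' if obstructed else 'no airflow obstruction'}"
    )
    if ratio.z_score is not None:
        margin = -(ratio.z_score + 1.645)  # >0 means below the LLN centile
    else:
        margin = (ratio.lln - ratio.measured) / max(ratio.lln, 1e-9) * 10.0
    confidence = float(1.0 / (1.0 + math.exp(-1.5 * margin)))
    if not obstructed:
        return Diagnosis(0, None, confidence, rationale)

    fev1 = pft.indices.get("FEV1")
    pct = fev1.pct_predicted if fev1 is not None else None
    if pct is None:
        rationale.append(
            "Step 2: FEV1 percent predicted unavailable; severity not graded"
        )
        return Diagnosis(1, None, confidence, rationale)
    if pct >= 80:
        grade = 1
    elif pct >= 50:
        grade = 2
    elif pct >= 30:
        grade = 3
    else:
        grade = 4
    rationale.append(
        f"Step 2 (severity): FEV1 {pct:.0f}% of predicted -> grade {grade}"
    )
    return Diagnosis(1, grade, confidence, rationale)


# ---------------------------------------------------------------------------
# report synthesis
# ---------------------------------------------------------------------------

_GRADE_WORD = {1: "mild", 2: "moderate", 3: "severe", 4: "very severe"}


def _findings_text(pft: PFTResult) -> str:
    lines = []
    for name in ("FVC", "FEV1", "FEV1_FVC", "PEF", "FEF25_75", "FEF75"):
        idx = pft.indices.get(name)
        if idx is None or idx.measured is None:
            continue
        label = name.replace("FEV1_FVC", "FEV1/FVC").replace("FEF25_75", "FEF25-75")
        parts = [f"{label}: {idx.measured:.3f}" if name == "FEV1_FVC"
                 else f"{label}: {idx.measured:.2f}"]
        if idx.predicted is not None:
            parts.append(f"predicted {idx.predicted:.2f}")
        if idx.lln is not None:
            parts.append(f"LLN {idx.lln:.2f}")
        if idx.z_score is not None:
            parts.append(f"z {idx.z_score:+.2f}")
        lines.append("- " + ", ".join(parts))
    return "\n".join(lines) if lines else "No valid indices."


def generate_report(
    record,
    pft: PFTResult,
    morphology: MorphologyDescription,
    snippets: list,
    generator=None,
) -> Report:
    """Synthesise the four-section report.

    The template fallback renders findings, morphology, impression, and
    recommendations deterministically from :func:`diagnose`, the morphology
    description, and the retrieved snippets; a pluggable generator adapter
    may replace the prose, with the fallback used on adapter failure.  In
    fallback mode the structured diagnosis and confidence always come from
    :func:`diagnose`.
    """
    dx = diagnose(pft)
    findings = _findings_text(pft)
    morph_text = morphology.text

    if dx.decision is None:
        impression = (
            "Inconclusive: " + dx.rationale[0] + ". No diagnosis is offered "
            "without the primary FEV1/FVC-vs-LLN comparison."
        )
    elif dx.decision == 0:
        impression = (
            f"{dx.rationale[0]}. Spirometry does not demonstrate airflow "
            "obstruction (non-COPD pattern). "
            f"Structured diagnosis: 0. Confidence: {dx.confidence:.2f}."
        )
    else:
        grade_txt = (
            f" Severity: grade {dx.grade} ({_GRADE_WORD[dx.grade]})."
            if dx.grade is not None
            else ""
        )
        impression = (
            f"{dx.rationale[0]}.{grade_txt} "
            f"Structured diagnosis: 1. Confidence: {dx.confidence:.2f}."
        )
        if len(dx.rationale) > 1:
            impression += " " + dx.rationale[-1] + "."

    rec_lines = [f"- {s.text}" for s, _ in snippets] if snippets else [
        "- Clinical correlation recommended."
    ]
    recommendations = "\n".join(rec_lines)

    if generator is not None:
        try:
            rendered = generator(
                {
                    "findings": findings,
                    "morphology": morph_text,
                    "impression": impression,
                    "recommendations": recommendations,
                    "diagnosis": dx.decision,
                    "confidence": dx.confidence,
                }
            )
            return Report(**rendered)
        except Exception as exc:
            logger.warning("report adapter failed (%s); using template", exc)

    return Report(
        findings=findings,
        morphology=morph_text,
        impression=impression,
        recommendations=recommendations,
        diagnosis=dx.decision,
        confidence=dx.confidence,
    )
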