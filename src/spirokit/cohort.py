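"""Cohort construction: case definition, quality filters, balancing,
label-consistency screening, and stratified splitting.

The pipeline order is fixed: label assignment -> validity / outlier /
blow-consistency filters -> class balancing -> label-consistency screen ->
stratified split.  Every excluded record carries a machine-readable
(stage, reason) pair so that input count = output count + exclusions at
each stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .simulate import Record

__all__ = [
    "CaseDefinition",
    "QCConfig",
    "Exclusion",
    "SplitAssignment",
    "assign_label",
    "trim_outliers",
    "blow_consistency_filter",
    "balance_downsample",
    "label_consistency_screen",
    "default_consistency_rule",
    "stratified_split",
    "run_qc",
]


@dataclass(frozen=True)
class CaseDefinition:
    """Which diagnosis codes define a case.

    Defaults follow the emphysema / chronic-obstruction ICD-10 chapters
    (J43, J44) plus a self-reported-illness code, matched by prefix.
    """

    icd_prefixes: tuple = ("J43", "J44")
    self_report_codes: tuple = ("self:1112",)

    def __post_init__(self) -> None:
        if not (self.icd_prefixes or self.self_report_codes):
            raise ValueError("case definition must list at least one code")


@dataclass(frozen=True)
class QCConfig:
    tail_fraction: float = 0.005  # per-tail outlier trim proportion
    max_blow_rel_diff: float = 0.10  # between-blow FVC relative difference
    metrics_for_trimming: tuple = ("FVC", "FEV1", "PEF")
    blow_metric: str = "FVC"

    def __post_init__(self) -> None:
        if not 0 <= self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must lie in [0, 0.5)")
        if not 0 < self.max_blow_rel_diff < 1:
            raise ValueError("max_blow_rel_diff must lie in (0, 1)")


@dataclass(frozen=True)
class Exclusion:
    subject_id: str
    stage: str
    reason: str


@dataclass
class SplitAssignment:
    """subject_id -> {train, val, test}; exhaustive and disjoint."""

    assignment: dict = field(default_factory=dict)

    def __getitem__(self, subject_id: str) -> str:
        return self.assignment[subject_id]

    def subjects(self, split: str) -> list:
        return [s for s, v in self.assignment.items() if v == split]

    def counts(self) -> dict:
        out = {"train": 0, "val": 0, "test": 0}
        for v in self.assignment.values():
            out[v] += 1
        return out


def assign_label(record: Record, case_def: CaseDefinition) -> int:
    """1 iff any diagnosis code matches an ICD prefix or self-report code."""
    for code in record.diagnosis_codes:
        if code in case_def.self_report_codes:
            return 1
        if any(code.startswith(p) for p in case_def.icd_prefixes):
            return 1
    return 0


def _record_metric(record: Record, name: str) -> float | None:
    if record.pft is None:
        return None
    return record.pft.measured(name)


def trim_outliers(records: list, qc: QCConfig) -> tuple:
    """Drop records with any trimming metric in the top/bottom tail.

    Percentile bounds use linear interpolation over the cohort's metric
    distribution.  Returns (survivors, exclusions).
    """
    if not records:
        raise ValueError("empty cohort")
    if qc.tail_fraction == 0:
        return list(records), []
    bounds = {}
    for name in qc.metrics_for_trimming:
        vals = np.array(
            [m for r in records if (m := _record_metric(r, name)) is not None]
        )
        if vals.size == 0:
            continue
        lo = np.percentile(vals, 100 * qc.tail_fraction)
        hi = np.percentile(vals, 100 * (1 - qc.tail_fraction))
        bounds[name] = (lo, hi)
    survivors, exclusions = [], []
    for r in records:
        reason = None
        for name, (lo, hi) in bounds.items():
            v = _record_metric(r, name)
            if v is None:
                continue
            if v < lo:
                reason = f"{name}={v:.4g} below P{100 * qc.tail_fraction:g}"
                break
            if v > hi:
                reason = f"{name}={v:.4g} above P{100 * (1 - qc.tail_fraction):g}"
                break
        if reason is None:
            survivors.append(r)
        else:
            exclusions.append(Exclusion(r.subject_id, "outlier_trim", reason))
    return survivors, exclusions


def blow_consistency_filter(
    record: Record, qc: QCConfig, blow_metrics: list | None = None
) -> tuple:
    """Keep/exclude decision from the two best repeated blows.

    ``blow_metrics`` supplies the per-blow comparison metric (default FVC)
    already computed for each curve; the two largest are compared by
    |a - b| / max(a, b).  A single-blow record is kept with a warning.
    Returns (keep: bool, reason: str | None).
    """
    if blow_metrics is None:
        from .metrics import compute_indices

        blow_metrics = [
            compute_indices(c).measured(qc.blow_metric) for c in record.curves
        ]
    vals = sorted((v for v in blow_metrics if v is not None), reverse=True)
    if len(vals) < 2:
        return True, "single blow: consistency not assessable"
    a, b = vals[0], vals[1]
    rel = abs(a - b) / max(a, b)
    if rel > qc.max_blow_rel_diff:
        return False, (
            f"{qc.blow_metric} relative difference {rel:.4f} > "
            f"{qc.max_blow_rel_diff}"
        )
    return True, None


def balance_downsample(records: list, seed=None) -> list:
    """Retain all cases; randomly downsample controls to a 1:1 ratio."""
    cases = [r for r in records if r.label == 1]
    controls = [r for r in records if r.label == 0]
    if len(controls) < len(cases):
        raise ValueError(
            f"cannot balance: {len(controls)} controls < {len(cases)} cases"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(controls), size=len(cases), replace=False)
    sampled = [controls[i] for i in sorted(keep)]
    return cases + sampled


def default_consistency_rule(record: Record) -> str | None:
    """Deterministic label-vs-physiology contradiction rule.

    Flags a record when the clinical label and the FEV1/FVC z-score are
    grossly incompatible: a case with z >= +1 (clearly supra-normal ratio)
    or a control with z <= -3 (severe obstruction).  Returns a reason string
    when flagged, else None.  This is a documented deterministic stand-in
    for an external consistency checker.
    """
    if record.pft is None:
        return None
    idx = record.pft.indices.get("FEV1_FVC")
    if idx is None or idx.z_score is None:
        return None
    z = idx.z_score
    if record.label == 1 and z >= 1.0:
        return f"label=1 but FEV1/FVC z={z:.2f} >= +1"
    if record.label == 0 and z <= -3.0:
        return f"label=0 but FEV1/FVC z={z:.2f} <= -3"
    return None


def label_consistency_screen(records: list, checker=None) -> tuple:
    """Exclude records the consistency checker flags as contradictory.

    ``checker`` maps a record to a reason string (flagged) or None (kept);
    a checker exception retains the record and logs the failure.  Returns
    (survivors, exclusions).
    """
    checker = checker or default_consistency_rule
    survivors, exclusions = [], []
    for r in records:
        try:
            reason = checker(r)
        except Exception as exc:  # checker failure: retain and log
            survivors.append(r)
            exclusions.append(
                Exclusion(r.subject_id, "consistency_screen_error",
                          f"checker failed ({exc}); record retained")
            )
            continue
        if reason is None:
            survivors.append(r)
        else:
            exclusions.append(Exclusion(r.subject_id, "consistency_screen", reason))
    return survivors, exclusions


def stratified_split(
    records: list, ratios: tuple = (8, 1, 1), seed=None
) -> SplitAssignment:
    """Stratified train/val/test split with per-class ceiling held-out sizes.

    Within each class, val and test sizes are ``ceil(frac * n_class)`` where
    frac is the ratio share; the remainder trains.  Membership is random by
    seed; classes with fewer than 3 members cannot be split.
    """
    if len(ratios) != 3 or any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise ValueError("ratios must be three non-negative numbers")
    labels = {r.label for r in records}
    if labels != {0, 1}:
        raise ValueError("both classes must be present to split")
    total = sum(ratios)
    frac_val, frac_test = ratios[1] / total, ratios[2] / total
    rng = np.random.default_rng(seed)
    assignment = {}
    for cls in (0, 1):
        members = [r.subject_id for r in records if r.label == cls]
        if len(members) < 3:
            raise ValueError(f"class {cls} has fewer than 3 records")
        n = len(members)
        n_val = math.ceil(frac_val * n) if frac_val > 0 else 0
        n_test = math.ceil(frac_test * n) if frac_test > 0 else 0
        if n_val + n_test >= n:
            raise ValueError("held-out allocation leaves no training records")
        order = rng.permutation(n)
        for j, i in enumerate(order):
            if j < n_val:
                assignment[members[i]] = "val"
            elif j < n_val + n_test:
                assignment[members[i]] = "test"
            else:
                assignment[members[i]] = "train"
    return SplitAssignment(assignment)


def run_qc(
    records: list,
    case_def: CaseDefinition | None = None,
    qc: QCConfig | None = None,
    checker=None,
    seed=None,
) -> tuple:
    """Run the full dataset-construction pipeline in its fixed order.

    Returns (survivors, exclusions, stage_log) where stage_log maps stage
    name to (n_in, n_out).
    """
    case_def = case_def or CaseDefinition()
    qc = qc or QCConfig()
    log, all_exclusions = {}, []

    n_in = len(records)
    for r in records:
        r.label = assign_label(r, case_def)
    log["assign_label"] = (n_in, n_in)

    survivors, excl = trim_outliers(records, qc)
    all_exclusions += excl
    log["outlier_trim"] = (n_in, len(survivors))

    kept = []
    for r in survivors:
        blow_vals = r.meta.get("blow_metrics")
        keep, reason = blow_consistency_filter(r, qc, blow_metrics=blow_vals)
        if keep:
            kept.append(r)
        else:
            all_exclusions.append(
                Exclusion(r.subject_id, "blow_consistency", reason)
            )
    log["blow_consistency"] = (len(survivors), len(kept))

    n_cases = sum(r.label for r in kept)
    balanced = balance_downsample(kept, seed=seed)
    dropped = {r.subject_id for r in kept} - {r.subject_id for r in balanced}
    all_exclusions += [
        Exclusion(s, "balance_downsample", "control downsampled") for s in sorted(dropped)
    ]
    log["balance_downsample"] = (len(kept), len(balanced))
    assert sum(r.label for r in balanced) == n_cases

    screened, excl = label_consistency_screen(balanced, checker=checker)
    all_exclusions += excl
    log["consistency_screen"] = (len(balanced), len(screened))
    return screened, all_exclusions, log
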