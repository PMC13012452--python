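"""Dataset-construction pipeline: labels, filters, balancing, splits."""

import math

import numpy as np
import pytest

from spirokit.cohort import (
    CaseDefinition,
    QCConfig,
    assign_label,
    balance_downsample,
    blow_consistency_filter,
    default_consistency_rule,
    label_consistency_screen,
    run_qc,
    stratified_split,
    trim_outliers,
)
from spirokit.metrics import PFTIndex, PFTResult
from spirokit.simulate import Demographics, Record, SpiroCurve


def light_record(subject_id, label=0, codes=(), fvc=None, ratio_z=None):
    """Record with a stub curve and optionally a precomputed PFT."""
    r = Record(
        subject_id=subject_id,
        curves=[SpiroCurve(flow=[1.0, 1.0], dt=0.01)],
        demographics=Demographics(age=55, sex="male", height=175),
        diagnosis_codes=list(codes),
        label=label,
    )
    if fvc is not None or ratio_z is not None:
        pft = PFTResult()
        if fvc is not None:
            pft.indices["FVC"] = PFTIndex("FVC", measured=fvc)
        if ratio_z is not None:
            pft.indices["FEV1_FVC"] = PFTIndex(
                "FEV1_FVC", measured=0.7, z_score=ratio_z
            )
        r.pft = pft
    return r


class TestAssignLabel:
    @pytest.mark.parametrize(
        "codes,expected",
        [(["J449"], 1), ([], 0), (["J45"], 0), (["self:1112"], 1),
         (["J431"], 1), (["I10", "J440"], 1)],
    )
    def test_prefix_and_self_report_matching(self, codes, expected):
        record = light_record("s", codes=codes)
        assert assign_label(record, CaseDefinition()) == expected


class TestTrimOutliers:
    def test_half_percent_tails_on_1_to_1000(self):
        records = [light_record(f"s{i}", fvc=float(i)) for i in range(1, 1001)]
        qc = QCConfig(tail_fraction=0.005, metrics_for_trimming=("FVC",))
        survivors, excl = trim_outliers(records, qc)
        assert len(survivors) == 990
        assert len(excl) == 10

    def test_zero_tail_keeps_all(self):
        records = [light_record(f"s{i}", fvc=float(i)) for i in range(10)]
        qc = QCConfig(tail_fraction=0.0, metrics_for_trimming=("FVC",))
        survivors, excl = trim_outliers(records, qc)
        assert len(survivors) == 10 and not excl

    def test_degenerate_identical_values_all_survive(self):
        records = [light_record(f"s{i}", fvc=3.0) for i in range(50)]
        qc = QCConfig(metrics_for_trimming=("FVC",))
        survivors, _ = trim_outliers(records, qc)
        assert len(survivors) == 50

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            trim_outliers([], QCConfig())

    def test_removal_bound(self):
        rng = np.random.default_rng(1)
        records = [
            light_record(f"s{i}", fvc=float(v))
            for i, v in enumerate(rng.normal(4, 1, 400))
        ]
        qc = QCConfig(tail_fraction=0.01, metrics_for_trimming=("FVC",))
        survivors, excl = trim_outliers(records, qc)
        assert len(excl) <= math.ceil(2 * 0.01 * 400) + 1


class TestBlowConsistency:
    def test_above_ten_percent_excluded(self):
        r = light_record("s")
        keep, reason = blow_consistency_filter(r, QCConfig(),
                                               blow_metrics=[3.0, 3.4])
        assert not keep and "0.1176" in reason

    def test_below_threshold_kept(self):
        r = light_record("s")
        keep, _ = blow_consistency_filter(r, QCConfig(), blow_metrics=[3.0, 3.2])
        assert keep

    def test_identical_blows_kept(self):
        r = light_record("s")
        keep, reason = blow_consistency_filter(r, QCConfig(),
                                               blow_metrics=[3.0, 3.0])
        assert keep and reason is None

    def test_single_blow_kept_with_warning(self):
        r = light_record("s")
        keep, reason = blow_consistency_filter(r, QCConfig(), blow_metrics=[3.0])
        assert keep and "single blow" in reason


class TestBalance:
    def test_paper_scale_arithmetic(self):
        """10,748 cases + 223,280 controls balance to 21,496 records."""
        records = [light_record(f"c{i}", label=1) for i in range(10748)]
        records += [light_record(f"n{i}", label=0) for i in range(223280)]
        balanced = balance_downsample(records, seed=0)
        assert len(balanced) == 21496
        assert sum(r.label for r in balanced) == 10748

    def test_already_balanced_unchanged_sizes(self):
        records = [light_record(f"c{i}", label=1) for i in range(5)]
        records += [light_record(f"n{i}", label=0) for i in range(5)]
        balanced = balance_downsample(records, seed=1)
        assert len(balanced) == 10

    def test_fewer_controls_than_cases_raises(self):
        records = [light_record("a", label=1), light_record("b", label=1),
                   light_record("c", label=0)]
        with pytest.raises(ValueError):
            balance_downsample(records)

    def test_seed_determinism(self):
        records = [light_record(f"c{i}", label=1) for i in range(20)]
        records += [light_record(f"n{i}", label=0) for i in range(80)]
        a = [r.subject_id for r in balance_downsample(records, seed=7)]
        b = [r.subject_id for r in balance_downsample(records, seed=7)]
        assert a == b


class TestConsistencyScreen:
    def test_case_with_supranormal_ratio_flagged(self):
        r = light_record("s", label=1, ratio_z=1.5)
        survivors, excl = label_consistency_screen([r])
        assert not survivors and excl[0].stage == "consistency_screen"

    def test_case_with_obstructed_ratio_kept(self):
        r = light_record("s", label=1, ratio_z=-2.5)
        survivors, _ = label_consistency_screen([r])
        assert survivors

    def test_control_with_severe_obstruction_flagged(self):
        r = light_record("s", label=0, ratio_z=-3.5)
        assert default_consistency_rule(r) is not None

    def test_null_checker_passes_everything(self):
        records = [light_record(f"s{i}", label=i % 2, ratio_z=0.0)
                   for i in range(6)]
        survivors, excl = label_consistency_screen(
            records, checker=lambda r: None
        )
        assert survivors == records and not excl

    def test_failing_checker_retains_record(self):
        def bad(record):
            raise RuntimeError("boom")

        r = light_record("s", label=1, ratio_z=2.0)
        survivors, excl = label_consistency_screen([r], checker=bad)
        assert survivors == [r]
        assert excl[0].stage == "consistency_screen_error"


class TestStratifiedSplit:
    def test_paper_scale_ceiling_arithmetic(self):
        """8,245 / 10,171 at 8:1:1 gives 14,730 / 1,843 / 1,843."""
        records = [light_record(f"c{i}", label=1) for i in range(8245)]
        records += [light_record(f"n{i}", label=0) for i in range(10171)]
        split = stratified_split(records, ratios=(8, 1, 1), seed=0)
        counts = split.counts()
        assert counts == {"train": 14730, "val": 1843, "test": 1843}

    def test_small_cohort_ceiling(self):
        records = [light_record(f"c{i}", label=1) for i in range(5)]
        records += [light_record(f"n{i}", label=0) for i in range(5)]
        counts = stratified_split(records, seed=1).counts()
        assert counts == {"train": 6, "val": 2, "test": 2}

    def test_all_train_ratios(self):
        records = [light_record(f"c{i}", label=1) for i in range(4)]
        records += [light_record(f"n{i}", label=0) for i in range(4)]
        counts = stratified_split(records, ratios=(1, 0, 0), seed=1).counts()
        assert counts == {"train": 8, "val": 0, "test": 0}

    def test_disjoint_exhaustive_and_class_balanced(self):
        records = [light_record(f"c{i}", label=1) for i in range(83)]
        records += [light_record(f"n{i}", label=0) for i in range(117)]
        split = stratified_split(records, seed=3)
        assert len(split.assignment) == 200
        for cls, n in ((1, 83), (0, 117)):
            ids = {r.subject_id for r in records if r.label == cls}
            n_val = sum(1 for s in ids if split[s] == "val")
            n_test = sum(1 for s in ids if split[s] == "test")
            assert n_val == math.ceil(0.1 * n)
            assert n_test == math.ceil(0.1 * n)

    def test_seed_reproducibility(self):
        records = [light_record(f"c{i}", label=i % 2) for i in range(40)]
        a = stratified_split(records, seed=11).assignment
        b = stratified_split(records, seed=11).assignment
        assert a == b

    def test_tiny_class_raises(self):
        records = [light_record("a", label=1), light_record("b", label=1),
                   light_record("c", label=0), light_record("d", label=0),
                   light_record("e", label=0)]
        with pytest.raises(ValueError):
            stratified_split(records)


class TestFullQCPipeline:
    def test_conservation_and_stage_order(self):
        rng = np.random.default_rng(5)
        records = []
        for i in range(120):
            label = i % 3 == 0
            codes = ["J440"] if label else []
            fvc = float(rng.normal(5 if not label else 3.5, 0.7))
            r = light_record(f"s{i}", label=int(label), codes=codes,
                             fvc=max(fvc, 0.5),
                             ratio_z=rng.normal(-3 if label else 0, 1))
            r.meta["blow_metrics"] = [fvc, fvc * (1 + rng.normal(0, 0.05))]
            records.append(r)
        survivors, exclusions, log = run_qc(records, seed=0)
        assert list(log) == ["assign_label", "outlier_trim", "blow_consistency",
                             "balance_downsample", "consistency_screen"]
        # conservation: each stage's output + its exclusions = its input
        for stage in ("outlier_trim", "blow_consistency",
                      "balance_downsample", "consistency_screen"):
            n_in, n_out = log[stage]
            n_excl = sum(1 for e in exclusions if e.stage == stage)
            assert n_in - n_out == n_excl
        # balanced before screening
        n_in, n_out = log["balance_downsample"]
        balanced_cases = sum(
            1 for r in records if r.label == 1
            and not any(e.subject_id == r.subject_id and e.stage in
                        ("outlier_trim", "blow_consistency")
                        for e in exclusions)
        )
        assert n_out == 2 * balanced_cases
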