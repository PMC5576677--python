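"""Grouped fold assignment, diagnostic metrics, and cross-validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myosono import (
    ConfusionCounts,
    CVConfig,
    ClassifierConfig,
    ProblemSpec,
    assign_folds,
    compute_metrics,
    cross_validate,
    extract_feature_table,
)
from myosono.dataset_io import Diagnosis, ImageRecord, MuscleGroup, Side
from myosono.errors import (
    ConfigurationError,
    FoldDegeneracyError,
    UndefinedMetricError,
)


def make_records(n_subjects_pos, n_subjects_neg, muscles=(MuscleGroup.BICEPS,),
                 sides=(Side.LEFT,), views=1):
    """Metadata-only records: one diagnosis per subject, IBM positive."""
    records, labels = [], []
    for k in range(n_subjects_pos + n_subjects_neg):
        positive = k < n_subjects_pos
        diagnosis = Diagnosis.IBM if positive else Diagnosis.N
        for mg in muscles:
            for side in sides:
                for view in range(1, views + 1):
                    records.append(
                        ImageRecord(
                            subject_id=f"s{k:02d}",
                            diagnosis=diagnosis,
                            muscle_group=mg,
                            side=side,
                            view_index=view,
                            depth_cm=6.0 if mg is MuscleGroup.RECTUS_FEMORIS else 4.0,
                            image_path=f"s{k}_{mg.value}_{side.value}_{view}.png",
                            mask_path=f"s{k}_{mg.value}_{side.value}_{view}_m.png",
                        )
                    )
                    labels.append(int(positive))
    return records, np.array(labels)


class TestAssignFolds:
    def test_ten_entities_five_folds_is_a_balanced_deal(self):
        records, labels = make_records(5, 5)
        folds = assign_folds(records, labels, n_folds=5, seed=3)
        sizes = np.bincount(list(folds.mapping.values()), minlength=5)
        assert (sizes == 2).all()

    def test_entities_never_span_folds(self):
        records, labels = make_records(
            4, 4, muscles=tuple(MuscleGroup), sides=(Side.LEFT, Side.RIGHT), views=3
        )
        folds = assign_folds(records, labels, n_folds=5, seed=0)
        seen = {}
        for record in records:
            fold = folds.fold_of(record)
            assert seen.setdefault(record.entity_key, fold) == fold

    def test_stratification_keeps_both_classes_per_fold(self):
        records, labels = make_records(5, 10)
        folds = assign_folds(records, labels, n_folds=5, seed=1)
        for f in range(5):
            fold_labels = {
                labels[i]
                for i, r in enumerate(records)
                if folds.fold_of(r) == f
            }
            assert fold_labels == {0, 1}

    def test_fewer_entities_than_folds_rejected(self):
        records, labels = make_records(2, 1)
        with pytest.raises(ConfigurationError):
            assign_folds(records, labels, n_folds=5, seed=0)

    def test_subject_level_grouping_unites_sides(self):
        records, labels = make_records(3, 3, sides=(Side.LEFT, Side.RIGHT))
        folds = assign_folds(records, labels, n_folds=3, seed=2, group_by="subject")
        for record in records:
            assert folds.fold_of(record, "subject") == folds.mapping[record.subject_id]


class TestComputeMetrics:
    def test_hand_computed_confusion_example(self):
        m = compute_metrics(ConfusionCounts(tp=40, fn=10, tn=35, fp=15))
        assert m.accuracy == pytest.approx(0.750)
        assert m.sensitivity == pytest.approx(0.800)
        assert m.specificity == pytest.approx(0.700)
        assert m.ppv == pytest.approx(40 / 55)
        assert m.npv == pytest.approx(35 / 45)
        assert m.kappa == pytest.approx(0.500)
        assert m.lr_pos == pytest.approx(8 / 3)
        assert m.lr_neg == pytest.approx(2 / 7)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert m.accuracy == 1.0
        assert m.kappa == 1.0
        assert m.lr_neg == 0.0
        assert math.isinf(m.lr_pos)

    def test_constant_positive_prediction_has_zero_kappa(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=10, tn=0, fn=0))
        assert m.kappa == pytest.approx(0.0)
        assert math.isnan(m.npv)  # no negative prediction made

    def test_missing_truth_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(tp=5, fp=0, tn=0, fn=5))

    @given(
        tp=st.integers(0, 50),
        fp=st.integers(0, 50),
        tn=st.integers(0, 50),
        fn=st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_accuracy_identity(self, tp, fp, tn, fn):
        # accuracy = (sens*P + spec*N) / (P + N)
        p, n = tp + fn, tn + fp
        if p == 0 or n == 0:
            return
        m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert m.accuracy == pytest.approx(
            (m.sensitivity * p + m.specificity * n) / (p + n)
        )
        assert -1.0 <= m.kappa <= 1.0


@pytest.fixture(scope="module")
def small_separable(tmp_path_factory):
    """Records + features of a small separable two-class study."""
    from myosono import StudyDesign, generate_study, load_manifest, make_preset

    design = StudyDesign(
        n_subjects={Diagnosis.N: 5, Diagnosis.IBM: 5, Diagnosis.PM: 0, Diagnosis.DM: 0},
        muscle_groups=(MuscleGroup.BICEPS, MuscleGroup.DELTOID),
        views_per_muscle=2,
        height=64,
        width=64,
        width_deep=64,
        seed=21,
    )
    out = tmp_path_factory.mktemp("cv_study")
    manifest = generate_study(design, make_preset("separable"), out)
    records = load_manifest(manifest)
    return records, extract_feature_table(records)


FAST_CLF = ClassifierConfig(n_trees=100, seed=0)


class TestCrossValidate:
    def test_no_leakage_between_train_and_test(self, small_separable):
        records, features = small_separable
        problem = ProblemSpec.problem("B")
        cv = CVConfig(n_folds=5, seed=4)
        folds = assign_folds(
            records, [int(r.diagnosis is Diagnosis.IBM) for r in records],
            cv.n_folds, cv.seed,
        )
        for f in range(cv.n_folds):
            test_entities = {
                r.entity_key for r in records if folds.fold_of(r) == f
            }
            train_entities = {
                r.entity_key for r in records if folds.fold_of(r) != f
            }
            assert not (test_entities & train_entities)

    def test_grouping_keeps_duplicates_co_fold(self, small_separable):
        import pandas as pd

        records, features = small_separable
        report = cross_validate(
            records, ProblemSpec.problem("B"), FAST_CLF, CVConfig(seed=4),
            features=features,
        )
        doubled = cross_validate(
            list(records) + list(records),
            ProblemSpec.problem("B"),
            FAST_CLF,
            CVConfig(seed=4),
            features=pd.concat([features, features], ignore_index=True),
        )
        assert doubled.mean == report.mean

    def test_invariant_to_record_order(self, small_separable):
        records, features = small_separable
        problem = ProblemSpec.problem("B")
        report = cross_validate(
            records, problem, FAST_CLF, CVConfig(seed=4), features=features
        )
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(records))
        shuffled = cross_validate(
            [records[i] for i in perm],
            problem,
            FAST_CLF,
            CVConfig(seed=4),
            features=features.iloc[perm].reset_index(drop=True),
        )
        assert shuffled.mean == report.mean
        assert shuffled.sd == report.sd

    def test_single_class_fold_raises(self):
        # 9 negative entities and 1 positive: most folds lack positives
        records, labels = make_records(1, 9)
        rng = np.random.default_rng(0)
        features = _fake_features(records, labels, rng)
        with pytest.raises(FoldDegeneracyError):
            cross_validate(
                records, ProblemSpec.problem("B"), FAST_CLF,
                CVConfig(n_folds=5, seed=0), features=features,
            )

    def test_report_shape_and_sample_sd(self, small_separable):
        records, features = small_separable
        report = cross_validate(
            records, ProblemSpec.problem("B"), FAST_CLF, CVConfig(seed=4),
            features=features,
        )
        assert len(report.per_fold) == 5
        assert len(report.confusions) == 5
        assert sum(c.total for c in report.confusions) == report.n_images
        accs = [m.accuracy for m in report.per_fold]
        assert report.sd["accuracy"] == pytest.approx(np.std(accs, ddof=1))


def _fake_features(records, labels, rng):
    """A feature table with mild class signal for guard-path tests."""
    import pandas as pd

    from myosono import FEATURE_NAMES

    rows = []
    for record, label in zip(records, labels):
        values = rng.normal(label, 1.0, len(FEATURE_NAMES))
        rows.append(
            {
                "subject_id": record.subject_id,
                "diagnosis": record.diagnosis.value,
                "muscle_group": record.muscle_group.value,
                "side": record.side.value,
                "view_index": record.view_index,
                **dict(zip(FEATURE_NAMES, values)),
            }
        )
    return pd.DataFrame(rows)
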