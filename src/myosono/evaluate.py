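"""Muscle-grouped N-fold cross-validation and diagnostic metrics.

The unit of fold assignment is the muscle entity (subject, muscle group,
side): all views of one physical muscle land in the same fold, so a
classifier is never tested on images of a muscle it trained on.  Metrics are
computed per image within each test fold; the report carries each metric's
across-fold mean and sample standard deviation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, predict, train_ensemble
from .dataset_io import (
    ImageRecord,
    MuscleEntityKey,
    ProblemSpec,
    filter_cohort,
)
from .errors import (
    ConfigurationError,
    FoldDegeneracyError,
    UndefinedMetricError,
)
from .features import FEATURE_NAMES, GLCMConfig

log = logging.getLogger(__name__)

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "kappa",
    "lr_pos",
    "lr_neg",
)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings."""

    n_folds: int = 5
    seed: int = 0
    group_by: str = "entity"  # "entity" (subject, muscle, side) or "subject"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.group_by not in ("entity", "subject"):
            raise ConfigurationError("group_by must be 'entity' or 'subject'")


@dataclass(frozen=True)
class FoldAssignment:
    n_folds: int
    mapping: Mapping[MuscleEntityKey | str, int]
    seed: int

    def fold_of(self, record: ImageRecord, group_by: str = "entity") -> int:
        key = record.subject_id if group_by == "subject" else record.entity_key
        return self.mapping[key]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, truth: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionCounts":
        truth = np.asarray(truth, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        return cls(
            tp=int(((truth == 1) & (predicted == 1)).sum()),
            fp=int(((truth == 0) & (predicted == 1)).sum()),
            tn=int(((truth == 0) & (predicted == 0)).sum()),
            fn=int(((truth == 1) & (predicted == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float
    lr_pos: float
    lr_neg: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class MetricReport:
    """Per-fold metric sets, confusion counts, and across-fold mean +/- SD."""

    per_fold: list[MetricSet]
    confusions: list[ConfusionCounts]
    mean: dict[str, float]
    sd: dict[str, float]
    problem_id: str = ""
    n_images: int = 0
    n_entities: int = 0

    def to_dict(self) -> dict:
        return {
            "problem_id": self.problem_id,
            "n_images": self.n_images,
            "n_entities": self.n_entities,
            "per_fold": [m.as_dict() for m in self.per_fold],
            "confusions": [
                {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                for c in self.confusions
            ],
            "mean": self.mean,
            "sd": self.sd,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(_json_safe(self.to_dict()), indent=indent)

    def to_table(self) -> str:
        rows = [
            f"{name:>12s}  {self.mean[name]:8.3f} +/- {self.sd[name]:.3f}"
            for name in METRIC_NAMES
        ]
        head = f"problem {self.problem_id}: {self.n_images} images, " \
               f"{self.n_entities} entities, {len(self.per_fold)} folds"
        return "\n".join([head, *rows])


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return "inf" if obj > 0 else ("-inf" if obj < 0 else "nan")
    if isinstance(obj, float) and math.isnan(obj):
        return "nan"
    return obj


def assign_folds(
    records: Sequence[ImageRecord],
    labels: Sequence[int],
    n_folds: int = 5,
    seed: int = 0,
    group_by: str = "entity",
) -> FoldAssignment:
    """Deal grouping entities to folds, shuffled and stratified by label.

    Entities of each class are shuffled with the seed and dealt round-robin,
    the second class continuing from where the first stopped, so fold sizes
    differ by at most one entity overall and per class.
    """
    labels = np.asarray(labels, dtype=int)
    entity_label: dict = {}
    for record, label in zip(records, labels):
        key = record.subject_id if group_by == "subject" else record.entity_key
        if entity_label.setdefault(key, int(label)) != int(label):
            raise ConfigurationError(f"conflicting labels within entity {key}")
    entities = sorted(entity_label, key=repr)
    if len(entities) < n_folds:
        raise ConfigurationError(
            f"{len(entities)} entities cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    mapping: dict = {}
    cursor = 0
    for cls in (0, 1):
        members = [e for e in entities if entity_label[e] == cls]
        for e in (members[i] for i in rng.permutation(len(members))):
            mapping[e] = cursor % n_folds
            cursor += 1
    per_fold_classes = {
        f: {entity_label[e] for e, fold in mapping.items() if fold == f}
        for f in range(n_folds)
    }
    short = [f for f, cs in per_fold_classes.items() if len(cs) < 2]
    if short:
        log.warning("folds %s contain a single class (small cohort)", short)
    return FoldAssignment(n_folds=n_folds, mapping=mapping, seed=seed)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The eight diagnostic metrics of one confusion table.

    Cohen's kappa uses the marginal-product chance agreement.  LR+ is ``inf``
    at specificity 1; PPV/NPV are NaN sentinels (logged) when no positive or
    negative prediction was made.
    """
    p, n = c.tp + c.fn, c.tn + c.fp
    if p == 0 or n == 0:
        raise UndefinedMetricError(
            f"confusion table lacks a truth class (P={p}, N={n})"
        )
    total = c.total
    accuracy = (c.tp + c.tn) / total
    sensitivity = c.tp / p
    specificity = c.tn / n
    if c.tp + c.fp == 0:
        log.warning("no positive predictions; PPV undefined")
        ppv = math.nan
    else:
        ppv = c.tp / (c.tp + c.fp)
    if c.tn + c.fn == 0:
        log.warning("no negative predictions; NPV undefined")
        npv = math.nan
    else:
        npv = c.tn / (c.tn + c.fn)
    p_o = accuracy
    p_e = ((c.tp + c.fn) * (c.tp + c.fp) + (c.tn + c.fp) * (c.tn + c.fn)) / total**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    lr_pos = math.inf if specificity == 1.0 else sensitivity / (1.0 - specificity)
    lr_neg = math.nan if specificity == 0.0 else (1.0 - sensitivity) / specificity
    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        kappa=kappa,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
    )


def summarize_folds(per_fold: Sequence[MetricSet]) -> tuple[dict, dict]:
    """Across-fold mean and sample SD per metric, over finite fold values."""
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name in METRIC_NAMES:
        values = np.array([getattr(m, name) for m in per_fold], dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            mean[name] = math.inf if np.isinf(values).any() else math.nan
            sd[name] = math.nan
        else:
            if finite.size < values.size:
                log.warning(
                    "%s: %d/%d folds non-finite; mean/SD over finite folds",
                    name, values.size - finite.size, values.size,
                )
            mean[name] = float(finite.mean())
            sd[name] = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    return mean, sd


def cross_validate(
    records: Sequence[ImageRecord],
    problem: ProblemSpec,
    clf_config: ClassifierConfig | None = None,
    cv_config: CVConfig | None = None,
    features: pd.DataFrame | None = None,
    glcm_config: GLCMConfig | None = None,
) -> MetricReport:
    """Grouped N-fold cross-validation of one binary problem.

    ``features`` may carry a precomputed per-record feature table (rows
    aligned with ``records``, columns ``FEATURE_NAMES``); otherwise images are
    read from disk and features extracted on the fly.
    """
    clf_config = clf_config or ClassifierConfig()
    cv_config = cv_config or CVConfig()
    cohort, labels = filter_cohort(records, problem)
    if features is None:
        from .pipeline import extract_feature_table

        features = extract_feature_table(records, glcm_config)
    if len(features) != len(records):
        raise ConfigurationError(
            f"feature table rows ({len(features)}) != records ({len(records)})"
        )
    keep = [i for i, r in enumerate(records) if r.diagnosis in problem.included_diagnoses]
    X = features.iloc[keep][list(FEATURE_NAMES)].to_numpy(dtype=float)

    # canonical ordering: results must not depend on manifest row order, and
    # tree bootstrap sampling is sensitive to row order
    order = sorted(
        range(len(cohort)),
        key=lambda i: (
            cohort[i].subject_id,
            cohort[i].muscle_group.value,
            cohort[i].side.value,
            cohort[i].view_index,
        ),
    )
    cohort = [cohort[i] for i in order]
    labels = labels[order]
    X = X[order]

    folds = assign_folds(
        cohort, labels, cv_config.n_folds, cv_config.seed, cv_config.group_by
    )
    fold_of = np.array(
        [folds.fold_of(r, cv_config.group_by) for r in cohort], dtype=int
    )
    per_fold: list[MetricSet] = []
    confusions: list[ConfusionCounts] = []
    for f in range(cv_config.n_folds):
        test = fold_of == f
        truth = labels[test]
        if truth.size == 0 or truth.min() == truth.max():
            raise FoldDegeneracyError(
                f"fold {f} has a single truth class; reseed or enlarge cohort"
            )
        ensemble = train_ensemble(X[~test], labels[~test], clf_config)
        predicted, _ = predict(ensemble, X[test])
        confusion = ConfusionCounts.from_predictions(truth, predicted)
        confusions.append(confusion)
        per_fold.append(compute_metrics(confusion))
    mean, sd = summarize_folds(per_fold)
    report = MetricReport(
        per_fold=per_fold,
        confusions=confusions,
        mean=mean,
        sd=sd,
        problem_id=problem.problem_id,
        n_images=len(cohort),
        n_entities=len(set(folds.mapping)),
    )
    log.info("problem %s: mean accuracy %.3f", problem.problem_id, mean["accuracy"])
    return report
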