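"""Pipeline orchestration: generate -> extract -> cross-validate per problem.

A single :class:`PipelineConfig` (loadable from YAML) names the dataset (a
manifest, or a synthetic design plus preset), the problems to run, and the
GLCM / classifier / cross-validation settings.  Features are extracted once
per image and shared across problems.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig
from .dataset_io import (
    Diagnosis,
    ImageRecord,
    MuscleGroup,
    ProblemSpec,
    Side,
    Tissue,
    load_image,
    load_manifest,
    load_mask,
)
from .errors import ConfigurationError
from .evaluate import CVConfig, MetricReport, cross_validate
from .features import FEATURE_NAMES, GLCMConfig, assemble_feature_vector
from .synthetic import StudyDesign, generate_study, make_preset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible run needs."""

    out_dir: Path = Path("myosono_out")
    manifest: Path | None = None
    synthetic: dict | None = None  # {"design": {...}, "preset": "separable"}
    problems: tuple = ("A", "B", "C")
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.synthetic is None):
            raise ConfigurationError(
                "config needs exactly one of 'manifest' or 'synthetic'"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path = Path(".")) -> "PipelineConfig":
        kwargs: dict = {}
        if "out_dir" in raw:
            kwargs["out_dir"] = base_dir / raw["out_dir"]
        if raw.get("manifest"):
            kwargs["manifest"] = base_dir / raw["manifest"]
        if raw.get("synthetic"):
            kwargs["synthetic"] = dict(raw["synthetic"])
        if "problems" in raw:
            kwargs["problems"] = tuple(str(p).upper() for p in raw["problems"])
        if "glcm" in raw:
            glcm = dict(raw["glcm"])
            if "tissue" in glcm:
                glcm["tissue"] = Tissue(glcm["tissue"])
            kwargs["glcm"] = GLCMConfig(**glcm)
        if "classifier" in raw:
            kwargs["classifier"] = ClassifierConfig(**raw["classifier"])
        if "cv" in raw:
            kwargs["cv"] = CVConfig(**raw["cv"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_as_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return str(obj) if isinstance(obj, Path) else obj


def _build_design(raw: dict) -> StudyDesign:
    raw = dict(raw)
    if "n_subjects" in raw:
        raw["n_subjects"] = {
            Diagnosis(k): int(v) for k, v in raw["n_subjects"].items()
        }
    if "muscle_groups" in raw:
        raw["muscle_groups"] = tuple(MuscleGroup(m) for m in raw["muscle_groups"])
    if "sides" in raw:
        raw["sides"] = tuple(Side(s) for s in raw["sides"])
    return StudyDesign(**raw)


def resolve_records(config: PipelineConfig, force: bool = False) -> list[ImageRecord]:
    """Load the manifest, generating the synthetic study first if configured."""
    if config.manifest is not None:
        return load_manifest(config.manifest)
    design = _build_design(config.synthetic.get("design", {}))
    preset = make_preset(config.synthetic.get("preset", "separable"))
    dataset_dir = Path(config.out_dir) / "dataset"
    manifest = dataset_dir / "manifest.csv"
    if manifest.exists() and not force:
        log.info("reusing existing synthetic dataset at %s", dataset_dir)
    else:
        generate_study(design, preset, dataset_dir, force=True)
    return load_manifest(manifest)


def extract_feature_table(
    records: Sequence[ImageRecord], glcm_config: GLCMConfig | None = None
) -> pd.DataFrame:
    """One row per record: record keys plus the 22 named features."""
    glcm_config = glcm_config or GLCMConfig()
    rows = []
    for record in records:
        image = load_image(record.image_path)
        mask = load_mask(record.mask_path)
        vector = assemble_feature_vector(record, image, mask, glcm_config)
        rows.append(
            {
                "subject_id": record.subject_id,
                "diagnosis": record.diagnosis.value,
                "muscle_group": record.muscle_group.value,
                "side": record.side.value,
                "view_index": record.view_index,
                **vector,
            }
        )
    return pd.DataFrame(rows)


def _load_or_extract_features(
    config: PipelineConfig, records: Sequence[ImageRecord]
) -> pd.DataFrame:
    out_dir = Path(config.out_dir)
    cache = out_dir / "features.csv"
    if cache.exists():
        table = pd.read_csv(cache)
        if len(table) == len(records) and all(
            name in table.columns for name in FEATURE_NAMES
        ):
            log.info("reusing feature table %s", cache)
            return table
    table = extract_feature_table(records, config.glcm)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(cache, index=False)
    return table


def run_problem(
    config: PipelineConfig,
    problem_id: str,
    records: Sequence[ImageRecord] | None = None,
    features: pd.DataFrame | None = None,
) -> MetricReport:
    """Run one binary problem end to end and write its artifacts.

    Writes ``features.csv`` (shared), ``report_<P>.json`` and
    ``run_<P>.log.json`` (config hash and seeds) under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = resolve_records(config)
    if features is None:
        features = _load_or_extract_features(config, records)
    problem = ProblemSpec.problem(problem_id)
    report = cross_validate(
        records,
        problem,
        clf_config=config.classifier,
        cv_config=config.cv,
        features=features,
    )
    (out_dir / f"report_{problem.problem_id}.json").write_text(report.to_json())
    run_log = {
        "version": __version__,
        "problem": problem.problem_id,
        "config_hash": config.config_hash(),
        "classifier_seed": config.classifier.seed,
        "cv_seed": config.cv.seed,
        "n_images": report.n_images,
        "n_entities": report.n_entities,
    }
    (out_dir / f"run_{problem.problem_id}.log.json").write_text(
        json.dumps(run_log, indent=2)
    )
    return report


def run_all(config: PipelineConfig) -> dict[str, MetricReport]:
    """Run every configured problem on a shared feature table."""
    records = resolve_records(config)
    features = _load_or_extract_features(config, records)
    return {
        pid: run_problem(config, pid, records=records, features=features)
        for pid in config.problems
    }
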