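"""Study manifest, image/mask loading, region extraction and cohort filters.

A study is described by a CSV manifest with one row per acquired B-mode view::

    subject_id,diagnosis,muscle_group,side,view_index,depth_cm,image_path,mask_path

Diagnoses are ``N`` (normal), ``PM`` (polymyositis), ``DM`` (dermatomyositis)
and ``IBM`` (inclusion body myositis).  Masks are label images with background
0, muscle 1 and subcutaneous fat 2, either as 8-bit PNG/TIFF rasters or as
NIfTI exports from ITK-Snap-style tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import (
    DegenerateCohortError,
    DimensionMismatchError,
    EmptyRegionError,
    ManifestSchemaError,
    ManifestValueError,
    MissingFileError,
)

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = (
    "subject_id",
    "diagnosis",
    "muscle_group",
    "side",
    "view_index",
    "depth_cm",
    "image_path",
    "mask_path",
)

#: Expected B-mode raster shapes (rows, cols) for the 4 cm and 6 cm depth
#: settings of the acquisition protocol.  Other shapes are accepted with a
#: warning so that scaled-down phantom studies remain loadable.
PROTOCOL_SHAPES = {4.0: (499, 476), 6.0: (499, 318)}

BACKGROUND_LABEL, MUSCLE_LABEL, FAT_LABEL = 0, 1, 2


class Diagnosis(str, Enum):
    N = "N"
    PM = "PM"
    DM = "DM"
    IBM = "IBM"


class MuscleGroup(str, Enum):
    DELTOID = "deltoid"
    BICEPS = "biceps"
    FLEXOR_CARPI_RADIALIS = "flexor_carpi_radialis"
    FLEXOR_DIGITORUM_PROFUNDUS = "flexor_digitorum_profundus"
    RECTUS_FEMORIS = "rectus_femoris"
    TIBIALIS_ANTERIOR = "tibialis_anterior"
    GASTROCNEMIUS = "gastrocnemius"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Tissue(str, Enum):
    MUSCLE = "muscle"
    FAT = "fat"


TISSUE_LABELS = {Tissue.MUSCLE: MUSCLE_LABEL, Tissue.FAT: FAT_LABEL}

AFFECTED = frozenset({Diagnosis.PM, Diagnosis.DM, Diagnosis.IBM})


@dataclass(frozen=True, order=True)
class MuscleEntityKey:
    """One physical muscle: the grouping unit that must not span CV folds."""

    subject_id: str
    muscle_group: MuscleGroup
    side: Side


@dataclass(frozen=True)
class ImageRecord:
    """One acquired B-mode view plus its study metadata."""

    subject_id: str
    diagnosis: Diagnosis
    muscle_group: MuscleGroup
    side: Side
    view_index: int
    depth_cm: float
    image_path: Path
    mask_path: Path

    def __post_init__(self) -> None:
        if not 1 <= int(self.view_index) <= 3:
            raise ManifestValueError(
                f"view_index must be 1..3, got {self.view_index!r} "
                f"(subject {self.subject_id})"
            )
        # Protocol: 6 cm depth is used for the rectus femoris only.
        deep = self.muscle_group is MuscleGroup.RECTUS_FEMORIS
        if (float(self.depth_cm) == 6.0) != deep:
            raise ManifestValueError(
                f"depth_cm must be 6 iff muscle is rectus_femoris; got depth "
                f"{self.depth_cm} for {self.muscle_group.value} "
                f"(subject {self.subject_id})"
            )

    @property
    def entity_key(self) -> MuscleEntityKey:
        return MuscleEntityKey(self.subject_id, self.muscle_group, self.side)


@dataclass(frozen=True)
class RegionPixels:
    """Bag of pixel intensities carrying one tissue label in one image."""

    tissue: Tissue
    values: np.ndarray

    @property
    def count(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ProblemSpec:
    """A binary diagnostic problem: which diagnoses are in, which are positive.

    The canonical problems:

    - ``A``: all subjects, affected ({PM, DM, IBM}) vs normal;
    - ``B``: normal and IBM only, IBM positive;
    - ``C``: myopathic subjects only, IBM vs {PM, DM}.
    """

    problem_id: str
    included_diagnoses: frozenset = field(default_factory=frozenset)
    positive_diagnoses: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.positive_diagnoses or not (
            self.included_diagnoses - self.positive_diagnoses
        ):
            raise ManifestValueError(
                "positive_diagnoses must be a non-empty strict subset of "
                "included_diagnoses"
            )

    @classmethod
    def problem(cls, problem_id: str) -> "ProblemSpec":
        problem_id = problem_id.upper()
        table = {
            "A": (set(Diagnosis), AFFECTED),
            "B": ({Diagnosis.N, Diagnosis.IBM}, {Diagnosis.IBM}),
            "C": (AFFECTED, {Diagnosis.IBM}),
        }
        try:
            included, positive = table[problem_id]
        except KeyError:
            raise ManifestValueError(f"unknown problem id {problem_id!r}") from None
        return cls(problem_id, frozenset(included), frozenset(positive))


def _parse_record(row: pd.Series, row_number: int, base_dir: Path) -> ImageRecord:
    def enum_value(enum_cls, token, column):
        try:
            return enum_cls(str(token).strip())
        except ValueError:
            raise ManifestValueError(
                f"row {row_number}: unknown {column} {token!r} "
                f"(expected one of {[e.value for e in enum_cls]})"
            ) from None

    try:
        return ImageRecord(
            subject_id=str(row["subject_id"]),
            diagnosis=enum_value(Diagnosis, row["diagnosis"], "diagnosis"),
            muscle_group=enum_value(MuscleGroup, row["muscle_group"], "muscle_group"),
            side=enum_value(Side, row["side"], "side"),
            view_index=int(row["view_index"]),
            depth_cm=float(row["depth_cm"]),
            image_path=base_dir / str(row["image_path"]),
            mask_path=base_dir / str(row["mask_path"]),
        )
    except ManifestValueError:
        raise
    except (TypeError, ValueError) as exc:
        raise ManifestValueError(f"row {row_number}: {exc}") from exc


def load_manifest(manifest_path: str | Path, check_files: bool = True) -> list[ImageRecord]:
    """Read and validate a study manifest.

    Relative image/mask paths are resolved against the manifest's directory.
    With ``check_files`` (default) every referenced file must exist.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingFileError(f"manifest not found: {manifest_path}")
    frame = pd.read_csv(manifest_path, comment="#", dtype=str)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ManifestSchemaError(
            f"manifest {manifest_path} is missing columns {missing_cols}"
        )
    if frame.empty:
        raise ManifestSchemaError(f"manifest {manifest_path} has no data rows")
    base = manifest_path.parent
    records = [
        _parse_record(row, i + 2, base)  # +2: 1-based, after the header line
        for i, (_, row) in enumerate(frame.iterrows())
    ]
    if check_files:
        missing = [
            str(p)
            for r in records
            for p in (r.image_path, r.mask_path)
            if not Path(p).exists()
        ]
        if missing:
            raise MissingFileError(
                f"{len(missing)} referenced files missing, e.g. {missing[:5]}"
            )
    log.info("loaded %d image records from %s", len(records), manifest_path)
    return records


def write_manifest(
    records: Iterable[ImageRecord],
    manifest_path: str | Path,
    header_comment: str | None = None,
) -> Path:
    """Write records as a manifest CSV (paths relative to the manifest dir)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "diagnosis": r.diagnosis.value,
                "muscle_group": r.muscle_group.value,
                "side": r.side.value,
                "view_index": r.view_index,
                "depth_cm": r.depth_cm,
                "image_path": _relpath(r.image_path, base),
                "mask_path": _relpath(r.mask_path, base),
            }
        )
    with open(manifest_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(fh, index=False)
    return manifest_path


def _relpath(path: Path, base: Path) -> str:
    try:
        return str(Path(path).relative_to(base))
    except ValueError:
        return str(path)


def load_image(path: str | Path, depth_cm: float | None = None) -> np.ndarray:
    """Load an 8-bit grayscale B-mode raster as a 2-D uint8 array."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse RGB(A) grayscale exports
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise DimensionMismatchError(f"{path}: expected a 2-D image, got {arr.shape}")
    if depth_cm is not None and arr.shape != PROTOCOL_SHAPES.get(float(depth_cm)):
        warnings.warn(
            f"{path}: shape {arr.shape} differs from the protocol shape "
            f"{PROTOCOL_SHAPES.get(float(depth_cm))} for depth {depth_cm} cm",
            stacklevel=2,
        )
    return arr.astype(np.uint8, copy=False)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a segmentation label image (PNG/TIFF or NIfTI), coded 0/1/2."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise DimensionMismatchError(
                f"{path}: NIfTI mask must squeeze to 2-D, got {arr.shape}"
            )
        # NIfTI stores x-y (column-major visual convention); transpose to the
        # raster row/column convention used everywhere else.
        arr = arr.T
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
    arr = arr.astype(np.int64, copy=False)
    labels = np.unique(arr)
    if not set(labels.tolist()) <= {BACKGROUND_LABEL, MUSCLE_LABEL, FAT_LABEL}:
        raise ManifestValueError(
            f"{path}: mask labels {labels.tolist()} outside {{0, 1, 2}}"
        )
    return arr


def extract_region(
    image: np.ndarray, mask: np.ndarray, tissue: Tissue | str
) -> RegionPixels:
    """Return the bag of intensities at positions carrying the tissue label."""
    tissue = Tissue(tissue)
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise DimensionMismatchError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    values = image[mask == TISSUE_LABELS[tissue]]
    if values.size == 0:
        raise EmptyRegionError(f"no pixels labelled {tissue.value} in mask")
    return RegionPixels(tissue=tissue, values=np.asarray(values).ravel())


def filter_cohort(
    records: Sequence[ImageRecord], spec: ProblemSpec
) -> tuple[list[ImageRecord], np.ndarray]:
    """Apply a problem's cohort filter and assign binary labels per record.

    Returns the retained records and an int array with 1 where the record's
    diagnosis is in ``spec.positive_diagnoses``.
    """
    kept = [r for r in records if r.diagnosis in spec.included_diagnoses]
    labels = np.array(
        [int(r.diagnosis in spec.positive_diagnoses) for r in kept], dtype=int
    )
    if labels.size == 0 or labels.min() == labels.max():
        raise DegenerateCohortError(
            f"problem {spec.problem_id}: cohort contains a single class "
            f"({labels.size} records)"
        )
    n_subjects = len({r.subject_id for r in kept})
    log.info(
        "problem %s cohort: %d subjects, %d images (%d positive)",
        spec.problem_id,
        n_subjects,
        len(kept),
        int(labels.sum()),
    )
    return kept, labels
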