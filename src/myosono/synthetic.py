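"""Synthetic speckle-phantom studies with known tissue statistics.

Each phantom image is a subcutaneous-fat band over muscle, every pixel drawn
independently from its tissue's Nakagami(m, omega) amplitude distribution
(optionally blurred to correlate the texture), then clipped and quantized to
8-bit — the statistical structure the feature model assumes, with ground truth
known exactly.  A study mirrors the acquisition protocol: 7 muscle groups,
bilateral, up to 3 transverse views per muscle, 6 cm depth for the rectus
femoris and 4 cm elsewhere.

Class presets make the disease effect explicit and tunable in one place:

- ``separable``: affected muscle is markedly brighter and more heterogeneous
  than normal muscle (the chronic fatty-replacement direction);
- ``overlapping``: the same direction with heavy overlap;
- ``null``: identical parameters for every diagnosis (negative control).

The preset values are generator conventions chosen to exercise the pipeline,
not clinical measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import gamma as gamma_fn

from .dataset_io import (
    FAT_LABEL,
    MUSCLE_LABEL,
    Diagnosis,
    ImageRecord,
    MuscleGroup,
    Side,
    write_manifest,
)
from .errors import ConfigurationError, GeometryError, OverwriteError

log = logging.getLogger(__name__)


def nakagami_mean(m: float, omega: float) -> float:
    """E[X] of Nakagami(m, omega): Gamma(m + 1/2)/Gamma(m) * sqrt(omega/m)."""
    return float(gamma_fn(m + 0.5) / gamma_fn(m) * np.sqrt(omega / m))


def omega_for_mean(m: float, mean: float) -> float:
    """Scale omega giving the requested E[X] at shape m."""
    return float(m * (mean * gamma_fn(m) / gamma_fn(m + 0.5)) ** 2)


def sample_nakagami(
    m: float, omega: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Draw Nakagami(m, omega) amplitudes: X = sqrt(Gamma(m, omega/m))."""
    return np.sqrt(rng.gamma(shape=m, scale=omega / m, size=size))


@dataclass(frozen=True)
class TissueParams:
    """Nakagami speckle parameters of one tissue.

    ``thickness_fraction`` applies to the fat band only; ``blur_sigma`` (in
    pixels) optionally correlates the speckle texture.  ``entity_sd`` is the
    between-muscle-entity standard deviation of the tissue's mean intensity:
    each physical muscle's tissue mean is shifted by a draw from
    N(0, entity_sd), emulating biological heterogeneity in echogenicity —
    without it, region features average over ~10^4 pixels and any class mean
    difference becomes trivially separable.  The shift is per entity (not per
    subject) so that, under entity-grouped cross-validation, heterogeneity
    never spans a train/test split.
    """

    m: float
    omega: float
    thickness_fraction: float | None = None
    blur_sigma: float = 0.0
    entity_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 0.5 or self.omega <= 0:
            raise ConfigurationError(
                f"need m >= 0.5 and omega > 0, got m={self.m}, omega={self.omega}"
            )
        if self.thickness_fraction is not None and not (
            0.0 < self.thickness_fraction < 1.0
        ):
            raise ConfigurationError(
                f"thickness_fraction must be in (0, 1), got {self.thickness_fraction}"
            )

    @classmethod
    def from_mean(
        cls,
        m: float,
        mean: float,
        thickness_fraction: float | None = None,
        blur_sigma: float = 0.0,
        entity_sd: float = 0.0,
    ) -> "TissueParams":
        return cls(
            m, omega_for_mean(m, mean), thickness_fraction, blur_sigma, entity_sd
        )

    def with_mean(self, mean: float) -> "TissueParams":
        """Same shape/geometry with the scale retargeted to a new E[X]."""
        return replace(self, omega=omega_for_mean(self.m, max(mean, 5.0)))


@dataclass(frozen=True)
class ClassPreset:
    """Per-diagnosis tissue parameters."""

    name: str
    params: Mapping[Diagnosis, Mapping[str, TissueParams]]

    def tissue_params(self, diagnosis: Diagnosis) -> Mapping[str, TissueParams]:
        return self.params[diagnosis]


_FAT = TissueParams.from_mean(
    m=1.2, mean=120.0, thickness_fraction=0.25, entity_sd=10.0
)


def _preset_from_muscle(name: str, normal: TissueParams, affected: TissueParams) -> ClassPreset:
    return ClassPreset(
        name=name,
        params={
            d: {"fat": _FAT, "muscle": normal if d is Diagnosis.N else affected}
            for d in Diagnosis
        },
    )


def make_preset(name: str) -> ClassPreset:
    """The named generator preset: ``separable``, ``overlapping`` or ``null``."""
    if name == "separable":
        return _preset_from_muscle(
            name,
            normal=TissueParams.from_mean(m=1.8, mean=50.0, entity_sd=8.0),
            affected=TissueParams.from_mean(m=0.8, mean=110.0, entity_sd=10.0),
        )
    if name == "overlapping":
        # same speckle shape for both classes: with ~10^4 pixels per region
        # the shape estimate is nearly noiseless, so any shape difference
        # would by itself separate the classes
        return _preset_from_muscle(
            name,
            normal=TissueParams.from_mean(m=1.2, mean=75.0, entity_sd=12.0),
            affected=TissueParams.from_mean(m=1.2, mean=90.0, entity_sd=12.0),
        )
    if name == "null":
        shared = TissueParams.from_mean(m=1.2, mean=80.0, entity_sd=10.0)
        return _preset_from_muscle(name, normal=shared, affected=shared)
    raise ConfigurationError(f"unknown preset {name!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Counts and geometry of a synthetic study.

    Defaults mirror the acquisition protocol of the clinical study this
    generator emulates: 33/19/14/14 subjects for N/IBM/PM/DM, 7 muscle
    groups, both sides, up to 3 views, 499-row rasters 476 (318) columns wide
    at 4 (6) cm depth.  Scaled-down designs override the counts and geometry.
    """

    n_subjects: Mapping[Diagnosis, int] = field(
        default_factory=lambda: {
            Diagnosis.N: 33,
            Diagnosis.IBM: 19,
            Diagnosis.PM: 14,
            Diagnosis.DM: 14,
        }
    )
    muscle_groups: tuple = tuple(MuscleGroup)
    sides: tuple = (Side.LEFT, Side.RIGHT)
    views_per_muscle: int = 3
    height: int = 499
    width: int = 476
    width_deep: int = 318
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.views_per_muscle <= 3:
            raise ConfigurationError("views_per_muscle must be 1..3")
        if any(n < 0 for n in self.n_subjects.values()):
            raise ConfigurationError("subject counts must be non-negative")

    @property
    def n_records(self) -> int:
        return (
            sum(self.n_subjects.values())
            * len(self.muscle_groups)
            * len(self.sides)
            * self.views_per_muscle
        )


def generate_phantom(
    fat: TissueParams,
    muscle: TissueParams,
    height: int,
    width: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One phantom: fat band of ``thickness_fraction`` over muscle.

    Returns ``(image uint8, mask uint8)`` with mask labels fat=2 (top band)
    and muscle=1.  Each tissue block is drawn i.i.d. Nakagami, blurred with
    its own ``blur_sigma`` if non-zero, then clipped to [0, 255] and rounded.
    """
    if fat.thickness_fraction is None:
        raise ConfigurationError("fat TissueParams needs thickness_fraction")
    band = int(round(fat.thickness_fraction * height))
    if band < 1 or band >= height:
        raise GeometryError(
            f"fat band of {band} rows invalid for height {height} "
            f"(thickness_fraction={fat.thickness_fraction})"
        )
    img = np.empty((height, width), dtype=float)
    img[:band] = sample_nakagami(fat.m, fat.omega, (band, width), rng)
    img[band:] = sample_nakagami(muscle.m, muscle.omega, (height - band, width), rng)
    if fat.blur_sigma > 0:
        img[:band] = gaussian_filter(img[:band], fat.blur_sigma)
    if muscle.blur_sigma > 0:
        img[band:] = gaussian_filter(img[band:], muscle.blur_sigma)
    image = np.rint(np.clip(img, 0.0, 255.0)).astype(np.uint8)
    mask = np.full((height, width), MUSCLE_LABEL, dtype=np.uint8)
    mask[:band] = FAT_LABEL
    return image, mask


def _record_rng(design: StudyDesign, subject_idx: int, muscle_idx: int,
                side_idx: int, view: int) -> np.random.Generator:
    """Independent, reproducible substream for one record.

    Keyed on indices only, so changing a diagnosis's parameters changes only
    that diagnosis's pixels, and single records can be regenerated.
    """
    ss = np.random.SeedSequence(
        entropy=design.seed, spawn_key=(subject_idx, muscle_idx, side_idx, view)
    )
    return np.random.default_rng(ss)


# spawn-key tag separating entity-level jitter streams from record streams
# (record streams carry the 1..3 view index in the fourth position)
_ENTITY_STREAM_TAG = 999


def _entity_params(
    design: StudyDesign,
    subject_idx: int,
    muscle_idx: int,
    side_idx: int,
    params: Mapping[str, TissueParams],
) -> dict[str, TissueParams]:
    """One muscle entity's tissue parameters with mean jitter applied.

    The jitter draw depends only on (seed, entity indices, tissue), never on
    the parameter values, so changing one diagnosis's preset leaves every
    other subject's pixels untouched.
    """
    out = {}
    for tissue_idx, tissue in enumerate(("fat", "muscle")):
        p = params[tissue]
        if p.entity_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=design.seed,
                    spawn_key=(
                        subject_idx, muscle_idx, side_idx,
                        _ENTITY_STREAM_TAG, tissue_idx,
                    ),
                )
            )
            shift = rng.normal(0.0, 1.0) * p.entity_sd
            p = p.with_mean(nakagami_mean(p.m, p.omega) + shift)
        out[tissue] = p
    return out


def design_records(design: StudyDesign, out_dir: str | Path = Path(".")) -> list[ImageRecord]:
    """The metadata-only record list a design implies (no files written).

    Subjects are named ``<diagnosis><index>``, e.g. ``IBM03``; file paths
    point at where :func:`generate_study` would write them under ``out_dir``.
    """
    out_dir = Path(out_dir)
    records = []
    for diagnosis in Diagnosis:
        for k in range(design.n_subjects.get(diagnosis, 0)):
            sid = f"{diagnosis.value}{k:03d}"
            for mg in design.muscle_groups:
                depth = 6.0 if mg is MuscleGroup.RECTUS_FEMORIS else 4.0
                for side in design.sides:
                    for view in range(1, design.views_per_muscle + 1):
                        stem = f"{sid}_{mg.value}_{side.value}_{view}"
                        records.append(
                            ImageRecord(
                                subject_id=sid,
                                diagnosis=diagnosis,
                                muscle_group=mg,
                                side=side,
                                view_index=view,
                                depth_cm=depth,
                                image_path=out_dir / "images" / f"{stem}.png",
                                mask_path=out_dir / "masks" / f"{stem}.png",
                            )
                        )
    return records


def generate_study(
    design: StudyDesign,
    preset: ClassPreset,
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Write a full synthetic study (images, masks, manifest) to ``out_dir``.

    Deterministic given ``design.seed``.  Refuses to write into an existing
    non-empty directory unless ``force`` is set.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise OverwriteError(f"{out_dir} exists and is not empty; use force")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    records = design_records(design, out_dir)
    subject_idx = {sid: i for i, sid in enumerate(
        dict.fromkeys(r.subject_id for r in records)
    )}
    muscle_idx = {mg: i for i, mg in enumerate(design.muscle_groups)}
    side_idx = {s: i for i, s in enumerate(design.sides)}
    entity_cache: dict = {}
    for record in records:
        ekey = record.entity_key
        if ekey not in entity_cache:
            entity_cache[ekey] = _entity_params(
                design,
                subject_idx[record.subject_id],
                muscle_idx[record.muscle_group],
                side_idx[record.side],
                preset.tissue_params(record.diagnosis),
            )
        params = entity_cache[ekey]
        width = design.width_deep if record.depth_cm == 6.0 else design.width
        rng = _record_rng(
            design,
            subject_idx[record.subject_id],
            muscle_idx[record.muscle_group],
            side_idx[record.side],
            record.view_index,
        )
        image, mask = generate_phantom(
            params["fat"], params["muscle"], design.height, width, rng
        )
        iio.imwrite(record.image_path, image)
        iio.imwrite(record.mask_path, mask)
    manifest = write_manifest(
        records,
        out_dir / "manifest.csv",
        header_comment=f"synthetic study, preset={preset.name}, seed={design.seed}",
    )
    log.info(
        "wrote %d synthetic records (preset %s, seed %d) to %s",
        len(records), preset.name, design.seed, out_dir,
    )
    return manifest
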