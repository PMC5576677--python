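"""Per-image feature extraction: echointensity, Nakagami speckle, Haralick texture.

Each B-mode view yields a 22-element feature vector:

- 5 echointensity features: mean and sample SD of muscle and fat intensity,
  and the muscle/fat mean ratio;
- 4 Nakagami speckle parameters: shape ``m`` and scale ``omega`` fitted to the
  muscle and to the fat region by the inverse-normalized-variance moment
  estimator (``omega = E[X^2]``, ``m = omega^2 / Var[X^2]``);
- 13 Haralick statistics of gray-level co-occurrence matrices accumulated at
  distance 1 in four directions over the muscle region (configurable),
  averaged across directions.

The Nakagami shape is clamped below at 0.5, the distribution's support bound,
with a logged warning.  Regions are quantized to ``n_levels`` uniform bins over
the region's own [min, max] before GLCM accumulation, so texture statistics are
invariant to adding a constant to every pixel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dataset_io import (
    ImageRecord,
    RegionPixels,
    Tissue,
    TISSUE_LABELS,
    extract_region,
)
from .errors import (
    DegenerateRatioError,
    DegenerateTextureError,
    DimensionMismatchError,
    EmptyRegionError,
    FeatureExtractionError,
    InsufficientDataError,
    InsufficientPairsError,
    MyosonoError,
)

log = logging.getLogger(__name__)

NAKAGAMI_MIN_SHAPE = 0.5
NAKAGAMI_MIN_PIXELS = 10

HARALICK_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

#: Canonical ordering and naming of the 22-element feature vector.
FEATURE_NAMES = (
    "echo_mean_muscle",
    "echo_sd_muscle",
    "echo_mean_fat",
    "echo_sd_fat",
    "echo_ratio_muscle_fat",
    "nakagami_m_muscle",
    "nakagami_omega_muscle",
    "nakagami_m_fat",
    "nakagami_omega_fat",
) + tuple(f"glcm_{name}" for name in HARALICK_NAMES)

#: Row/column offsets for GLCM directions 0, 45, 90 and 135 degrees at
#: distance 1 (image rows grow downward, so 45 degrees is up-and-right).
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class GLCMConfig:
    """Gray-level co-occurrence settings for the Haralick features."""

    n_levels: int = 32
    distance: int = 1
    offsets: tuple = GLCM_OFFSETS
    tissue: Tissue = Tissue.MUSCLE


@dataclass(frozen=True)
class EchoFeatures:
    mean_muscle: float
    sd_muscle: float
    mean_fat: float
    sd_fat: float
    ratio_muscle_fat: float

    def as_tuple(self) -> tuple:
        return (
            self.mean_muscle,
            self.sd_muscle,
            self.mean_fat,
            self.sd_fat,
            self.ratio_muscle_fat,
        )


@dataclass(frozen=True)
class NakagamiParams:
    m: float
    omega: float


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def echo_features(muscle: RegionPixels, fat: RegionPixels) -> EchoFeatures:
    """Mean/SD of each tissue's echointensity and the muscle/fat mean ratio."""
    mv = np.asarray(muscle.values, dtype=float)
    fv = np.asarray(fat.values, dtype=float)
    if mv.size == 0 or fv.size == 0:
        raise EmptyRegionError("echo features require non-empty regions")
    mean_fat = float(fv.mean())
    if mean_fat == 0.0:
        raise DegenerateRatioError("fat mean intensity is zero; ratio undefined")
    mean_muscle = float(mv.mean())
    return EchoFeatures(
        mean_muscle=mean_muscle,
        sd_muscle=_sample_sd(mv),
        mean_fat=mean_fat,
        sd_fat=_sample_sd(fv),
        ratio_muscle_fat=mean_muscle / mean_fat,
    )


def fit_nakagami(region: RegionPixels | np.ndarray) -> NakagamiParams:
    """Moment (inverse-normalized-variance) fit of the Nakagami distribution.

    With ``y = x**2``: ``omega = mean(y)`` and ``m = omega**2 / var(y)``
    (sample variance).  ``m`` below the support bound 0.5 is clamped with a
    warning — sub-Rayleigh speckle estimates do occur on quantized pixels.
    """
    values = region.values if isinstance(region, RegionPixels) else region
    x = np.asarray(values, dtype=float).ravel()
    if x.size < NAKAGAMI_MIN_PIXELS:
        raise InsufficientDataError(
            f"Nakagami fit needs >= {NAKAGAMI_MIN_PIXELS} pixels, got {x.size}"
        )
    y = x * x
    omega = float(y.mean())
    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        raise DegenerateTextureError("constant region: Nakagami shape undefined")
    if omega == 0.0:
        raise DegenerateTextureError("all-zero region: Nakagami scale undefined")
    m = omega * omega / var_y
    if m < NAKAGAMI_MIN_SHAPE:
        log.warning("Nakagami shape %.4f clamped to %.1f", m, NAKAGAMI_MIN_SHAPE)
        m = NAKAGAMI_MIN_SHAPE
    return NakagamiParams(m=m, omega=omega)


def quantize_region(
    image: np.ndarray, in_region: np.ndarray, n_levels: int
) -> np.ndarray:
    """Quantize in-region pixels to ``n_levels`` uniform bins over [min, max].

    Out-of-region positions get level -1.  A constant region maps to level 0.
    """
    img = np.asarray(image, dtype=float)
    vals = img[in_region]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.full(img.shape, -1, dtype=np.int64)
    if hi == lo:
        q[in_region] = 0
        return q
    scaled = (img[in_region] - lo) / (hi - lo) * n_levels
    q[in_region] = np.clip(scaled.astype(np.int64), 0, n_levels - 1)
    return q


def glcm_matrices(
    image: np.ndarray,
    mask: np.ndarray,
    tissue: Tissue | str = Tissue.MUSCLE,
    config: GLCMConfig | None = None,
) -> list[np.ndarray]:
    """Normalized symmetric GLCMs, one per direction with >= 1 in-region pair.

    Only pairs with both pixels inside the requested tissue label are counted.
    """
    config = config or GLCMConfig()
    tissue = Tissue(tissue)
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise DimensionMismatchError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    in_region = mask == TISSUE_LABELS[tissue]
    if not in_region.any():
        raise EmptyRegionError(f"no pixels labelled {tissue.value} in mask")
    q = quantize_region(image, in_region, config.n_levels)
    G = config.n_levels
    matrices: list[np.ndarray] = []
    for dr, dc in config.offsets:
        dr, dc = dr * config.distance, dc * config.distance
        counts = _pair_counts(q, in_region, dr, dc, G)
        total = counts.sum()
        if total == 0:
            continue
        matrices.append(counts / total)
    if not matrices:
        raise InsufficientPairsError(
            f"no co-occurring {tissue.value} pixel pair for any direction"
        )
    return matrices


def _pair_counts(
    q: np.ndarray, in_region: np.ndarray, dr: int, dc: int, G: int
) -> np.ndarray:
    """Symmetric pair counts for one offset (both pixels in-region)."""
    rows, cols = q.shape
    r0 = slice(max(0, -dr), min(rows, rows - dr))
    c0 = slice(max(0, -dc), min(cols, cols - dc))
    r1 = slice(max(0, dr), min(rows, rows + dr))
    c1 = slice(max(0, dc), min(cols, cols + dc))
    a, b = q[r0, c0], q[r1, c1]
    ok = in_region[r0, c0] & in_region[r1, c1]
    a, b = a[ok], b[ok]
    counts = np.bincount(a * G + b, minlength=G * G).reshape(G, G).astype(float)
    return counts + counts.T  # symmetric accumulation


def haralick_statistics(P: np.ndarray) -> dict[str, float]:
    """The 13 classical Haralick statistics of one normalized GLCM.

    Natural logarithms throughout; 0·log 0 is taken as 0.  For a degenerate
    (single-level) matrix the correlation is defined as 0 and the information
    measures as 0.
    """
    P = np.asarray(P, dtype=float)
    G = P.shape[0]
    i = np.arange(G, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = math.sqrt(max(float((i - mu_x) ** 2 @ px), 0.0))
    sd_y = math.sqrt(max(float((i - mu_y) ** 2 @ py), 0.0))

    # distributions of i+j (0..2G-2) and |i-j| (0..G-1)
    p_sum = np.zeros(2 * G - 1)
    p_diff = np.zeros(G)
    ii, jj = np.meshgrid(np.arange(G), np.arange(G), indexing="ij")
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2 * G - 1, dtype=float)
    k_diff = np.arange(G, dtype=float)

    def neg_entropy(p: np.ndarray) -> float:
        nz = p > 0
        return float(-(p[nz] * np.log(p[nz])).sum())

    asm = float((P * P).sum())
    contrast = float(k_diff**2 @ p_diff)
    if sd_x > 0 and sd_y > 0:
        correlation = (float((ii * jj * P).sum()) - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    sum_of_squares = float(((ii - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float(k_sum @ p_sum)
    sum_variance = float((k_sum - sum_average) ** 2 @ p_sum)
    sum_entropy = neg_entropy(p_sum)
    entropy = neg_entropy(P.ravel())
    diff_mean = float(k_diff @ p_diff)
    diff_variance = float((k_diff - diff_mean) ** 2 @ p_diff)
    diff_entropy = neg_entropy(p_diff)

    hx = neg_entropy(px)
    hy = neg_entropy(py)
    outer = np.outer(px, py)
    nz = (P > 0) & (outer > 0)
    hxy1 = float(-(P[nz] * np.log(outer[nz])).sum())
    nz2 = outer > 0
    hxy2 = float(-(outer[nz2] * np.log(outer[nz2])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - entropy)), 0.0))

    return dict(
        zip(
            HARALICK_NAMES,
            (
                asm,
                contrast,
                correlation,
                sum_of_squares,
                idm,
                sum_average,
                sum_variance,
                sum_entropy,
                entropy,
                diff_variance,
                diff_entropy,
                imc1,
                imc2,
            ),
        )
    )


def haralick_features(
    image: np.ndarray,
    mask: np.ndarray,
    tissue: Tissue | str = Tissue.MUSCLE,
    config: GLCMConfig | None = None,
) -> dict[str, float]:
    """Across-direction mean of the 13 Haralick statistics for one region."""
    matrices = glcm_matrices(image, mask, tissue, config)
    per_direction = [haralick_statistics(P) for P in matrices]
    return {
        name: float(np.mean([stats[name] for stats in per_direction]))
        for name in HARALICK_NAMES
    }


def assemble_feature_vector(
    record: ImageRecord,
    image: np.ndarray,
    mask: np.ndarray,
    config: GLCMConfig | None = None,
) -> dict[str, float]:
    """The full 22-element named feature vector for one image.

    Component failures are re-raised as :class:`FeatureExtractionError`
    tagged with the record's subject/muscle/side/view.
    """
    config = config or GLCMConfig()
    try:
        muscle = extract_region(image, mask, Tissue.MUSCLE)
        fat = extract_region(image, mask, Tissue.FAT)
        echo = echo_features(muscle, fat)
        nak_muscle = fit_nakagami(muscle)
        nak_fat = fit_nakagami(fat)
        texture = haralick_features(image, mask, config.tissue, config)
    except MyosonoError as exc:
        raise FeatureExtractionError(
            f"feature extraction failed for subject={record.subject_id} "
            f"muscle={record.muscle_group.value} side={record.side.value} "
            f"view={record.view_index}: {exc}"
        ) from exc
    vector = dict(zip(FEATURE_NAMES[:5], echo.as_tuple()))
    vector["nakagami_m_muscle"] = nak_muscle.m
    vector["nakagami_omega_muscle"] = nak_muscle.omega
    vector["nakagami_m_fat"] = nak_fat.m
    vector["nakagami_omega_fat"] = nak_fat.omega
    for name in HARALICK_NAMES:
        vector[f"glcm_{name}"] = texture[name]
    values = np.array([vector[n] for n in FEATURE_NAMES])
    if not np.all(np.isfinite(values)):
        bad = [n for n in FEATURE_NAMES if not np.isfinite(vector[n])]
        raise FeatureExtractionError(
            f"non-finite features {bad} for subject={record.subject_id}"
        )
    return {name: vector[name] for name in FEATURE_NAMES}
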