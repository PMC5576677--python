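"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from myosono import StudyDesign, generate_study, load_manifest, make_preset
from myosono.dataset_io import Diagnosis


# ---------------------------------------------------------------------------
# Brute-force Haralick oracle: enumerates pixel pairs with explicit Python
# loops and applies the textbook GLCM formulas with scalar arithmetic.
# Deliberately independent of the vectorized implementation it checks.
# ---------------------------------------------------------------------------

def oracle_quantize(image, in_region, n_levels):
    vals = [image[r][c] for r in range(len(image)) for c in range(len(image[0]))
            if in_region[r][c]]
    lo, hi = min(vals), max(vals)
    q = {}
    for r in range(len(image)):
        for c in range(len(image[0])):
            if not in_region[r][c]:
                continue
            if hi == lo:
                q[(r, c)] = 0
            else:
                q[(r, c)] = min(int((image[r][c] - lo) / (hi - lo) * n_levels),
                                n_levels - 1)
    return q


def oracle_glcm(q, offset, n_levels, shape):
    """Normalized symmetric GLCM for one offset as a dict {(i, j): p}."""
    dr, dc = offset
    counts: dict = {}
    total = 0
    for (r, c), level in q.items():
        r2, c2 = r + dr, c + dc
        if 0 <= r2 < shape[0] and 0 <= c2 < shape[1] and (r2, c2) in q:
            other = q[(r2, c2)]
            for pair in ((level, other), (other, level)):
                counts[pair] = counts.get(pair, 0) + 1
                total += 1
    if total == 0:
        return None
    return {pair: n / total for pair, n in counts.items()}


def oracle_statistics(P, n_levels):
    """The 13 Haralick statistics of one normalized GLCM, scalar arithmetic."""
    G = n_levels
    px = [sum(P.get((i, j), 0.0) for j in range(G)) for i in range(G)]
    py = [sum(P.get((i, j), 0.0) for i in range(G)) for j in range(G)]
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(G)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(G)))
    p_sum = [0.0] * (2 * G - 1)
    p_diff = [0.0] * G
    for (i, j), p in P.items():
        p_sum[i + j] += p
        p_diff[abs(i - j)] += p

    def H(ps):
        return -sum(p * math.log(p) for p in ps if p > 0)

    asm = sum(p * p for p in P.values())
    contrast = sum(k * k * p_diff[k] for k in range(G))
    if sd_x > 0 and sd_y > 0:
        correlation = (sum(i * j * P.get((i, j), 0.0)
                           for i in range(G) for j in range(G))
                       - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    sum_sq = sum((i - mu_x) ** 2 * P.get((i, j), 0.0)
                 for i in range(G) for j in range(G))
    idm = sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items())
    sum_avg = sum(k * p_sum[k] for k in range(2 * G - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * G - 1))
    sum_ent = H(p_sum)
    entropy = H(P.values())
    d_mean = sum(k * p_diff[k] for k in range(G))
    d_var = sum((k - d_mean) ** 2 * p_diff[k] for k in range(G))
    d_ent = H(p_diff)
    hx, hy = H(px), H(py)
    hxy1 = -sum(p * math.log(px[i] * py[j])
                for (i, j), p in P.items() if px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j])
                for i in range(G) for j in range(G) if px[i] * py[j] > 0)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - entropy)), 0.0))
    return {
        "angular_second_moment": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares_variance": sum_sq,
        "inverse_difference_moment": idm,
        "sum_average": sum_avg,
        "sum_variance": sum_var,
        "sum_entropy": sum_ent,
        "entropy": entropy,
        "difference_variance": d_var,
        "difference_entropy": d_ent,
        "imc1": imc1,
        "imc2": imc2,
    }


def haralick_oracle(image, mask, tissue_label=1, n_levels=32,
                    offsets=((0, 1), (-1, 1), (-1, 0), (-1, -1))):
    """Across-direction mean of the 13 statistics, fully brute-force."""
    image = [list(map(float, row)) for row in np.asarray(image)]
    in_region = [[int(v) == tissue_label for v in row] for row in np.asarray(mask)]
    shape = (len(image), len(image[0]))
    q = oracle_quantize(image, in_region, n_levels)
    per_direction = []
    for offset in offsets:
        P = oracle_glcm(q, offset, n_levels, shape)
        if P is not None:
            per_direction.append(oracle_statistics(P, n_levels))
    assert per_direction, "oracle found no co-occurring pair"
    return {
        name: sum(d[name] for d in per_direction) / len(per_direction)
        for name in per_direction[0]
    }


# ---------------------------------------------------------------------------
# Shared datasets
# ---------------------------------------------------------------------------

TINY_DESIGN = StudyDesign(
    n_subjects={Diagnosis.N: 2, Diagnosis.IBM: 2, Diagnosis.PM: 1, Diagnosis.DM: 1},
    views_per_muscle=1,
    height=64,
    width=64,
    width_deep=64,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A small separable synthetic study on disk: manifest path + records."""
    out = tmp_path_factory.mktemp("tiny_study")
    manifest = generate_study(TINY_DESIGN, make_preset("separable"), out)
    return manifest, load_manifest(manifest)


@pytest.fixture()
def toy_image_mask():
    """A fixed 6x6 image with an irregular muscle/fat mask."""
    rng = np.random.default_rng(42)
    image = rng.integers(0, 256, size=(6, 6)).astype(np.uint8)
    mask = np.zeros((6, 6), dtype=np.uint8)
    mask[1:5, 0:4] = 1
    mask[0, :] = 2
    mask[5, 2:] = 2
    return image, mask
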