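"""Speckle-phantom generator: moments, geometry, determinism, isolation."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from myosono import (
    StudyDesign,
    TissueParams,
    design_records,
    extract_region,
    fit_nakagami,
    generate_phantom,
    generate_study,
    load_manifest,
    make_preset,
    nakagami_mean,
    omega_for_mean,
)
from myosono.dataset_io import Diagnosis, MuscleGroup, Tissue
from myosono.errors import ConfigurationError, GeometryError, OverwriteError

FAT = TissueParams.from_mean(m=1.2, mean=120.0, thickness_fraction=0.25)


class TestPhantom:
    def test_region_mean_matches_closed_form(self):
        # omega chosen so E[X] = 60 via E[X] = Gamma(m+1/2)/Gamma(m)*sqrt(omega/m)
        muscle = TissueParams(m=1.0, omega=omega_for_mean(1.0, 60.0))
        assert nakagami_mean(muscle.m, muscle.omega) == pytest.approx(60.0)
        image, mask = generate_phantom(FAT, muscle, 256, 256, np.random.default_rng(0))
        region = extract_region(image, mask, Tissue.MUSCLE)
        assert region.values.mean() == pytest.approx(60.0, rel=0.02)

    def test_second_moment_matches_omega(self):
        muscle = TissueParams(m=2.0, omega=omega_for_mean(2.0, 80.0) )
        image, mask = generate_phantom(FAT, muscle, 256, 256, np.random.default_rng(1))
        region = extract_region(image, mask, Tissue.MUSCLE)
        x = region.values.astype(float)
        assert (x ** 2).mean() == pytest.approx(muscle.omega, rel=0.02)

    def test_estimator_round_trip(self):
        muscle = TissueParams(m=1.0, omega=omega_for_mean(1.0, 60.0))
        image, mask = generate_phantom(FAT, muscle, 256, 256, np.random.default_rng(2))
        fit = fit_nakagami(extract_region(image, mask, Tissue.MUSCLE))
        assert fit.m == pytest.approx(muscle.m, rel=0.05)
        assert fit.omega == pytest.approx(muscle.omega, rel=0.02)

    def test_mask_band_proportion_within_one_row(self):
        image, mask = generate_phantom(FAT, TissueParams(1.0, 100.0), 97, 50,
                                       np.random.default_rng(3))
        fat_rows = (mask == 2).sum() / 50
        assert abs(fat_rows - 0.25 * 97) <= 1.0

    def test_zero_row_band_is_geometry_error(self):
        thin = TissueParams.from_mean(m=1.2, mean=120.0, thickness_fraction=0.01)
        with pytest.raises(GeometryError):
            generate_phantom(thin, TissueParams(1.0, 100.0), 20, 20,
                             np.random.default_rng(0))

    def test_blur_correlates_texture(self):
        rng = np.random.default_rng(4)
        sharp, mask = generate_phantom(FAT, TissueParams(1.0, omega_for_mean(1.0, 80.0)),
                                       128, 128, rng)
        rng = np.random.default_rng(4)
        smooth, _ = generate_phantom(
            FAT,
            TissueParams(1.0, omega_for_mean(1.0, 80.0), blur_sigma=2.0),
            128, 128, rng,
        )
        def lag1(img):
            region = img[mask == 1].reshape(-1, 128).astype(float)
            return np.corrcoef(region[:, :-1].ravel(), region[:, 1:].ravel())[0, 1]
        assert lag1(smooth) > lag1(sharp) + 0.3

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            TissueParams(m=0.3, omega=1.0)
        with pytest.raises(ConfigurationError):
            TissueParams(m=1.0, omega=1.0, thickness_fraction=1.5)


SMALL = StudyDesign(
    n_subjects={Diagnosis.N: 1, Diagnosis.IBM: 1, Diagnosis.PM: 1, Diagnosis.DM: 1},
    muscle_groups=(MuscleGroup.BICEPS, MuscleGroup.RECTUS_FEMORIS),
    views_per_muscle=2,
    height=48,
    width=48,
    width_deep=32,
    seed=5,
)


def _tree_digest(root: Path) -> dict:
    return {
        p.relative_to(root).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


class TestGenerateStudy:
    def test_full_roster_design_counts(self):
        design = StudyDesign()
        assert sum(design.n_subjects.values()) == 80
        assert design.n_records == 3360
        records = design_records(design)
        assert len(records) == 3360
        assert len({r.subject_id for r in records}) == 80

    def test_every_record_loads_and_validates(self, tmp_path):
        manifest = generate_study(SMALL, make_preset("separable"), tmp_path / "s")
        records = load_manifest(manifest)  # validates rows and file existence
        assert len(records) == SMALL.n_records
        depths = {r.muscle_group: r.depth_cm for r in records}
        assert depths[MuscleGroup.RECTUS_FEMORIS] == 6.0
        assert depths[MuscleGroup.BICEPS] == 4.0

    def test_same_seed_is_byte_identical(self, tmp_path):
        generate_study(SMALL, make_preset("separable"), tmp_path / "a")
        generate_study(SMALL, make_preset("separable"), tmp_path / "b")
        assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")

    def test_changing_affected_params_leaves_normals_untouched(self, tmp_path):
        from myosono import ClassPreset

        base = make_preset("separable")
        altered = ClassPreset(
            name="altered",
            params={
                d: dict(base.tissue_params(d))
                if d is Diagnosis.N
                else {
                    "fat": base.tissue_params(d)["fat"],
                    "muscle": TissueParams.from_mean(m=0.9, mean=140.0, entity_sd=5.0),
                }
                for d in Diagnosis
            },
        )
        generate_study(SMALL, base, tmp_path / "a")
        generate_study(SMALL, altered, tmp_path / "b")
        digests_a = _tree_digest(tmp_path / "a")
        digests_b = _tree_digest(tmp_path / "b")
        # fat band parameters are shared; only muscle params differ by class,
        # so normal subjects' images must be identical across presets
        normal = [k for k in digests_a if k.startswith("images/N")]
        assert normal
        for key in normal:
            assert digests_a[key] == digests_b[key]
        affected = [k for k in digests_a if k.startswith("images/IBM")]
        assert any(digests_a[k] != digests_b[k] for k in affected)

    def test_refuses_to_overwrite_without_force(self, tmp_path):
        out = tmp_path / "s"
        generate_study(SMALL, make_preset("separable"), out)
        with pytest.raises(OverwriteError):
            generate_study(SMALL, make_preset("separable"), out)
        generate_study(SMALL, make_preset("separable"), out, force=True)

    def test_null_preset_assigns_identical_parameters(self):
        preset = make_preset("null")
        params = {d: preset.tissue_params(d) for d in Diagnosis}
        reference = params[Diagnosis.N]
        assert all(p == reference for p in params.values())
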