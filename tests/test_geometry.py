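"""Sphere fitting, angular coordinates, registration and surface patches."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from dvpattern.geometry import (
    SphereFit,
    UnorientableEmbryoError,
    align_to_reference,
    assign_angles,
    estimate_ventral_pole,
    fit_sphere,
    patch_grid_shape,
    patch_means,
)
from dvpattern.synthetic import EmbryoSpec, sample_embryo

ANIMAL = np.array([0.0, 0.0, 1.0])
VENTRAL = np.array([1.0, 0.0, 0.0])


def _cap_points(rng, n=600, radius=350.0, center=(0, 0, 0), jitter=0.0):
    cos_p = rng.uniform(np.cos(np.deg2rad(120.0)), 1.0, n)
    az = rng.uniform(-np.pi, np.pi, n)
    sin_p = np.sqrt(1 - cos_p**2)
    pts = radius * np.column_stack([sin_p * np.cos(az), sin_p * np.sin(az), cos_p])
    if jitter:
        pts = pts + rng.normal(0, jitter, pts.shape)
    return pts + np.asarray(center, dtype=float)


class TestFitSphere:
    def test_exact_points_recovered(self):
        pts = _cap_points(np.random.default_rng(0))
        fit = fit_sphere(pts)
        assert fit.center == pytest.approx((0, 0, 0), abs=1e-9)
        assert fit.radius_um == pytest.approx(350.0, abs=1e-9)
        assert fit.rms_residual_um == pytest.approx(0.0, abs=1e-9)

    def test_jittered_fit_matches_nonlinear_oracle(self):
        """Algebraic fit within 1 um of truth and of a geometric LSQ oracle."""
        rng = np.random.default_rng(1)
        pts = _cap_points(rng, n=2000, center=(12.0, -8.0, 30.0), jitter=2.0)

        def residuals(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        oracle = least_squares(residuals, x0=[0, 0, 0, 300.0]).x
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, (12.0, -8.0, 30.0), atol=1.0)
        assert fit.radius_um == pytest.approx(350.0, abs=1.0)
        assert np.allclose(fit.center, oracle[:3], atol=0.5)
        assert fit.radius_um == pytest.approx(oracle[3], abs=0.5)

    def test_three_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_sphere(np.eye(3))

    def test_coplanar_rejected(self):
        rng = np.random.default_rng(2)
        xy = rng.normal(0, 100, (50, 2))
        pts = np.column_stack([xy, np.zeros(50)])
        with pytest.raises(ValueError):
            fit_sphere(pts)


class TestAssignAngles:
    @pytest.fixture
    def sphere(self):
        return SphereFit((0.0, 0.0, 0.0), 350.0, 0.0)

    def test_convention_anchor_points(self, sphere):
        margin = np.deg2rad(120.0)
        pts = np.array(
            [
                [350 * np.sin(margin), 0.0, 350 * np.cos(margin)],  # ventral margin
                [-350 * np.sin(margin), 0.0, 350 * np.cos(margin)],  # dorsal margin
                [0.0, 0.0, 350.0],  # animal pole
            ]
        )
        df = assign_angles(pts, sphere, VENTRAL, ANIMAL, cap_extent_deg=120.0)
        assert df.dv_angle_deg.iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert df.av_angle_deg.iloc[0] == pytest.approx(-100.0, abs=1e-6)
        assert df.dv_angle_deg.iloc[1] == pytest.approx(180.0, abs=1e-6)
        assert df.av_angle_deg.iloc[1] == pytest.approx(100.0, abs=1e-6)
        assert df.polar_deg.iloc[2] == pytest.approx(0.0, abs=1e-6)

    def test_round_trip_recovers_generator_truth(self, wt_gradient, genes, threshold_model, sphere):
        table = sample_embryo(EmbryoSpec(n_nuclei=500, seed=4), wt_gradient, genes, threshold_model)
        df = assign_angles(table, sphere, VENTRAL, ANIMAL)
        assert np.allclose(df.dv_angle_deg, table.true_dv_angle_deg, atol=0.5)
        assert np.allclose(df.av_angle_deg, table.true_av_angle_deg, atol=0.5)

    def test_translation_invariance_rotation_equivariance(self, sphere):
        rng = np.random.default_rng(5)
        pts = _cap_points(rng, n=300)
        base = assign_angles(pts, sphere, VENTRAL, ANIMAL)
        shifted = assign_angles(
            pts + [50.0, -30.0, 10.0], SphereFit((50.0, -30.0, 10.0), 350.0, 0.0), VENTRAL, ANIMAL
        )
        assert np.allclose(base.dv_angle_deg, shifted.dv_angle_deg, atol=1e-9)
        rot = Rotation.from_euler("z", 40, degrees=True)
        rotated = assign_angles(pts @ rot.as_matrix().T, sphere, rot.apply(VENTRAL), ANIMAL)
        assert np.allclose(base.dv_angle_deg, rotated.dv_angle_deg, atol=1e-9)

    def test_parallel_axes_rejected(self, sphere):
        with pytest.raises(ValueError, match="parallel"):
            assign_angles(np.eye(3) * 350.0, sphere, ANIMAL, ANIMAL)


class TestVentralPole:
    def test_wild_type_pole_recovered(self, wt_gradient, genes, threshold_model):
        table = sample_embryo(
            EmbryoSpec(n_nuclei=4000, noise_sd=0.0, seed=6), wt_gradient, genes, threshold_model
        )
        fit = fit_sphere(table)
        pole = estimate_ventral_pole(table, fit, ANIMAL)
        angle = np.degrees(np.arccos(np.clip(pole @ VENTRAL, -1, 1)))
        assert angle < 2.0

    def test_rotation_equivariance(self, wt_gradient, genes, threshold_model):
        table = sample_embryo(EmbryoSpec(n_nuclei=4000, seed=8), wt_gradient, genes, threshold_model)
        fit = fit_sphere(table)
        pole = estimate_ventral_pole(table, fit, ANIMAL)
        rot = Rotation.from_euler("z", 73, degrees=True)
        rotated = table.copy()
        rotated[["x_um", "y_um", "z_um"]] = table[["x_um", "y_um", "z_um"]].to_numpy() @ rot.as_matrix().T
        pole_rot = estimate_ventral_pole(rotated, fit, ANIMAL)
        assert np.allclose(rot.apply(pole), pole_rot, atol=1e-6)

    def test_flat_profile_unorientable(self, genes, threshold_model):
        from dvpattern.gradients import make_canonical_gradient

        table = sample_embryo(
            EmbryoSpec(n_nuclei=2000, seed=9), make_canonical_gradient("bmp7_mutant"), genes, threshold_model
        )
        with pytest.raises(UnorientableEmbryoError):
            estimate_ventral_pole(table, fit_sphere(table), ANIMAL)


class TestAlignToReference:
    def test_self_alignment_identity(self, wt_cohort):
        rot, moved = align_to_reference(wt_cohort[0], wt_cohort[0])
        assert np.allclose(rot, np.eye(3), atol=1e-6)

    def test_known_rotation_recovered(self, wt_cohort):
        cloud = wt_cohort[0]
        rot30 = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        turned = cloud.copy()
        turned[["x_um", "y_um", "z_um"]] = cloud[["x_um", "y_um", "z_um"]].to_numpy() @ rot30.T
        recovered, moved = align_to_reference(turned, cloud)
        angle = np.degrees(
            np.arccos(np.clip((np.trace(recovered) - 1) / 2, -1, 1))
        )
        assert angle == pytest.approx(30.0, abs=1.0)
        back = moved[["x_um", "y_um", "z_um"]].to_numpy()
        orig = cloud[["x_um", "y_um", "z_um"]].to_numpy()
        assert np.sqrt(np.mean((back - orig) ** 2)) < 10.0

    def test_unorientable_cloud_rejected(self, genes, threshold_model, wt_cohort):
        from dvpattern.gradients import make_canonical_gradient

        flat = sample_embryo(
            EmbryoSpec(n_nuclei=1000, seed=10), make_canonical_gradient("bmp7_mutant"), genes, threshold_model
        )
        with pytest.raises(UnorientableEmbryoError):
            align_to_reference(flat, wt_cohort[0])


class TestPatchMeans:
    def test_default_grid_is_40_by_60(self):
        assert patch_grid_shape(4800) == (40, 60)

    def test_invalid_counts_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="nearest valid"):
            patch_grid_shape(4801)
        with pytest.raises(ValueError, match="nearest valid"):
            patch_grid_shape(4)

    def test_partition_and_uniform_means(self, wt_cohort):
        """Every nucleus lands in exactly one patch; a constant channel stays constant."""
        df = assign_angles(
            wt_cohort[0], SphereFit((0.0, 0.0, 0.0), 350.0, 0.0), VENTRAL, ANIMAL
        )
        df = df.assign(uniform_au=5.0)
        grid = patch_means(df, n_patches=4800, channels=["uniform_au"])
        assert len(grid) == 4800
        assert grid.n_nuclei.sum() == len(df)
        non_empty = grid[grid.n_nuclei > 0]
        assert np.allclose(non_empty.mean_uniform_au, 5.0)
        assert grid[grid.n_nuclei == 0].mean_uniform_au.isna().all()
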