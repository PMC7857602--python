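"""Normalization, band profiles, lowess smoothing/slopes, grid heat maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dvpattern.geometry import SphereFit, assign_angles
from dvpattern.profiles import (
    AngularProfile,
    band_profile,
    grid_heatmap,
    normalize_percentile,
    normalize_to_bead,
    smooth_and_slope,
)

SPHERE = SphereFit((0.0, 0.0, 0.0), 350.0, 0.0)
VENTRAL = np.array([1.0, 0.0, 0.0])
ANIMAL = np.array([0.0, 0.0, 1.0])


def _ring_table(rng, n=3000, polar_deg=96.0, polar_spread=3.0, intensity=None):
    """Nuclei on a band of latitudes, azimuth uniform over the circle."""
    polar = np.deg2rad(rng.uniform(polar_deg - polar_spread, polar_deg + polar_spread, n))
    azim = rng.uniform(-np.pi, np.pi, n)
    pts = 350.0 * np.column_stack(
        [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)]
    )
    df = pd.DataFrame(pts, columns=["x_um", "y_um", "z_um"])
    df = assign_angles(df, SPHERE, VENTRAL, ANIMAL)
    df["value_au"] = intensity(df) if intensity is not None else 1.0
    return df


class TestNormalizeToBead:
    def test_identity_and_linearity(self):
        x = np.array([1.0, 5.0, 10.0])
        assert np.allclose(normalize_to_bead(x, 100.0, 100.0), x)
        assert np.allclose(normalize_to_bead(x, 50.0, 100.0), 2 * x)

    def test_two_sessions_converge(self, wt_cohort):
        """A known gain between sessions disappears after bead normalization."""
        raw = wt_cohort[0]["psmad5_au"].to_numpy()
        session_b = raw * 1.7  # imaged hotter; its bead reads 1.7x too
        fixed = normalize_to_bead(session_b, observed_bead=170.0, reference_bead=100.0)
        assert np.allclose(fixed, raw)

    def test_nonpositive_bead_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_bead([1.0], 0.0, 100.0)


class TestNormalizePercentile:
    def test_endpoint_mapping(self):
        ref = np.linspace(0, 100, 1000)
        k = 50
        m_low = np.median(np.sort(ref)[:k])
        m_high = np.median(np.sort(ref)[-k:])
        out = normalize_percentile([m_low, m_high], ref)
        assert out == pytest.approx([0.0, 100.0], abs=1e-9)

    def test_uniform_grid_recovers_affine_map(self):
        """Reference 0..100 -> anchors near 2.5 and 97.5 (brute-force medians)."""
        ref = np.arange(0.0, 100.5, 0.5)
        out = normalize_percentile(np.array([2.5, 50.0]), ref)
        # brute force
        s = np.sort(ref)
        k = int(np.floor(0.05 * len(s)))
        lo, hi = np.median(s[:k]), np.median(s[-k:])
        assert np.allclose(out, 100 * (np.array([2.5, 50.0]) - lo) / (hi - lo))

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_percentile([1.0], np.full(100, 3.0))

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            normalize_percentile([1.0], np.arange(10))

    @given(st.lists(st.floats(0, 1000), min_size=40, max_size=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force(self, ref):
        ref = np.asarray(ref)
        s = np.sort(ref)
        k = max(1, int(np.floor(0.05 * len(s))))
        lo, hi = np.median(s[:k]), np.median(s[-k:])
        x = ref[:5]
        if hi <= lo:
            with pytest.raises(ValueError):
                normalize_percentile(x, ref)
        else:
            assert np.allclose(
                normalize_percentile(x, ref), 100 * (x - lo) / (hi - lo)
            )


class TestBandProfile:
    def test_uniform_intensity(self):
        df = _ring_table(np.random.default_rng(0), intensity=lambda d: np.full(len(d), 5.0))
        prof = band_profile(df, "DV", 80.0, 40.0, 2.0, "value_au", 350.0)
        good = np.isfinite(prof.mean_intensity)
        assert good.sum() > 80
        assert np.allclose(prof.mean_intensity[good], 5.0)

    def test_bin_means_match_brute_force(self):
        """Intensity equal to the DV angle: bin means approximate bin centers."""
        df = _ring_table(np.random.default_rng(1), intensity=lambda d: d.dv_angle_deg)
        prof = band_profile(df, "DV", 80.0, 40.0, 2.0, "value_au", 350.0)
        in_band = np.abs(df.polar_deg - 96.0) <= np.degrees(20.0 / 350.0)
        sel = df[in_band]
        for i, c in enumerate(prof.bin_centers):
            sub = sel[(sel.dv_angle_deg >= c - 1.0) & (sel.dv_angle_deg < c + 1.0)]
            if len(sub):
                assert prof.mean_intensity[i] == pytest.approx(sub.value_au.mean())
                assert prof.mean_intensity[i] == pytest.approx(c, abs=1.0)

    def test_empty_band_rejected(self):
        df = _ring_table(np.random.default_rng(2), n=50, polar_deg=30.0, polar_spread=1.0)
        with pytest.raises(ValueError, match="empty band"):
            band_profile(df, "DV", 100.0, 40.0, 2.0, "value_au", 350.0)

    def test_av_axis_band(self):
        rng = np.random.default_rng(3)
        # nuclei spread over the whole cap so the meridian band is populated
        polar = np.arccos(rng.uniform(np.cos(np.deg2rad(120.0)), 1.0, 20000))
        azim = rng.uniform(-np.pi, np.pi, 20000)
        pts = 350.0 * np.column_stack(
            [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)]
        )
        df = assign_angles(pd.DataFrame(pts, columns=["x_um", "y_um", "z_um"]), SPHERE, VENTRAL, ANIMAL)
        df["value_au"] = 7.0
        prof = band_profile(df, "AV", 0.0, 40.0, 5.0, "value_au", 350.0)
        good = np.isfinite(prof.mean_intensity)
        assert good.sum() > 20
        assert np.allclose(prof.mean_intensity[good], 7.0)
        assert prof.bin_centers.min() < -80 and prof.bin_centers.max() > 80


class TestSmoothAndSlope:
    def _profile_from_curve(self, fn, step=1.0):
        centers = np.arange(0.0, 180.0, step) + step / 2
        y = fn(centers)
        return AngularProfile(
            axis="DV",
            channel="psmad5_au",
            band_center=80.0,
            band_width_um=40.0,
            bin_centers=centers,
            mean_intensity=y,
            n_per_bin=np.ones_like(centers, dtype=int),
        )

    def test_linear_profile_slope_one(self):
        prof = smooth_and_slope(self._profile_from_curve(lambda t: 100.0 - t * 0.55))
        interior = slice(5, -5)
        assert np.allclose(prof.slope_magnitude[interior], 0.55, atol=0.01)
        assert np.allclose(prof.smoothed_intensity[interior], prof.mean_intensity[interior], atol=0.1)

    def test_canonical_slope_at_sizzled_boundary(self, wt_gradient):
        """Noiseless canonical profile at 1 degree: slope at 75 within 5% of 1.4."""
        prof = smooth_and_slope(self._profile_from_curve(wt_gradient))
        at_75 = np.interp(75.0, prof.bin_centers, prof.slope_magnitude)
        assert at_75 == pytest.approx(1.4, rel=0.05)

    def test_matches_analytic_derivative_oracle(self, wt_gradient):
        """Smoothed slope tracks the spline derivative on dense noiseless input."""
        prof = smooth_and_slope(self._profile_from_curve(wt_gradient), 0.1)
        interior = (prof.bin_centers > 10) & (prof.bin_centers < 170)
        truth = wt_gradient.slope_magnitude(prof.bin_centers[interior])
        assert np.max(np.abs(prof.slope_magnitude[interior] - truth)) < 0.12

    def test_too_few_bins_rejected(self):
        prof = self._profile_from_curve(lambda t: t, step=30.0)
        with pytest.raises(ValueError, match="at least 10"):
            smooth_and_slope(prof)


class TestGridHeatmap:
    def _table(self, av_abs, azim_deg, value):
        polar = np.deg2rad(np.abs(av_abs) / 100.0 * 120.0)
        azim = np.deg2rad(azim_deg)
        pts = 350.0 * np.column_stack(
            [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)]
        )
        df = pd.DataFrame(pts, columns=["x_um", "y_um", "z_um"])
        df = assign_angles(df, SPHERE, VENTRAL, ANIMAL)
        df["value_au"] = value
        return df

    def test_single_hot_cell(self):
        df = self._table(np.array([5.0, 5.0]), np.array([3.0, -3.0]), np.array([10.0, 10.0]))
        hm = grid_heatmap(df, "value_au")
        assert hm.values[0, 0] == 1.0
        assert hm.values.sum() == 1.0

    def test_bilateral_symmetry_preserved_by_folding(self):
        rng = np.random.default_rng(4)
        av = rng.uniform(0, 100, 800)
        az = rng.uniform(0, 180, 800)
        value = rng.uniform(0, 50, 800)
        # mirror every nucleus across the midline with the same intensity
        df = self._table(np.concatenate([av, av]), np.concatenate([az, -az]), np.concatenate([value, value]))
        one_half = self._table(av, az, value)
        hm = grid_heatmap(df, "value_au")
        hm_half = grid_heatmap(one_half, "value_au")
        assert np.allclose(hm.values, hm_half.values, atol=1e-9)

    def test_dv_profile_is_column_sum(self, wt_quantified, wt_cohort):
        from dvpattern.geometry import fit_sphere, estimate_ventral_pole

        table = wt_cohort[0]
        fit = fit_sphere(table)
        pole = estimate_ventral_pole(table, fit, ANIMAL)
        df = assign_angles(table, fit, pole, ANIMAL)
        hm = grid_heatmap(df, "fish_sizzled_au")
        assert np.allclose(hm.dv_profile, hm.values.sum(axis=0))
        assert hm.values.max() == pytest.approx(1.0)

    def test_empty_rejected(self):
        df = self._table(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError, match="no nuclei"):
            grid_heatmap(df, "value_au")
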