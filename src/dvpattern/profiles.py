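"""Angular intensity profiles, normalization, smoothing and grid heat maps.

A *band profile* is the per-bin mean channel intensity of nuclei lying in a
40-um-wide band of cells on the embryo sphere, binned by DV (or AV) angle --
the quantity from which gradient levels, slopes and expression boundaries
are read.  Smoothing uses robust locally weighted regression (lowess) so a
sharp expression front is preserved while measurement noise is suppressed;
slopes come from centered finite differences of the smoothed curve.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AngularProfile",
    "GridHeatmap",
    "normalize_to_bead",
    "normalize_percentile",
    "band_profile",
    "smooth_and_slope",
    "grid_heatmap",
]


@dataclass(frozen=True)
class AngularProfile:
    """Mean intensity versus angle in a band of cells.

    ``bin_centers`` are degrees along the chosen axis (DV angle in [0, 180]
    or AV arc position in [-100, 100]); empty bins carry NaN means and are
    propagated as missing, never as zero.
    """

    axis: str  # "DV" or "AV"
    channel: str
    band_center: float
    band_width_um: float
    bin_centers: np.ndarray
    mean_intensity: np.ndarray
    n_per_bin: np.ndarray
    smoothed_intensity: np.ndarray | None = None
    slope_magnitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.axis not in ("DV", "AV"):
            raise ValueError("axis must be 'DV' or 'AV'")
        if self.band_width_um <= 0:
            raise ValueError("band_width_um must be > 0")
        n = len(self.bin_centers)
        for name in ("mean_intensity", "n_per_bin", "smoothed_intensity", "slope_magnitude"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length differs from bin_centers")

    @property
    def max_smoothed(self) -> float:
        if self.smoothed_intensity is None:
            raise ValueError("profile not smoothed yet")
        return float(np.nanmax(self.smoothed_intensity))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": self.bin_centers,
                "mean_au": self.mean_intensity,
                "n": self.n_per_bin,
                "smoothed_au": (
                    np.full_like(self.bin_centers, np.nan)
                    if self.smoothed_intensity is None
                    else self.smoothed_intensity
                ),
                "slope_au_per_deg": (
                    np.full_like(self.bin_centers, np.nan)
                    if self.slope_magnitude is None
                    else self.slope_magnitude
                ),
            }
        )


@dataclass(frozen=True)
class GridHeatmap:
    """8 x 8 (AV x DV) expression heat map normalized to its maximum bin."""

    channel: str
    values: np.ndarray  # shape (8, 8), rows = AV (pole -> margin), cols = DV
    dv_profile: np.ndarray  # column sums, length 8

    def __post_init__(self) -> None:
        if self.values.shape != (8, 8):
            raise ValueError("heat map must be 8 x 8")
        if len(self.dv_profile) != 8:
            raise ValueError("dv_profile must have 8 values")


def normalize_to_bead(intensities, observed_bead: float, reference_bead: float):
    """Rescale intensities by a calibration-bead reading.

    Multiplies every value by ``reference_bead / observed_bead`` so sessions
    imaged at different gains land on one scale.
    """
    if observed_bead <= 0 or reference_bead <= 0:
        raise ValueError("bead intensities must be > 0")
    return np.asarray(intensities, dtype=float) * (reference_bead / observed_bead)


def normalize_percentile(cell_intensities, reference_cells):
    """Map intensities onto the 0-100 scale set by a reference population.

    0 corresponds to the median of the bottom 5% of the reference cells and
    100 to the median of the top 5% (wild-type early gastrula embryos in
    practice); values outside [0, 100] are allowed.
    """
    ref = np.sort(np.asarray(reference_cells, dtype=float))
    if len(ref) < 20:
        raise ValueError("reference needs at least 20 cells")
    k = max(1, int(np.floor(0.05 * len(ref))))
    m_low = float(np.median(ref[:k]))
    m_high = float(np.median(ref[-k:]))
    if m_high <= m_low:
        raise ValueError("degenerate reference: top and bottom 5% medians coincide")
    x = np.asarray(cell_intensities, dtype=float)
    return 100.0 * (x - m_low) / (m_high - m_low)


def band_profile(
    points: pd.DataFrame,
    axis: str,
    band_center: float,
    band_width_um: float,
    bin_width_deg: float,
    channel: str,
    radius_um: float,
    cap_extent_deg: float = 120.0,
) -> AngularProfile:
    """Bin channel intensity along one axis within a band of cells.

    DV: the band is the ring of nuclei whose arc distance from the parallel
    at AV position ``band_center`` is at most ``band_width_um / 2``; nuclei
    are binned by folded DV angle over [0, 180].  AV: the band hugs the
    ventral -> animal -> dorsal meridian (arc distance from that great
    circle <= half the band width); nuclei are binned by AV arc position
    over [-100, 100].
    """
    if band_width_um <= 0:
        raise ValueError("band_width_um must be > 0")
    if bin_width_deg <= 0:
        raise ValueError("bin_width_deg must be > 0")
    needed = {"polar_deg", "azimuth_deg", "dv_angle_deg", "av_angle_deg", channel}
    if not needed <= set(points.columns):
        missing = sorted(needed - set(points.columns))
        raise ValueError(f"missing columns: {', '.join(missing)} (assign angles first)")
    half_arc = band_width_um / 2.0
    polar = np.deg2rad(points["polar_deg"].to_numpy(dtype=float))
    if axis == "DV":
        polar_center = np.deg2rad(abs(band_center) / 100.0 * cap_extent_deg)
        arc = radius_um * np.abs(polar - polar_center)
        in_band = arc <= half_arc
        angle = points["dv_angle_deg"].to_numpy(dtype=float)
        lo, hi = 0.0, 180.0
    elif axis == "AV":
        azim = np.deg2rad(points["azimuth_deg"].to_numpy(dtype=float))
        # Distance from the meridian plane spanned by ventral + animal axes.
        arc = radius_um * np.abs(np.arcsin(np.sin(polar) * np.sin(azim)))
        in_band = arc <= half_arc
        angle = points["av_angle_deg"].to_numpy(dtype=float)
        lo, hi = -100.0, 100.0
    else:
        raise ValueError("axis must be 'DV' or 'AV'")
    if not np.any(in_band):
        raise ValueError("empty band: no nuclei within the requested band")
    angle = angle[in_band]
    intens = points.loc[in_band, channel].to_numpy(dtype=float)

    n_bins = int(np.ceil((hi - lo) / bin_width_deg))
    edges = lo + bin_width_deg * np.arange(n_bins + 1)
    idx = np.clip(np.floor((angle - lo) / bin_width_deg).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=intens, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return AngularProfile(
        axis=axis,
        channel=channel,
        band_center=band_center,
        band_width_um=band_width_um,
        bin_centers=centers,
        mean_intensity=means,
        n_per_bin=counts,
    )


def smooth_and_slope(
    profile: AngularProfile,
    smoothing_fraction: float = 0.2,
    iterations: int = 2,
) -> AngularProfile:
    """Lowess-smooth a profile and differentiate it.

    Robust locally weighted regression (``iterations`` re-weighting passes)
    of mean intensity on angle; the slope magnitude per bin is the absolute
    centered finite difference of the smoothed curve, in A.U./degree.
    Empty bins stay missing.
    """
    good = np.isfinite(profile.mean_intensity)
    if good.sum() < 10:
        raise ValueError("need at least 10 non-empty bins to smooth")
    x = profile.bin_centers[good]
    y = profile.mean_intensity[good]
    # Robustify only when there is noise to robustify against: on (near-)
    # noiseless input the bisquare weights are computed from curvature
    # residuals and arbitrarily zero out high-curvature points, corrupting
    # the fit.  Noise scale estimated from second differences (a smooth
    # curve contributes O(h^2 f'') there, white noise sd*sqrt(6)).
    d2 = np.diff(y, 2)
    noise_scale = 0.0
    if len(d2):
        noise_scale = float(np.median(np.abs(d2 - np.median(d2)))) / (0.6745 * np.sqrt(6))
    it = iterations if noise_scale > 1e-3 * (1.0 + np.ptp(y)) else 0
    smoothed = sm.nonparametric.lowess(
        y, x, frac=smoothing_fraction, it=it, return_sorted=False
    )
    slope = np.abs(np.gradient(smoothed, x))
    full_s = np.full(len(profile.bin_centers), np.nan)
    full_g = np.full(len(profile.bin_centers), np.nan)
    full_s[good] = smoothed
    full_g[good] = slope
    return dataclasses.replace(
        profile, smoothed_intensity=full_s, slope_magnitude=full_g
    )


def grid_heatmap(points: pd.DataFrame, channel: str) -> GridHeatmap:
    """8 x 8 expression heat map of one channel over the embryo surface.

    Nuclei are partitioned into 8 AV rows (animal pole to margin, by |AV|
    position) by 16 DV columns spanning the full circumference; the two
    bilaterally symmetric halves are averaged together into 8 DV columns,
    the map is normalized by its maximum bin, and the DV profile is the
    column sum over AV rows.
    """
    needed = {"azimuth_deg", "av_angle_deg", channel}
    if not needed <= set(points.columns):
        missing = sorted(needed - set(points.columns))
        raise ValueError(f"missing columns: {', '.join(missing)} (assign angles first)")
    if len(points) == 0:
        raise ValueError("no nuclei to grid")
    av = np.abs(points["av_angle_deg"].to_numpy(dtype=float))
    azim = points["azimuth_deg"].to_numpy(dtype=float)
    intens = points[channel].to_numpy(dtype=float)

    row = np.clip(np.floor(av / 100.0 * 8).astype(int), 0, 7)
    col16 = np.clip(np.floor((azim + 180.0) / 360.0 * 16).astype(int), 0, 15)

    sums = np.zeros((8, 16))
    counts = np.zeros((8, 16))
    np.add.at(sums, (row, col16), intens)
    np.add.at(counts, (row, col16), 1.0)
    with np.errstate(invalid="ignore"):
        mean16 = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)

    # Fold: full column c covers azimuth [-180 + 22.5 c, ...); its |azimuth|
    # bin k = |c - 7.5| rounded down pairs c with 15 - c.
    values = np.zeros((8, 8))
    for k in range(8):
        pair = np.stack([mean16[:, 8 + k], mean16[:, 7 - k]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-empty pairs
            folded = np.nanmean(pair, axis=0)
        values[:, k] = np.where(np.isfinite(folded), folded, 0.0)
    vmax = values.max()
    if vmax > 0:
        values = values / vmax
    dv_profile = values.sum(axis=0)
    return GridHeatmap(channel=channel, values=values, dv_profile=dv_profile)
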