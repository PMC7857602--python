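"""Spherical geometry: sphere fitting, angular coordinates, registration, patches.

Raw nuclei positions (um) are reduced to two angular coordinates on the
embryo sphere: a dorsoventral angle in [0, 180] degrees (0 = ventral-most,
180 = dorsal-most, the two lateral halves folded together) and an
animal-vegetal arc position scaled to [-100, 100] (ventral margin -100,
animal pole 0, dorsal margin +100).  Embryos are registered to each other by
a rigid rotation aligning their pole frames, and surface intensities are
averaged over a deterministic triangular latitude-longitude tessellation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SphereFit",
    "UnorientableEmbryoError",
    "fit_sphere",
    "assign_angles",
    "estimate_ventral_pole",
    "align_to_reference",
    "patch_grid_shape",
    "patch_means",
]


class UnorientableEmbryoError(ValueError):
    """Raised when a cloud has no usable pSmad5 gradient to orient by."""


@dataclass(frozen=True)
class SphereFit:
    center: tuple[float, float, float]
    radius_um: float
    rms_residual_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be > 0")
        if self.rms_residual_um < 0:
            raise ValueError("rms residual must be >= 0")


def _as_points(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        pts = points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array or a nuclei table")
    return pts


def fit_sphere(points) -> SphereFit:
    """Algebraic least-squares sphere through a point cloud.

    Solves the linear system ``2 p . c + k = |p|^2`` for the center ``c`` and
    ``k = r^2 - |c|^2`` (Coope's method), which minimizes the summed squared
    algebraic residuals.  Needs >= 4 points not all on one plane.
    """
    pts = _as_points(points)
    if len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 points")
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts**2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise ValueError("points are coplanar (or otherwise degenerate); cannot fit a sphere")
    center, k = sol[:3], sol[3]
    r2 = k + center @ center
    if r2 <= 0:
        raise ValueError("degenerate configuration: non-positive fitted radius")
    radius = float(np.sqrt(r2))
    radial = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((radial - radius) ** 2)))
    return SphereFit(tuple(float(c) for c in center), radius, rms)


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} must be a nonzero vector")
    return v / n


def _frame(ventral_direction, animal_direction) -> np.ndarray:
    """Right-handed orthonormal frame [ventral, lateral, animal] as rows."""
    a = _unit(animal_direction, "animal_direction")
    v = np.asarray(ventral_direction, dtype=float)
    v = v - (v @ a) * a
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise ValueError("ventral and animal directions must not be parallel")
    v = v / n
    w = np.cross(a, v)
    return np.vstack([v, w, a])


def assign_angles(
    points,
    sphere: SphereFit,
    ventral_direction,
    animal_direction,
    cap_extent_deg: float = 120.0,
) -> pd.DataFrame:
    """Attach angular coordinates to a nuclei table.

    Adds ``polar_deg`` (angle from the animal pole), ``azimuth_deg`` (signed
    angle from the ventral meridian in (-180, 180]), ``dv_angle_deg``
    (= |azimuth|, both lateral halves folded into [0, 180]) and
    ``av_angle_deg`` (signed arc position along the ventral -> animal ->
    dorsal great circle, the cap extent scaled to [-100, 100]; ventral half
    negative).
    """
    frame = _frame(ventral_direction, animal_direction)
    if isinstance(points, pd.DataFrame):
        df = points.copy()
    else:
        pts = _as_points(points)
        df = pd.DataFrame(pts, columns=["x_um", "y_um", "z_um"])
    pts = _as_points(df) - np.asarray(sphere.center, dtype=float)
    local = pts @ frame.T  # columns: ventral, lateral, animal components
    r = np.linalg.norm(local, axis=1)
    if np.any(r == 0):
        raise ValueError("a point coincides with the sphere center")
    polar = np.degrees(np.arccos(np.clip(local[:, 2] / r, -1.0, 1.0)))
    azimuth = np.degrees(np.arctan2(local[:, 1], local[:, 0]))
    dv = np.abs(azimuth)
    av = np.where(dv < 90.0, -1.0, 1.0) * 100.0 * polar / cap_extent_deg
    df["polar_deg"] = polar
    df["azimuth_deg"] = azimuth
    df["dv_angle_deg"] = dv
    df["av_angle_deg"] = av
    return df


def estimate_ventral_pole(
    points,
    sphere: SphereFit,
    animal_direction,
    channel: str = "psmad5_au",
    top_fraction: float = 0.10,
    min_concentration: float = 0.3,
) -> np.ndarray:
    """Estimate the ventral direction from the pSmad5 high point.

    Takes the top decile of nuclei by pSmad5, forms their intensity-weighted
    mean radial direction, projects it orthogonal to the animal axis and
    normalizes.  A flat (e.g. bmp7-mutant) signal gives directions spread
    uniformly in azimuth whose projected resultant is short; such clouds are
    flagged as unorientable rather than silently oriented by noise.
    """
    if channel not in points.columns:
        raise ValueError(f"channel {channel!r} missing from the table")
    intens = points[channel].to_numpy(dtype=float)
    if np.ptp(intens) == 0:
        raise UnorientableEmbryoError("constant signal: cannot orient the embryo")
    a = _unit(animal_direction, "animal_direction")
    pts = _as_points(points) - np.asarray(sphere.center, dtype=float)
    u = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    cutoff = np.quantile(intens, 1.0 - top_fraction)
    sel = intens >= cutoff
    w = intens[sel]
    proj = u[sel] - np.outer(u[sel] @ a, a)
    norms = np.linalg.norm(proj, axis=1)
    ok = norms > 1e-12
    if not np.any(ok):
        raise UnorientableEmbryoError("top-intensity nuclei all sit on the animal axis")
    resultant = (w[ok, None] * proj[ok] / norms[ok, None]).sum(axis=0)
    # Concentration: resultant length relative to total weight; ~1 when the
    # bright nuclei share an azimuth, ~0 for azimuthally uniform noise.
    concentration = np.linalg.norm(resultant) / w[ok].sum()
    if concentration < min_concentration:
        raise UnorientableEmbryoError(
            f"no coherent intensity pole (concentration {concentration:.2f} < "
            f"{min_concentration}); gradient too flat to orient"
        )
    return resultant / np.linalg.norm(resultant)


def align_to_reference(
    cloud: pd.DataFrame,
    reference: pd.DataFrame,
    animal_direction=(0.0, 0.0, 1.0),
    channel: str = "psmad5_au",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rigidly register a nuclei cloud onto a reference cloud.

    Both clouds are sphere-fitted and pole-estimated; the rotation maps the
    cloud's (ventral, lateral, animal) frame onto the reference's, and the
    returned table has positions rotated about the cloud center and
    translated onto the reference center.  Raises
    :class:`UnorientableEmbryoError` if either cloud has no gradient.
    """
    sph_c = fit_sphere(cloud)
    sph_r = fit_sphere(reference)
    v_c = estimate_ventral_pole(cloud, sph_c, animal_direction, channel)
    v_r = estimate_ventral_pole(reference, sph_r, animal_direction, channel)
    f_c = _frame(v_c, animal_direction)
    f_r = _frame(v_r, animal_direction)
    rotation = f_r.T @ f_c
    pts = _as_points(cloud) - np.asarray(sph_c.center)
    moved = pts @ rotation.T + np.asarray(sph_r.center)
    out = cloud.copy()
    out[["x_um", "y_um", "z_um"]] = moved
    return rotation, out


def patch_grid_shape(n_patches: int) -> tuple[int, int]:
    """Rows x columns of the triangular tessellation with ``n_patches`` triangles.

    Each latitude-longitude quad is split into two triangles, so n_patches
    must be even (and >= 8); among the factorizations rows * cols =
    n_patches / 2 the one closest to the 2:3 row:column aspect of the default
    4,800-triangle (40 x 60) grid is chosen.
    """
    if n_patches < 8 or n_patches % 2:
        lower = max(8, (n_patches // 2) * 2)
        raise ValueError(
            f"n_patches must be an even count >= 8 (got {n_patches}); "
            f"nearest valid counts: {lower}, {lower + 2}"
        )
    quads = n_patches // 2
    best = None
    for rows in range(1, int(np.sqrt(quads)) + 1):
        if quads % rows:
            continue
        cols = quads // rows
        score = abs(cols / rows - 1.5)
        if best is None or score < best[0]:
            best = (score, rows, cols)
    assert best is not None
    return best[1], best[2]


def patch_means(
    points: pd.DataFrame,
    n_patches: int = 4800,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average channel intensities over a triangular surface tessellation.

    The sphere is divided into ``rows`` latitude bands (polar angle 0-180)
    by ``cols`` longitude sectors (azimuth -180..180), each quad split along
    its diagonal into two triangles, giving exactly ``n_patches`` patches.
    Every nucleus lands in exactly one patch; empty patches are reported
    with n = 0 and missing means, never zero-filled.
    """
    required = {"polar_deg", "azimuth_deg"}
    if not required <= set(points.columns):
        raise ValueError("assign angles first: polar_deg/azimuth_deg columns missing")
    rows, cols = patch_grid_shape(n_patches)
    if channels is None:
        channels = [
            c for c in points.columns if c == "psmad5_au" or c.startswith("fish_")
        ]
    polar = points["polar_deg"].to_numpy(dtype=float)
    azim = points["azimuth_deg"].to_numpy(dtype=float)

    u = polar / 180.0 * rows
    row = np.clip(np.floor(u).astype(int), 0, rows - 1)
    v = (azim + 180.0) / 360.0 * cols
    col = np.clip(np.floor(v).astype(int), 0, cols - 1)
    fu = u - row
    fv = v - col
    tri = (fu + fv >= 1.0).astype(int)  # lower/upper triangle of the quad
    patch_id = (row * cols + col) * 2 + tri

    grid = pd.DataFrame(
        {
            "patch_id": np.arange(n_patches),
        }
    )
    grid["row"] = grid["patch_id"] // 2 // cols
    grid["col"] = grid["patch_id"] // 2 % cols
    grid["triangle"] = grid["patch_id"] % 2
    grid["polar_center_deg"] = (grid["row"] + 0.5) * 180.0 / rows
    grid["azimuth_center_deg"] = -180.0 + (grid["col"] + 0.5) * 360.0 / cols

    by = points.assign(patch_id=patch_id).groupby("patch_id")
    counts = by.size().reindex(grid["patch_id"], fill_value=0)
    grid["n_nuclei"] = counts.to_numpy()
    for ch in channels:
        means = by[ch].mean().reindex(grid["patch_id"])
        grid[f"mean_{ch}"] = means.to_numpy()
    return grid
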