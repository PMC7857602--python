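"""Expression-boundary calling and pSmad5 readouts at boundaries.

A gene's expression boundary is the angular position where its smoothed
FISH profile falls to a fraction (default 10%) of its maximum, located by
linear interpolation between bracketing bins while walking outward from the
high-expression end.  At the called boundary the pSmad5 level (A.U. and %
of the profile maximum) and gradient slope magnitude are interpolated from
the smoothed pSmad5 profile of the same embryo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import AngularProfile

__all__ = [
    "BoundaryCall",
    "detect_boundary",
    "readout_at_boundary",
    "expressing_fraction",
    "above_threshold_fraction",
]

NO_BOUNDARY = "no_boundary"
BOUNDARY_AT_EDGE = "boundary_at_edge"
MULTIPLE_CROSSINGS = "multiple_crossings"


@dataclass(frozen=True)
class BoundaryCall:
    gene: str
    embryo_id: str
    axis: str
    boundary_angle_deg: float
    level_au: float
    level_pct_max: float
    slope_au_per_deg: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "gene": self.gene,
            "embryo_id": self.embryo_id,
            "axis": self.axis,
            "boundary_angle_deg": self.boundary_angle_deg,
            "level_au": self.level_au,
            "level_pct_max": self.level_pct_max,
            "slope_au_per_deg": self.slope_au_per_deg,
            "flags": ";".join(self.flags),
        }
        return d


def _profile_curve(profile: AngularProfile) -> tuple[np.ndarray, np.ndarray]:
    y = (
        profile.smoothed_intensity
        if profile.smoothed_intensity is not None
        else profile.mean_intensity
    )
    good = np.isfinite(y)
    return profile.bin_centers[good], np.asarray(y)[good]


def detect_boundary(
    expression_profile: AngularProfile, fraction: float = 0.10
) -> tuple[float, tuple[str, ...]]:
    """Angle where smoothed expression first falls below ``fraction`` x max.

    Walks from the profile maximum toward the low-expression end and linearly
    interpolates the crossing between the bracketing bins.  Returns
    ``(angle, flags)``; flags mark profiles with no callable boundary
    (flat or all-zero), boundaries clamped at the domain edge, and profiles
    that re-cross the cutoff beyond the first crossing.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    x, y = _profile_curve(expression_profile)
    if len(x) == 0 or np.nanmax(y) <= 0:
        return float("nan"), (NO_BOUNDARY,)
    cutoff = fraction * float(np.max(y))
    i_max = int(np.argmax(y))

    def walk(indices: np.ndarray) -> tuple[float, tuple[str, ...]] | None:
        prev = i_max
        for pos, k in enumerate(indices):
            if y[k] < cutoff:
                x0, x1 = x[prev], x[k]
                y0, y1 = y[prev], y[k]
                angle = x0 + (y0 - cutoff) / (y0 - y1) * (x1 - x0)
                flags: tuple[str, ...] = ()
                # anything beyond the crossing rising above the cutoff again?
                if any(y[j] >= cutoff for j in indices[pos + 1 :]):
                    flags = (MULTIPLE_CROSSINGS,)
                return float(angle), flags
            prev = k
        return None

    forward = np.arange(i_max + 1, len(x))
    backward = np.arange(i_max - 1, -1, -1)
    hit = walk(forward)
    if hit is None:
        hit = walk(backward)
    if hit is None:
        edge = x[-1] if len(forward) >= len(backward) else x[0]
        return float(edge), (BOUNDARY_AT_EDGE,)
    return hit


def readout_at_boundary(
    psmad5_profile: AngularProfile,
    boundary_angle_deg: float,
    gene: str = "",
    embryo_id: str = "",
    flags: Sequence[str] = (),
) -> BoundaryCall:
    """Interpolate pSmad5 level and slope at a boundary angle.

    Level and slope magnitude are linearly interpolated from the smoothed
    pSmad5 profile; the percent-of-max readout is taken against the same
    profile's maximum smoothed value (per-embryo normalization).
    """
    if psmad5_profile.smoothed_intensity is None:
        raise ValueError("smooth the pSmad5 profile before reading out")
    x, y = _profile_curve(psmad5_profile)
    if not (x[0] <= boundary_angle_deg <= x[-1]):
        raise ValueError(
            f"boundary angle {boundary_angle_deg:.2f} outside the profile range "
            f"[{x[0]:.2f}, {x[-1]:.2f}]"
        )
    good = np.isfinite(psmad5_profile.smoothed_intensity)
    slope = np.asarray(psmad5_profile.slope_magnitude)[good]
    level = float(np.interp(boundary_angle_deg, x, y))
    slope_at = float(np.interp(boundary_angle_deg, x, slope))
    pct = 100.0 * level / float(np.max(y))
    return BoundaryCall(
        gene=gene,
        embryo_id=embryo_id,
        axis=psmad5_profile.axis,
        boundary_angle_deg=float(boundary_angle_deg),
        level_au=level,
        level_pct_max=pct,
        slope_au_per_deg=slope_at,
        flags=tuple(flags),
    )


def expressing_fraction(
    cells: pd.DataFrame,
    channel: str,
    fraction: float = 0.10,
    reference_max: float | None = None,
) -> float:
    """Proportion of cells expressing a gene by the 10%-of-maximum rule.

    A cell expresses if its channel intensity is strictly greater than
    ``fraction`` times the maximum intensity -- by default the maximum over
    these cells; pass ``reference_max`` to judge against a common scale
    pooled across conditions (so an all-negative condition is not normalized
    to its own noise floor).
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    values = cells[channel].to_numpy(dtype=float)
    top = float(np.max(values)) if reference_max is None else float(reference_max)
    return float(np.mean(values > fraction * top))


def above_threshold_fraction(
    cells: pd.DataFrame, threshold_au: float, channel: str = "psmad5_au"
) -> float:
    """Proportion of cells whose pSmad5 exceeds a predicted threshold."""
    if len(cells) == 0:
        raise ValueError("empty cell table")
    return float(np.mean(cells[channel].to_numpy(dtype=float) > threshold_au))
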