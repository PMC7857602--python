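"""Monotone parametric models of the dorsoventral pSmad5 gradient.

The nuclear pSmad5 gradient along the zebrafish DV axis is represented as a
monotone cubic Hermite spline anchored at a small set of (angle, value,
derivative) triples.  Anchors carry the measured readouts of the real
gradient -- e.g. the wild-type profile passes through 60 A.U. with slope
-1.4 A.U./degree at the sizzled expression boundary -- and the Hermite
segments interpolate between them without introducing spurious extrema.

Monotonicity is enforced with the Fritsch-Carlson box condition: on every
segment both endpoint derivatives must lie between zero and three times the
secant slope.  That condition is sufficient for the cubic to be monotone on
the segment (at the extreme corner d0 = d1 = 3*secant the derivative is
3*s*(2t-1)**2 >= 0), so a validated profile is non-increasing everywhere.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "Anchor",
    "GradientProfile",
    "GENOTYPES",
    "make_canonical_gradient",
    "window_mean_slope",
]

GENOTYPES = ("wild_type", "chordin_mutant", "bmp7_mutant")

#: Dorsoventral angular window over which the chordin-mutant gradient is half
#: as steep as wild type (ventral-lateral), and window over which it is twice
#: as steep (dorsal-lateral).
CHD_SHALLOW_WINDOW = (25.0, 75.0)
CHD_STEEP_WINDOW = (125.0, 155.0)


@dataclass(frozen=True)
class Anchor:
    """One gradient anchor: DV angle (degrees), value (A.U.), derivative (A.U./degree)."""

    angle: float
    value: float
    derivative: float


@dataclass(frozen=True)
class GradientProfile:
    """Monotone non-increasing DV intensity curve defined by Hermite anchors.

    Parameters
    ----------
    anchors
        Ordered anchors with strictly increasing angles, first at 0 and last
        at 180 degrees, non-increasing values and non-positive derivatives.
    genotype_label
        One of :data:`GENOTYPES`.
    """

    anchors: tuple[Anchor, ...]
    genotype_label: str
    _spline: CubicHermiteSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        a = np.array([p.angle for p in self.anchors], dtype=float)
        v = np.array([p.value for p in self.anchors], dtype=float)
        d = np.array([p.derivative for p in self.anchors], dtype=float)
        if len(a) < 2:
            raise ValueError("a gradient profile needs at least two anchors")
        if not (np.all(np.diff(a) > 0) and a[0] == 0.0 and a[-1] == 180.0):
            raise ValueError(
                "anchor angles must be strictly increasing from 0 to 180 degrees"
            )
        if np.any(np.diff(v) > 0):
            raise ValueError("anchor values must be non-increasing")
        if np.any(v < 0):
            raise ValueError("anchor values must be non-negative")
        if np.any(d > 0):
            raise ValueError("anchor derivatives must be non-positive")
        self._check_fritsch_carlson(a, v, d)
        object.__setattr__(self, "_spline", CubicHermiteSpline(a, v, d))

    @staticmethod
    def _check_fritsch_carlson(a: np.ndarray, v: np.ndarray, d: np.ndarray) -> None:
        # Box condition per segment: 3*secant <= derivative <= 0 (secant <= 0).
        secants = np.diff(v) / np.diff(a)
        for k, s in enumerate(secants):
            lo = 3.0 * s  # negative or zero
            tol = 1e-9 * (1.0 + abs(lo))
            for dk in (d[k], d[k + 1]):
                if not (lo - tol <= dk <= 0.0):
                    raise ValueError(
                        f"segment {a[k]:.1f}-{a[k + 1]:.1f} deg violates the "
                        f"Fritsch-Carlson monotonicity condition: derivative "
                        f"{dk:g} not in [{lo:g}, 0]"
                    )

    # -- evaluation ---------------------------------------------------------

    def __call__(self, angle_deg):
        """pSmad5 intensity (A.U.) at one or more DV angles."""
        return self._spline(np.asarray(angle_deg, dtype=float))

    def derivative(self, angle_deg):
        """d(intensity)/d(angle) in A.U./degree (non-positive)."""
        return self._spline.derivative()(np.asarray(angle_deg, dtype=float))

    def slope_magnitude(self, angle_deg):
        return np.abs(self.derivative(angle_deg))

    @property
    def max_value(self) -> float:
        return float(self.anchors[0].value)

    def boundary_angle(self, level_au: float, xtol: float = 1e-10) -> float:
        """DV angle at which the gradient crosses ``level_au``, by bisection.

        For a non-increasing profile the crossing is unique up to plateaus;
        the root of ``G(theta) - level`` bracketed on [0, 180] is returned.
        """
        g0 = float(self(0.0))
        g1 = float(self(180.0))
        if not (g1 <= level_au <= g0):
            raise ValueError(
                f"level {level_au} A.U. outside the profile range [{g1:g}, {g0:g}]"
            )
        if g0 == level_au:
            return 0.0
        if g1 == level_au:
            return 180.0
        return float(brentq(lambda t: float(self(t)) - level_au, 0.0, 180.0, xtol=xtol))


def window_mean_slope(profile: GradientProfile, lo_deg: float, hi_deg: float) -> float:
    """Window-mean |dG/dtheta| over [lo, hi] degrees.

    For a monotone non-increasing profile this equals the net drop divided by
    the window width, which is exact (no quadrature needed).
    """
    if not hi_deg > lo_deg:
        raise ValueError("window must satisfy hi > lo")
    return float((profile(lo_deg) - profile(hi_deg)) / (hi_deg - lo_deg))


# -- canonical profiles -----------------------------------------------------


def _anchors_from_slope_knots(
    knot_angles: Sequence[float], knot_slopes: Sequence[float], top_value: float
) -> tuple[Anchor, ...]:
    """Integrate a piecewise-linear slope-magnitude profile into anchors.

    With the slope magnitude linear between knots the intensity curve is
    piecewise quadratic; the trapezoid rule integrates it exactly, and the
    cubic Hermite segments reproduce the quadratic pieces exactly (cubic
    Hermite interpolation is exact for polynomials of degree <= 3).
    """
    a = np.asarray(knot_angles, dtype=float)
    s = np.asarray(knot_slopes, dtype=float)
    drops = np.concatenate([[0.0], np.cumsum((s[1:] + s[:-1]) / 2.0 * np.diff(a))])
    values = top_value - drops
    return tuple(
        Anchor(float(t), float(v), float(-m)) for t, v, m in zip(a, values, s)
    )


# The wild-type gradient is constructed from its slope-magnitude profile: a
# piecewise-linear |dG/dtheta| pinned to the measured boundary readouts --
# sizzled at 75 deg reads 60 A.U. (60% of the 100 A.U. ventral maximum) with
# slope 1.4 A.U./deg; foxi1 reads 25 A.U. at slope 0.76; bambia 7 A.U. at
# slope 0.35.  The foxi1 and bambia boundary angles follow by integration:
# the gradient must shed 35 A.U. between the sizzled and foxi1 boundaries at
# a slope interpolating 1.4 -> 0.76 (i.e. over 35 / 1.08 degrees), and
# 18 A.U. between foxi1 and bambia at 0.76 -> 0.35 (18 / 0.555 degrees).
# A smoothly varying slope near each boundary mirrors the measured curves
# and keeps local slope readouts well-defined under smoothing.
_WT_FOXI1_ANGLE = 75.0 + 35.0 / ((1.4 + 0.76) / 2.0)  # ~107.41 deg
_WT_BAMBIA_ANGLE = _WT_FOXI1_ANGLE + 18.0 / ((0.76 + 0.35) / 2.0)  # ~139.84 deg
# Ventral approach: slope rises from 0 at the pole through a knee at 45 deg
# to a gentle peak at 65 deg, arriving at 75 deg with the same downward
# trend as the sizzled->foxi1 stretch (no kink at the sizzled boundary);
# the knee slope is solved so the total ventral drop is exactly 40 A.U.
_WT_S65 = 1.4 + 10.0 * (1.4 - 0.76) / (_WT_FOXI1_ANGLE - 75.0)
_WT_S45 = (33.0 - 15.0 * _WT_S65) / 32.5
_WT_SLOPE_KNOTS = (
    (0.0, 0.0),
    (45.0, _WT_S45),
    (65.0, _WT_S65),
    (75.0, 1.4),
    (_WT_FOXI1_ANGLE, 0.76),
    (_WT_BAMBIA_ANGLE, 0.35),
    (_WT_BAMBIA_ANGLE + 22.0, 0.1),
    (180.0, 0.0),
)

#: Wild-type anchors: max 100 A.U. at the ventral pole, flat at both poles,
#: the three gene-boundary readouts exact at 75 / ~107.4 / ~139.8 degrees.
WT_ANCHORS = _anchors_from_slope_knots(
    [k[0] for k in _WT_SLOPE_KNOTS], [k[1] for k in _WT_SLOPE_KNOTS], 100.0
)

#: chordin-mutant anchor angles; the values at 50 and 148 degrees are solved
#: at import time against the two slope-ratio constraints (see
#: :func:`_calibrate_chd_values`).  The 100- and 125-degree anchors pin the
#: laterally expanded sizzled (60 A.U.) and foxi1 (25 A.U.) crossings.
_CHD_ANGLES = np.array([0.0, 50.0, 100.0, 125.0, 148.0, 180.0])


def _pchip_anchors(angles: np.ndarray, values: np.ndarray) -> tuple[Anchor, ...]:
    """Anchors with derivatives from the shape-preserving PCHIP rule.

    Endpoint derivatives are set to zero: the profile is even about both
    poles of the folded DV axis, so a symmetric gradient is flat there.
    """
    derivs = PchipInterpolator(angles, values).derivative()(angles)
    derivs = np.minimum(derivs, 0.0)  # clamp -0.0 artefacts
    derivs[0] = derivs[-1] = 0.0
    return tuple(Anchor(float(a), float(v), float(d)) for a, v, d in zip(angles, values, derivs))


def _chd_values(v50: float, v148: float) -> np.ndarray:
    return np.array([100.0, v50, 60.0, 25.0, v148, 1.0])


def _calibrate_chd_values() -> tuple[float, float]:
    """Solve the chordin-mutant anchor values at 50 and 148 degrees.

    The mutant gradient expands laterally: its mean slope magnitude over the
    ventral-lateral window (25-75 deg) is half the wild-type value, and over
    the dorsal-lateral window (125-155 deg) twice the wild-type value.  Both
    are window-mean constraints on a monotone spline, i.e. constraints on the
    net drop across each window, each solved by 1-D bisection in one free
    anchor value (the two are decoupled: the 50-deg value only influences the
    curve below the 100-deg anchor, the 148-deg value only above 125 deg).
    """
    wt = GradientProfile(WT_ANCHORS, "wild_type")
    target_shallow = 0.5 * window_mean_slope(wt, *CHD_SHALLOW_WINDOW)
    target_steep = 2.0 * window_mean_slope(wt, *CHD_STEEP_WINDOW)

    def profile(v50: float, v148: float) -> GradientProfile:
        return GradientProfile(
            _pchip_anchors(_CHD_ANGLES, _chd_values(v50, v148)), "chordin_mutant"
        )

    def shallow_gap(v50: float) -> float:
        p = profile(v50, 22.0)  # v148 does not enter the 25-75 deg window
        return window_mean_slope(p, *CHD_SHALLOW_WINDOW) - target_shallow

    v50 = _first_root(shallow_gap, 60.5, 99.5)

    def steep_gap(v148: float) -> float:
        p = profile(v50, v148)
        return window_mean_slope(p, *CHD_STEEP_WINDOW) - target_steep

    v148 = _first_root(steep_gap, 1.5, 24.5)
    return v50, v148


def _first_root(f, lo: float, hi: float, n_scan: int = 80) -> float:
    """First sign change of ``f`` on [lo, hi], refined by bisection.

    The calibration gaps are smooth but not monotone in the free anchor
    value, so the bracket is located by a grid scan before brentq.
    """
    grid = np.linspace(lo, hi, n_scan)
    values = [f(g) for g in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
        if fa == 0.0:
            return float(a)
        if fa * fb < 0:
            return float(brentq(f, a, b, xtol=1e-12))
    raise RuntimeError("calibration constraint has no solution in the scanned range")


@functools.lru_cache(maxsize=None)
def make_canonical_gradient(genotype_label: str) -> GradientProfile:
    """Canonical pSmad5 gradient for a genotype.

    ``wild_type`` carries the measured boundary readouts (max 100 A.U. at the
    ventral pole); ``chordin_mutant`` is the laterally expanded gradient
    calibrated so its window-mean slope magnitude is x0.5 the wild-type value
    over 25-75 degrees and x2 over 125-155 degrees; ``bmp7_mutant`` is flat at
    1 A.U. (no BMP signaling).
    """
    if genotype_label == "wild_type":
        return GradientProfile(WT_ANCHORS, "wild_type")
    if genotype_label == "chordin_mutant":
        v50, v148 = _calibrate_chd_values()
        return GradientProfile(
            _pchip_anchors(_CHD_ANGLES, _chd_values(v50, v148)), "chordin_mutant"
        )
    if genotype_label == "bmp7_mutant":
        return GradientProfile(
            (Anchor(0.0, 1.0, 0.0), Anchor(180.0, 1.0, 0.0)), "bmp7_mutant"
        )
    raise ValueError(
        f"unknown genotype {genotype_label!r}; valid labels: {', '.join(GENOTYPES)}"
    )
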