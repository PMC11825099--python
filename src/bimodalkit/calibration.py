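"""Cross-fluorophore calibration via a 4-anchor piecewise-linear map.

Two reporter libraries (e.g. a GFP promoter-fusion library and a YFP
protein-fusion library) measure the same promoters on different fluorescence
scales.  Four anchor points of each single-cell distribution — the lowest
cell signal, the weak-mode mean, the high-mode mean, and the highest cell
signal — are matched between scales, and values are mapped by linear
interpolation through the four anchor pairs (linear extrapolation with the
terminal segment's slope outside the anchor span).  The map is strictly
monotone, so it preserves order statistics and the mode structure of the
distribution.

Ordinary least-squares statistics for paired summary levels (slope, R²,
slope t-test, 95% CI) are provided for reporting calibration quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .modality import ModalityCall

__all__ = [
    "AnchorSet",
    "PiecewiseLinearMap",
    "LinearFitStats",
    "compute_anchors",
    "fit_anchor_map",
    "apply_map",
    "linear_fit_stats",
]


@dataclass(frozen=True)
class AnchorSet:
    """Four ordered anchor values on one fluorescence scale."""

    minimum: float
    weak_mode: float
    high_mode: float
    maximum: float

    def __post_init__(self) -> None:
        a = self.as_array()
        if not np.all(np.diff(a) > 0):
            raise ValueError(f"anchors must be strictly increasing, got {tuple(a)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.minimum, self.weak_mode, self.high_mode, self.maximum])


def compute_anchors(values, call: ModalityCall) -> AnchorSet:
    """Anchor set of a bimodal sample: (min, weak-mode mean, high-mode mean, max).

    Mode means are the 2-component mixture means on the analysis scale,
    back-transformed to the raw scale when the analysis was on log10.
    """
    if not call.is_bimodal:
        raise ValueError("anchors require a bimodal call")
    if call.fit2 is None:
        raise ValueError("bimodal call lacks a 2-component mixture fit")
    values = np.asarray(values, dtype=float)
    m1, m2 = call.fit2.means
    if call.scale == "log10":
        m1, m2 = 10.0**m1, 10.0**m2
    if m1 == m2:
        raise ValueError("degenerate mixture fit: coincident mode means")
    return AnchorSet(float(values.min()), float(m1), float(m2), float(values.max()))


@dataclass(frozen=True)
class PiecewiseLinearMap:
    """Strictly increasing piecewise-linear map through four anchor pairs."""

    src: AnchorSet
    dst: AnchorSet

    def __call__(self, values) -> np.ndarray:
        return apply_map(self, values)

    def inverse(self) -> "PiecewiseLinearMap":
        return PiecewiseLinearMap(self.dst, self.src)


def fit_anchor_map(src: AnchorSet, dst: AnchorSet) -> PiecewiseLinearMap:
    """Calibration map sending the source anchors exactly onto the target ones."""
    return PiecewiseLinearMap(src, dst)


def apply_map(mapping: PiecewiseLinearMap, values) -> np.ndarray:
    """Apply the calibration elementwise (monotone; extrapolates linearly)."""
    x = np.asarray(values, dtype=float)
    xs = mapping.src.as_array()
    ys = mapping.dst.as_array()
    out = np.interp(x, xs, ys)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    below = x < xs[0]
    above = x > xs[-1]
    out[below] = ys[0] + lo_slope * (x[below] - xs[0])
    out[above] = ys[-1] + hi_slope * (x[above] - xs[-1])
    return out


@dataclass(frozen=True)
class LinearFitStats:
    """OLS fit summary: slope, intercept, R², slope t-test p, 95% CI on slope."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


def linear_fit_stats(x, y) -> LinearFitStats:
    """Ordinary least squares of y on x with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = stats.linregress(x, y)
    dof = x.size - 2
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    return LinearFitStats(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        n=int(x.size),
    )
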