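"""Scalar dosimetric statistics for depth-dose curves and lateral profiles.

Profile conventions: positions in mm about the CAX; values in percent after
normalisation.  Flattened profiles are normalised to their CAX maximum;
unflattened (FFF) profiles are first rescaled by the shoulder-point
renormalisation so that flat-beam edge metrics (penumbra, field size) apply.

Numerical choices: inflection points are located at the extremum of a
Savitzky-Golay smoothed first derivative (window 5, quadratic) with
parabolic refinement; the shoulder point is operationalised as the maximum
magnitude of the smoothed second derivative between the peak region and the
inflection point of each penumbra.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .scoring import ScanCurve


class MetricError(ValueError):
    """A profile lacks the feature a metric requires (no crossing, etc.)."""


# ---------------------------------------------------------------------- #
# depth-dose metrics
# ---------------------------------------------------------------------- #
def d20_d10(pdd: ScanCurve) -> float:
    """Dose ratio at 20 cm depth to 10 cm depth (beam penetration index).

    Linear interpolation of the curve at exactly 100 mm and 200 mm.
    """
    if pdd.kind != "depth":
        raise MetricError("d20_d10 requires a depth-dose curve")
    if pdd.positions[0] > 100.0 or pdd.positions[-1] < 200.0:
        raise MetricError("depth-dose curve must cover 10 cm and 20 cm")
    d10 = float(pdd.interp(100.0))
    d20 = float(pdd.interp(200.0))
    if d10 <= 0:
        raise MetricError("zero dose at 10 cm depth")
    return d20 / d10


def dmax_position(pdd: ScanCurve, smooth_window: int = 0) -> float:
    """Depth of maximum dose (mm), optionally from a smoothed curve."""
    c = pdd.smoothed(smooth_window) if smooth_window else pdd
    return float(c.positions[int(np.argmax(c.values))])


# ---------------------------------------------------------------------- #
# edge helpers
# ---------------------------------------------------------------------- #
def _smooth(values: np.ndarray, window: int = 5, polyorder: int = 2,
            deriv: int = 0, delta: float = 1.0) -> np.ndarray:
    if values.size < window:
        window = values.size - (1 - values.size % 2)
    if window < polyorder + 2:
        if deriv == 0:
            return values
        return np.gradient(values, delta) if deriv == 1 else np.gradient(
            np.gradient(values, delta), delta)
    return savgol_filter(values, window, polyorder, deriv=deriv, delta=delta)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through three samples around index i."""
    if i <= 0 or i >= x.size - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-30:
        return float(x[i])
    return float(x[i] + 0.5 * (y[i - 1] - y[i + 1]) / denom * (x[i + 1] - x[i]))


def inflection_points(profile: ScanCurve, window: int = 5) -> tuple:
    """(I_L, I_R): positions (mm) of the steepest points of the two
    penumbrae, from the extremum of the smoothed first derivative."""
    x = profile.positions
    step = float(np.median(np.diff(x)))
    d1 = _smooth(profile.values, window, 2, deriv=1, delta=step)
    mid = int(np.argmin(np.abs(x)))
    if mid <= 1 or mid >= x.size - 2:
        raise MetricError("profile does not bracket the CAX")
    il_i = int(np.argmax(d1[:mid]))
    ir_i = mid + int(np.argmin(d1[mid:]))
    if d1[il_i] <= 0 or d1[ir_i] >= 0:
        raise MetricError("no inflection point found (flat or noisy profile)")
    i_l = _parabolic_refine(x[:mid], d1[:mid], il_i)
    i_r = _parabolic_refine(x, d1, ir_i)
    if not i_l < i_r:
        raise MetricError("inflection points out of order")
    return i_l, i_r


def _level_crossing(x: np.ndarray, v: np.ndarray, level: float,
                    rising: bool) -> float:
    """Position of the first crossing of ``level`` on a monotone edge.

    ``rising=True`` scans left-to-right for v passing upward through level
    (left penumbra); ``rising=False`` scans for the downward crossing on the
    right side (last crossing).
    """
    above = v >= level
    idx = np.flatnonzero(above[1:] != above[:-1])
    if idx.size == 0:
        raise MetricError(f"profile never crosses {level}")
    i = idx[0] if rising else idx[-1]
    x0, x1 = x[i], x[i + 1]
    v0, v1 = v[i], v[i + 1]
    if v1 == v0:
        return float(0.5 * (x0 + x1))
    return float(x0 + (level - v0) / (v1 - v0) * (x1 - x0))


# ---------------------------------------------------------------------- #
# profile metrics
# ---------------------------------------------------------------------- #
def penumbra(profile: ScanCurve, side: str = "left") -> float:
    """20%-80% penumbra width (mm) on the given side of a normalised
    profile, by monotone linear interpolation within the penumbral window."""
    if profile.normalization == "raw":
        raise MetricError("penumbra requires a normalised profile")
    x = profile.positions
    v = profile.values
    mid = int(np.argmin(np.abs(x)))
    if side == "left":
        xs, vs = x[:mid + 1], v[:mid + 1]
        x20 = _level_crossing(xs, vs, 20.0, rising=True)
        x80 = _level_crossing(xs, vs, 80.0, rising=True)
    elif side == "right":
        xs, vs = x[mid:], v[mid:]
        x20 = _level_crossing(xs, vs, 20.0, rising=False)
        x80 = _level_crossing(xs, vs, 80.0, rising=False)
    else:
        raise ValueError("side must be 'left' or 'right'")
    return abs(x20 - x80)


def dosimetric_field_size(profile: ScanCurve) -> float:
    """Distance (mm) between the left and right inflection points."""
    i_l, i_r = inflection_points(profile)
    return i_r - i_l


def renormalize_fff(profile: ScanCurve, window: int = 5) -> ScanCurve:
    """Shoulder-point renormalisation of a single-peaked (FFF) profile.

    Locates the penumbral inflection points, then the shoulder point of each
    side: the maximum-magnitude of the smoothed second derivative between
    the peak region and the inflection point.  The profile is rescaled so
    that the mean shoulder dose reads 100%; the scale factor is recorded in
    ``meta['shoulder_scale']``.  Applying the operation twice is a no-op.
    """
    if profile.normalization == "fff_renorm":
        return ScanCurve(profile.positions, profile.values.copy(),
                         profile.kind, "fff_renorm",
                         profile.uncertainty_pct, dict(profile.meta))
    base = profile if profile.normalization != "raw" else profile.normalized("cax")
    x = base.positions
    step = float(np.median(np.diff(x)))
    i_l, i_r = inflection_points(base, window)
    d2 = _smooth(base.values, window, 2, deriv=2, delta=step)
    half = 0.5 * (i_r - i_l)
    shoulders = []
    for i_edge, sign in ((i_l, +1), (i_r, -1)):
        # search between the inflection point and the inner 40% of the side
        lo = min(i_edge, i_edge + sign * 0.6 * half)
        hi = max(i_edge, i_edge + sign * 0.6 * half)
        m = (x >= lo) & (x <= hi)
        if not np.any(m):
            raise MetricError("empty shoulder search window")
        j = int(np.argmax(np.abs(d2[m])))
        xi = x[m][j]
        shoulders.append((xi, float(base.interp(xi))))
    shoulder_dose = 0.5 * (shoulders[0][1] + shoulders[1][1])
    if shoulder_dose <= 0:
        raise MetricError("non-positive shoulder dose")
    scale = 100.0 / shoulder_dose
    meta = dict(base.meta)
    meta["shoulder_scale"] = scale
    meta["shoulder_positions_mm"] = (shoulders[0][0], shoulders[1][0])
    return ScanCurve(x, base.values * scale, base.kind, "fff_renorm",
                     base.uncertainty_pct, meta)


def unflatness(profile: ScanCurve, field_size_mm=None) -> float:
    """D_CAX / D_off-axis with the off-axis dose read at 80% of the field
    size (mean of the two sides)."""
    fs = field_size_mm if field_size_mm else dosimetric_field_size(profile)
    x80 = 0.8 * fs / 2.0
    if x80 > profile.positions[-1] or -x80 < profile.positions[0]:
        raise MetricError("80% field-size points outside the profile")
    d_cax = float(profile.interp(0.0))
    d_off = 0.5 * (float(profile.interp(-x80)) + float(profile.interp(x80)))
    if d_off <= 0:
        raise MetricError("non-positive off-axis dose")
    return d_cax / d_off


def slope(profile: ScanCurve, field_size_mm=None) -> float:
    """Mean absolute dose gradient (%/mm) between the points at 2/3 and 1/3
    of the half-profile on each side."""
    fs = field_size_mm if field_size_mm else dosimetric_field_size(profile)
    h = fs / 2.0
    out = []
    for sgn in (-1.0, +1.0):
        x1, x2 = sgn * 2.0 / 3.0 * h, sgn * 1.0 / 3.0 * h
        d1, d2 = float(profile.interp(x1)), float(profile.interp(x2))
        out.append(abs((d1 - d2) / (x1 - x2)))
    return float(np.mean(out))


def peak_position(profile: ScanCurve, field_size_mm=None) -> float:
    """Intersection of straight-line fits to the two half-profile slope
    windows ([1/3, 2/3] of each half side): (I_L - I_R) / (S_R - S_L) with
    I, S the intercept and slope of each side's fitted line."""
    fs = field_size_mm if field_size_mm else dosimetric_field_size(profile)
    h = fs / 2.0
    x = profile.positions
    fits = []
    for sgn in (-1.0, +1.0):
        lo, hi = sorted((sgn * 2.0 / 3.0 * h, sgn * 1.0 / 3.0 * h))
        m = (x >= lo) & (x <= hi)
        if m.sum() < 2:
            raise MetricError("too few points in the slope window")
        s, i = np.polyfit(x[m], profile.values[m], 1)
        fits.append((s, i))
    (s_l, i_l), (s_r, i_r) = fits
    if abs(s_l - s_r) < 1e-12:
        raise MetricError("degenerate geometry: equal side slopes")
    return float((i_l - i_r) / (s_r - s_l))


def symmetry(profile: ScanCurve, field_size_mm=None) -> float:
    """Maximum variation max_x |D(x) - D(-x)| (percent points) over the
    dosimetric field."""
    fs = field_size_mm if field_size_mm else dosimetric_field_size(profile)
    h = fs / 2.0
    x = profile.positions
    m = (x > 0) & (x <= h)
    xs = x[m]
    if xs.size == 0:
        return 0.0
    d_pos = profile.interp(xs)
    d_neg = profile.interp(-xs)
    return float(np.max(np.abs(d_pos - d_neg)))


def compare_curves(sim: ScanCurve, ref: ScanCurve) -> tuple:
    """(max |difference|, per-point differences) between two curves
    normalised per their beam's convention, on the overlapping range of the
    simulated grid (reference linearly interpolated onto it)."""
    lo = max(sim.positions[0], ref.positions[0])
    hi = min(sim.positions[-1], ref.positions[-1])
    if lo >= hi:
        raise MetricError("curves have disjoint position ranges")
    m = (sim.positions >= lo) & (sim.positions <= hi)
    diffs = sim.values[m] - ref.interp(sim.positions[m])
    return float(np.max(np.abs(diffs))), diffs


def profile_metrics(profile: ScanCurve, mode: str = "fff") -> dict:
    """All profile statistics in one report (dict keyed by metric name)."""
    prof = renormalize_fff(profile) if mode == "fff" else (
        profile.normalized("cax") if profile.normalization == "raw" else profile)
    i_l, i_r = inflection_points(prof)
    fs = i_r - i_l
    out = {
        "penumbra_left_mm": penumbra(prof, "left"),
        "penumbra_right_mm": penumbra(prof, "right"),
        "dosimetric_field_size_mm": fs,
        "inflection_left_mm": i_l,
        "inflection_right_mm": i_r,
        "symmetry_pct": symmetry(prof, fs),
        "peak_position_mm": peak_position(prof, fs),
    }
    if mode == "fff":
        out["unflatness"] = unflatness(prof, fs)
        out["slope_pct_per_mm"] = slope(prof, fs)
        out["shoulder_scale"] = prof.meta.get("shoulder_scale")
    return out
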