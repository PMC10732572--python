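"""Nano-DSF melt curves and inflection-temperature (Ti) detection.

The instrument records the ratio of intrinsic fluorescence at 350 nm and
330 nm while heating; unfolding shifts tryptophan emission and the ratio
traces a sigmoid.  A two-state van 't Hoff model with linear folded and
unfolded baselines generates synthetic curves::

    ratio(T) = B_F(T) + (B_U(T) - B_F(T)) * theta_U(T)
    theta_U(T) = 1 / (1 + exp[(dH_vH / R)(1/T - 1/Tm)])      (T in kelvin)

Ti detection mirrors the instrument readout: smooth the ratio, take the
first derivative in temperature, and report every peak above a prominence
threshold.  Peak positions are refined by parabolic interpolation of the
three derivative samples around each grid maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .equilibria import R_CAL

__all__ = [
    "MeltCurve",
    "TiResult",
    "two_state_ratio_curve",
    "unfolded_fraction",
    "detect_ti",
]

_C_TO_K = 273.15


@dataclass(frozen=True)
class MeltCurve:
    """350/330 nm fluorescence ratio vs temperature (degC)."""

    temperature: np.ndarray
    ratio: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        if t.size != r.size:
            raise ValueError("temperature and ratio lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("fluorescence ratio must be positive")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "ratio", r)


@dataclass
class TiResult:
    """Detected inflection temperatures, hottest-last, with peak metadata."""

    ti: np.ndarray  # degC, sorted ascending; empty if nothing detected
    prominence: np.ndarray  # derivative-peak prominences, same order
    smoothing_window_c: float
    diagnostics: str = ""


def unfolded_fraction(t_celsius, tm: float, dh_vh: float) -> np.ndarray:
    """Two-state unfolded fraction at temperature(s) t_celsius (degC)."""
    t_k = np.asarray(t_celsius, dtype=float) + _C_TO_K
    tm_k = tm + _C_TO_K
    r_kcal = R_CAL / 1000.0
    return 1.0 / (1.0 + np.exp((dh_vh / r_kcal) * (1.0 / t_k - 1.0 / tm_k)))


def two_state_ratio_curve(
    tm: float,
    dh_vh: float,
    folded_baseline: tuple[float, float] = (0.8, 0.0),
    unfolded_baseline: tuple[float, float] = (1.0, 0.0),
    t_grid=None,
    sample: str = "",
) -> MeltCurve:
    """Synthesize a two-state 350/330 melt curve.

    Baselines are (intercept, slope-per-degC) evaluated at the Celsius
    temperature; the default grid spans 35-95 degC at 0.1 degC.
    """
    if dh_vh <= 0:
        raise ValueError("van 't Hoff enthalpy must be positive")
    if t_grid is None:
        t_grid = np.arange(35.0, 95.0 + 1e-9, 0.1)
    t = np.asarray(t_grid, dtype=float)
    theta_u = unfolded_fraction(t, tm, dh_vh)
    b_f = folded_baseline[0] + folded_baseline[1] * t
    b_u = unfolded_baseline[0] + unfolded_baseline[1] * t
    return MeltCurve(t, b_f + (b_u - b_f) * theta_u, sample)


def detect_ti(
    curve: MeltCurve,
    smoothing_window_c: float = 1.5,
    min_prominence_frac: float = 0.05,
    max_transitions: int | None = None,
) -> TiResult:
    """Find inflection temperatures as first-derivative peaks.

    The ratio is smoothed with a local quadratic (Savitzky-Golay) filter of
    width ``smoothing_window_c`` degC, differentiated on the grid, and peaks
    with prominence above ``min_prominence_frac`` of the derivative range are
    reported.  Detection only uses the shape of the curve, so it is
    invariant to affine rescaling of the ratio axis.
    """
    t, r = curve.temperature, curve.ratio
    if t.size < 50:
        raise ValueError("need >= 50 points for Ti detection")
    dt = float(np.median(np.diff(t)))
    window = max(int(round(smoothing_window_c / dt)) | 1, 5)
    window = min(window, t.size if t.size % 2 else t.size - 1)
    smooth = savgol_filter(r, window_length=window, polyorder=2)
    deriv = np.gradient(smooth, t)

    d_range = float(np.max(deriv) - np.min(deriv))
    # baseline-only curves leave the derivative (numerically) constant: a
    # flat signal, or a derivative whose variation is at rounding level
    d_scale = float(np.max(np.abs(deriv)))
    signal_flat = float(np.ptp(smooth)) <= 1e-9 * float(np.max(np.abs(r)))
    if signal_flat or d_range <= max(1e-8 * d_scale, 1e-300):
        return TiResult(np.array([]), np.array([]), smoothing_window_c,
                        "flat derivative; no transition")
    peaks, props = find_peaks(deriv, prominence=min_prominence_frac * d_range)
    if peaks.size == 0:
        return TiResult(np.array([]), np.array([]), smoothing_window_c,
                        "no derivative peak above prominence threshold")

    prominences = props["prominences"]
    if max_transitions is not None and peaks.size > max_transitions:
        keep = np.argsort(prominences)[::-1][:max_transitions]
        peaks, prominences = peaks[np.sort(keep)], prominences[np.sort(keep)]

    ti = np.array([_refine_peak(t, deriv, p) for p in peaks])
    order = np.argsort(ti)
    return TiResult(ti[order], prominences[order], smoothing_window_c)


def _refine_peak(t: np.ndarray, deriv: np.ndarray, idx: int) -> float:
    """Sub-grid peak position by a parabola through the three nearest points."""
    if idx == 0 or idx == t.size - 1:
        return float(t[idx])
    y0, y1, y2 = deriv[idx - 1], deriv[idx], deriv[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[idx])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    dt = t[idx + 1] - t[idx] if shift >= 0 else t[idx] - t[idx - 1]
    return float(t[idx] + shift * dt)
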