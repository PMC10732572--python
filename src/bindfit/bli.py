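"""Biolayer-interferometry 1:1 Langmuir sensogram simulation and fitting.

A sensor with immobilised receptor reports binding of an analyte at
concentration ``C`` as a wavelength shift R(t) (nm).  For a 1:1 interaction
the association phase follows

    R(t) = R_eq * (1 - exp(-k_obs t)),   k_obs = k_on C + k_off,
    R_eq = R_max * C / (C + k_off/k_on)

and the dissociation phase (analyte-free buffer) decays as
``R(t_a + t) = R(t_a) * exp(-k_off t)``.  The apparent dissociation constant
is ``K_d = k_off / k_on``.

The global fitter shares k_off between phases and weights both phases
equally.  At a single analyte concentration k_on and R_max are only jointly
determined through R_eq; when C is far from K_d the response carries little
information about K_d and the fit flags weak identifiability instead of
reporting a confident value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Sensogram",
    "KineticFit",
    "simulate_sensogram",
    "fit_1to1_kinetics",
    "fit_steady_state",
]

PHASES = ("baseline", "association", "dissociation")


@dataclass(frozen=True)
class Sensogram:
    """Time-resolved wavelength-shift trace with phase labels."""

    time: np.ndarray  # s, strictly increasing
    shift: np.ndarray  # nm
    phase: np.ndarray  # str per point, from PHASES
    analyte_conc: float  # molar
    t_assoc_start: float = 0.0  # s, association-phase origin

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.shift, dtype=float)
        ph = np.asarray(self.phase)
        if not (t.size == r.size == ph.size):
            raise ValueError("time, shift and phase lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("shift must be finite")
        bad = set(np.unique(ph)) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        ia = np.flatnonzero(ph == "association")
        idx_d = np.flatnonzero(ph == "dissociation")
        if ia.size and idx_d.size and ia[0] > idx_d[0]:
            raise ValueError("association must precede dissociation")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "shift", r)
        object.__setattr__(self, "phase", ph)

    def phase_slice(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.phase == name
        return self.time[m], self.shift[m]


@dataclass
class KineticFit:
    k_on: float  # 1/(M s)
    k_off: float  # 1/s
    r_max: float  # nm
    k_on_stderr: float
    k_off_stderr: float
    r_max_stderr: float
    rss: float
    converged: bool
    mode: str = "kinetic"
    warnings: list[str] = field(default_factory=list)

    @property
    def kd_app(self) -> float:
        """Apparent dissociation constant k_off/k_on (molar)."""
        return self.k_off / self.k_on

    @property
    def kd_app_stderr(self) -> float:
        """First-order propagated SE of k_off/k_on (rates taken independent)."""
        rel = np.hypot(self.k_off_stderr / self.k_off, self.k_on_stderr / self.k_on)
        return self.kd_app * rel


def simulate_sensogram(
    k_on: float,
    k_off: float,
    r_max: float,
    analyte_conc: float,
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    dt: float = 0.5,
    t_baseline: float = 0.0,
) -> Sensogram:
    """Closed-form 1:1 sensogram over association then dissociation."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    if r_max < 0 or analyte_conc < 0:
        raise ValueError("r_max and analyte_conc must be non-negative")
    n_b = int(round(t_baseline / dt))
    n_a = int(round(t_assoc / dt))
    n_d = int(round(t_dissoc / dt))
    t_b = np.arange(n_b) * dt - t_baseline
    t_a = np.arange(n_a + 1) * dt
    t_d = t_assoc + np.arange(1, n_d + 1) * dt
    c = analyte_conc
    k_obs = k_on * c + k_off
    r_eq = r_max * c / (c + k_off / k_on) if c > 0 else 0.0
    r_a = r_eq * (1.0 - np.exp(-k_obs * t_a))
    r_end = r_a[-1] if r_a.size else 0.0
    r_d = r_end * np.exp(-k_off * (t_d - t_assoc))
    time = np.concatenate([t_b, t_a, t_d])
    shift = np.concatenate([np.zeros(n_b), r_a, r_d])
    phase = np.concatenate([
        np.full(n_b, "baseline"),
        np.full(t_a.size, "association"),
        np.full(t_d.size, "dissociation"),
    ])
    return Sensogram(time, shift, phase, analyte_conc)


def _subtract_baseline(s: Sensogram) -> Sensogram:
    """Subtract a straight line fitted to the pre-association baseline."""
    tb, rb = s.phase_slice("baseline")
    if tb.size < 2:
        return s
    coeffs = np.polyfit(tb, rb, 1)
    corrected = s.shift - np.polyval(coeffs, s.time)
    return Sensogram(s.time, corrected, s.phase, s.analyte_conc, s.t_assoc_start)


def fit_1to1_kinetics(sensogram: Sensogram) -> KineticFit:
    """Global 1:1 fit of (k_on, k_off, R_max) across both phases.

    k_off is shared between phases; rates are fitted in log10 space.  A
    dissociation-only trace still yields k_off, with k_on reported as NaN.
    """
    s = _subtract_baseline(sensogram)
    t_a, r_a = s.phase_slice("association")
    t_d, r_d = s.phase_slice("dissociation")
    warns: list[str] = []
    c = s.analyte_conc

    if t_a.size < 20 and t_d.size >= 20:
        return _fit_dissociation_only(s, warns)
    if t_a.size < 20 or t_d.size < 20:
        raise ValueError("need >= 20 points in each phase")

    span = float(np.max(np.abs(s.shift)))
    if span < 1e-12:
        warns.append("flat trace: parameters unidentifiable")
        return KineticFit(np.nan, np.nan, 0.0, np.nan, np.nan, np.nan,
                          float(np.sum(s.shift**2)), False, "kinetic", warns)

    t0 = float(t_a[0])
    t_assoc_end = float(t_a[-1])
    r_end_obs = float(r_a[-1])

    # crude initialisation: k_obs from 63% rise time, k_off from dissoc decay
    k_off0 = _decay_rate_guess(t_d - t_assoc_end, r_d)
    k_obs0 = _rise_rate_guess(t_a - t0, r_a)
    k_on0 = max((k_obs0 - k_off0) / c, 0.1 * k_obs0 / c) if c > 0 else 1.0
    r_max0 = max(r_end_obs, span) * 2.0

    def model(theta):
        k_on, k_off, r_max = 10.0 ** theta[0], 10.0 ** theta[1], theta[2]
        k_obs = k_on * c + k_off
        r_eq = r_max * c / (c + k_off / k_on)
        ra = r_eq * (1.0 - np.exp(-k_obs * (t_a - t0)))
        r_at_end = r_eq * (1.0 - np.exp(-k_obs * (t_assoc_end - t0)))
        rd = r_at_end * np.exp(-k_off * (t_d - t_assoc_end))
        return np.concatenate([ra, rd])

    obs = np.concatenate([r_a, r_d])

    def resid(theta):
        return model(theta) - obs

    theta0 = np.array([np.log10(k_on0), np.log10(k_off0), r_max0])
    sol = least_squares(resid, theta0, method="lm", max_nfev=5000)
    k_on, k_off, r_max = 10.0 ** sol.x[0], 10.0 ** sol.x[1], sol.x[2]
    rss = float(np.sum(sol.fun**2))

    dof = max(obs.size - 3, 1)
    s2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    cond = np.linalg.cond(jtj)
    cov = np.linalg.pinv(jtj) * s2
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    k_on_se = np.log(10.0) * k_on * se[0]
    k_off_se = np.log(10.0) * k_off * se[1]

    kd = k_off / k_on
    sat = c / (c + kd)
    if sat < 0.02 or sat > 0.98:
        warns.append(
            f"analyte concentration far from Kd (fractional saturation "
            f"{sat:.3g}): Kd weakly identifiable"
        )
    if cond > 1e10:
        warns.append(f"ill-conditioned fit (cond={cond:.2e})")
    return KineticFit(float(k_on), float(k_off), float(r_max),
                      float(k_on_se), float(k_off_se), float(se[2]),
                      rss, bool(sol.success), "kinetic", warns)


def _fit_dissociation_only(s: Sensogram, warns: list[str]) -> KineticFit:
    t_d, r_d = s.phase_slice("dissociation")
    t0 = float(t_d[0])
    if np.max(np.abs(r_d)) < 1e-12:
        raise ValueError("dissociation trace is flat; nothing to fit")

    def resid(theta):
        return theta[1] * np.exp(-(10.0 ** theta[0]) * (t_d - t0)) - r_d

    k0 = _decay_rate_guess(t_d - t0, r_d)
    sol = least_squares(resid, np.array([np.log10(k0), r_d[0]]), method="lm")
    k_off = 10.0 ** sol.x[0]
    dof = max(t_d.size - 2, 1)
    cov = np.linalg.pinv(sol.jac.T @ sol.jac) * float(np.sum(sol.fun**2)) / dof
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    warns.append("association phase missing: k_on not determined")
    return KineticFit(np.nan, float(k_off), np.nan,
                      np.nan, float(np.log(10.0) * k_off * se[0]), np.nan,
                      float(np.sum(sol.fun**2)), bool(sol.success),
                      "dissociation-only", warns)


def fit_steady_state(r_eq: np.ndarray, concs: np.ndarray) -> tuple[float, float, float]:
    """Fallback: fit R_eq(C) = R_max C/(C + Kd) across concentrations.

    Returns (kd, r_max, rss).  Use when kinetic traces are unreliable but
    equilibrium plateaus at several concentrations are available.
    """
    r_eq = np.asarray(r_eq, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if r_eq.size != concs.size or r_eq.size < 3:
        raise ValueError("need >= 3 matched (R_eq, C) points")

    def resid(theta):
        kd, rmax = 10.0 ** theta[0], theta[1]
        return rmax * concs / (concs + kd) - r_eq

    kd0 = float(np.median(concs[concs > 0]))
    sol = least_squares(resid, np.array([np.log10(kd0), float(np.max(r_eq))]),
                        method="lm")
    return float(10.0 ** sol.x[0]), float(sol.x[1]), float(np.sum(sol.fun**2))


def _decay_rate_guess(t: np.ndarray, r: np.ndarray) -> float:
    """Log-linear decay-rate estimate from the positive part of a trace."""
    m = r > 0.05 * np.max(np.abs(r)) if np.max(np.abs(r)) > 0 else np.zeros(r.size, bool)
    if m.sum() >= 2:
        slope = np.polyfit(t[m], np.log(r[m]), 1)[0]
        if slope < 0:
            return float(-slope)
    return 1.0 / max(float(t[-1] - t[0]), 1.0)


def _rise_rate_guess(t: np.ndarray, r: np.ndarray) -> float:
    """k_obs estimate from the time to reach 63% of the final level."""
    r_end = r[-1]
    if abs(r_end) < 1e-12:
        return 1.0 / max(float(t[-1]), 1.0)
    idx = np.argmax(r >= 0.632 * r_end)
    t63 = float(t[idx]) if idx > 0 else float(t[-1]) * 0.1
    return 1.0 / max(t63, 1e-6)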