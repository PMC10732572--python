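"""Cation fluorescence-titration fits: 1:1 saturation vs linear response.

Tryptophan emission changes on cation binding are normalised as
``y = |I - I0| / I0`` and fitted either to a 1:1 saturation law

    y(L) = y_max * L / (Kd_app + L)

(free ligand ~ total ligand, valid at the >=1000-fold ligand excess these
titrations use: tens of mM cation vs ~10 uM protein), or to a straight line
for a non-saturating response.  Corrected-AIC comparison picks between the
two, with ties going to the linear (more parsimonious) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationCurve",
    "SaturationFit",
    "LinearFit",
    "fit_saturation_1to1",
    "fit_linear",
    "select_binding_model",
    "aicc",
]


@dataclass(frozen=True)
class TitrationCurve:
    """Normalised fluorescence response vs ligand concentration (molar)."""

    ligand_conc: np.ndarray
    y: np.ndarray
    replicate: str = "r1"

    def __post_init__(self) -> None:
        conc = np.asarray(self.ligand_conc, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if conc.size != y.size:
            raise ValueError("ligand_conc and y lengths differ")
        if np.any(conc < 0):
            raise ValueError("ligand concentrations must be non-negative")
        if np.any(np.diff(conc) < 0):
            raise ValueError("ligand_conc must be sorted ascending")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        object.__setattr__(self, "ligand_conc", conc)
        object.__setattr__(self, "y", y)


@dataclass
class SaturationFit:
    kd_app: float  # molar
    y_max: float
    kd_stderr: float
    y_max_stderr: float
    rss: float
    n_points: int
    warnings: list[str] = field(default_factory=list)

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.y_max * conc / (self.kd_app + conc)

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.n_points, 2)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    rss: float
    n_points: int

    def predict(self, conc) -> np.ndarray:
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.n_points, 2)


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike criterion for a Gaussian least-squares fit.

    Uses the residual-variance form n*ln(rss/n) + 2k with the small-sample
    correction 2k(k+1)/(n-k-1).  ``k`` counts mean-model parameters (the
    noise variance is profiled out identically for the compared models).
    """
    if n <= k + 1:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_saturation_1to1(curve: TitrationCurve) -> SaturationFit:
    """Least-squares fit of the 1:1 saturation law to a titration curve."""
    conc, y = curve.ligand_conc, curve.y
    if conc.size < 5:
        raise ValueError("need >= 5 points for a saturation fit")
    warns: list[str] = []
    y_span = float(np.max(np.abs(y)))
    if y_span < 1e-12:
        # flat data: amplitude 0, kd meaningless
        kd0 = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
        warns.append("flat response: y_max ~ 0, Kd unidentifiable")
        return SaturationFit(kd0, 0.0, np.inf, 0.0, float(np.sum(y**2)),
                             conc.size, warns)

    # start at half-max concentration; kd in log space to stay positive
    y_max0 = float(np.max(y))
    half = 0.5 * y_max0
    kd0 = float(np.interp(half, y, conc)) if np.any(y > half) else float(conc[-1])
    kd0 = max(kd0, float(np.min(conc[conc > 0])) * 1e-3)

    def resid(theta):
        kd, ymax = 10.0 ** theta[0], theta[1]
        return ymax * conc / (kd + conc) - y

    sol = least_squares(resid, np.array([np.log10(kd0), y_max0]), method="lm")
    kd, y_max = 10.0 ** sol.x[0], sol.x[1]
    rss = float(np.sum(sol.fun**2))

    dof = max(conc.size - 2, 1)
    s2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    cov = np.linalg.pinv(jtj) * s2
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    kd_se = np.log(10.0) * kd * se[0]

    # identifiability: curve must bend, i.e. sample below and above kd
    if kd > conc[-1] or np.linalg.cond(jtj) > 1e10:
        warns.append(
            "no curvature within the sampled range: Kd weakly identified"
        )
    return SaturationFit(float(kd), float(y_max), float(kd_se), float(se[1]),
                         rss, conc.size, warns)


def fit_linear(curve: TitrationCurve) -> LinearFit:
    """Ordinary least-squares straight line, closed form."""
    conc, y = curve.ligand_conc, curve.y
    if conc.size < 2:
        raise ValueError("need >= 2 points for a linear fit")
    coeffs, res, *_ = np.polyfit(conc, y, 1, full=True)
    pred = np.polyval(coeffs, conc)
    rss = float(np.sum((y - pred) ** 2))
    return LinearFit(float(coeffs[0]), float(coeffs[1]), rss, conc.size)


def select_binding_model(
    curve: TitrationCurve,
) -> tuple[str, dict[str, float], SaturationFit, LinearFit]:
    """Choose between saturating and linear response by corrected AIC.

    Returns (label, {"saturating": aicc, "linear": aicc}, sat_fit, lin_fit);
    ties (within 1e-9) go to the linear model on parsimony grounds.
    """
    sat = fit_saturation_1to1(curve)
    lin = fit_linear(curve)
    scores = {"saturating": sat.aicc, "linear": lin.aicc}
    label = "saturating" if sat.aicc < lin.aicc - 1e-9 else "linear"
    return label, scores, sat, lin
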