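"""Nucleotide-exchange progress curves and Ca2+ activation analysis.

GTPgammaS binding to a Galpha subunit is followed by the rise of intrinsic
tryptophan fluorescence.  Progress curves are fitted empirically to one or
two rising exponentials::

    F(t) = F0 + sum_i a_i (1 - exp(-k_i t))

The slower rate of a biphasic curve is taken as the catalysed nucleotide
exchange rate (fixed convention; the fast phase reports binding to an
intermediary complex and is not modelled mechanistically).  Exchange rates
measured across a CaCl2 series, after subtraction of the intrinsic
(uncatalysed) rate at each matched Ca2+ concentration, follow a one-site
total-binding velocity law::

    v([Ca]) = v0 + v_max [Ca] / (K_a + [Ca])

whose apparent activation constant K_a is the Ca2+ concentration of
half-maximal enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .titration import aicc

__all__ = [
    "ProgressCurve",
    "ExponentialFit",
    "ActivationFit",
    "fit_exponential",
    "choose_exponential_model",
    "subtract_intrinsic",
    "fit_activation",
    "activation_velocity",
]


@dataclass(frozen=True)
class ProgressCurve:
    """One fluorescence progress curve at a given CaCl2 concentration."""

    time: np.ndarray  # s
    fluorescence: np.ndarray  # a.u.
    condition: str = ""
    ca_conc: float = 0.0  # molar

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size != f.size:
            raise ValueError("time and fluorescence lengths differ")
        if t.size < 30:
            raise ValueError("need >= 30 points in a progress curve")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass
class ExponentialFit:
    model_order: int
    f0: float
    amplitudes: np.ndarray  # a1 [, a2]
    rates: np.ndarray  # k1 [, k2], 1/s, sorted k1 >= k2
    rss: float
    n_points: int
    stderr: np.ndarray  # SEs in parameter order (f0, a..., k...)
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def slow_rate(self) -> float:
        """Slowest fitted rate; the catalysed-exchange rate by convention."""
        return float(self.rates[-1])

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.n_points, 1 + 2 * self.model_order)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.f0)
        for a, k in zip(self.amplitudes, self.rates):
            out = out + a * (1.0 - np.exp(-k * t))
        return out


@dataclass
class ActivationFit:
    v0: float  # 1/s, basal rate
    v_max: float  # 1/s, maximal enhancement
    ka: float  # molar, apparent activation constant
    v0_stderr: float
    v_max_stderr: float
    ka_stderr: float
    rss: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def predict(self, ca) -> np.ndarray:
        return activation_velocity(ca, self.v0, self.v_max, self.ka)


def activation_velocity(ca, v0: float, v_max: float, ka: float) -> np.ndarray:
    """One-site total-binding velocity law v = v0 + v_max [Ca]/(Ka + [Ca])."""
    ca = np.asarray(ca, dtype=float)
    return v0 + v_max * ca / (ka + ca)


def _fit_exp_fixed_order(t, f, order: int):
    span = float(np.max(f) - np.min(f))
    t_span = float(t[-1] - t[0])
    k0 = 2.0 / t_span

    if order == 1:
        theta0 = np.array([f[0], span if span > 0 else 1e-9, np.log10(k0)])
    else:
        theta0 = np.array([f[0], 0.6 * span if span > 0 else 1e-9,
                           0.4 * span if span > 0 else 1e-9,
                           np.log10(10 * k0), np.log10(k0 / 3)])

    def resid(theta):
        f0 = theta[0]
        a = theta[1 : 1 + order]
        k = 10.0 ** theta[1 + order :]
        pred = f0 + (a[:, None] * (1.0 - np.exp(-np.outer(k, t)))).sum(axis=0)
        return pred - f

    sol = least_squares(resid, theta0, method="lm", max_nfev=10000)
    return sol


def fit_exponential(curve: ProgressCurve, order: int = 1) -> ExponentialFit:
    """Fit a single or double rising-exponential model to a progress curve.

    Rates are fitted in log10 space; for ``order=2`` the returned rates are
    sorted descending so ``rates[-1]`` (``slow_rate``) is the slow phase.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    t, f = curve.time, curve.fluorescence
    warns: list[str] = []
    sol = _fit_exp_fixed_order(t, f, order)
    if not sol.success:
        warns.append(f"optimizer did not converge: {sol.message}")
    f0 = float(sol.x[0])
    amps = np.asarray(sol.x[1 : 1 + order], dtype=float)
    rates = 10.0 ** np.asarray(sol.x[1 + order :], dtype=float)
    rss = float(np.sum(sol.fun**2))

    n_par = 1 + 2 * order
    dof = max(t.size - n_par, 1)
    cov = np.linalg.pinv(sol.jac.T @ sol.jac) * rss / dof
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    se[1 + order :] = np.log(10.0) * rates * se[1 + order :]

    # enforce k1 >= k2 by sorting phases jointly with amplitudes and SEs
    idx = np.argsort(rates)[::-1]
    amps, rates = amps[idx], rates[idx]
    se_a, se_k = se[1 : 1 + order][idx], se[1 + order :][idx]
    se = np.concatenate([[se[0]], se_a, se_k])

    span = float(np.max(f) - np.min(f))
    if span < 1e-12 or np.max(np.abs(amps)) < 1e-9 * max(abs(f0), 1.0):
        warns.append("amplitude ~ 0: rate(s) unidentifiable")
    return ExponentialFit(order, f0, amps, rates, rss, t.size, se,
                          bool(sol.success), warns)


def choose_exponential_model(
    curve: ProgressCurve,
) -> tuple[int, dict[int, float], ExponentialFit]:
    """Pick exponential order 1 vs 2 by corrected AIC (ties -> order 1).

    When the single-exponential fit is already at the numerical noise floor
    (residuals ~ machine precision of the signal) the comparison is a tie by
    construction and order 1 wins on parsimony; AICc on machine-zero RSS
    values would otherwise amplify meaningless rounding differences.
    """
    fit1 = fit_exponential(curve, 1)
    fit2 = fit_exponential(curve, 2)
    scores = {1: fit1.aicc, 2: fit2.aicc}
    scale = float(np.ptp(curve.fluorescence))
    rss_floor = curve.time.size * (1e-8 * max(scale, 1e-300)) ** 2
    if fit1.rss <= rss_floor:
        return 1, scores, fit1
    if fit2.aicc < fit1.aicc - 1e-9:
        return 2, scores, fit2
    return 1, scores, fit1


def subtract_intrinsic(rates: pd.DataFrame, intrinsic: pd.DataFrame) -> pd.DataFrame:
    """Subtract the intrinsic rate at each matched Ca2+ concentration.

    ``rates`` needs columns (condition, ca_conc, rate); ``intrinsic`` needs
    (ca_conc, rate).  Matching is exact on ca_conc — no interpolation; a
    missing match raises.
    """
    for col in ("condition", "ca_conc", "rate"):
        if col not in rates.columns:
            raise ValueError(f"rates table missing column {col!r}")
    for col in ("ca_conc", "rate"):
        if col not in intrinsic.columns:
            raise ValueError(f"intrinsic table missing column {col!r}")
    lookup = dict(zip(intrinsic["ca_conc"], intrinsic["rate"]))
    missing = sorted(set(rates["ca_conc"]) - set(lookup))
    if missing:
        raise ValueError(
            f"no intrinsic rate measured at ca_conc={missing}; "
            "matched subtraction requires identical concentration sets"
        )
    out = rates.copy()
    out["rate_corrected"] = out["rate"] - out["ca_conc"].map(lookup)
    return out


def fit_activation(ca_conc, rate) -> ActivationFit:
    """Fit the Ca2+-activation hyperbola v = v0 + v_max [Ca]/(Ka + [Ca]).

    Needs >= 4 distinct concentrations including 0 (which anchors v0).
    Ka is fitted in log10 space.
    """
    ca = np.asarray(ca_conc, dtype=float)
    v = np.asarray(rate, dtype=float)
    if ca.size != v.size:
        raise ValueError("ca_conc and rate lengths differ")
    if np.unique(ca).size < 4:
        raise ValueError("need >= 4 distinct Ca2+ concentrations")
    if not np.any(ca == 0):
        raise ValueError("need a 0 Ca2+ point to anchor the basal rate")
    warns: list[str] = []

    v0_0 = float(np.mean(v[ca == 0]))
    v_span = float(np.max(v) - np.min(v))
    if v_span < 1e-15:
        warns.append("no rate enhancement: Ka unidentifiable")
        return ActivationFit(v0_0, 0.0, float(np.median(ca[ca > 0])),
                             0.0, np.inf, np.inf, float(np.sum((v - v0_0) ** 2)),
                             True, warns)
    ka0 = float(np.median(ca[ca > 0]))

    def resid(theta):
        return activation_velocity(ca, theta[0], theta[1], 10.0 ** theta[2]) - v

    sol = least_squares(resid, np.array([v0_0, v_span, np.log10(ka0)]),
                        method="lm", max_nfev=5000)
    v0, v_max, ka = float(sol.x[0]), float(sol.x[1]), float(10.0 ** sol.x[2])
    rss = float(np.sum(sol.fun**2))
    dof = max(ca.size - 3, 1)
    jtj = sol.jac.T @ sol.jac
    cov = np.linalg.pinv(jtj) * rss / dof
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    ka_se = float(np.log(10.0) * ka * se[2])
    if abs(v_max) < 1e-6 * max(abs(v0), 1e-12) or np.linalg.cond(jtj) > 1e12:
        warns.append("hyperbola has no resolvable curvature: Ka weakly identified")
    if not sol.success:
        warns.append(f"optimizer did not converge: {sol.message}")
    return ActivationFit(v0, v_max, ka, float(se[0]), float(se[1]), ka_se,
                         rss, bool(sol.success), warns)
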