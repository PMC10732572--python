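"""VP-ITC forward model and sequential-model fitter.

The calorimeter cell (volume ``V0``) is loaded with macromolecule and
titrated by stepwise injections from a syringe of concentrated ligand.  The
perfusion cell overflows, so after injection j the remaining fraction of the
original cell content is ``d_j = prod_{k<=j} (1 - v_k/V0)`` and the in-cell
totals are::

    m_j = m_0 * d_j          l_j = c_syr * (1 - d_j)

The heat content of the cell after injection j is the enthalpy held by every
bound state, ``H_j = V0 * m_j * sum_i DH_cum(i) * f_{i,j}``, where
``DH_cum(i)`` is the cumulative per-step enthalpy of the i-ligand species and
``f_{i,j}`` the population fraction from the sequential equilibrium.  The
measured heat of injection j is the change in heat content corrected for the
enthalpy carried out by the displaced volume, taken at the mean of the
adjacent compositions::

    q_j = H_j - H_{j-1} + (v_j/V0) * (H_j + H_{j-1}) / 2

and is reported per mole of injectant, q_j / (c_syr * v_j).  Heats of
dilution are not modelled (measured separately and negligible in the assays
this reproduces).

Fitting is plain nonlinear least squares on the per-mole heats with the
stepwise dissociation constants in log10 space and the enthalpies linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .equilibria import SequentialBindingModel, _fractions_at, _solve_free_vec

__all__ = [
    "ITCProtocol",
    "Isotherm",
    "ITCFitResult",
    "default_injection_volumes",
    "injection_concentrations",
    "simulate_isotherm",
    "fit_sequential_itc",
]


def default_injection_volumes(
    n_main: int = 28, main_ul: float = 10.0, first_ul: float = 2.0
) -> np.ndarray:
    """Standard VP-ITC schedule: a small discardable first injection followed
    by ``n_main`` equal injections.  Volumes in liters."""
    return np.array([first_ul] + [main_ul] * n_main) * 1e-6


@dataclass(frozen=True)
class ITCProtocol:
    """Geometry and concentrations of one ITC titration."""

    cell_volume: float = 1.4619e-3  # liters
    cell_conc: float = 110e-6  # molar macromolecule in cell
    syringe_conc: float = 1.5e-3  # molar ligand in syringe
    injection_volumes: np.ndarray = field(default_factory=default_injection_volumes)
    temperature: float = 298.15  # kelvin
    discard_first: bool = True

    def __post_init__(self) -> None:
        vols = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be positive")
        if vols.size == 0 or np.any(vols <= 0):
            raise ValueError("injection volumes must be positive")
        if np.any(vols > self.cell_volume):
            raise ValueError("injection volume exceeds cell volume")
        if not self.syringe_conc > self.cell_conc:
            raise ValueError("syringe_conc must exceed cell_conc")
        object.__setattr__(self, "injection_volumes", vols)

    @property
    def n_injections(self) -> int:
        return int(np.asarray(self.injection_volumes).size)


@dataclass(frozen=True)
class Isotherm:
    """Per-injection heats of one titration.

    ``q_per_mol`` is kcal per mole of injectant; ``raw_heat`` is the absolute
    heat of each injection in kcal; ``molar_ratio`` is the in-cell
    ligand/macromolecule total ratio after each injection.
    """

    molar_ratio: np.ndarray
    q_per_mol: np.ndarray
    raw_heat: np.ndarray
    protocol: ITCProtocol

    def __post_init__(self) -> None:
        mr = np.asarray(self.molar_ratio, dtype=float)
        q = np.asarray(self.q_per_mol, dtype=float)
        raw = np.asarray(self.raw_heat, dtype=float)
        if not (mr.size == q.size == raw.size):
            raise ValueError("molar_ratio, q_per_mol and raw_heat lengths differ")
        if np.any(np.diff(mr) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")
        object.__setattr__(self, "molar_ratio", mr)
        object.__setattr__(self, "q_per_mol", q)
        object.__setattr__(self, "raw_heat", raw)

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of injections used for fitting (first dropped when
        the protocol marks it discardable)."""
        mask = np.ones(self.q_per_mol.size, dtype=bool)
        if self.protocol.discard_first and mask.size:
            mask[0] = False
        return mask


@dataclass
class ITCFitResult:
    model: SequentialBindingModel
    kd_stderr: np.ndarray  # molar
    dh_stderr: np.ndarray  # kcal/mol
    rss: float
    converged: bool
    n_evaluations: int
    warnings: list[str] = field(default_factory=list)


def injection_concentrations(protocol: ITCProtocol, j: int) -> tuple[float, float]:
    """In-cell (m_total, l_total) after the j-th injection (1-based)."""
    if not 1 <= j <= protocol.n_injections:
        raise IndexError(
            f"injection index {j} out of range 1..{protocol.n_injections}"
        )
    m, ltot = _concentration_series(protocol)
    return float(m[j - 1]), float(ltot[j - 1])


def _concentration_series(protocol: ITCProtocol) -> tuple[np.ndarray, np.ndarray]:
    d = np.cumprod(1.0 - protocol.injection_volumes / protocol.cell_volume)
    return protocol.cell_conc * d, protocol.syringe_conc * (1.0 - d)


def _heat_contents(
    model: SequentialBindingModel, protocol: ITCProtocol
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell heat content H_j (kcal) plus the concentration series."""
    m, ltot = _concentration_series(protocol)
    kd = np.asarray(model.kd)
    l_free = _solve_free_vec(kd, m, ltot)
    fracs = _fractions_at(kd, l_free)  # (n+1, n_inj)
    h = protocol.cell_volume * m * (model.cumulative_dh @ fracs[1:])
    return h, m, ltot


def simulate_isotherm(model: SequentialBindingModel, protocol: ITCProtocol) -> Isotherm:
    """Forward-simulate the per-injection heats of a sequential titration."""
    h, m, ltot = _heat_contents(model, protocol)
    v = protocol.injection_volumes
    v0 = protocol.cell_volume
    h_prev = np.concatenate(([0.0], h[:-1]))
    q = h - h_prev + (v / v0) * 0.5 * (h + h_prev)
    q_per_mol = q / (protocol.syringe_conc * v)
    return Isotherm(ltot / m, q_per_mol, q, protocol)


def _residuals(theta: np.ndarray, isotherm: Isotherm, n_sites: int) -> np.ndarray:
    kd = 10.0 ** theta[:n_sites]
    dh = theta[n_sites:]
    model = SequentialBindingModel(kd=tuple(kd), dh=tuple(dh),
                                   temperature=isotherm.protocol.temperature)
    sim = simulate_isotherm(model, isotherm.protocol)
    mask = isotherm.usable
    return sim.q_per_mol[mask] - isotherm.q_per_mol[mask]


def fit_sequential_itc(
    isotherm: Isotherm,
    init: SequentialBindingModel,
    max_nfev: int = 2000,
    multistart: bool = True,
) -> ITCFitResult:
    """Fit the stepwise (Kd_i, dH_i) of a sequential model to an isotherm.

    Dissociation constants are optimised in log10 space, enthalpies on their
    natural scale.  If the single start stalls at a poor minimum, restarts
    with all Kd scaled by 0.1 and 10 are attempted and the best kept.
    """
    n_usable = int(isotherm.usable.sum())
    n_par = 2 * init.n_sites
    if n_usable < max(12, n_par):
        raise ValueError(f"need >= 12 usable injections, got {n_usable}")

    warns: list[str] = []
    q_scale = float(np.max(np.abs(isotherm.q_per_mol[isotherm.usable])))
    if q_scale < 1e-12:
        warns.append("all heats ~0: Kd unidentifiable, dH ~ 0")

    def run(start_kd_scale: float):
        theta0 = np.concatenate(
            [np.log10(np.asarray(init.kd) * start_kd_scale), np.asarray(init.dh)]
        )
        return least_squares(
            _residuals, theta0, args=(isotherm, init.n_sites),
            method="lm", max_nfev=max_nfev,
        )

    best = run(1.0)
    nfev = best.nfev
    if multistart and q_scale > 0:
        rms = np.sqrt(np.mean(best.fun**2))
        if rms > 1e-3 * q_scale:
            for scale in (0.1, 10.0):
                alt = run(scale)
                nfev += alt.nfev
                if np.sum(alt.fun**2) < np.sum(best.fun**2):
                    best = alt

    n = init.n_sites
    kd_fit = 10.0 ** best.x[:n]
    dh_fit = best.x[n:]
    model = SequentialBindingModel(kd=tuple(kd_fit), dh=tuple(dh_fit),
                                   temperature=isotherm.protocol.temperature)
    rss = float(np.sum(best.fun**2))
    kd_se, dh_se, cond_warn = _stderr_from_jacobian(best.jac, best.fun, kd_fit)
    if cond_warn:
        warns.append(cond_warn)
    converged = bool(best.success) and not np.any(np.isnan(best.x))
    if not converged:
        warns.append(f"optimizer did not converge: {best.message}")
    return ITCFitResult(model, kd_se, dh_se, rss, converged, int(nfev), warns)


def _stderr_from_jacobian(jac, resid, kd_fit):
    """Linearised parameter standard errors at the optimum.

    Errors for the log10-space Kd parameters are propagated to the natural
    scale (se_kd = ln(10) * kd * se_log10kd).
    """
    n_par = jac.shape[1]
    n = kd_fit.size
    dof = max(jac.shape[0] - n_par, 1)
    s2 = float(np.sum(resid**2)) / dof
    jtj = jac.T @ jac
    warn = None
    try:
        cond = np.linalg.cond(jtj)
        if cond > 1e12:
            warn = f"ill-conditioned fit (cond={cond:.2e}); errors unreliable"
        cov = np.linalg.pinv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)
        warn = "singular Jacobian; no parameter errors"
    kd_se = np.log(10.0) * kd_fit * se[:n]
    dh_se = se[n:]
    return kd_se, dh_se, warn
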