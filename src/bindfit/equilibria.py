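"""Stoichiometric sequential binding equilibria.

A macromolecule M binds up to ``n`` ligands L through a ladder of
stoichiometric (stepwise) steps::

    M + L <-> ML1,   ML1 + L <-> ML2,   ...   (K_1 ... K_n)

Each step i is characterised by a stepwise dissociation constant ``kd[i]``
(molar) and a per-step molar enthalpy change ``dh[i]`` (kcal/mol).  These
constants are stoichiometric: they describe adding the i-th ligand to the
population, irrespective of which physical site it occupies.  The overall
association constants are the cascade products ``beta_i = prod_{k<=i} 1/kd[k]``
and the fraction of macromolecule carrying exactly i ligands at free-ligand
concentration ``l`` is the binding-polynomial term::

    f_i = beta_i l^i / (1 + sum_k beta_k l^k)

The only nonlinear step is inverting the ligand mass balance
``l + m_tot * nbar(l) = l_tot`` for the free concentration; the left side is
strictly increasing in ``l`` so a bracketed bisection on ``[0, l_tot]`` is
exact and unconditionally robust.

All concentrations are molar and temperatures kelvin inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_CAL",
    "SequentialBindingModel",
    "SpeciesState",
    "ThetaProfile",
    "stepwise_to_overall",
    "solve_free_ligand",
    "site_occupancy_profile",
    "delta_g",
    "one_to_one_bound_fraction",
]

#: Gas constant used for all thermodynamic conversions, cal/(mol K).
R_CAL = 1.986

_BISECT_ITER = 90  # interval shrinks by 2**-90, far below 1e-12 relative


@dataclass(frozen=True)
class SequentialBindingModel:
    """Stepwise dissociation constants and enthalpies for an n-step ladder.

    Parameters
    ----------
    kd
        Stepwise dissociation constants, molar, one per binding step.
    dh
        Per-step molar enthalpy changes, kcal/mol.
    temperature
        Absolute temperature in kelvin (default 298.15, i.e. 25 degC).
    """

    kd: tuple[float, ...]
    dh: tuple[float, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        kd = tuple(float(k) for k in self.kd)
        dh = tuple(float(h) for h in self.dh)
        if len(kd) != len(dh):
            raise ValueError("kd and dh must have the same length")
        if len(kd) < 1:
            raise ValueError("at least one binding step required")
        if any(not np.isfinite(k) or k <= 0 for k in kd):
            raise ValueError(f"all stepwise Kd must be positive and finite, got {kd}")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")
        object.__setattr__(self, "kd", kd)
        object.__setattr__(self, "dh", dh)

    @property
    def n_sites(self) -> int:
        return len(self.kd)

    @property
    def beta(self) -> np.ndarray:
        """Overall association constants beta_i = prod_{k<=i} 1/kd[k]."""
        return np.cumprod(1.0 / np.asarray(self.kd))

    @property
    def cumulative_dh(self) -> np.ndarray:
        """Total enthalpy content of the i-ligand species, kcal/mol."""
        return np.cumsum(np.asarray(self.dh))


@dataclass(frozen=True)
class SpeciesState:
    """Speciation of the ladder at one (m_total, l_total) composition."""

    l_free: float
    fractions: np.ndarray  # f_0 .. f_n, population fractions
    m_total: float
    l_total: float

    @property
    def bound_per_macromolecule(self) -> float:
        """Mean number of ligands bound, <n> = sum i * f_i."""
        i = np.arange(self.fractions.size)
        return float(np.dot(i, self.fractions))


@dataclass(frozen=True)
class ThetaProfile:
    """Per-step availability along a titration.

    ``theta[i - 1, j]`` is the fraction of macromolecules at which
    stoichiometric step ``i`` has not yet occurred (fewer than i ligands
    bound) at total-ligand grid point j.  This stoichiometric-step reading
    of "fraction of sites available" is an interpretive choice recorded in
    :attr:`definition`.
    """

    l_total_grid: np.ndarray
    theta: np.ndarray  # shape (n_sites, len(grid))
    definition: str = "theta_i = P(fewer than i ligands bound) = sum_{j<i} f_j"


def stepwise_to_overall(model: SequentialBindingModel) -> np.ndarray:
    """Convert stepwise Kd to overall association constants beta_i.

    beta_i has units M^-i; beta_1 = 1/kd[0].
    """
    return model.beta


def _fractions_at(kd: np.ndarray, l_free):
    """Population fractions f_0..f_n at free-ligand concentration(s) l_free."""
    l = np.asarray(l_free, dtype=float)
    n = kd.size
    # terms_i = beta_i * l^i built as a running product of l/kd_i, which keeps
    # intermediates near unity even for nanomolar kd
    terms = np.empty((n,) + l.shape)
    running = np.ones_like(l)
    for i in range(n):
        running = running * l / kd[i]
        terms[i] = running
    poly = 1.0 + terms.sum(axis=0)
    fracs = np.empty((n + 1,) + l.shape)
    fracs[0] = 1.0 / poly
    fracs[1:] = terms / poly
    return fracs


def _nbar(kd: np.ndarray, l_free):
    """Mean ligands bound per macromolecule at free concentration l_free."""
    fracs = _fractions_at(kd, l_free)
    i = np.arange(kd.size + 1).reshape((-1,) + (1,) * (np.ndim(l_free)))
    return (i * fracs).sum(axis=0)


def _solve_free_vec(kd: np.ndarray, m_total, l_total: np.ndarray) -> np.ndarray:
    """Vectorised bisection for the free-ligand concentration.

    The residual g(l) = l + m_total*nbar(l) - l_total is strictly increasing
    on [0, l_total] with g(0) <= 0 and g(l_total) >= 0, so the bracket never
    fails.  ``m_total`` may be a scalar or an array broadcastable against
    ``l_total`` (titrations dilute the macromolecule as ligand accumulates).
    """
    l_total = np.asarray(l_total, dtype=float)
    m_total = np.broadcast_to(np.asarray(m_total, dtype=float), l_total.shape)
    lo = np.zeros_like(l_total)
    hi = l_total.copy()
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        resid = mid + m_total * _nbar(kd, mid) - l_total
        high = resid > 0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


def solve_free_ligand(
    model: SequentialBindingModel, m_total: float, l_total: float
) -> SpeciesState:
    """Solve the ligand mass balance for one composition.

    Returns the free-ligand concentration and the population fractions
    f_0..f_n of macromolecules carrying exactly i ligands.
    """
    if m_total < 0 or l_total < 0:
        raise ValueError("totals must be non-negative")
    kd = np.asarray(model.kd)
    if l_total == 0.0:
        fracs = np.zeros(model.n_sites + 1)
        fracs[0] = 1.0
        return SpeciesState(0.0, fracs, m_total, l_total)
    if m_total == 0.0:
        return SpeciesState(
            float(l_total), _fractions_at(kd, float(l_total)), m_total, l_total
        )
    l_free = float(_solve_free_vec(kd, m_total, np.asarray([l_total]))[0])
    return SpeciesState(l_free, _fractions_at(kd, l_free), m_total, l_total)


def site_occupancy_profile(
    model: SequentialBindingModel, m_total: float, l_total_grid
) -> ThetaProfile:
    """Availability of each stoichiometric step along a titration grid."""
    grid = np.asarray(l_total_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("l_total_grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("l_total_grid must be sorted ascending")
    kd = np.asarray(model.kd)
    l_free = _solve_free_vec(kd, m_total, grid)
    fracs = _fractions_at(kd, l_free)  # (n+1, m)
    # theta_i = sum_{j<i} f_j = cumulative fraction with fewer than i bound
    theta = np.cumsum(fracs, axis=0)[:-1]
    return ThetaProfile(grid, theta)


def delta_g(kd: float, temperature: float) -> float:
    """Binding free energy dG = -R T ln(1/Kd), in kcal/mol.

    Uses R = 1.986 cal/(mol K).  Negative for sub-molar Kd (favourable
    binding); zero at the 1 M reference state.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -(R_CAL / 1000.0) * temperature * np.log(1.0 / kd)


def one_to_one_bound_fraction(kd: float, m_total: float, l_total: float) -> float:
    """Fraction of macromolecule bound in a 1:1 equilibrium, exact quadratic.

    The complex concentration is the stable root of
    c**2 - c (m + l + kd) + m l = 0; dividing by ``m_total`` gives the bound
    fraction.  In the ligand-excess limit this reduces to l/(kd + l).
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if m_total < 0 or l_total < 0:
        raise ValueError("totals must be non-negative")
    if m_total == 0.0 or l_total == 0.0:
        return 0.0
    b = m_total + l_total + kd
    disc = b * b - 4.0 * m_total * l_total
    # numerically stable smaller root: 2 m l / (b + sqrt(disc))
    complex_conc = 2.0 * m_total * l_total / (b + np.sqrt(disc))
    return float(complex_conc / m_total)
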