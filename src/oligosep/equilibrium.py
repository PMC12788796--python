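"""Chemical (assembly) equilibrium in one homogeneous phase.

At assembly equilibrium every species shares the monomer exchange
chemical potential, ``mu_i = mu_1``.  Solving this condition for the free
energy of :mod:`oligosep.thermo` gives each ``phi_i`` explicitly in terms
of the monomer fraction ``phi_1`` and the solvent fraction ``phi_s``:

``phi_i = i (phi_1)^i exp[ i (1 - (omega_i - omega_1)/T
- (chi_is - chi_1s) phi_s / T) - 1 ]``

Monomer conservation ``sum_i phi_i = phi_tot`` then fixes ``phi_1`` for a
given conserved total ``phi_tot``; the left side is strictly increasing
in ``phi_1``, so a bracketed root solve is unconditionally safe.  All
sums are evaluated in log space because the exponents grow linearly with
assembly size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import linregress

from .thermo import (
    InteractionClass,
    MixtureSpec,
    SizeDistribution,
    free_energy_density,
)

__all__ = [
    "GelationError",
    "ThresholdCurve",
    "DistributionStats",
    "log_distribution_from_monomer",
    "distribution_from_monomer",
    "equilibrium_distribution",
    "assembly_threshold",
    "effective_free_energy",
    "distribution_statistics",
]

_LOG_OVERFLOW = 700.0  # ln of ~largest double


class GelationError(RuntimeError):
    """Raised when the finite-size series cannot absorb phi_tot.

    For d > 1 this signals gelation: beyond the sol-gel threshold the
    sum over finite assembly sizes saturates and the missing material
    belongs to a macroscopic (gel) assembly.
    """


def _log_phi(log_phi1: float, phi_s: float, spec: MixtureSpec, M: int | None = None) -> np.ndarray:
    """log(phi_i) for i = 1..M at given monomer fraction (vectorized).

    ``phi_s`` enters only through the class-2 interaction difference
    (chi_is - chi_1s); for class 1 that term vanishes identically.
    """
    i = np.arange(1, (M or spec.M) + 1, dtype=float)
    T = spec.T
    dw = spec.delta_omega  # omega_i - omega_1 = dw*(1 - i^(-1/d))
    shape = 1.0 - i ** (-1.0 / spec.d)
    b = dw * shape
    if spec.interaction_class is InteractionClass.CLASS2:
        b = b + (spec.chi_prime - spec.chi) * shape * phi_s
    return np.log(i) + i * log_phi1 + i * (1.0 - b / T) - 1.0


def log_distribution_from_monomer(
    log_phi1: float, phi_tot: float, spec: MixtureSpec
) -> np.ndarray:
    """log(phi_i), i = 1..M, with phi_s = 1 - phi_tot in the class-2 term."""
    return _log_phi(log_phi1, 1.0 - phi_tot, spec)


def distribution_from_monomer(
    phi_1: float, phi_tot_guess: float, spec: MixtureSpec
) -> SizeDistribution:
    """Size distribution implied by a given monomer volume fraction.

    The solvent fraction appearing in the class-2 Boltzmann factor is
    taken as ``1 - phi_tot_guess`` (at the self-consistent solution of
    the conservation equation this agrees with the distribution's own
    solvent fraction).
    """
    if not 0.0 < phi_1 < 1.0:
        raise ValueError(f"phi_1 must lie in (0, 1), got {phi_1}")
    lp = log_distribution_from_monomer(math.log(phi_1), phi_tot_guess, spec)
    bad = np.nonzero(lp > _LOG_OVERFLOW)[0]
    if bad.size:
        raise OverflowError(
            f"phi_i overflows at assembly size i={bad[0] + 1} "
            f"(log phi_i = {lp[bad[0]]:.3g}); phi_1={phi_1} is far beyond "
            "the physical range for this parameter set"
        )
    return SizeDistribution(np.exp(lp))


def _solve_log_phi1(phi_tot: float, spec: MixtureSpec) -> float:
    """Root of logsumexp(log phi_i(phi_1)) = log phi_tot, in log phi_1."""
    log_target = math.log(phi_tot)

    def g(lp1: float) -> float:
        return logsumexp(log_distribution_from_monomer(lp1, phi_tot, spec)) - log_target

    hi = log_target  # phi_1 = phi_tot alone already gives sum >= phi_tot
    lo = hi - 4.0
    glo = g(lo)
    while glo > 0.0:
        lo -= 8.0
        if lo < -1400.0:  # pragma: no cover - pathological parameters
            raise RuntimeError("could not bracket the conservation root")
        glo = g(lo)
    return brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)


def equilibrium_distribution(phi_tot: float, spec: MixtureSpec) -> SizeDistribution:
    """Assembly-equilibrium distribution at fixed total volume fraction.

    Finds ``phi_1`` such that monomer conservation holds (residual below
    1e-12 relative) and returns the full distribution, which satisfies
    ``mu_i = mu_1`` by construction.

    Raises
    ------
    GelationError
        For d > 1 when material piles up at the truncation boundary
        (``phi_M`` not negligible), i.e. beyond the gel point where no
        finite-size distribution can absorb ``phi_tot``.
    """
    if not 0.0 < phi_tot < 1.0:
        raise ValueError(f"phi_tot must lie in (0, 1), got {phi_tot}")
    if spec.M == 1:
        return SizeDistribution(np.array([phi_tot]))
    lp1 = _solve_log_phi1(phi_tot, spec)
    phi = np.exp(log_distribution_from_monomer(lp1, phi_tot, spec))
    if spec.d > 1 and phi[-1] > 1e-6 * phi_tot:
        raise GelationError(
            f"no valid finite-size root: phi_M/phi_tot = {phi[-1] / phi_tot:.2e} "
            f"at M={spec.M}; for d={spec.d} this indicates gelation "
            "(phi_tot beyond the sol-gel threshold) or an insufficient truncation"
        )
    return SizeDistribution(phi)


def _dlog_phi_di_at_1(log_phi1: float, phi_tot: float, spec: MixtureSpec) -> float:
    """d(ln phi_i)/di at i = 1, treating i as continuous (analytic).

    From ``ln phi_i = ln i + i ln phi_1 + i(1 - B(1 - i^(-1/d))) - 1``
    with ``B = (delta_omega + (chi' - chi) phi_s)/T`` (class-2 term only),
    the derivative at i = 1 is ``2 + ln phi_1 - B/d``.
    """
    B = spec.delta_omega
    if spec.interaction_class is InteractionClass.CLASS2:
        B = B + (spec.chi_prime - spec.chi) * (1.0 - phi_tot)
    B /= spec.T
    return 2.0 + log_phi1 - B / spec.d


@dataclass
class ThresholdCurve:
    """Sampled assembly-threshold curve ``phi*(T)``.

    Interpolates with a monotone piecewise-linear rule; defined only at
    temperatures where the threshold condition has a solution.
    """

    T: np.ndarray
    phi_star: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.phi_star = np.asarray(self.phi_star, dtype=float)
        order = np.argsort(self.T)
        self.T = self.T[order]
        self.phi_star = self.phi_star[order]

    def __call__(self, T: np.ndarray | float) -> np.ndarray | float:
        return np.interp(T, self.T, self.phi_star)


def assembly_threshold(T: float, spec: MixtureSpec) -> float | None:
    """Total volume fraction ``phi*`` where the monomer peak flattens.

    ``phi*`` is the ``phi_tot`` at which the continuous-i derivative of
    the size distribution vanishes at i = 1; below it the distribution is
    monomer dominated, above it intermediate sizes appear.  Returns
    ``None`` when the derivative never vanishes for ``phi_tot`` in (0, 1)
    ("no threshold").
    """
    if spec.M < 2:
        raise ValueError("assembly threshold requires M >= 2")
    spec = spec.at_temperature(T)

    def g(phi_tot: float) -> float:
        lp1 = _solve_log_phi1(phi_tot, spec)
        return _dlog_phi_di_at_1(lp1, phi_tot, spec)

    lo, hi = 1e-12, 1.0 - 1e-12
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0.0:
        return None
    return brentq(g, lo, hi, xtol=1e-10, rtol=8.9e-16)


def threshold_curve(spec: MixtureSpec, T_grid: np.ndarray) -> ThresholdCurve:
    """Sample ``phi*(T)`` on a temperature grid (NaN where undefined)."""
    phis = np.array(
        [assembly_threshold(float(T), spec) or np.nan for T in np.asarray(T_grid, float)]
    )
    return ThresholdCurve(np.asarray(T_grid, float), phis)


def effective_free_energy(phi_tot: float, spec: MixtureSpec) -> float:
    """Free energy density at assembly equilibrium, ``f(phi_tot)``.

    Recasts the multicomponent free energy in terms of the conserved
    variable.  Smooth across the assembly threshold for d = 1 (crossing
    ``phi*`` is not a phase transition).
    """
    return free_energy_density(equilibrium_distribution(phi_tot, spec), spec)


@dataclass
class DistributionStats:
    i_max: int
    mean_size: float
    tail_decay_rate: float | None
    tail_r2: float | None


def distribution_statistics(state: SizeDistribution) -> DistributionStats:
    """Peak position, phi-weighted mean size and exponential tail fit.

    The tail decay rate is the magnitude of the slope of ``ln phi_i``
    versus ``i`` for ``i > i_max`` (exponential decay of the large-size
    tail); unavailable (None) when fewer than two sizes lie beyond the
    peak or M < 3.
    """
    phi = state.phi
    i_max = int(np.argmax(phi)) + 1
    mean = float(np.dot(state.sizes, phi) / phi.sum())
    rate = r2 = None
    if state.M >= 3:
        tail = np.arange(i_max, state.M)  # indices of i > i_max
        tail = tail[phi[tail] > 0.0]
        if tail.size >= 2:
            fit = linregress(tail + 1.0, np.log(phi[tail]))
            rate = float(-fit.slope)
            r2 = float(fit.rvalue**2)
    return DistributionStats(i_max, mean, rate, r2)
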