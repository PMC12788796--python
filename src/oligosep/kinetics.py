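"""Reaction-limited assembly kinetics in two coexisting phases.

The two phases are held at phase equilibrium at all times (diffusion
across the interface is fast), while association/dissociation reactions
relax the size distribution slowly.  Within each phase the volume
fraction of size-``i`` assemblies obeys

``d(phi_i)/dt = r_i - j_i - phi_i * dln(V)/dt``

where ``r_i`` are mass-action reaction rates driven by the exchange
chemical potentials,

``Delta_r_ij = k_ij [exp((i mu_i + j mu_j)/T) - exp((i+j) mu_{i+j}/T)]``,

``j_i`` are diffusive exchange rates between the phases, and the last
term accounts for the phase volumes changing.  Mass conservation at the
interface ties the fluxes of the two phases together
(``j_i^I = -j_i^II V^II/V^I``); the fluxes themselves are determined by
requiring that the phase-equilibrium conditions (equal ``mu_i`` and
equal osmotic pressure) are preserved in time, which yields an
(M+1)-dimensional linear system per step.

Only linear assemblies (d = 1) are supported: for d > 1 gelation would
require tracking an unbounded size range along the trajectory.

Time is measured in units of ``t_0 = 0.01/k_tilde``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import root

from .equilibrium import equilibrium_distribution
from .phases import CoexistenceState, common_tangent
from .thermo import (
    MixtureSpec,
    SizeDistribution,
    chemical_potential_jacobian,
    exchange_chemical_potentials,
    free_energy_density,
    osmotic_pressure,
)

__all__ = [
    "RateForm",
    "RateModel",
    "TwoPhaseState",
    "KineticsTrajectory",
    "pair_rate",
    "referenced_rate_model",
    "net_rates",
    "exchange_fluxes",
    "step",
    "integrate",
    "embed_monomer_coexistence",
    "volume_change_map",
]


class RateForm(enum.Enum):
    """Size dependence of the kinetic rate coefficient ``k_ij``."""

    CONSTANT = "constant"
    PRODUCT = "product"  # k_tilde/(i*j): reduced mobility of large assemblies
    CUSTOM = "custom"


@dataclass(frozen=True)
class RateModel:
    """Kinetic rate coefficients and step-size convention.

    ``k_tilde`` sets the time unit through ``t_0 = 0.01/k_tilde``; the
    default size dependence is a constant ``k_ij = k_tilde`` (the form is
    pluggable because the size dependence is system specific).
    """

    k_tilde: float = 1.0
    k_ij_form: RateForm = RateForm.CONSTANT
    dt_factor: float = 1.0
    custom_k: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.k_tilde <= 0:
            raise ValueError("k_tilde must be positive")
        if not isinstance(self.k_ij_form, RateForm):
            object.__setattr__(self, "k_ij_form", RateForm(self.k_ij_form))
        if self.k_ij_form is RateForm.CUSTOM and self.custom_k is None:
            raise ValueError("custom rate form requires custom_k")

    @property
    def t0(self) -> float:
        return 0.01 / self.k_tilde

    def k_matrix(self, M: int) -> np.ndarray:
        i = np.arange(1, M + 1, dtype=float)
        if self.k_ij_form is RateForm.CONSTANT:
            K = np.full((M, M), self.k_tilde)
        elif self.k_ij_form is RateForm.PRODUCT:
            K = self.k_tilde / np.outer(i, i)
        else:
            K = np.asarray(self.custom_k(i[:, None], i[None, :]), dtype=float)
        if not np.allclose(K, K.T, rtol=1e-12):
            raise ValueError("k_ij must be symmetric")
        if np.any(K < 0):
            raise ValueError("k_ij must be non-negative")
        return K

    def log_k_matrix(self, M: int) -> np.ndarray:
        """log(k_ij), cached; -inf marks forbidden channels."""
        cache = self.__dict__.setdefault("_logk_cache", {})
        if M not in cache:
            with np.errstate(divide="ignore"):
                cache[M] = np.log(self.k_matrix(M))
        return cache[M]


def referenced_rate_model(
    spec: MixtureSpec,
    mu_ref: float,
    k_tilde: float = 1.0,
    dt_factor: float = 1.0,
) -> RateModel:
    """Rate coefficients referenced to a chemical potential ``mu_ref``.

    ``k_ij = k_tilde * exp(-(i+j) mu_ref / k_B T)`` measures the
    mass-action activities relative to a reference state instead of the
    dilute standard state.  With ``mu_ref`` near the equilibrium
    chemical potential the reaction channels relax on comparable O(1/k)
    timescales; with a constant coefficient the large-size channels are
    exponentially frozen whenever the equilibrium chemical potential is
    appreciably negative.  Equilibria and detailed balance are
    unaffected (the prefactor is positive and symmetric).
    """
    T = spec.T

    def k(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return k_tilde * np.exp(-(i + j) * mu_ref / T)

    return RateModel(
        k_tilde=k_tilde, k_ij_form=RateForm.CUSTOM, dt_factor=dt_factor, custom_k=k
    )


@dataclass
class TwoPhaseState:
    """Instantaneous state: per-phase distributions and relative volume.

    ``v_I = V^I/V``; the global composition ``psi_i = v_I phi_i^I +
    (1 - v_I) phi_i^II`` and the total volume are the conserved
    quantities of the kinetics.
    """

    phi_I: np.ndarray
    phi_II: np.ndarray
    v_I: float

    def __post_init__(self) -> None:
        self.phi_I = np.asarray(self.phi_I, dtype=float)
        self.phi_II = np.asarray(self.phi_II, dtype=float)
        if not 0.0 < self.v_I < 1.0:
            raise ValueError("v_I must lie strictly between 0 and 1")

    @property
    def M(self) -> int:
        return self.phi_I.size

    @property
    def psi(self) -> np.ndarray:
        return self.v_I * self.phi_I + (1.0 - self.v_I) * self.phi_II

    @property
    def phi_tot(self) -> float:
        return float(self.psi.sum())

    def distributions(self) -> tuple[SizeDistribution, SizeDistribution]:
        return SizeDistribution(self.phi_I), SizeDistribution(self.phi_II)

    def total_free_energy(self, spec: MixtureSpec) -> float:
        """F/V = v_I f(phase I) + (1 - v_I) f(phase II)."""
        dI, dII = self.distributions()
        return self.v_I * free_energy_density(dI, spec) + (
            1.0 - self.v_I
        ) * free_energy_density(dII, spec)

    def phase_equilibrium_residual(self, spec: MixtureSpec) -> float:
        dI, dII = self.distributions()
        muI = exchange_chemical_potentials(dI, spec)
        muII = exchange_chemical_potentials(dII, spec)
        dPi = osmotic_pressure(dI, spec) - osmotic_pressure(dII, spec)
        return max(float(np.max(np.abs(muI - muII))), abs(dPi))


@dataclass
class KineticsTrajectory:
    """Recorded time series of a two-phase relaxation."""

    times: np.ndarray  # in units of t_0
    phi_I: np.ndarray  # (n_times, M)
    phi_II: np.ndarray
    v_I: np.ndarray
    free_energy: np.ndarray  # F/V
    rates_I: np.ndarray | None = None
    rates_II: np.ndarray | None = None
    converged: bool = False

    def final_state(self) -> TwoPhaseState:
        return TwoPhaseState(self.phi_I[-1], self.phi_II[-1], float(self.v_I[-1]))


def _mu_exponents(phi: np.ndarray, spec: MixtureSpec) -> np.ndarray:
    """e_i = i*mu_i/(k_B T) for one phase."""
    st = SizeDistribution(phi)
    mu = exchange_chemical_potentials(st, spec)
    return st.sizes * mu / spec.T


def pair_rate(
    i: int, j: int, state: SizeDistribution, spec: MixtureSpec, rates: RateModel
) -> float:
    """Net mass-action rate of the reaction (i) + (j) <-> (i+j).

    Positive for net association.  Returns 0 when ``i + j > M``
    (truncation closure).  The two exponentials share an exponent shift
    so the difference stays finite as the exponents grow with size.
    """
    if i < 1 or j < 1:
        raise ValueError("assembly sizes must be >= 1")
    if i + j > spec.M:
        return 0.0
    e = _mu_exponents(state.phi, spec)
    a = e[i - 1] + e[j - 1]
    b = e[i + j - 1]
    m = max(a, b)
    logk = rates.log_k_matrix(spec.M)[i - 1, j - 1]
    return float(math.exp(logk + m) * (math.exp(a - m) - math.exp(b - m)))


def _pair_rate_matrix(phi: np.ndarray, spec: MixtureSpec, logK: np.ndarray) -> np.ndarray:
    """Delta_r[i-1, j-1] for all pairs with i + j <= M (0 elsewhere).

    Works with log(k_ij) and a shared per-pair exponent shift so that
    neither large rate coefficients nor large chemical-potential
    exponents overflow individually."""
    M = spec.M
    e = _mu_exponents(phi, spec)
    a = e[:, None] + e[None, :]
    b = np.full((M, M), -np.inf)
    ii = np.arange(M)
    mask = ii[:, None] + ii[None, :] + 2 <= M
    b[mask] = e[(ii[:, None] + ii[None, :] + 1)[mask]]
    m = np.maximum(a, b)
    dr = np.zeros((M, M))
    with np.errstate(over="raise"):
        dr[mask] = np.exp(logK[mask] + m[mask]) * (
            np.exp(a[mask] - m[mask]) - np.exp(b[mask] - m[mask])
        )
    return dr


def net_rates(state: SizeDistribution, spec: MixtureSpec, rates: RateModel) -> np.ndarray:
    """Volume-fraction reaction rates r_1..r_M for one phase.

    ``r_i = (i/2) * sum_{j+k=i} Delta_r_jk - i * sum_j Delta_r_ij`` with
    standard mass-action stoichiometry: a like-pair reaction (j = k, or
    j = i) consumes/produces two identical partners per event, so the
    diagonal terms carry multiplicity two in both the gain convolution
    and the loss sum.  The rates are volume conserving:
    ``sum_i r_i = 0`` identically.
    """
    dr = _pair_rate_matrix(state.phi, spec, rates.log_k_matrix(spec.M))
    return _net_rates_from_matrix(dr, spec.M)


def _net_rates_from_matrix(dr: np.ndarray, M: int) -> np.ndarray:
    sizes = np.arange(1, M + 1, dtype=float)
    # gain: ordered convolution with the symmetric pair counted twice
    gain = np.zeros(M)
    for n in range(2, M + 1):
        j = np.arange(1, n)
        g = dr[j - 1, n - j - 1].sum()
        if n % 2 == 0:
            g += dr[n // 2 - 1, n // 2 - 1]
        gain[n - 1] = g
    loss = dr.sum(axis=1) + np.diagonal(dr)
    return sizes / 2.0 * gain - sizes * loss


def exchange_fluxes(
    state: TwoPhaseState,
    r_I: np.ndarray,
    r_II: np.ndarray,
    spec: MixtureSpec,
) -> tuple[np.ndarray, float]:
    """Diffusive exchange rates that preserve phase equilibrium.

    Returns ``(j^II_1..M, j_s^II)``; phase-I fluxes follow from interface
    mass conservation, ``j^I = -j^II V^II/V^I``.  Obtained by chain-ruling
    ``d(mu_i^I - mu_i^II)/dt = 0`` for every i and
    ``d(Pi^I - Pi^II)/dt = 0`` through the evolution equations, which is
    linear in the M+1 unknown fluxes.
    """
    dI, dII = state.distributions()
    JI = chemical_potential_jacobian(dI, spec)
    JII = chemical_potential_jacobian(dII, spec)
    v = state.v_I
    beta = (1.0 - v) / v
    # unknowns x = (u_1..u_M, u_s) with u = j^II; S = sum(u) + u_s;
    # dphi^II/dt = r^II - u + phi^II S ; dphi^I/dt = r^I + beta u - beta phi^I S
    cI = beta * (JI @ state.phi_I)
    cII = JII @ state.phi_II
    A = np.empty((state.M + 1, state.M + 1))
    A[: state.M, : state.M] = beta * JI + JII - np.outer(cI + cII, np.ones(state.M))
    A[: state.M, state.M] = -(cI + cII)
    b = np.empty(state.M + 1)
    b[: state.M] = JII @ r_II - JI @ r_I
    # pressure row: dPi/dphi_k = (phi . J)_k / nu_1
    pI = state.phi_I @ JI / spec.nu_1
    pII = state.phi_II @ JII / spec.nu_1
    cPi = beta * float(pI @ state.phi_I) + float(pII @ state.phi_II)
    A[state.M, : state.M] = beta * pI + pII - cPi
    A[state.M, state.M] = -cPi
    b[state.M] = float(pII @ r_II - pI @ r_I)
    # row equilibration: constraint rows for trace species carry 1/phi_i
    # factors of ~1/floor; left unscaled they leak O(eps/phi_i) errors
    # into the monomer and solvent fluxes during elimination
    row = np.max(np.abs(A), axis=1)
    row[row == 0.0] = 1.0
    try:
        x = np.linalg.solve(A / row[:, None], b / row)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(
            "singular phase-equilibrium constraint system (state too close to "
            "a critical point); use a smaller step or a different state"
        ) from err
    return x[:-1], float(x[-1])


def _derivatives(state: TwoPhaseState, spec: MixtureSpec, rates: RateModel):
    """Time derivatives of the conserved variables (y^I, y^II, v).

    ``y^P = v^P phi^P`` are per-phase amounts per total volume; their sum
    over phases and sizes is the conserved phi_tot, so an explicit Euler
    update of (y, v) conserves composition and volume to round-off.
    """
    logK = rates.log_k_matrix(spec.M)
    r_I = _net_rates_from_matrix(_pair_rate_matrix(state.phi_I, spec, logK), spec.M)
    r_II = _net_rates_from_matrix(_pair_rate_matrix(state.phi_II, spec, logK), spec.M)
    u, u_s = exchange_fluxes(state, r_I, r_II, spec)
    S = float(u.sum()) + u_s
    v, w = state.v_I, 1.0 - state.v_I
    dy_I = v * r_I + w * u
    dy_II = w * r_II - w * u
    dv = S * w
    return dy_I, dy_II, dv, r_I, r_II


def step(
    state: TwoPhaseState,
    spec: MixtureSpec,
    rates: RateModel,
    dt: float | None = None,
) -> TwoPhaseState:
    """One explicit-Euler step of size ``dt`` (default ``dt_factor*t_0``).

    The step is rejected and retried with a halved dt (floor 1e-6*t_0)
    if any volume fraction would leave [0, 1].
    """
    if dt is None:
        dt = rates.dt_factor * rates.t0
    if dt > rates.dt_factor * rates.t0 * (1.0 + 1e-12):
        raise ValueError("dt exceeds dt_factor * t0")
    dy_I, dy_II, dv, _, _ = _derivatives(state, spec, rates)
    floor = 1e-6 * rates.t0
    while True:
        v = state.v_I + dt * dv
        y_I = state.v_I * state.phi_I + dt * dy_I
        y_II = (1.0 - state.v_I) * state.phi_II + dt * dy_II
        if 0.0 < v < 1.0:
            phi_I, phi_II = y_I / v, y_II / (1.0 - v)
            ok = (
                np.all(phi_I > 0.0)
                and np.all(phi_II > 0.0)
                and phi_I.sum() < 1.0
                and phi_II.sum() < 1.0
            )
            if ok:
                return TwoPhaseState(phi_I, phi_II, float(v))
        dt *= 0.5
        if dt < floor:
            raise RuntimeError("step size underflow: state leaves the physical domain")


def flash_projection(state: TwoPhaseState, spec: MixtureSpec) -> TwoPhaseState:
    """Re-project onto exact phase equilibrium at fixed composition.

    Solves the multicomponent flash: find the partitioning of the
    per-species totals ``psi_i`` over two phases such that every
    ``mu_i`` and the osmotic pressure match.  Unknowns are the log
    partition ratios ``t_i = ln(phi_i^I/phi_i^II)`` and ``logit(v_I)``,
    which keeps all volume fractions positive by construction.
    """
    psi = state.psi
    t0 = np.log(state.phi_I / state.phi_II)
    x0 = np.concatenate([t0, [math.log(state.v_I / (1.0 - state.v_I))]])
    scale = max(spec.T, 1.0)

    def resid(x: np.ndarray) -> np.ndarray:
        t, lv = x[:-1], x[-1]
        v = 1.0 / (1.0 + math.exp(-lv))
        R = np.exp(t)
        denom = v * R + (1.0 - v)
        phi_I = psi * R / denom
        phi_II = psi / denom
        if phi_I.sum() >= 1.0 or phi_II.sum() >= 1.0:
            return np.full(x.size, 1e6)
        dI, dII = SizeDistribution(phi_I), SizeDistribution(phi_II)
        dmu = exchange_chemical_potentials(dI, spec) - exchange_chemical_potentials(
            dII, spec
        )
        dPi = osmotic_pressure(dI, spec) - osmotic_pressure(dII, spec)
        return np.concatenate([dmu, [dPi]]) / scale

    sol = root(resid, x0, method="hybr", tol=1e-13)
    if not sol.success and np.max(np.abs(sol.fun)) > 1e-9:
        raise RuntimeError(f"flash projection failed: {sol.message}")
    t, lv = sol.x[:-1], sol.x[-1]
    v = 1.0 / (1.0 + math.exp(-lv))
    R = np.exp(t)
    denom = v * R + (1.0 - v)
    return TwoPhaseState(psi * R / denom, psi / denom, float(v))


def embed_monomer_coexistence(
    phi_tot: float, spec: MixtureSpec, floor: float = 1e-30
) -> TwoPhaseState:
    """Initial condition: monomer-solvent coexistence embedded in size M.

    Solves the monomer-only (M = 1) coexistence at the given overall
    composition and pads sizes i >= 2 with a trace amount (``floor`` in
    the dilute phase) partitioned so that the embedded state is at phase
    equilibrium for every species, not just the monomers.
    """
    mono = common_tangent(phi_tot, spec.with_size(1))
    if mono is None:
        raise ValueError("no monomer-only demixing at this (phi_tot, T)")
    if not 0.0 < mono.v_I < 1.0:
        raise ValueError("phi_tot lies outside the monomer-only binodal")
    phi_I = np.full(spec.M, floor)
    phi_II = np.full(spec.M, floor)
    phi_I[0] = mono.phi_tot_I
    phi_II[0] = mono.phi_tot_II
    st = TwoPhaseState(phi_I, phi_II, mono.v_I)
    # partition the trace species so mu_i^I = mu_i^II exactly at the floor
    dI, dII = st.distributions()
    muI = exchange_chemical_potentials(dI, spec)
    muII = exchange_chemical_potentials(dII, spec)
    i = np.arange(1, spec.M + 1, dtype=float)
    # mu_i depends on ln(phi_i) through T/i * ln(phi_i); shift phase-I traces
    shift = i / spec.T * (muII - muI)
    phi_I[1:] = floor * np.exp(shift[1:])
    return flash_projection(TwoPhaseState(phi_I, phi_II, mono.v_I), spec)


def integrate(
    initial: TwoPhaseState,
    spec: MixtureSpec,
    rates: RateModel,
    t_end: float,
    record_every: int = 50,
    n_project: int = 100,
    equilibrium_tol: float = 1e-9,
) -> KineticsTrajectory:
    """Integrate the two-phase assembly kinetics until ``t_end`` (units t_0).

    Explicit Euler on the conserved variables with a multicomponent
    flash re-projection every ``n_project`` steps to keep the phases at
    phase equilibrium to round-off.  Integration stops early once the
    assembly-equilibrium residual ``max_i |mu_i - mu_1|/T`` falls below
    ``equilibrium_tol`` in both phases (steady state).
    """
    if spec.d != 1:
        raise ValueError(
            "kinetics supports linear assemblies (d=1) only; gelation for "
            "d>1 would require an unbounded size range"
        )
    dt_max = rates.dt_factor * rates.t0
    dt = dt_max
    dt_floor = 1e-9 * rates.t0
    drift_tol = 1e-6 * max(spec.T, 1.0)
    state = initial
    t = 0.0
    times, sI, sII, vs, Fs = [], [], [], [], []

    def record(t_now: float, st: TwoPhaseState) -> None:
        times.append(t_now / rates.t0)
        sI.append(st.phi_I.copy())
        sII.append(st.phi_II.copy())
        vs.append(st.v_I)
        Fs.append(st.total_free_energy(spec))

    record(0.0, state)
    converged = False
    k = 0
    t_stop = t_end * rates.t0
    while t < t_stop:
        if state.phase_equilibrium_residual(spec) > 0.5 * drift_tol:
            state = flash_projection(state, spec)
        dy_I, dy_II, dv, _, _ = _derivatives(state, spec, rates)
        res_cap = drift_tol
        while True:
            v = state.v_I + dt * dv
            y_I = state.v_I * state.phi_I + dt * dy_I
            y_II = (1.0 - state.v_I) * state.phi_II + dt * dy_II
            trial = None
            if 0.0 < v < 1.0:
                phi_I, phi_II = y_I / v, y_II / (1.0 - v)
                if (
                    np.all(phi_I > 0.0)
                    and np.all(phi_II > 0.0)
                    and phi_I.sum() < 1.0
                    and phi_II.sum() < 1.0
                ):
                    trial = TwoPhaseState(phi_I, phi_II, float(v))
                    # reject steps that let the phases drift off equilibrium
                    # (explicit-Euler instability shows up here first)
                    if trial.phase_equilibrium_residual(spec) > res_cap:
                        trial = None
            if trial is not None:
                break
            dt *= 0.5
            if dt < dt_floor:
                raise RuntimeError(
                    "step size underflow: kinetics cannot maintain phase "
                    "equilibrium (state may be near a critical point)"
                )
        state = trial
        t += dt
        k += 1
        dt = min(dt * 1.25, dt_max)
        if k % n_project == 0:
            state = flash_projection(state, spec)
        if k % record_every == 0 or t >= t_stop:
            record(t, state)
            dI, dII = state.distributions()
            muI = exchange_chemical_potentials(dI, spec)
            muII = exchange_chemical_potentials(dII, spec)
            resI = float(np.max(np.abs(muI - muI[0]))) / spec.T
            resII = float(np.max(np.abs(muII - muII[0]))) / spec.T
            if max(resI, resII) < equilibrium_tol:
                state = flash_projection(state, spec)
                record(t, state)
                converged = True
                break
    if not converged:
        warnings.warn(
            f"kinetics did not reach assembly equilibrium by t_end={t_end} t0"
        )
    return KineticsTrajectory(
        times=np.asarray(times),
        phi_I=np.asarray(sI),
        phi_II=np.asarray(sII),
        v_I=np.asarray(vs),
        free_energy=np.asarray(Fs),
        converged=converged,
    )


def volume_change_map(
    spec: MixtureSpec,
    phi_tot_grid,
    T_grid,
    tol: float = 1e-10,
):
    """Growth/shrinkage of the dense phase upon assembly formation.

    For each (phi_tot, T) inside the *initial* (monomer-only) binodal,
    compares the lever-rule volume ``V^I/V`` of the initial monomer
    coexistence with that of the final full assembly equilibrium; no
    time integration is involved.  Labels: GROW, SHRINK, NEUTRAL, or
    'not-demixed-initially'.
    """
    import pandas as pd

    recs = []
    mono_spec = spec.with_size(1)
    for T in np.asarray(T_grid, dtype=float):
        sM = spec.at_temperature(float(T))
        s1 = mono_spec.at_temperature(float(T))
        ct0 = common_tangent(0.5, s1)
        ct1 = common_tangent(0.5, sM) if ct0 is not None else None
        for phi in np.asarray(phi_tot_grid, dtype=float):
            label = "not-demixed-initially"
            v0 = v1 = np.nan
            if ct0 is not None and ct0.phi_tot_II < phi < ct0.phi_tot_I:
                v0 = ct0.lever(phi)
                if ct1 is None or not (ct1.phi_tot_II < phi < ct1.phi_tot_I):
                    v1 = 0.0 if (ct1 is None or phi <= ct1.phi_tot_II) else 1.0
                else:
                    v1 = ct1.lever(phi)
                dv = v1 - v0
                label = "NEUTRAL" if abs(dv) < tol else ("GROW" if dv > 0 else "SHRINK")
            recs.append({"phi_tot": phi, "T": T, "v_initial": v0, "v_final": v1, "label": label})
    return pd.DataFrame.from_records(recs)
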