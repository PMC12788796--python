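"""Free-energy model for a solution of self-assembling monomers.

The solution contains solvent plus assemblies of ``i = 1..M`` monomers.
Assemblies occupy a relative molecular volume ``rho_i = i`` (no solvent
inside an assembly), carry an internal free energy per monomer ``omega_i``
from their internal bonds, and interact with the solvent through a
Flory-Huggins parameter ``chi_is`` whose size dependence defines two
interaction classes:

* class 1 -- every monomer interacts with the solvent the same way,
  ``chi_is = chi`` (oligomerisation domains separate from the sticky
  phase-separation domains, e.g. Corelets, NPM1);
* class 2 -- monomers buried in the assembly bulk interact with strength
  ``chi'`` while boundary monomers keep ``chi``, giving
  ``chi_is = chi' + (chi - chi')/i^(1/d)`` (overlapping domains, e.g. FUS
  LARKS).

Assembly-assembly interaction parameters vanish in both classes.

Units: ``k_B = 1``; all energies are dimensionless multiples of
``k_B*T_0`` where ``T_0 = chi/k_B`` is the natural temperature scale of
the phase diagram, and the solvent molecular volume ``nu_s`` (default 1)
sets the volume unit.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "InteractionClass",
    "MixtureSpec",
    "SizeDistribution",
    "internal_free_energy",
    "assembly_solvent_chi",
    "free_energy_density",
    "exchange_chemical_potentials",
    "osmotic_pressure",
    "chemical_potential_jacobian",
]


class InteractionClass(enum.Enum):
    """Size dependence of the assembly-solvent interaction parameter."""

    CLASS1 = "class1"
    CLASS2 = "class2"


def _xlogx(x: np.ndarray | float) -> np.ndarray | float:
    """x*ln(x) with the continuity convention x*ln(x) -> 0 as x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0.0
    out[pos] = x[pos] * np.log(x[pos])
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MixtureSpec:
    """All thermodynamic parameters of the mixture.

    Parameters
    ----------
    M : int
        Maximum assembly size of the finite truncation (``M >= 1``).  The
        ``M -> inf`` limit needed for gelation is handled analytically in
        :mod:`oligosep.phases`.
    d : {1, 2, 3}
        Assembly dimensionality (linear, planar, three-dimensional); sets
        the ``i^(1/d)`` scaling of bonds and of buried monomers.
    interaction_class : InteractionClass
        Class 1 (constant ``chi_is``) or class 2 (size dependent).
    chi : float
        Monomer-solvent interaction energy, in units of ``k_B*T_0``.
    chi_prime : float
        Bulk monomer-solvent energy for class 2; ignored for class 1.
    e_int, s_int : float
        Enthalpic and entropic contribution of one internal bond; the bond
        free energy is ``e_int - s_int*T``.
    omega_inf : float or None
        Internal free energy per monomer of an infinite assembly (the gel
        bond energy).  ``None`` (default) ties it to the bond free energy
        with proportionality factor 1: ``omega_inf = e_int - s_int*T``.
    omega_s : float
        Solvent internal free energy; a pure constant offset, default 0.
    nu_s : float
        Solvent molecular volume, default 1 (volume unit).  Monomers have
        ``nu_1 = nu_s`` and assemblies ``nu_i = i*nu_s``.
    T : float
        Absolute temperature in units of ``T_0``.
    """

    M: int
    d: int = 1
    interaction_class: InteractionClass = InteractionClass.CLASS1
    chi: float = 1.0
    chi_prime: float = 0.0
    e_int: float = 0.0
    s_int: float = 0.0
    omega_inf: float | None = None
    omega_s: float = 0.0
    nu_s: float = 1.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if int(self.M) != self.M or self.M < 1:
            raise ValueError(f"M must be an integer >= 1, got {self.M}")
        if self.d not in (1, 2, 3):
            raise ValueError(f"d must be 1, 2 or 3, got {self.d}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.nu_s <= 0:
            raise ValueError(f"nu_s must be positive, got {self.nu_s}")
        if not isinstance(self.interaction_class, InteractionClass):
            object.__setattr__(
                self, "interaction_class", InteractionClass(self.interaction_class)
            )

    # -- derived quantities -------------------------------------------------

    @property
    def nu_1(self) -> float:
        return self.nu_s

    @property
    def delta_omega(self) -> float:
        """Bond free energy ``e_int - s_int*T`` (negative for binding)."""
        return self.e_int - self.s_int * self.T

    @property
    def omega_inf_eff(self) -> float:
        """Gel bond energy; defaults to the bond free energy itself."""
        return self.delta_omega if self.omega_inf is None else self.omega_inf

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.M + 1)

    def at_temperature(self, T: float) -> "MixtureSpec":
        return replace(self, T=T)

    def with_size(self, M: int) -> "MixtureSpec":
        return replace(self, M=M)

    def omega(self, i: np.ndarray | float) -> np.ndarray | float:
        return internal_free_energy(i, self)

    def chi_is(self, i: np.ndarray | float) -> np.ndarray | float:
        return assembly_solvent_chi(i, self)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.value if isinstance(v, InteractionClass) else v
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "MixtureSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown MixtureSpec keys: {sorted(unknown)}")
        kw = dict(mapping)
        if "interaction_class" in kw:
            kw["interaction_class"] = InteractionClass(kw["interaction_class"])
        return cls(**kw)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def internal_free_energy(i, spec: MixtureSpec):
    """Internal free energy per monomer of a size-``i`` assembly.

    ``omega_i = omega_inf - (e_int - s_int*T)/i^(1/d)``: an assembly of
    dimensionality d has ~``i - i^(1-1/d)`` internal bonds, so the bond
    free energy per monomer approaches ``omega_inf`` from below (for
    binding bonds) as ``1/i^(1/d)``.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i < 1):
        raise ValueError("assembly size i must be >= 1")
    out = spec.omega_inf_eff - spec.delta_omega / i ** (1.0 / spec.d)
    return out if out.ndim else float(out)


def assembly_solvent_chi(i, spec: MixtureSpec):
    """Assembly-solvent Flory-Huggins parameter ``chi_is`` for size ``i``."""
    i = np.asarray(i, dtype=float)
    if np.any(i < 1):
        raise ValueError("assembly size i must be >= 1")
    if spec.interaction_class is InteractionClass.CLASS1:
        out = np.full_like(i, spec.chi)
    else:
        out = spec.chi_prime + (spec.chi - spec.chi_prime) / i ** (1.0 / spec.d)
    return out if out.ndim else float(out)


@dataclass
class SizeDistribution:
    """Volume fractions ``phi_1..phi_M`` of one homogeneous phase.

    The solvent fraction is fixed by incompressibility,
    ``phi_s = 1 - sum_i phi_i``.
    """

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 1 or self.phi.size < 1:
            raise ValueError("phi must be a 1-d array of length M >= 1")
        if np.any(self.phi < 0.0) or np.any(self.phi > 1.0):
            raise ValueError("all phi_i must lie in [0, 1]")
        if self.phi.sum() > 1.0 + 1e-12:
            raise ValueError("sum of phi_i exceeds 1 (no solvent left)")

    @property
    def M(self) -> int:
        return self.phi.size

    @property
    def phi_tot(self) -> float:
        return float(self.phi.sum())

    @property
    def phi_s(self) -> float:
        return max(1.0 - self.phi_tot, 0.0)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.M + 1)

    def monomer_fraction(self) -> float:
        """phi_1 / phi_tot."""
        return float(self.phi[0] / self.phi.sum())


def _check_state(state: SizeDistribution, spec: MixtureSpec) -> None:
    if state.M != spec.M:
        raise ValueError(f"state has M={state.M} but spec has M={spec.M}")


def free_energy_density(state: SizeDistribution, spec: MixtureSpec) -> float:
    """Flory-Huggins free energy per volume of the solution.

    ``f = (k_B T/nu_s) [ sum_i (phi_i/i) ln(phi_i/i) + (omega_i/k_B T) phi_i
    + phi_s ln phi_s + (omega_s/k_B T) phi_s + sum_i (chi_is/k_B T) phi_i phi_s ]``
    with the convention ``x ln x -> 0`` at ``x = 0`` (assembly-assembly
    interaction parameters are zero in both classes).
    """
    _check_state(state, spec)
    i = state.sizes.astype(float)
    phi = state.phi
    phi_s = state.phi_s
    T = spec.T
    omega = internal_free_energy(i, spec)
    chi_is = assembly_solvent_chi(i, spec)
    # mixing entropy (phi_i/rho_i) ln(phi_i/rho_i) with rho_i = i
    mix = float(np.sum(_xlogx(phi / i)))
    f = (
        mix
        + float(np.dot(omega, phi)) / T
        + _xlogx(phi_s)
        + spec.omega_s * phi_s / T
        + float(np.dot(chi_is, phi)) * phi_s / T
    )
    return T * f / spec.nu_s


def exchange_chemical_potentials(
    state: SizeDistribution, spec: MixtureSpec, on_zero: str = "raise"
) -> np.ndarray:
    """Exchange chemical potentials ``mu_i = nu_1 * df/dphi_i``.

    The solvent fraction is eliminated through incompressibility before
    differentiating, so ``mu_i`` is the free-energy change of swapping
    solvent for material in a size-``i`` assembly:

    ``mu_i = T[(1/i)(ln(phi_i/i) + 1) - ln(phi_s) - 1] + omega_i - omega_s
    + chi_is*phi_s - sum_j chi_js*phi_j``

    Parameters
    ----------
    on_zero : {"raise", "neginf"}
        Behaviour when some ``phi_i = 0`` (the log derivative is not
        defined): raise, or return ``-inf`` for those entries.
    """
    _check_state(state, spec)
    phi = state.phi
    if np.any(phi <= 0.0):
        if on_zero == "raise":
            raise ValueError(
                "exchange chemical potential undefined at phi_i = 0 "
                "(pass on_zero='neginf' for a -inf sentinel)"
            )
        if on_zero != "neginf":
            raise ValueError(f"on_zero must be 'raise' or 'neginf', got {on_zero!r}")
    i = state.sizes.astype(float)
    phi_s = state.phi_s
    if phi_s <= 0.0:
        raise ValueError("chemical potentials undefined at phi_s = 0")
    T = spec.T
    omega = internal_free_energy(i, spec)
    chi_is = assembly_solvent_chi(i, spec)
    cross = float(np.dot(chi_is, phi))
    with np.errstate(divide="ignore"):
        log_term = np.log(phi / i)
    mu = (
        T * ((log_term + 1.0) / i - np.log(phi_s) - 1.0)
        + omega
        - spec.omega_s
        + chi_is * phi_s
        - cross
    )
    return mu


def osmotic_pressure(state: SizeDistribution, spec: MixtureSpec) -> float:
    """Osmotic pressure ``Pi = -f + sum_i phi_i df/dphi_i`` (analytic form).

    Equality of ``Pi`` between two phases, together with equality of all
    ``mu_i``, defines phase equilibrium in the incompressible mixture.
    Terms ``phi_i*ln(phi_i)`` cancel between ``-f`` and the derivative
    sum, so the result is finite even when some ``phi_i = 0``.
    """
    _check_state(state, spec)
    if state.phi_s <= 0.0:
        raise ValueError("osmotic pressure undefined at phi_s = 0")
    f = free_energy_density(state, spec)
    # phi_i*mu_i -> 0 as phi_i -> 0, so zero entries contribute nothing
    mu = _mu_allow_zero(state, spec)
    return -f + float(np.dot(state.phi, mu)) / spec.nu_1


def _mu_allow_zero(state: SizeDistribution, spec: MixtureSpec) -> np.ndarray:
    """mu_i with phi_i*mu_i -> well defined products: returns mu_i where
    phi_i > 0 and 0 where phi_i = 0 (the product phi_i*mu_i vanishes)."""
    phi = state.phi
    mu = exchange_chemical_potentials(state, spec, on_zero="neginf")
    mu = np.where(phi > 0.0, mu, 0.0)
    return mu


def chemical_potential_jacobian(state: SizeDistribution, spec: MixtureSpec) -> np.ndarray:
    """Analytic Jacobian ``J[i, k] = d mu_i / d phi_k`` (M x M).

    ``J_ik = T[delta_ik/(i*phi_i) + 1/phi_s] - chi_is - chi_ks``.
    Needed by the kinetics module to propagate phase-equilibrium
    constraints; also yields the osmotic-pressure gradient as
    ``dPi/dphi_k = (phi . J)_k / nu_1``.
    """
    _check_state(state, spec)
    phi = state.phi
    if np.any(phi <= 0.0) or state.phi_s <= 0.0:
        raise ValueError("Jacobian requires all phi_i > 0 and phi_s > 0")
    i = state.sizes.astype(float)
    T = spec.T
    chi_is = assembly_solvent_chi(i, spec)
    J = np.full((state.M, state.M), T / state.phi_s)
    J -= chi_is[:, None]
    J -= chi_is[None, :]
    J[np.diag_indices(state.M)] += T / (i * phi)
    return J


def osmotic_pressure_gradient(state: SizeDistribution, spec: MixtureSpec) -> np.ndarray:
    """``dPi/dphi_k = sum_i phi_i dmu_i/dphi_k / nu_1`` (analytic)."""
    J = chemical_potential_jacobian(state, spec)
    return state.phi @ J / spec.nu_1
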