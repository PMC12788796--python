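"""Phase coexistence, binodals, gelation and the triple point.

At assembly equilibrium the multicomponent free energy collapses onto a
one-variable effective free energy ``f(phi_tot)``; its derivative is the
common exchange chemical potential, ``mu(phi_tot) = nu_1 f'(phi_tot) =
mu_1``, and the osmotic pressure is ``Pi = -f + mu*phi_tot/nu_1``.  Two
coexisting liquid phases are found by the common-tangent (Maxwell)
construction on ``f``; equality of the tangent slope and intercept is
equivalent to equality of all ``mu_i`` and of ``Pi`` on the full
multicomponent state.

For planar and three-dimensional assemblies (d > 1) the ``M -> inf``
series for the size distribution converges only up to a finite total
volume fraction: beyond the sol-gel threshold ``phi_sg`` the surplus
material forms a single macroscopic assembly, the gel, modelled as a
boundary state with no solvent (``phi_tot = 1``) and free-energy density
``omega_inf/nu_1``.  Sol-gel coexistence is the tangent from ``f`` to
that boundary point, and the triple point is the temperature at which
the sol-sol tangent line passes exactly through it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .equilibrium import (
    GelationError,
    _log_phi,
    assembly_threshold,
    equilibrium_distribution,
)
from .thermo import (
    InteractionClass,
    MixtureSpec,
    SizeDistribution,
    exchange_chemical_potentials,
    free_energy_density,
)

__all__ = [
    "CoexistenceState",
    "PhaseDiagram",
    "TriplePoint",
    "common_tangent",
    "binodal_trace",
    "critical_point",
    "gelation_threshold",
    "sol_gel_coexistence",
    "triple_point",
    "classify_region",
]

_EPS = 1e-12


@dataclass
class CoexistenceState:
    """Two coexisting phases: a dense phase I and a dilute phase II.

    ``phase_I`` is ``None`` when phase I is the gel (a solvent-free
    macroscopic assembly with ``phi_tot_I = 1`` exactly).  ``v_I`` is the
    relative volume ``V^I/V`` fixed by the lever rule for the overall
    composition the state was constructed at.
    """

    phase_II: SizeDistribution
    phase_I: SizeDistribution | None = None
    v_I: float = float("nan")
    is_gel: bool = False

    def __post_init__(self) -> None:
        if not self.is_gel and self.phase_I is None:
            raise ValueError("phase_I may be None only for a gel state")
        if not self.is_gel and self.phase_I.phi_tot <= self.phase_II.phi_tot:
            raise ValueError("phase I must be the dense phase (phi_tot_I > phi_tot_II)")

    @property
    def phi_tot_I(self) -> float:
        return 1.0 if self.is_gel else self.phase_I.phi_tot

    @property
    def phi_tot_II(self) -> float:
        return self.phase_II.phi_tot

    def lever(self, phi_tot: float) -> float:
        """V^I/V from conservation of the overall composition."""
        return (phi_tot - self.phi_tot_II) / (self.phi_tot_I - self.phi_tot_II)


@dataclass
class TriplePoint:
    T: float
    phi_sol_dilute: float
    phi_sol_dense: float
    phi_gel: float = 1.0


# ---------------------------------------------------------------------------
# effective one-variable thermodynamics


def _effective(phi_tot: float, spec: MixtureSpec) -> tuple[float, float, float]:
    """(f, mu, Pi) of the assembly-equilibrium state at phi_tot."""
    st = equilibrium_distribution(phi_tot, spec)
    f = free_energy_density(st, spec)
    mu = float(exchange_chemical_potentials(st, spec, on_zero="neginf")[0])
    return f, mu, -f + mu * phi_tot / spec.nu_1


def effective_mu(phi_tot: float, spec: MixtureSpec) -> float:
    """Common chemical potential mu(phi_tot) = nu_1 df/dphi_tot."""
    st = equilibrium_distribution(phi_tot, spec)
    return float(exchange_chemical_potentials(st, spec, on_zero="neginf")[0])


def _scan_grid(lo: float, hi: float, n: int = 240) -> np.ndarray:
    """Composition grid mixing log spacing (dilute side) and linear."""
    n_log = n // 2
    g = np.concatenate(
        [
            np.geomspace(lo, min(0.2, hi * 0.5), n_log),
            np.linspace(min(0.2, hi * 0.5), hi, n - n_log),
        ]
    )
    return np.unique(np.clip(g, lo, hi))


def common_tangent(
    phi_tot_probe: float,
    spec: MixtureSpec,
    domain: tuple[float, float] | None = None,
) -> CoexistenceState | None:
    """Maxwell construction on the effective free energy.

    Solves ``mu(phi_I) = mu(phi_II)`` together with equal tangent
    intercepts (equivalently ``Pi_I = Pi_II``).  Returns ``None`` when
    the effective free energy is convex (no demixing).  The returned
    state's ``v_I`` is the lever-rule volume for ``phi_tot_probe``.

    The initial bracket comes from the spinodal (sign change of the
    numerical slope of ``mu``); an outer scalar root solve on the tangent
    slope is followed by Newton polish to residuals below 1e-9.
    """
    lo, hi = domain if domain is not None else (1e-8, 1.0 - 1e-7)
    grid = _scan_grid(lo, hi)
    mu_g = np.array([effective_mu(p, spec) for p in grid])
    dmu = np.diff(mu_g)
    dec = np.nonzero(dmu < 0.0)[0]
    if dec.size == 0:
        return None  # mu monotone: f convex, no demixing
    i0, i1 = dec[0], dec[-1] + 1  # local max before, local min after
    mu_hi = mu_g[: i0 + 1].max()
    mu_lo = mu_g[i1:].min()
    phi_smax, phi_smin = grid[np.argmax(mu_g[: i0 + 1])], grid[i1 + np.argmin(mu_g[i1:])]

    def branch_roots(m: float) -> tuple[float, float]:
        a = brentq(lambda p: effective_mu(p, spec) - m, lo, phi_smax, xtol=1e-15)
        b = brentq(lambda p: effective_mu(p, spec) - m, phi_smin, hi, xtol=1e-15)
        return a, b

    def tangent_gap(m: float) -> float:
        a, b = branch_roots(m)
        fa, _, _ = _effective(a, spec)
        fb, _, _ = _effective(b, spec)
        # difference of tangent intercepts f - m*phi/nu_1
        return (fb - m * b / spec.nu_s) - (fa - m * a / spec.nu_s)

    span = mu_hi - mu_lo
    m_lo, m_hi = mu_lo + 1e-10 * max(span, 1.0), mu_hi - 1e-10 * max(span, 1.0)
    if m_lo >= m_hi:
        return None
    try:
        g_lo, g_hi = tangent_gap(m_lo), tangent_gap(m_hi)
    except ValueError:
        # a branch root is missing inside the restricted domain (e.g. the
        # dense contact would sit beyond the gel point): no construction
        return None
    if g_lo * g_hi > 0.0:
        return None  # numerically convex (e.g. at/above the critical point)
    m = brentq(tangent_gap, m_lo, m_hi, xtol=1e-14, rtol=8.9e-16)
    a, b = branch_roots(m)

    # Newton polish on (a, b) for mu and Pi equality
    for _ in range(4):
        fa, mua, Pia = _effective(a, spec)
        fb, mub, Pib = _effective(b, spec)
        F = np.array([mua - mub, Pia - Pib])
        if np.max(np.abs(F)) < 1e-12:
            break
        h = 1e-7
        dmu_a = (effective_mu(min(a + h, 1 - _EPS), spec) - effective_mu(a - h, spec)) / (
            min(a + h, 1 - _EPS) - (a - h)
        )
        dmu_b = (effective_mu(min(b + h, 1 - _EPS), spec) - effective_mu(b - h, spec)) / (
            min(b + h, 1 - _EPS) - (b - h)
        )
        J = np.array(
            [[dmu_a, -dmu_b], [a * dmu_a / spec.nu_s, -b * dmu_b / spec.nu_s]]
        )
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            break
        a = float(np.clip(a - step[0], lo, hi))
        b = float(np.clip(b - step[1], lo, hi))

    fa, mua, Pia = _effective(a, spec)
    fb, mub, Pib = _effective(b, spec)
    res = max(abs(mua - mub), abs(Pia - Pib))
    if res > 1e-7:
        raise RuntimeError(
            f"Maxwell construction did not converge: residuals mu={mua - mub:.2e}, "
            f"Pi={Pia - Pib:.2e}"
        )
    dense = equilibrium_distribution(b, spec)
    dilute = equilibrium_distribution(a, spec)
    state = CoexistenceState(phase_II=dilute, phase_I=dense)
    state.v_I = state.lever(phi_tot_probe)
    return state


def critical_point(
    spec: MixtureSpec, T_lo: float, T_hi: float, tol: float = 1e-9
) -> float:
    """Critical temperature: where the spinodal window closes.

    Finds the T at which ``min_phi dmu/dphi = 0`` by bisection; above it
    the effective free energy is strictly convex and no demixing occurs.
    """

    def min_slope(T: float) -> float:
        s = spec.at_temperature(T)
        grid = _scan_grid(1e-6, 1.0 - 1e-6, 200)
        mu = np.array([effective_mu(p, s) for p in grid])
        k = int(np.argmin(np.diff(mu) / np.diff(grid)))
        # golden refinement around the coarse minimum
        a_, b_ = grid[max(k - 1, 0)], grid[min(k + 2, grid.size - 1)]
        h = 1e-5
        from scipy.optimize import minimize_scalar

        r = minimize_scalar(
            lambda p: (effective_mu(p + h, s) - effective_mu(p - h, s)) / (2 * h),
            bounds=(a_ + h, b_ - h),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(r.fun)

    lo_v, hi_v = min_slope(T_lo), min_slope(T_hi)
    if lo_v * hi_v > 0.0:
        raise ValueError(
            "critical point not bracketed: spinodal state is the same at both ends"
        )
    return brentq(min_slope, T_lo, T_hi, xtol=tol)


# ---------------------------------------------------------------------------
# gelation (d > 1, M -> inf)


def _boundary_series(B: float, alpha: float, cap: int = 1_000_000) -> float:
    """sum_{i>=1} i * exp(B*i^alpha - 1) evaluated at the convergence boundary.

    B < 0 is required for convergence (stretched-exponential decay).
    """
    total = 0.0
    start = 1
    block = 4096
    while start <= cap:
        i = np.arange(start, min(start + block, cap + 1), dtype=float)
        t = i * np.exp(B * i**alpha - 1.0)
        total += float(t.sum())
        if t[-1] < 1e-16 * max(total, 1e-300):
            return total
        start += block
        block = min(block * 2, 262144)
    raise GelationError(
        "boundary series did not converge within the term cap; "
        "no finite sol-gel threshold for these parameters"
    )


def gelation_threshold(spec: MixtureSpec, T: float | None = None) -> float:
    """Sol-gel threshold ``phi_sg`` for d in {2, 3} (M -> inf limit).

    The supremum of the converged size-distribution series over
    admissible monomer fractions: above it no finite-size distribution
    absorbs all material and a macroscopic assembly must appear.
    Returns ``inf`` when the bond free energy is non-negative (the
    series absorbs any total volume fraction; no gelation, as for
    linear assemblies).
    """
    if spec.d == 1:
        raise ValueError(
            "gelation threshold is undefined for d=1: the linear-assembly "
            "series absorbs any phi_tot < 1"
        )
    if T is not None:
        spec = spec.at_temperature(T)
    alpha = 1.0 - 1.0 / spec.d

    if spec.interaction_class is InteractionClass.CLASS1:
        B = spec.delta_omega / spec.T
        if B >= 0.0:
            return math.inf
        return _boundary_series(B, alpha)

    # class 2: B depends on phi_s = 1 - phi_tot -> self-consistent root
    def resid(phi: float) -> float:
        B = (spec.delta_omega + (spec.chi_prime - spec.chi) * (1.0 - phi)) / spec.T
        if B >= 0.0:
            return math.inf
        return _boundary_series(B, alpha) - phi

    grid = np.linspace(1e-6, 1.0 - 1e-6, 200)
    vals = np.array([resid(p) for p in grid])
    sign = np.sign(vals)
    flips = np.nonzero(np.diff(sign) < 0)[0]
    if not flips.size:
        if np.all(vals > 0):
            return math.inf  # series exceeds phi everywhere: no finite threshold
        raise GelationError("no self-consistent sol-gel threshold found")
    k = flips[0]
    return brentq(resid, grid[k], grid[k + 1], xtol=1e-12)


def _inf_equilibrium(
    phi_tot: float, spec: MixtureSpec, phi_sg: float | None = None
) -> SizeDistribution:
    """Assembly equilibrium for d > 1 without a size cap.

    Adaptive truncation: sizes are included until terms fall below
    1e-18 of the running sum.  Raises GelationError beyond ``phi_sg``.
    """
    if spec.d == 1:
        raise ValueError("use equilibrium_distribution for d=1")
    if phi_sg is None:
        phi_sg = gelation_threshold(spec)
    if phi_tot >= phi_sg:
        raise GelationError(
            f"phi_tot={phi_tot:.6g} is at/beyond the sol-gel threshold "
            f"phi_sg={phi_sg:.6g}; the sol branch does not exist there"
        )

    def total(lp1: float, need_M: bool = False):
        M = 256
        while True:
            lp = _log_phi(lp1, 1.0 - phi_tot, spec, M=M)
            s = logsumexp(lp)
            if lp[-1] < s + math.log(1e-18):
                return (s, M) if need_M else s
            M *= 2
            if M > 2_000_000:  # pragma: no cover
                raise GelationError("series truncation failed to converge")

    # bracket in log phi_1 below the convergence boundary
    B = spec.delta_omega
    if spec.interaction_class is InteractionClass.CLASS2:
        B = B + (spec.chi_prime - spec.chi) * (1.0 - phi_tot)
    lp1_max = B / spec.T - 1.0  # radius boundary of the series
    log_target = math.log(phi_tot)
    hi = lp1_max - 1e-9
    if total(hi) < log_target:
        raise GelationError(
            "series cannot absorb phi_tot below the convergence boundary "
            "(phi_tot beyond the effective gel point)"
        )
    lo = min(hi - 1.0, log_target)
    while total(lo) > log_target:
        lo -= 4.0
    lp1 = brentq(lambda x: total(x) - log_target, lo, hi, xtol=1e-15, rtol=8.9e-16)
    _, M = total(lp1, need_M=True)
    phi = np.exp(_log_phi(lp1, 1.0 - phi_tot, spec, M=M))
    return SizeDistribution(phi)


def _effective_inf(
    phi_tot: float, spec: MixtureSpec, phi_sg: float | None = None
) -> tuple[float, float]:
    """(f, mu) for the M -> inf sol branch (d > 1)."""
    st = _inf_equilibrium(phi_tot, spec, phi_sg=phi_sg)
    s = spec.with_size(st.M)
    f = free_energy_density(st, s)
    mu = float(exchange_chemical_potentials(st, s, on_zero="neginf")[0])
    return f, mu


def _sol_mu_f(phi_tot: float, spec: MixtureSpec, phi_sg: float | None = None):
    if spec.d == 1:
        f, mu, _ = _effective(phi_tot, spec)
        return f, mu
    return _effective_inf(phi_tot, spec, phi_sg=phi_sg)


def _gel_structure(spec: MixtureSpec):
    """Classify the coexistence structure of a gel-capable mixture at T.

    The free-energy graph consists of the sol branch on (0, phi_sg] plus
    the isolated gel point (1, omega_inf/nu_1).  Its lower convex hull
    takes one of four forms:

    * ``no-gel``   -- phi_sg >= 1: the sol branch spans all compositions;
    * ``sol-sol``  -- an interior common tangent (two liquid sols), with a
      saturated-sol/gel band beyond phi_sg;
    * ``corner``   -- the dense contact is pinned at the convergence
      boundary phi_sg (a saturated sol), which is a hull vertex;
    * ``detached`` -- the boundary vertex has left the hull and a dilute
      sol coexists directly with the gel (true sol-gel region).

    The triple point is the temperature at which the corner detaches:
    there the dilute sol, the saturated sol and the gel share one
    tangent line.
    """
    phi_sg = gelation_threshold(spec)
    f_gel = spec.omega_inf_eff / spec.nu_1
    if not math.isfinite(phi_sg) or phi_sg >= 1.0 - 1e-9:
        dom = (1e-8, min(phi_sg * (1 - 1e-7), 1 - 1e-7)) if math.isfinite(phi_sg) else None
        ct = common_tangent(0.5, spec, domain=dom)
        return {"kind": "no-gel", "phi_sg": phi_sg, "ct": ct,
                "a": None if ct is None else ct.phi_tot_II,
                "b": None if ct is None else ct.phi_tot_I}
    hi = phi_sg * (1.0 - 1e-7)
    ct = common_tangent(0.5, spec, domain=(1e-8, hi))
    if ct is not None:
        return {"kind": "sol-sol", "phi_sg": phi_sg, "ct": ct,
                "a": ct.phi_tot_II, "b": ct.phi_tot_I}
    fc, _ = _sol_mu_f(hi, spec, phi_sg=phi_sg)
    slope_gel = (f_gel - fc) / (1.0 - hi)

    def chord_resid(a: float) -> float:
        fa, mua = _sol_mu_f(a, spec, phi_sg=phi_sg)
        return mua - spec.nu_1 * (fc - fa) / (hi - a)

    grid = _scan_grid(1e-8, hi * 0.9, 80)
    vals = np.array([chord_resid(p) for p in grid])
    flips = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if flips.size == 0:
        return {"kind": "convex", "phi_sg": phi_sg, "ct": None, "a": None, "b": None}
    a_c = brentq(chord_resid, grid[flips[0]], grid[flips[0] + 1], xtol=1e-13)
    fa, _ = _sol_mu_f(a_c, spec, phi_sg=phi_sg)
    h2 = slope_gel - (fc - fa) / (hi - a_c)
    if h2 > 0.0:
        return {"kind": "corner", "phi_sg": phi_sg, "ct": None, "a": a_c, "b": phi_sg,
                "h2": h2}

    def gel_resid(a: float) -> float:
        fa, mua = _sol_mu_f(a, spec, phi_sg=phi_sg)
        return mua - spec.nu_1 * (f_gel - fa) / (1.0 - a)

    vals = np.array([gel_resid(p) for p in grid])
    flips = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    a_g = brentq(gel_resid, grid[flips[0]], grid[flips[0] + 1], xtol=1e-14)
    return {"kind": "detached", "phi_sg": phi_sg, "ct": None, "a": a_g, "b": 1.0,
            "h2": h2}


def sol_gel_coexistence(spec: MixtureSpec, T: float | None = None) -> CoexistenceState | None:
    """Coexistence of a solution phase with the gel (d in {2, 3}).

    The gel is the boundary state ``phi_tot = 1`` with free-energy
    density ``omega_inf/nu_1``.  Below the triple point the partner is a
    dilute sol satisfying the tangency condition
    ``mu(phi_sol) = nu_1 (omega_inf/nu_1 - f(phi_sol))/(1 - phi_sol)``;
    above it the partner is the saturated sol pinned at the convergence
    boundary ``phi_sg``.  Returns ``None`` when the gel point is
    unreachable (``phi_sg >= 1``).
    """
    if spec.d == 1:
        raise ValueError("sol-gel coexistence requires d in {2, 3}")
    if T is not None:
        spec = spec.at_temperature(T)
    st = _gel_structure(spec)
    if st["kind"] == "no-gel":
        return None
    phi_sg = st["phi_sg"]
    c = st["a"] if st["kind"] == "detached" else phi_sg * (1.0 - 1e-7)
    sol = _inf_equilibrium(c, spec, phi_sg=phi_sg)
    return CoexistenceState(phase_II=sol, phase_I=None, is_gel=True)


def triple_point(
    spec: MixtureSpec, T_lo: float, T_hi: float, tol: float = 1e-7
) -> TriplePoint | None:
    """Temperature at which two sol phases and the gel share a tangent.

    Found by bisection on the convexity excess of the saturated-sol hull
    vertex: above the triple point the vertex (the dense saturated sol)
    lies strictly below the dilute-sol/gel line, below it the line from
    the dilute sol runs directly to the gel.  ``None`` when there is no
    crossing in the scanned range.
    """
    if spec.d == 1:
        raise ValueError("triple point requires d in {2, 3}")

    def h2(T: float) -> float:
        st = _gel_structure(spec.at_temperature(T))
        if st["kind"] in ("corner", "detached"):
            return st["h2"]
        if st["kind"] == "sol-sol":
            return 1.0  # interior sol-sol: corner comfortably on the hull
        return math.nan

    h_lo, h_hi = h2(T_lo), h2(T_hi)
    if math.isnan(h_lo) or math.isnan(h_hi) or h_lo * h_hi > 0.0:
        return None
    T_t = brentq(h2, T_lo, T_hi, xtol=tol)
    st = _gel_structure(spec.at_temperature(T_t))
    return TriplePoint(T=T_t, phi_sol_dilute=st["a"], phi_sol_dense=st["phi_sg"])


# ---------------------------------------------------------------------------
# phase diagram assembly and region classification


@dataclass
class PhaseDiagram:
    """Per-temperature coexistence records over (phi_tot, T/T_0).

    Arrays are aligned with ``T``; NaN marks temperatures where the
    corresponding feature does not exist.  ``region`` labels the type of
    coexistence found at each temperature.
    """

    spec: MixtureSpec
    T: np.ndarray
    phi_I: np.ndarray
    phi_II: np.ndarray
    monomer_frac_I: np.ndarray
    monomer_frac_II: np.ndarray
    phi_star: np.ndarray
    region: list[str]
    sol_gel_phi_sol: np.ndarray | None = None
    triple: TriplePoint | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "T": self.T,
                "phi_I": self.phi_I,
                "phi_II": self.phi_II,
                "monomer_frac_I": self.monomer_frac_I,
                "monomer_frac_II": self.monomer_frac_II,
                "phi_star": self.phi_star,
                "region": self.region,
            }
        )


def binodal_trace(spec: MixtureSpec, T_grid) -> PhaseDiagram:
    """Trace the binodal (and gel boundary for d > 1) over temperature.

    ``T_grid`` is traversed from the highest temperature downward so the
    trace starts above or near the critical point.  For each temperature
    the coexistence compositions, their monomer fractions and the
    assembly threshold are recorded; for gel-capable mixtures the
    sol-gel contact and the triple point are recorded as well.
    """
    T_grid = np.sort(np.asarray(T_grid, dtype=float))[::-1]
    n = T_grid.size
    out = {k: np.full(n, np.nan) for k in ("pI", "pII", "mI", "mII", "star", "sg")}
    region: list[str] = []
    gel_capable = spec.d > 1
    for k, T in enumerate(T_grid):
        s = spec.at_temperature(float(T))
        star = assembly_threshold(float(T), spec) if spec.M > 1 else None
        if star is not None:
            out["star"][k] = star
        label = "none"
        try:
            if gel_capable:
                stc = _gel_structure(s)
                if math.isfinite(stc["phi_sg"]):
                    out["sg"][k] = min(stc["phi_sg"], 1.0)
                if stc["kind"] in ("sol-sol", "no-gel") and stc["ct"] is not None:
                    ct = stc["ct"]
                    out["pI"][k], out["pII"][k] = ct.phi_tot_I, ct.phi_tot_II
                    out["mI"][k] = ct.phase_I.monomer_fraction()
                    out["mII"][k] = ct.phase_II.monomer_fraction()
                    label = "sol-sol"
                elif stc["kind"] == "corner":
                    sat = _inf_equilibrium(stc["b"] * (1 - 1e-7), s, phi_sg=stc["phi_sg"])
                    dil = _inf_equilibrium(stc["a"], s, phi_sg=stc["phi_sg"])
                    out["pI"][k], out["pII"][k] = stc["b"], stc["a"]
                    out["mI"][k] = sat.monomer_fraction()
                    out["mII"][k] = dil.monomer_fraction()
                    label = "sol-sol"
                elif stc["kind"] == "detached":
                    dil = _inf_equilibrium(stc["a"], s, phi_sg=stc["phi_sg"])
                    out["pI"][k], out["pII"][k] = 1.0, stc["a"]
                    out["mI"][k] = 0.0
                    out["mII"][k] = dil.monomer_fraction()
                    label = "sol-gel"
            else:
                ct = common_tangent(0.5, s)
                if ct is not None:
                    out["pI"][k], out["pII"][k] = ct.phi_tot_I, ct.phi_tot_II
                    out["mI"][k] = ct.phase_I.monomer_fraction()
                    out["mII"][k] = ct.phase_II.monomer_fraction()
                    if star is None:
                        label = "demixed"
                    elif ct.phi_tot_II >= star:
                        label = "iii"
                    elif ct.phi_tot_I <= star:
                        label = "iv"
                    else:
                        label = "v"
        except (RuntimeError, ValueError) as err:  # loss of bracket near critical point
            warnings.warn(f"binodal trace truncated at T={T:.6g}: {err}")
        region.append(label)
    triple = None
    if gel_capable:
        labels = np.array(region)
        if "sol-sol" in labels and "sol-gel" in labels:
            T_ss = T_grid[labels == "sol-sol"].min()
            T_sg = T_grid[labels == "sol-gel"].max()
            lo, hi = min(T_ss, T_sg), max(T_ss, T_sg)
            if lo < hi:
                triple = triple_point(spec, lo, hi)
    return PhaseDiagram(
        spec=spec,
        T=T_grid,
        phi_I=out["pI"],
        phi_II=out["pII"],
        monomer_frac_I=out["mI"],
        monomer_frac_II=out["mII"],
        phi_star=out["star"],
        region=region,
        sol_gel_phi_sol=out["sg"] if gel_capable else None,
        triple=triple,
    )


def classify_region(phi_tot: float, T: float, spec: MixtureSpec) -> str:
    """Label the state at (phi_tot, T).

    d = 1 mixtures use the five-region taxonomy: 'i' homogeneous
    monomeric, 'ii' homogeneous with intermediate assemblies, 'iii'
    demixed with both phases above the assembly threshold, 'iv' demixed
    with both phases monomeric, 'v' demixed with only the dense phase
    above the threshold.  Gel-capable mixtures (d > 1) are labelled
    {'homogeneous', 'sol-sol', 'sol-gel'}.
    """
    if not 0.0 < phi_tot < 1.0:
        raise ValueError(f"phi_tot must lie in (0, 1), got {phi_tot}")
    s = spec.at_temperature(T)
    if spec.d == 1:
        star = assembly_threshold(T, spec) if spec.M > 1 else None
        ct = common_tangent(phi_tot, s)
        demixed = ct is not None and ct.phi_tot_II < phi_tot < ct.phi_tot_I
        if not demixed:
            return "ii" if (star is not None and phi_tot >= star) else "i"
        if star is None or ct.phi_tot_II >= star:
            return "iii"
        if ct.phi_tot_I <= star:
            return "iv"
        return "v"
    # gel-capable
    st = _gel_structure(s)
    kind = st["kind"]
    if kind in ("sol-sol", "no-gel"):
        ct = st["ct"]
        if ct is not None and ct.phi_tot_II < phi_tot < ct.phi_tot_I:
            return "sol-sol"
        if kind == "sol-sol" and phi_tot > st["phi_sg"]:
            return "sol-gel"  # saturated sol + gel beyond the boundary
        return "homogeneous"
    if kind == "corner":
        if st["a"] < phi_tot < st["b"]:
            return "sol-sol"  # dilute sol + saturated sol
        if phi_tot >= st["b"]:
            return "sol-gel"
        return "homogeneous"
    if kind == "detached" and phi_tot > st["a"]:
        return "sol-gel"
    return "homogeneous"
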