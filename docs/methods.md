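# Methods

`oligosep` models a solution of a single self-assembling macromolecular
species (protein, peptide, DNA nanostructure) in solvent. Monomers can
bind into assemblies of `i = 1..M` subunits and, independently, the
mixture can demix into coexisting liquid phases. The package computes
equilibrium size distributions, full phase diagrams including gelation
of the dense phase, and the reaction-limited kinetics by which a
phase-separated system relaxes to assembly equilibrium.

## Free-energy model

The solution free energy per volume is a multicomponent Flory–Huggins
form over the volume fractions `phi_1..phi_M` and the solvent
`phi_s = 1 − Σ phi_i` (incompressibility):

```
f_sol = (k_B T / nu_s) [ Σ_i (phi_i/i) ln(phi_i/i) + (omega_i/k_B T) phi_i
        + phi_s ln phi_s + (omega_s/k_B T) phi_s
        + Σ_i (chi_is/k_B T) phi_i phi_s ]
```

Relative molecular volumes are `rho_i = i` (assemblies contain no
solvent), assembly–assembly interaction parameters vanish, and each
internal bond contributes a free energy `Δω = e_int − s_int·T`
(enthalpy minus the entropic penalty of binding). Counting bonds in a
`d`-dimensional cluster gives the internal free energy per monomer

```
omega_i = omega_inf − Δω / i^(1/d),      omega_inf = lim_{i→∞} omega_i .
```

Two interaction classes encode how burying monomers inside an assembly
changes their solvent contact:

* **class 1** — `chi_is = chi` for all sizes (oligomerisation domains
  separate from the sticky domains);
* **class 2** — `chi_is = chi' + (chi − chi')/i^(1/d)` (bulk monomers
  interact with strength `chi'`, boundary monomers with `chi`).

Units: `k_B = 1`, `nu_s = 1`, energies in multiples of `k_B T_0` with
`T_0 = chi/k_B`, so phase diagrams are drawn over `(phi_tot, T/T_0)`.
Adding a constant to all internal free energies (including the gel term
below) tilts `f` by an affine function of composition and changes no
equilibrium; consequently `omega_inf` itself never enters equilibria —
only `Δω` does. Its default value is tied to the bond free energy
(`omega_inf = Δω`), which makes `omega_1 = 0` for linear assemblies.

## Assembly equilibrium

Chemical equilibrium of the association network means all exchange
chemical potentials are equal, `mu_i = mu_1` with
`mu_i = nu_1 ∂f/∂phi_i` (solvent eliminated first). Solving this gives
each `phi_i` explicitly in terms of `phi_1`:

```
phi_i = i · phi_1^i · exp[ i (1 − (omega_i − omega_1)/T
         − (chi_is − chi)·phi_s/T) − 1 ]
```

and monomer conservation `Σ phi_i = phi_tot` fixes `phi_1`. The sum is
strictly increasing in `phi_1`, so the implementation brackets the root
in `ln phi_1` and solves it with Brent's method on a log-sum-exp of the
per-size logarithms (exponents grow linearly in `i`; nothing is
exponentiated before the solution is known). The residual tolerance is
1e−12 in the conservation constraint, which carries `mu_i = mu_1` to
better than 1e−8 k_BT (both are verified in the test suite, where the
d = 1 solution is cross-checked against an independently derived
geometric-series closed form to 1e−10 relative at M = 500).

The **assembly threshold** `phi*` is the composition at which the size
distribution's maximum at `i = 1` flattens, `∂phi_i/∂i|_{i=1} = 0` with
`i` treated as continuous. The derivative is analytic
(`2 + ln phi_1 − B/d`, with `B` collecting the bond and class-2 terms),
and `phi*` is found by bisection on `phi_tot` to 1e−10. Above `phi*`
the distribution develops a peak at `i_max > 1` with an exponential
large-size tail, and both the peak and the mean size grow like
`sqrt(phi_tot)`.

## Phase equilibrium

At assembly equilibrium the free energy collapses to a one-variable
function `f(phi_tot)` whose derivative is the common chemical potential
(`nu_1 f' = mu_1`, an envelope identity — no numerical differentiation
is needed) and whose osmotic pressure is `Pi = −f + mu·phi_tot/nu_1`.
Two-phase coexistence is the common-tangent (Maxwell) construction:
equal `mu` and equal `Pi`. The solver scans `mu(phi)` for a spinodal
window, brackets the tangent slope between the local extrema of `mu`,
solves the equal-intercept condition by an outer Brent iteration, and
polishes with 2×2 Newton steps to residuals below 1e−9. Equality of
*all* `M` chemical potentials and of the pressure on the full
multicomponent states follows and is asserted to 1e−7 in the tests.
The equal-size monomer limit reproduces the closed-form symmetric
Flory–Huggins binodal with critical point at `chi/k_BT = 2`,
`phi = 1/2`.

## Gelation (d = 2, 3)

For planar and three-dimensional assemblies the `M → ∞` size series
converges only while `ln phi_1 ≤ B − 1`; the total volume fraction it
can absorb is capped at the sol–gel threshold

```
phi_sg = Σ_{i≥1} i · exp(B i^(1−1/d) − 1),   B = (Δω + (chi'−chi) phi_s)/T < 0,
```

evaluated term-wise until terms fall below 1e−16 of the running sum
(cap 1e6 terms; `B ≥ 0` means no finite threshold, as for d = 1).
Beyond `phi_sg` the surplus material forms a single macroscopic
assembly — the gel — modelled as the boundary state `phi_tot = 1`
with free-energy density `omega_inf/nu_1` (the delta-distribution gel
term is implemented as an isolated point of the free-energy graph, a
mathematically equivalent and numerically exact treatment of the
tangency condition).

The phase behaviour follows from the lower convex hull of the sol
branch on `(0, phi_sg]` plus the gel point. Four regimes occur as
temperature drops: no gel (`phi_sg ≥ 1`); an interior sol–sol tangent;
a band in which the dense contact is *pinned at the boundary*
`phi_sg` (the saturated sol is a hull vertex, analogous to a
stoichiometric compound); and, below the triple point, a direct
tangent from the dilute sol to the gel. The **triple point** is the
temperature at which the boundary vertex detaches from the hull: there
the dilute sol, the saturated sol and the gel share one tangent line.
It is located by bisection on the vertex's convexity excess. Crossing
it, `phi_tot` of the dense phase jumps discontinuously to 1 while the
dilute branch varies continuously — the gelation signature of the
dense phase. Because of the tilt invariance noted above, the triple
point responds to the bond free energy `Δω` (stronger bonds raise it),
not to `omega_inf` separately.

## Reaction-limited kinetics (d = 1)

Two phases are held at phase equilibrium while association and
dissociation relax the size distribution:

```
d(phi_i)/dt = r_i − j_i − phi_i · d ln V / dt
d ln(V^P/V)/dt = −j_s^P − Σ_i j_i^P ,     j_i^I = −j_i^II V^II/V^I .
```

Mass-action rates follow from the exchange chemical potentials,

```
Δr_ij = k_ij [exp((i mu_i + j mu_j)/k_BT) − exp((i+j) mu_{i+j}/k_BT)],
r_i = (i/2) Σ_{j+k=i} Δr_jk − i Σ_j Δr_ij ,
```

with standard stoichiometry for like pairs (a j = k reaction
consumes/produces two identical partners, so diagonal terms carry
multiplicity two in both sums); `Σ_i r_i = 0` identically and `Δr`
vanishes exactly at assembly equilibrium (detailed balance). The
exchange rates `j` are obtained each step from the (M+1)-dimensional
linear system that keeps `d(mu_i^I − mu_i^II)/dt = 0` and
`d(Pi^I − Pi^II)/dt = 0`; the rows are equilibrated because trace
species contribute `1/phi_i` factors that would otherwise leak
round-off into the monomer and solvent fluxes.

The integrator is explicit Euler on the conserved variables
`y_i^P = (V^P/V) phi_i^P` and `v = V^I/V`, which conserves the global
composition and the total volume to round-off by construction. Steps
that would leave the physical domain or let the phase-equilibrium
residual exceed 1e−6 k_BT are rejected and retried with half the step
(recovering up to the cap `dt = dt_factor·t_0`, `t_0 = 0.01/k̃`); a
multicomponent flash — Newton/hybrid solve for the partitioning with
log partition-ratio unknowns, which keeps all volume fractions
positive — re-projects the state onto exact phase equilibrium every
`n_project = 100` steps and whenever drift accumulates. The total free
energy `F/V = v f^I + (1−v) f^II` is non-increasing along every
trajectory, and the endpoint reproduces the statically computed
thermodynamic equilibrium to better than 1e−6 per species (M = 10,
both classes, verified in the tests).

Rate coefficients default to a constant `k_ij = k̃`. Because the
mass-action form measures activities from the dilute reference state,
channels forming large assemblies carry factors
`exp((i+j) mu_eq/k_BT)` near equilibrium and freeze out under deep
quenches; an activity-referenced form
`k_ij = k̃ exp(−(i+j) mu_ref/k_BT)` (symmetric, positive — identical
equilibria and detailed balance) is provided for such cases. The size
dependence of `k_ij` is system specific, so the form is pluggable.

Initial states for the ageing scenario are a monomer–solvent
coexistence embedded in the size-M space: trace amounts (1e−30) of
every larger size are partitioned between the phases so that the
embedded state is at phase equilibrium for every species before the
first step.

**Condensate growth vs shrinkage** is decided without time integration
by comparing lever-rule volumes `V^I/V` between the initial
(monomer-only) and final (full assembly equilibrium) coexistence at
the same overall composition. For class 1 the final binodal is wider,
giving growth at low `phi_tot` and shrinkage at high `phi_tot`; for
class 2 near its screened critical point the final binodal is a lens
strictly inside the monomer binodal, reversing the order (droplets at
low `phi_tot` dissolve as assemblies form).

## Fixture parameter choices

The named fixtures reproduce the qualitative regimes with deliberately
small systems (they are study conditions, not fits):

| fixture | parameters | regime |
|---|---|---|
| fig2-high-strength | d=1, class 1, `e_int=−3`, M=200, T∈[0.6,1.0] | threshold precedes dilute binodal branch |
| fig2-low-strength | d=1, class 1, `e_int=−1`, `s_int=−3`, M=60, T∈[0.38,0.48] | binodal precedes threshold; regions iv and v |
| fig3-gel | d=3, class 1, `e_int=−0.5`, T∈[0.36,0.50] | sol–sol, triple point at T≈0.41 T₀, sol–gel |
| fig4-class1 | d=1, class 1, `e_int=−0.1`, M=10, T=0.48, `phi_tot=0.4` | condensate grows during assembly |
| fig4-class2 | d=1, class 2, `chi'=0.34`, `e_int=−0.2`, M=10, T=0.465, `phi_tot=0.30` | condensate shrinks during assembly |
| fig5-class1/2 | as fig4 thermodynamics | growth/shrink maps, orderings as above |

The low-strength fixture uses an entropic binding penalty
(`s_int = −3`, i.e. `Δω = −1 + 3T`): near the critical temperature the
bonds are effectively weak, which raises the assembly threshold above
both binodal branches and realises the monomer-dominated demixed
region. The kinetics fixtures are shallow quenches (equilibrium
`mu/k_BT ≈ −1`) so that relaxation completes within ~1e5 `t_0` with
constant rate coefficients; the class-2 shrink fixture stops after a
finite window (20 `t_0`) because its droplet ultimately dissolves and
the two-phase description ends there.

## What the fixtures do and do not show

Fixtures demonstrate the mechanisms — threshold/binodal orderings,
gelation with a jump of the dense branch, growth/shrink reversal
between the classes — on small truncations and shallow quenches chosen
for fast, well-conditioned numerics. They are not parameterisations of
any specific protein: real systems have sequence-dependent, coupled
interaction parameters, polydisperse molecular volumes, diffusion
limitation and non-equilibrium (fuel-driven) turnover, none of which
are modelled. Passing tests show the implementation solves the stated
model correctly at the stated tolerances; they do not by themselves
validate the model against experimental data.

## Numerical choices and degenerate inputs

* `x ln x → 0` at `x = 0`; chemical potentials at `phi_i = 0` either
  raise or return a `−inf` sentinel, at the caller's choice.
* All size sums are evaluated in log space (log-sum-exp); the public
  distribution constructor raises, naming the offending size, if a
  requested monomer fraction would overflow any `phi_i`.
* Truncation: production d = 1 runs use M = 200 by default; doubling M
  must change the effective free energy by < 1e−8 (tested). For d > 1
  the `M → ∞` series uses adaptive truncation (terms < 1e−18 of the
  running sum); the finite-M solver raises a gelation error when mass
  piles up at the truncation boundary.
* The kinetics rejects d > 1 mixtures: gelation would require an
  unbounded size range along the trajectory.
* Near-critical common tangents return `None` when the spinodal window
  closes numerically; binodal traces warn and truncate instead of
  failing.
* Everything is deterministic; no random numbers are used outside the
  test utilities, which take explicit seeds.

## Known limitations

* Spatially resolved transport (diffusion-limited regimes, interfacial
  profiles, nucleation) is out of scope; phases are homogeneous and
  instantaneous phase equilibrium is imposed.
* Only binary association/dissociation reactions are modelled.
* Interaction parameters are independent control knobs; couplings such
  as chain swelling with binding strength are not represented.
* The gel is solvent-free by construction; hydrated gels would require
  adding solvent to the association scheme.
* At most two coexisting phases are tracked in the kinetics; a phase
  that shrinks to zero volume terminates the trajectory.
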