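"""Named parameter sets covering the qualitative regimes of the theory.

Each fixture bundles a mixture specification with the scenario settings
(temperature grids, compositions, rate model) that exhibit one regime:
assembly before or after saturation, gelation with a triple point, and
condensate growth or shrinkage during assembly.  ``run_fixture``
executes the scenario end to end and reports pass/fail for the regime's
qualitative assertions.

Parameter values are this package's own choices (selected to satisfy
the defining inequalities of each regime, e.g. high assembly strength
``-e_int/chi >> 1`` versus low ``~ 1``, and screening ``chi' < chi``
for class 2); see docs/methods.md for the rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .kinetics import RateModel, embed_monomer_coexistence, integrate, volume_change_map
from .phases import binodal_trace
from .thermo import InteractionClass, MixtureSpec

__all__ = ["FIXTURES", "Fixture", "run_fixture"]


@dataclass(frozen=True)
class Fixture:
    name: str
    description: str
    spec: MixtureSpec
    scenario: dict = field(default_factory=dict)


FIXTURES: dict[str, Fixture] = {
    "fig2-high-strength": Fixture(
        "fig2-high-strength",
        "linear assemblies, class 1, high assembly strength (-e_int/chi = 3): "
        "the assembly threshold precedes the dilute binodal branch",
        MixtureSpec(M=200, d=1, chi=1.0, e_int=-3.0, T=0.8),
        {"T_grid": [0.6, 0.7, 0.8, 0.9, 1.0]},
    ),
    "fig2-low-strength": Fixture(
        "fig2-low-strength",
        "linear assemblies, class 1, low assembly strength (-e_int/chi = 1, "
        "entropic bond penalty): the binodal precedes the assembly threshold",
        MixtureSpec(M=60, d=1, chi=1.0, e_int=-1.0, s_int=-3.0, T=0.45),
        {"T_grid": [0.38, 0.42, 0.45, 0.49]},
    ),
    "fig3-gel": Fixture(
        "fig3-gel",
        "three-dimensional assemblies, class 1: sol-sol coexistence at high T, "
        "sol-gel below the triple point with a jump of phi_I to 1",
        MixtureSpec(M=600, d=3, chi=1.0, e_int=-0.5, T=0.47),
        {"T_grid": [0.36, 0.38, 0.40, 0.42, 0.44, 0.46, 0.48, 0.50],
         "triple_window": (0.36, 0.47)},
    ),
    "fig4-class1": Fixture(
        "fig4-class1",
        "assembly kinetics, class 1, shallow quench: the dense phase grows "
        "as assemblies form",
        MixtureSpec(M=10, d=1, chi=1.0, e_int=-0.1, T=0.48),
        {"phi_tot": 0.4, "t_end": 1.0e5, "rates": RateModel(dt_factor=5.0)},
    ),
    "fig4-class2": Fixture(
        "fig4-class2",
        "assembly kinetics, class 2 (screened interactions): the dense phase "
        "shrinks as assemblies form",
        MixtureSpec(
            M=10, d=1, interaction_class=InteractionClass.CLASS2,
            chi=1.0, chi_prime=0.34, e_int=-0.2, T=0.465,
        ),
        {"phi_tot": 0.30, "t_end": 20.0, "rates": RateModel(dt_factor=5.0),
         "expect_converged": False},
    ),
    "fig5-class1": Fixture(
        "fig5-class1",
        "volume-change map, class 1: growth at low phi_tot, shrinkage at high",
        MixtureSpec(M=60, d=1, chi=1.0, e_int=-1.0, T=0.45),
        {"phi_grid": np.round(np.arange(0.20, 0.81, 0.05), 3).tolist(),
         "T_grid": [0.44, 0.46]},
    ),
    "fig5-class2": Fixture(
        "fig5-class2",
        "volume-change map, class 2: shrinkage precedes growth in phi_tot",
        MixtureSpec(
            M=10, d=1, interaction_class=InteractionClass.CLASS2,
            chi=1.0, chi_prime=0.34, e_int=-0.2, T=0.465,
        ),
        {"phi_grid": np.round(np.arange(0.275, 0.441, 0.005), 3).tolist(),
         "T_grid": [0.465]},
    ),
}


def _first_order(labels: list[str], first: str, second: str) -> bool:
    """True if `first` occurs, `second` occurs, and all `first` precede."""
    if first not in labels or second not in labels:
        return False
    return max(i for i, l in enumerate(labels) if l == first) < min(
        i for i, l in enumerate(labels) if l == second
    )


def run_fixture(name: str, verbose: bool = False):
    """Execute a named fixture scenario and check its regime assertions.

    Returns ``(result, report)`` where ``report`` is a list of
    ``(assertion, passed)`` pairs.
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    fx = FIXTURES[name]
    spec = fx.spec
    sc = fx.scenario
    report: list[tuple[str, bool]] = []

    if name.startswith("fig2"):
        diagram = binodal_trace(spec, np.asarray(sc["T_grid"]))
        demixed = ~np.isnan(diagram.phi_II) & ~np.isnan(diagram.phi_star)
        if name == "fig2-high-strength":
            ok = bool(demixed.any()) and bool(
                np.all(diagram.phi_star[demixed] < diagram.phi_II[demixed])
            )
            report.append(("assembly threshold precedes dilute binodal branch", ok))
        else:
            ok = bool(demixed.any()) and bool(
                np.all(diagram.phi_II[demixed] < diagram.phi_star[demixed])
            )
            report.append(("dilute binodal branch precedes assembly threshold", ok))
            iv = any(r == "iv" for r in diagram.region)
            v = any(r == "v" for r in diagram.region)
            report.append(("regions iv and v both occur along the trace", iv and v))
        return diagram, report

    if name == "fig3-gel":
        diagram = binodal_trace(spec, np.asarray(sc["T_grid"]))
        labels = diagram.region  # rows ordered by descending T
        report.append(
            ("sol-sol at high T and sol-gel at low T",
             _first_order(labels, "sol-sol", "sol-gel"))
        )
        tp = diagram.triple
        report.append(("triple point found inside the scanned window", tp is not None))
        ss = [k for k, l in enumerate(labels) if l == "sol-sol"]
        sg = [k for k, l in enumerate(labels) if l == "sol-gel"]
        if ss and sg:
            k1, k2 = max(ss), min(sg)
            jump = diagram.phi_I[k2] - diagram.phi_I[k1]
            cont = abs(diagram.phi_II[k2] - diagram.phi_II[k1])
            report.append(("phi_I jumps discontinuously to 1", jump > 0.2
                           and diagram.phi_I[k2] == 1.0))
            report.append(("phi_II continuous across the boundary", cont < 0.05))
        return diagram, report

    if name.startswith("fig4"):
        init = embed_monomer_coexistence(sc["phi_tot"], spec)
        with warnings.catch_warnings():
            if not sc.get("expect_converged", True):
                warnings.simplefilter("ignore")
            traj = integrate(init, spec, sc["rates"], t_end=sc["t_end"],
                             record_every=500)
        dv = traj.v_I[-1] - traj.v_I[0]
        if name == "fig4-class1":
            report.append(("dense-phase volume V_I increases", dv > 0))
        else:
            report.append(("dense-phase volume V_I decreases (net)", dv < 0))
        return traj, report

    # fig5 volume maps
    df = volume_change_map(spec, np.asarray(sc["phi_grid"]), np.asarray(sc["T_grid"]))
    ok_rows = 0
    for T, sub in df.groupby("T"):
        labels = [l for l in sub.sort_values("phi_tot")["label"]
                  if l in ("GROW", "SHRINK")]
        want = ("GROW", "SHRINK") if name == "fig5-class1" else ("SHRINK", "GROW")
        if _first_order(labels, *want):
            ok_rows += 1
    if name == "fig5-class1":
        report.append(("growth precedes shrinkage in phi_tot", ok_rows == len(sc["T_grid"])))
    else:
        report.append(("shrinkage precedes growth in phi_tot", ok_rows == len(sc["T_grid"])))
    return df, report
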