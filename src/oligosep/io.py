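"""Serialization of results: CSV, JSON sidecars and HDF5 trajectories.

Column names are part of the tool's contract (stable across versions);
floating point is written at full round-trip precision.  Every writer
drops a ``<path>.meta.json`` sidecar with the tool version and, when
available, the hash of the resolved configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import KineticsTrajectory
from .phases import PhaseDiagram

__all__ = [
    "read_table",
    "write_distribution",
    "write_threshold",
    "write_phase_diagram",
    "write_trajectory",
    "read_trajectory",
    "write_volume_map",
]

PHASE_DIAGRAM_COLUMNS = [
    "T", "phi_I", "phi_II", "monomer_frac_I", "monomer_frac_II", "phi_star", "region",
]


def read_table(path) -> pd.DataFrame:
    """Read back a written CSV with exact (round-trip) float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def _meta(path: Path, config_hash: str | None) -> None:
    meta = {"tool": "oligosep", "version": __version__}
    if config_hash is not None:
        meta["config_hash"] = config_hash
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str | None) -> None:
    df.to_csv(path, index=False, float_format="%.17g")
    _meta(path, config_hash)


def write_distribution(dist, mu, path, config_hash: str | None = None) -> None:
    """CSV with columns i, phi_i, mu_i for one size distribution."""
    path = Path(path)
    df = pd.DataFrame({"i": dist.sizes, "phi_i": dist.phi, "mu_i": mu})
    _write_csv(df, path, config_hash)


def write_threshold(curve, path, config_hash: str | None = None) -> None:
    """CSV with columns T, phi_star for an assembly-threshold curve."""
    path = Path(path)
    df = pd.DataFrame({"T": curve.T, "phi_star": curve.phi_star})
    _write_csv(df, path, config_hash)


def write_phase_diagram(
    diagram: PhaseDiagram, path, config_hash: str | None = None
) -> None:
    """CSV (contracted column set) plus a JSON sidecar with gel data."""
    path = Path(path)
    df = diagram.to_dataframe()[PHASE_DIAGRAM_COLUMNS]
    _write_csv(df, path, config_hash)
    side = {
        "triple_point": None
        if diagram.triple is None
        else {
            "T": diagram.triple.T,
            "phi_sol_dilute": diagram.triple.phi_sol_dilute,
            "phi_sol_dense": diagram.triple.phi_sol_dense,
            "phi_gel": diagram.triple.phi_gel,
        },
        "sol_gel_threshold": None
        if diagram.sol_gel_phi_sol is None
        else [None if np.isnan(x) else float(x) for x in diagram.sol_gel_phi_sol],
    }
    Path(str(path.with_suffix("")) + ".sidecar.json").write_text(
        json.dumps(side, indent=1)
    )


def write_trajectory(
    traj: KineticsTrajectory, path, format: str = "hdf5",
    config_hash: str | None = None,
) -> None:
    """Kinetics trajectory as HDF5 groups or a long-format CSV.

    HDF5 layout: /time, /phase_I/phi, /phase_II/phi, /volume,
    /free_energy.  CSV columns: t_over_t0, phase, i, phi_i,
    V_I_over_V, F_total.
    """
    path = Path(path)
    if format == "hdf5":
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("time", data=traj.times)
            h5.create_dataset("phase_I/phi", data=traj.phi_I)
            h5.create_dataset("phase_II/phi", data=traj.phi_II)
            h5.create_dataset("volume", data=traj.v_I)
            h5.create_dataset("free_energy", data=traj.free_energy)
            h5.attrs["tool"] = "oligosep"
            h5.attrs["version"] = __version__
            h5.attrs["converged"] = traj.converged
    elif format == "csv":
        M = traj.phi_I.shape[1]
        rows = []
        for k, t in enumerate(traj.times):
            for phase, phi in (("I", traj.phi_I[k]), ("II", traj.phi_II[k])):
                for i in range(M):
                    rows.append(
                        (t, phase, i + 1, phi[i], traj.v_I[k], traj.free_energy[k])
                    )
        df = pd.DataFrame(
            rows,
            columns=["t_over_t0", "phase", "i", "phi_i", "V_I_over_V", "F_total"],
        )
        _write_csv(df, path, config_hash)
        return
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    _meta(path, config_hash)


def read_trajectory(path) -> KineticsTrajectory:
    """Read back an HDF5 trajectory (bit-for-bit at stored precision)."""
    import h5py

    with h5py.File(path, "r") as h5:
        return KineticsTrajectory(
            times=h5["time"][:],
            phi_I=h5["phase_I/phi"][:],
            phi_II=h5["phase_II/phi"][:],
            v_I=h5["volume"][:],
            free_energy=h5["free_energy"][:],
            converged=bool(h5.attrs.get("converged", False)),
        )


def write_volume_map(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """CSV with columns phi_tot, T, v_initial, v_final, label."""
    _write_csv(df, Path(path), config_hash)
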