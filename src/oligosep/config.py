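"""Run configuration: strict YAML/JSON schema for reproducible runs.

A configuration file holds a ``spec`` mapping (the thermodynamic
parameters), an optional ``rates`` mapping (kinetic coefficients) and a
``params`` mapping with command-specific grids and tolerances.  Unknown
keys are rejected everywhere so a config cannot silently mistype a
parameter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .kinetics import RateForm, RateModel
from .thermo import MixtureSpec

__all__ = ["RunConfig", "load_config", "dump_config"]

_PARAM_KEYS = {
    "phi_tot": float,
    "temperature": float,
    "t_min": float,
    "t_max": float,
    "n_samples": int,
    "t_grid": list,
    "phi_grid": list,
    "t_end": float,
    "record_every": int,
    "n_project": int,
    "equilibrium_tol": float,
}
_TOL_KEYS = {"equilibrium_tol", "t_end"}


@dataclass
class RunConfig:
    """Validated run configuration."""

    spec: MixtureSpec
    rates: RateModel | None = None
    params: dict = field(default_factory=dict)
    out: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for k, v in self.params.items():
            if k not in _PARAM_KEYS:
                raise ValueError(
                    f"unknown config parameter {k!r}; allowed: {sorted(_PARAM_KEYS)}"
                )
            if k in _TOL_KEYS and not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"parameter {k!r} must be positive, got {v!r}")

    def to_dict(self) -> dict:
        out: dict = {"spec": self.spec.to_dict()}
        if self.rates is not None:
            out["rates"] = {
                "k_tilde": self.rates.k_tilde,
                "k_ij_form": self.rates.k_ij_form.value,
                "dt_factor": self.rates.dt_factor,
            }
        if self.params:
            out["params"] = dict(self.params)
        if self.out is not None:
            out["out"] = self.out
        out["log_level"] = self.log_level
        return out

    def content_hash(self) -> str:
        """Stable hash of the fully resolved configuration."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        known = {"spec", "rates", "params", "out", "log_level"}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spec" not in mapping:
            raise ValueError("config must contain a 'spec' mapping")
        spec = MixtureSpec.from_dict(mapping["spec"])
        rates = None
        if "rates" in mapping and mapping["rates"] is not None:
            r = dict(mapping["rates"])
            rknown = {"k_tilde", "k_ij_form", "dt_factor"}
            runknown = set(r) - rknown
            if runknown:
                raise ValueError(f"unknown rates keys: {sorted(runknown)}")
            if "k_ij_form" in r:
                r["k_ij_form"] = RateForm(r["k_ij_form"])
            rates = RateModel(**r)
        return cls(
            spec=spec,
            rates=rates,
            params=dict(mapping.get("params", {})),
            out=mapping.get("out"),
            log_level=mapping.get("log_level", "INFO"),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.from_dict(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (defaults filled in)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
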