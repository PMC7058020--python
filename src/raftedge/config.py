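"""Run configuration: YAML/JSON parsing, validation, output writing.

A run configuration fully specifies one scan:

.. code-block:: yaml

    membrane: default          # preset name, or an inline parameter table
    solver:
      dx: 0.025                # nm
      half_width: 20.0         # nm beyond the outermost structure
    scan:
      kind: inclusion_position # or boundary_shift
      start: -20.0             # nm
      stop: 20.0
      step: 0.25
      L: 3.0                   # fixed boundary shift (inclusion scans)
    inclusion:                 # inclusion scans only
      family: lipid_stripe
      deltaL: 1.3
      h0: 1.55
      B0: 10.0
      J0: 0.0

The pipeline is deterministic (fixed grid, direct sparse solves), so a
summary written by one run can be re-run bit-identically from the config
echoed inside it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import presets
from .inclusions import InclusionSpec
from .parameters import MembraneParameters, MonolayerParameters
from .solver import Grid

__all__ = ["RunConfig", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def _membrane_from_entry(entry) -> tuple[MembraneParameters, object]:
    if isinstance(entry, str):
        try:
            return presets.membrane(entry), entry
        except KeyError as exc:
            raise ConfigError(str(exc)) from None
    if isinstance(entry, dict):
        try:
            common = dict(
                Kt_mN_per_m=entry["Kt_mN_per_m"],
                Ka_mN_per_m=entry["Ka_mN_per_m"],
                sigma0_kBT_per_nm2=entry["sigma0_kBT_per_nm2"],
            )
            mem = MembraneParameters(
                ordered=MonolayerParameters.from_conventional_units(
                    B_kBT=entry["B_r_kBT"], J0_per_nm=entry.get("J_r_per_nm", 0.0),
                    h_nm=entry["h_r_nm"], **common),
                disordered=MonolayerParameters.from_conventional_units(
                    B_kBT=entry["B_s_kBT"], J0_per_nm=entry.get("J_s_per_nm", 0.0),
                    h_nm=entry["h_s_nm"], **common),
            )
        except KeyError as exc:
            raise ConfigError(f"membrane table misses key {exc}") from None
        return mem, entry
    raise ConfigError("membrane must be a preset name or a parameter table")


@dataclass
class RunConfig:
    """Fully resolved configuration of one scan."""

    membrane: MembraneParameters
    grid: Grid
    kind: str                       # 'boundary_shift' | 'inclusion_position'
    abscissa: np.ndarray
    L: float | None = None
    inclusion: InclusionSpec | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        mem, _ = _membrane_from_entry(data.get("membrane", "default"))
        sol = data.get("solver", {})
        try:
            grid = Grid(dx=float(sol.get("dx", 0.025)),
                        half_width=float(sol.get("half_width", 20.0)))
        except ValueError as exc:
            raise ConfigError(f"solver block: {exc}") from None

        scan = data.get("scan")
        if not isinstance(scan, dict) or "kind" not in scan:
            raise ConfigError("a 'scan' block with a 'kind' entry is required")
        kind = scan["kind"]
        if kind not in ("boundary_shift", "inclusion_position"):
            raise ConfigError(f"unknown scan kind {kind!r}")
        try:
            start, stop = float(scan["start"]), float(scan["stop"])
            step = float(scan.get("step", 0.25))
        except KeyError as exc:
            raise ConfigError(f"scan block misses {exc}") from None
        if step <= 0 or stop <= start:
            raise ConfigError("scan range must satisfy start < stop, step > 0")
        abscissa = np.arange(start, stop + step / 2, step)

        L = scan.get("L")
        inclusion = None
        if kind == "inclusion_position":
            if L is None:
                raise ConfigError("inclusion scans need a fixed boundary shift L")
            inc = data.get("inclusion")
            if not isinstance(inc, dict) or "family" not in inc:
                raise ConfigError("inclusion scans need an 'inclusion' block "
                                  "with a 'family' entry")
            kwargs = {k: v for k, v in inc.items() if k != "family"}
            kwargs.setdefault("deltaL", presets.DELTA_L)
            try:
                inclusion = InclusionSpec(family=inc["family"], X0=0.0, **kwargs)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"inclusion block: {exc}") from None
        return cls(membrane=mem, grid=grid, kind=kind, abscissa=abscissa,
                   L=None if L is None else float(L),
                   inclusion=inclusion, raw=data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        try:
            data = (json.loads(text) if path.suffix == ".json"
                    else yaml.safe_load(text))
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from None
        return cls.from_dict(data)

    def describe(self) -> dict:
        """JSON-serializable echo of the configuration (logged at startup)."""
        out = {"schema_version": SCHEMA_VERSION, "config": self.raw,
               "solver": {"dx_nm": self.grid.dx,
                          "half_width_nm": self.grid.half_width}}
        if self.inclusion is not None:
            out["inclusion"] = dataclasses.asdict(self.inclusion)
        return out
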