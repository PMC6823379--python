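"""Run configuration shared by the CLI subcommands.

A RunConfig mirrors the CLI flags; values can come from a YAML config file
(keys identical to the field names), with explicit CLI flags taking
precedence over the file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    input: str | None = None
    out: str = "."
    seed: int = 0
    # generator
    n_ions: int = 100
    box: tuple[float, float, float] = (10.0, 10.0, 10.0)
    field_e: float = 0.0            # V/nm
    temperature: float = 320.0      # K
    d_plus: float = 2.54            # nm^2/ns
    d_minus: float = 2.45           # nm^2/ns
    timestep: float = 0.01          # ns
    run_time: float = 10.0          # ns
    sample_interval: float = 0.5    # ns (bulk default; pore runs use 0.1)
    membrane_center: float | None = None
    half_thickness: float = 2.0
    pore_radius: float = 1.3
    # analysis
    plane_z: float | None = None
    n_slices: int = 100
    q_ini: int = 5
    delta_q: int = 40
    stride: int = 190
    window: float = 50.0            # ns, plateau rolling window
    tolerance: float = 0.10

    def __post_init__(self):
        if self.sample_interval <= 0 or self.timestep <= 0:
            raise ConfigurationError("sampling intervals must be > 0")
        if self.n_slices < 2:
            raise ConfigurationError("bin count must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> dict:
    """Read a YAML config file into a flat dict of RunConfig keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    return data
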