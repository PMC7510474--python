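"""Structured-text (YAML) configuration binding every tunable of the pipeline.

A config file carries five sections - geometry, rate_constants, totals,
theta, sensor and simulation/fitting settings - with full defaults, so a
run is reproducible bit-for-bit from the file alone.  ``default_config()``
returns the canonical defaults; ``config init`` on the command line writes
them to disk.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from mitonadph.errors import ConfigurationError
from mitonadph.redox_network import Geometry, KineticParameters, THETA_NAMES
from mitonadph.sensor import SensorCalibration
from mitonadph.steady_state import MoietyTotals
from mitonadph.synthetic_data import SyntheticStudyDesign


@dataclass
class SimulationSettings:
    t_end_min: float = 60.0
    dt_report_min: float = 3.0
    rtol: float = 1e-8
    atol: float = 1e-12


@dataclass
class FitSettings:
    n_starts: int = 1000
    seed: int = 0
    fit_conditions_mm: tuple[float, ...] = (50.0,)
    bound_decades: float = 2.0


@dataclass
class PipelineConfig:
    geometry: Geometry = field(default_factory=Geometry)
    rate_constants: KineticParameters = field(default_factory=KineticParameters)
    totals: MoietyTotals = field(default_factory=MoietyTotals)
    sensor: SensorCalibration = field(default_factory=SensorCalibration)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    fitting: FitSettings = field(default_factory=FitSettings)
    synthesis: SyntheticStudyDesign = field(default_factory=SyntheticStudyDesign)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            section = asdict(getattr(self, f.name))
            # theta lives in its own section for readability
            if f.name == "rate_constants":
                theta = {k: section.pop(k) for k in THETA_NAMES}
                out["rate_constants"] = section
                out["theta"] = theta
            else:
                out[f.name] = section
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)} | {"theta"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
        rc = dict(data.get("rate_constants", {}))
        rc.update(data.get("theta", {}))
        listy = lambda d, keys: {  # noqa: E731 - tuple-ify list-valued yaml entries
            k: tuple(v) if k in keys and isinstance(v, list) else v for k, v in d.items()
        }
        return cls(
            geometry=Geometry(**data.get("geometry", {})),
            rate_constants=KineticParameters.from_dict(rc),
            totals=MoietyTotals(**data.get("totals", {})),
            sensor=SensorCalibration(**data.get("sensor", {})),
            simulation=SimulationSettings(**data.get("simulation", {})),
            fitting=FitSettings(**listy(data.get("fitting", {}), {"fit_conditions_mm"})),
            synthesis=SyntheticStudyDesign(
                **listy(data.get("synthesis", {}), {"conditions_mm", "n_cells"})
            ),
        )

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config() -> PipelineConfig:
    return PipelineConfig()


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return PipelineConfig.from_dict(data)
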