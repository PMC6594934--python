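"""YAML configuration round-trip for model and scenario settings.

One structured YAML file holds every knob; omitted sections fall back
to the package defaults, so an empty file is a valid configuration.
Transports are written in Sverdrup for readability.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .airsea import GasExchangeParams
from .circulation import CirculationScheme
from .ecosystem import EcosystemParams
from .geometry import BoxGeometry
from .model import (
    ModelConfig,
    default_base_temperature,
    default_downstream,
)
from .scenario import ScenarioParams
from .stoichiometry import StoichiometryParams
from .units import SV


class ConfigError(ValueError):
    pass


def _geometry_to_dict(g: BoxGeometry) -> dict:
    return {
        "labels": list(g.labels),
        "volumes_m3": [float(v) for v in g.volumes],
        "is_surface": [bool(s) for s in g.is_surface],
        "surface_areas_m2": [float(a) for a in g.surface_areas],
    }


def _geometry_from_dict(d: dict) -> BoxGeometry:
    return BoxGeometry(
        labels=tuple(d["labels"]),
        volumes=np.array(d["volumes_m3"], dtype=float),
        is_surface=np.array(d["is_surface"], dtype=bool),
        surface_areas=np.array(d["surface_areas_m2"], dtype=float),
    )


def _circulation_to_dict(c: CirculationScheme) -> dict:
    return {
        "overturning_sv": [
            {"from": a, "to": b, "sv": q / SV}
            for (a, b), q in c.overturning.items()
        ],
        "mixing_sv": [
            {"a": a, "b": b, "sv": k / SV} for (a, b), k in c.mixing.items()
        ],
    }


def _circulation_from_dict(d: dict) -> CirculationScheme:
    return CirculationScheme(
        overturning={
            (e["from"], e["to"]): float(e["sv"]) * SV
            for e in d["overturning_sv"]
        },
        mixing={
            (e["a"], e["b"]): float(e["sv"]) * SV for e in d["mixing_sv"]
        },
    )


def config_to_dict(config: ModelConfig, scenario: ScenarioParams | None = None) -> dict:
    d = {
        "geometry": _geometry_to_dict(config.geometry),
        "circulation": _circulation_to_dict(config.circulation),
        "stoichiometry": asdict(config.stoichiometry),
        "ecosystem": asdict(config.ecosystem),
        "gas_exchange": asdict(config.gas_exchange),
        "base_temperature_degC": dict(config.base_temperature),
        "downstream": dict(config.downstream),
        "integration": {
            "dt_yr": config.dt,
            "output_interval_yr": config.output_interval,
            "spinup_tol": config.spinup_tol,
            "spinup_max_years": config.spinup_max_years,
            "spinup_check_interval_yr": config.spinup_check_interval,
        },
        "switches": {
            "biology_enabled": config.biology_enabled,
            "diazotrophs_enabled": config.diazotrophs_enabled,
            "denitrification_enabled": config.denitrification_enabled,
        },
        "remainder_warn_fraction": config.remainder_warn_fraction,
        "seed": config.seed,
    }
    d["scenario"] = asdict(scenario or ScenarioParams())
    return d


def config_from_dict(d: dict) -> tuple[ModelConfig, ScenarioParams]:
    d = d or {}
    try:
        geometry = (
            _geometry_from_dict(d["geometry"]) if "geometry" in d
            else BoxGeometry()
        )
        circulation = (
            _circulation_from_dict(d["circulation"]) if "circulation" in d
            else CirculationScheme()
        )
        stoich = StoichiometryParams(**d.get("stoichiometry", {}))
        eco = EcosystemParams(**d.get("ecosystem", {}))
        gas = GasExchangeParams(**d.get("gas_exchange", {}))
        integ = d.get("integration", {})
        switches = d.get("switches", {})
        config = ModelConfig(
            geometry=geometry,
            circulation=circulation,
            stoichiometry=stoich,
            ecosystem=eco,
            gas_exchange=gas,
            base_temperature=d.get(
                "base_temperature_degC", default_base_temperature()
            ),
            downstream=d.get("downstream", default_downstream()),
            dt=float(integ.get("dt_yr", 0.05)),
            output_interval=float(integ.get("output_interval_yr", 1.0)),
            spinup_tol=float(integ.get("spinup_tol", 1.0e-8)),
            spinup_max_years=float(integ.get("spinup_max_years", 60000.0)),
            spinup_check_interval=float(
                integ.get("spinup_check_interval_yr", 100.0)
            ),
            biology_enabled=bool(switches.get("biology_enabled", True)),
            diazotrophs_enabled=bool(switches.get("diazotrophs_enabled", True)),
            denitrification_enabled=bool(
                switches.get("denitrification_enabled", True)
            ),
            remainder_warn_fraction=float(
                d.get("remainder_warn_fraction", 0.01)
            ),
            seed=int(d.get("seed", 0)),
        )
        scenario = ScenarioParams(**d.get("scenario", {}))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return config, scenario


def load_config(path: str | Path) -> tuple[ModelConfig, ScenarioParams]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping: {path}")
    return config_from_dict(data or {})


def dump_config(
    config: ModelConfig | None = None,
    scenario: ScenarioParams | None = None,
    path: str | Path | None = None,
) -> str:
    text = yaml.safe_dump(
        config_to_dict(config or ModelConfig(), scenario),
        sort_keys=False, default_flow_style=False,
    )
    if path is not None:
        Path(path).write_text(text)
    return text
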