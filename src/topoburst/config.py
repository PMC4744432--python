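"""YAML configuration for systems, simulations and thermodynamic parameters.

Schema::

    globals:            # optional, defaults gamma=50, d=1
      gamma: 50
      d: 1
    domains:
      - name: domain1
        max_rcoil: 4
        K1: 10
        K2: 35
        R: 1000
        genes:
          - {name: gene1, a_o: 100, b_o: 2, translated: true}
    simulation:         # optional
      t_end: 20
      n_cells: 4000
      burn_in: 10
      seed: 1
      record_interval: 0.1
    thermo: {}          # optional overrides of the melting-model constants
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import ConfigError, DomainSpec, GeneSpec, GlobalRates, SystemSpec
from .thermo import ThermoParams

__all__ = ["SimulationSettings", "Config", "load_config", "system_from_dict"]


@dataclass(frozen=True)
class SimulationSettings:
    t_end: float = 20.0
    n_cells: int = 4000
    burn_in: float = 10.0
    seed: int = 0
    record_interval: float | None = None


@dataclass(frozen=True)
class Config:
    system: SystemSpec
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    thermo: ThermoParams = field(default_factory=ThermoParams)


def _require_keys(d: dict, allowed: set[str], where: str) -> None:
    extra = set(d) - allowed
    if extra:
        raise ConfigError(f"unknown keys {sorted(extra)} in {where}")


def system_from_dict(data: dict) -> SystemSpec:
    _require_keys(data, {"globals", "domains", "simulation", "thermo"}, "config")
    g = data.get("globals", {})
    _require_keys(g, {"gamma", "d"}, "globals")
    global_rates = GlobalRates(gamma=float(g.get("gamma", 50.0)), d=float(g.get("d", 1.0)))
    if "domains" not in data or not data["domains"]:
        raise ConfigError("config must define at least one domain")
    domains = []
    for dom in data["domains"]:
        _require_keys(dom, {"name", "max_rcoil", "K1", "K2", "R", "genes"}, f"domain {dom.get('name')}")
        genes = []
        for gene in dom.get("genes", []):
            _require_keys(gene, {"name", "a_o", "b_o", "translated"}, f"gene {gene.get('name')}")
            genes.append(
                GeneSpec(
                    name=str(gene["name"]), a_o=float(gene["a_o"]),
                    b_o=float(gene.get("b_o", 2.0)),
                    translated=bool(gene.get("translated", True)),
                )
            )
        domains.append(
            DomainSpec(
                name=str(dom["name"]), genes=tuple(genes),
                max_rcoil=int(dom.get("max_rcoil", 4)),
                K1=float(dom.get("K1", 10.0)), K2=float(dom.get("K2", 35.0)),
                R=float(dom.get("R", 1000.0)),
            )
        )
    return SystemSpec(domains=tuple(domains), global_rates=global_rates)


def load_config(path) -> Config:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    system = system_from_dict(data)
    sim = data.get("simulation", {})
    _require_keys(sim, {"t_end", "n_cells", "burn_in", "seed", "record_interval"}, "simulation")
    settings = SimulationSettings(
        t_end=float(sim.get("t_end", 20.0)),
        n_cells=int(sim.get("n_cells", 4000)),
        burn_in=float(sim.get("burn_in", 10.0)),
        seed=int(sim.get("seed", 0)),
        record_interval=(
            float(sim["record_interval"]) if sim.get("record_interval") is not None else None
        ),
    )
    thermo = ThermoParams(**data.get("thermo", {}))
    return Config(system=system, simulation=settings, thermo=thermo)
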