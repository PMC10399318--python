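"""YAML run-configuration loading for the CLI.

A run config is a single YAML document with optional sections ``chain``,
``bead``, ``forcefield``, ``forcing``, ``simulation`` and ``topology``;
omitted fields fall back to the study defaults.  All values are SI.

Example::

    chain: {n_beads: 14, slack_length: 3.4e-3}
    forcefield: {kv: 0.1}
    forcing: {kind: laplace, seed: 7, targets: all}
    simulation: {n_steps: 400000, equilibration_steps: 100000,
                 record_stride: 100}
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .chain import BeadSpec, ChainSpec, ChainTopology, build_topology
from .forcefield import ForceField, ForcingModel
from .simulator import SimulationConfig

__all__ = ["RunSetup", "load_run_config", "default_run_config"]


@dataclass
class RunSetup:
    chain: ChainSpec
    bead: BeadSpec
    forces: ForceField
    forcing: ForcingModel
    simulation: SimulationConfig
    topology_options: dict

    def build_topology(self) -> ChainTopology:
        return build_topology(self.chain, self.bead, self.forces,
                              **self.topology_options)


def default_run_config() -> dict:
    """A complete run-config dict with all defaults spelled out."""
    return {
        "chain": ChainSpec().__dict__.copy(),
        "bead": BeadSpec().__dict__.copy(),
        "forcefield": ForceField().to_dict(),
        "forcing": {"kind": "laplace", "kr": ForceField().kr, "seed": 0,
                    "targets": "all"},
        "simulation": SimulationConfig().to_dict(),
        "topology": {},
    }


def load_run_config(path) -> RunSetup:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    chain = ChainSpec(**doc.get("chain", {}))
    bead = BeadSpec(**doc.get("bead", {}))
    forces = ForceField(**doc.get("forcefield", {}))
    forcing_doc = dict(doc.get("forcing", {}))
    forcing_doc.setdefault("kr", forces.kr)
    forcing = ForcingModel(**forcing_doc)
    sim = SimulationConfig(**doc.get("simulation", {}))
    return RunSetup(chain=chain, bead=bead, forces=forces, forcing=forcing,
                    simulation=sim, topology_options=dict(doc.get("topology", {})))
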