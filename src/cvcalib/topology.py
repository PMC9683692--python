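"""Declarative description of the closed-loop circulation network.

The compiled simulator in :mod:`cvcalib.model` realizes exactly one
topology — the packaged reduced closed-loop network.  The JSON topology
file documents that network (compartments and directed flow paths) and is
validated structurally: unique names, the full named compartment set
(heart chambers, valves, pulmonary vessels, terminal beds, venous
compartments), and a single closed loop in the graph sense (strongly
connected, every compartment with at least one inflow and one outflow, so
net flow can balance at every junction).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = ["CVSTopology", "default_topology", "REQUIRED_COMPARTMENTS"]

#: Compartments that must be present in any valid topology.
REQUIRED_COMPARTMENTS = frozenset(
    {
        "RA", "RV", "LA", "LV",
        "trv", "puv", "miv", "aov",
        "par", "pvn",
        "LE_T", "BR_T", "AC_T", "EC_T", "MC_T", "PC_T", "TR_T",
        "vub", "svc", "vlb", "ivc",
    }
)


@dataclass
class CVSTopology:
    name: str
    compartments: list[dict] = field(default_factory=list)
    connections: list[tuple[str, str]] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        self.connections = [tuple(c) for c in self.connections]
        self.validate()

    @property
    def compartment_names(self) -> list[str]:
        return [c["name"] for c in self.compartments]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.compartment_names)
        g.add_edges_from(self.connections)
        return g

    def validate(self) -> None:
        names = self.compartment_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names in topology")
        missing = REQUIRED_COMPARTMENTS - set(names)
        if missing:
            raise ValueError(f"topology missing required compartments: {sorted(missing)}")
        g = self.graph()
        unknown = [(a, b) for a, b in self.connections if a not in g or b not in g]
        if unknown:
            raise ValueError(f"connections reference unknown compartments: {unknown}")
        if not nx.is_strongly_connected(g):
            raise ValueError("topology is not a single closed loop "
                             "(graph not strongly connected)")
        for n in g.nodes:
            if g.in_degree(n) == 0 or g.out_degree(n) == 0:
                raise ValueError(f"compartment {n!r} lacks inflow or outflow")

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "CVSTopology":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            name=d["name"],
            compartments=d["compartments"],
            connections=[tuple(c) for c in d["connections"]],
            description=d.get("description", ""),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "description": self.description,
                    "compartments": self.compartments,
                    "connections": [list(c) for c in self.connections],
                },
                fh,
                indent=1,
            )


def default_topology() -> CVSTopology:
    """The packaged reduced closed-loop topology (the one the solver compiles)."""
    ref = importlib.resources.files("cvcalib.data").joinpath("topology.json")
    with importlib.resources.as_file(ref) as p:
        return CVSTopology.from_json(p)
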