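"""Core domain types shared across the pipeline.

Coordinates are planar, in kilometres; there is no geodesy. Road segment
lengths are stored in metres and speeds in km/h, matching the conventions
of national road databases. All travel times are minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import networkx as nx

#: Ambulance driving time as a fraction of speed-limit driving time
#: (ambulances drive faster than the posted limit).
DEFAULT_SPEED_FACTOR = 0.8

#: Marker for cells/nodes with no route to any facility.
UNREACHABLE = math.inf


@dataclass(frozen=True)
class Edge:
    """A directed or bidirectional road segment.

    A two-way segment (``oneway=False``) is traversable in both directions;
    it is stored once. Ferry segments carry a positive ``crossing_min``
    added on top of the sailing time implied by ``length_m``/``speed_kmh``.
    """

    u: int
    v: int
    length_m: float
    speed_kmh: float
    oneway: bool = False
    ferry: bool = False
    crossing_min: float = 0.0

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise ValueError(f"edge ({self.u},{self.v}): length_m must be > 0")
        if self.speed_kmh <= 0:
            raise ValueError(f"edge ({self.u},{self.v}): speed_kmh must be > 0")
        if self.crossing_min < 0:
            raise ValueError(f"edge ({self.u},{self.v}): crossing_min must be >= 0")
        if self.ferry != (self.crossing_min > 0):
            raise ValueError(
                f"edge ({self.u},{self.v}): crossing_min must be > 0 iff ferry"
            )

    @property
    def minutes(self) -> float:
        """Traversal time at the speed limit, including ferry crossing."""
        return 60.0 * (self.length_m / 1000.0) / self.speed_kmh + self.crossing_min


@dataclass
class RoadNetwork:
    """A road network: node coordinates (km) plus a list of segments."""

    nodes: dict[int, tuple[float, float]]
    edges: list[Edge]

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.u not in self.nodes or e.v not in self.nodes:
                raise ValueError(f"edge ({e.u},{e.v}) references unknown node")

    @cached_property
    def graph(self) -> nx.DiGraph:
        """Directed graph with per-edge ``minutes`` weights at speed limits."""
        g = nx.DiGraph()
        for nid, (x, y) in self.nodes.items():
            g.add_node(nid, x=x, y=y)
        for e in self.edges:
            m = e.minutes
            g.add_edge(e.u, e.v, minutes=m)
            if not e.oneway:
                g.add_edge(e.v, e.u, minutes=m)
        return g

    @cached_property
    def reverse_graph(self) -> nx.DiGraph:
        return self.graph.reverse(copy=True)

    def invalidate_caches(self) -> None:
        """Drop memoised graphs after mutating ``nodes``/``edges``."""
        self.__dict__.pop("graph", None)
        self.__dict__.pop("reverse_graph", None)


@dataclass
class PopulationCell:
    """A square population grid cell snapped to its nearest road node."""

    cell_id: int
    centroid: tuple[float, float]
    population: int
    area_km2: float
    node: int | None = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be >= 0")
        if self.area_km2 <= 0:
            raise ValueError("area_km2 must be > 0")


HOSPITAL = "hospital"
EVT = "evt"  # EVT-capable hospital (comprehensive stroke centre)
CANDIDATE = "candidate"  # potential rural CT site (public-building proxy)
CT_STATION = "ct"  # a deployed rural CT station

FACILITY_KINDS = (HOSPITAL, EVT, CANDIDATE, CT_STATION)


@dataclass
class Facility:
    """A hospital, EVT centre, deployed CT station or candidate CT site.

    Door times are per-facility service parameters in minutes:

    - ``door_to_needle_min``: arrival to thrombolysis start;
    - ``door_in_door_out_min``: arrival to onward departure when the site
      is an intermediate stop (for hospitals this is door-to-needle plus a
      fixed 30-min needle-to-door-out; rural CT stations use 50 min);
    - ``door_to_groin_min``: arrival to groin puncture, EVT centres only.
    """

    facility_id: str
    x: float
    y: float
    kind: str
    door_to_needle_min: float = 30.0
    door_in_door_out_min: float = 60.0
    door_to_groin_min: float = math.nan
    node: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in FACILITY_KINDS:
            raise ValueError(f"unknown facility kind {self.kind!r}")
        if self.kind == EVT and not (self.door_to_groin_min > 0):
            raise ValueError("EVT centre requires a positive door_to_groin_min")

    @property
    def is_hospital(self) -> bool:
        return self.kind in (HOSPITAL, EVT)

    @property
    def is_evt_centre(self) -> bool:
        return self.kind == EVT

    @property
    def offers_thrombolysis(self) -> bool:
        return self.kind in (HOSPITAL, EVT, CT_STATION)
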