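"""Ambulance travel times over the road network.

Implements the closest-facility step: shortest driving times at speed
limits from every population cell to its nearest facility, scaled by a
speed factor (default 0.8 — ambulances cover a route in 80% of the
speed-limit driving time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .core import DEFAULT_SPEED_FACTOR, UNREACHABLE, Facility, PopulationCell, RoadNetwork


def snap_to_network(point: tuple[float, float], network: RoadNetwork) -> int:
    """Nearest network node to a planar point; ties broken by lowest node id."""
    if not network.nodes:
        raise ValueError("cannot snap to an empty network")
    px, py = point
    best_id, best_d2 = None, math.inf
    for nid in sorted(network.nodes):
        x, y = network.nodes[nid]
        d2 = (x - px) ** 2 + (y - py) ** 2
        if d2 < best_d2:
            best_id, best_d2 = nid, d2
    return best_id


def driving_minutes(network: RoadNetwork, origin: int, destination: int) -> float:
    """Time-shortest directed path length in minutes at speed limits.

    Returns ``math.inf`` when no path exists. One-way segments are
    traversable only in their stored direction; ferry crossings add their
    crossing time.
    """
    g = network.graph
    if origin not in g or destination not in g:
        raise ValueError(f"unknown node id: {origin if origin not in g else destination}")
    try:
        return nx.dijkstra_path_length(g, origin, destination, weight="minutes")
    except nx.NetworkXNoPath:
        return UNREACHABLE


def minutes_to_node(network: RoadNetwork, target: int) -> dict[int, float]:
    """Driving minutes from every node TO ``target`` (reverse Dijkstra)."""
    if target not in network.reverse_graph:
        raise ValueError(f"unknown node id: {target}")
    return nx.single_source_dijkstra_path_length(
        network.reverse_graph, target, weight="minutes"
    )


@dataclass
class TravelTimeField:
    """Per-cell nearest facility and ambulance minutes.

    ``minutes`` holds ``speed_factor`` × shortest driving minutes;
    unreachable cells carry ``math.inf`` and a ``None`` facility — never a
    silent zero.
    """

    minutes: dict[int, float]
    facility: dict[int, str | None]
    speed_factor: float = DEFAULT_SPEED_FACTOR

    def is_unreachable(self, cell_id: int) -> bool:
        return not math.isfinite(self.minutes[cell_id])

    @property
    def unreachable_cells(self) -> list[int]:
        return [c for c, m in self.minutes.items() if not math.isfinite(m)]

    def reachable(self) -> dict[int, float]:
        return {c: m for c, m in self.minutes.items() if math.isfinite(m)}


def snap_facilities(network: RoadNetwork, facilities: list[Facility]) -> None:
    """Fill in ``Facility.node`` for facilities lacking a snapped node."""
    for f in facilities:
        if f.node is None:
            f.node = snap_to_network((f.x, f.y), network)


def closest_facility_field(
    network: RoadNetwork,
    cells: list[PopulationCell],
    facilities: list[Facility],
    speed_factor: float = DEFAULT_SPEED_FACTOR,
) -> TravelTimeField:
    """Nearest facility (by ambulance time) for every cell.

    Ties broken by lowest facility id. Cells with no route to any facility
    are flagged unreachable. ``speed_factor`` must lie in (0, 1]; it is a
    uniform scaling, so it cannot change which facility is nearest.
    """
    if not facilities:
        raise ValueError("facilities must be non-empty")
    if not (0 < speed_factor <= 1):
        raise ValueError("speed_factor must lie in (0, 1]")
    snap_facilities(network, facilities)
    # One reverse Dijkstra per facility: minutes from every node to it.
    per_fac: list[tuple[str, dict[int, float]]] = [
        (f.facility_id, minutes_to_node(network, f.node))
        for f in sorted(facilities, key=lambda f: f.facility_id)
    ]
    minutes: dict[int, float] = {}
    nearest: dict[int, str | None] = {}
    for cell in cells:
        best_m, best_f = UNREACHABLE, None
        for fid, dist in per_fac:
            m = dist.get(cell.node, UNREACHABLE)
            if m < best_m:  # strict: earlier (lower) id wins ties
                best_m, best_f = m, fid
        minutes[cell.cell_id] = speed_factor * best_m if math.isfinite(best_m) else UNREACHABLE
        nearest[cell.cell_id] = best_f
    return TravelTimeField(minutes=minutes, facility=nearest, speed_factor=speed_factor)
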