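"""Seeded synthetic geographies for the pipeline.

The generator emulates the statistical structure the analysis assumes for
a sparsely populated country: a handful of dense towns connected by fast
trunk roads, slow rural branch roads reaching into remote valleys and
along fjords (optionally via ferries), and a population that is mostly
urban with a configurable minority living more than 70 ambulance-minutes
from the nearest hospital.

Population is allocated *after* travel times are computed, so the share of
residents beyond the 70-minute rurality threshold matches the requested
``rural_tail_fraction`` up to integer rounding — the calibration is by
construction, not by tuning.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .core import (
    CANDIDATE,
    DEFAULT_SPEED_FACTOR,
    EVT,
    HOSPITAL,
    Edge,
    Facility,
    PopulationCell,
    RoadNetwork,
)
from .traveltime import snap_to_network


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of a synthetic region.

    ``rural_tail_fraction`` is the target share of the population whose
    baseline ambulance time to the nearest hospital exceeds 70 minutes;
    ``town_population_fraction`` lives in the town cores; the remainder is
    spread over accessible countryside within the threshold.
    """

    grid_extent_km: tuple[float, float] = (120.0, 120.0)
    cell_size_m: float = 250.0
    n_towns: int = 5
    town_population_fraction: float = 0.70
    rural_tail_fraction: float = 0.12
    n_hospitals: int = 3
    n_evt_centres: int = 1
    n_candidate_sites: int = 25
    speed_limit_set: tuple[float, ...] = (50.0, 60.0, 80.0, 90.0)
    ferry_probability: float = 0.05
    total_population: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        for name in ("town_population_fraction", "rural_tail_fraction", "ferry_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.town_population_fraction + self.rural_tail_fraction > 1.0:
            raise ValueError("town + rural population fractions exceed 1")
        for name in ("n_towns", "n_hospitals", "n_candidate_sites", "total_population"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_evt_centres < 0:
            raise ValueError("n_evt_centres must be >= 0")
        if self.n_evt_centres > self.n_hospitals:
            raise ValueError("EVT centres are a subset of hospitals")
        if self.n_hospitals > self.n_towns:
            raise ValueError("need at least one town per hospital")
        if self.cell_size_m <= 0 or min(self.grid_extent_km) <= 0:
            raise ValueError("cell_size_m and grid_extent_km must be positive")
        if not self.speed_limit_set or min(self.speed_limit_set) <= 0:
            raise ValueError("speed_limit_set must contain positive speeds")


#: Rurality threshold used for calibration (ambulance minutes).
RURAL_THRESHOLD_MIN = 70.0


class RegionGenerationError(RuntimeError):
    """Raised when no valid region could be generated within the retry bound."""


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer split of ``total`` proportional to ``weights`` (largest remainder)."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
    return base


class _Builder:
    """Single-attempt region builder; all randomness from one Generator."""

    def __init__(self, spec: RegionSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.nodes: dict[int, tuple[float, float]] = {}
        self.edges: list[Edge] = []
        self._next = 0
        self.town_centres: list[int] = []  # node ids, ordered by town size
        self.branch_nodes: list[int] = []

    def new_node(self, x: float, y: float) -> int:
        nid = self._next
        self._next += 1
        self.nodes[nid] = (round(float(x), 4), round(float(y), 4))
        return nid

    def add_edge(self, u: int, v: int, speed: float, *, oneway=False, ferry=False,
                 crossing_min=0.0) -> None:
        (x1, y1), (x2, y2) = self.nodes[u], self.nodes[v]
        length_m = max(1.0, round(1000.0 * math.hypot(x2 - x1, y2 - y1), 1))
        self.edges.append(Edge(u, v, length_m, speed, oneway=oneway, ferry=ferry,
                               crossing_min=round(float(crossing_min), 2)))

    # -- layout -------------------------------------------------------

    def place_towns(self) -> list[tuple[float, float]]:
        w, h = self.spec.grid_extent_km
        margin = 0.08 * min(w, h)
        pts = [(margin + self.rng.random() * (w - 2 * margin),
                margin + self.rng.random() * (h - 2 * margin))]
        while len(pts) < self.spec.n_towns:
            # best-candidate sampling spreads towns apart
            cands = self.rng.random((12, 2)) * (w - 2 * margin, h - 2 * margin) + margin
            d = [min((cx - x) ** 2 + (cy - y) ** 2 for x, y in pts) for cx, cy in cands]
            pts.append(tuple(cands[int(np.argmax(d))]))
        return pts

    def build_town(self, cx: float, cy: float) -> int:
        """Town = centre node plus a ring of streets; returns the centre id."""
        slow = min(self.spec.speed_limit_set)
        centre = self.new_node(cx, cy)
        ring = []
        n_ring = 6
        r = 0.9
        for i in range(n_ring):
            a = 2 * math.pi * i / n_ring
            ring.append(self.new_node(cx + r * math.cos(a), cy + r * math.sin(a)))
        oneway_ring = self.rng.random() < 0.35  # a clockwise one-way ring stays strongly connected
        for i in range(n_ring):
            u, v = ring[i], ring[(i + 1) % n_ring]
            self.add_edge(u, v, slow, oneway=oneway_ring)
        for i in range(0, n_ring, 2):
            self.add_edge(centre, ring[i], slow)
        return centre

    def corridor(self, u: int, v: int, speed: float, seg_km: float,
                 allow_ferry: bool = True) -> list[int]:
        """Subdivided road between two existing nodes; returns interior nodes."""
        (x1, y1), (x2, y2) = self.nodes[u], self.nodes[v]
        dist = math.hypot(x2 - x1, y2 - y1)
        n_seg = max(1, int(round(dist / seg_km)))
        interior = []
        prev = u
        ferry_seg = -1
        if allow_ferry and n_seg >= 3 and self.rng.random() < self.spec.ferry_probability:
            ferry_seg = int(self.rng.integers(1, n_seg - 1))
        for i in range(1, n_seg + 1):
            t = i / n_seg
            jitter = 0.15 * seg_km
            if i <= n_seg - 1:
                nid = self.new_node(x1 + t * (x2 - x1) + self.rng.normal(0, jitter),
                                    y1 + t * (y2 - y1) + self.rng.normal(0, jitter))
                interior.append(nid)
            else:
                nid = v
            if i - 1 == ferry_seg:
                self.add_edge(prev, nid, 17.0, ferry=True,
                              crossing_min=float(self.rng.uniform(8, 20)))
            else:
                self.add_edge(prev, nid, speed)
            prev = nid
        return interior

    def build(self) -> tuple[RoadNetwork, list[int], np.ndarray]:
        spec = self.spec
        centres_xy = self.place_towns()
        # Town sizes: power-law-ish weights, largest first.
        sizes = np.sort(self.rng.pareto(1.2, spec.n_towns) + 1.0)[::-1]
        for cx, cy in centres_xy:
            self.town_centres.append(self.build_town(cx, cy))

        # Trunk roads: MST over town centres, subdivided into fast segments.
        fast = [s for s in spec.speed_limit_set if s >= np.median(spec.speed_limit_set)]
        g = nx.Graph()
        for i, u in enumerate(self.town_centres):
            for j in range(i + 1, len(self.town_centres)):
                v = self.town_centres[j]
                (x1, y1), (x2, y2) = self.nodes[u], self.nodes[v]
                g.add_edge(u, v, w=math.hypot(x2 - x1, y2 - y1))
        trunk_interior: list[int] = []
        for u, v in nx.minimum_spanning_edges(g, weight="w", data=False):
            speed = float(self.rng.choice(fast))
            trunk_interior += self.corridor(u, v, speed, seg_km=3.0)

        # Rural branches: slow chains leaving trunk/town nodes for the hinterland.
        slow_speeds = [s for s in spec.speed_limit_set if s <= np.median(spec.speed_limit_set)]
        anchors = trunk_interior if trunk_interior else list(self.town_centres)
        n_branches = max(4, spec.n_towns + 2)
        w, h = spec.grid_extent_km
        for _ in range(n_branches):
            start = int(self.rng.choice(anchors))
            x, y = self.nodes[start]
            # head roughly away from the region centre
            a = math.atan2(y - h / 2, x - w / 2) + self.rng.normal(0, 0.7)
            prev = start
            for _seg in range(int(self.rng.integers(6, 14))):
                a += self.rng.normal(0, 0.45)
                step = self.rng.uniform(2.5, 5.5)
                x, y = x + step * math.cos(a), y + step * math.sin(a)
                nid = self.new_node(x, y)
                speed = float(self.rng.choice(slow_speeds))
                if self.rng.random() < spec.ferry_probability / 3:
                    self.add_edge(prev, nid, 17.0, ferry=True,
                                  crossing_min=float(self.rng.uniform(8, 20)))
                else:
                    self.add_edge(prev, nid, speed)
                self.branch_nodes.append(nid)
                prev = nid
        net = RoadNetwork(nodes=self.nodes, edges=self.edges)
        return net, self.town_centres, sizes

    def extend_remote_branch(self, net: RoadNetwork, tip: int, minutes_at_tip: dict[int, float],
                             n_seg: int = 3) -> None:
        """Grow a branch tip outward with slow segments (deepens the rural tail)."""
        slow = min(self.spec.speed_limit_set)
        x, y = self.nodes[tip]
        w, h = self.spec.grid_extent_km
        a = math.atan2(y - h / 2, x - w / 2) + self.rng.normal(0, 0.4)
        prev = tip
        t = minutes_at_tip[tip]
        for _ in range(n_seg):
            a += self.rng.normal(0, 0.3)
            step = self.rng.uniform(3.0, 6.0)
            x, y = x + step * math.cos(a), y + step * math.sin(a)
            nid = self.new_node(x, y)
            self.add_edge(prev, nid, slow)
            self.branch_nodes.append(nid)
            t += self.edges[-1].minutes
            minutes_at_tip[nid] = t
            prev = nid
        net.invalidate_caches()


def _hospital_minutes(net: RoadNetwork, hospital_nodes: list[int]) -> dict[int, float]:
    """Driving minutes from every node to its nearest hospital node."""
    dist = nx.multi_source_dijkstra_path_length(
        net.reverse_graph, set(hospital_nodes), weight="minutes"
    )
    return dist


def generate_region(
    spec: RegionSpec, max_retries: int = 5
) -> tuple[RoadNetwork, list[PopulationCell], list[Facility]]:
    """Generate a synthetic region satisfying the spec's structure.

    Deterministic for a given ``spec.seed``. Retries with a fresh internal
    stream (still derived from the seed) if a draw produces a hospital
    layout that cannot reach the bulk of the population; raises
    :class:`RegionGenerationError` after ``max_retries`` failures.
    """
    spec.validate()
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % 2**31, attempt]))
        try:
            return _generate_once(spec, rng)
        except RegionGenerationError as err:  # retry with attempt-shifted stream
            last_err = err
    raise RegionGenerationError(f"no valid region after {max_retries} attempts: {last_err}")


def _generate_once(spec, rng):
    b = _Builder(spec, rng)
    net, town_centres, town_sizes = b.build()

    # Hospitals in the largest towns; the very largest get EVT capability.
    hosp_nodes = town_centres[: spec.n_hospitals]
    minutes = _hospital_minutes(net, hosp_nodes)
    amb = {n: DEFAULT_SPEED_FACTOR * m for n, m in minutes.items()}

    # Every town core must reach a hospital; otherwise the draw is unusable.
    if any(c not in minutes for c in town_centres):
        raise RegionGenerationError("a town core cannot reach any hospital")

    # Deepen branches until the rural tail has enough distinct settlements
    # (node times along a new chain accumulate; no global recompute needed).
    need_rural = spec.rural_tail_fraction > 0
    want_nodes = max(10, 2 * spec.n_candidate_sites)
    guard = 0
    while need_rural:
        rural_nodes = [n for n in b.branch_nodes
                       if n in amb and amb[n] > RURAL_THRESHOLD_MIN + 3.0]
        if len(rural_nodes) >= want_nodes and max(
                (amb[n] for n in rural_nodes), default=0) > 110.0:
            break
        guard += 1
        if guard > 60:
            raise RegionGenerationError("could not grow a deep enough rural tail")
        reach = {n: minutes[n] for n in b.branch_nodes if n in minutes}
        if not reach:
            raise RegionGenerationError("no branch node reaches a hospital")
        tip = max(reach, key=lambda n: reach[n])
        b.extend_remote_branch(net, tip, minutes)
        amb = {n: DEFAULT_SPEED_FACTOR * m for n, m in minutes.items()}

    cells = _allocate_population(spec, b, net, amb, rng)

    # Reachability must partition the cells exactly.
    unreachable = [c for c in cells if c.node not in minutes]
    pop_reach = sum(c.population for c in cells if c.node in minutes)
    if pop_reach < 0.5 * spec.total_population:
        raise RegionGenerationError("hospitals disconnected from most of the population")
    for c in unreachable:
        c.node = None  # flagged: excluded from downstream denominators

    facilities = _make_facilities(spec, b, net, amb, cells, rng)
    return net, cells, facilities


def _allocate_population(spec, b, net, amb, rng) -> list[PopulationCell]:
    cs_km = spec.cell_size_m / 1000.0
    area = cs_km * cs_km
    cells: list[PopulationCell] = []
    cid = 0

    def add_cell(x, y, node, pop):
        nonlocal cid
        cells.append(PopulationCell(cid, (round(float(x), 4), round(float(y), 4)),
                                    int(pop), area, node))
        cid += 1

    n_towns = spec.n_towns
    town_pop_total = int(round(spec.total_population * spec.town_population_fraction))
    rural_pop_total = int(round(spec.total_population * spec.rural_tail_fraction))
    mid_pop_total = spec.total_population - town_pop_total - rural_pop_total

    # Town blocks: square patches of grid cells around each centre, population
    # Gaussian-peaked at the core.
    sizes = np.asarray([float(s) for s in np.sort(rng.pareto(1.2, n_towns) + 1.0)[::-1]])
    per_town = _apportion(town_pop_total, sizes)
    for t in range(n_towns):
        centre = b.town_centres[t]
        cx, cy = net.nodes[centre]
        side = int(np.clip(round(math.sqrt(per_town[t] / 400.0)), 2, 12))
        offs = (np.arange(side) - (side - 1) / 2.0) * cs_km
        xs, ys = np.meshgrid(cx + offs, cy + offs)
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        wts = np.exp(-d2 / (2 * (0.4 * side * cs_km) ** 2)).ravel()
        pops = _apportion(int(per_town[t]), wts)
        for (x, y, p) in zip(xs.ravel(), ys.ravel(), pops):
            add_cell(x, y, centre, p)

    # Rural tail: settlements on branch nodes beyond the threshold.
    rural_nodes = sorted(n for n in b.branch_nodes
                         if n in amb and amb[n] > RURAL_THRESHOLD_MIN + 3.0)
    if rural_pop_total > 0 and not rural_nodes:
        raise RegionGenerationError("no settlement sites beyond the rural threshold")
    if rural_nodes:
        # Settlement size thins out with remoteness beyond the threshold.
        depth = np.array([amb[n] - RURAL_THRESHOLD_MIN for n in rural_nodes])
        wts = rng.gamma(2.0, 1.0, len(rural_nodes)) * np.exp(-depth / 45.0)
        pops = _apportion(rural_pop_total, wts)
        for n, p in zip(rural_nodes, pops):
            x, y = net.nodes[n]
            add_cell(x, y, n, p)

    # Accessible countryside: branch/trunk nodes inside the threshold.
    mid_nodes = sorted(n for n in b.branch_nodes
                       if n in amb and amb[n] <= RURAL_THRESHOLD_MIN - 3.0)
    if not mid_nodes:
        mid_nodes = [b.town_centres[-1]]
    wts = rng.gamma(2.0, 1.0, len(mid_nodes))
    pops = _apportion(mid_pop_total, wts)
    for n, p in zip(mid_nodes, pops):
        x, y = net.nodes[n]
        add_cell(x, y, n, p)
    return cells


def _make_facilities(spec, b, net, amb, cells, rng) -> list[Facility]:
    facs: list[Facility] = []
    for i in range(spec.n_hospitals):
        node = b.town_centres[i]
        x, y = net.nodes[node]
        dtn = float(rng.integers(25, 41))
        kind = EVT if i < spec.n_evt_centres else HOSPITAL
        facs.append(Facility(
            facility_id=f"H{i:02d}", x=x, y=y, kind=kind,
            door_to_needle_min=dtn,
            door_in_door_out_min=dtn + 30.0,  # fixed 30-min needle-to-door-out
            door_to_groin_min=float(rng.integers(60, 91)) if kind == EVT else math.nan,
            node=node,
        ))
    # Candidate CT sites: public-building proxy, drawn near rural population mass.
    pop_at = {}
    for c in cells:
        if c.node is not None:
            pop_at[c.node] = pop_at.get(c.node, 0) + c.population
    cand_pool = sorted(n for n in set(b.branch_nodes)
                       if n in amb and amb[n] > 0.6 * RURAL_THRESHOLD_MIN)
    if len(cand_pool) < spec.n_candidate_sites:
        cand_pool = sorted(set(b.branch_nodes) & set(amb))
    k = min(spec.n_candidate_sites, len(cand_pool))
    wts = np.array([pop_at.get(n, 0) + 1.0 for n in cand_pool])
    chosen = rng.choice(len(cand_pool), size=k, replace=False, p=wts / wts.sum())
    for j, idx in enumerate(sorted(int(i) for i in chosen)):
        node = cand_pool[idx]
        x, y = net.nodes[node]
        facs.append(Facility(
            facility_id=f"C{j:02d}", x=x, y=y, kind=CANDIDATE,
            door_to_needle_min=30.0,       # telestroke-supervised thrombolysis
            door_in_door_out_min=50.0,     # rural CT station door-in-door-out
            door_to_groin_min=math.nan, node=node,
        ))
    return facs


# ---------------------------------------------------------------------------
# Deterministic plain-text writers / readers (GeoJSON + CSV dialect)
# ---------------------------------------------------------------------------

def _dump_geojson(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n"


def _rnd(v: float, p: int = 4) -> float:
    return round(float(v), p)


def network_to_geojson(net: RoadNetwork) -> dict:
    feats = []
    for e in net.edges:
        (x1, y1), (x2, y2) = net.nodes[e.u], net.nodes[e.v]
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[_rnd(x1), _rnd(y1)], [_rnd(x2), _rnd(y2)]]},
            "properties": {"u": e.u, "v": e.v, "length_m": _rnd(e.length_m, 1),
                           "speed_kmh": _rnd(e.speed_kmh, 1), "oneway": e.oneway,
                           "ferry": e.ferry, "crossing_min": _rnd(e.crossing_min, 2)},
        })
    return {"type": "FeatureCollection", "features": feats}


def cells_to_geojson(cells: list[PopulationCell]) -> dict:
    feats = []
    for c in cells:
        x, y = c.centroid
        h = math.sqrt(c.area_km2) / 2.0
        ring = [[_rnd(x - h), _rnd(y - h)], [_rnd(x + h), _rnd(y - h)],
                [_rnd(x + h), _rnd(y + h)], [_rnd(x - h), _rnd(y + h)],
                [_rnd(x - h), _rnd(y - h)]]
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"cell_id": c.cell_id, "population": c.population,
                           "area_km2": _rnd(c.area_km2, 6),
                           "node": c.node if c.node is not None else None},
        })
    return {"type": "FeatureCollection", "features": feats}


def write_region(outdir: str | Path, net: RoadNetwork, cells: list[PopulationCell],
                 facilities: list[Facility]) -> None:
    """Write ``network.geojson``, ``cells.geojson`` and ``facilities.csv``.

    Output is byte-identical for identical inputs (sorted keys, fixed
    rounding, ``\\n`` newlines).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "network.geojson").write_text(_dump_geojson(network_to_geojson(net)))
    (out / "cells.geojson").write_text(_dump_geojson(cells_to_geojson(cells)))
    buf = io.StringIO()
    wtr = csv.writer(buf, lineterminator="\n")
    wtr.writerow(["id", "x", "y", "kind", "door_to_needle_min",
                  "door_in_door_out_min", "door_to_groin_min", "node"])
    for f in facilities:
        wtr.writerow([f.facility_id, _rnd(f.x), _rnd(f.y), f.kind,
                      _rnd(f.door_to_needle_min, 1), _rnd(f.door_in_door_out_min, 1),
                      "" if math.isnan(f.door_to_groin_min) else _rnd(f.door_to_groin_min, 1),
                      "" if f.node is None else f.node])
    (out / "facilities.csv").write_text(buf.getvalue())


def read_region(indir: str | Path) -> tuple[RoadNetwork, list[PopulationCell], list[Facility]]:
    """Read a region directory written by :func:`write_region` (or the same dialect)."""
    indir = Path(indir)
    netj = json.loads((indir / "network.geojson").read_text())
    nodes: dict[int, tuple[float, float]] = {}
    edges: list[Edge] = []
    for ft in netj["features"]:
        p = ft["properties"]
        (x1, y1), (x2, y2) = ft["geometry"]["coordinates"][0], ft["geometry"]["coordinates"][-1]
        nodes.setdefault(int(p["u"]), (x1, y1))
        nodes.setdefault(int(p["v"]), (x2, y2))
        edges.append(Edge(int(p["u"]), int(p["v"]), float(p["length_m"]),
                          float(p["speed_kmh"]), oneway=bool(p["oneway"]),
                          ferry=bool(p["ferry"]), crossing_min=float(p["crossing_min"])))
    net = RoadNetwork(nodes=nodes, edges=edges)
    cellj = json.loads((indir / "cells.geojson").read_text())
    cells = []
    for ft in cellj["features"]:
        p = ft["properties"]
        ring = ft["geometry"]["coordinates"][0]
        cx = (ring[0][0] + ring[2][0]) / 2.0
        cy = (ring[0][1] + ring[2][1]) / 2.0
        cells.append(PopulationCell(int(p["cell_id"]), (cx, cy), int(p["population"]),
                                    float(p["area_km2"]),
                                    None if p["node"] is None else int(p["node"])))
    facs = []
    with open(indir / "facilities.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            facs.append(Facility(
                row["id"], float(row["x"]), float(row["y"]), row["kind"],
                float(row["door_to_needle_min"]), float(row["door_in_door_out_min"]),
                float(row["door_to_groin_min"]) if row["door_to_groin_min"] else math.nan,
                int(row["node"]) if row["node"] else None))
    return net, cells, facs
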