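import math

import numpy as np
import pytest

from ruralct.core import Edge, Facility, PopulationCell, RoadNetwork


def make_network(coords, edge_specs):
    """Build a RoadNetwork from {id: (x,y)} and (u, v, length_m, speed, kw...) tuples."""
    edges = []
    for spec in edge_specs:
        u, v, length_m, speed = spec[:4]
        kw = spec[4] if len(spec) > 4 else {}
        edges.append(Edge(u, v, length_m, speed, **kw))
    return RoadNetwork(nodes=dict(coords), edges=edges)


def line_network(n_nodes=5, spacing_km=10.0, speed=60.0):
    """Nodes 0..n-1 on a line, bidirectional edges at a single speed."""
    coords = {i: (i * spacing_km, 0.0) for i in range(n_nodes)}
    edges = [(i, i + 1, spacing_km * 1000.0, speed) for i in range(n_nodes - 1)]
    return make_network(coords, edges)


def cell_at(cid, node, net, population=100, area=0.0625):
    x, y = net.nodes[node]
    return PopulationCell(cid, (x, y), population, area, node)


def hospital(fid, node, net, dtn=30.0, evt=False, dtg=75.0):
    x, y = net.nodes[node]
    return Facility(fid, x, y, "evt" if evt else "hospital",
                    door_to_needle_min=dtn, door_in_door_out_min=dtn + 30.0,
                    door_to_groin_min=dtg if evt else math.nan, node=node)


def ct_site(fid, node, net, kind="candidate"):
    x, y = net.nodes[node]
    return Facility(fid, x, y, kind, door_to_needle_min=30.0,
                    door_in_door_out_min=50.0, node=node)


def random_digraph(rng, n_max=8):
    """A random strongly-sparse digraph as a RoadNetwork (may be disconnected)."""
    n = int(rng.integers(2, n_max + 1))
    coords = {i: (float(rng.uniform(0, 50)), float(rng.uniform(0, 50)))
              for i in range(n)}
    edges = []
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < 0.35:
                edges.append((u, v, float(rng.uniform(500, 20000)),
                              float(rng.choice([30.0, 50.0, 60.0, 90.0])),
                              {"oneway": True}))
    if not edges:
        edges = [(0, 1, 1000.0, 60.0, {"oneway": True})]
    return make_network(coords, edges)


def exhaustive_driving_minutes(net, origin, destination):
    """Brute-force shortest time over all simple paths (independent oracle)."""
    if origin == destination:
        return 0.0
    adj = {}
    for e in net.edges:
        adj.setdefault(e.u, []).append((e.v, e.minutes))
        if not e.oneway:
            adj.setdefault(e.v, []).append((e.u, e.minutes))
    best = math.inf

    def walk(node, seen, t):
        nonlocal best
        if t >= best:
            return
        if node == destination:
            best = t
            return
        for nxt, m in adj.get(node, []):
            if nxt not in seen:
                walk(nxt, seen | {nxt}, t + m)

    walk(origin, {origin}, 0.0)
    return best


@pytest.fixture(scope="session")
def small_region():
    """A small seeded synthetic region shared by read-only tests."""
    from ruralct.region import RegionSpec, generate_region

    spec = RegionSpec(n_towns=4, n_hospitals=2, n_evt_centres=1,
                      n_candidate_sites=12, total_population=50_000, seed=42)
    return generate_region(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
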