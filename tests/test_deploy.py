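"""Location-allocation: rural subgroup, greedy and exact deployment."""

import itertools
import math

import numpy as np
import pytest

from ruralct.deploy import (
    DeploymentConfig,
    apply_deployment,
    exact_deploy,
    greedy_deploy,
    rural_subgroup,
)
from ruralct.traveltime import TravelTimeField, closest_facility_field, minutes_to_node

from conftest import cell_at, ct_site, hospital, line_network, make_network, random_digraph


def _field(cells, minutes, speed_factor=0.8):
    return TravelTimeField(
        minutes={c.cell_id: m for c, m in zip(cells, minutes)},
        facility={c.cell_id: "H0" for c in cells},
        speed_factor=speed_factor,
    )


class TestRuralSubgroup:
    def test_strict_threshold(self):
        net = line_network(4)
        cells = [cell_at(i, i, net) for i in range(3)]
        fld = _field(cells, [60.0, 71.0, 90.0])
        assert [c.cell_id for c in rural_subgroup(fld, cells, 70.0)] == [1, 2]

    def test_all_within_threshold_gives_empty_subgroup(self):
        net = line_network(3)
        cells = [cell_at(i, i, net) for i in range(3)]
        fld = _field(cells, [10.0, 20.0, 30.0])
        assert rural_subgroup(fld, cells, 70.0) == []

    def test_unreachable_cells_not_in_subgroup(self):
        net = line_network(3)
        cells = [cell_at(0, 0, net), cell_at(1, 1, net)]
        fld = _field(cells, [math.inf, 100.0])
        assert [c.cell_id for c in rural_subgroup(fld, cells, 70.0)] == [1]


def _brute_force_objective(net, candidates, cells, fld, subset):
    """Independent recomputation: per-cell best of baseline vs chosen sites."""
    total = 0.0
    for c in cells:
        base = fld.minutes[c.cell_id]
        best = base
        for f in candidates:
            if f.facility_id in subset:
                d = minutes_to_node(net, f.node).get(c.node, math.inf)
                best = min(best, fld.speed_factor * d)
        total += c.population * (base - best)
    return total


class TestGreedy:
    def test_dominant_population_attracts_the_station(self):
        # cells at nodes 1, 5, 6 (pop 100/10/10); hospital at 0 far away;
        # candidate A adjacent to the pop-100 cell, candidate B near the others.
        net = line_network(8, spacing_km=20.0, speed=60.0)
        cells = [cell_at(0, 1, net, population=100),
                 cell_at(1, 5, net, population=10),
                 cell_at(2, 6, net, population=10)]
        hosp = [hospital("H0", 0, net)]
        fld = closest_facility_field(net, cells, hosp, 0.8)
        cands = [ct_site("A", 1, net), ct_site("B", 6, net)]
        res = greedy_deploy(net, cands, cells, fld, DeploymentConfig(k=1))
        assert res.chosen_sites == ["A"]

    def test_k_equal_to_all_candidates_is_exhaustion(self, small_region):
        net, cells, facs = small_region
        hosp = [f for f in facs if f.is_hospital]
        cands = [f for f in facs if f.kind == "candidate"]
        fld = closest_facility_field(net, cells, hosp)
        rural = rural_subgroup(fld, cells)
        res = greedy_deploy(net, cands, rural, fld, DeploymentConfig(k=len(cands)))
        assert sorted(res.chosen_sites) == sorted(f.facility_id for f in cands)

    def test_k_beyond_candidates_warns_and_deploys_all(self, small_region):
        net, cells, facs = small_region
        hosp = [f for f in facs if f.is_hospital]
        cands = [f for f in facs if f.kind == "candidate"][:3]
        fld = closest_facility_field(net, cells, hosp)
        rural = rural_subgroup(fld, cells)
        with pytest.warns(UserWarning):
            res = greedy_deploy(net, cands, rural, fld, DeploymentConfig(k=10))
        assert len(res.chosen_sites) == 3

    def test_stations_never_worsen_access(self, small_region):
        net, cells, facs = small_region
        hosp = [f for f in facs if f.is_hospital]
        cands = [f for f in facs if f.kind == "candidate"]
        fld = closest_facility_field(net, cells, hosp)
        rural = rural_subgroup(fld, cells)
        res = greedy_deploy(net, cands, rural, fld, DeploymentConfig(k=4))
        for c in rural:
            assert res.per_cell_new_minutes[c.cell_id] <= fld.minutes[c.cell_id] + 1e-9
        new_fld = apply_deployment(fld, res)
        for cid, m in fld.minutes.items():
            assert new_fld.minutes[cid] <= m + 1e-9

    def test_objective_monotone_in_k(self, small_region):
        net, cells, facs = small_region
        hosp = [f for f in facs if f.is_hospital]
        cands = [f for f in facs if f.kind == "candidate"]
        fld = closest_facility_field(net, cells, hosp)
        rural = rural_subgroup(fld, cells)
        vals = [greedy_deploy(net, cands, rural, fld,
                              DeploymentConfig(k=k)).objective_value
                for k in (1, 2, 4, 8)]
        assert vals == sorted(vals)

    def test_doubling_a_population_never_hurts_that_cell(self, small_region):
        net, cells, facs = small_region
        hosp = [f for f in facs if f.is_hospital]
        cands = [f for f in facs if f.kind == "candidate"]
        fld = closest_facility_field(net, cells, hosp)
        rural = rural_subgroup(fld, cells)
        target = max(rural, key=lambda c: fld.minutes[c.cell_id])
        res1 = greedy_deploy(net, cands, rural, fld, DeploymentConfig(k=2))
        boosted = [c if c is not target else
                   cell_at(c.cell_id, c.node, net, population=2 * c.population)
                   for c in rural]
        res2 = greedy_deploy(net, cands, boosted, fld, DeploymentConfig(k=2))
        assert res2.per_cell_new_minutes[target.cell_id] <= \
            res1.per_cell_new_minutes[target.cell_id] + 1e-9


class TestExact:
    def _instance(self, rng, n_cand=6, n_cells=8):
        net = random_digraph(rng, n_max=8)
        ids = sorted(net.nodes)
        cells = [cell_at(i, int(rng.choice(ids)), net,
                         population=int(rng.integers(1, 200)))
                 for i in range(n_cells)]
        cands = [ct_site(f"C{j}", int(rng.choice(ids)), net) for j in range(n_cand)]
        minutes = [float(rng.uniform(71, 200)) for _ in cells]
        return net, cells, cands, _field(cells, minutes)

    def test_single_candidate_identity(self, rng):
        net, cells, cands, fld = self._instance(rng, n_cand=1)
        res = exact_deploy(net, cands, cells, fld, DeploymentConfig(k=1))
        assert res.chosen_sites == ["C0"]

    def test_tied_subsets_resolve_lexicographically(self):
        # two candidates at the same node: identical objective, C0 must win
        net = line_network(4, spacing_km=30.0)
        cells = [cell_at(0, 3, net, population=50)]
        fld = _field(cells, [100.0])
        cands = [ct_site("C1", 3, net), ct_site("C0", 3, net)]
        res = exact_deploy(net, cands, cells, fld, DeploymentConfig(k=1))
        assert res.chosen_sites == ["C0"]

    def test_cap_exceeded_is_an_error(self, rng):
        net, cells, cands, fld = self._instance(rng, n_cand=6)
        with pytest.raises(ValueError, match="greedy_deploy"):
            exact_deploy(net, cands, cells, fld,
                         DeploymentConfig(k=3, enumeration_cap=2))

    def test_matches_independent_brute_force(self, rng):
        for _ in range(10):
            net, cells, cands, fld = self._instance(rng, n_cand=6)
            cfg = DeploymentConfig(k=2)
            res = exact_deploy(net, cands, cells, fld, cfg)
            best_val, best_sub = -1.0, None
            for sub in itertools.combinations(
                    sorted(f.facility_id for f in cands), 2):
                v = _brute_force_objective(net, cands, cells, fld, set(sub))
                if v > best_val:
                    best_val, best_sub = v, sub
            assert res.objective_value == pytest.approx(best_val)
            assert _brute_force_objective(
                net, cands, cells, fld, set(res.chosen_sites)) == pytest.approx(best_val)

    def test_greedy_within_submodular_bound_of_exact(self, rng):
        bound = 1.0 - 1.0 / math.e
        for _ in range(10):
            net, cells, cands, fld = self._instance(rng, n_cand=6)
            cfg = DeploymentConfig(k=2)
            g = greedy_deploy(net, cands, cells, fld, cfg)
            e = exact_deploy(net, cands, cells, fld, cfg)
            assert g.objective_value >= bound * e.objective_value - 1e-9
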