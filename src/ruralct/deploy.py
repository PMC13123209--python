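"""Location-allocation of rural CT stations.

Chooses k station sites from the candidate pool to maximise the
population-weighted reduction of ambulance transport time among cells
whose baseline time to the nearest hospital exceeds the rurality
threshold (70 min). A station only serves cells for which it beats the
incumbent option; no cell is ever reassigned to a slower route.

The default objective (total minutes saved, population weighted) is
monotone submodular, so greedy forward selection carries the classical
(1 − 1/e) guarantee; :func:`exact_deploy` enumerates subsets and serves
as the small-instance oracle.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Facility, PopulationCell, RoadNetwork
from .traveltime import TravelTimeField, minutes_to_node, snap_facilities

MAX_TIME_REDUCTION = "max_time_reduction"
MAX_COVERAGE = "max_coverage_within_threshold"


@dataclass(frozen=True)
class DeploymentConfig:
    k: int
    rural_threshold_min: float = 70.0
    objective: str = MAX_TIME_REDUCTION
    enumeration_cap: int = 200_000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.rural_threshold_min <= 0:
            raise ValueError("rural_threshold_min must be > 0")
        if self.objective not in (MAX_TIME_REDUCTION, MAX_COVERAGE):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class DeploymentResult:
    chosen_sites: list[str]
    per_cell_new_minutes: dict[int, float]
    objective_value: float
    summary: dict[str, float] = field(default_factory=dict)


def rural_subgroup(
    field_: TravelTimeField, cells: list[PopulationCell], threshold: float = 70.0
) -> list[PopulationCell]:
    """Cells with baseline ambulance minutes strictly above ``threshold``.

    Unreachable cells are excluded (they have no baseline time, mirroring
    the exclusion of residents without road access).
    """
    return [
        c for c in cells
        if not field_.is_unreachable(c.cell_id) and field_.minutes[c.cell_id] > threshold
    ]


def _candidate_minutes(
    network: RoadNetwork,
    candidates: list[Facility],
    cells: list[PopulationCell],
    speed_factor: float,
) -> dict[str, np.ndarray]:
    """Ambulance minutes from each rural cell to each candidate site."""
    snap_facilities(network, candidates)
    out = {}
    for f in sorted(candidates, key=lambda f: f.facility_id):
        dist = minutes_to_node(network, f.node)
        out[f.facility_id] = np.array(
            [speed_factor * dist.get(c.node, math.inf) for c in cells]
        )
    return out


def _weighted_quantiles(values, weights, qs=(0.25, 0.5, 0.75)):
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights, dtype=float)[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        return [math.nan] * len(qs)
    return [float(v[np.searchsorted(cw, q * cw[-1])]) for q in qs]


class _Instance:
    """Precomputed objective machinery shared by greedy and exact search."""

    def __init__(self, network, candidates, rural_cells, field_, config):
        if not candidates:
            raise ValueError("candidates must be non-empty")
        self.config = config
        self.cells = rural_cells
        self.pop = np.array([c.population for c in rural_cells], dtype=float)
        self.base = np.array([field_.minutes[c.cell_id] for c in rural_cells])
        self.cand_ids = sorted(f.facility_id for f in candidates)
        cm = _candidate_minutes(network, candidates, rural_cells, field_.speed_factor)
        self.cand_min = {fid: cm[fid] for fid in self.cand_ids}

    def new_minutes(self, chosen: tuple[str, ...]) -> np.ndarray:
        cur = self.base.copy()
        for fid in chosen:
            cur = np.minimum(cur, self.cand_min[fid])
        return cur

    def value(self, chosen: tuple[str, ...]) -> float:
        cur = self.new_minutes(chosen)
        if self.config.objective == MAX_TIME_REDUCTION:
            return float(np.sum(self.pop * (self.base - cur)))
        covered = cur <= self.config.rural_threshold_min
        return float(np.sum(self.pop[covered]))

    def result(self, chosen: list[str], field_: TravelTimeField) -> DeploymentResult:
        cur = self.new_minutes(tuple(chosen))
        before_q = _weighted_quantiles(self.base, self.pop)
        after_q = _weighted_quantiles(cur, self.pop)
        summary = {
            "rural_population": float(self.pop.sum()),
            "median_before": before_q[1], "iqr_before": (before_q[0], before_q[2]),
            "median_after": after_q[1], "iqr_after": (after_q[0], after_q[2]),
            "total_minutes_saved_weighted": float(np.sum(self.pop * (self.base - cur))),
        }
        per_cell = {c.cell_id: float(m) for c, m in zip(self.cells, cur)}
        return DeploymentResult(list(chosen), per_cell, self.value(tuple(chosen)), summary)


def greedy_deploy(
    network: RoadNetwork,
    candidates: list[Facility],
    rural_cells: list[PopulationCell],
    field_: TravelTimeField,
    config: DeploymentConfig,
) -> DeploymentResult:
    """Greedy forward selection of k station sites (ties: lowest id)."""
    inst = _Instance(network, candidates, rural_cells, field_, config)
    k = config.k
    if k > len(inst.cand_ids):
        warnings.warn(
            f"k={k} exceeds the {len(inst.cand_ids)} candidates; deploying all",
            stacklevel=2,
        )
        k = len(inst.cand_ids)
    chosen: list[str] = []
    cur_val = 0.0
    for _ in range(k):
        best_fid, best_val = None, -math.inf
        for fid in inst.cand_ids:  # sorted: lowest id wins ties via strict >
            if fid in chosen:
                continue
            val = inst.value(tuple(chosen) + (fid,))
            if val > best_val:
                best_fid, best_val = fid, val
        chosen.append(best_fid)
        cur_val = best_val
    return inst.result(chosen, field_)


def exact_deploy(
    network: RoadNetwork,
    candidates: list[Facility],
    rural_cells: list[PopulationCell],
    field_: TravelTimeField,
    config: DeploymentConfig,
) -> DeploymentResult:
    """Exhaustive optimum over all C(n, k) candidate subsets.

    Ties broken lexicographically. Refuses instances whose subset count
    exceeds ``config.enumeration_cap``.
    """
    inst = _Instance(network, candidates, rural_cells, field_, config)
    n, k = len(inst.cand_ids), min(config.k, len(inst.cand_ids))
    if math.comb(n, k) > config.enumeration_cap:
        raise ValueError(
            f"C({n},{k}) exceeds the enumeration cap "
            f"({config.enumeration_cap}); use greedy_deploy"
        )
    best_subset, best_val = None, -math.inf
    for subset in itertools.combinations(inst.cand_ids, k):  # lexicographic order
        val = inst.value(subset)
        if val > best_val:  # strict: first (lexicographically smaller) kept on ties
            best_subset, best_val = subset, val
    return inst.result(list(best_subset), field_)


def apply_deployment(
    field_: TravelTimeField, result: DeploymentResult
) -> TravelTimeField:
    """Travel-time field after deployment: per-cell min of baseline and new."""
    minutes = dict(field_.minutes)
    facility = dict(field_.facility)
    for cid, m in result.per_cell_new_minutes.items():
        if m < minutes[cid]:
            minutes[cid] = m
    return TravelTimeField(minutes=minutes, facility=facility,
                           speed_factor=field_.speed_factor)
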