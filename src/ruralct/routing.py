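"""Mothership vs drip-and-ship transport strategy maps for suspected LVO.

For a FAST+ patient in a given cell the two strategies are:

- **mothership** — drive directly to the nearest EVT centre;
- **drip-and-ship** — drive to a nearer thrombolysis-capable site
  (hospital or rural CT station) for the needle, then transfer to the
  EVT centre for the groin puncture.

Each cell is labelled with the strategy maximising the expected
probability of good outcome over the FAST+ case mix (14.5% LVO, 31%
non-LVO ischemic, remainder unaffected by routing). The published
transport-model outcome equations are proprietary; here the thrombolysis
curve is derived from the Emberson odds-ratio relation around a
configurable untreated baseline and the EVT curve is a configurable
monotone linear decay — the decision surface depends only on these
monotone relative comparisons, and none of the constants claim to be the
proprietary originals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Facility, PopulationCell, RoadNetwork
from .simulate import TimeComponentModel, emberson_or
from .traveltime import TravelTimeField, minutes_to_node, snap_facilities

MOTHERSHIP = "mothership"
DRIPSHIP_HOSPITAL = "dripship_hospital"
DRIPSHIP_CT = "dripship_ct"
NEAR_EQUIVALENT = "near_equivalent"
EXCLUDED = "excluded"

#: Preference at exact score ties: fewer handovers first.
_TIE_ORDER = {MOTHERSHIP: 0, DRIPSHIP_HOSPITAL: 1, DRIPSHIP_CT: 2}


@dataclass(frozen=True)
class CaseMix:
    """Composition of the FAST+ prehospital population."""

    f_lvo: float = 0.145
    f_nonlvo_ischemic: float = 0.31

    def __post_init__(self) -> None:
        if not (0 <= self.f_lvo <= 1 and 0 <= self.f_nonlvo_ischemic <= 1):
            raise ValueError("case-mix fractions must lie in [0, 1]")
        if self.f_lvo + self.f_nonlvo_ischemic > 1 + 1e-12:
            raise ValueError("case-mix fractions exceed 1")

    @property
    def f_other(self) -> float:
        return 1.0 - self.f_lvo - self.f_nonlvo_ischemic


@dataclass(frozen=True)
class OutcomeCurves:
    """Good-outcome probability curves for thrombolysis and EVT.

    ``p_good_tpa`` converts the Emberson OR at the needle time into a
    probability via the odds transform around the untreated baseline
    ``p0``. ``p_good_evt`` decays linearly from ``evt_p_max`` (at or
    before ``evt_t_min`` minutes to groin) to ``evt_p_floor`` at the
    ``groin_window_min`` limit. Outside the treatment windows both curves
    return the untreated baseline. ``prior_tpa_bonus`` is an additive
    probability bonus on the EVT outcome when thrombolysis was given
    first (drip-and-ship); its default is 0 (no claimed synergy).
    """

    p0: float = 0.30
    needle_window_min: float = 270.0
    groin_window_min: float = 360.0
    evt_p_max: float = 0.70
    evt_t_min: float = 60.0
    evt_p_floor: float = 0.30
    prior_tpa_bonus: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie in (0, 1)")
        if not self.evt_p_max >= self.evt_p_floor:
            raise ValueError("EVT curve must be non-increasing")
        if not self.evt_t_min < self.groin_window_min:
            raise ValueError("evt_t_min must precede the groin window limit")

    def p_good_tpa(self, t_needle_min: float) -> float:
        if not math.isfinite(t_needle_min) or t_needle_min > self.needle_window_min:
            return self.p0
        odds0 = self.p0 / (1.0 - self.p0)
        odds = odds0 * emberson_or(max(t_needle_min, 1e-9) / 60.0)
        return min(1.0, max(0.0, odds / (1.0 + odds)))

    def p_good_evt(self, t_groin_min: float, prior_tpa: bool = False) -> float:
        if not math.isfinite(t_groin_min) or t_groin_min > self.groin_window_min:
            return self.p0
        t = max(t_groin_min, self.evt_t_min)
        frac = (t - self.evt_t_min) / (self.groin_window_min - self.evt_t_min)
        p = self.evt_p_max - frac * (self.evt_p_max - self.evt_p_floor)
        if prior_tpa:
            p += self.prior_tpa_bonus
        return min(1.0, max(0.0, p))


@dataclass(frozen=True)
class StrategyTimes:
    """Needle and groin times (minutes from onset) for one routing option."""

    label: str            # mothership / dripship_hospital / dripship_ct
    via: str | None       # drip site facility id (None for mothership)
    evt_centre: str
    t_needle_min: float
    t_groin_min: float
    prior_tpa: bool


@dataclass
class StrategyMap:
    """Per-cell strategy labels with km² aggregates."""

    labels: dict[int, str]
    delta_p: dict[int, float]
    area_km2: dict[str, float]
    best_option: dict[int, StrategyTimes | None]

    def total_included_area(self) -> float:
        return sum(a for lbl, a in self.area_km2.items() if lbl != EXCLUDED)


def _site_dido(site: Facility) -> float:
    """Door-in-door-out minutes when the site is an intermediate stop."""
    return site.door_in_door_out_min


def strategy_times(
    cell: PopulationCell,
    facilities: list[Facility],
    network: RoadNetwork,
    tcm: TimeComponentModel,
    speed_factor: float = 0.8,
) -> list[StrategyTimes]:
    """All routing options for one cell (convenience wrapper for small cases)."""
    evt_centres = [f for f in facilities if f.is_evt_centre]
    if not evt_centres:
        raise ValueError("at least one EVT centre is required")
    snap_facilities(network, facilities)
    sites = [f for f in facilities if f.offers_thrombolysis]
    to_node = {f.facility_id: minutes_to_node(network, f.node) for f in facilities}
    pre = tcm.prehospital_median_min()

    def amb(dist_map, node):
        d = dist_map.get(node, math.inf)
        return speed_factor * d

    out = []
    # mothership: direct to the nearest EVT centre
    best = min(
        evt_centres,
        key=lambda e: (amb(to_node[e.facility_id], cell.node), e.facility_id),
    )
    arrive = pre + amb(to_node[best.facility_id], cell.node)
    out.append(StrategyTimes(MOTHERSHIP, None, best.facility_id,
                             arrive + best.door_to_needle_min,
                             arrive + best.door_to_groin_min, prior_tpa=False))
    for s in sites:
        arrive_s = pre + amb(to_node[s.facility_id], cell.node)
        # transfer from the drip site to its best EVT centre
        evt, t_evt = None, math.inf
        for e in sorted(evt_centres, key=lambda e: e.facility_id):
            t = speed_factor * to_node[e.facility_id].get(s.node, math.inf)
            if t < t_evt:
                evt, t_evt = e, t
        label = DRIPSHIP_CT if s.kind == "ct" else DRIPSHIP_HOSPITAL
        out.append(StrategyTimes(
            label, s.facility_id, evt.facility_id,
            arrive_s + s.door_to_needle_min,
            arrive_s + _site_dido(s) + t_evt + evt.door_to_groin_min,
            prior_tpa=True))
    return out


def expected_p_good(times: StrategyTimes, mix: CaseMix, curves: OutcomeCurves,
                    c_other: float = 0.0) -> float:
    """Expected probability of good outcome over the FAST+ case mix.

    The non-stroke/haemorrhage remainder contributes a routing-independent
    constant ``c_other`` (default 0); it cancels between strategies.
    """
    return (
        mix.f_lvo * curves.p_good_evt(times.t_groin_min, prior_tpa=times.prior_tpa)
        + mix.f_nonlvo_ischemic * curves.p_good_tpa(times.t_needle_min)
        + mix.f_other * c_other
    )


def classify_region(
    cells: list[PopulationCell],
    facilities: list[Facility],
    network: RoadNetwork,
    mix: CaseMix | None = None,
    curves: OutcomeCurves | None = None,
    epsilon: float = 0.01,
    tcm: TimeComponentModel | None = None,
    speed_factor: float = 0.8,
) -> StrategyMap:
    """Label every cell with its best transport strategy.

    A cell is ``near_equivalent`` when the best and second-best strategy
    *classes* differ by less than ``epsilon`` in expected probability;
    cells with no finite route to any EVT centre are ``excluded``.
    """
    mix = mix or CaseMix()
    curves = curves or OutcomeCurves()
    tcm = tcm or TimeComponentModel()
    evt_centres = sorted((f for f in facilities if f.is_evt_centre),
                         key=lambda f: f.facility_id)
    if not evt_centres:
        raise ValueError("at least one EVT centre is required")
    snap_facilities(network, facilities)
    sites = sorted((f for f in facilities if f.offers_thrombolysis),
                   key=lambda f: f.facility_id)
    pre = tcm.prehospital_median_min()

    # One reverse Dijkstra per facility covers every cell and transfer leg.
    dist = {f.facility_id: minutes_to_node(network, f.node)
            for f in {id(x): x for x in (sites + evt_centres)}.values()}

    # Transfer leg (site -> best EVT centre) is cell-independent.
    transfer: dict[str, tuple[Facility, float]] = {}
    for s in sites:
        evt, t_evt = None, math.inf
        for e in evt_centres:
            t = speed_factor * dist[e.facility_id].get(s.node, math.inf)
            if t < t_evt:
                evt, t_evt = e, t
        transfer[s.facility_id] = (evt, t_evt)

    labels: dict[int, str] = {}
    delta_p: dict[int, float] = {}
    best_opt: dict[int, StrategyTimes | None] = {}
    area: dict[str, float] = {}

    for cell in cells:
        options: list[StrategyTimes] = []
        if cell.node is not None:
            evt_best, evt_t = None, math.inf
            for e in evt_centres:
                t = speed_factor * dist[e.facility_id].get(cell.node, math.inf)
                if t < evt_t:
                    evt_best, evt_t = e, t
            if math.isfinite(evt_t):
                arrive = pre + evt_t
                options.append(StrategyTimes(
                    MOTHERSHIP, None, evt_best.facility_id,
                    arrive + evt_best.door_to_needle_min,
                    arrive + evt_best.door_to_groin_min, prior_tpa=False))
                for s in sites:
                    t_s = speed_factor * dist[s.facility_id].get(cell.node, math.inf)
                    evt, t_evt = transfer[s.facility_id]
                    if not (math.isfinite(t_s) and math.isfinite(t_evt)):
                        continue
                    arrive_s = pre + t_s
                    lbl = DRIPSHIP_CT if s.kind == "ct" else DRIPSHIP_HOSPITAL
                    options.append(StrategyTimes(
                        lbl, s.facility_id, evt.facility_id,
                        arrive_s + s.door_to_needle_min,
                        arrive_s + _site_dido(s) + t_evt + evt.door_to_groin_min,
                        prior_tpa=True))
        if not options:
            labels[cell.cell_id] = EXCLUDED
            delta_p[cell.cell_id] = math.nan
            best_opt[cell.cell_id] = None
            area[EXCLUDED] = area.get(EXCLUDED, 0.0) + cell.area_km2
            continue

        # Best option per strategy class, then compare the top two classes.
        per_class: dict[str, tuple[float, StrategyTimes]] = {}
        for opt in options:
            score = expected_p_good(opt, mix, curves)
            cur = per_class.get(opt.label)
            if cur is None or score > cur[0]:
                per_class[opt.label] = (score, opt)
        ranked = sorted(per_class.items(),
                        key=lambda kv: (-kv[1][0], _TIE_ORDER[kv[0]]))
        best_lbl, (best_score, best_times) = ranked[0]
        margin = best_score - ranked[1][1][0] if len(ranked) > 1 else math.inf
        label = NEAR_EQUIVALENT if margin < epsilon else best_lbl
        labels[cell.cell_id] = label
        delta_p[cell.cell_id] = margin if math.isfinite(margin) else 0.0
        best_opt[cell.cell_id] = best_times
        area[label] = area.get(label, 0.0) + cell.area_km2

    return StrategyMap(labels=labels, delta_p=delta_p, area_km2=area,
                       best_option=best_opt)


def strategy_map_geojson(smap: StrategyMap, cells: list[PopulationCell]) -> dict:
    """Cell polygons with strategy label and decision margin (GeoJSON dict)."""
    feats = []
    for c in cells:
        x, y = c.centroid
        h = math.sqrt(c.area_km2) / 2.0
        ring = [[round(x - h, 4), round(y - h, 4)], [round(x + h, 4), round(y - h, 4)],
                [round(x + h, 4), round(y + h, 4)], [round(x - h, 4), round(y + h, 4)],
                [round(x - h, 4), round(y - h, 4)]]
        dp = smap.delta_p[c.cell_id]
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"cell_id": c.cell_id,
                           "label": smap.labels[c.cell_id],
                           "delta_p": None if math.isnan(dp) else round(dp, 6)},
        })
    return {"type": "FeatureCollection", "features": feats}


def strategy_area_report(baseline: StrategyMap, deployed: StrategyMap) -> dict:
    """km² per label before/after plus drip-and-ship and mothership changes."""
    from .report import percent_change

    labels = sorted(set(baseline.area_km2) | set(deployed.area_km2))
    rows = {lbl: {"before_km2": baseline.area_km2.get(lbl, 0.0),
                  "after_km2": deployed.area_km2.get(lbl, 0.0)} for lbl in labels}
    drip_b = sum(baseline.area_km2.get(l, 0.0) for l in (DRIPSHIP_HOSPITAL, DRIPSHIP_CT))
    drip_a = sum(deployed.area_km2.get(l, 0.0) for l in (DRIPSHIP_HOSPITAL, DRIPSHIP_CT))
    moth_b = baseline.area_km2.get(MOTHERSHIP, 0.0)
    moth_a = deployed.area_km2.get(MOTHERSHIP, 0.0)
    out = {"per_label": rows,
           "dripship_before_km2": drip_b, "dripship_after_km2": drip_a,
           "mothership_before_km2": moth_b, "mothership_after_km2": moth_a}
    if drip_b > 0:
        out["dripship_percent_change"] = percent_change(drip_b, drip_a)
    if moth_b > 0:
        out["mothership_percent_change"] = percent_change(moth_b, moth_a)
    return out
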