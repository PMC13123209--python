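"""Pipeline orchestration and headline summary reporting.

Runs generate → travel time → deployment → cohort simulation → LVO
strategy maps, and writes machine- (JSON) and human-readable (Markdown)
reports whose printed percents are always recomputed from their own
counts (half-away-from-zero integer rounding).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import deploy as dep
from . import routing as rt
from .core import CT_STATION, Facility
from .region import RegionSpec, generate_region, write_region
from .simulate import (
    CohortConfig,
    CohortResult,
    TimeComponentModel,
    compare_scenarios,
    sample_cohort,
)
from .traveltime import closest_facility_field

log = logging.getLogger("ruralct")


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent_of(count: float, total: float) -> int:
    """``round(100 × count/total)`` to nearest integer, half away from zero."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    return _round_half_away(100.0 * count / total)


def percent_change(before: float, after: float) -> int:
    """Signed integer percent change from ``before`` to ``after``.

    Magnitude is ``round(100 × |after − before| / before)`` half away from
    zero; the sign is that of ``after − before``.
    """
    if before <= 0:
        raise ValueError("before must be > 0")
    mag = _round_half_away(100.0 * abs(after - before) / before)
    return mag if after >= before else -mag


@dataclass
class RunConfig:
    region: RegionSpec = field(default_factory=RegionSpec)
    k_list: tuple[int, ...] = (10, 20, 30)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    time_components: TimeComponentModel = field(default_factory=TimeComponentModel)
    case_mix: rt.CaseMix = field(default_factory=rt.CaseMix)
    curves: rt.OutcomeCurves = field(default_factory=rt.OutcomeCurves)
    speed_factor: float = 0.8
    rural_threshold_min: float = 70.0
    epsilon: float = 0.01
    seed: int = 0
    outdir: str = "runs/out"

    def __post_init__(self) -> None:
        if list(self.k_list) != sorted(set(self.k_list)):
            raise ValueError("k_list must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "region" in raw:
            kw["region"] = RegionSpec(**raw["region"])
        if "cohort" in raw:
            kw["cohort"] = CohortConfig(**raw["cohort"])
        if "case_mix" in raw:
            kw["case_mix"] = rt.CaseMix(**raw["case_mix"])
        if "curves" in raw:
            kw["curves"] = rt.OutcomeCurves(**raw["curves"])
        for key in ("k_list", "speed_factor", "rural_threshold_min", "epsilon",
                    "seed", "outdir"):
            if key in raw:
                kw[key] = tuple(raw[key]) if key == "k_list" else raw[key]
        return cls(**kw)


#: Stage indices of the per-stage seed scheme: the stage seed is
#: ``SeedSequence([global_seed, stage_index])`` reduced below 2^31.
STAGE_REGION, STAGE_COHORT, STAGE_BOOTSTRAP = 0, 1, 2


def stage_seed(global_seed: int, stage_index: int) -> int:
    ss = np.random.SeedSequence([int(global_seed) % 2**31, stage_index])
    return int(ss.generate_state(1)[0] % 2**31)


def deployed_facilities(
    facilities: list[Facility], chosen_ids: list[str]
) -> list[Facility]:
    """Facility list with the chosen candidate sites promoted to CT stations."""
    out = []
    chosen = set(chosen_ids)
    for f in facilities:
        if f.facility_id in chosen:
            out.append(dataclasses.replace(f, kind=CT_STATION))
        elif f.kind != CT_STATION:
            out.append(f)
    return out


@dataclass
class SummaryReport:
    config_seed: int
    total_population: int
    rural_population: int
    rural_percent: int
    scenarios: dict  # name -> {deployment, cohort aggregates, comparison}
    strategy_areas: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o).__name__)

        return json.dumps(self.to_dict(), sort_keys=True, indent=1,
                          default=_default, allow_nan=True) + "\n"

    def to_markdown(self) -> str:
        lines = [
            "# Rural CT deployment report",
            "",
            f"Rural subgroup: {self.rural_population:,} of "
            f"{self.total_population:,} residents "
            f"({self.rural_percent}% beyond the 70-min threshold).",
            "",
            "| scenario | median transport (IQR) | mean OTT | OTT<180 | OTT>270 | mean OR |",
            "|---|---|---|---|---|---|",
        ]
        for name, s in self.scenarios.items():
            agg = s["cohort"]
            med = s["deployment"]["median_after"] if s.get("deployment") else \
                s["median_transport"]
            iqr = s["deployment"]["iqr_after"] if s.get("deployment") else s["iqr_transport"]
            lines.append(
                f"| {name} | {med:.0f} ({iqr[0]:.0f}–{iqr[1]:.0f}) "
                f"| {agg['mean_ott_min']:.0f} min "
                f"| {percent_of(agg['fraction_ott_under_180'] * agg['n'], agg['n'])}% "
                f"| {percent_of(agg['fraction_ott_over_270'] * agg['n'], agg['n'])}% "
                f"| {agg['mean_or']:.2f} |"
            )
        sa = self.strategy_areas
        if sa:
            lines += ["", "## LVO transport strategy areas (20-station scenario)", ""]
            for key, val in sorted(sa.items()):
                if key == "per_label":
                    continue
                lines.append(f"- {key}: {val:,.1f}" if isinstance(val, float)
                             else f"- {key}: {val}")
        return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Re-running with an identical config reproduces identical numeric
    output. Cohorts for all scenarios share one stage seed (common random
    numbers), so scenario differences are purely due to travel times.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=generate start seed=%d", stage_seed(config.seed, STAGE_REGION))
    region_spec = dataclasses.replace(
        config.region, seed=stage_seed(config.seed, STAGE_REGION))
    net, cells, facilities = generate_region(region_spec)
    write_region(out / "region", net, cells, facilities)
    log.info("stage=generate end nodes=%d cells=%d", len(net.nodes), len(cells))

    hospitals = [f for f in facilities if f.is_hospital]
    candidates = [f for f in facilities if f.kind == "candidate"]
    baseline_field = closest_facility_field(net, cells, hospitals, config.speed_factor)

    total_pop = sum(c.population for c in cells)
    rural_cells = dep.rural_subgroup(baseline_field, cells, config.rural_threshold_min)
    rural_pop = sum(c.population for c in rural_cells)
    rural_percent = percent_of(rural_pop, total_pop)
    log.info("stage=traveltime end rural_pop=%d (%d%%)", rural_pop, rural_percent)

    cohort_seed = stage_seed(config.seed, STAGE_COHORT)
    cohort_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)
    tcm = config.time_components

    # The cohort concerns the rural subgroup: sample its cells throughout.
    baseline_cohort = sample_cohort(rural_cells, baseline_field, tcm, cohort_cfg) \
        if rural_cells else None

    scenarios: dict[str, dict] = {}
    if baseline_cohort is not None:
        base_minutes = np.array([baseline_field.minutes[c.cell_id] for c in rural_cells])
        pops = np.array([c.population for c in rural_cells], dtype=float)
        q = dep._weighted_quantiles(base_minutes, pops)
        scenarios["baseline"] = {
            "deployment": None,
            "median_transport": q[1], "iqr_transport": (q[0], q[2]),
            "cohort": baseline_cohort.aggregates(),
            "comparison": None,
        }

    maps: dict[str, rt.StrategyMap] = {}
    maps["baseline"] = rt.classify_region(
        cells, hospitals, net, config.case_mix, config.curves,
        config.epsilon, tcm, config.speed_factor)

    mid_k = None
    for k in config.k_list:
        name = f"k{k}"
        log.info("stage=deploy start k=%d", k)
        if not rural_cells:
            log.info("stage=deploy skip: nothing to deploy (no rural cells)")
            scenarios[name] = {"deployment": None, "cohort": None, "comparison": None}
            continue
        cfg_k = dep.DeploymentConfig(k=k, rural_threshold_min=config.rural_threshold_min)
        result = dep.greedy_deploy(net, candidates, rural_cells, baseline_field, cfg_k)
        new_field = dep.apply_deployment(baseline_field, result)
        cohort = sample_cohort(rural_cells, new_field, tcm, cohort_cfg)
        comparison = compare_scenarios(
            baseline_cohort, cohort, seed=stage_seed(config.seed, STAGE_BOOTSTRAP))
        scenarios[name] = {
            "deployment": result.summary | {"chosen_sites": result.chosen_sites},
            "cohort": cohort.aggregates(),
            "comparison": comparison,
        }
        facs_k = deployed_facilities(facilities, result.chosen_sites)
        maps[name] = rt.classify_region(
            cells, [f for f in facs_k if f.kind != "candidate"], net,
            config.case_mix, config.curves, config.epsilon, tcm, config.speed_factor)
        (out / f"deployment_k{k}.json").write_text(json.dumps(
            {"chosen_sites": result.chosen_sites,
             "objective_value": result.objective_value,
             "summary": result.summary,
             "per_cell_new_minutes": {str(c): round(m, 4) for c, m
                                      in sorted(result.per_cell_new_minutes.items())}},
            sort_keys=True, indent=1) + "\n")
        cohort.patients.to_csv(out / f"cohort_{name}.csv", index=False,
                               float_format="%.4f")
        mid_k = mid_k or name
        log.info("stage=deploy end k=%d sites=%s", k, ",".join(result.chosen_sites))

    # Strategy-area changes reported against the middle k (the showcase scenario).
    showcase = f"k{config.k_list[len(config.k_list) // 2]}" if config.k_list else None
    strategy_areas = {}
    if showcase in maps:
        strategy_areas = rt.strategy_area_report(maps["baseline"], maps[showcase])
        strategy_areas["showcase_scenario"] = showcase
    for name, smap in maps.items():
        (out / f"strategy_map_{name}.geojson").write_text(json.dumps(
            rt.strategy_map_geojson(smap, cells),
            sort_keys=True, separators=(",", ":")) + "\n")

    report = SummaryReport(
        config_seed=config.seed,
        total_population=total_pop,
        rural_population=rural_pop,
        rural_percent=rural_percent,
        scenarios=scenarios,
        strategy_areas=strategy_areas,
    )
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(report.to_markdown())
    log.info("stage=report end outdir=%s", out)
    return report
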