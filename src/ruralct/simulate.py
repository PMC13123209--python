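"""Monte Carlo onset-to-treatment simulation and the Emberson outcome model.

A simulated cohort draws patient locations proportional to cell
population, samples the non-transport time components from gamma
distributions, adds the cell's ambulance transport time, and converts
each onset-to-treatment time (OTT) into an odds ratio for good outcome
(mRS 0–1) via the Emberson meta-analytic relation. Patients beyond the
270-minute window receive no thrombolysis and carry OR = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PopulationCell
from .traveltime import TravelTimeField

# Emberson et al. meta-analytic relation: time t in HOURS from onset to
# thrombolysis; OR for mRS 0-1 at 3 months.
_EMB_INTERCEPT = 0.2749
_EMB_SLOPE = -0.1458
_EMB_CENTRE_H = 4.02
_EMB_SCALE_H = 1.228

#: Fixed intermediate-site service constants (minutes).
NEEDLE_TO_DOOR_OUT_MIN = 30.0
CT_STATION_DIDO_MIN = 50.0

#: Every minute saved from onset to revascularisation buys, on average,
#: at least this many days of healthy life (Meretoja-style conversion).
HEALTHY_LIFE_DAYS_PER_MIN = 1.8


def emberson_or(t_hours):
    """Odds ratio for good outcome after thrombolysis at time ``t_hours``.

    ``exp(0.2749 − 0.1458 (t − 4.02) / 1.228)``; strictly decreasing in t.
    Accepts scalars or arrays; every time must be positive.
    """
    t = np.asarray(t_hours, dtype=float)
    if np.any(t <= 0):
        raise ValueError("onset-to-treatment time must be positive")
    out = np.exp(_EMB_INTERCEPT + _EMB_SLOPE * (t - _EMB_CENTRE_H) / _EMB_SCALE_H)
    return float(out) if np.isscalar(t_hours) else out


def healthy_life_days(minutes_saved: float) -> float:
    """Convert minutes of earlier treatment into days of extra healthy life."""
    return HEALTHY_LIFE_DAYS_PER_MIN * minutes_saved


@dataclass(frozen=True)
class GammaComponent:
    """A gamma-distributed activity duration (shape α, scale β, minutes)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")

    @property
    def median_min(self) -> float:
        return float(stats.gamma.median(self.shape, scale=self.scale))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, n)


@dataclass(frozen=True)
class ConstantComponent:
    """A zero-variance duration; useful for exact degenerate-limit checks."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("duration must be >= 0")

    @property
    def median_min(self) -> float:
        return float(self.value)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        rng.gamma(1.0, 1.0, n)  # keep the stream aligned with gamma sampling
        return np.full(n, float(self.value))


#: Order in which components are sampled (fixed for reproducibility).
COMPONENT_ORDER = ("onset_to_alarm", "alarm_to_scene", "on_scene", "door_to_needle")


@dataclass(frozen=True)
class TimeComponentModel:
    """Gamma models for the non-transport components of OTT (minutes).

    Defaults are calibrated so the median of the summed components is
    ~110 min, the registry-based share of OTT not spent in transport.
    """

    onset_to_alarm: GammaComponent | ConstantComponent = GammaComponent(2.0, 28.0)
    alarm_to_scene: GammaComponent | ConstantComponent = GammaComponent(4.0, 4.0)
    on_scene: GammaComponent | ConstantComponent = GammaComponent(5.0, 3.2)
    door_to_needle: GammaComponent | ConstantComponent = GammaComponent(7.0, 4.3)
    needle_to_door_out_min: float = NEEDLE_TO_DOOR_OUT_MIN
    ct_station_dido_min: float = CT_STATION_DIDO_MIN

    def components(self) -> dict[str, GammaComponent]:
        return {name: getattr(self, name) for name in COMPONENT_ORDER}

    def sample_nontransport(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n draws of the summed non-transport minutes (fixed component order)."""
        total = np.zeros(n)
        for name in COMPONENT_ORDER:
            total += getattr(self, name).sample(rng, n)
        return total

    def prehospital_median_min(self) -> float:
        """Median onset-to-scene-departure time (excludes door-to-needle)."""
        return sum(getattr(self, n).median_min
                   for n in COMPONENT_ORDER if n != "door_to_needle")

    def nontransport_median_min(self, n: int = 200_000, seed: int = 12345) -> float:
        """Monte Carlo median of the summed components (calibration check)."""
        rng = np.random.default_rng(seed)
        return float(np.median(self.sample_nontransport(rng, n)))


@dataclass(frozen=True)
class CohortConfig:
    n_strokes: int = 1000
    incidence_per_100k: float = 200.0
    thrombolysis_fraction: float = 0.25
    seed: int = 0
    fast_window_min: float = 180.0
    max_window_min: float = 270.0

    def __post_init__(self) -> None:
        if self.n_strokes < 1:
            raise ValueError("n_strokes must be >= 1")
        if not (0 <= self.thrombolysis_fraction <= 1):
            raise ValueError("thrombolysis_fraction must lie in [0, 1]")
        if not self.fast_window_min < self.max_window_min:
            raise ValueError("fast_window must be below max_window")


@dataclass
class CohortResult:
    """Per-patient OTT/OR table plus cohort aggregates."""

    patients: pd.DataFrame  # cell_id, transport_min, ott_min, treated, or_good_outcome
    config: CohortConfig

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def fraction_under_fast(self) -> float:
        return float((self.patients.ott_min < self.config.fast_window_min).mean())

    @property
    def fraction_over_max(self) -> float:
        return float((self.patients.ott_min > self.config.max_window_min).mean())

    @property
    def mean_ott(self) -> float:
        return float(self.patients.ott_min.mean())

    @property
    def mean_or(self) -> float:
        return float(self.patients.or_good_outcome.mean())

    def aggregates(self) -> dict[str, float]:
        ott = self.patients.ott_min
        q25, q75 = ott.quantile([0.25, 0.75])
        return {
            "n": self.n,
            "mean_ott_min": self.mean_ott,
            "median_ott_min": float(ott.median()),
            "iqr_ott_min": (float(q25), float(q75)),
            "fraction_ott_under_180": self.fraction_under_fast,
            "fraction_ott_over_270": self.fraction_over_max,
            "untreated_fraction": float((~self.patients.treated).mean()),
            "mean_or": self.mean_or,
            "mean_or_treated": float(
                self.patients.loc[self.patients.treated, "or_good_outcome"].mean()
            ) if self.patients.treated.any() else math.nan,
        }


def sample_cohort(
    cells: list[PopulationCell],
    field_: TravelTimeField,
    tcm: TimeComponentModel,
    cfg: CohortConfig,
) -> CohortResult:
    """Simulate a cohort of ischemic strokes over the given cells.

    Locations are drawn with probability proportional to cell population
    (reachable cells only); OTT = gamma components + ambulance transport.
    Treated iff OTT ≤ 270 min; untreated patients carry OR = 1 exactly.
    Fully reproducible for a given ``cfg.seed``; the draw order (cells
    first, then components) is fixed so that two scenarios sharing a seed
    share their random numbers.
    """
    pool = [c for c in cells
            if c.population > 0 and c.node is not None
            and not field_.is_unreachable(c.cell_id)]
    if not pool:
        raise ValueError("no reachable populated cells to sample from")
    rng = np.random.default_rng(cfg.seed)
    pop = np.array([c.population for c in pool], dtype=float)
    idx = rng.choice(len(pool), size=cfg.n_strokes, p=pop / pop.sum())
    transport = np.array([field_.minutes[pool[i].cell_id] for i in idx])
    nontransport = tcm.sample_nontransport(rng, cfg.n_strokes)
    ott = transport + nontransport
    treated = ott <= cfg.max_window_min
    or_good = np.ones(cfg.n_strokes)
    if treated.any():
        or_good[treated] = emberson_or(ott[treated] / 60.0)
    patients = pd.DataFrame({
        "cell_id": [pool[i].cell_id for i in idx],
        "transport_min": transport,
        "ott_min": ott,
        "treated": treated,
        "or_good_outcome": or_good,
    })
    return CohortResult(patients=patients, config=cfg)


def two_proportion_test(count1: int, count2: int, n1: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test (pooled variance); returns (z, p)."""
    from statsmodels.stats.proportion import proportions_ztest

    if count1 == count2 and n1 == n2:
        return 0.0, 1.0  # identical samples: no evidence of difference
    z, p = proportions_ztest([count1, count2], [n1, n2])
    return float(z), float(p)


def compare_scenarios(
    baseline: CohortResult,
    deployed: CohortResult,
    seed: int = 0,
    n_boot: int = 2000,
) -> dict:
    """Differences between two same-size cohorts with significance machinery.

    Two-proportion z-tests for the 180/270-min threshold fractions and a
    seeded paired bootstrap percentile CI for the mean-OR difference.
    """
    if baseline.n != deployed.n:
        raise ValueError("cohorts must have equal n")
    n = baseline.n
    u1 = int((baseline.patients.ott_min > baseline.config.max_window_min).sum())
    u2 = int((deployed.patients.ott_min > deployed.config.max_window_min).sum())
    f1 = int((baseline.patients.ott_min < baseline.config.fast_window_min).sum())
    f2 = int((deployed.patients.ott_min < deployed.config.fast_window_min).sum())
    z_over, p_over = two_proportion_test(u1, u2, n, n)
    z_fast, p_fast = two_proportion_test(f1, f2, n, n)

    or_b = baseline.patients.or_good_outcome.to_numpy()
    or_d = deployed.patients.or_good_outcome.to_numpy()
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        take = rng.integers(0, n, n)
        boots[i] = or_d[take].mean() - or_b[take].mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "n": n,
        "diff_fraction_under_180": deployed.fraction_under_fast - baseline.fraction_under_fast,
        "diff_fraction_over_270": deployed.fraction_over_max - baseline.fraction_over_max,
        "diff_mean_ott": deployed.mean_ott - baseline.mean_ott,
        "diff_mean_or": deployed.mean_or - baseline.mean_or,
        "p_under_180": p_fast,
        "p_over_270": p_over,
        "or_diff_ci95": (float(lo), float(hi)),
    }
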