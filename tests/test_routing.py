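"""LVO transport strategy: time bundles, outcome curves, strategy maps."""

import math

import numpy as np
import pytest

from ruralct.core import Facility
from ruralct.routing import (
    DRIPSHIP_CT,
    DRIPSHIP_HOSPITAL,
    EXCLUDED,
    MOTHERSHIP,
    NEAR_EQUIVALENT,
    CaseMix,
    OutcomeCurves,
    classify_region,
    expected_p_good,
    strategy_area_report,
    strategy_times,
)
from ruralct.simulate import emberson_or

from conftest import cell_at, ct_site, hospital, line_network
from test_simulate import constant_tcm


class TestCaseMix:
    def test_default_mix_sums_to_one(self):
        mix = CaseMix()
        assert mix.f_lvo == 0.145
        assert mix.f_nonlvo_ischemic == 0.31
        assert mix.f_lvo + mix.f_nonlvo_ischemic + mix.f_other == pytest.approx(1.0)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            CaseMix(f_lvo=0.8, f_nonlvo_ischemic=0.5)
        with pytest.raises(ValueError):
            CaseMix(f_lvo=-0.1)


class TestOutcomeCurves:
    def test_curves_non_increasing_and_clamped(self):
        curves = OutcomeCurves()
        ts = np.linspace(1.0, 500.0, 600)
        tpa = [curves.p_good_tpa(t) for t in ts]
        evt = [curves.p_good_evt(t) for t in ts]
        for seq in (tpa, evt):
            assert all(b <= a + 1e-12 for a, b in zip(seq, seq[1:]))
            assert all(0.0 <= p <= 1.0 for p in seq)

    def test_beyond_window_returns_untreated_baseline(self):
        curves = OutcomeCurves()
        assert curves.p_good_tpa(271.0) == curves.p0
        assert curves.p_good_evt(361.0) == curves.p0
        assert curves.p_good_tpa(math.inf) == curves.p0

    def test_tpa_curve_is_odds_transform_of_emberson(self):
        curves = OutcomeCurves()
        t = 120.0
        odds = (curves.p0 / (1 - curves.p0)) * emberson_or(t / 60.0)
        assert curves.p_good_tpa(t) == pytest.approx(odds / (1 + odds))


def _hallingdal_line():
    """Cell – CT station – long road – EVT centre, on one line."""
    # spacing so ambulance times are 10 min cell->CT and 144 min CT->EVT at 0.8
    net = line_network(2, spacing_km=1.0)
    coords = {0: (0.0, 0.0), 1: (12.5, 0.0), 2: (192.5, 0.0)}
    from conftest import make_network
    net = make_network(coords, [(0, 1, 12_500.0, 60.0), (1, 2, 180_000.0, 60.0)])
    ct = ct_site("S0", 1, net, kind="ct")
    evt = hospital("E0", 2, net, dtn=30.0, evt=True, dtg=75.0)
    return net, ct, evt


class TestStrategyTimes:
    def test_hand_computed_bundle_on_line_fixture(self):
        net, ct, evt = _hallingdal_line()
        cell = cell_at(0, 0, net)
        tcm = constant_tcm()  # prehospital (non-needle) components sum to 80
        bundles = {b.label: b for b in strategy_times(cell, [ct, evt], net, tcm, 0.8)}
        # ambulance: cell->CT 10 min, CT->EVT 144 min, cell->EVT 154 min
        m = bundles[MOTHERSHIP]
        assert m.t_needle_min == pytest.approx(80 + 154 + 30)
        assert m.t_groin_min == pytest.approx(80 + 154 + 75)
        d = bundles[DRIPSHIP_CT]
        assert d.t_needle_min == pytest.approx(80 + 10 + 30)
        assert d.t_groin_min == pytest.approx(80 + 10 + 50 + 144 + 75)
        assert d.t_needle_min < m.t_needle_min  # local needle first

    def test_hospital_dido_is_needle_plus_thirty(self):
        net = line_network(3, spacing_km=30.0)
        h = hospital("H0", 1, net, dtn=35.0)
        evt = hospital("E0", 2, net, evt=True, dtg=80.0)
        cell = cell_at(0, 0, net)
        tcm = constant_tcm()
        bundles = {b.via: b for b in strategy_times(cell, [h, evt], net, tcm, 0.8)}
        d = bundles["H0"]
        assert d.label == DRIPSHIP_HOSPITAL
        t_cell_h = 0.8 * 30.0  # 30 km at 60 km/h, speed factor 0.8
        t_h_evt = 0.8 * 30.0
        assert d.t_needle_min == pytest.approx(80 + t_cell_h + 35.0)
        assert d.t_groin_min == pytest.approx(80 + t_cell_h + (35.0 + 30.0)
                                              + t_h_evt + 80.0)

    def test_no_evt_centre_is_an_error(self):
        net = line_network(3)
        with pytest.raises(ValueError):
            strategy_times(cell_at(0, 0, net), [hospital("H0", 1, net)], net,
                           constant_tcm())


class TestExpectedPGood:
    def _times(self, label, needle, groin):
        from ruralct.routing import StrategyTimes
        return StrategyTimes(label, None, "E0", needle, groin, prior_tpa=False)

    def test_pure_lvo_mix_ties_on_equal_groin_times(self):
        mix = CaseMix(f_lvo=1.0, f_nonlvo_ischemic=0.0)
        curves = OutcomeCurves()
        a = self._times(MOTHERSHIP, 150.0, 240.0)
        b = self._times(DRIPSHIP_HOSPITAL, 500.0, 240.0)
        assert expected_p_good(a, mix, curves) == \
            pytest.approx(expected_p_good(b, mix, curves))

    def test_pure_nonlvo_mix_prefers_earliest_needle(self):
        mix = CaseMix(f_lvo=0.0, f_nonlvo_ischemic=1.0)
        curves = OutcomeCurves()
        early = self._times(DRIPSHIP_CT, 120.0, 400.0)
        late = self._times(MOTHERSHIP, 200.0, 200.0)
        assert expected_p_good(early, mix, curves) > \
            expected_p_good(late, mix, curves)

    def test_default_mix_equals_hand_weighted_sum(self):
        mix, curves = CaseMix(), OutcomeCurves()
        t = self._times(MOTHERSHIP, 190.0, 250.0)
        hand = (0.145 * curves.p_good_evt(250.0)
                + 0.31 * curves.p_good_tpa(190.0)
                + mix.f_other * 0.0)
        assert expected_p_good(t, mix, curves) == pytest.approx(hand)


class TestClassifyRegion:
    def test_sole_evt_site_makes_everything_mothership(self):
        net = line_network(6, spacing_km=15.0)
        evt = hospital("E0", 0, net, evt=True)
        cells = [cell_at(i, i, net) for i in range(6)]
        smap = classify_region(cells, [evt], net, epsilon=0.0, tcm=constant_tcm())
        assert all(lbl == MOTHERSHIP for lbl in smap.labels.values())

    def test_area_conservation(self, small_region):
        net, cells, facs = small_region
        roster = [f for f in facs if f.is_hospital]
        smap = classify_region(cells, roster, net, tcm=constant_tcm())
        total = sum(c.area_km2 for c in cells)
        assert sum(smap.area_km2.values()) == pytest.approx(total)
        included = sum(c.area_km2 for c in cells
                       if smap.labels[c.cell_id] != EXCLUDED)
        assert smap.total_included_area() == pytest.approx(included)

    def test_unroutable_cell_is_excluded(self):
        from conftest import make_network
        net = make_network({0: (0, 0), 1: (10, 0), 2: (90, 90)},
                           [(0, 1, 10_000.0, 60.0)])
        evt = hospital("E0", 0, net, evt=True)
        cells = [cell_at(0, 1, net), cell_at(1, 2, net)]
        smap = classify_region(cells, [evt], net, tcm=constant_tcm())
        assert smap.labels[1] == EXCLUDED
        assert math.isnan(smap.delta_p[1])
        assert smap.labels[0] == MOTHERSHIP

    def test_adding_ct_station_never_grows_mothership_or_hospital_dripship(self):
        net = line_network(12, spacing_km=12.0)
        evt = hospital("E0", 0, net, evt=True)
        h = hospital("H0", 11, net)
        cells = [cell_at(i, i, net) for i in range(12)]
        tcm = constant_tcm()
        before = classify_region(cells, [evt, h], net, tcm=tcm)
        station = ct_site("S0", 6, net, kind="ct")
        after = classify_region(cells, [evt, h, station], net, tcm=tcm)
        assert after.area_km2.get(MOTHERSHIP, 0.0) <= \
            before.area_km2.get(MOTHERSHIP, 0.0) + 1e-9
        assert after.area_km2.get(DRIPSHIP_HOSPITAL, 0.0) <= \
            before.area_km2.get(DRIPSHIP_HOSPITAL, 0.0) + 1e-9

    def test_mothership_cells_form_a_prefix_toward_the_evt_centre(self):
        # along one road, moving closer to the EVT centre never flips a cell
        # from mothership to drip-and-ship
        net = line_network(25, spacing_km=10.0)
        evt = hospital("E0", 0, net, evt=True)
        h = hospital("H0", 24, net)
        cells = [cell_at(i, i, net) for i in range(25)]
        smap = classify_region(cells, [evt, h], net, epsilon=0.0,
                               tcm=constant_tcm())
        labels = [smap.labels[i] for i in range(25)]
        assert labels[0] == MOTHERSHIP
        first_non = next((i for i, l in enumerate(labels) if l != MOTHERSHIP),
                         len(labels))
        assert all(l != MOTHERSHIP for l in labels[first_non:])

    def test_area_report_percent_changes(self):
        net = line_network(12, spacing_km=12.0)
        evt = hospital("E0", 0, net, evt=True)
        h = hospital("H0", 11, net)
        cells = [cell_at(i, i, net, area=1.0) for i in range(12)]
        tcm = constant_tcm()
        before = classify_region(cells, [evt, h], net, tcm=tcm)
        after = classify_region(cells, [evt, h, ct_site("S0", 6, net, "ct")],
                                net, tcm=tcm)
        rep = strategy_area_report(before, after)
        total_b = sum(v["before_km2"] for v in rep["per_label"].values())
        total_a = sum(v["after_km2"] for v in rep["per_label"].values())
        assert total_b == pytest.approx(total_a) == pytest.approx(12.0)
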