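import numpy as np
import pytest

from whi import (
    CorrectedTotals,
    DesatEvent,
    Dip,
    ExcludedEvent,
    Hypnogram,
    LowerAboveUpper,
    SyntheticSpec,
    WHIConfig,
    ZeroSleepTime,
    compute_whi,
    compute_whi_grid,
    detect_events,
    event_area,
    event_weight,
    generate_recording,
    metric_name,
    normalization_factor,
)
from conftest import make_signal, all_n2
from oracle import random_recording


def r1_signal():
    v = np.full(90, 95.0)
    v[10:20] = 85.0
    return make_signal(v)


def r1_event():
    return detect_events(r1_signal(), (0, 90), 90.0)[0]


class TestEventArea:
    def test_aac_exact_trapezoids(self):
        """Two crossing triangles (1.25 each) plus the 45 %*s plateau."""
        assert event_area(r1_signal(), r1_event(), 90.0, "AAC") == \
            pytest.approx(47.5, abs=1e-12)

    def test_auc_is_complement(self):
        assert event_area(r1_signal(), r1_event(), 90.0, "AUC") == \
            pytest.approx(852.5, abs=1e-12)

    def test_zero_duration_event(self):
        ev = DesatEvent(index=0, start_s=5.0, end_s=5.0, duration_s=0.0,
                        nadir_pct=89.0, threshold_pct=90.0)
        assert event_area(r1_signal(), ev, 90.0, "AAC") == 0.0

    def test_excluded_event_refused(self):
        ev = DesatEvent(index=0, start_s=5.0, end_s=8.0, duration_s=3.0,
                        nadir_pct=40.0, threshold_pct=90.0, excluded=True,
                        reason="below_lower_threshold")
        with pytest.raises(ExcludedEvent):
            event_area(r1_signal(), ev, 90.0, "AAC")

    def test_conservation_on_random_events(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = random_recording(rng, 100, 400)
            sig = make_signal(v)
            for ev in detect_events(sig, (0, len(v)), 90.0):
                aac = event_area(sig, ev, 90.0, "AAC")
                auc = event_area(sig, ev, 90.0, "AUC")
                total = 90.0 * ev.duration_s
                assert abs(aac + auc - total) <= 1e-9 * max(total, 1.0)


class TestEventWeight:
    def test_weighted_is_duration(self):
        assert event_weight(r1_event(), weighted=True) == pytest.approx(10.0)

    def test_unweighted_is_one(self):
        assert event_weight(r1_event(), weighted=False) == 1.0

    def test_one_second_events_equalize_modes(self):
        ev = DesatEvent(index=0, start_s=3.0, end_s=4.0, duration_s=1.0,
                        nadir_pct=88.0, threshold_pct=90.0)
        assert event_weight(ev, True) == event_weight(ev, False) == 1.0


class TestNormalization:
    def test_ratio(self):
        assert normalization_factor(CorrectedTotals(90, 10)) == \
            pytest.approx(1 / 9)

    def test_zero_numerator(self):
        assert normalization_factor(CorrectedTotals(90, 0)) == 0.0

    def test_zero_sleep_time(self):
        with pytest.raises(ZeroSleepTime):
            normalization_factor(CorrectedTotals(0, 0))


class TestComputeWhi:
    def test_r1_aac(self, r1):
        sig, hyp = r1
        res = compute_whi(sig, hyp, WHIConfig(area_mode="AAC"))
        assert res.whi == pytest.approx(47.5 * 10 * (10 / 90), rel=1e-12)
        assert res.omega == pytest.approx(1 / 9)
        assert res.per_event == [(pytest.approx(47.5), pytest.approx(10.0))]

    def test_r1_auc(self, r1):
        sig, hyp = r1
        res = compute_whi(sig, hyp, WHIConfig(area_mode="AUC"))
        assert res.whi == pytest.approx(947.2222222222, rel=1e-10)

    def test_r2_artifact_removed_from_denominator(self, r2):
        sig, hyp = r2
        res = compute_whi(sig, hyp, WHIConfig(area_mode="AAC"))
        assert res.totals.tstc_s == 85
        assert res.totals.tst90c_s == 10
        assert res.whi == pytest.approx(475 * 10 / 85, rel=1e-12)

    def test_whi_zero_iff_no_events(self):
        sig = make_signal(np.full(90, 95.0))
        res = compute_whi(sig, Hypnogram(["N2"] * 3),
                          WHIConfig(normalization="none"))
        assert res.whi == 0.0
        assert res.per_event == []

    def test_result_identity(self, r2):
        """whi == omega * sum(delta*phi) holds exactly."""
        sig, hyp = r2
        res = compute_whi(sig, hyp, WHIConfig(area_mode="AAC"))
        assert res.whi == res.omega * sum(d * p for d, p in res.per_event)

    def test_invalid_config_rejected(self):
        with pytest.raises(LowerAboveUpper):
            WHIConfig(upper_threshold_pct=50.0, lower_threshold_pct=50.0)

    def test_full_recording_window(self):
        v = np.full(90, 95.0)
        v[10:20] = 85.0
        res = compute_whi(make_signal(v), None,
                          WHIConfig(window="full_recording", area_mode="AAC"))
        assert res.whi == pytest.approx(47.5 * 10 * (10 / 90), rel=1e-12)

    def test_aac_monotone_in_depth(self):
        """Lowering the plateau strictly increases the weighted AAC sum."""
        prev = -1.0
        for nadir in (89.0, 87.0, 85.0, 80.0):
            spec = SyntheticSpec(duration_s=90,
                                 dips=[Dip(onset_s=10, duration_s=10,
                                           nadir_pct=nadir)],
                                 hypnogram_pattern=[("N2", 3)])
            sig, hyp, _ = generate_recording(spec)
            res = compute_whi(sig, hyp, WHIConfig(area_mode="AAC",
                                                  normalization="none"))
            total = sum(d * p for d, p in res.per_event)
            assert total > prev
            prev = total

    def test_locality_of_high_samples(self):
        """Samples >= 90 and not adjacent to an event never change the
        index."""
        v = np.full(150, 95.0)
        v[30:40] = 85.0
        sig = make_signal(v)
        hyp = all_n2(150)
        base = compute_whi(sig, hyp, WHIConfig(area_mode="AAC")).whi
        v2 = v.copy()
        v2[60:100] = 93.0  # still above threshold, far from the event
        pert = compute_whi(make_signal(v2), hyp,
                           WHIConfig(area_mode="AAC")).whi
        assert pert == base

    def test_units_scaling_duration_doubles_term_quadruples(self):
        """Stretching a triangle dip 2x doubles both its area and its
        duration, so each weighted term scales by 4 (Omega pinned to 1)."""
        terms = {}
        for w in (20, 40):
            spec = SyntheticSpec(duration_s=300,
                                 dips=[Dip(onset_s=50, duration_s=w,
                                           nadir_pct=80.0, shape="triangle")],
                                 hypnogram_pattern=[("N2", 10)])
            sig, hyp, _ = generate_recording(spec)
            res = compute_whi(sig, hyp, WHIConfig(area_mode="AAC",
                                                  normalization="none"))
            terms[w] = sum(d * p for d, p in res.per_event)
        assert terms[40] == pytest.approx(4 * terms[20], rel=1e-12)


class TestComparators:
    def test_r1_values(self, r1):
        sig, hyp = r1
        comp = compute_whi(sig, hyp).comparators
        assert comp["tst90_pct"] == pytest.approx(100 * 10 / 90)
        assert comp["min_sat_pct"] == 85.0
        assert comp["aut90"] == pytest.approx(47.5 / 90)

    def test_hl100_mean_deficit(self):
        sig = make_signal(np.full(90, 95.0))
        comp = compute_whi(sig, Hypnogram(["N2"] * 3),
                           WHIConfig(normalization="none")).comparators
        assert comp["hl100"] == pytest.approx(5.0)
        assert comp["aut90"] == 0.0

    def test_artifact_dip_does_not_set_min_sat(self, r2):
        sig, hyp = r2
        comp = compute_whi(sig, hyp, WHIConfig(area_mode="AAC")).comparators
        assert comp["min_sat_pct"] == 85.0  # not the 45% artifact


class TestGrid:
    def test_sixteen_variants(self, r1):
        sig, hyp = r1
        grid = compute_whi_grid(sig, hyp)
        assert len(grid) == 16
        assert grid["whi_auc90"] == pytest.approx(947.2222222222, rel=1e-9)
        assert grid["whi_aac90"] == pytest.approx(52.7777777777, rel=1e-9)
        # deeper thresholds see a shallower event, higher ones a deeper one
        assert 0 < grid["whi_aac86"] < grid["whi_aac90"] < grid["whi_aac92"]

    def test_metric_names(self):
        assert metric_name(90, "AUC", True) == "whi_auc90"
        assert metric_name(88, "AAC", False) == "aac88_unweighted"
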