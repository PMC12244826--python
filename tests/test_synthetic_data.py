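import numpy as np
import pytest

from whi import (
    Dip,
    NoEvents,
    OverlappingDips,
    SyntheticSpec,
    UnsupportedShape,
    WHIConfig,
    analytic_ground_truth,
    compute_whi,
    fit_cox_models,
    generate_cohort,
    generate_recording,
)


class TestGroundTruth:
    def test_r1_closed_forms(self, r1_spec):
        gt = analytic_ground_truth(r1_spec, WHIConfig(area_mode="AAC"))
        d = gt.per_dip[0]
        assert d["aac"] == pytest.approx(47.5)
        assert d["auc"] == pytest.approx(852.5)
        assert d["phi_s"] == pytest.approx(10.0)
        assert gt.omega == pytest.approx(1 / 9)
        assert gt.whi == pytest.approx(52.777777777, rel=1e-9)

    def test_triangle_area_verified_by_dense_integration(self):
        """Symmetric 20 s triangle from 95 to 85: each ramp contributes a
        12.5 %*s sub-threshold triangle, 25 in total."""
        spec = SyntheticSpec(duration_s=120,
                             dips=[Dip(onset_s=30, duration_s=20,
                                       nadir_pct=85.0, shape="triangle")],
                             hypnogram_pattern=[("N2", 4)])
        gt = analytic_ground_truth(spec, WHIConfig(area_mode="AAC"))
        assert gt.per_dip[0]["aac"] == pytest.approx(25.0, rel=1e-12)
        # independent check: dense trapezoid on the designed polyline
        t = np.linspace(30, 50, 200001)
        v = np.interp(t, [30, 40, 50], [95, 85, 95])
        dense = np.trapezoid(np.clip(90 - v, 0, None), t)
        assert gt.per_dip[0]["aac"] == pytest.approx(dense, rel=1e-6)

    def test_dip_above_threshold_is_no_event(self):
        spec = SyntheticSpec(duration_s=90,
                             dips=[Dip(onset_s=10, duration_s=10,
                                       nadir_pct=92.0)],
                             hypnogram_pattern=[("N2", 3)])
        gt = analytic_ground_truth(spec)
        assert gt.per_dip[0]["event"] is False
        assert gt.whi == 0.0

    def test_two_identical_dips_double_the_sum(self):
        one = SyntheticSpec(duration_s=300,
                            dips=[Dip(onset_s=50, duration_s=10,
                                      nadir_pct=85.0)],
                            hypnogram_pattern=[("N2", 10)])
        two = SyntheticSpec(duration_s=300,
                            dips=[Dip(onset_s=50, duration_s=10, nadir_pct=85.0),
                                  Dip(onset_s=150, duration_s=10,
                                      nadir_pct=85.0)],
                            hypnogram_pattern=[("N2", 10)])
        cfg = WHIConfig(area_mode="AAC", normalization="none")
        assert analytic_ground_truth(two, cfg).whi == \
            pytest.approx(2 * analytic_ground_truth(one, cfg).whi, rel=1e-12)

    @pytest.mark.parametrize("shape", ["square", "triangle", "trapezoid"])
    def test_pipeline_matches_truth_per_shape(self, shape):
        """generate -> compute agrees with the closed forms to 1e-9 relative
        on 100 random noise-free specs per dip shape."""
        rng = np.random.default_rng(
            {"square": 11, "triangle": 22, "trapezoid": 33}[shape])
        for _ in range(100):
            dips, t = [], 40
            while t < 1100:
                w = int(rng.integers(3, 15)) * 2
                dips.append(Dip(onset_s=t, duration_s=w,
                                nadir_pct=float(rng.uniform(55, 93)),
                                shape=shape,
                                ramp_s=max(1, w // 4)))
                t += w + int(rng.integers(5, 40))
            spec = SyntheticSpec(duration_s=1200, dips=dips,
                                 hypnogram_pattern=[("N2", 40)])
            for mode in ("AAC", "AUC"):
                cfg = WHIConfig(area_mode=mode)
                gt = analytic_ground_truth(spec, cfg)
                sig, hyp, _ = generate_recording(spec)
                res = compute_whi(sig, hyp, cfg)
                assert res.whi == pytest.approx(gt.whi, rel=1e-9, abs=1e-9)

    def test_artifact_dip_bookkeeping(self, r2_spec):
        gt = analytic_ground_truth(r2_spec, WHIConfig(area_mode="AAC"))
        assert gt.tstc_s == 85
        assert gt.tst90c_s == 10
        assert gt.whi == pytest.approx(475 * 10 / 85, rel=1e-12)


class TestGenerateRecording:
    def test_seed_determinism(self):
        spec = SyntheticSpec(duration_s=600, noise_sd_pct=1.0, seed=42,
                             dips=[Dip(onset_s=100, duration_s=20,
                                       nadir_pct=80.0)])
        a, _, _ = generate_recording(spec)
        b, _, _ = generate_recording(spec)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.valid, b.valid)

    def test_noise_clipped_to_physio_range(self):
        spec = SyntheticSpec(duration_s=600, noise_sd_pct=30.0, seed=1)
        sig, _, _ = generate_recording(spec)
        assert (sig.values > 0).all() and (sig.values <= 100).all()

    def test_noise_convergence_to_truth(self):
        """Mean |WHI - truth| shrinks as the noise SD drops."""
        base = dict(duration_s=1200,
                    dips=[Dip(onset_s=100 + 60 * i, duration_s=20,
                              nadir_pct=82.0) for i in range(10)],
                    hypnogram_pattern=[("N2", 40)])
        cfg = WHIConfig(area_mode="AAC")
        truth = analytic_ground_truth(SyntheticSpec(**base), cfg).whi
        errs = []
        for sd in (0.5, 0.1, 0.01):
            diffs = []
            for seed in range(5):
                sig, hyp, _ = generate_recording(
                    SyntheticSpec(**base, noise_sd_pct=sd, seed=seed), cfg)
                diffs.append(abs(compute_whi(sig, hyp, cfg).whi - truth))
            errs.append(np.mean(diffs))
        assert errs[0] > errs[1] > errs[2]

    def test_dropouts_invalid_and_excluding(self):
        spec = SyntheticSpec(duration_s=300,
                             dips=[Dip(onset_s=50, duration_s=20,
                                       nadir_pct=80.0)],
                             dropout_spans=[(55, 5)],
                             hypnogram_pattern=[("N2", 10)])
        sig, hyp, _ = generate_recording(spec)
        assert not sig.valid[55:60].any()
        res = compute_whi(sig, hyp, WHIConfig(area_mode="AAC"))
        assert all(ev.reason == "contains_invalid"
                   for ev in res.events if ev.excluded)
        assert res.whi == 0.0

    def test_overlapping_dips_rejected(self):
        with pytest.raises(OverlappingDips):
            SyntheticSpec(duration_s=300,
                          dips=[Dip(onset_s=50, duration_s=20, nadir_pct=80.0),
                                Dip(onset_s=60, duration_s=20,
                                    nadir_pct=85.0)])

    def test_unknown_shape_rejected(self):
        with pytest.raises(UnsupportedShape):
            Dip(onset_s=10, duration_s=10, nadir_pct=80.0, shape="sine")

    def test_yaml_roundtrip(self, tmp_path, r2_spec):
        p = tmp_path / "spec.yaml"
        r2_spec.to_yaml(p)
        back = SyntheticSpec.from_yaml(p)
        assert back == r2_spec


class TestGenerateCohort:
    def test_determinism_and_schema(self):
        a = generate_cohort(200, seed=9)
        b = generate_cohort(200, seed=9)
        assert a.equals(b)
        for col in ("whi_auc90", "survival_time", "event_indicator", "age",
                    "gender", "race", "bmi", "smoking", "alcohol",
                    "sleep_duration", "hypertension", "lipid_med"):
            assert col in a.columns
        assert (a["survival_time"] > 0).all()
        assert set(a["event_indicator"]) <= {0, 1}

    def test_censor_rate_respected(self):
        df = generate_cohort(4000, censor_rate=0.3, seed=1)
        assert 1 - df["event_indicator"].mean() == pytest.approx(0.3, abs=0.03)

    def test_all_censored_flags_no_events(self):
        df = generate_cohort(100, censor_rate=1.0, seed=0)
        assert df["event_indicator"].sum() == 0
        with pytest.raises(NoEvents):
            fit_cox_models(df, "whi_auc90", "model0")

    def test_severity_grid_sampling(self):
        grid = np.array([1.0, 10.0, 100.0])
        df = generate_cohort(300, severity_grid=grid, seed=2)
        assert set(df["whi_auc90"]) <= set(grid)

    def test_quintile_hazard_gradient(self):
        """Q5 subjects die faster than Q1 when the log-HR step is positive."""
        df = generate_cohort(2000, hazard_spec={"log_hr_per_quintile": 0.5},
                             censor_rate=0.0, seed=3)
        q = df["whi_auc90"].rank(method="first")
        lo = df.loc[q <= 400, "survival_time"].mean()
        hi = df.loc[q > 1600, "survival_time"].mean()
        assert hi < lo / 3
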