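"""Handcrafted feature extraction: structural counts, oracles, selection."""

import numpy as np
import pandas as pd
import pytest

from heartmil import features as ft
from heartmil.segmentation import Interval, PhaseSegmentation
from heartmil.simulate import DemographicRecord, SimConfig, synth_recording

RATE = 2000.0


def make_segmentation(n_cycles=4, s1=100, sys=300, s2=80, dias=400, start=0):
    ivs, t = [], start
    for _ in range(n_cycles):
        for lab, ln in (("S1", s1), ("systole", sys), ("S2", s2),
                        ("diastole", dias)):
            ivs.append(Interval(t, t + ln, lab))
            t += ln
    return PhaseSegmentation(ivs), t


class TestBandEnvelope:
    def test_tone_inside_band_recovers_amplitude(self):
        from heartmil.preprocess import band_envelope
        t = np.arange(int(4 * RATE)) / RATE
        x = 0.7 * np.sin(2 * np.pi * 160 * t)  # mid-band, away from edges
        env = band_envelope(x, RATE, (100.0, 250.0))
        inner = env[2000:-2000]
        assert np.median(inner) == pytest.approx(0.7, rel=0.05)

    def test_tone_outside_band_suppressed(self):
        from heartmil.preprocess import band_envelope
        t = np.arange(int(4 * RATE)) / RATE
        x = np.sin(2 * np.pi * 20 * t)
        env = band_envelope(x, RATE, (200.0, 450.0))
        assert np.max(env[2000:-2000]) < 0.05

    def test_zero_in_zero_out_and_invalid_band(self):
        from heartmil.preprocess import band_envelope
        assert np.allclose(band_envelope(np.zeros(4000), RATE, (100, 250)), 0.0)
        with pytest.raises(ValueError):
            band_envelope(np.zeros(4000), RATE, (500, 1500))


class TestTransformations:
    def test_registry_has_18_aligned_signals(self, rng):
        x = rng.standard_normal(int(2 * RATE))
        out = ft.compute_transformations(x, RATE)
        assert len(out) == 18
        assert set(out) == {t for t, _ in ft.TRANSFORMATIONS}
        assert all(len(v) == len(x) for v in out.values())

    def test_white_noise_centroid_near_quarter_rate(self, rng):
        x = rng.standard_normal(int(4 * RATE))
        centroid = ft.compute_transformations(x, RATE)["t3"]
        assert np.mean(centroid) == pytest.approx(RATE / 4, rel=0.2)

    def test_hf_lf_ratio_small_for_low_tone(self):
        t = np.arange(int(2 * RATE)) / RATE
        x = np.sin(2 * np.pi * 50 * t)
        ratio = ft.compute_transformations(x, RATE)["t12"]
        assert np.median(ratio[1000:-1000]) < 0.1


class TestRegionStats:
    def test_constant_signal(self):
        seg, n = make_segmentation()
        stats = ft.region_stats(np.full(n, 2.5), seg)
        for region in ("", "S1", "Sys", "S2", "Dias", "RR"):
            assert stats[f"a{region}"] == pytest.approx(2.5)
            assert stats[f"m{region}"] == pytest.approx(2.5)
            assert stats[f"s{region}"] == pytest.approx(0.0)

    def test_indicator_signal_interval_arithmetic(self):
        seg, n = make_segmentation()
        x = np.zeros(n)
        for iv in seg.labelled("systole"):
            x[iv.start:iv.end] = 1.0
        stats = ft.region_stats(x, seg)
        assert stats["aSys"] == pytest.approx(1.0)
        assert stats["aDias"] == pytest.approx(0.0)
        assert stats["aRR"] == pytest.approx(300 / 880)

    def test_single_cycle_average_is_that_cycle(self):
        seg, n = make_segmentation(n_cycles=1)
        x = np.arange(n, dtype=float)
        stats = ft.region_stats(x, seg)
        iv = seg.labelled("S1")[0]
        assert stats["aS1"] == pytest.approx(np.mean(x[iv.start:iv.end]))

    def test_no_cycle_rejected(self):
        with pytest.raises(ValueError):
            ft.region_stats(np.zeros(100), PhaseSegmentation([]))


class TestStatRatios:
    def test_flat_signal_ratios(self):
        seg, n = make_segmentation()
        ratios = ft.stat_ratios(ft.region_stats(np.full(n, 3.0), seg))
        assert len(ratios) == 15
        for name, val in ratios.items():
            if name.startswith("r_a"):
                assert val == pytest.approx(1.0, rel=1e-6)
            else:  # std/mean ratios
                assert val == pytest.approx(0.0, abs=1e-9)

    def test_known_mean_ratio(self):
        seg, n = make_segmentation()
        x = np.zeros(n)
        for iv in seg.labelled("systole"):
            x[iv.start:iv.end] = 2.0
        for iv in seg.labelled("diastole"):
            x[iv.start:iv.end] = 1.0
        ratios = ft.stat_ratios(ft.region_stats(x, seg))
        assert ratios["r_aSys_aDias"] == pytest.approx(2.0, rel=1e-6)


class TestDurations:
    def test_identical_cycles_and_known_ratio(self):
        seg, _ = make_segmentation(s2=200, sys=600)  # S2 0.1 s, systole 0.3 s
        out = ft.duration_features(seg, RATE)
        assert len(out) == 15
        assert out["dur_S2"] == pytest.approx(0.1)
        assert out["dur_Sys"] == pytest.approx(0.3)
        assert out["dur_r_S2_Sys"] == pytest.approx(1 / 3, rel=1e-6)

    def test_no_cycle_rejected(self):
        with pytest.raises(ValueError):
            ft.duration_features(PhaseSegmentation([]), RATE)


class TestShapes:
    def test_crescendo_self_correlation(self):
        seg, n = make_segmentation()
        env = np.zeros(n)
        for iv in seg.labelled("systole"):
            env[iv.start:iv.end] = np.linspace(0, 1, iv.length)
        out = ft.shape_features(env, seg)
        assert out["shape_crescendo_sys"] == pytest.approx(1.0, abs=1e-6)

    def test_diamond_symmetric_under_time_reversal(self):
        seg, n = make_segmentation()
        env_f, env_r = np.zeros(n), np.zeros(n)
        for iv in seg.labelled("systole"):
            tpl = ft.shape_template("diamond", iv.length) + 0.1
            env_f[iv.start:iv.end] = tpl
            env_r[iv.start:iv.end] = tpl[::-1]
        f = ft.shape_features(env_f, seg)["shape_diamond_sys"]
        r = ft.shape_features(env_r, seg)["shape_diamond_sys"]
        assert f == pytest.approx(r, abs=1e-9)

    def test_crescendo_vs_decrescendo_negative(self):
        """Closed form: two opposite mean-centred ramps correlate at -1."""
        seg, n = make_segmentation()
        env = np.zeros(n)
        for iv in seg.labelled("systole"):
            env[iv.start:iv.end] = np.linspace(1, 0, iv.length)  # decrescendo
        out = ft.shape_features(env, seg)
        assert out["shape_crescendo_sys"] == pytest.approx(-1.0, abs=1e-6)
        assert out["shape_decrescendo_sys"] == pytest.approx(1.0, abs=1e-6)

    def test_template_validation(self):
        with pytest.raises(ValueError):
            ft.shape_template("triangle", 10)


class TestDemographics:
    def test_weight_height_ratio(self):
        rec = DemographicRecord(age_months=24, sex="female", weight_kg=20,
                                height_cm=100)
        out = ft.demographic_features(rec)
        assert len(out) == 5
        assert out["weight_height"] == pytest.approx(0.2)

    def test_missing_height_propagates_sentinel(self):
        rec = DemographicRecord(age_months=24, sex="male", weight_kg=20)
        out = ft.demographic_features(rec)
        assert np.isnan(out["height"]) and np.isnan(out["weight_height"])
        assert out["sex"] == 1.0


class TestFullVector:
    def test_count_identity_and_block_sizes(self):
        assert len(ft.feature_names()) == 622
        assert len(ft.demographic_feature_names()) == 5
        assert len(ft.duration_feature_names()) == 15
        assert len(ft.tf_feature_names()) == 594
        assert len(ft.shape_feature_names()) == 8

    def test_extraction_has_622_entries_and_is_deterministic(self, murmur_recording):
        rec = murmur_recording
        a = ft.extract_features(rec.samples, RATE, rec.segmentation,
                                rec.demographics)
        b = ft.extract_features(rec.samples, RATE, rec.segmentation,
                                rec.demographics)
        assert len(a) == 622
        assert list(a.index) == ft.feature_names()
        pd.testing.assert_series_equal(a, b)

    def test_ratio_features_invariant_to_global_scaling(self, murmur_recording):
        rec = murmur_recording
        a = ft.extract_features(rec.samples, RATE, rec.segmentation,
                                rec.demographics)
        b = ft.extract_features(10.0 * rec.samples, RATE, rec.segmentation,
                                rec.demographics)
        ratio_cols = [c for c in a.index if "_r_" in c and c.startswith("t")]
        assert len(ratio_cols) == 15 * 18
        # the 1e-8 denominator floor leaves relative deviations up to ~1e-4
        # where phase means are tiny; everything else cancels exactly
        assert np.allclose(a[ratio_cols], b[ratio_cols], rtol=1e-3, atol=1e-8)

    def test_murmur_raises_hf_systole_diastole_ratio(self):
        """Systolic high-band murmur must push t9_r_aSys_aDias upward."""
        twin_cfg = dict(heart_rate=80.0, seed=7)
        murmur = synth_recording(SimConfig(murmur_present=True, murmur_snr=6.0,
                                           **twin_cfg))
        silent = synth_recording(SimConfig(murmur_present=False, **twin_cfg))
        fm = ft.extract_features(murmur.samples, RATE, murmur.segmentation,
                                 murmur.demographics)
        fs = ft.extract_features(silent.samples, RATE, silent.segmentation,
                                 silent.demographics)
        assert fm["t9_r_aSys_aDias"] > fs["t9_r_aSys_aDias"]

    def test_envelope_features_nonnegative_shapes_bounded(self, clean_recording):
        rec = clean_recording
        v = ft.extract_features(rec.samples, RATE, rec.segmentation,
                                rec.demographics)
        env_cols = [f"t{k}_a" for k in range(7, 12)]
        assert (v[env_cols] >= 0).all()
        shape_cols = ft.shape_feature_names()
        assert ((v[shape_cols] >= -1 - 1e-9) & (v[shape_cols] <= 1 + 1e-9)).all()


class TestSelection:
    def _table(self, rng, n=200):
        X = pd.DataFrame(rng.standard_normal((n, 30)),
                         columns=[f"f{i}" for i in range(28)] + ["age", "weight"])
        y = (rng.random(n) < 0.5).astype(int)
        # graded, imperfect signal: f0 strongest, f2..f27 progressively weaker,
        # so many features earn importance and top-k fills before age/weight
        X["f0"] += y * 3.0
        for i in range(2, 28):
            X[f"f{i}"] += y * (1.2 - 0.03 * i)
        X["f1"] = 3.14                               # constant column
        return X, y

    def test_planted_feature_ranks_first_constant_gets_zero(self, rng):
        X, y = self._table(rng)
        result = ft.rank_and_select(X, y, k=5)
        assert result.ranking[0][0] == "f0"
        assert result.importances["f1"] == 0.0

    def test_selected_set_is_top_k_plus_age_weight(self, rng):
        X, y = self._table(rng)
        result = ft.rank_and_select(X, y, k=20)
        assert len(result.selected) == 22
        assert {"age", "weight"} <= set(result.selected)

    def test_single_class_rejected(self, rng):
        X, _ = self._table(rng)
        with pytest.raises(ValueError):
            ft.rank_and_select(X, np.zeros(len(X)))

    def test_selector_transform_round(self, rng):
        X, y = self._table(rng)
        sel = ft.ImportanceFeatureSelector(k=10).fit(X, y)
        out = sel.transform(X)
        assert list(out.columns) == sel.selected_features_
        assert len(sel.selected_features_) == 12
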