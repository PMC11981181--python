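import dataclasses

import numpy as np
import pytest
from scipy import stats

from drawscreen import cohort as cs
from drawscreen import features as ft
from drawscreen import recording_io as rio
from drawscreen import synthetic as syn
from tests.conftest import label_sheets


class TestCohortSpec:
    def test_invalid_fields_named(self):
        with pytest.raises(syn.SpecError, match="n_high"):
            syn.CohortSpec(n_high=-1).validate()
        with pytest.raises(syn.SpecError, match="srs_high_sd"):
            syn.CohortSpec(srs_high_sd=0).validate()
        with pytest.raises(syn.SpecError, match="gaze_coupling_low"):
            syn.CohortSpec(gaze_coupling_low=1.5).validate()
        with pytest.raises(syn.SpecError, match="effect_map"):
            syn.CohortSpec(effect_map={"NotAFeature": 1.0}).validate()

    def test_null_spec_is_effect_free(self):
        spec = syn.null_spec(seed=4)
        assert all(v == 0.0 for v in spec.effect_map.values())
        assert spec.gaze_coupling_high == spec.gaze_coupling_low


class TestGenerateCohort:
    def test_count_conservation(self):
        spec = syn.CohortSpec(n_high=4, n_low=6, seed=1)
        cohort, recs = syn.generate_cohort(spec)
        assert len(cohort) == 10
        assert len(recs) == 10 * 4 * 2  # 4 shapes x 2 phases each

    def test_degenerate_single_group(self):
        spec = syn.CohortSpec(n_high=0, n_low=2, shapes=("square",), seed=1)
        cohort, _ = syn.generate_cohort(spec)
        assert list(cohort["group"]) == ["low", "low"]

    def test_determinism_byte_identical(self):
        spec = syn.CohortSpec(n_high=2, n_low=3, shapes=("sun",), seed=11)
        c1, r1 = syn.generate_cohort(spec)
        c2, r2 = syn.generate_cohort(spec)
        assert c1.equals(c2)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.pressure, b.pressure)
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.gaze_x, b.gaze_x)

    def test_all_channels_in_range(self):
        spec = syn.CohortSpec(n_high=2, n_low=2, seed=5)
        _, recs = syn.generate_cohort(spec)
        for rec in recs:
            rec.validate()  # raises on any out-of-range value

    def test_group_labels_consistent_with_cutoffs(self):
        cohort, _ = syn.generate_cohort(
            syn.CohortSpec(n_high=10, n_low=10, shapes=("square",), seed=9)
        )
        for _, row in cohort.iterrows():
            assert cs.assign_group(row["sex"], row["srs2_score"]) == row["group"]

    def test_age_distribution_plausible(self):
        cohort, _ = syn.generate_cohort(
            syn.CohortSpec(n_high=30, n_low=70, shapes=("square",), seed=2)
        )
        assert cohort["age_years"].between(4.5, 5.5).all()
        assert cohort["age_years"].mean() == pytest.approx(5.05, abs=0.08)


def _constant_profile(**over):
    targets = {k: v for k, (v, _) in syn.LATENT_BASE.items()}
    targets.update(over)
    return syn.ParticipantProfile(targets=targets, coupling=0.6)


class TestGenerateDrawing:
    def test_stroke_count_matches_template(self):
        tmpl = syn.TEMPLATES["equilateral_triangle"]
        rec = syn.generate_drawing(tmpl, _constant_profile(), seed=0)
        segs = rio.segment_active_drawing(rec)
        assert len(segs) == 3

    def test_noise_free_constant_speed_and_pressure(self):
        tmpl = syn.ShapeTemplate("square", (((0.1, 0.5), (0.9, 0.5)),), 10.0)
        prof = _constant_profile(
            Mpenpressure=0.5, SDpenpressure=0.0, Mpenpressurechange=0.0,
            Mdrawingspeed=0.2, SDdrawingspeed=0.0, Mdrawingacceleration=0.0,
        )
        rec = syn.generate_drawing(tmpl, prof, seed=0)
        segs = rio.segment_active_drawing(rec)
        fv_p = ft.pressure_features([s.channel("pressure") for s in segs])
        assert fv_p == (0.5, 0.0, 0.0)
        m, sd, _ = ft.kinematics_features(
            [(s.channel("x"), s.channel("y")) for s in segs],
            [s.channel("t") for s in segs],
        )
        assert m == pytest.approx(0.2, rel=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_pen_up_gaps_have_zero_pressure(self):
        tmpl = syn.TEMPLATES["square"]
        rec = syn.generate_drawing(tmpl, _constant_profile(), seed=3)
        segs = rio.segment_active_drawing(rec)
        covered = np.zeros(len(rec), bool)
        for s in segs:
            covered[s.sl] = True
        assert (rec.pressure[~covered] == 0.0).all()


class TestGenerateGaze:
    def _drawing(self, seed=0):
        return syn.generate_drawing(
            syn.TEMPLATES["equilateral_triangle"], _constant_profile(), seed=seed
        )

    @pytest.mark.parametrize("coupling", [1.0, -1.0])
    def test_exact_linear_coupling(self, coupling):
        rec = syn.generate_gaze(self._drawing(), coupling, seed=1)
        active = rec.pressure > 0
        r = np.corrcoef(rec.gaze_x[active], rec.x[active])[0, 1]
        assert r == pytest.approx(coupling, abs=1e-12)

    def test_calibrated_intermediate_coupling(self):
        rec = syn.generate_gaze(self._drawing(), 0.5, seed=2)
        active = rec.pressure > 0
        assert active.sum() >= 200
        r = np.corrcoef(rec.gaze_x[active], rec.x[active])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_zero_coupling_uncorrelated(self):
        for seed in range(3):
            rec = syn.generate_gaze(self._drawing(seed), 0.0, seed=seed + 10)
            active = rec.pressure > 0
            r = np.corrcoef(rec.gaze_x[active], rec.x[active])[0, 1]
            assert abs(r) < 0.2

    def test_empty_drawing_rejected(self):
        rec = self._drawing()
        rec.pressure[:] = 0.0
        with pytest.raises(syn.SpecError, match="empty drawing"):
            syn.generate_gaze(rec, 0.5, seed=0)

    def test_gaze_within_range(self):
        rec = syn.generate_gaze(self._drawing(), 0.9, seed=4)
        ok = ~np.isnan(rec.gaze_x)
        assert np.all(np.abs(rec.gaze_x[ok]) <= 90.0)


class TestEffectCalibration:
    def test_planted_mean_shift_detectable(self):
        """d=2 on mean pressure with 50+50 gives t well above 5."""
        for seed in range(3):
            emap = {k: 0.0 for k in syn.LATENT_BASE}
            emap["Mpenpressure"] = 2.0
            spec = dataclasses.replace(
                syn.null_spec(seed=40 + seed), effect_map=emap,
                n_high=50, n_low=50, shapes=("equilateral_triangle",),
            )
            cohort, recs = syn.generate_cohort(spec)
            df = label_sheets(cohort, ft.extract_feature_table(recs))["equilateral_triangle"]
            t = stats.ttest_ind(
                df[df.group == "high"]["Mpenpressure"],
                df[df.group == "low"]["Mpenpressure"],
                equal_var=False,
            ).statistic
            assert t > 5.0

    def test_null_cohort_t_statistics_calibrated(self):
        """With no planted effects, group t statistics look null."""
        within = total = 0
        for seed in range(10):
            spec = dataclasses.replace(
                syn.null_spec(seed=60 + seed), n_high=15, n_low=15, shapes=("square",)
            )
            cohort, recs = syn.generate_cohort(spec)
            df = label_sheets(cohort, ft.extract_feature_table(recs))["square"]
            hi, lo = df[df.group == "high"], df[df.group == "low"]
            for f in rio.FEATURE_NAMES:
                t = stats.ttest_ind(hi[f], lo[f], equal_var=False).statistic
                total += 1
                within += abs(t) <= 3.0
        assert within / total >= 0.95
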