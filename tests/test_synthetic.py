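"""Synthetic cohort generator: AIF, curves, volumes, exact-moment mode."""

import numpy as np
import pandas as pd
import pytest

import synovadce as sv
from synovadce.synthetic import AIFShape, PainModel, Population, TreatmentEffect


class TestPopulationAIF:
    def test_zero_amplitude_gives_zero_aif(self):
        aif = sv.make_population_aif(AIFShape(peak=0.0), protocol=sv.STANDARD)
        assert np.all(aif.cp == 0.0)

    def test_causality_before_bolus(self):
        delay = sv.STANDARD.default_bolus_delay_s()
        aif = sv.make_population_aif(protocol=sv.STANDARD, bolus_delay_s=delay)
        assert np.all(aif.cp[aif.times_s < delay] == 0.0)

    def test_peak_location_and_monotone_decay(self):
        delay = 55.0
        aif = sv.make_population_aif(protocol=sv.STANDARD, bolus_delay_s=delay)
        i_peak = int(np.argmax(aif.cp))
        assert delay <= aif.times_s[i_peak] <= delay + 60.0
        assert np.all(np.diff(aif.cp[i_peak:]) <= 1e-12)

    def test_bolus_outside_window_rejected(self):
        with pytest.raises(ValueError, match="scan window"):
            sv.make_population_aif(protocol=sv.STANDARD, bolus_delay_s=1e5)

    def test_dense_grid_covers_protocol(self):
        aif = sv.make_population_aif(protocol=sv.LTR)
        assert aif.times_s[0] == 0.0
        assert aif.times_s[-1] >= sv.LTR.duration_s
        assert np.max(np.diff(aif.times_s)) <= 1.0

    def test_table_round_trip(self, tmp_path, std_aif):
        path = tmp_path / "aif.csv"
        std_aif.to_table(path)
        back = sv.AIF.from_table(path)
        assert np.allclose(back.times_s, std_aif.times_s)
        assert np.allclose(back.cp, std_aif.cp)


class TestSignalCurve:
    def test_no_uptake_constant_series(self, std_aif):
        s = sv.simulate_signal_curve(sv.ToftsParams(0.0, 0.3, 0.0), std_aif,
                                     sv.STANDARD, s0=80.0)
        assert np.allclose(s.signal, 80.0)

    def test_noiseless_precontrast_frames_equal_s0(self, std_aif):
        s = sv.simulate_signal_curve(sv.ToftsParams(0.1, 0.3, 0.02), std_aif,
                                     sv.STANDARD, s0=100.0)
        assert np.allclose(s.signal[:sv.STANDARD.precontrast_frames], 100.0)

    def test_re_late_matches_convolution_oracle(self, std_aif):
        """Noiseless RE_late equals 1 + gain * mean of the last four C_t values,
        with C_t from the trapezoidal convolution."""
        p, gain = sv.ToftsParams(0.07, 0.35, 0.03), 0.5
        s = sv.simulate_signal_curve(p, std_aif, sv.STANDARD, s0=100.0, gain=gain)
        ct = sv.extended_tofts_forward(p, std_aif, sv.STANDARD.frame_times()).ct
        expected = 1.0 + gain * np.mean(ct[-4:])
        assert sv.re_late(s, sv.baseline_signal(s)) == pytest.approx(expected, rel=1e-12)

    def test_same_seed_reproduces_series(self, std_aif):
        p = sv.ToftsParams(0.05, 0.3, 0.02)
        a = sv.simulate_signal_curve(p, std_aif, sv.STANDARD, 100.0, noise_sd=3.0, seed=9)
        b = sv.simulate_signal_curve(p, std_aif, sv.STANDARD, 100.0, noise_sd=3.0, seed=9)
        assert np.array_equal(a.signal, b.signal)


class TestCohort:
    def test_default_shape_93_subjects(self):
        _, truth = sv.simulate_cohort(n_subjects=93, seed=1)
        assert len(truth) == 186
        for col in ("volume_mm3", "rer", "re_late", "re_max", "ktrans", "ve", "koos_pain"):
            assert col in truth.columns

    def test_reproducible_and_prefix_stable(self):
        _, a = sv.simulate_cohort(n_subjects=10, seed=4)
        _, b = sv.simulate_cohort(n_subjects=10, seed=4)
        pd.testing.assert_frame_equal(a, b)
        # growing the cohort leaves earlier subjects' kinetics untouched
        _, big = sv.simulate_cohort(n_subjects=12, seed=4)
        kin = ["volume_mm3", "rer", "re_late", "re_max", "ktrans", "ve"]
        pd.testing.assert_frame_equal(
            a[["subject_id", "visit"] + kin],
            big[big["subject_id"].isin(a["subject_id"])][["subject_id", "visit"] + kin]
            .reset_index(drop=True))

    def test_null_effect_zero_standardized_change(self):
        """No treatment effect and a silent pain model: every standardized
        change is statistically indistinguishable from zero at n=500."""
        effect = TreatmentEffect(ktrans_ratio=1.0, ve_ratio=1.0, vp_ratio=1.0,
                                 volume_ratio=1.0, subject_sd_log=0.0)
        pain = PainModel(mean_change=0.0, sd_change=15.0, target_r=0.0)
        _, truth = sv.simulate_cohort(n_subjects=500, seed=8, effect=effect, pain_model=pain)
        resp = sv.responsiveness_table(truth)
        for _, row in resp.iterrows():
            se = (row["ci_high"] - row["ci_low"]) / (2 * 1.96)
            assert abs(row["estimate"]) < 3 * se

    def test_followup_ktrans_never_exceeds_baseline(self):
        subs, _ = sv.simulate_cohort(n_subjects=50, seed=2)
        for s in subs:
            assert s.tofts["followup"].ktrans <= s.tofts["baseline"].ktrans + 1e-12

    def test_protocol_mix_fraction(self):
        subs, _ = sv.simulate_cohort(n_subjects=400, seed=6, protocol_mix=16 / 93)
        frac = np.mean([s.protocol.name == "LTR" for s in subs])
        assert abs(frac - 16 / 93) < 0.06

    def test_degenerate_effect_with_correlation_target_rejected(self):
        effect = TreatmentEffect(ktrans_ratio=1.0, ve_ratio=1.0, vp_ratio=1.0,
                                 volume_ratio=1.0, subject_sd_log=0.0)
        pop = Population(ktrans_sd=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            sv.simulate_cohort(n_subjects=10, seed=0, effect=effect, population=pop,
                               pain_model=PainModel(target_r=-0.3))


class TestRender:
    def test_mask_voxels_carry_dynamic_signal(self):
        subs, _ = sv.simulate_cohort(n_subjects=2, seed=3)
        sub = subs[0]
        sub.mask_voxels["baseline"] = 10
        sub.noise_sd = 0.0
        sub.voxel_jitter_cv = 0.0
        vol, mask = sv.render_4d_volume(sub, "baseline", grid_shape=(16, 16, 4),
                                        voxel_size_mm=(1.5, 1.5, 3.0))
        varying = np.ptp(vol, axis=-1) > 1e-9
        assert varying.sum() == 10
        assert np.array_equal(varying, mask.data)

    def test_mask_volume_arithmetic(self):
        mask = sv.make_roi_mask((16, 16, 4), 100, (1.5, 1.5, 3.0))
        assert sv.synovial_volume(mask) == pytest.approx(675.0)

    def test_nifti_round_trip_identical(self, tmp_path):
        import nibabel as nib
        subs, _ = sv.simulate_cohort(n_subjects=2, seed=3)
        sub = subs[1]
        sub.mask_voxels["baseline"] = 12
        vol, mask = sv.render_4d_volume(sub, "baseline", grid_shape=(12, 12, 4))
        dyn_path, mask_path = sv.synthetic.write_nifti_pair(vol, mask, tmp_path,
                                                            sub.subject_id, "baseline")
        back = np.asarray(nib.load(dyn_path).get_fdata())
        assert np.array_equal(back, vol)
        back_mask = np.asarray(nib.load(mask_path).get_fdata()) > 0.5
        assert np.array_equal(back_mask, mask.data)

    def test_mask_too_big_for_grid_rejected(self):
        subs, _ = sv.simulate_cohort(n_subjects=2, seed=3)
        subs[0].mask_voxels["baseline"] = 10_000
        with pytest.raises(ValueError, match="fit"):
            sv.render_4d_volume(subs[0], "baseline", grid_shape=(8, 8, 2))


class TestExactMoments:
    def test_moments_reproduced_to_machine_precision(self):
        df = sv.exact_moment_cohort(93, seed=0)
        for var, per_visit in sv.STUDY_MOMENTS.items():
            for visit, (mean, sd) in per_visit.items():
                vals = df.loc[df["visit"] == visit, var]
                assert vals.mean() == pytest.approx(mean, abs=1e-10)
                assert vals.std(ddof=1) == pytest.approx(sd, abs=1e-10)

    def test_different_seeds_different_draws_same_moments(self):
        a = sv.exact_moment_cohort(50, seed=1)
        b = sv.exact_moment_cohort(50, seed=2)
        assert not np.allclose(a["re_late"], b["re_late"])
        assert a["re_late"].mean() == pytest.approx(b["re_late"].mean())
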