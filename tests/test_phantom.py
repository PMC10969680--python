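"""Phantom and cohort simulator: forward model, noise and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qdwiqc import (NoiseModel, VialSpec, default_layout,
                    make_phantom_layout, qiba_phantom_params, sigma_for_snr,
                    simulate_dwi_exam, simulate_patient_cohort,
                    simulate_repeated_exams)
from qdwiqc.phantom import GeometryError, PhantomLayout


class TestLayout:
    def test_default_central_vial_is_water_reference(self, layout):
        assert layout.central_vial.true_adc == 1100.0
        assert layout.central_vial.pvp_concentration == 0.0

    def test_default_has_13_unique_vials_one_central(self, layout):
        labels = [v.label for v in layout.vials]
        assert len(labels) == 13
        assert len(set(labels)) == 13
        assert sum(lbl == "central" for lbl in labels) == 1

    def test_zero_radius_vial_rejected(self):
        with pytest.raises((GeometryError, ValueError)):
            VialSpec("v", (10, 10), radius_mm=0.0, true_adc=1100.0)

    def test_vial_outside_grid_rejected(self):
        vial = VialSpec("central", (2.0, 2.0), radius_mm=20.0,
                        true_adc=1100.0)
        with pytest.raises(GeometryError):
            PhantomLayout((vial,), (3, 32, 32), voxel_size_mm=1.72)

    def test_overlapping_vials_rejected(self):
        a = VialSpec("central", (16.0, 12.0), 10.0, 1100.0)
        b = VialSpec("v1", (16.0, 20.0), 10.0, 900.0)
        with pytest.raises(GeometryError):
            PhantomLayout((a, b), (3, 32, 32), voxel_size_mm=1.72)

    def test_duplicate_labels_rejected(self):
        a = VialSpec("central", (40.0, 30.0), 5.0, 1100.0)
        b = VialSpec("central", (40.0, 70.0), 5.0, 900.0)
        with pytest.raises(GeometryError):
            PhantomLayout((a, b), (3, 100, 100), voxel_size_mm=1.72)

    def test_ladder_monotone_decreasing_from_water(self, layout):
        non_central = [v.true_adc for v in layout.vials
                       if v.label != "central"]
        assert all(a > b for a, b in zip(non_central, non_central[1:]))
        assert max(non_central) < 1100.0


class TestForwardModel:
    def test_noiseless_signal_is_exact_mono_exponential(self, layout,
                                                        qiba_params):
        exam = simulate_dwi_exam(layout, qiba_params, NoiseModel(), seed=0)
        b = np.asarray(qiba_params.b_values)
        for vial in layout.vials:
            mask = layout.vial_mask(vial.label)
            expected = vial.s0 * np.exp(-b * vial.true_adc * 1e-6)
            observed = exam.signal[mask]
            assert np.allclose(observed, expected[None, :], rtol=1e-12)

    def test_closed_form_voxel_value_at_b1000(self, layout, qiba_params):
        exam = simulate_dwi_exam(layout, qiba_params, NoiseModel(), seed=0)
        mask = layout.vial_mask("central")
        # s0=1000, ADC=1100 um^2/s, b=1000 -> 1000*exp(-1.1)
        assert exam.b_volume(1000.0)[mask] == pytest.approx(
            1000.0 * np.exp(-1.1), abs=1e-9)

    def test_b0_equals_s0_in_vials(self, layout, qiba_params):
        exam = simulate_dwi_exam(layout, qiba_params, NoiseModel(), seed=0)
        mask = layout.vial_mask("central")
        assert np.all(exam.b_volume(0.0)[mask] == 1000.0)

    def test_same_seed_is_bit_identical(self, mc_layout, qiba_params):
        noise = NoiseModel("rician", 20.0)
        a = simulate_dwi_exam(mc_layout, qiba_params, noise, seed=42)
        b = simulate_dwi_exam(mc_layout, qiba_params, noise, seed=42)
        assert np.array_equal(a.signal, b.signal)

    def test_rician_positive_bias(self, rng):
        """Magnitude reconstruction biases the mean signal upward."""
        s_true, sigma = 100.0, 40.0
        n1 = rng.normal(0, sigma, 200_000)
        n2 = rng.normal(0, sigma, 200_000)
        mc_mean = np.mean(np.sqrt((s_true + n1) ** 2 + n2 ** 2))
        assert mc_mean > s_true
        # simulator agrees with the direct Monte-Carlo construction
        layout = make_phantom_layout(n_vials=1, grid_shape=(1, 64, 64),
                                     vial_radius_mm=40.0, s0=s_true)
        params = qiba_phantom_params(nex=1, b_values=(0.0,))
        exam = simulate_dwi_exam(layout, params,
                                 NoiseModel("rician", sigma), seed=3)
        vals = exam.signal[layout.vial_mask("central")]
        assert np.mean(vals) == pytest.approx(mc_mean, rel=0.02)
        assert np.mean(vals) > s_true

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(min_value=0.1, max_value=50.0))
    def test_scale_equivariance_of_noiseless_signal(self, c):
        params = qiba_phantom_params()
        base = make_phantom_layout(n_vials=5, grid_shape=(1, 64, 64),
                                   adc_ladder=(900.0, 600.0, 400.0, 250.0),
                                   ring_radii_mm=(32.0,), s0=1000.0)
        scaled = make_phantom_layout(n_vials=5, grid_shape=(1, 64, 64),
                                     adc_ladder=(900.0, 600.0, 400.0, 250.0),
                                     ring_radii_mm=(32.0,), s0=1000.0 * c)
        a = simulate_dwi_exam(base, params, NoiseModel(), seed=0)
        b = simulate_dwi_exam(scaled, params, NoiseModel(), seed=0)
        assert np.allclose(b.signal, c * a.signal, rtol=1e-12)


class TestRepeatedExams:
    def test_noiseless_zero_drift_repeats_identical(self, layout,
                                                    qiba_params):
        series = simulate_repeated_exams(layout, qiba_params, NoiseModel(),
                                         n_repeats=4, inter_exam_cv=0.0,
                                         seed=0)
        assert len(series) == 4
        assert [s.repeat_index for s in series] == [0, 1, 2, 3]
        for s in series[1:]:
            assert np.array_equal(s.signal, series[0].signal)

    def test_single_repeat_rejected(self, layout, qiba_params):
        with pytest.raises(ValueError):
            simulate_repeated_exams(layout, qiba_params, n_repeats=1)

    def test_drift_changes_s0_between_repeats(self, mc_layout, qiba_params):
        series = simulate_repeated_exams(mc_layout, qiba_params,
                                         NoiseModel(), n_repeats=3,
                                         inter_exam_cv=0.05, seed=5)
        b0_means = [s.b_volume(0.0)[mc_layout.vial_mask("central")].mean()
                    for s in series]
        assert len(set(np.round(b0_means, 6))) > 1


class TestSigmaForSnr:
    def test_difference_method_snr_matches_target(self, mc_layout,
                                                  qiba_params):
        """Measured b0 SNR lands near the sigma-implied prediction."""
        from qdwiqc import make_noise_image, snr

        target = 100.0
        sigma = sigma_for_snr(1000.0, target, nex=qiba_params.nex)
        noise = NoiseModel("rician", sigma)
        vals = []
        for seed in range(20):
            reps = simulate_repeated_exams(mc_layout, qiba_params, noise,
                                           n_repeats=2, seed=seed)
            img = make_noise_image(reps[0].b_volume(0.0),
                                   reps[1].b_volume(0.0))
            vals.append(snr(reps[0].b_volume(0.0), img,
                            mc_layout.vial_mask("central")))
        assert np.mean(vals) == pytest.approx(target, rel=0.15)


class TestPatientCohort:
    def test_zero_wcv_gives_identical_scans_per_patient(self):
        cohort = simulate_patient_cohort(n_patients=5, scans_per_patient=3,
                                         within_subject_cv=0.0, seed=0)
        for (_, _), grp in cohort.records.groupby(["patient_id", "tissue"]):
            assert grp["roi_mean_adc"].nunique() == 1

    def test_zero_cvs_reproduce_reference_input(self):
        cohort = simulate_patient_cohort(
            n_patients=3, scans_per_patient=2,
            tissue_means={"csf": 3037.7}, within_subject_cv=0.0,
            between_subject_cv=0.0, seed=0)
        assert np.allclose(cohort.records["roi_mean_adc"], 3037.7)

    def test_nonpositive_tissue_mean_rejected(self):
        with pytest.raises(ValueError):
            simulate_patient_cohort(tissue_means={"white_matter": -5.0})

    def test_csv_round_trip(self, tmp_path):
        cohort = simulate_patient_cohort(n_patients=4, seed=2)
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        from qdwiqc import PatientScanSet

        back = PatientScanSet.from_csv(path)
        assert np.allclose(back.records["roi_mean_adc"],
                           cohort.records["roi_mean_adc"])
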