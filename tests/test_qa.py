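"""Range metrics, profile comparison, SOBP synthesis, characterization."""

import numpy as np
import pytest
from scipy.optimize import brentq

from scintqa import BC408, QuenchModel
from scintqa.profiles import DepthProfile
from scintqa.qa import (closed_loop, compare_profiles, characterization_suite,
                        distal_range, peak_plateau, profile_report,
                        sobp_weights_flat, synthesize_sobp)

from scintqa import PMMA, degrade_energy

# component energies from the clinical range modulator: 0.84 mm PMMA steps
SOBP_ENERGIES = sorted(degrade_energy(60.0, PMMA, k * 0.84) for k in range(13))
SOBP_KW = dict(n_protons=2500)


def triangle(peak_z=10.0, half=4.0, n=400):
    z = np.linspace(0, 20, n)
    v = np.clip(1.0 - np.abs(z - peak_z) / half, 0.0, None)
    return DepthProfile(z, v, "dose")


class TestDistalRange:
    def test_triangle_half_height_by_hand(self):
        # distal edge of a triangle peaking at 10 with half-width 4:
        # the 50% point sits at 10 + 2 = 12 mm
        p = triangle()
        assert distal_range(p, 0.5) == pytest.approx(12.0, abs=0.06)

    def test_level_ordering(self, sim60):
        dose, _ = sim60
        assert distal_range(dose, 0.9) <= distal_range(dose, 0.5)

    def test_translation_equivariance(self, sim60):
        dose, _ = sim60
        dz = 3.375
        shifted = DepthProfile(dose.depths + dz, dose.values, "dose")
        for level in (0.9, 0.8, 0.5):
            assert distal_range(shifted, level) - distal_range(dose, level) \
                == pytest.approx(dz, abs=1e-9)

    def test_against_root_finding_oracle(self, sim60):
        dose, _ = sim60
        thr = 0.9 * dose.values.max()
        i_peak = int(np.argmax(dose.values))

        def f(z):
            return np.interp(z, dose.depths, dose.values) - thr

        z_peak = dose.depths[i_peak]
        # bracket the first distal crossing on the grid, then solve exactly
        below = np.nonzero((dose.depths > z_peak) & (dose.values < thr))[0][0]
        oracle = brentq(f, dose.depths[below - 1], dose.depths[below],
                        xtol=1e-12)
        assert distal_range(dose, 0.9) == pytest.approx(oracle, abs=1e-9)

    def test_truncated_profile_rejected(self):
        z = np.linspace(0, 5, 50)
        rising = DepthProfile(z, z + 1.0, "dose")
        with pytest.raises(ValueError):
            distal_range(rising, 0.9)


class TestPeakPlateau:
    def test_flat_profile_is_one(self):
        z = np.linspace(0, 20, 100)
        p = DepthProfile(z, np.ones_like(z), "dose")
        assert peak_plateau(p) == 1.0

    def test_scale_invariance(self, sim60):
        dose, _ = sim60
        scaled = DepthProfile(dose.depths, 13.0 * dose.values, "dose")
        assert peak_plateau(scaled) == pytest.approx(peak_plateau(dose),
                                                     rel=1e-12)

    def test_window_outside_grid_rejected(self, sim60):
        dose, _ = sim60
        with pytest.raises(ValueError):
            peak_plateau(dose, plateau_window=(500.0, 600.0))


class TestCompareProfiles:
    def test_self_comparison_passes_with_zero_deltas(self, sim60):
        dose, _ = sim60
        report = compare_profiles(dose, dose)
        assert report.all_pass
        assert all(abs(c["delta"]) < 1e-9 for c in report.comparisons[:2])

    def test_small_shift_fails_range_tolerance(self, sim60):
        dose, _ = sim60
        shifted = DepthProfile(dose.depths + 0.3, dose.values, "dose")
        report = compare_profiles(shifted, dose,
                                  tolerances={"range_mm": 0.2})
        range_check = [c for c in report.comparisons
                       if c["metric"] == "range_d90_mm"][0]
        assert not range_check["passed"]
        assert range_check["delta"] == pytest.approx(0.3, abs=1e-6)

    def test_corrected_measurement_passes_study_tolerances(self, scene60):
        loop = closed_loop(scene60)
        report = compare_profiles(loop["corrected"], scene60.truth_dose)
        range_check, pp_check = report.comparisons[:2]
        assert range_check["passed"] and pp_check["passed"]

    def test_no_overlap_rejected(self, sim60):
        dose, _ = sim60
        far = DepthProfile(dose.depths + 1e4, dose.values, "dose")
        with pytest.raises(ValueError):
            compare_profiles(far, dose)


class TestSobp:
    def test_single_component_identity(self):
        from scintqa.qa import pristine_curves

        doses, _ = pristine_curves([60.0], BC408, **SOBP_KW)
        sobp = synthesize_sobp([60.0], [1.0], BC408, **SOBP_KW)
        np.testing.assert_array_equal(sobp.values, doses[0].values)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            synthesize_sobp([60.0, 55.0], [1.0], BC408, **SOBP_KW)

    def test_flat_weights_give_flat_modulation(self):
        w, flatness = sobp_weights_flat(SOBP_ENERGIES, (18.0, 28.0), BC408,
                                        **SOBP_KW)
        assert flatness < 0.03
        sobp = synthesize_sobp(SOBP_ENERGIES, w, BC408, **SOBP_KW)
        z = sobp.depths
        sel = (z >= 18.0) & (z <= 28.0)
        mod = sobp.values[sel]
        assert np.abs(mod / mod.mean() - 1).max() < 0.05

    def test_flatness_improves_with_more_components(self):
        flats = []
        for k in (3, 5, 7):
            _, f = sobp_weights_flat(SOBP_ENERGIES[-k:], (22.0, 28.0), BC408,
                                     **SOBP_KW)
            flats.append(f)
        assert flats[2] <= flats[1] <= flats[0]

    def test_sobp_distal_range_set_by_deepest_component(self):
        from scintqa.qa import pristine_curves

        w, _ = sobp_weights_flat(SOBP_ENERGIES, (18.0, 28.0), BC408, **SOBP_KW)
        sobp = synthesize_sobp(SOBP_ENERGIES, w, BC408, **SOBP_KW)
        doses, _ = pristine_curves(tuple(SOBP_ENERGIES), BC408, **SOBP_KW)
        deepest = doses[-1]
        assert abs(distal_range(sobp, 0.9) - distal_range(deepest, 0.9)) <= 0.5

    def test_quenching_tilts_sobp_downward_distally(self):
        dose, light = synthesize_sobp(SOBP_ENERGIES, np.ones(len(SOBP_ENERGIES)),
                                      BC408, quench=QuenchModel(0.154),
                                      **SOBP_KW)
        z = dose.depths
        prox = (z >= 18.0) & (z <= 20.0)
        dist = (z >= 26.0) & (z <= 28.0)
        ratio = light.values / np.maximum(dose.values, 1e-300)
        assert ratio[dist].mean() < ratio[prox].mean()

    def test_duplicate_energies_warn(self):
        with pytest.warns(UserWarning):
            sobp_weights_flat([60.0, 60.0], (20.0, 25.0), BC408, **SOBP_KW)

    def test_interval_beyond_range_rejected(self):
        with pytest.raises(ValueError):
            sobp_weights_flat([50.0, 60.0], (20.0, 60.0), BC408, **SOBP_KW)


class TestCharacterization:
    def test_noiseless_series_are_perfect(self, sim60):
        from dataclasses import replace

        from scintqa.synthetic_data import (NoiseSpec, ScenePhantom,
                                            render_scene)
        from scintqa import BeamSpec

        ph = ScenePhantom(beam=BeamSpec(n_protons=8000, rng_seed=8),
                          rng_seed=60, noise=NoiseSpec(0, 0, 0),
                          psf_sigma_px=0.0, tail_amplitude=0.0)
        repeats = [render_scene(replace(ph, rng_seed=60 + i), truth=sim60)
                   for i in range(3)]
        doses = [render_scene(replace(ph, dose_gy=d, rng_seed=70), truth=sim60)
                 for d in (0.45, 4.5, 9.0)]
        with pytest.warns(UserWarning):     # energy + rate series skipped
            report = characterization_suite(repeatability=repeats,
                                            dose_series=doses)
        assert report["sections"]["repeatability"]["cv"] < 1e-9
        assert report["sections"]["dose_linearity"]["r_squared"] > 0.999999

    def test_study_noise_repeatability_below_0p8_percent(self, sim60):
        from dataclasses import replace

        from scintqa.synthetic_data import ScenePhantom, render_scene
        from scintqa import BeamSpec

        ph = ScenePhantom(beam=BeamSpec(n_protons=8000, rng_seed=8),
                          rng_seed=80)
        repeats = [render_scene(replace(ph, rng_seed=80 + i), truth=sim60)
                   for i in range(5)]
        with pytest.warns(UserWarning):
            report = characterization_suite(repeatability=repeats)
        assert report["sections"]["repeatability"]["cv"] <= 0.008

    def test_report_serializes(self, sim60, tmp_path):
        import json

        from scintqa.synthetic_data import ScenePhantom, render_scene
        from scintqa import BeamSpec

        ph = ScenePhantom(beam=BeamSpec(n_protons=8000, rng_seed=8), rng_seed=90)
        r = render_scene(ph, truth=sim60)
        with pytest.warns(UserWarning):
            characterization_suite(repeatability=[r, r],
                                   json_path=tmp_path / "report.json")
        loaded = json.loads((tmp_path / "report.json").read_text())
        assert "repeatability" in loaded["sections"]


class TestReportValidation:
    def test_report_orders_ranges(self, sim60):
        dose, _ = sim60
        rep = profile_report(dose)
        assert rep.range_d90 <= rep.range_d80 <= rep.range_d50
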