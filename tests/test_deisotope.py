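import numpy as np
import pytest

from isopick.deisotope import (FitParams, choose_reference_model,
                               extract_peak_list, fit_score, prune_tid,
                               render_tid)
from isopick.detect import DetectionParams, build_threshold, find_peaks
from isopick.io import ReplicateSet
from isopick.isotopes import FWHM_OVER_SIGMA, ISOTOPE_SPACING
from isopick.preprocess import preprocess
from isopick.simulate import SpeciesSpec, make_grid, simulate_spectrum


class TestReferenceModel:
    @pytest.mark.parametrize("mz,rp,z,expected", [
        (2000.0, 10000.0, 1, "monoisotopic"),   # 0.2 < 1
        (20000.0, 500.0, 1, "most_likely"),     # 40 >= 1
        (1500.0, 3000.0, 2, "most_likely"),     # 0.5 vs 0.5: strict < fails
    ])
    def test_resolvability_rule(self, mz, rp, z, expected):
        assert choose_reference_model(mz, z, rp) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            choose_reference_model(-1.0, 1, 1000.0)


class TestPrune:
    def test_keeps_contiguous_significant_run(self):
        k0, kept = prune_tid(np.array([1e-5, 0.5, 1.0, 0.3, 1e-6]), ratio=1e-3)
        assert k0 == 1
        assert np.allclose(kept, [0.5, 1.0, 0.3])

    def test_all_pruned_rejected(self):
        with pytest.raises(ValueError):
            prune_tid(np.array([0.0, 0.0]))


class TestRender:
    def test_sigma_formula(self):
        assert 1000.0 / (2.35482 * 1000.0) == pytest.approx(0.42466, abs=1e-5)
        assert FWHM_OVER_SIGMA == pytest.approx(2.35482, abs=1e-5)

    def test_single_peak_is_closed_form_gaussian(self):
        grid = np.linspace(999.0, 1001.0, 2001)
        curve, positions, sticks, scale = render_tid(
            np.array([1.0]), 1, 1000.0, 50.0, 1000.0, grid, baseline_offset=5.0)
        sigma = 1000.0 / (FWHM_OVER_SIGMA * 1000.0)
        expected = 5.0 + 45.0 * np.exp(-((grid - 1000.0) ** 2) / (2 * sigma**2))
        assert np.max(np.abs(curve - expected)) < 1e-9

    def test_charge_two_halves_position_spacing(self):
        grid = np.linspace(998.0, 1004.0, 4001)
        _, positions, _, _ = render_tid(np.array([1.0, 0.8, 0.4]), 2, 1000.0,
                                        10.0, 5000.0, grid, 0.0)
        assert np.allclose(np.diff(positions), ISOTOPE_SPACING / 2, atol=1e-12)

    def test_reference_outside_tid_rejected(self):
        with pytest.raises(ValueError):
            render_tid(np.array([1.0]), 1, 1000.0, 10.0, 1000.0,
                       np.linspace(999, 1001, 100), 0.0, k_ref=3)


class TestScore:
    def test_perfect_fit_scores_zero(self):
        curve = np.array([1.0, 2.0, 3.0])
        assert fit_score(curve, curve.copy(), [0, 1, 2], np.ones(3), 2.0, 1, 1) == 0.0

    def test_single_point_normalized_difference(self):
        score = fit_score(np.array([1.0]), np.array([0.6]), [0], np.ones(1),
                          ref_intensity=1.0, z=1, z_ref=1)
        assert score == pytest.approx(0.4, abs=1e-12)

    def test_weight_scaling_invariance(self):
        curve = np.array([1.0, 0.5, 0.2])
        spec = np.array([0.9, 0.6, 0.1])
        w = np.array([1.0, 2.0, 0.5])
        s1 = fit_score(curve, spec, [0, 1, 2], w, 1.0, 1, 1)
        s2 = fit_score(curve, spec, [0, 1, 2], 2 * w, 1.0, 1, 1)
        assert s1 == pytest.approx(s2, abs=1e-14)

    def test_zero_weights_warn_and_score_zero(self):
        with pytest.warns(UserWarning):
            s = fit_score(np.array([1.0]), np.array([0.0]), [0], np.zeros(1),
                          1.0, 1, 1)
        assert s == 0.0

    def test_esi_penalty_inflates_low_charge(self):
        args = (np.array([1.0, 0.5]), np.array([0.8, 0.4]), [0, 1], np.ones(2), 1.0)
        base_z1 = fit_score(*args, 1, 10, esi_mode=True, charge_prior_lambda=0.1)
        base_z10 = fit_score(*args, 10, 10, esi_mode=True, charge_prior_lambda=0.1)
        assert base_z1 > base_z10


class TestExtraction:
    def _extract(self, species, rp, grid, tables, models, z_max, noise=0.0,
                 seed=None, preprocess_first=False):
        spec, truth = simulate_spectrum(species, rp, grid, noise_sigma=noise,
                                        seed=seed, tables=tables)
        if preprocess_first:
            spec = preprocess(spec)
        rs = ReplicateSet(spec.mz, spec.intensity[:, None])
        det = DetectionParams(rp_in=rp, z_max=z_max, rp_est=rp)
        entries = extract_peak_list(rs, det, FitParams(), tables, models)
        return entries, rs

    def test_single_species_exact_recovery(self, ave_models):
        tables, models = ave_models
        grid = make_grid(1500, 2500, 10000)
        entries, _ = self._extract([SpeciesSpec(2000.0, 1, 100.0)], 10000, grid,
                                   tables, models, z_max=2)
        assert len(entries) == 1
        assert entries[0].charge == 1
        assert abs(entries[0].monoisotopic_mass - 2000.0) < 0.01

    def test_charge_two_identified_from_spacing(self, ave_models):
        tables, models = ave_models
        grid = make_grid(800, 1300, 10000)
        entries, _ = self._extract([SpeciesSpec(2000.0, 2, 100.0)], 10000, grid,
                                   tables, models, z_max=2)
        assert len(entries) == 1
        assert entries[0].charge == 2
        assert abs(entries[0].monoisotopic_mass - 2000.0) < 0.05

    def test_all_entries_below_score_threshold_and_in_range(self, ave_models):
        tables, models = ave_models
        species = [SpeciesSpec(1200.0, 1, 120.0), SpeciesSpec(1800.0, 2, 100.0)]
        grid = make_grid(700, 2500, 10000)
        spec, _ = simulate_spectrum(species, 10000, grid, noise_sigma=8.0,
                                    seed=0, tables=tables)
        spec = preprocess(spec)
        rs = ReplicateSet(spec.mz, spec.intensity[:, None])
        det = DetectionParams(rp_in=10000, z_max=2, rp_est=10000)
        fitp = FitParams()
        entries = extract_peak_list(rs, det, fitp, tables, models)
        assert entries, "expected at least the two real species"
        for e in entries:
            assert e.score < fitp.score_threshold
            assert 0 < e.monoisotopic_mass <= det.z_max * grid[-1]
            assert e.intensity > 0

    def test_representative_never_negative_after_subtraction(self, ave_models):
        tables, models = ave_models
        grid = make_grid(700, 2500, 10000)
        species = [SpeciesSpec(1200.0, 1, 120.0), SpeciesSpec(1800.0, 2, 100.0)]
        _, rs = self._extract(species, 10000, grid, tables, models, z_max=2,
                              noise=8.0, seed=1, preprocess_first=True)
        assert rs.representative.min() >= 0.0

    def test_noise_only_spectrum_yields_sparse_output(self, ave_models):
        # the mu+2sigma threshold admits a few percent of noise maxima;
        # only those can become (false) entries
        tables, models = ave_models
        rng = np.random.default_rng(5)
        mz = np.linspace(1000, 1400, 40000)
        rs = ReplicateSet(mz, rng.normal(20, 3, mz.size)[:, None])
        det = DetectionParams(rp_in=5000, z_max=1, rp_est=5000)
        peaks = find_peaks(rs.representative_spectrum(), 5000)
        thr = build_threshold(peaks, rs.representative_spectrum())
        entries = extract_peak_list(rs, det, FitParams(), tables, models,
                                    peaks=peaks, threshold=thr)
        assert len(entries) <= 0.1 * len(peaks)

    def test_low_resolution_double_model(self, ave_models_170k):
        tables, models = ave_models_170k
        grid = make_grid(18000, 22000, 500)
        entries, _ = self._extract([SpeciesSpec(20000.0, 1, 100.0)], 500, grid,
                                   tables, models, z_max=1)
        assert len(entries) >= 1
        best = min(entries, key=lambda e: abs(e.monoisotopic_mass - 20000.0))
        assert abs(best.monoisotopic_mass - 20000.0) < 1.5
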