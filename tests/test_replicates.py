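import numpy as np
import pytest

from isopick.detect import Peak
from isopick.io import ReplicateSet
from isopick.isotopes import ISOTOPE_SPACING
from isopick.replicates import (align_replicates, correlation_weights,
                                overlap_aware_removal)
from isopick.simulate import SpeciesSpec, make_grid, simulate_replicates


def _apply_shifts(rs, shifts):
    n = rs.grid.size
    for j, s in enumerate(shifts):
        col = rs.matrix[:, j].copy()
        out = np.zeros(n)
        if s > 0:
            out[s:] = col[:n - s]
        elif s < 0:
            out[:s] = col[-s:]
        else:
            out = col
        rs.matrix[:, j] = out
    rs.recompute_representative()


class TestCorrelationWeights:
    def test_identical_replicates_fall_back_to_one(self):
        rs = ReplicateSet(np.arange(100.0), np.ones((100, 5)))
        ref = Peak(10.0, 1.0, 10)
        with pytest.warns(UserWarning):
            w = correlation_weights(rs, ref, np.array([20.0, 30.0]))
        assert np.all(w == 1.0)

    def test_requires_three_replicates(self):
        rs = ReplicateSet(np.arange(10.0), np.ones((10, 2)))
        with pytest.raises(ValueError):
            correlation_weights(rs, Peak(1.0, 1.0, 1), np.array([2.0]))

    def test_negative_correlation_clamped_to_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        matrix = np.vstack([x, -x, rng.normal(0, 1, 30)])
        rs = ReplicateSet(np.arange(3.0), matrix)
        w = correlation_weights(rs, Peak(0.0, 1.0, 0), np.array([1.0]))
        assert w[0] == 0.0

    def test_overlapping_species_get_low_foreign_weights(self, ave_models):
        tables, _ = ave_models
        species = [SpeciesSpec(2000.0, 1, 100.0), SpeciesSpec(2003.0, 1, 80.0)]
        grid = make_grid(1950, 2070, 10000)
        rs, truth = simulate_replicates(species, 10000, grid, 30,
                                        intensity_cv=0.4, noise_sigma=0.5,
                                        seed=7, tables=tables)
        apex = truth["species"].most_likely_mz[0]
        gi = int(np.argmin(np.abs(grid - apex)))
        ref = Peak(float(grid[gi]), float(rs.representative[gi]), gi)
        own = apex + np.array([-1.0, 1.0]) * ISOTOPE_SPACING
        foreign = truth["species"].most_likely_mz[1] + \
            np.array([1.0, 2.0]) * ISOTOPE_SPACING
        assert np.all(correlation_weights(rs, ref, own) > 0.8)
        assert np.all(correlation_weights(rs, ref, foreign) < 0.3)

    def test_invariant_to_global_replicate_scaling(self, ave_models):
        tables, _ = ave_models
        grid = make_grid(1950, 2070, 10000)
        rs, truth = simulate_replicates([SpeciesSpec(2000.0, 1, 100.0)], 10000,
                                        grid, 10, intensity_cv=0.3,
                                        noise_sigma=0.0, seed=3, tables=tables)
        apex = truth["species"].most_likely_mz[0]
        gi = int(np.argmin(np.abs(grid - apex)))
        ref = Peak(float(grid[gi]), float(rs.representative[gi]), gi)
        pos = apex + np.array([-1.0, 1.0]) * ISOTOPE_SPACING
        w1 = correlation_weights(rs, ref, pos)
        scaled = ReplicateSet(rs.grid, rs.matrix * np.linspace(1, 5, 10)[None, :])
        w2 = correlation_weights(scaled, ref, pos)
        assert np.allclose(w1, w2, atol=1e-9)


class TestOverlapRemoval:
    def _replicates(self, seed=0):
        rng = np.random.default_rng(seed)
        n, m = 50, 30
        matrix = rng.normal(10, 0.1, (n, m))
        driver = rng.normal(0, 1, m)
        matrix[10, :] += 5 * driver          # reference peak
        matrix[20, :] += 5 * driver          # co-varying satellite
        matrix[30, :] += 5 * rng.normal(0, 1, m)  # independent species
        return ReplicateSet(np.arange(float(n)), matrix)

    def test_covarying_satellite_removed_independent_kept(self):
        rs = self._replicates()
        ref = Peak(10.0, float(rs.representative[10]), 10)
        cands = [Peak(20.0, 1.0, 20), Peak(30.0, 1.0, 30)]
        kept = overlap_aware_removal(cands, ref, rs, corr_cut=0.8)
        assert [c.grid_index for c in kept] == [30]

    def test_unattainable_cut_removes_nothing(self):
        rs = self._replicates()
        ref = Peak(10.0, 1.0, 10)
        cands = [Peak(20.0, 1.0, 20), Peak(30.0, 1.0, 30)]
        kept = overlap_aware_removal(cands, ref, rs, corr_cut=1.01)
        assert len(kept) == 2


class TestAlignment:
    def _gaussian_replicates(self, tables, m=3, seed=11):
        grid = make_grid(1950, 2070, 10000)
        rs, _ = simulate_replicates([SpeciesSpec(2000.0, 1, 100.0)], 10000,
                                    grid, m, intensity_cv=0.0, noise_sigma=0.0,
                                    seed=seed, tables=tables)
        return rs

    def test_known_shifts_recovered_exactly(self, ave_models):
        tables, _ = ave_models
        rs = self._gaussian_replicates(tables)
        applied = [2, -1, 0]
        _apply_shifts(rs, applied)
        recovered = align_replicates(rs, (0, rs.grid.size), max_shift=5)
        assert list(recovered) == [-2, 1, 0]

    def test_aligned_replicates_untouched(self, ave_models):
        tables, _ = ave_models
        rs = self._gaussian_replicates(tables)
        before = rs.representative.copy()
        shifts = align_replicates(rs, (0, rs.grid.size), max_shift=5)
        assert np.all(shifts == 0)
        assert np.allclose(rs.representative, before, atol=0)

    def test_mean_correlation_never_decreases(self, ave_models):
        tables, _ = ave_models
        grid = make_grid(1950, 2070, 10000)
        for seed in range(5):
            rs, _ = simulate_replicates([SpeciesSpec(2000.0, 1, 100.0)], 10000,
                                        grid, 6, jitter_sigma=1.5,
                                        intensity_cv=0.2, noise_sigma=0.5,
                                        seed=seed, tables=tables)
            m = rs.n_replicates
            pre = np.mean([np.corrcoef(rs.matrix[:, j], rs.representative)[0, 1]
                           for j in range(m)])
            align_replicates(rs, (0, rs.grid.size), max_shift=6)
            post = np.mean([np.corrcoef(rs.matrix[:, j], rs.representative)[0, 1]
                            for j in range(m)])
            assert post >= pre - 1e-9

    def test_alignment_sharpens_representative(self, ave_models):
        # FWHM of a known peak after alignment never exceeds the jittered one
        tables, _ = ave_models
        grid = make_grid(1950, 2070, 10000)

        def fwhm_points(rep):
            half = rep.max() / 2
            return int(np.sum(rep >= half))

        worse = 0
        for seed in range(10):
            rs, _ = simulate_replicates([SpeciesSpec(2000.0, 1, 100.0)], 10000,
                                        grid, 8, jitter_sigma=2.0,
                                        intensity_cv=0.1, noise_sigma=0.2,
                                        seed=seed, tables=tables)
            before = fwhm_points(rs.representative)
            align_replicates(rs, (0, rs.grid.size), max_shift=8)
            after = fwhm_points(rs.representative)
            worse += after > before
        assert worse == 0

    def test_short_region_skipped_with_warning(self, ave_models):
        tables, _ = ave_models
        rs = self._gaussian_replicates(tables)
        with pytest.warns(UserWarning):
            shifts = align_replicates(rs, (0, 5), max_shift=10)
        assert np.all(shifts == 0)
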