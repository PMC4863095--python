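"""Mixture fitting, normalized RMS error and the component-library grid."""

import numpy as np
import pytest

from codespectrum import (
    build_component_library,
    fit_mixture,
    grid_fit,
    mix_spectrum,
    normalized_rms,
    synthesize_target,
)
from codespectrum.codes import N_CODES
from codespectrum.fitting import fit_mixture_grid_oracle, ms_to_bins


def random_components(rng, k=4, sparse=False):
    comps = rng.random((N_CODES, k)) * 10
    if sparse:
        comps *= rng.random((N_CODES, k)) < 0.4
    return comps


class TestMsToBins:
    @pytest.mark.parametrize("ms,bins", [(5.5, 55), (8.0, 80), (10.0, 100), (0.5, 5)])
    def test_conversion(self, ms, bins):
        assert ms_to_bins(ms) == bins

    def test_non_integral_rejected(self):
        with pytest.raises(ValueError):
            ms_to_bins(0.55)


class TestNormalizedRms:
    def test_identical_spectra_zero(self, rng):
        t = rng.random(N_CODES)
        assert normalized_rms(t, t) == 0.0

    def test_scale_invariance(self, rng):
        t = rng.random(N_CODES) + 0.1
        assert normalized_rms(3.7 * t, t) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_vs_point_mass_hand_value(self):
        # s = (1/21,...), t = e_1: direct evaluation of the formula
        sim = np.ones(N_CODES)
        target = np.zeros(N_CODES)
        target[0] = 5.0
        n = N_CODES
        num = np.sqrt(((1 / n - 1) ** 2 + (n - 1) * (1 / n) ** 2) / n)
        den = np.sqrt(1 / n)
        assert normalized_rms(sim, target) == pytest.approx(num / den, rel=1e-12)

    def test_all_zero_target_rejected(self):
        with pytest.raises(ValueError):
            normalized_rms(np.ones(N_CODES), np.zeros(N_CODES))


class TestMixSpectrum:
    def test_point_mass_returns_normalized_component(self, rng):
        comps = random_components(rng)
        q = np.array([0.0, 0.0, 1.0, 0.0])
        expected = comps[:, 2] / comps[:, 2].sum()
        assert np.allclose(mix_spectrum(q, comps), expected)

    def test_uniform_pair_is_elementwise_mean(self, rng):
        comps = random_components(rng, k=2)
        norm = comps / comps.sum(axis=0)
        got = mix_spectrum(np.array([0.5, 0.5]), comps)
        assert np.allclose(got, norm.mean(axis=1))

    def test_convexity_bounds(self, rng):
        comps = random_components(rng, k=5)
        norm = comps / comps.sum(axis=0)
        for _ in range(20):
            q = rng.dirichlet(np.ones(5))
            mix = mix_spectrum(q, comps)
            assert np.all(mix >= norm.min(axis=1) - 1e-12)
            assert np.all(mix <= norm.max(axis=1) + 1e-12)

    def test_simplex_violation_rejected(self, rng):
        comps = random_components(rng)
        with pytest.raises(ValueError):
            mix_spectrum(np.array([0.5, 0.5, 0.5, -0.5]), comps)


class TestFitMixture:
    def test_exact_component_recovered_with_zero_error(self, rng):
        comps = random_components(rng, k=6)
        q, err = fit_mixture(comps[:, 3], comps)
        assert err == pytest.approx(0.0, abs=1e-9)
        assert q[3] == pytest.approx(1.0, abs=0.02)

    def test_constructed_mixture_recovered(self, rng):
        comps = random_components(rng, k=8, sparse=True)
        norm = comps / comps.sum(axis=0)
        true_q = np.zeros(8)
        true_q[[0, 7]] = 0.5
        target = norm @ true_q
        q, err = fit_mixture(target, comps)
        assert np.all(np.abs(q - true_q) < 0.05)
        assert err < 0.02

    def test_identical_components_tie_broken_uniform(self):
        comps = np.tile(np.arange(1.0, N_CODES + 1)[:, None], (1, 4))
        q, err = fit_mixture(np.arange(1.0, N_CODES + 1), comps)
        assert np.allclose(q, 0.25)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_never_worse_than_any_vertex(self, rng):
        for trial in range(5):
            comps = random_components(rng, k=5, sparse=True)
            target = rng.random(N_CODES)
            _, err = fit_mixture(target, comps)
            for j in range(5):
                q = np.zeros(5)
                q[j] = 1.0
                assert err <= normalized_rms(mix_spectrum(q, comps), target) + 1e-9

    def test_matches_exhaustive_simplex_oracle(self, rng):
        for trial in range(3):
            comps = random_components(rng, k=4)
            target = rng.random(N_CODES)
            _, err = fit_mixture(target, comps)
            _, oracle_err = fit_mixture_grid_oracle(target, comps, step=0.1)
            assert err <= oracle_err + 1e-9

    def test_all_zero_target_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mixture(np.zeros(N_CODES), random_components(rng))


@pytest.fixture(scope="module")
def mini_library():
    # two active cells, one dead cell; small horizon keeps this quick
    return build_component_library(
        a0_grid=(30, 40), c_grid=(0.3, 3.0), m_values=(2, 5, 9),
        n_trials=1, seed=21, horizon=600,
    )


class TestComponentLibrary:
    def test_entry_per_m_at_non_missing_cells(self, mini_library):
        for cell in mini_library.non_missing_cells():
            spec = mini_library.spectra[cell]
            assert spec.shape == (N_CODES, 3)
            assert np.all(spec >= 0)

    def test_low_activity_cells_marked_missing(self, mini_library):
        assert mini_library.is_missing((30, 3.0))  # activity dies, no codes
        assert not mini_library.is_missing((30, 0.3))
        assert not mini_library.is_missing((40, 0.3))

    def test_same_seed_identical_library(self):
        kw = dict(a0_grid=(30,), c_grid=(0.3,), m_values=(3,), n_trials=1,
                  seed=5, horizon=400)
        l1 = build_component_library(**kw)
        l2 = build_component_library(**kw)
        assert np.array_equal(l1.spectra[(30, 0.3)], l2.spectra[(30, 0.3)])

    def test_ms_grid_accepted(self):
        lib = build_component_library(
            a0_grid=(3.0,), c_grid=(0.3,), m_values=(3,), n_trials=1, horizon=300
        )
        assert lib.a0_grid == (30,)


class TestGridFit:
    def test_single_cell_library_is_best(self, mini_library):
        cells = mini_library.non_missing_cells()
        target = mini_library.spectra[cells[0]][:, -1]
        res = grid_fit(target, mini_library)
        assert res.best_cell in cells
        assert res.error <= min(res.error_grid.values()) + 1e-12

    def test_error_grid_covers_exactly_non_missing_cells(self, mini_library):
        target = mini_library.spectra[mini_library.non_missing_cells()[0]][:, 0]
        res = grid_fit(target, mini_library)
        assert set(res.error_grid) == set(mini_library.non_missing_cells())

    def test_component_target_yields_zero_error_at_own_cell(self, mini_library):
        cell = mini_library.non_missing_cells()[0]
        target = mini_library.spectra[cell][:, 1]
        res = grid_fit(target, mini_library)
        assert res.error_grid[cell] == pytest.approx(0.0, abs=1e-9)
        assert res.best_cell == cell

    def test_all_missing_rejected(self, mini_library):
        import dataclasses

        dead = dataclasses.replace(mini_library, spectra={}, totals={})
        with pytest.raises(ValueError):
            grid_fit(np.ones(N_CODES), dead)


class TestSynthesizeTarget:
    def test_deterministic_given_seed(self):
        kw = dict(a0=30, c=0.3, q={m: 1 / 8 for m in range(2, 10)},
                  n_trials=1, seed=3, horizon=500)
        assert np.array_equal(synthesize_target(**kw), synthesize_target(**kw))

    def test_shape_and_nonnegativity(self):
        t = synthesize_target(30, 0.3, {m: 1 / 8 for m in range(2, 10)},
                              n_trials=1, seed=4, horizon=500)
        assert t.shape == (N_CODES,)
        assert np.all(t >= 0) and t.sum() > 0

    def test_point_mass_approximates_component(self):
        # an array whose every electrode pools m=9 neurons should look like E_9
        lib = build_component_library(
            a0_grid=(30,), c_grid=(0.3,), m_values=(2, 9), n_trials=2,
            seed=6, horizon=800,
        )
        target = synthesize_target(30, 0.3, {9: 1.0}, n_trials=2, seed=7, horizon=800)
        comps = lib.spectra[(30, 0.3)]
        err9 = normalized_rms(target, comps[:, 1])
        err2 = normalized_rms(target, comps[:, 0])
        assert err9 < err2
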