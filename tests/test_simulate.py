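"""Simulator unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import kinenet as kn
from kinenet.simulate import NoiseSpec, _gaussian_bump_spectra

from conftest import random_rate_matrix


class TestLogTimeGrid:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((1, 100, 1), [1.0, 10.0, 100.0]),
            ((1, 10, 2), [1.0, 10**0.5, 10.0]),
        ],
    )
    def test_small_grids(self, args, expected):
        np.testing.assert_allclose(kn.log_time_grid(*args), expected, rtol=1e-12)

    def test_nine_per_decade_span(self):
        # 5.63 decades at 9 points/decade -> 51 points by direct enumeration
        t = kn.log_time_grid(1e-7, 4.3e-2, 9)
        assert t.size == 51
        assert t[0] == 1e-7 and t[-1] <= 4.3e-2
        np.testing.assert_allclose(np.diff(np.log10(t)), 1 / 9, rtol=1e-9)

    def test_exact_count_mode(self):
        t = kn.log_time_grid(1e-7, 4.3e-2, n_points=50)
        assert t.size == 50
        np.testing.assert_allclose(t[[0, -1]], [1e-7, 4.3e-2], rtol=1e-12)

    @pytest.mark.parametrize("bad", [(0, 1, 9), (-1, 1, 9), (2, 1, 9), (1, 2, 0)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            kn.log_time_grid(*bad)


class TestRateMatrix:
    def test_single_decay(self):
        model = kn.RateMatrix(K=[[-2.0]], c0=[1.0])
        macro = kn.solve_rate_matrix(model)
        np.testing.assert_allclose(macro.macro_taus, [0.5])
        t = np.linspace(0, 3, 7)
        np.testing.assert_allclose(
            macro.concentrations(t)[:, 0], np.exp(-2 * t), rtol=1e-12
        )

    def test_irreversible_pair_has_infinite_tau(self):
        k = 1.5
        model = kn.RateMatrix(K=[[-k, 0.0], [k, 0.0]], c0=[1.0, 0.0])
        macro = kn.solve_rate_matrix(model)
        assert np.isinf(macro.macro_taus[-1])
        np.testing.assert_allclose(macro.macro_taus[0], 1 / k, rtol=1e-12)

    def test_reversible_pair_matches_closed_form(self):
        # A <-> B with k12 = 1 (B->A), k21 = 2 (A->B): relaxation rate 3
        model = kn.RateMatrix(K=[[-2.0, 1.0], [2.0, -1.0]], c0=[1.0, 0.0])
        macro = kn.solve_rate_matrix(model)
        finite = macro.macro_taus[np.isfinite(macro.macro_taus)]
        np.testing.assert_allclose(finite, [1 / 3], rtol=1e-12)

    def test_eigen_solution_matches_ode_integration(self, rng):
        times = np.linspace(0.0, 4.0, 25)
        for _ in range(5):
            model = random_rate_matrix(rng)
            macro = kn.solve_rate_matrix(model)
            num = solve_ivp(
                lambda t, c: model.K @ c,
                (0, times[-1]),
                model.c0,
                t_eval=times,
                rtol=1e-11,
                atol=1e-13,
            )
            ana = macro.concentrations(times)
            assert np.abs(ana.T - num.y).max() < 1e-8 * max(1.0, np.abs(num.y).max())

    def test_degenerate_eigenvalues_rejected(self):
        # sequential S1 -> S2 -> S3 with equal rates: defective K
        k = 1.0
        K = [[-k, 0, 0], [k, -k, 0], [0, k, 0]]
        with pytest.raises(ValueError, match="[Dd]egenerate|Erlang"):
            kn.solve_rate_matrix(kn.RateMatrix(K=K, c0=[1, 0, 0]))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            kn.RateMatrix(K=[[-1.0, -0.5], [1.0, 0.5]], c0=[1, 0])
        with pytest.raises(ValueError):
            kn.RateMatrix(K=[[1.0]], c0=[1.0])  # positive diagonal

    def test_dads_compose_to_concentration_signal(self, rng):
        model = random_rate_matrix(rng)
        w = np.linspace(400, 700, 5)
        spectra = np.exp(-((w[None, :] - np.array([450, 550, 650])[:, None]) / 60) ** 2)
        macro = kn.solve_rate_matrix(model, spectra=spectra)
        t = np.linspace(0, 2, 11)
        direct = macro.concentrations(t) @ spectra
        via_dads = kn.compose_signal(macro.macro_taus, macro.dads, t)
        np.testing.assert_allclose(via_dads, direct, atol=1e-10)


class TestComposeSignal:
    def test_single_component_value(self):
        sig = kn.compose_signal([1.0], np.ones((1, 4)), np.array([0.5, 1.0]))
        np.testing.assert_allclose(sig[1], np.exp(-1.0), rtol=1e-12)

    def test_zero_amplitudes_and_inf_tau(self):
        t = np.array([0.1, 1.0, 10.0])
        assert np.all(kn.compose_signal([1.0, np.inf], np.zeros((2, 3)), t) == 0)
        sig = kn.compose_signal([np.inf], np.full((1, 2), 0.7), t)
        np.testing.assert_allclose(sig, 0.7)

    def test_two_components_match_direct_evaluation(self):
        t = np.array([0.0, 0.3, 2.0, 9.0])
        sig = kn.compose_signal([0.5, 5.0], np.array([[2.0], [-1.0]]), t)
        expected = 2 * np.exp(-t / 0.5) - np.exp(-t / 5.0)
        np.testing.assert_allclose(sig[:, 0], expected, rtol=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            kn.compose_signal([1.0, 2.0], np.ones((3, 2)), np.array([1.0, 2.0]))


class TestPhotocycleFixture:
    def test_noise_free_single_wavelength_value(self):
        sim = kn.photocycle_fixture(sigma_rel=0.0, p=1, seed=0)
        t0 = sim.dataset.times[0]
        expected = np.sum(sim.dads[:, 0] * np.exp(-t0 / kn.PHOTOCYCLE_TAUS))
        np.testing.assert_allclose(sim.dataset.signal[0, 0], expected, rtol=1e-12)
        # p=1 profiles are constant 1 -> DADS peak equals the truth amplitude
        np.testing.assert_allclose(sim.dads[:, 0], kn.PHOTOCYCLE_AMPS, rtol=1e-12)

    def test_deterministic_under_seed(self):
        a = kn.photocycle_fixture(sigma_rel=1e-3, p=5, seed=42)
        b = kn.photocycle_fixture(sigma_rel=1e-3, p=5, seed=42)
        np.testing.assert_array_equal(a.dataset.signal, b.dataset.signal)

    def test_noise_level_matches_sigma_rel(self):
        sim = kn.photocycle_fixture(sigma_rel=1e-3, p=30, seed=3)
        resid = sim.dataset.signal - sim.clean_signal
        target = 1e-3 * np.abs(sim.clean_signal).max()
        assert abs(resid.std() / target - 1) < 0.1

    def test_spectra_scaled_to_truth_amplitudes(self):
        sim = kn.photocycle_fixture(sigma_rel=0.0, p=16, seed=0)
        np.testing.assert_allclose(
            np.abs(sim.dads).max(axis=1), kn.PHOTOCYCLE_AMPS, rtol=1e-12
        )
        # profiles are linearly independent
        assert np.linalg.matrix_rank(sim.dads) == sim.dads.shape[0]


class TestNoise:
    def test_iid_zero_sigma_identity(self, rng):
        sig = rng.normal(size=(6, 3))
        out = kn.add_iid_noise(sig, NoiseSpec(kind="iid", sigma_rel=0.0, seed=0))
        np.testing.assert_array_equal(out, sig)

    def test_iid_reproducible_and_correct_std(self):
        sig = np.ones((300, 40))
        spec = NoiseSpec(kind="iid", sigma_rel=0.05, seed=9)
        a = kn.add_iid_noise(sig, spec)
        b = kn.add_iid_noise(sig, spec)
        np.testing.assert_array_equal(a, b)
        assert abs((a - sig).std() / 0.05 - 1) < 0.05

    def test_structured_segment_attenuation(self):
        times = kn.log_time_grid(1e-7, 4.3e-2, 9)
        w = np.linspace(355, 730, 200)
        sig = np.ones((times.size, w.size))
        spec = NoiseSpec(
            kind="structured",
            sigma_rel=1e-2,
            intensity_model=np.ones(w.size),
            segment_bounds=(1e-6,),
            segment_factors=(1.0, 4.0),
            seed=5,
        )
        noise = kn.add_structured_noise(sig, spec, times, w) - sig
        early = noise[times < 1e-6].std()
        late = noise[times >= 1e-6].std()
        assert abs(early / late - 2.0) < 0.15  # sqrt(4) attenuation

    def test_structured_intensity_scaling(self):
        times = np.linspace(1, 2, 400)
        w = np.array([1.0, 2.0])
        intensity = np.array([1.0, 2.0])
        spec = NoiseSpec(
            kind="structured",
            sigma_rel=1e-2,
            intensity_model=intensity,
            segment_bounds=(),
            segment_factors=(1.0,),
            seed=6,
        )
        sig = np.ones((400, 2))
        noise = kn.add_structured_noise(sig, spec, times, w) - sig
        ratio = noise[:, 0].std() / noise[:, 1].std()
        assert abs(ratio - np.sqrt(2)) < 0.15

    def test_noise_is_mean_preserving(self):
        # mean of replicates converges to the clean signal as 1/sqrt(N)
        sig = np.full((10, 4), 0.5)
        times = np.linspace(1, 10, 10)
        w = np.linspace(0, 1, 4)
        n = 2000
        acc_i = np.zeros_like(sig)
        acc_s = np.zeros_like(sig)
        for s in range(n):
            acc_i += kn.add_iid_noise(sig, NoiseSpec(kind="iid", sigma_rel=0.1, seed=s))
            acc_s += kn.add_structured_noise(
                sig, NoiseSpec(kind="structured", sigma_rel=0.1, seed=s), times, w
            )
        for acc in (acc_i, acc_s):
            err = np.abs(acc / n - sig).max()
            assert err < 5 * 0.1 * 0.5 / np.sqrt(n)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            NoiseSpec(kind="weird")
        with pytest.raises(ValueError):
            NoiseSpec(kind="structured", segment_bounds=(2.0, 1.0),
                      segment_factors=(1, 2, 3))
        with pytest.raises(ValueError):
            kn.add_iid_noise(np.empty((0, 0)), NoiseSpec(kind="iid", sigma_rel=0.1))


class TestDistributed:
    def test_rate_and_tau_at_weight_mode(self):
        spec = kn.ArrheniusSpec()
        taus, w, _ = kn.sim_distributed(spec, np.array([0.0, 1.0]))
        i = np.argmax(w)
        np.testing.assert_allclose(spec.e_grid[i], 200.0)
        np.testing.assert_allclose(taus[i], np.exp(4.0), rtol=1e-12)

    def test_weights_normalized_trace_starts_at_one(self):
        t = kn.log_time_grid(0.1, 1e4, 9)
        _, w, trace = kn.sim_distributed(kn.ArrheniusSpec(), np.insert(t, 0, 0.0))
        np.testing.assert_allclose(w.sum(), 1.0, rtol=1e-12)
        np.testing.assert_allclose(trace[0], 1.0, rtol=1e-12)
        assert np.all(np.diff(trace) <= 1e-15)  # monotone non-increasing

    def test_narrow_weight_limit_is_single_exponential(self):
        t = kn.log_time_grid(0.1, 1e3, 5)
        spec = kn.ArrheniusSpec(weight_sd=1e-6)
        _, _, trace = kn.sim_distributed(spec, t)
        np.testing.assert_allclose(trace, np.exp(-np.exp(-4.0) * t), rtol=1e-9)


class TestMixture:
    def test_erlang_values(self):
        spec = kn.MixtureSpec(family="erlang", tau1=10.0, amp=2.0)
        out = kn.sim_mixture(spec, np.array([0.0, 10.0]))
        np.testing.assert_allclose(out[0], 2 * 2.0)  # t=0: 0 + 2A
        pure = kn.sim_mixture(
            kn.MixtureSpec(family="erlang", tau1=10.0, amp=0.0), np.array([10.0])
        )
        np.testing.assert_allclose(pure[0], 10 * np.exp(-1), rtol=1e-12)

    def test_second_order_value(self):
        spec = kn.MixtureSpec(family="second_order", tau1=10.0, amp=0.0, conc=8.0)
        out = kn.sim_mixture(spec, np.array([10.0]))
        np.testing.assert_allclose(out[0], 8.0 / 9.0, rtol=1e-12)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            kn.MixtureSpec(family="zeroth_order")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    sigma=st.floats(1e-5, 1e-1),
    seed=st.integers(0, 2**20),
    p=st.integers(1, 6),
)
def test_fixture_bit_reproducible(sigma, seed, p):
    a = kn.photocycle_fixture(sigma_rel=sigma, p=p, seed=seed)
    b = kn.photocycle_fixture(sigma_rel=sigma, p=p, seed=seed)
    np.testing.assert_array_equal(a.dataset.signal, b.dataset.signal)


def test_bump_spectra_peak_normalized():
    w = np.linspace(0, 1, 23)
    prof = _gaussian_bump_spectra(7, w)
    np.testing.assert_allclose(prof.max(axis=1), 1.0, rtol=1e-12)
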