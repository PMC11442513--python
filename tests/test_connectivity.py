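import numpy as np
import pytest
from scipy import signal as sg

from bgosc import synth
from bgosc.connectivity import (
    cross_spectrum,
    direction_verdict,
    directionality_designation,
    granger_corrected,
    granger_nonparametric,
    imaginary_coherence,
    magnitude_coherence,
    shuffle_surrogate,
    time_reversed_correction,
    wilson_factorize,
    wpli,
    CrossSpectrum,
)
from bgosc.preprocess import epoch
from bgosc.spectral import band_mask, default_freq_grid, morlet_transform

FS = 200.0
FREQS = default_freq_grid(2.0, 45.0)


def _tfc(x, structure=None):
    return morlet_transform(epoch(np.asarray(x, float), FS, 2.0, structure=structure), FREQS)


def _delayed_pair(rng, f0=8.0, gain=0.8, lag_samples=5, n=24_000, noise=1.0):
    z = synth._narrowband(n + lag_samples, rng, f0, FS)
    a = z[lag_samples:] + noise * synth._pink_noise(n, rng)
    b = gain * z[:n] + noise * synth._pink_noise(n, rng)
    return a, b


class TestCrossSpectrum:
    def test_self_pair_is_real_and_equals_autospectrum(self, rng):
        ca = _tfc(rng.standard_normal(8000))
        cs = cross_spectrum(ca, ca)
        np.testing.assert_allclose(np.imag(cs.S_ab), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.real(cs.S_ab), cs.S_aa, rtol=1e-10)

    def test_pure_delay_phase(self, rng):
        """Phase of S_ab for b = a delayed by dt is ~2 pi f dt at the peak."""
        a, b = _delayed_pair(rng, noise=0.05)
        cs = cross_spectrum(_tfc(a), _tfc(b))
        i = np.argmin(np.abs(cs.freqs - 8.0))
        expected = 2 * np.pi * cs.freqs[i] * (5 / FS)
        assert np.angle(cs.S_ab[i]) == pytest.approx(expected, abs=0.15)

    def test_independent_channels_average_out(self, rng):
        cs = cross_spectrum(_tfc(rng.standard_normal(60_000)), _tfc(rng.standard_normal(60_000)))
        assert np.max(np.abs(cs.S_ab) / np.sqrt(cs.S_aa * cs.S_bb)) < 0.35

    def test_epoch_mismatch_is_an_error(self, rng):
        with pytest.raises(ValueError, match="epoching|shape"):
            cross_spectrum(_tfc(rng.standard_normal(8000)), _tfc(rng.standard_normal(4000)))

    def test_cauchy_schwarz_bound_holds(self, rng):
        a, b = _delayed_pair(rng)
        cs = cross_spectrum(_tfc(a), _tfc(b))
        coh = np.abs(cs.S_ab) / np.sqrt(cs.S_aa * cs.S_bb)
        assert np.all(coh <= 1.0 + 1e-12)


class TestImaginaryCoherence:
    def test_zero_lag_copy_gives_zero_icoh(self, rng):
        x = rng.standard_normal(12_000)
        cs = cross_spectrum(_tfc(x), _tfc(3.0 * x))
        np.testing.assert_allclose(imaginary_coherence(cs), 0.0, atol=1e-10)

    def test_antisymmetry_under_pair_reversal(self, rng):
        a, b = _delayed_pair(rng)
        cs = cross_spectrum(_tfc(a), _tfc(b))
        np.testing.assert_allclose(
            imaginary_coherence(cs), -imaginary_coherence(cs.reversed()), rtol=1e-10
        )

    def test_quadrature_pair_matches_dft_oracle(self, rng):
        """90-degree-shifted band-limited coupling: Morlet |iCOH| within 5%
        of a direct Welch-segment coherency oracle at the band center
        (where the underlying coherence profile is flat, so the comparison
        measures estimator agreement rather than resolution differences)."""
        n = int(180 * FS)
        sos = sg.butter(6, [5 / 100, 11 / 100], btype="bandpass", output="sos")
        z = sg.sosfiltfilt(sos, rng.standard_normal(n))
        zq = np.imag(sg.hilbert(z))  # 90-degree shifted copy
        a = z + 0.7 * synth._pink_noise(n, rng)
        b = zq + 0.7 * synth._pink_noise(n, rng)
        cs = cross_spectrum(_tfc(a), _tfc(b))
        i = np.argmin(np.abs(cs.freqs - 8.0))
        ours = np.abs(imaginary_coherence(cs)[i])
        f_w, Sab = sg.csd(a, b, fs=FS, nperseg=400)
        _, Saa = sg.welch(a, fs=FS, nperseg=400)
        _, Sbb = sg.welch(b, fs=FS, nperseg=400)
        j = np.argmin(np.abs(f_w - 8.0))
        oracle = np.abs(np.imag(Sab / np.sqrt(Saa * Sbb))[j])
        assert ours == pytest.approx(oracle, rel=0.05)


class TestWpli:
    def test_identical_channels_degenerate_to_zero(self, rng):
        x = rng.standard_normal(8000)
        cs = cross_spectrum(_tfc(x), _tfc(x))
        with pytest.warns(UserWarning, match="wPLI"):
            assert np.all(wpli(cs) == 0.0)

    def test_consistent_lag_approaches_one(self, rng):
        a, b = _delayed_pair(rng, noise=0.05, n=48_000)
        cs = cross_spectrum(_tfc(a), _tfc(b))
        i = np.argmin(np.abs(cs.freqs - 8.0))
        assert wpli(cs)[i] > 0.9

    def test_independent_channels_fluctuate_around_zero(self, rng):
        vals = []
        for _ in range(8):
            cs = cross_spectrum(_tfc(rng.standard_normal(24_000)), _tfc(rng.standard_normal(24_000)))
            vals.append(wpli(cs)[band_mask(cs.freqs, (3, 12))].mean())
        vals = np.array(vals)
        assert np.abs(vals.mean()) < 0.1
        assert (vals < 0).any() or np.abs(vals).max() < 0.05  # debiased null not positive-bounded

    def test_bounded_by_one(self, rng):
        a, b = _delayed_pair(rng)
        cs = cross_spectrum(_tfc(a), _tfc(b))
        assert np.all(np.abs(wpli(cs)) <= 1.0 + 1e-12)


class TestShuffleSurrogate:
    def test_same_seed_reproduces_draws(self, conditioned_pair):
        ca, cb = conditioned_pair
        s1 = shuffle_surrogate(ca, cb, 20, seed=5)
        s2 = shuffle_surrogate(ca, cb, 20, seed=5)
        np.testing.assert_array_equal(s1["icoh"], s2["icoh"])

    def test_coupled_pair_exceeds_null(self, conditioned_pair):
        ca, cb = conditioned_pair
        cs = cross_spectrum(ca, cb)
        m = band_mask(cs.freqs, (3, 12))
        obs = np.abs(imaginary_coherence(cs)[m]).mean()
        sur = shuffle_surrogate(ca, cb, 100, seed=3)
        null95 = np.percentile(np.abs(sur["icoh"][:, m]).mean(axis=1), 95)
        assert obs > null95

    def test_uncoupled_pair_within_null(self, rng):
        ca = _tfc(rng.standard_normal(36_000))
        cb = _tfc(rng.standard_normal(36_000))
        cs = cross_spectrum(ca, cb)
        m = band_mask(cs.freqs, (3, 12))
        obs = np.abs(imaginary_coherence(cs)[m]).mean()
        sur = shuffle_surrogate(ca, cb, 200, seed=3)
        dist = np.abs(sur["icoh"][:, m]).mean(axis=1)
        lo, hi = np.percentile(dist, [2.5, 97.5])
        assert lo <= obs <= hi

    def test_invalid_count_is_an_error(self, conditioned_pair):
        ca, cb = conditioned_pair
        with pytest.raises(ValueError):
            shuffle_surrogate(ca, cb, 0)


class TestWilsonGranger:
    @staticmethod
    def _var_spectrum(freqs, fs, a1=0.55, a2=-0.35, c=0.35):
        A1 = np.array([[a1, c], [0, a1]])
        A2 = np.array([[a2, 0], [0, a2]])
        S = np.empty((len(freqs), 2, 2), complex)
        for i, f in enumerate(freqs):
            Af = np.eye(2) - A1 * np.exp(-2j * np.pi * f / fs) - A2 * np.exp(-4j * np.pi * f / fs)
            H = np.linalg.inv(Af)
            S[i] = H @ H.conj().T
        return S

    def test_factorization_reconstructs_spectrum(self):
        freqs = np.arange(0, 100.5, 0.5)
        S = self._var_spectrum(freqs, 200.0)
        H, Sigma, n_iter, residual = wilson_factorize(S)
        Smod = H @ Sigma[None] @ np.conj(np.transpose(H, (0, 2, 1)))
        assert np.linalg.norm(Smod - S) / np.linalg.norm(S) < 1e-6

    def test_var_oracle_agreement(self, rng):
        """Nonparametric path within 10% of the parametric VAR oracle."""
        from bgosc.experiments import _simulate_var2, parametric_var_granger

        data = _simulate_var2(40_000, c=0.35, rng=rng)
        freqs = default_freq_grid(1.0, 90.0)
        cs = cross_spectrum(
            morlet_transform(epoch(data[:, 1], FS, 2.0), freqs),
            morlet_transform(epoch(data[:, 0], FS, 2.0), freqs),
        )
        g = granger_nonparametric(cs)
        band = (freqs >= 20) & (freqs <= 50)
        oracle, _ = parametric_var_granger(data, 2, freqs[band], 200.0)
        assert g.fwd[band].mean() == pytest.approx(oracle.mean(), rel=0.10)
        assert g.rev[band].mean() < 0.1 * g.fwd[band].mean()

    def test_independent_channels_near_zero(self, rng):
        cs = cross_spectrum(_tfc(rng.standard_normal(100_000)), _tfc(rng.standard_normal(100_000)))
        g = granger_nonparametric(cs)
        assert np.all(g.fwd < 0.02) and np.all(g.rev < 0.02)

    def test_channel_swap_exchanges_directions(self, conditioned_pair):
        """Swapping the channel order exchanges the two directed spectra
        (up to the factorization's discretization floor)."""
        ca, cb = conditioned_pair
        cs = cross_spectrum(ca, cb)
        g = granger_nonparametric(cs)
        g_swapped = granger_nonparametric(cs.reversed())
        np.testing.assert_allclose(g.fwd, g_swapped.rev, rtol=0.02, atol=1e-3)
        np.testing.assert_allclose(g.rev, g_swapped.fwd, rtol=0.02, atol=1e-3)


class TestTimeReversal:
    def test_grid_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            time_reversed_correction(np.zeros(5), np.zeros(5), np.zeros(4), np.zeros(4))

    def test_time_symmetric_data_corrects_to_zero(self, rng):
        """A pair whose cross-spectrum is purely real equals its own time
        reversal, so the corrected spectra vanish."""
        x = rng.standard_normal(24_000)
        cs = cross_spectrum(_tfc(x + 0.5 * rng.standard_normal(24_000)),
                            _tfc(x + 0.5 * rng.standard_normal(24_000)))
        cs.S_ab = np.real(cs.S_ab) + 0j  # enforce exact time symmetry
        cs.per_epoch_S_ab = np.real(cs.per_epoch_S_ab) + 0j
        g = granger_corrected(cs)
        np.testing.assert_allclose(g.corrected_fwd, 0.0, atol=1e-9)
        np.testing.assert_allclose(g.corrected_rev, 0.0, atol=1e-9)

    def test_lagged_coupling_survives_correction(self, conditioned_pair):
        ca, cb = conditioned_pair
        cs = cross_spectrum(ca, cb)
        g = granger_corrected(cs)
        m = band_mask(cs.freqs, (3, 12))
        assert (g.corrected_fwd - g.corrected_rev)[m].mean() > 0


class TestDirectionality:
    def test_uniform_dominance(self):
        freqs = default_freq_grid(2.0, 45.0)
        n = band_mask(freqs, (3, 12)).sum()
        d = directionality_designation(np.ones_like(freqs), np.zeros_like(freqs), freqs)
        assert d.striatal_driving and d.n_bins_gpi == 0 and d.n_bins_str == n

    def test_exact_ties_designate_nothing(self):
        freqs = default_freq_grid(2.0, 45.0)
        d = directionality_designation(np.ones_like(freqs), np.ones_like(freqs), freqs)
        assert not d.striatal_driving and not d.pallidal_driving
        assert d.n_bins_tied == d.n_bins_total

    def test_margin_turns_small_differences_into_ties(self):
        freqs = default_freq_grid(2.0, 45.0)
        fwd = np.full_like(freqs, 0.005)
        d = directionality_designation(fwd, np.zeros_like(freqs), freqs, margin=0.01)
        assert not d.striatal_driving and d.n_bins_tied == d.n_bins_total

    def test_gated_verdict_on_coupled_hemisphere(self, conditioned_pair):
        ca, cb = conditioned_pair
        g = granger_corrected(cross_spectrum(ca, cb))
        assert direction_verdict(g) == "striatal"

    def test_bootstrap_band_diff_centers_on_estimate(self, conditioned_pair):
        from bgosc.connectivity import bootstrap_granger_band_diff

        ca, cb = conditioned_pair
        cs = cross_spectrum(ca, cb)
        g = granger_corrected(cs)
        m = band_mask(cs.freqs, (3, 12))
        obs = (g.corrected_fwd - g.corrected_rev)[m].mean()
        boot = bootstrap_granger_band_diff(cs, (3, 12), n_boot=20, seed=0)
        assert boot.shape == (20,)
        assert abs(boot.mean() - obs) < 5 * boot.std(ddof=1) + 1e-9
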