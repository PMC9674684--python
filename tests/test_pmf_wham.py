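"""WHAM reconstruction against analytically planted potentials."""

import numpy as np
import pytest

from qsplit import (
    UmbrellaWindow,
    detect_poor_sampling,
    endpoint_symmetry,
    wham_solve,
    windows_from_pull,
)
from qsplit.errors import (
    DisconnectedHistogramError,
    InvalidParameterError,
    TooShortPullError,
)
from qsplit.fixtures import make_umbrella_samples, stair_potential
from qsplit.pmf_wham import R_KJ_PER_MOL_K

KT = R_KJ_PER_MOL_K * 310.15


def harmonic(x):
    return 0.5 * 100.0 * np.asarray(x) ** 2


@pytest.fixture(scope="module")
def harmonic_windows():
    centers = np.arange(-1.45, 1.4501, 0.1)  # 30 windows
    return make_umbrella_samples(harmonic, centers, spring_k=1000.0,
                                 n_per_window=10_000, seed=31)[0]


@pytest.fixture(scope="module")
def stair_windows():
    centers = np.arange(-3.0, 3.0001, 0.2)
    return make_umbrella_samples(stair_potential(), centers, spring_k=500.0,
                                 n_per_window=5_000, seed=32)[0]


def aligned_rms_kt(profile, potential):
    """RMS mismatch (kT) between profile and planted potential over the
    well-sampled bins, both gauge-fixed to zero minimum there."""
    mask = np.isfinite(profile.free_energy) & (profile.counts >= 0.01 * profile.counts.max())
    planted = potential(profile.bin_centers[mask])
    planted = planted - planted.min()
    recovered = profile.free_energy[mask] - profile.free_energy[mask].min()
    return float(np.sqrt(np.mean((recovered - planted) ** 2))) / profile.kt


class TestWindowsFromPull:
    def test_symmetric_pull_yields_29_centers(self):
        t = np.linspace(0.0, 100.0, 4000)
        xi = -2.8 + 5.6 * t / 100.0
        windows = windows_from_pull(t, xi, spacing=0.2)
        assert len(windows) == 29
        assert windows[0].center == pytest.approx(-2.8)
        assert windows[-1].center == pytest.approx(2.8)

    def test_default_spacing_is_two_angstrom(self):
        t = np.linspace(0.0, 10.0, 500)
        windows = windows_from_pull(t, np.linspace(-1.0, 1.0, 500))
        spacings = np.diff([w.center for w in windows])
        np.testing.assert_allclose(spacings, 0.2, atol=1e-12)

    def test_spacing_larger_than_range_rejected(self):
        t = np.linspace(0.0, 1.0, 100)
        with pytest.raises(TooShortPullError):
            windows_from_pull(t, np.linspace(0.0, 0.1, 100), spacing=0.2)


class TestWhamSolve:
    def test_near_unbiased_uniform_density_gives_flat_pmf(self, rng):
        # a single nearly-flat window over a uniform density: the closed-form
        # limit PMF = -kT ln(histogram) up to the weak bias correction
        samples = rng.uniform(-1.0, 1.0, 200_000)
        window = UmbrellaWindow(center=0.0, spring_k=1e-6, samples=samples)
        profile = wham_solve([window], n_bins=20)
        inner = profile.free_energy[2:-2]
        assert np.nanmax(np.abs(inner - inner.mean())) < 0.1 * KT

    def test_single_window_reduces_to_log_histogram(self, rng):
        samples = rng.normal(0.3, 0.1, 50_000)
        window = UmbrellaWindow(center=0.3, spring_k=50.0, samples=samples)
        profile = wham_solve([window], n_bins=40)
        counts = profile.counts.astype(float)
        ref = -profile.kt * np.log(counts / counts.sum())
        bias = 0.5 * 50.0 * (profile.bin_centers - 0.3) ** 2
        expected = ref - bias
        expected -= expected[counts > 0].min()
        good = counts > 100
        np.testing.assert_allclose(profile.free_energy[good], expected[good], atol=0.05)

    def test_harmonic_pmf_recovered(self, harmonic_windows):
        profile = wham_solve(harmonic_windows)
        assert aligned_rms_kt(profile, harmonic) <= 0.2

    def test_stair_pmf_recovers_step_ordering_and_endpoints(self, stair_windows):
        profile = wham_solve(stair_windows)
        assert aligned_rms_kt(profile, stair_potential()) <= 0.5
        fe = profile.free_energy
        c = profile.bin_centers

        def mean_over(lo, hi):
            m = (c >= lo) & (c <= hi) & np.isfinite(fe)
            return fe[m].mean()

        well = mean_over(-2.0, -1.6)
        step1 = mean_over(-0.6, -0.4)
        step2 = mean_over(0.9, 1.1)
        assert well < step1 < step2  # the ascending potential stair
        assert abs(endpoint_symmetry(profile, margin=0.3)) < 0.2 * KT

    def test_gauge_minimum_is_zero(self, harmonic_windows):
        profile = wham_solve(harmonic_windows)
        assert np.nanmin(profile.free_energy[np.isfinite(profile.free_energy)]) == 0.0

    def test_disconnected_windows_rejected_with_gap_list(self, rng):
        far = [
            UmbrellaWindow(center=c, spring_k=5000.0, samples=rng.normal(c, 0.02, 500))
            for c in (-2.0, 2.0)
        ]
        with pytest.raises(DisconnectedHistogramError) as err:
            wham_solve(far, n_bins=100)
        assert len(err.value.gaps) >= 1

    def test_small_windows_rejected(self, rng):
        w = UmbrellaWindow(center=0.0, spring_k=100.0, samples=rng.normal(0, 0.1, 50))
        with pytest.raises(InvalidParameterError, match="100"):
            wham_solve([w])

    def test_mixed_temperatures_rejected(self, rng):
        a = UmbrellaWindow(0.0, 100.0, rng.normal(0, 0.1, 500), temperature=300.0)
        b = UmbrellaWindow(0.1, 100.0, rng.normal(0.1, 0.1, 500), temperature=310.0)
        with pytest.raises(InvalidParameterError):
            wham_solve([a, b])

    def test_non_convergence_warns_but_returns(self, harmonic_windows):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            profile = wham_solve(harmonic_windows[:6], tol=1e-15, max_iter=5)
        assert np.isfinite(profile.free_energy).any()

    def test_bootstrap_uncertainty_shrinks_with_samples(self):
        centers = np.arange(-0.5, 0.501, 0.1)
        small, _ = make_umbrella_samples(harmonic, centers, 1000.0,
                                         n_per_window=200, seed=7)
        large, _ = make_umbrella_samples(harmonic, centers, 1000.0,
                                         n_per_window=5000, seed=7)
        u_small = wham_solve(small, n_bins=50, n_bootstrap=10, seed=1).uncertainty
        u_large = wham_solve(large, n_bins=50, n_bootstrap=10, seed=1).uncertainty
        assert np.nanmedian(u_large) < np.nanmedian(u_small)

    def test_default_temperature_is_310_k(self, harmonic_windows):
        assert wham_solve(harmonic_windows).temperature == pytest.approx(310.15)


class TestPoorSampling:
    def test_dense_windows_show_no_gaps(self, stair_windows):
        assert detect_poor_sampling(stair_windows) == []

    @pytest.mark.parametrize("removed", [-2.0, 0.0, 1.0])
    def test_removed_window_is_flagged_at_its_center(self, stair_windows, removed):
        subset = [w for w in stair_windows if abs(w.center - removed) > 0.01]
        gaps = detect_poor_sampling(subset)
        assert any(lo < removed < hi for lo, hi in gaps)

    def test_single_window_warns_and_returns_empty(self, rng):
        w = UmbrellaWindow(0.0, 100.0, rng.normal(0, 0.1, 500))
        with pytest.warns(RuntimeWarning):
            assert detect_poor_sampling([w]) == []


class TestEndpointSymmetry:
    def make_profile(self, fe):
        from qsplit import PMFProfile

        centers = np.linspace(-3.0, 3.0, fe.size)
        return PMFProfile(centers, fe - fe.min(), np.ones(fe.size, dtype=int))

    def test_tilted_profile_reports_offset(self):
        x = np.linspace(-3.0, 3.0, 100)
        fe = 2.0 * KT / 6.0 * (x + 3.0)  # linear ramp, 2 kT end to end
        profile = self.make_profile(fe)
        assert endpoint_symmetry(profile, 0.5) == pytest.approx(-2.0 * KT, abs=0.2 * KT)

    def test_mirrored_profile_negates_difference(self):
        x = np.linspace(-3.0, 3.0, 100)
        fe = np.exp(-x) * KT
        fwd = endpoint_symmetry(self.make_profile(fe), 0.5)
        rev = endpoint_symmetry(self.make_profile(fe[::-1]), 0.5)
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_margin_exceeding_half_range_rejected(self):
        profile = self.make_profile(np.zeros(50))
        with pytest.raises(InvalidParameterError):
            endpoint_symmetry(profile, margin=4.0)


class TestGaugeInvariance:
    def test_shifting_window_free_energies_leaves_distribution_unchanged(self, harmonic_windows):
        # one WHAM iteration from f and from f + const must give the same P
        windows = harmonic_windows[:8]
        edges = np.linspace(-1.45, -0.6, 101)
        counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
        centers = 0.5 * (edges[:-1] + edges[1:])
        bias = np.stack(
            [0.5 * w.spring_k * (centers - w.center) ** 2 / KT for w in windows]
        )
        n_i = counts.sum(axis=1).astype(float)

        def one_step(f):
            denom = (n_i[:, None] * np.exp(f)[:, None] * np.exp(-bias)).sum(axis=0)
            p = counts.sum(axis=0) / denom
            return p / p.sum()

        f0 = np.zeros(len(windows))
        np.testing.assert_allclose(one_step(f0), one_step(f0 + 3.7), rtol=1e-10)
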