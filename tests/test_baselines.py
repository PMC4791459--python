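import numpy as np
import pytest

from motorimagery import (
    FeatureMatrix,
    FilterBankSpec,
    SegmentSet,
    bandpower_features,
    csp_features,
    csp_from_covariances,
    fbcsp_features,
    fit_csp,
    fit_fbcsp,
    fit_lda,
    predict_lda,
)
from motorimagery.baselines import mutual_information

from conftest import make_noise_segments


def _angle_between(u, v):
    cos = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(cos, 0, 1)))


class TestCSP:
    def test_diagonal_covariances_give_08_02_eigenvalues(self):
        bank = csp_from_covariances(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]), n_pairs=1)
        np.testing.assert_allclose(bank.eigenvalues, [0.8, 0.2], atol=1e-6)
        # first filter selects channel 1, last channel 2
        assert abs(bank.W[0, 0]) > 100 * abs(bank.W[1, 0])
        assert abs(bank.W[1, 1]) > 100 * abs(bank.W[0, 1])

    def test_top_filter_matches_brute_force_angle_sweep(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((2, 2))
        C1 = np.diag([4.0, 1.0]) + 0.3 * (A + A.T)
        C1 = C1 @ C1.T  # SPD
        C2 = np.diag([1.0, 4.0])
        bank = csp_from_covariances(C1, C2, n_pairs=1)
        angles = np.radians(np.arange(0, 180, 0.05))
        best = None
        for th in angles:
            w = np.array([np.cos(th), np.sin(th)])
            ratio = (w @ C1 @ w) / (w @ C2 @ w)
            if best is None or ratio > best[0]:
                best = (ratio, w)
        assert _angle_between(best[1], bank.W[:, 0]) < 2.0

    def test_identical_covariances_give_half_eigenvalues(self):
        C = np.diag([2.0, 3.0, 1.0])
        bank = csp_from_covariances(C, C, n_pairs=1)
        np.testing.assert_allclose(bank.eigenvalues, 0.5, atol=1e-6)

    def test_eigenvalues_of_both_classes_sum_to_one(self, rng):
        X = rng.standard_normal((4, 200))
        C1 = X @ X.T / 200
        Y = rng.standard_normal((4, 200))
        C2 = Y @ Y.T / 200
        bank = csp_from_covariances(C1, C2, n_pairs=2)
        lam2 = np.array([w @ C2 @ w / (w @ (C1 + C2) @ w) for w in bank.W.T])
        np.testing.assert_allclose(bank.eigenvalues + lam2, 1.0, atol=1e-6)

    def test_invariance_under_congruence_of_covariances(self, rng):
        X = rng.standard_normal((4, 300))
        Y = rng.standard_normal((4, 300)) * np.array([3.0, 1, 1, 0.5])[:, None]
        C1, C2 = X @ X.T / 300, Y @ Y.T / 300
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)  # invertible mixing
        bank = csp_from_covariances(C1, C2, n_pairs=2)
        bank_m = csp_from_covariances(A @ C1 @ A.T, A @ C2 @ A.T, n_pairs=2)
        np.testing.assert_allclose(bank_m.eigenvalues, bank.eigenvalues, atol=1e-7)

    def test_fit_invariant_under_orthogonal_channel_mixing(self, rng):
        # orthogonal mixing preserves each segment's covariance trace, so the
        # trace-normalized class covariances transform by pure congruence
        segs = make_noise_segments(rng, n_per_class=15, scale_by_class=(1.0, 3.0))
        bank = fit_csp(segs, n_pairs=2)
        Q = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        mixed = SegmentSet(
            data=np.einsum("dc,scn->sdn", Q, segs.data),
            labels=segs.labels,
            parent_trial=segs.parent_trial,
            fs=segs.fs,
        )
        bank_m = fit_csp(mixed, n_pairs=2)
        np.testing.assert_allclose(bank_m.eigenvalues, bank.eigenvalues, atol=1e-8)

    def test_single_class_rejected(self, rng):
        segs = make_noise_segments(rng, n_per_class=5)
        segs.labels[:] = 0
        with pytest.raises(ValueError, match="2 classes"):
            fit_csp(segs)


class TestCSPFeatures:
    def test_three_pairs_give_six_features(self, rng):
        segs = make_noise_segments(rng, n_per_class=10, n_channels=8)
        bank = fit_csp(segs, n_pairs=3)
        F = csp_features(segs, bank)
        assert F.values.shape == (20, 6)

    def test_scale_invariance_of_normalized_log_variance(self, rng):
        segs = make_noise_segments(rng, n_per_class=5)
        bank = fit_csp(segs, n_pairs=1)
        F1 = csp_features(segs, bank)
        segs.data *= 7.3
        F2 = csp_features(segs, bank)
        np.testing.assert_allclose(F1.values, F2.values, atol=1e-10)

    def test_single_component_feature_is_identically_zero(self, rng):
        segs = make_noise_segments(rng, n_per_class=5)
        bank = fit_csp(segs, n_pairs=1)
        bank.W = bank.W[:, :1]
        F = csp_features(segs, bank)
        np.testing.assert_allclose(F.values, 0.0, atol=1e-12)


class TestFBCSP:
    @staticmethod
    def _banded_segments(rng, n_per_class=25, fs=250.0, n=250):
        """Class contrast only in 10-14 Hz on channel 0."""
        from scipy import signal as sg

        segs = make_noise_segments(rng, n_per_class=n_per_class, n_channels=4,
                                   n_samples=n, fs=fs)
        sos = sg.butter(4, [10, 14], btype="bandpass", fs=fs, output="sos")
        burst = sg.sosfilt(sos, rng.standard_normal((n_per_class, n)), axis=-1)
        burst *= 3.0 / burst.std()
        segs.data[segs.labels == 1, 0, :] += burst
        return segs

    def test_selection_localizes_the_informative_band(self, rng):
        spec = FilterBankSpec(bands=((6, 10), (10, 14), (14, 18), (18, 22)), n_select=2)
        segs = self._banded_segments(rng)
        banks, selected = fit_fbcsp(segs, spec, n_pairs=1)
        per_band = banks[0].n_components
        assert all(sel // per_band == 1 for sel in selected)  # band index 1 = 10-14 Hz
        F = fbcsp_features(segs, banks, selected)
        assert F.values.shape == (50, 2)

    def test_single_band_degenerates_to_plain_csp_selection(self, rng):
        spec = FilterBankSpec(bands=((8, 16),), n_select=2)
        segs = self._banded_segments(rng)
        banks, selected = fit_fbcsp(segs, spec, n_pairs=1)
        assert len(banks) == 1 and len(selected) == 2

    def test_n_select_beyond_pool_rejected(self, rng):
        spec = FilterBankSpec(bands=((8, 16),), n_select=10)
        with pytest.raises(ValueError, match="n_select"):
            fit_fbcsp(self._banded_segments(rng, n_per_class=5), spec, n_pairs=1)

    def test_shuffled_labels_select_only_chance_level_information(self, rng):
        from scipy import stats

        spec = FilterBankSpec(bands=((6, 10), (10, 14), (14, 18)), n_select=2)
        segs = self._banded_segments(rng, n_per_class=25)

        def selected_mi(s):
            banks, sel = fit_fbcsp(s, spec, n_pairs=1)
            F = fbcsp_features(s, banks, sel)
            return np.mean([mutual_information(F.values[:, j], s.labels)
                            for j in range(F.values.shape[1])])

        shuffled_mi, chance_mi = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            s2 = SegmentSet(segs.data, r.permutation(segs.labels),
                            segs.parent_trial, segs.fs)
            shuffled_mi.append(selected_mi(s2))
            # chance reference: the identical fit+select pipeline on segments
            # carrying no class structure at all
            chance_mi.append(selected_mi(make_noise_segments(r, n_per_class=25)))
        true_mi = selected_mi(segs)
        assert stats.ttest_ind(shuffled_mi, chance_mi).pvalue > 0.01
        assert np.mean(shuffled_mi) < 0.5 * true_mi

    def test_selection_invariant_to_band_ordering(self, rng):
        # permuting the pooled columns (here: listing the bands in another
        # order) must permute, not change, the selected feature set
        segs = self._banded_segments(rng)
        bands = ((6, 10), (10, 14), (14, 18))
        spec_fwd = FilterBankSpec(bands=bands, n_select=2)
        spec_rev = FilterBankSpec(bands=bands[::-1], n_select=2)
        names = []
        for spec in (spec_fwd, spec_rev):
            banks, sel = fit_fbcsp(segs, spec, n_pairs=1)
            names.append(set(fbcsp_features(segs, banks, sel).feature_names))
        assert names[0] == names[1]


class TestBandPower:
    @staticmethod
    def _sine_segments(freq, amp, fs=1000.0, n=3000):
        t = np.arange(n) / fs
        x = amp * np.sin(2 * np.pi * freq * t)
        data = np.stack([x[None, :], x[None, :]])  # 2 segments, 1 channel
        return SegmentSet(data, np.array([0, 1]), np.array([0, 1]), fs,
                          channel_labels=["C3"])

    def test_in_band_sine_gives_log_half_amplitude_squared(self):
        segs = self._sine_segments(10.0, amp=2.0)
        F = bandpower_features(segs, bands=[(8, 12)])
        assert F.values[0, 0] == pytest.approx(np.log(2.0**2 / 2), abs=0.1)

    def test_doubling_amplitude_adds_log_four(self):
        f1 = bandpower_features(self._sine_segments(10.0, 1.0), bands=[(8, 12)])
        f2 = bandpower_features(self._sine_segments(10.0, 2.0), bands=[(8, 12)])
        assert f2.values[0, 0] - f1.values[0, 0] == pytest.approx(np.log(4), abs=1e-6)

    def test_out_of_band_sine_is_heavily_attenuated(self):
        in_band = bandpower_features(self._sine_segments(10.0, 2.0), bands=[(8, 12)])
        out_band = bandpower_features(self._sine_segments(50.0, 2.0), bands=[(8, 12)])
        # attenuation is limited by filter edge transients, not the (far
        # smaller) stopband frequency response; > 5 nats is a >99% power drop
        assert out_band.values[0, 0] < in_band.values[0, 0] - 5

    def test_feature_count_is_channels_times_bands(self, rng):
        segs = make_noise_segments(rng, n_per_class=3, n_channels=4, fs=1000.0)
        F = bandpower_features(segs, bands=[(8, 12), (18, 26)])
        assert F.values.shape == (6, 8)


class TestLDA:
    def test_separated_clouds_classified_perfectly(self, rng):
        X = np.vstack([rng.standard_normal((50, 3)) - 5, rng.standard_normal((50, 3)) + 5])
        y = np.repeat([0, 1], 50)
        F = FeatureMatrix(X, ["a", "b", "c"], y)
        model = fit_lda(F)
        assert np.mean(predict_lda(model, F) == y) == 1.0

    def test_identical_distributions_stay_at_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((2000, 4))
            y = rng.integers(0, 2, 2000)
            half = 1000
            F_tr = FeatureMatrix(X[:half], list("abcd"), y[:half])
            model = fit_lda(F_tr)
            accs.append(np.mean(predict_lda(model, X[half:]) == y[half:]))
        assert abs(100 * np.mean(accs) - 50) < 3

    def test_spherical_classes_give_mean_difference_weights(self, rng):
        mu = np.array([1.0, -2.0, 0.5])
        X = np.vstack(
            [rng.standard_normal((4000, 3)), rng.standard_normal((4000, 3)) + mu]
        )
        y = np.repeat([0, 1], 4000)
        model = fit_lda(FeatureMatrix(X, list("abc"), y), shrinkage=0.0)
        w = model.weights / np.linalg.norm(model.weights)
        np.testing.assert_allclose(np.abs(w @ (mu / np.linalg.norm(mu))), 1.0, atol=0.05)

    def test_single_class_rejected(self, rng):
        F = FeatureMatrix(rng.standard_normal((10, 2)), ["a", "b"], np.zeros(10, int))
        with pytest.raises(ValueError, match="2 classes"):
            fit_lda(F)
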