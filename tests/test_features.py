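"""Cropping, feature fusion, entropy curves, interval selection, DWC stats."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from wcmfe import (BPNetClassifier, EEGTrial, FEParams, Interval,
                   WCMFEFeatureExtractor, crop, dwc_stats, extract_features,
                   fuzzy_entropy, mean_entropy_curve, select_interval, wcmfe)


def make_trial(data, fs=128.0, names=None, label=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = names or tuple(f"ch{i}" for i in range(data.shape[0]))
    return EEGTrial(data=data, fs=fs, channel_names=names, label=label)


class TestCrop:
    def test_study_interval_length(self, rng):
        trial = make_trial(rng.standard_normal((2, 1152)))
        out = crop(trial, Interval(450, 900))
        assert out.n_samples == 451
        np.testing.assert_array_equal(out.data, trial.data[:, 449:900])

    def test_single_sample_and_identity(self, rng):
        trial = make_trial(rng.standard_normal((1, 10)))
        assert crop(trial, Interval(4, 4)).n_samples == 1
        np.testing.assert_array_equal(crop(trial, Interval(1, 10)).data,
                                      trial.data)

    def test_out_of_bounds(self, rng):
        trial = make_trial(rng.standard_normal((1, 10)))
        with pytest.raises(ValueError, match="exceeds"):
            crop(trial, Interval(5, 11))
        with pytest.raises(ValueError):
            Interval(0, 5)
        with pytest.raises(ValueError):
            Interval(7, 3)


class TestExtractFeatures:
    def test_two_channels_seven_scales_gives_14(self, rng):
        trial = make_trial(rng.standard_normal((2, 451)), names=("C3", "C4"))
        f = extract_features(trial, tau_max=7)
        assert f.shape == (14,)
        assert np.all(np.isfinite(f))

    def test_single_scale_single_channel_is_fe(self, rng):
        x = rng.standard_normal(100)
        trial = make_trial(x)
        f = extract_features(trial, tau_max=1)
        assert f.shape == (1,)
        assert f[0] == fuzzy_entropy(x, FEParams())

    def test_identical_channels_repeat_blocks(self, rng):
        x = rng.standard_normal(200)
        trial = make_trial(np.vstack([x, x]))
        f = extract_features(trial, tau_max=4)
        np.testing.assert_array_equal(f[0::2], f[1::2])

    def test_deterministic_and_channel_permutation(self, rng):
        data = rng.standard_normal((2, 200))
        t1 = make_trial(data, names=("C3", "C4"))
        t2 = make_trial(data[::-1], names=("C4", "C3"))
        f1 = extract_features(t1, tau_max=3)
        np.testing.assert_array_equal(f1, extract_features(t1, tau_max=3))
        f2 = extract_features(t2, tau_max=3)
        np.testing.assert_array_equal(f1[0::2], f2[1::2])
        np.testing.assert_array_equal(f1[1::2], f2[0::2])

    def test_error_names_channel_and_scale(self):
        trial = make_trial(np.random.default_rng(0).standard_normal((1, 20)),
                           names=("C3",))
        with pytest.raises(ValueError, match=r"channel 'C3', scale tau=\d"):
            extract_features(trial, tau_max=7)

    def test_uniform_h_matches_wcmfe_uniform(self, rng):
        x = rng.standard_normal(150)
        trial = make_trial(x)
        from wcmfe import uniform_weights
        f = extract_features(trial, tau_max=3, h="uniform")
        p = FEParams().resolved(x)
        for tau in (1, 2, 3):
            assert f[tau - 1] == wcmfe(x, tau, uniform_weights(tau), p)


class TestTransformer:
    def test_sklearn_api_roundtrip(self, rng):
        X = rng.standard_normal((4, 2, 160))
        fe = WCMFEFeatureExtractor(tau_max=3)
        F = fe.fit_transform(X)
        assert F.shape == (4, 6)
        assert fe.n_features_out_ == 6
        params = fe.get_params()
        assert params["tau_max"] == 3 and params["h"] == 3
        F2 = clone(fe).fit(X).transform(X)
        np.testing.assert_array_equal(F, F2)
        names = fe.get_feature_names_out()
        assert list(names[:2]) == ["wcmfe_tau1_ch0", "wcmfe_tau1_ch1"]

    def test_interval_applied_before_extraction(self, rng):
        X = rng.standard_normal((2, 1, 300))
        fe = WCMFEFeatureExtractor(tau_max=2, interval=(101, 300))
        F = fe.fit_transform(X)
        Fc = WCMFEFeatureExtractor(tau_max=2).fit_transform(X[:, :, 100:300])
        np.testing.assert_array_equal(F, Fc)

    def test_accepts_eegtrial_objects(self, small_dataset):
        _, trials, _ = small_dataset
        fe = WCMFEFeatureExtractor(tau_max=2, interval=(450, 900))
        F = fe.fit(trials[:1]).transform(trials[:3])
        assert F.shape == (3, 4)
        assert fe.channel_names_ == ("C3", "C4")

    def test_pipeline_composition(self, rng):
        # a full sklearn pipeline: trials in, class labels out
        X = rng.standard_normal((12, 2, 120))
        X[6:, :, :] *= 0.2  # second class: different amplitude dynamics
        y = np.array(["a"] * 6 + ["b"] * 6)
        pipe = Pipeline([
            ("fe", WCMFEFeatureExtractor(tau_max=2)),
            ("clf", BPNetClassifier(random_state=0)),
        ])
        pipe.fit(X, y)
        assert pipe.predict(X).shape == (12,)


class TestMeanEntropyCurve:
    def test_constant_trial_gives_zero_curve(self):
        trial = make_trial(np.full((1, 40), 3.0), fs=16.0)
        curve = mean_entropy_curve([trial], "ch0", window_s=1.0,
                                   step_samples=4, tau=2)
        np.testing.assert_array_equal(curve, 0.0)

    def test_curve_length_arithmetic(self, rng):
        trials = [make_trial(rng.standard_normal((1, 256)), fs=128.0)
                  for _ in range(2)]
        curve = mean_entropy_curve(trials, "ch0", window_s=1.0,
                                   step_samples=1, tau=2)
        assert curve.size == (256 - 128) // 1 + 1 == 129

    def test_class_curves_separate_on_modulated_channel(self, small_dataset):
        # left trials carry ERS (stronger mu) on C3, right trials ERD, so the
        # class-mean entropy curves must separate during the imagery period
        _, trials, labels = small_dataset
        left = [t for t, l in zip(trials, labels) if l == "left"]
        right = [t for t, l in zip(trials, labels) if l == "right"]
        curves = {}
        per_trial = {}
        for name, grp in (("left", left), ("right", right)):
            vals = np.array([
                mean_entropy_curve([t], "C3", window_s=1.0, step_samples=64,
                                   tau=2) for t in grp])
            per_trial[name] = vals
            curves[name] = vals.mean(axis=0)
        # imagery period: window starts between 3.5 s and 6 s
        sl = slice(7, 12)
        gap = np.abs(curves["left"][sl] - curves["right"][sl])
        se = np.sqrt(per_trial["left"][:, sl].var(axis=0, ddof=1) / len(left) +
                     per_trial["right"][:, sl].var(axis=0, ddof=1) / len(right))
        assert np.all(gap > 2 * se)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_entropy_curve([], "C3")


class TestSelectInterval:
    def test_identical_curves_tie_break_earliest(self):
        c = np.ones(50)
        iv = select_interval(c, c, 10)
        assert (iv.b, iv.d) == (1, 10)

    def test_difference_window_found(self):
        c1 = np.zeros(1000)
        c2 = np.zeros(1000)
        c2[449:900] = 1.0
        iv = select_interval(c1, c2, 200)
        assert 450 <= iv.b and iv.d <= 900

    def test_agrees_with_exhaustive_scan(self, rng):
        c1 = rng.standard_normal(120)
        c2 = rng.standard_normal(120)
        length = 17
        diff = np.abs(c1 - c2)
        means = [diff[s:s + length].mean() for s in range(120 - length + 1)]
        best = int(np.argmax(means))
        iv = select_interval(c1, c2, length)
        assert (iv.b, iv.d) == (best + 1, best + length)

    def test_length_exceeds_curve(self):
        with pytest.raises(ValueError):
            select_interval(np.zeros(5), np.zeros(5), 6)


class TestDWCStats:
    def test_identical_channels_zero(self):
        v = np.array([0.5, 0.7, 0.9, 1.1])
        labels = np.array(["left", "left", "right", "right"])
        out = dwc_stats(v, v, labels)
        for s in out.values():
            assert s.mwc == 0.0 and s.sdwc == 0.0

    def test_hand_arithmetic(self):
        c3 = np.array([2.0, 4.0, 3.0, 5.0])
        c4 = np.array([1.0, 1.0, 1.0, 1.0])
        labels = np.array(["left", "left", "right", "right"])
        out = dwc_stats(c3, c4, labels)
        assert out["left"].mwc == pytest.approx(2.0)
        assert out["left"].sdwc == pytest.approx(1.0)
        assert out["right"].mwc == pytest.approx(3.0)

    def test_synthetic_classes_have_opposite_sign(self, small_dataset):
        # ERD/ERS acts on opposite hemispheres per class, so the mean
        # C3 - C4 entropy difference flips sign between classes
        _, trials, labels = small_dataset
        p = FEParams()
        from wcmfe import make_weights
        w = make_weights(3, 3)
        c3 = [wcmfe(crop(t, Interval(450, 900)).channel("C3"), 3, w, p)
              for t in trials]
        c4 = [wcmfe(crop(t, Interval(450, 900)).channel("C4"), 3, w, p)
              for t in trials]
        out = dwc_stats(c3, c4, labels)
        assert np.sign(out["left"].mwc) != np.sign(out["right"].mwc)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dwc_stats([1.0, 2.0], [1.0], ["a", "b"])
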