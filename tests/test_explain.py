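"""Grad-CAM++ mechanics: normalisation, the single-filter closed form,
finite-difference gradient agreement, aggregation rules and the overlap
arithmetic."""

import numpy as np
import pytest

from conftest import tiny_spec
from pedecg import explain, nn
from pedecg.explain import (ClassCAMProfile, EmptyProfileError,
                            aggregate_class_cam, diff_window_samples,
                            gradcampp_1d, localization_score, overlap_cam)
from pedecg.model import TrainConfig, build_model


def beat_like(seed=0, n=1):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 0.1, size=(n, 300))
    x[:, 95:105] += 1.0
    return x[0] if n == 1 else x


class TestPerBeatCAM:
    def test_normalisation_contract(self):
        net = build_model(tiny_spec(), TrainConfig(seed=3))
        cam = gradcampp_1d(net, beat_like(), class_index=0)
        assert cam.shape == (300,)
        assert (cam >= 0).all()
        assert cam.max() == pytest.approx(1.0)

    def test_batch_shape(self):
        net = build_model(tiny_spec(), TrainConfig(seed=3))
        cams = gradcampp_1d(net, beat_like(n=4), class_index=1)
        assert cams.shape == (4, 300)

    def test_single_filter_closed_form(self):
        """With one conv filter and a uniform positive read-out weight,
        the gradient at every location is the same constant, the alpha
        terms cancel filter-wide, and the CAM must be proportional to
        the (rectified) feature map itself."""
        rng = np.random.default_rng(5)
        conv = nn.Conv1dSame(1, 1, 3, rng)
        relu = nn.ReLU()
        flat = nn.Flatten()
        dense = nn.Dense(300, 2, rng)
        dense.params["W"] = np.full((300, 2), 0.0, dtype=nn.DTYPE)
        dense.params["W"][:, 1] = 0.01          # uniform positive weight
        net = nn.Network([conv, relu, flat, dense], tap_index=1)

        beat = beat_like(seed=8)
        cam = gradcampp_1d(net, beat, class_index=1)
        fmap = relu.forward(conv.forward(
            beat.astype(nn.DTYPE)[None, None, :], False), False)[0, 0]
        expected = fmap / fmap.max()
        np.testing.assert_allclose(cam, expected, atol=1e-5)

    def test_model_without_conv_rejected(self):
        rng = np.random.default_rng(0)
        net = nn.Network([nn.Flatten(), nn.Dense(300, 2, rng)],
                         tap_index=None)
        with pytest.raises(explain.UnsupportedModelError):
            gradcampp_1d(net, beat_like(), 0)


class TestGradientOracle:
    def test_tap_gradients_match_finite_differences(self, float64_engine):
        """d(class score)/d(feature map) from backprop agrees with
        central finite differences through the network tail."""
        net = build_model(tiny_spec((3, 2)), TrainConfig(seed=9))
        x = beat_like(seed=4)[None, :]
        from pedecg.model import _as_nc_l
        a, grad = net.class_score_grad_at_tap(_as_nc_l(x), class_index=1)

        rng = np.random.default_rng(2)
        h = 1e-5
        for _ in range(12):
            c = int(rng.integers(a.shape[1]))
            l = int(rng.integers(a.shape[2]))
            up, down = a.copy(), a.copy()
            up[0, c, l] += h
            down[0, c, l] -= h
            fd = (net.forward_from_tap(up)[0, 1]
                  - net.forward_from_tap(down)[0, 1]) / (2 * h)
            assert grad[0, c, l] == pytest.approx(fd, rel=1e-3, abs=1e-10)


class TestAggregation:
    def test_only_correct_beats_enter_the_mean(self, tiny_trained):
        fitted, ds = tiny_trained
        x, y = ds.split("val")
        pred = fitted.predict(x)
        n_correct_obese = int(((y == 1) & (pred == 1)).sum())
        profile = aggregate_class_cam(fitted, (x, y), "obese")
        assert profile.n_beats == n_correct_obese
        assert profile.mean_cam.shape == (300,)

    def test_identical_beats_mean_equals_single_cam(self):
        net = build_model(tiny_spec(), TrainConfig(seed=13))
        beat = beat_like(seed=3)
        x = np.stack([beat, beat])
        cls = int(net.predict_proba(x[:, None, :])[0].argmax())
        y = np.array([cls, cls])
        profile = aggregate_class_cam(net, (x, y),
                                      ("normal", "obese")[cls])
        single = gradcampp_1d(net, beat, cls)
        np.testing.assert_allclose(profile.mean_cam, single, atol=1e-6)

    def test_no_correct_beats_raises(self, tiny_trained):
        fitted, ds = tiny_trained
        x, y = ds.split("val")
        wrong = 1 - fitted.predict(x)       # force all-incorrect labels
        with pytest.raises(EmptyProfileError):
            aggregate_class_cam(fitted, (x, wrong), "obese")


class TestOverlap:
    def prof(self, vec, label="normal"):
        return ClassCAMProfile(label, np.asarray(vec, dtype=float), 1)

    def test_identical_profiles(self):
        v = np.linspace(0, 1, 300)
        out = overlap_cam(self.prof(v), self.prof(v, "obese"))
        np.testing.assert_allclose(out.overlap, v)

    def test_zero_profile_halves_the_other(self):
        v = np.linspace(0, 1, 300)
        out = overlap_cam(self.prof(v), self.prof(np.zeros(300), "obese"))
        np.testing.assert_allclose(out.overlap, v / 2)

    def test_disjoint_supports_union_halved(self):
        a, b = np.zeros(300), np.zeros(300)
        a[:100] = 1.0
        b[200:] = 1.0
        out = overlap_cam(self.prof(a), self.prof(b, "obese")).overlap
        assert (out[:100] == 0.5).all() and (out[200:] == 0.5).all()
        assert (out[100:200] == 0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_cam(self.prof(np.zeros(300)),
                        self.prof(np.zeros(299), "obese"))


class TestLocalization:
    def test_uniform_cam_half_axis(self):
        assert localization_score(np.ones(300), 0, 150) == pytest.approx(0.5)

    def test_all_mass_inside(self):
        v = np.zeros(300)
        v[175:275] = 1.0
        assert localization_score(v, 175, 275) == 1.0

    def test_zero_mass_undefined(self):
        with pytest.raises(ValueError):
            localization_score(np.zeros(300), 0, 100)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            localization_score(np.ones(300), 200, 100)

    def test_window_mapping(self):
        assert diff_window_samples((150.0, 350.0)) == (175, 275)
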