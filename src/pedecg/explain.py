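"""Grad-CAM++ for 1D CNNs: per-beat relevance over the 300-sample beat
axis, per-class aggregation over correctly classified beats, and the
two-class overlap profile.

For a class score :math:`S^c` (the pre-softmax logit) and the feature
maps :math:`A^k_l` of the last convolutional block (k = filter,
l = position along the beat), Grad-CAM++ forms per-location weights

.. math::

    \\alpha^{kc}_l = \\frac{(\\partial S^c/\\partial A^k_l)^2}
        {2 (\\partial S^c/\\partial A^k_l)^2
         + \\sum_m A^k_m (\\partial S^c/\\partial A^k_m)^3}

    w^c_k = \\sum_l \\alpha^{kc}_l \\,
            \\mathrm{relu}(\\partial S^c/\\partial A^k_l)

and the map :math:`\\mathrm{CAM}^c_l = \\mathrm{relu}(\\sum_k w^c_k
A^k_l)`.  The higher-order derivative terms follow the usual
exponential-score reduction that expresses them through powers of the
first derivative.  Because every convolution in the classifier is
stride-1 with length-preserving padding, the map already lives on the
300-sample axis and needs no upsampling.  Each per-beat map is
normalised to maximum 1 (an all-zero map stays zero); a raw mode is
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TrainedModel, _as_nc_l
from .nn import Network

BEAT_AXIS = 300


class UnsupportedModelError(TypeError):
    pass


def _net_of(model) -> Network:
    net = model.net if isinstance(model, TrainedModel) else model
    if not isinstance(net, Network) or net.tap_index is None:
        raise UnsupportedModelError(
            "model exposes no convolutional feature maps")
    return net


def gradcampp_1d(model, beats: np.ndarray, class_index: int,
                 normalise: bool = True, eps: float = 1e-8) -> np.ndarray:
    """Grad-CAM++ relevance for one beat (300,) or a batch (N, 300).

    Returns an array of the same leading shape with a non-negative
    relevance vector over the 300-sample axis, max-normalised to 1
    unless ``normalise=False``.
    """
    net = _net_of(model)
    x = _as_nc_l(np.atleast_2d(np.asarray(beats)))
    a, grad = net.class_score_grad_at_tap(x, class_index)
    a = a.astype(np.float64)
    grad = grad.astype(np.float64)

    g2 = grad ** 2
    g3 = g2 * grad
    denom = 2.0 * g2 + np.sum(a * g3, axis=2, keepdims=True)
    # where the denominator vanishes the gradient is zero too -> alpha 0
    nonzero = denom != 0.0
    alpha = np.where(nonzero, g2 / np.where(nonzero, denom, 1.0), 0.0)
    weights = np.sum(alpha * np.maximum(grad, 0.0), axis=2)   # (N, C)
    cam = np.maximum(np.einsum("nc,ncl->nl", weights, a), 0.0)

    if normalise:
        peak = cam.max(axis=1, keepdims=True)
        cam = np.where(peak > 0, cam / np.where(peak > 0, peak, 1.0), cam)
    return cam[0] if np.asarray(beats).ndim == 1 else cam


@dataclass
class ClassCAMProfile:
    """Mean CAM over the correctly classified beats of one class."""

    class_label: str
    mean_cam: np.ndarray
    n_beats: int


@dataclass
class OverlapProfile:
    """Pointwise mean of the two class profiles."""

    overlap: np.ndarray


class EmptyProfileError(ValueError):
    pass


def aggregate_class_cam(model, split, class_label: str,
                        class_names=("normal", "obese"),
                        normalise: bool = True,
                        only_correct: bool = True) -> ClassCAMProfile:
    """Average the per-beat CAMs over exactly the beats of
    ``class_label`` that the model classifies correctly.

    ``only_correct=False`` aggregates over all beats of the class
    instead; that is the appropriate mode for permutation-null controls,
    where a chance-level model may classify no beat of some class
    correctly and "correctly classified" carries no information.
    """
    x, y = np.asarray(split[0]), np.asarray(split[1])
    class_index = class_names.index(class_label)
    net = _net_of(model)
    mask = y == class_index
    if only_correct:
        pred = net.predict_proba(_as_nc_l(x)).argmax(axis=1)
        mask &= pred == class_index
    if not mask.any():
        raise EmptyProfileError(
            f"no correctly classified beats of class {class_label!r}")
    cams = gradcampp_1d(model, x[mask], class_index, normalise=normalise)
    cams = np.atleast_2d(cams)
    return ClassCAMProfile(class_label=class_label,
                           mean_cam=cams.mean(axis=0),
                           n_beats=int(mask.sum()))


def overlap_cam(profile_normal: ClassCAMProfile,
                profile_obese: ClassCAMProfile) -> OverlapProfile:
    a, b = profile_normal.mean_cam, profile_obese.mean_cam
    if a.shape != b.shape:
        raise ValueError("profile length mismatch")
    return OverlapProfile(overlap=(a + b) / 2.0)


def localization_score(cam_vector: np.ndarray, region_start: int,
                       region_end: int) -> float:
    """Fraction of total CAM mass inside [region_start, region_end)."""
    cam = np.asarray(cam_vector, dtype=np.float64)
    if not (0 <= region_start < region_end <= cam.size):
        raise ValueError("invalid region bounds")
    total = cam.sum()
    if total <= 0:
        raise ValueError("zero total CAM mass: score undefined")
    return float(cam[region_start:region_end].sum() / total)


def diff_window_samples(diff_window_ms: tuple[float, float],
                        pre_samples: int = 100,
                        fs: int = 500) -> tuple[int, int]:
    """Map a difference window (ms relative to the R peak) onto beat
    sample indices (R sits at ``pre_samples``)."""
    lo = pre_samples + int(round(diff_window_ms[0] / 1000.0 * fs))
    hi = pre_samples + int(round(diff_window_ms[1] / 1000.0 * fs))
    return max(lo, 0), min(hi, BEAT_AXIS)
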