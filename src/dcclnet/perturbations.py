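"""Perturbation operators for consistency learning.

Three feature-map perturbations act on the shared encoder's bottleneck
before it enters an auxiliary decoder:

* **feature noise** — elementwise multiplicative uniform noise,
  ``h' = h * N + h`` with ``N ~ U(-3, 3)``, so the injected noise is
  proportional to each activation;
* **feature dropout** — a spatial attention map (channel-mean of ``h``,
  max-normalised to [0, 1]) is thresholded at ``gamma ~ U(0.6, 0.9)`` and
  the *most active* spatial regions are zeroed (10–40 % of a uniformly
  active map);
* **dropout** — standard channel-wise (spatial) dropout with inverted
  scaling.

A fourth operator perturbs the *input* image fed to the mean-teacher:
clipped additive Gaussian noise.

All operators preserve tensor shape, are driven by an explicit
``numpy.random.Generator``, and are only ever applied on unlabeled-data
paths (enforced in the trainer wiring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class InvalidConfigError(ValueError):
    pass


@dataclass
class PerturbationConfig:
    noise_low: float = -3.0
    noise_high: float = 3.0
    gamma_low: float = 0.6
    gamma_high: float = 0.9
    dropout_p: float = 0.5
    input_noise_sigma: float = 0.1
    input_noise_clip: float = 0.2
    mask_target: str = "features"  # or "attention": mask the attention map itself

    def __post_init__(self):
        if not self.noise_low < self.noise_high:
            raise InvalidConfigError("noise_low must be < noise_high")
        if not (0.0 < self.gamma_low < self.gamma_high <= 1.0):
            raise InvalidConfigError("need 0 < gamma_low < gamma_high <= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise InvalidConfigError("dropout_p must be in [0, 1)")
        if self.mask_target not in ("features", "attention"):
            raise InvalidConfigError(f"unknown mask_target {self.mask_target!r}")


def feature_noise(h, rng: np.random.Generator,
                  config: PerturbationConfig | None = None) -> Tensor:
    """``h' = h * N + h`` with ``N`` i.i.d. uniform; proportional noise."""
    config = config or PerturbationConfig()
    h = ad.as_tensor(h)
    noise = rng.uniform(config.noise_low, config.noise_high, size=h.shape).astype(
        h.dtype if np.issubdtype(h.dtype, np.floating) else np.float64)
    return h * noise + h


def _attention_map(hdata: np.ndarray, channel_axis: int) -> np.ndarray:
    """Channel-mean, normalised to [0, 1] by its spatial maximum."""
    att = hdata.mean(axis=channel_axis, keepdims=True)
    denom = np.abs(att).max(axis=tuple(range(channel_axis, att.ndim)), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(denom > 0, att / np.where(denom == 0, 1.0, denom), 0.0)
    return norm, denom


def feature_dropout(h, rng: np.random.Generator,
                    config: PerturbationConfig | None = None) -> Tensor:
    """Zero the most active spatial regions of ``h``.

    Accepts ``(C, H, W)`` or batched ``(N, C, H, W)`` maps; in the batched
    case the threshold ``gamma`` is drawn per sample.  A map whose
    attention is identically zero is returned unchanged (there is no
    "most active" region to mask).
    """
    config = config or PerturbationConfig()
    h = ad.as_tensor(h)
    if h.ndim == 3:
        channel_axis = 0
        gamma = rng.uniform(config.gamma_low, config.gamma_high)
    elif h.ndim == 4:
        channel_axis = 1
        gamma = rng.uniform(config.gamma_low, config.gamma_high,
                            size=(h.shape[0], 1, 1, 1))
    else:
        raise ValueError(f"feature_dropout expects (C,H,W) or (N,C,H,W), got {h.shape}")
    att, denom = _attention_map(h.data, channel_axis)
    keep = (att < gamma) | (denom == 0)  # degenerate maps pass through
    keep = keep.astype(h.dtype if np.issubdtype(h.dtype, np.floating) else np.float64)
    if config.mask_target == "features":
        return h * keep
    # literal reading: mask the attention map itself, broadcast over channels
    att_t = ad.mean(h, axis=channel_axis, keepdims=True) * (
        1.0 / np.where(denom == 0, 1.0, denom))
    masked = att_t * keep
    return masked + (h * 0.0)  # broadcast back to the feature-map shape


def dropout_perturb(h, rng: np.random.Generator, p: float = 0.5) -> Tensor:
    """Channel-wise (spatial) dropout with inverted scaling."""
    if not 0.0 <= p < 1.0:
        raise InvalidConfigError(f"dropout probability must be in [0, 1), got {p}")
    h = ad.as_tensor(h)
    if p == 0.0:
        return h
    if h.ndim == 3:
        mask_shape = (h.shape[0], 1, 1)
    elif h.ndim == 4:
        mask_shape = (h.shape[0], h.shape[1], 1, 1)
    else:
        mask_shape = h.shape
    dtype = h.dtype if np.issubdtype(h.dtype, np.floating) else np.float64
    mask = (rng.random(mask_shape) >= p).astype(dtype) / np.asarray(1.0 - p, dtype=dtype)
    return h * mask


def input_noise(x: np.ndarray, rng: np.random.Generator,
                config: PerturbationConfig | None = None) -> np.ndarray:
    """Clipped additive Gaussian noise for the teacher's input."""
    config = config or PerturbationConfig()
    x = np.asarray(x)
    if config.input_noise_sigma == 0.0:
        return x.copy()
    eps = rng.normal(0.0, config.input_noise_sigma, size=x.shape)
    eps = np.clip(eps, -config.input_noise_clip, config.input_noise_clip)
    return (x + eps).astype(x.dtype if np.issubdtype(x.dtype, np.floating) else np.float64)
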