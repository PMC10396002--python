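"""Fusion strategy: base-layer extrema, sigma-weighted base fusion, and the
standard-deviation-adaptive detail weight.

The two base layers are combined through their pixelwise maximum and
minimum; the fused base is a convex combination weighted by the standard
deviations of those extrema images, with the *larger* weight on the
minimum image (tempering over-bright regions):

    I_BF = [min(s_max, s_min)/(s_max+s_min)] I_Bmax
         + [max(s_max, s_min)/(s_max+s_min)] I_Bmin.

Detail layers from both sources are then added back with a single adaptive
weight k driven by four standard deviations — sigma1, sigma2 of the source
images and sigma3, sigma4 of I_Bmax, I_Bmin:

    rho = (sqrt(sigma1+sigma2) - sqrt(sigma3+sigma4)) / sqrt(sigma3+sigma4)
    k   = 1 + sgn(min(sigma1, sigma2) - T) * rho        (T = 30, 8-bit scale)

so high-contrast pairs (both source sigmas above the threshold) get detail
*enhancement* (k > 1) and low-contrast pairs get *attenuation* (k < 1).
The fused image is ``I_BF + k*(bright1+bright2) - k*(dark1+dark2)``,
clamped to [0, 255].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .decomposition import LayerSet, decompose
from .wmf import INTENSITY_MAX, as_intensity

logger = logging.getLogger("icif")


@dataclass
class FusionConfig:
    """Tunable parameters of the whole pipeline.

    radius, ni, nf, bandwidth, wmf_mode parameterize the guided weighted
    median filter; weight_mode selects the detail-weight branch
    (``auto`` switches on the sigma threshold, ``positive``/``negative``
    force a branch, ``fixed`` uses ``fixed_k``); radical_grouping chooses
    between the grouped radical ``sqrt(s1+s2)`` (default) and the per-term
    ``sqrt(s1)+sqrt(s2)`` reading; sigma_source picks whether sigma3/4 come
    from the base-extrema images (default) or from each source's own base.
    """

    radius: int = 5
    ni: int = 256
    nf: int = 32
    bandwidth: float = 0.1
    wmf_mode: str = "accelerated"
    weight_mode: str = "auto"  # auto | positive | negative | fixed
    fixed_k: float | None = None
    sigma_threshold: float = 30.0
    radical_grouping: str = "grouped"  # grouped | per-term
    sigma_source: str = "extrema"  # extrema | own_base

    def __post_init__(self):
        if self.sigma_threshold <= 0:
            raise ValueError("sigma_threshold must be > 0")
        if self.weight_mode not in ("auto", "positive", "negative", "fixed"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.weight_mode == "fixed":
            if self.fixed_k is None or self.fixed_k <= 0:
                raise ValueError("weight_mode='fixed' requires fixed_k > 0")
        if self.radical_grouping not in ("grouped", "per-term"):
            raise ValueError(f"unknown radical_grouping {self.radical_grouping!r}")
        if self.sigma_source not in ("extrema", "own_base"):
            raise ValueError(f"unknown sigma_source {self.sigma_source!r}")


@dataclass
class FusionWeights:
    """Diagnostic record of the adaptive weighting for one fusion job."""

    sigma1: float
    sigma2: float
    sigma3: float
    sigma4: float
    k: float
    branch: str  # positive | negative | neutral | fixed

    def as_dict(self) -> dict:
        return {"sigma1": self.sigma1, "sigma2": self.sigma2,
                "sigma3": self.sigma3, "sigma4": self.sigma4,
                "k": self.k, "branch": self.branch}


def base_extrema(b1, b2) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise maximum and minimum of the two base layers."""
    b1 = np.asarray(b1, dtype=np.float64)
    b2 = np.asarray(b2, dtype=np.float64)
    if b1.shape != b2.shape:
        raise ValueError(f"shape mismatch: {b1.shape} vs {b2.shape}")
    return np.maximum(b1, b2), np.minimum(b1, b2)


def fuse_base(ib_max, ib_min) -> np.ndarray:
    """Standard-deviation-weighted combination of the base extrema.

    Weights sum to 1; when both extrema images are flat (zero sigma) the
    combination falls back to the plain average.
    """
    ib_max = np.asarray(ib_max, dtype=np.float64)
    ib_min = np.asarray(ib_min, dtype=np.float64)
    if ib_max.shape != ib_min.shape:
        raise ValueError(f"shape mismatch: {ib_max.shape} vs {ib_min.shape}")
    s_max = float(np.std(ib_max))
    s_min = float(np.std(ib_min))
    total = s_max + s_min
    if total == 0.0:
        w_max = w_min = 0.5
    else:
        w_max = min(s_max, s_min) / total
        w_min = max(s_max, s_min) / total
    return w_max * ib_max + w_min * ib_min


def _detail_weights(sigma1: float, sigma2: float, sigma3: float, sigma4: float,
                    config: FusionConfig | None = None) -> FusionWeights:
    config = config or FusionConfig()
    sigmas = (sigma1, sigma2, sigma3, sigma4)
    if any(not math.isfinite(s) or s < 0 for s in sigmas):
        raise ValueError(f"standard deviations must be finite and >= 0: {sigmas}")

    if config.radical_grouping == "grouped":
        num = math.sqrt(sigma1 + sigma2)
        den = math.sqrt(sigma3 + sigma4)
    else:  # per-term
        num = math.sqrt(sigma1) + math.sqrt(sigma2)
        den = math.sqrt(sigma3) + math.sqrt(sigma4)
    rho = 0.0 if den == 0.0 else (num - den) / den

    mode = config.weight_mode
    if mode == "fixed":
        return FusionWeights(*sigmas, k=float(config.fixed_k), branch="fixed")
    if mode == "positive":
        return FusionWeights(*sigmas, k=1.0 + rho, branch="positive")
    if mode == "negative":
        return FusionWeights(*sigmas, k=1.0 - rho, branch="negative")
    # auto
    margin = min(sigma1, sigma2) - config.sigma_threshold
    if margin > 0:
        return FusionWeights(*sigmas, k=1.0 + rho, branch="positive")
    if margin < 0:
        return FusionWeights(*sigmas, k=1.0 - rho, branch="negative")
    return FusionWeights(*sigmas, k=1.0, branch="neutral")


def detail_weight_k(sigma1: float, sigma2: float, sigma3: float, sigma4: float,
                    config: FusionConfig | None = None) -> float:
    """Adaptive detail-layer weight k from the four standard deviations.

    In ``auto`` mode the sign term ``sgn(min(sigma1, sigma2) - threshold)``
    selects enhancement (k > 1) or attenuation (k < 1); exactly at the
    threshold the sign is defined as 0 and k = 1.  When sigma3 + sigma4 = 0
    (flat base extrema) k = 1.
    """
    return _detail_weights(sigma1, sigma2, sigma3, sigma4, config).k


def recombine(ib_f, layers1: LayerSet, layers2: LayerSet, k: float) -> np.ndarray:
    """Fused image before clamping: I_BF + k*(brights) - k*(darks)."""
    return (ib_f
            + k * (layers1.bright + layers2.bright)
            - k * (layers1.dark + layers2.dark))


def fuse_images(image1, image2, config: FusionConfig | None = None,
                ) -> tuple[np.ndarray, FusionWeights]:
    """Full fusion pipeline for one co-registered pair.

    Cross-clusters both images, decomposes them, fuses the bases through
    their sigma-weighted extrema, applies the adaptive detail weight, and
    clamps the recombination to [0, 255].  Symmetric under input swap.

    Returns the fused image and the :class:`FusionWeights` diagnostics.
    """
    config = config or FusionConfig()
    i1 = as_intensity(image1, "image1")
    i2 = as_intensity(image2, "image2")
    if i1.shape != i2.shape:
        raise ValueError(f"shape mismatch: {i1.shape} vs {i2.shape}")

    layers1 = decompose(i1, i2, config)
    layers2 = decompose(i2, i1, config)
    ib_max, ib_min = base_extrema(layers1.base, layers2.base)
    ib_f = fuse_base(ib_max, ib_min)

    sigma1 = float(np.std(i1))
    sigma2 = float(np.std(i2))
    if config.sigma_source == "extrema":
        sigma3 = float(np.std(ib_max))
        sigma4 = float(np.std(ib_min))
    else:
        sigma3 = float(np.std(layers1.base))
        sigma4 = float(np.std(layers2.base))
        if sigma3 < sigma4:  # keep swap symmetry
            sigma3, sigma4 = sigma4, sigma3

    weights = _detail_weights(sigma1, sigma2, sigma3, sigma4, config)
    fused = recombine(ib_f, layers1, layers2, weights.k)

    n_clamped = int(np.count_nonzero((fused < 0.0) | (fused > INTENSITY_MAX)))
    if n_clamped:
        logger.info("fusion clamped %d pixel(s) to [0, 255]", n_clamped)
    fused = np.clip(fused, 0.0, INTENSITY_MAX)
    logger.debug("fusion weights: %s", weights.as_dict())
    return fused, weights
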