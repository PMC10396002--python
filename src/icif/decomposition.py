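"""Cross-guided two-scale decomposition.

Each source image is split into a *base layer* — the information-clustering
result ``IC(I)``, i.e. the guided weighted median filter of the image under
a guidance map built from the *other* modality — and two nonnegative detail
layers: the bright details (source above base) and the dark details (base
above source).  The decomposition reconstructs exactly:

    I = base + bright - dark,   bright >= 0, dark >= 0, bright * dark = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wmf import INTENSITY_MAX, as_intensity, guided_wmf


@dataclass
class LayerSet:
    """Base + bright-detail + dark-detail layers of one source image."""

    base: np.ndarray
    bright: np.ndarray
    dark: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.base + self.bright - self.dark


def guidance_map(other) -> np.ndarray:
    """Guidance map ``f = 0.5 * I*`` from the other modality.

    ``I*`` is the other image normalized from the 0-255 scale to [0, 1],
    so the guidance lies in [0, 0.5].  When clustering the infrared image
    the guidance comes from the visible image and vice versa.
    """
    other = as_intensity(other, "guidance source")
    return 0.5 * (other / INTENSITY_MAX)


def cluster_base(image, other, config) -> np.ndarray:
    """Base layer ``IC(I)``: guided WMF of ``image`` under the other modality.

    ``config`` supplies the filter parameters (radius, bin counts,
    bandwidth, backend); see :class:`icif.fusion.FusionConfig`.
    """
    image = as_intensity(image, "image")
    other = as_intensity(other, "other")
    if image.shape != other.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {other.shape}")
    return guided_wmf(image, guidance_map(other),
                      radius=config.radius, ni=config.ni, nf=config.nf,
                      bandwidth=config.bandwidth, mode=config.wmf_mode)


def detail_layers(image, base) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative bright/dark detail layers about the base.

    ``bright = max(I - base, 0)`` and ``dark = max(base - I, 0)``; as the
    positive and negative parts of the same residual they have disjoint
    support and satisfy the exact reconstruction identity.
    """
    image = np.asarray(image, dtype=np.float64)
    base = np.asarray(base, dtype=np.float64)
    if image.shape != base.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {base.shape}")
    residual = image - base
    return np.maximum(residual, 0.0), np.maximum(-residual, 0.0)


def decompose(image, other, config) -> LayerSet:
    """Full layer set of ``image`` clustered under guidance from ``other``."""
    base = cluster_base(image, other, config)
    bright, dark = detail_layers(image, base)
    return LayerSet(base=base, bright=bright, dark=dark)
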