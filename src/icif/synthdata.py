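"""Seeded generator of co-registered two-modality image pairs.

Stands in for field data (thermal + visible surveillance pairs, CT + MRI):
a shared piecewise-smooth scene is rendered twice with modality-specific
contrast.  Modality A is "visible-like" (rich large-scale structure plus
fine texture); modality B is "thermal-like" (flattened structure) with
bright blob targets at mask locations.  The structure fields are
standardized before amplitude scaling, so the ``high`` texture preset
reliably yields source standard deviations above the 8-bit adaptive-weight
threshold (30) and the ``low`` preset below it — both branches of the
detail-weight rule are exercised.

All randomness flows from one ``numpy`` Generator seeded by
``SynthParams.seed``; identical parameters give bit-identical pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .wmf import INTENSITY_MAX

# amplitudes of the standardized structure field per preset (8-bit scale)
_STRUCT_AMP = {"high": (52.0, 40.0), "low": (11.0, 8.0)}
_TEXTURE_AMP = {"high": (8.0, 5.0), "low": (3.0, 2.0)}
_MEAN_LEVEL = (128.0, 115.0)


@dataclass
class SynthParams:
    """Parameters of one synthetic co-registered pair."""

    seed: int = 0
    size: tuple[int, int] = (96, 96)
    n_blobs: int = 3
    texture_preset: str = "high"  # high | low
    target_contrast: float = 140.0
    noise_sd: float = 2.0

    def __post_init__(self):
        h, w = self.size
        if h <= 0 or w <= 0:
            raise ValueError(f"image size must be positive, got {self.size}")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        if self.texture_preset not in _STRUCT_AMP:
            raise ValueError(f"unknown texture_preset {self.texture_preset!r}")
        if not 0 <= self.target_contrast <= INTENSITY_MAX:
            raise ValueError("target_contrast must be on the 0-255 scale")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _standardize(field: np.ndarray) -> np.ndarray:
    sd = field.std()
    if sd == 0.0:
        return np.zeros_like(field)
    return (field - field.mean()) / sd


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    return _standardize(ndimage.gaussian_filter(rng.standard_normal(shape), sigma))


def _blob_mask(rng, shape, n_blobs) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    r_lo = max(2.0, 0.05 * min(h, w))
    r_hi = max(r_lo + 1.0, 0.10 * min(h, w))
    for _ in range(n_blobs):
        cy = rng.uniform(0.15 * h, 0.85 * h)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        ry = rng.uniform(r_lo, r_hi)
        rx = rng.uniform(r_lo, r_hi)
        mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return mask


def make_pair(params: SynthParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one co-registered pair plus the bright-target mask.

    Returns ``(mod_a, mod_b, target_mask)``: two float images quantized to
    whole 8-bit levels on the 0-255 scale and a boolean grid marking the
    thermal-like targets (nonempty whenever ``n_blobs > 0``).
    """
    h, w = params.size
    rng = np.random.default_rng(params.seed)
    scale = max(2.0, min(h, w) / 12.0)

    structure = _smooth_field(rng, (h, w), scale)
    # modality B sees a flatter version of the same geometry
    structure_b = _standardize(ndimage.gaussian_filter(structure, scale / 3.0))
    tex_a = _smooth_field(rng, (h, w), 1.0)
    tex_b = _smooth_field(rng, (h, w), 1.5)
    mask = _blob_mask(rng, (h, w), params.n_blobs)
    # full contrast inside the mask, blurred halo outside: the mask
    # faithfully marks the rendered bright region
    soft = np.maximum(mask.astype(np.float64),
                      ndimage.gaussian_filter(mask.astype(np.float64), 1.5))

    amp_a, amp_b = _STRUCT_AMP[params.texture_preset]
    tex_amp_a, tex_amp_b = _TEXTURE_AMP[params.texture_preset]
    mean_a, mean_b = _MEAN_LEVEL

    mod_a = (mean_a + amp_a * structure + tex_amp_a * tex_a
             + 0.3 * params.target_contrast * soft)
    mod_b = (mean_b + amp_b * structure_b + tex_amp_b * tex_b
             + params.target_contrast * soft)
    if params.noise_sd > 0:
        mod_a = mod_a + rng.normal(0.0, params.noise_sd, (h, w))
        mod_b = mod_b + rng.normal(0.0, params.noise_sd, (h, w))

    # quantize to whole 8-bit levels, like the raster data this emulates
    mod_a = np.round(np.clip(mod_a, 0.0, INTENSITY_MAX))
    mod_b = np.round(np.clip(mod_b, 0.0, INTENSITY_MAX))
    return mod_a, mod_b, mask
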