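"""Fusion-quality metrics.

Single-image sharpness/information measures — average gradient (AG),
Shannon entropy (H), standard deviation (SD), spatial frequency (SF), edge
intensity (EI) — and the Xydeas-Petrovic gradient-preservation triple for a
source pair and its fused result: the fusion quantity Q^AB/F, the fusion
loss L^AB/F and the fusion artifacts N^AB/F.

The Petrovic model compares Sobel gradient strength and orientation of the
fused image against each source, maps the strength- and
orientation-preservation ratios through sigmoids with the published
constants, and aggregates with edge-strength weights:

    Q^AB/F = sum(Q_AF w_A + Q_BF w_B) / sum(w_A + w_B),   w_X = g_X.

Loss accumulates the unpreserved fraction where the fused gradient is
weaker than a source's; artifacts accumulate it where the fused gradient
exceeds both sources (spurious edge energy).  With these (weight-bounded)
definitions Q and L lie in [0, 1] and N in [0, 1]; no Q + L + N = 1
constraint holds or is imposed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger("icif")

# Published sigmoid constants of the gradient-preservation model
# (strength: Gamma_g, kappa_g, sigma_g; orientation: Gamma_a, kappa_a, sigma_a).
PETROVIC_CONSTANTS = {
    "gamma_g": 0.9994, "kappa_g": -15.0, "sigma_g": 0.5,
    "gamma_a": 0.9879, "kappa_a": -22.0, "sigma_a": 0.8,
}


def _check_image(image, min_side: int = 1) -> np.ndarray:
    a = np.asarray(image, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {a.shape}")
    if min(a.shape) < min_side:
        raise ValueError(f"image too small for this metric: {a.shape}")
    return a


def average_gradient(image) -> float:
    """Mean of sqrt((dx^2 + dy^2)/2) over forward-difference pixels."""
    a = _check_image(image)
    if a.shape[0] < 2 or a.shape[1] < 2:
        logger.warning("average_gradient of degenerate image; returning 0")
        return 0.0
    dx = a[:-1, 1:] - a[:-1, :-1]
    dy = a[1:, :-1] - a[:-1, :-1]
    return float(np.mean(np.sqrt((dx * dx + dy * dy) / 2.0)))


def entropy(image) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram."""
    a = _check_image(image)
    hist, _ = np.histogram(a, bins=256, range=(0.0, 256.0))
    p = hist[hist > 0] / a.size
    return float(-np.sum(p * np.log2(p)))


def std_dev(image) -> float:
    """Population standard deviation of intensities (0-255 scale)."""
    return float(np.std(_check_image(image)))


def spatial_frequency(image) -> float:
    """sqrt(RF^2 + CF^2): RMS of horizontal and vertical neighbour steps."""
    a = _check_image(image, min_side=2)
    rf = math.sqrt(float(np.mean((a[:, 1:] - a[:, :-1]) ** 2)))
    cf = math.sqrt(float(np.mean((a[1:, :] - a[:-1, :]) ** 2)))
    return math.hypot(rf, cf)


def _sobel(image):
    sx = ndimage.sobel(image, axis=1, mode="reflect")
    sy = ndimage.sobel(image, axis=0, mode="reflect")
    return sx, sy


def edge_intensity(image) -> float:
    """Mean Sobel gradient magnitude (reflect padding)."""
    a = _check_image(image, min_side=3)
    sx, sy = _sobel(a)
    return float(np.mean(np.hypot(sx, sy)))


def _grad_polar(image):
    sx, sy = _sobel(image)
    g = np.hypot(sx, sy)
    # orientation in (-pi/2, pi/2]; vertical edge convention where sx == 0
    alpha = np.where(sx == 0.0, np.pi / 2.0,
                     np.arctan(np.divide(sy, sx, out=np.zeros_like(sy),
                                         where=sx != 0.0)))
    return g, alpha


def _sigmoid(x, gamma, kappa, sigma):
    return gamma / (1.0 + np.exp(kappa * (x - sigma)))


def _preservation(g_src, a_src, g_fus, a_fus, constants):
    """Per-pixel edge-information preservation Q_XF of one source in F."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            g_src == g_fus, 1.0,
            np.where(g_src > g_fus,
                     np.divide(g_fus, g_src, out=np.zeros_like(g_fus),
                               where=g_src != 0.0),
                     np.divide(g_src, g_fus, out=np.zeros_like(g_src),
                               where=g_fus != 0.0)))
    a_pres = 1.0 - np.abs(a_src - a_fus) / (np.pi / 2.0)
    qg = _sigmoid(ratio, constants["gamma_g"], constants["kappa_g"],
                  constants["sigma_g"])
    qa = _sigmoid(a_pres, constants["gamma_a"], constants["kappa_a"],
                  constants["sigma_a"])
    return qg * qa


def petrovic_scores(image_a, image_b, fused,
                    constants: dict | None = None) -> tuple[float, float, float]:
    """Gradient-preservation triple (Q^AB/F, L^AB/F, N^AB/F).

    Q weighs per-pixel preservation of each source by that source's edge
    strength; L counts unpreserved information where the fused gradient is
    weaker than the source's; N counts it where the fused gradient exceeds
    both sources.  Returns (0, 0, 0) with a warning for edge-free sources.
    """
    a = _check_image(image_a, min_side=3)
    b = _check_image(image_b, min_side=3)
    f = _check_image(fused, min_side=3)
    if not (a.shape == b.shape == f.shape):
        raise ValueError(
            f"shape mismatch: {a.shape}, {b.shape}, {f.shape}")
    constants = constants or PETROVIC_CONSTANTS

    g_a, al_a = _grad_polar(a)
    g_b, al_b = _grad_polar(b)
    g_f, al_f = _grad_polar(f)

    q_af = _preservation(g_a, al_a, g_f, al_f, constants)
    q_bf = _preservation(g_b, al_b, g_f, al_f, constants)

    w_total = float(np.sum(g_a + g_b))
    if w_total == 0.0:
        logger.warning("petrovic_scores: both sources are edge-free")
        return 0.0, 0.0, 0.0

    q = float(np.sum(q_af * g_a + q_bf * g_b)) / w_total
    loss = float(np.sum((g_f < g_a) * (1.0 - q_af) * g_a
                        + (g_f < g_b) * (1.0 - q_bf) * g_b)) / w_total
    artifact_mask = (g_f > g_a) & (g_f > g_b)
    n = float(np.sum(artifact_mask * ((1.0 - q_af) * g_a
                                      + (1.0 - q_bf) * g_b))) / w_total
    return q, loss, n


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """All metrics for one (source A, source B, fused) triple."""

    ag: float
    h: float
    sd: float
    sf: float
    ei: float
    q_abf: float
    l_abf: float
    n_abf: float

    FIELDS = ("ag", "h", "sd", "sf", "ei", "q_abf", "l_abf", "n_abf")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)

    def to_tsv(self, label: str = "fused", header: bool = True) -> str:
        lines = []
        if header:
            lines.append("\t".join(("image",) + self.FIELDS))
        lines.append("\t".join([label] + [f"{getattr(self, n):.6g}"
                                          for n in self.FIELDS]))
        return "\n".join(lines) + "\n"


def image_metrics(image) -> dict:
    """The five single-image metrics as a dict."""
    return {"ag": average_gradient(image), "h": entropy(image),
            "sd": std_dev(image), "sf": spatial_frequency(image),
            "ei": edge_intensity(image)}


def metric_report(image_a, image_b, fused) -> MetricReport:
    """Single-image metrics of the fused result plus the Petrovic triple."""
    single = image_metrics(fused)
    q, loss, n = petrovic_scores(image_a, image_b, fused)
    return MetricReport(q_abf=q, l_abf=loss, n_abf=n, **single)
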