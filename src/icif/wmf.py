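"""Guided weighted median filtering ("information clustering").

The operator smooths an intensity image while respecting edges of a
*guidance* image: each output pixel is the weighted median of its window,
where a neighbour's weight is an exponential affinity between its guidance
value and the centre's guidance value.  Smoothing one modality under the
guidance of the other is what couples the two sensors' feature layers.

Two backends compute the same result:

``naive``
    Direct per-window evaluation: quantize the window, accumulate the
    weighted counts, select the median bin.
``accelerated``
    Sliding-window joint histogram over (intensity bin, guidance bin),
    incremental balance-counting-box updates against a running cut point,
    and a necklace table (circular linked ring) over the nonempty guidance
    bins so traversal skips zero columns.

Both backends evaluate the balance statistic at a cut ``c``,

    b(c) = sum_f (2 * #{i <= c at f} - n_f) * g(f_center, f(p)),

with :func:`math.fsum` over identical integer-count/weight products, so
they agree bit-for-bit; the median bin is the smallest ``c`` with
``b(c) >= 0``.  Windows at the image border are truncated (only in-image
pixels enter the histogram), which preserves the selection property: every
output value occurs among the window's input values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("icif")

#: Intensity scale assumed throughout: 8-bit range [0, 255].
INTENSITY_MAX = 255.0


# ---------------------------------------------------------------------------
# validation / quantization
# ---------------------------------------------------------------------------

def _as_float_image(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def as_intensity(arr, name: str = "image") -> np.ndarray:
    """Coerce to a 2-D float intensity grid on the 0-255 scale (clamped)."""
    a = _as_float_image(arr, name)
    if a.size and (a.min() < 0.0 or a.max() > INTENSITY_MAX):
        logger.warning("%s has values outside [0, 255]; clamping on ingest", name)
        a = np.clip(a, 0.0, INTENSITY_MAX)
    return a


def as_guidance(arr, name: str = "guidance") -> np.ndarray:
    """Coerce to a 2-D float guidance grid in [0, 1] (clamped)."""
    a = _as_float_image(arr, name)
    if a.size and (a.min() < 0.0 or a.max() > 1.0):
        logger.warning("%s has values outside [0, 1]; clamping on ingest", name)
        a = np.clip(a, 0.0, 1.0)
    return a


def quantize_intensity(values: np.ndarray, ni: int) -> np.ndarray:
    """Map 0-255 intensities to bin indices 0..ni-1 (edge bins clamp)."""
    bins = np.floor(np.asarray(values, dtype=np.float64) * (ni / 256.0)).astype(np.int64)
    return np.clip(bins, 0, ni - 1)


def quantize_guidance(values: np.ndarray, nf: int) -> np.ndarray:
    """Map [0, 1] guidance values to bin indices 0..nf-1 (edge bins clamp)."""
    bins = np.floor(np.asarray(values, dtype=np.float64) * nf).astype(np.int64)
    return np.clip(bins, 0, nf - 1)


def guidance_bin_centers(nf: int) -> np.ndarray:
    """Centre guidance value of each of the ``nf`` bins on [0, 1]."""
    return (np.arange(nf, dtype=np.float64) + 0.5) / nf


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def affinity_weight(fp: float, fq: float, bandwidth: float) -> float:
    """Affinity ``exp(-|fp - fq| / bandwidth)`` between two guidance values.

    Symmetric, in (0, 1], and equal to 1 iff ``fp == fq``.  ``bandwidth``
    sets the guidance-contrast scale at which neighbours stop influencing
    the median (default 0.1 elsewhere, on [0, 1] guidance).
    """
    if not (math.isfinite(fp) and math.isfinite(fq) and math.isfinite(bandwidth)):
        raise ValueError("affinity_weight requires finite inputs")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    return math.exp(-abs(fp - fq) / bandwidth)


def weighted_median(values, weights) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half.

    Pairs are sorted ascending by value (stable); the returned value is
    always a member of ``values``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    w = np.asarray(weights, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("weighted_median of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1], side="left"))
    return float(v[order[idx]])


# ---------------------------------------------------------------------------
# joint histogram / balance counting box
# ---------------------------------------------------------------------------

@dataclass
class JointHistogram:
    """Per-window count table over (intensity bin, guidance bin)."""

    counts: np.ndarray  # (ni, nf) nonnegative ints
    ni: int
    nf: int
    n: int  # total pixel count in the window


@dataclass
class BalanceState:
    """A cut point and its signed left-minus-right weighted count."""

    cut: int
    balance: float


def build_joint_histogram(window_intensities, window_guidance,
                          ni: int, nf: int) -> JointHistogram:
    """Count window pixels into an ``ni`` x ``nf`` joint histogram.

    Out-of-range values clamp to the edge bins (logged once per call).
    """
    iv = np.asarray(window_intensities, dtype=np.float64).ravel()
    fv = np.asarray(window_guidance, dtype=np.float64).ravel()
    if iv.shape != fv.shape:
        raise ValueError("intensity and guidance windows must match in length")
    if ni < 1 or nf < 1:
        raise ValueError("bin counts must be >= 1")
    out_of_range = (iv.size and (iv.min() < 0 or iv.max() > INTENSITY_MAX
                                 or fv.min() < 0 or fv.max() > 1))
    if out_of_range:
        logger.warning("joint histogram input outside range; clamping to edge bins")
    ib = quantize_intensity(iv, ni)
    fb = quantize_guidance(fv, nf)
    counts = np.zeros((ni, nf), dtype=np.int64)
    np.add.at(counts, (ib, fb), 1)
    return JointHistogram(counts=counts, ni=ni, nf=nf, n=int(iv.size))


def column_weight_sum(hist: JointHistogram, i: int,
                      center_guidance: float, bandwidth: float) -> float:
    """Weighted count of intensity bin ``i``: sum_f H(i,f) * g(f_center, f(p))."""
    if not 0 <= i < hist.ni:
        raise ValueError(f"intensity bin {i} out of range [0, {hist.ni})")
    centers = guidance_bin_centers(hist.nf)
    row = hist.counts[i]
    nz = np.nonzero(row)[0]
    return math.fsum(
        float(row[f]) * affinity_weight(centers[f], center_guidance, bandwidth)
        for f in nz
    )


def balance_at_cut(hist: JointHistogram, cut: int,
                   center_guidance: float, bandwidth: float) -> BalanceState:
    """Weighted (count at intensity <= cut) minus (count at intensity > cut).

    The weighted-median bin is the smallest cut with nonnegative balance.
    """
    if not 0 <= cut < hist.ni:
        raise ValueError(f"cut {cut} out of range [0, {hist.ni})")
    centers = guidance_bin_centers(hist.nf)
    left = hist.counts[: cut + 1].sum(axis=0)
    total = hist.counts.sum(axis=0)
    bcb = 2 * left - total  # B(f) aggregated against the cut
    nz = np.nonzero(total)[0]
    b = math.fsum(
        float(bcb[f]) * affinity_weight(centers[f], center_guidance, bandwidth)
        for f in nz
    )
    return BalanceState(cut=int(cut), balance=b)


# ---------------------------------------------------------------------------
# necklace table
# ---------------------------------------------------------------------------

class NecklaceTable:
    """Circular doubly-linked ring over the nonempty guidance bins.

    Insert/delete are O(1); traversal touches only nonempty entries, so
    per-pixel balance sums skip the (typically many) zero columns of the
    joint histogram.  Slot ``nf`` is the head sentinel.
    """

    def __init__(self, nf: int):
        self.nf = nf
        self._next = np.empty(nf + 1, dtype=np.int64)
        self._prev = np.empty(nf + 1, dtype=np.int64)
        self.member = np.zeros(nf + 1, dtype=bool)
        self.clear()

    def clear(self) -> None:
        head = self.nf
        self._next[head] = head
        self._prev[head] = head
        self.member[:] = False

    def insert(self, f: int) -> None:
        if self.member[f]:
            raise ValueError(f"bin {f} already in ring")
        head = self.nf
        nxt = self._next[head]
        self._next[head] = f
        self._prev[f] = head
        self._next[f] = nxt
        self._prev[nxt] = f
        self.member[f] = True

    def delete(self, f: int) -> None:
        if not self.member[f]:
            raise ValueError(f"bin {f} not in ring")
        p, nx = self._prev[f], self._next[f]
        self._next[p] = nx
        self._prev[nx] = p
        self.member[f] = False

    def __iter__(self):
        head = self.nf
        f = self._next[head]
        while f != head:
            yield int(f)
            f = self._next[f]

    def __len__(self) -> int:
        return int(self.member[: self.nf].sum())


# ---------------------------------------------------------------------------
# guided weighted median filter
# ---------------------------------------------------------------------------

def _representative(window_vals: np.ndarray, window_ibins: np.ndarray,
                    median_bin: int) -> float:
    """Representative output value of the median bin.

    The lower median of the window's original values inside the bin: for
    8-bit data with 256 bins this is the bin's single value (lossless);
    for finer data it is the bin's median original value.
    """
    vals = window_vals[window_ibins == median_bin]
    m = (vals.size - 1) // 2
    return float(np.partition(vals, m)[m])


def _guided_wmf_naive(image, guidance, radius, ni, nf, bandwidth):
    h, w = image.shape
    centers = guidance_bin_centers(nf)
    ibin = quantize_intensity(image, ni)
    fbin = quantize_guidance(guidance, nf)
    out = np.empty_like(image)
    for y in range(h):
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        for x in range(w):
            x0, x1 = max(0, x - radius), min(w, x + radius + 1)
            win_v = image[y0:y1, x0:x1].ravel()
            win_i = ibin[y0:y1, x0:x1].ravel()
            win_f = fbin[y0:y1, x0:x1].ravel()
            fp = float(guidance[y, x])
            # per-guidance-bin counts and weights
            colcnt = np.bincount(win_f, minlength=nf)
            nz = np.nonzero(colcnt)[0]
            g = {int(f): affinity_weight(float(centers[f]), fp, bandwidth) for f in nz}
            # scan candidate cuts in ascending intensity order
            cand = np.unique(win_i)
            left = np.zeros(nf, dtype=np.int64)
            median_bin = int(cand[-1])
            for c in cand:
                left += np.bincount(win_f[win_i == c], minlength=nf)
                b = math.fsum(float(2 * left[f] - colcnt[f]) * g[int(f)] for f in nz)
                if b >= 0:
                    median_bin = int(c)
                    break
            out[y, x] = _representative(win_v, win_i, median_bin)
    return out


def _guided_wmf_accelerated(image, guidance, radius, ni, nf, bandwidth):
    h, w = image.shape
    centers = guidance_bin_centers(nf)
    ibin = quantize_intensity(image, ni)
    fbin = quantize_guidance(guidance, nf)
    out = np.empty_like(image)

    H = np.zeros((ni, nf), dtype=np.int64)
    colcnt = np.zeros(nf, dtype=np.int64)
    B = np.zeros(nf, dtype=np.int64)  # balance counting box vs. current cut
    neck = NecklaceTable(nf)

    def add_pixel(i, f, cut):
        H[i, f] += 1
        if colcnt[f] == 0:
            neck.insert(f)
        colcnt[f] += 1
        B[f] += 1 if i <= cut else -1

    def remove_pixel(i, f, cut):
        H[i, f] -= 1
        colcnt[f] -= 1
        B[f] -= 1 if i <= cut else -1
        if colcnt[f] == 0:
            neck.delete(f)

    for y in range(h):
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        # fresh window and cut at the row start (cut propagation is
        # column-wise within a row)
        H[:] = 0
        colcnt[:] = 0
        neck.clear()
        cut = 0
        for xc in range(0, min(w, radius + 1)):
            for yy in range(y0, y1):
                i, f = ibin[yy, xc], fbin[yy, xc]
                H[i, f] += 1
                colcnt[f] += 1
        B[:] = 2 * H[0] - colcnt
        for f in np.nonzero(colcnt)[0]:
            neck.insert(f)

        for x in range(w):
            if x > 0:
                x_in, x_out = x + radius, x - radius - 1
                if x_in < w:
                    for yy in range(y0, y1):
                        add_pixel(ibin[yy, x_in], fbin[yy, x_in], cut)
                if x_out >= 0:
                    for yy in range(y0, y1):
                        remove_pixel(ibin[yy, x_out], fbin[yy, x_out], cut)

            fp = float(guidance[y, x])
            ring = list(neck)
            g = [affinity_weight(float(centers[f]), fp, bandwidth) for f in ring]
            b = math.fsum(float(B[f]) * gf for f, gf in zip(ring, g))
            # move the cut up until the balance is nonnegative
            while b < 0 and cut < ni - 1:
                cut += 1
                row = H[cut]
                for f in ring:
                    d = row[f]
                    if d:
                        B[f] += 2 * d
                b = math.fsum(float(B[f]) * gf for f, gf in zip(ring, g))
            # then down to the smallest nonnegative cut
            while cut > 0:
                row = H[cut]
                moved = [(f, row[f]) for f in ring if row[f]]
                for f, d in moved:
                    B[f] -= 2 * d
                b_prev = math.fsum(float(B[f]) * gf for f, gf in zip(ring, g))
                if b_prev >= 0:
                    cut -= 1
                    b = b_prev
                else:  # undo
                    for f, d in moved:
                        B[f] += 2 * d
                    break

            x0, x1 = max(0, x - radius), min(w, x + radius + 1)
            out[y, x] = _representative(
                image[y0:y1, x0:x1].ravel(), ibin[y0:y1, x0:x1].ravel(), cut
            )
    return out


def guided_wmf(image, guidance, radius: int = 5, ni: int = 256, nf: int = 32,
               bandwidth: float = 0.1, mode: str = "accelerated") -> np.ndarray:
    """Guided weighted median filter of ``image`` under ``guidance``.

    Parameters
    ----------
    image
        2-D intensity grid on the 0-255 scale.
    guidance
        2-D guidance grid in [0, 1], same shape as ``image``.
    radius
        Window radius ``r``; the window is (2r+1) x (2r+1), truncated at
        the borders.
    ni, nf
        Number of intensity and guidance quantization bins.
    bandwidth
        Affinity bandwidth on the [0, 1] guidance scale.
    mode
        ``"naive"`` (per-window reference) or ``"accelerated"``
        (sliding joint histogram + balance box + necklace table).  The two
        agree pixel-exactly.
    """
    img = as_intensity(image, "image")
    gd = as_guidance(guidance, "guidance")
    if img.shape != gd.shape:
        raise ValueError(f"image shape {img.shape} != guidance shape {gd.shape}")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if ni < 1 or nf < 1:
        raise ValueError("bin counts must be >= 1")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    if img.size == 0:
        raise ValueError("empty image")
    if mode == "naive":
        return _guided_wmf_naive(img, gd, radius, ni, nf, bandwidth)
    if mode == "accelerated":
        return _guided_wmf_accelerated(img, gd, radius, ni, nf, bandwidth)
    raise ValueError(f"unknown mode {mode!r}")


def median_filter_truncated(image, radius: int) -> np.ndarray:
    """Plain (unweighted) median filter with the same truncated-border rule.

    Independent reference for the constant-guidance reduction of
    :func:`guided_wmf`: per window the lower median (index ``(n-1)//2`` of
    the ascending sort), which is what the cumulative-half-weight rule
    selects under uniform weights.
    """
    img = as_intensity(image, "image")
    h, w = img.shape
    out = np.empty_like(img)
    for y in range(h):
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        for x in range(w):
            x0, x1 = max(0, x - radius), min(w, x + radius + 1)
            win = np.sort(img[y0:y1, x0:x1], axis=None)
            out[y, x] = win[(win.size - 1) // 2]
    return out
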