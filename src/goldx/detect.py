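"""Per-tilt fiducial detection: score map, thresholding, erosion, peaks.

The score at position ``p`` is the contrast between the template's outer
(halo) and inner (bead) point sets, normalized by the local standard
deviation of the image over the union of both sets:

    score(p) = (mean_outer(p) - mean_inner(p)) / s(p)

so a dark center with a bright surround scores high.  Local normalization
makes the score robust to the strong intensity and contrast drifts across a
tilt series (the maximal tilts have the lowest contrast).  ``s(p)`` is
floored at 1e-6 times the global image SD to avoid division blow-ups in
flat areas.

The score map is thresholded at ``mean + threshold_sd * SD`` of its valid
(non-margin) values, eroded with a small disk to kill single-pixel spurious
peaks, and each surviving 8-connected component contributes one marker at
its score maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import ParameterError
from .io_formats import MARKER_COLUMNS, empty_marker_table
from .template import ReducedTemplate, point_kernels

SD_FLOOR_FRACTION = 1e-6


@dataclass
class ScoreMap:
    """Template score at every pixel of one tilt image.

    ``valid_margin`` is the border width (pixels) where the template did not
    fully fit; those positions carry the minimum of the valid scores.
    """

    values: np.ndarray
    valid_margin: int

    def valid_slice(self) -> tuple:
        m = self.valid_margin
        return (slice(m, self.values.shape[0] - m),
                slice(m, self.values.shape[1] - m))


def disk_offsets(radius: float) -> np.ndarray:
    """Boolean footprint of the discrete disk (Euclidean radius <= radius)."""
    r = int(math.floor(radius))
    offs = np.arange(-r, r + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return (dy**2 + dx**2) <= radius**2


def score_map(image: np.ndarray, template: ReducedTemplate) -> ScoreMap:
    """Evaluate the reduced-template score at every valid position."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError(f"expected a 2D image, got ndim={img.ndim}")
    margin = template.span
    ny, nx = img.shape
    if ny <= 2 * template.r_out or nx <= 2 * template.r_out or \
            ny - 2 * margin < 1 or nx - 2 * margin < 1:
        raise ParameterError(
            f"image {img.shape} smaller than the template span "
            f"(needs > {2 * margin} in both dimensions)"
        )

    global_sd = float(img.std())
    if global_sd <= 1e-12 * max(1.0, abs(float(img.mean()))):
        # constant image: no contrast anywhere
        return ScoreMap(values=np.zeros_like(img), valid_margin=margin)
    # demeaning makes the score invariant to constant offsets (to rounding)
    # and improves FFT conditioning
    img0 = img - img.mean()

    k_in, k_out, _ = point_kernels(template)
    n_in, n_out = k_in.sum(), k_out.sum()
    n_union = n_in + n_out
    # correlation via convolution with the flipped kernel
    kf_in = k_in[::-1, ::-1]
    kf_out = k_out[::-1, ::-1]
    s_in = fftconvolve(img0, kf_in, mode="same")
    s_out = fftconvolve(img0, kf_out, mode="same")
    s2 = fftconvolve(img0**2, kf_in + kf_out, mode="same")
    mean_in = s_in / n_in
    mean_out = s_out / n_out
    mean_u = (s_in + s_out) / n_union
    var = np.maximum(s2 / n_union - mean_u**2, 0.0)
    s = np.maximum(np.sqrt(var), SD_FLOOR_FRACTION * global_sd)
    score = (mean_out - mean_in) / s

    valid = score[margin:ny - margin, margin:nx - margin]
    vmin = float(valid.min())
    out = np.full_like(score, vmin)
    out[margin:ny - margin, margin:nx - margin] = valid
    return ScoreMap(values=out, valid_margin=margin)


def binarize(smap: ScoreMap, threshold_sd: float = 5.0) -> np.ndarray:
    """Threshold a score map at ``mean + threshold_sd * SD`` of valid scores.

    Margin positions are always False.  A degenerate all-equal map yields an
    all-False result (strict inequality).
    """
    valid = smap.values[smap.valid_slice()]
    mu = float(valid.mean())
    sd = float(valid.std())
    out = np.zeros(smap.values.shape, dtype=bool)
    out[smap.valid_slice()] = valid > mu + threshold_sd * sd
    return out


def erode_binary(binary: np.ndarray, radius_px: int = 1) -> np.ndarray:
    """Binary erosion with a discrete disk; removes spurious single-pixel peaks.

    Pixels outside the image are treated as False, so an all-true map loses a
    border of width ``radius_px``.
    """
    if radius_px < 1:
        raise ParameterError(f"erosion radius must be >= 1, got {radius_px}")
    return ndimage.binary_erosion(
        binary, structure=disk_offsets(radius_px), border_value=0
    )


def extract_markers(
    binary: np.ndarray, smap: ScoreMap, tilt_index: int
) -> pd.DataFrame:
    """One marker per 8-connected component, at the component's score maximum.

    Ties within a component go to the smallest ``(y, x)``.  Labels are
    assigned ``1..N`` in order of decreasing marker score (ties broken by
    position) so label 1 is always the strongest detection.
    """
    if binary.shape != smap.values.shape:
        raise ParameterError("binary map and score map shapes differ")
    lab, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return empty_marker_table()
    rows = []
    score = smap.values
    objects = ndimage.find_objects(lab)
    for comp, sl in enumerate(objects, start=1):
        mask = lab[sl] == comp
        local = np.where(mask, score[sl], -np.inf)
        # argmax of the flattened array = first occurrence in C order,
        # i.e. the lexicographically smallest (y, x)
        flat = int(np.argmax(local))
        iy, ix = np.unravel_index(flat, local.shape)
        y = iy + sl[0].start
        x = ix + sl[1].start
        rows.append((float(score[y, x]), int(y), int(x)))
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    return pd.DataFrame(
        {
            "tilt_index": [tilt_index] * len(rows),
            "y": [float(r[1]) for r in rows],
            "x": [float(r[2]) for r in rows],
            "score": [r[0] for r in rows],
            "label": list(range(1, len(rows) + 1)),
        }
    )[MARKER_COLUMNS]


def detect_image(image: np.ndarray, params, tilt_index: int = 0):
    """Full detection chain for one tilt image.

    Returns ``(markers, score_map, binary_map)`` where the binary map is the
    post-erosion map the markers were extracted from.  ``params`` is a
    :class:`goldx.params.GoldXParams`.
    """
    template = params.template()
    img = np.asarray(image, dtype=float)
    if params.polarity == "bright_beads":
        img = -img
    smap = score_map(img, template)
    binary = binarize(smap, params.threshold_sd)
    binary = erode_binary(binary, params.erode_radius_px)
    markers = extract_markers(binary, smap, tilt_index)
    return markers, smap, binary
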