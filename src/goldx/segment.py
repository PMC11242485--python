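"""Marker-based watershed segmentation of bead shapes and halo dilation.

Markers from the detection stage seed a watershed flood of the (lightly
smoothed) raw intensity: dark beads are basins, so each marker's catchment
is the exact shape of its bead.  A marker placed on one bead of a touching
cluster floods the whole connected dark region, so aggregated fiducials are
segmented as long as one border bead is detected.  The step introduces no
new user parameters: the background seed and the smoothing scale derive
from the template geometry and image statistics alone.

Masks are then expanded with a disk dilation to cover the bright defocus
halo; where two dilated regions would overlap, each contested pixel goes to
the nearest original region (ties to the lower label), so regions stay
disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

from .errors import ParameterError
from .template import ReducedTemplate


@dataclass
class FiducialMap:
    """Per-image segmentation result.

    ``labels`` is the watershed label map (0 = background, k >= 1 = fiducial
    k), ``dilated_labels`` the halo-expanded map; each dilated region is a
    superset of its watershed region and distinct regions are disjoint.
    """

    labels: np.ndarray
    dilated_labels: np.ndarray
    markers: pd.DataFrame
    dilation_radius_px: int


def watershed_masks(
    image: np.ndarray,
    markers: pd.DataFrame,
    template: ReducedTemplate,
) -> np.ndarray:
    """Flood the intensity landscape from marker seeds; return a label map.

    The flooding surface is the raw intensity after a small Gaussian blur of
    scale ``r_in / 8`` (skipped for beads under 4 px radius), which
    suppresses single-pixel noise without displacing the halo ridge that
    bounds each basin.

    Background seeds are all pixels that (a) are not bead-dark — more than
    two robust SDs (1.4826 MAD) below the smoothed-image median — and (b)
    are farther than ``2 r_out`` both from every marker and from every
    certainly-dark core pixel (four robust SDs below the median).  The
    robust cut keeps seeds inside ordinary dark texture patches — which
    would otherwise drain into an adjacent bead's basin and balloon its
    region — while the core-anchored exclusion protects the dim rim of a
    long bead aggregate whose single marker is far away, so aggregated
    fiducials remain floodable from one marker.  All constants derive from
    the template geometry and image statistics; the step takes no user
    parameters.

    Marker seeds are placed last so a marker pixel always carries its own
    label; a marker that lands on a would-be background seed is reported
    with a warning.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    n = len(markers)
    if n == 0:
        return np.zeros((ny, nx), dtype=np.int32)

    ys = markers["y"].to_numpy().astype(int)
    xs = markers["x"].to_numpy().astype(int)
    labs = markers["label"].to_numpy().astype(int)
    if (ys < 0).any() or (ys >= ny).any() or (xs < 0).any() or (xs >= nx).any():
        raise ParameterError("marker outside image bounds")

    # light blur only: a heavier one (e.g. r_in / 4) visibly displaces the
    # halo ridge outward and inflates every basin
    sigma = template.r_in / 8.0
    smooth = ndimage.gaussian_filter(img, sigma) if template.r_in >= 4 else img

    marker_mask = np.zeros((ny, nx), dtype=bool)
    marker_mask[ys, xs] = True
    far = ndimage.distance_transform_edt(~marker_mask) > 2.0 * template.r_out
    med = np.median(smooth)
    robust_sd = 1.4826 * np.median(np.abs(smooth - med))
    bright = smooth > med - 2.0 * robust_sd
    # pixels certain to be bead interior anchor a protection zone so that the
    # dim rim of a long aggregate, far from its single marker, is not seeded
    core = smooth < med - 4.0 * robust_sd
    if core.any():
        far &= ndimage.distance_transform_edt(~core) > 2.0 * template.r_out

    bg_label = int(labs.max()) + 1
    seeds = np.zeros((ny, nx), dtype=np.int32)
    seeds[bright & far] = bg_label
    collisions = bright[ys, xs] & far[ys, xs]
    if collisions.any():
        warnings.warn(
            f"markers {labs[collisions].tolist()} sit on background-like "
            "bright pixels; their regions may be unreliable",
            stacklevel=2,
        )
    seeds[ys, xs] = labs  # markers win contested pixels

    out = watershed(smooth, markers=seeds)
    out[out == bg_label] = 0
    return out.astype(np.int32)


def dilate_masks(labels: np.ndarray, radius_px: int) -> np.ndarray:
    """Expand each labeled region by a disk of ``radius_px``.

    Contested pixels (reachable from several regions) go to the nearest
    original region, ties to the lower label, so the output is still a
    label map with disjoint regions, each containing its original region.
    """
    if radius_px < 1:
        raise ParameterError(f"dilation radius must be >= 1, got {radius_px}")
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    best = np.full(labels.shape, np.inf)
    pad = radius_px + 1
    for k in sorted(int(v) for v in np.unique(labels) if v != 0):
        mask = labels == k
        sl = ndimage.find_objects(mask.astype(np.int8), max_label=1)[0]
        win = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0])),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1])),
        )
        d = ndimage.distance_transform_edt(~mask[win])
        take = (d <= radius_px) & (d < best[win])  # strict: ties keep lower k
        out[win][take] = k
        best[win][take] = d[take]
    return out


def preview_constant(
    image: np.ndarray, dilated_labels: np.ndarray, value: float
) -> np.ndarray:
    """Fill every masked pixel with a constant, for visual mask validation."""
    img = np.asarray(image)
    if img.shape != np.asarray(dilated_labels).shape:
        raise ParameterError("image and label shapes differ")
    out = img.copy()
    out[dilated_labels != 0] = value
    return out


def segment_image(
    image: np.ndarray,
    markers: pd.DataFrame,
    template: ReducedTemplate,
    dilation_radius_px: int,
) -> FiducialMap:
    """Watershed + halo dilation in one call."""
    labels = watershed_masks(image, markers, template)
    dilated = dilate_masks(labels, dilation_radius_px) if labels.any() \
        else labels.copy()
    return FiducialMap(
        labels=labels,
        dilated_labels=dilated,
        markers=markers,
        dilation_radius_px=dilation_radius_px,
    )
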