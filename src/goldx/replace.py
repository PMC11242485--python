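"""Texture-matched background replacement of segmented fiducials.

The replacement must not introduce texture borders: any statistical
difference between the patch and its surroundings propagates through the
missing wedge into non-local reconstruction artifacts.  The strategy is to

1. pick one featureless square block per tilt image, by drawing
   ``n_candidates`` random mask-free squares and keeping the flattest
   (lowest RMS deviation about its mean);
2. for every fiducial, draw a random dihedral transform (mirror / 90-degree
   rotations) of that block and a random window within it, so replaced
   patches are mutually uncorrelated;
3. rescale the patch affinely to the mean and RMS deviation of the ring of
   pixels immediately surrounding the fiducial's dilated mask;
4. write the patch into the dilated mask only — every pixel outside the
   masks stays bit-identical.

Randomness is drawn from per-(tilt, fiducial) substreams of one master
seed, so results are reproducible and independent of processing order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dataclass_replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .detect import detect_image
from .errors import ConfigurationError, ParameterError
from .io_formats import TiltSeries, empty_marker_table
from .params import GoldXParams
from .segment import preview_constant, segment_image

__all__ = [
    "BackgroundPatch",
    "GoldXParams",
    "select_background",
    "select_background_manual",
    "random_patch",
    "surround_stats",
    "scale_patch",
    "replace_fiducial",
    "process_stack",
]

N_DIHEDRAL = 8
FLAT_RMS_EPS = 1e-12
MAX_REJECTIONS = 1000


@dataclass
class BackgroundPatch:
    """A square background block with provenance."""

    block: np.ndarray
    origin: tuple
    rmsd: float
    source_tilt: int = 0


def _rmsd(block: np.ndarray) -> float:
    """RMS deviation about the mean (population SD)."""
    return float(np.asarray(block, dtype=float).std())


def _window_mask_free(cum: np.ndarray, y: int, x: int, side: int) -> bool:
    # cum is the zero-padded 2D integral image of the mask indicator
    s = (cum[y + side, x + side] - cum[y, x + side]
         - cum[y + side, x] + cum[y, x])
    return s == 0


def select_background(
    image: np.ndarray,
    dilated_labels: np.ndarray,
    side_px: int,
    n_candidates: int = 50,
    rng: np.random.Generator | None = None,
    source_tilt: int = 0,
    return_candidates: bool = False,
):
    """Draw random mask-free squares and keep the one with minimal RMSD.

    Each of the ``n_candidates`` candidates is rejection-sampled against the
    dilated masks (up to 1000 rejections per candidate).  Ties on RMSD go to
    the first candidate drawn.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_candidates < 1:
        raise ParameterError("n_candidates must be >= 1")
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    if side_px > ny or side_px > nx:
        raise ConfigurationError(
            f"background side {side_px} exceeds image dimensions {img.shape}; "
            "use a smaller side_px or select the background manually"
        )
    masked = (np.asarray(dilated_labels) != 0) if dilated_labels is not None \
        else np.zeros((ny, nx), dtype=bool)
    cum = np.zeros((ny + 1, nx + 1), dtype=np.int64)
    np.cumsum(np.cumsum(masked, axis=0), axis=1, out=cum[1:, 1:])

    candidates = []
    best = None
    for _ in range(n_candidates):
        for _ in range(MAX_REJECTIONS):
            y = int(rng.integers(0, ny - side_px + 1))
            x = int(rng.integers(0, nx - side_px + 1))
            if _window_mask_free(cum, y, x, side_px):
                block = img[y:y + side_px, x:x + side_px]
                cand = BackgroundPatch(
                    block=block.copy(), origin=(y, x), rmsd=_rmsd(block),
                    source_tilt=source_tilt,
                )
                candidates.append(cand)
                if best is None or cand.rmsd < best.rmsd:
                    best = cand
                break
    if best is None:
        raise ConfigurationError(
            f"no mask-free {side_px} x {side_px} background square found; "
            "use a smaller side_px or select the background manually"
        )
    if return_candidates:
        return best, candidates
    return best


def select_background_manual(
    image: np.ndarray,
    origin: tuple,
    side_px: int,
    dilated_labels: np.ndarray | None = None,
    source_tilt: int = 0,
) -> BackgroundPatch:
    """Take exactly the requested block, verifying bounds and mask overlap."""
    img = np.asarray(image, dtype=float)
    y, x = int(origin[0]), int(origin[1])
    ny, nx = img.shape
    if y < 0 or x < 0 or y + side_px > ny or x + side_px > nx:
        raise ParameterError(
            f"background square at {origin} side {side_px} exceeds "
            f"image bounds {img.shape}"
        )
    if dilated_labels is not None and \
            np.any(np.asarray(dilated_labels)[y:y + side_px, x:x + side_px]):
        raise ParameterError(
            f"background square at {origin} overlaps a fiducial mask"
        )
    block = img[y:y + side_px, x:x + side_px]
    return BackgroundPatch(block=block.copy(), origin=(y, x),
                           rmsd=_rmsd(block), source_tilt=source_tilt)


def dihedral_transform(block: np.ndarray, index: int) -> np.ndarray:
    """Apply one of the 8 square symmetries (0-3: rotations by ``90 * index``
    degrees; 4-7: the same rotations followed by a left-right mirror)."""
    if not 0 <= index < N_DIHEDRAL:
        raise ParameterError(f"dihedral index must be in [0, 8), got {index}")
    out = np.rot90(block, k=index % 4)
    if index >= 4:
        out = out[:, ::-1]
    return out


def random_patch(
    background: BackgroundPatch,
    patch_shape: tuple,
    rng: np.random.Generator,
) -> np.ndarray:
    """A random window from a uniformly random dihedral transform of the block."""
    h, w = int(patch_shape[0]), int(patch_shape[1])
    s = background.block.shape[0]
    if h > s or w > s:
        raise ParameterError(
            f"patch {patch_shape} larger than background block side {s}"
        )
    t = int(rng.integers(0, N_DIHEDRAL))
    block = dihedral_transform(background.block, t)
    y = int(rng.integers(0, s - h + 1))
    x = int(rng.integers(0, s - w + 1))
    return block[y:y + h, x:x + w].copy()


def surround_stats(
    image: np.ndarray,
    dilated_labels: np.ndarray,
    label_k: int,
    ring_width_px: int,
    fallback: tuple | None = None,
):
    """Mean and RMS deviation of the ring immediately surrounding region k.

    The ring is every pixel within ``ring_width_px`` (disk dilation) of the
    region, excluding the region itself and pixels of any other dilated
    region; it is clipped at the image border.  If the ring is empty (region
    fully surrounded by other masks) the ``fallback`` statistics — normally
    those of the background block — are returned.
    """
    img = np.asarray(image, dtype=float)
    labels = np.asarray(dilated_labels)
    region = labels == label_k
    if not region.any():
        raise ParameterError(f"label {label_k} not present in the label map")
    pad = ring_width_px + 1
    sl = ndimage.find_objects(region.astype(np.int8), max_label=1)[0]
    win = (
        slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, img.shape[0])),
        slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, img.shape[1])),
    )
    d = ndimage.distance_transform_edt(~region[win])
    ring = (d > 0) & (d <= ring_width_px) & (labels[win] == 0)
    vals = img[win][ring]
    if vals.size == 0:
        if fallback is not None:
            return float(fallback[0]), float(fallback[1])
        raise ConfigurationError(
            f"region {label_k} has an empty surround ring and no fallback "
            "statistics were provided"
        )
    return float(vals.mean()), float(vals.std())


def scale_patch(
    patch: np.ndarray, target_mean: float, target_rms: float
) -> np.ndarray:
    """Affine rescale of a patch to a target mean and RMS deviation.

    A flat patch (RMS below 1e-12) cannot reach a nonzero target RMS; it is
    returned as a constant ``target_mean`` with a warning.
    """
    p = np.asarray(patch, dtype=float)
    if p.size == 0:
        raise ParameterError("cannot scale an empty patch")
    mu = p.mean()
    rms = p.std()
    if rms < FLAT_RMS_EPS:
        if target_rms > 0:
            warnings.warn(
                "flat patch cannot match a nonzero target RMS; inserting a "
                "constant at the target mean",
                stacklevel=2,
            )
        return np.full_like(p, float(target_mean))
    return (p - mu) * (float(target_rms) / rms) + float(target_mean)


def replace_fiducial(
    image: np.ndarray,
    dilated_labels: np.ndarray,
    label_k: int,
    background: BackgroundPatch,
    params: GoldXParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replace one dilated fiducial region with a statistics-matched patch.

    Only the pixels of region ``label_k`` change; everything else, including
    non-region pixels inside the region's bounding box, is bit-identical to
    the input.
    """
    labels = np.asarray(dilated_labels)
    region = labels == label_k
    out = np.array(image, copy=True)
    if not region.any():
        warnings.warn(
            f"region {label_k} is empty; image returned unchanged",
            stacklevel=2,
        )
        return out
    sl = ndimage.find_objects(region.astype(np.int8), max_label=1)[0]
    h = sl[0].stop - sl[0].start
    w = sl[1].stop - sl[1].start
    patch = random_patch(background, (h, w), rng)
    mean, rms = surround_stats(
        image, labels, label_k, params.ring_width_px,
        fallback=(float(np.mean(background.block)), background.rmsd),
    )
    scaled = scale_patch(patch, mean, rms)
    sub = region[sl]
    out[sl][sub] = scaled[sub].astype(out.dtype, copy=False)
    return out


def _substream(seed: int, *key: int) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF, *[int(k) for k in key]]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _auto_background(image, dilated, side, template, n_candidates, rng,
                     tilt, warn_list):
    """Auto mode: shrink the square (x0.8 steps) until it is placeable.

    The floor is two bead footprints (or the largest region bounding box,
    which a patch must be able to cover)."""
    region_extent = 0
    for sl in ndimage.find_objects(dilated):
        if sl is not None:
            region_extent = max(region_extent,
                                sl[0].stop - sl[0].start,
                                sl[1].stop - sl[1].start)
    floor = max(int(round(2 * 2 * template.r_out)), region_extent, 16)
    side = max(side, region_extent)
    side = min(side, min(image.shape))
    while True:
        try:
            return select_background(
                image, dilated, side, n_candidates, rng, source_tilt=tilt
            )
        except ConfigurationError:
            if side <= floor:
                raise
            new_side = max(int(side * 0.8), floor)
            warn_list.append(
                f"no mask-free {side} px background square; retrying "
                f"with side {new_side}"
            )
            side = new_side


def process_stack(series: TiltSeries, params: GoldXParams,
                  tilt_order=None, preview_value: float | None = None,
                  background_origin: tuple | None = None):
    """Run detect -> watershed -> dilate -> replace on every tilt.

    Returns ``(cleaned, markers, report)``: a cleaned stack of identical
    shape, the concatenated marker table, and a per-tilt report (marker
    count, background origin and RMSD, warnings).  All randomness derives
    from ``params.seed`` through per-(tilt, fiducial) substreams, so two
    runs are bit-identical and the result does not depend on ``tilt_order``.

    With ``preview_value`` set, masks are filled with that constant instead
    of matched patches (mask-validation mode) and no background is selected.
    With ``background_origin`` set, the background square is taken at that
    ``(y, x)`` on every tilt instead of being searched automatically; this
    requires an explicit ``background_side_px``.
    """
    if background_origin is not None and params.background_side_px == "auto":
        raise ParameterError(
            "a manual background origin requires an explicit "
            "background_side_px"
        )
    template = params.template()
    dilate_radius = params.resolved_dilate_radius(template)
    flip = params.polarity == "bright_beads"

    cleaned = np.array(series.data, copy=True)
    all_markers = []
    report = {
        "parameters": params.to_dict(),
        "dilate_radius_px": dilate_radius,
        "tilts": {},
        "status": "completed",
    }
    order = list(tilt_order) if tilt_order is not None \
        else list(range(series.n_tilts))

    for t in order:
        work = np.asarray(series.data[t], dtype=float)
        if flip:
            work = -work
        tilt_warnings: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            markers, smap, binary = detect_image(work, _canonical(params), t)
            entry = {"n_markers": int(len(markers))}
            if len(markers) > 0:
                fmap = segment_image(work, markers, template, dilate_radius)
                if preview_value is not None:
                    out = preview_constant(
                        work, fmap.dilated_labels, preview_value
                    )
                else:
                    side = params.resolved_background_side(work.shape, template)
                    rng_bg = _substream(params.seed, t, 0)
                    try:
                        if background_origin is not None:
                            bg = select_background_manual(
                                work, background_origin, side,
                                fmap.dilated_labels, source_tilt=t,
                            )
                        elif params.background_side_px == "auto":
                            bg = _auto_background(
                                work, fmap.dilated_labels, side, template,
                                params.n_candidates, rng_bg, t, tilt_warnings,
                            )
                        else:
                            bg = select_background(
                                work, fmap.dilated_labels, side,
                                params.n_candidates, rng_bg, source_tilt=t,
                            )
                    except (ConfigurationError, ParameterError) as exc:
                        raise type(exc)(f"tilt {t}: {exc}") from exc
                    entry["background_origin"] = list(bg.origin)
                    entry["background_rmsd"] = bg.rmsd
                    entry["background_side"] = int(bg.block.shape[0])
                    out = work
                    for k in sorted(markers["label"].astype(int)):
                        rng_k = _substream(params.seed, t, 1, k)
                        out = replace_fiducial(
                            out, fmap.dilated_labels, k, bg, params, rng_k
                        )
                # bit-identical outside the masks: copy only masked pixels
                changed = fmap.dilated_labels != 0
                tilt_out = np.array(series.data[t], copy=True)
                vals = -out[changed] if flip else out[changed]
                tilt_out[changed] = vals.astype(tilt_out.dtype, copy=False)
                cleaned[t] = tilt_out
            all_markers.append(markers)
        tilt_warnings.extend(str(w.message) for w in caught)
        entry["warnings"] = tilt_warnings
        report["tilts"][str(t)] = entry

    markers = pd.concat(all_markers, ignore_index=True) if all_markers \
        else empty_marker_table()
    markers = markers.sort_values(["tilt_index", "label"],
                                  kind="stable").reset_index(drop=True)
    out_series = TiltSeries(
        data=cleaned,
        pixel_size_angstrom=series.pixel_size_angstrom,
        tilt_angles_deg=series.tilt_angles_deg,
        source_path=series.source_path,
    )
    return out_series, markers, report


def _canonical(params: GoldXParams) -> GoldXParams:
    """Detection operates on the already-flipped image, so polarity is
    neutralized before delegating."""
    if params.polarity == "dark_beads":
        return params
    return dataclass_replace(params, polarity="dark_beads")
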