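"""Synthetic tilt-series generator with ground truth.

Emulates the appearance of gold fiducials in defocused bright-field tilt
images: a dark bead disk with a quartic super-Gaussian edge plus a bright
Gaussian defocus-halo ring, on a background of weak low-frequency texture
and white noise.  Bead and halo amplitudes are expressed in units of the
background-noise SD and are multiplied by ``cos(tilt)**exponent`` to model
the contrast loss at high tilt.  The tilt axis runs along y, so a bead at
``(x, y, z)`` (pixels, relative to the volume center) projects at tilt
``theta`` to column ``x cos(theta) + z sin(theta)`` relative to the image
center, with its row fixed.

The generator is a fixture factory for testing the detection / segmentation
/ replacement contracts; it deliberately models no CTF, no projection
thickness and no bead elongation at high tilt.

Ground truth
------------
Per tilt: projected bead centers and an integer footprint-label map (pixel
value ``bead_id + 1``).  The footprint of a bead is where its rendered
intensity deficit exceeds one background-noise SD, i.e. the disk of radius
``r0 * ln(depth * contrast)^(1/4)`` — the part of the bead actually visible
above the noise and hence the target a segmentation can recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dataclass_replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .io_formats import TiltSeries

# canonical acquisition parameters used by the fixture helpers
DEFAULT_PIXEL_SIZE_A = 4.59
DEFAULT_BEAD_NM = 10.0
HALO_SIGMA_FACTOR = 0.25  # Gaussian ring width relative to the bead radius


@dataclass
class SynthParams:
    """Scene description for one synthetic tilt series.

    ``bead_positions_3d`` are ``(x, y, z)`` pixel offsets from the volume
    center.  ``bead_depth`` and ``halo_amplitude`` are in background-noise
    SD units; ``texture_amplitude`` scales a smooth random field in the same
    units (0 disables texture).
    """

    image_shape: Tuple[int, int] = (512, 512)
    n_tilts: int = 1
    tilt_range_deg: Tuple[float, float] = (-60.0, 60.0)
    bead_positions_3d: Sequence[Tuple[float, float, float]] = ()
    bead_diameter_px: float = DEFAULT_BEAD_NM * 10.0 / DEFAULT_PIXEL_SIZE_A
    bead_depth: float = 10.0
    halo_amplitude: float = 3.0
    halo_radius_factor: float = 1.3
    noise_sd: float = 1.0
    texture_amplitude: float = 0.5
    tilt_contrast_exponent: float = 1.0
    pixel_size_angstrom: float = DEFAULT_PIXEL_SIZE_A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tilts < 1:
            raise ParameterError("n_tilts must be >= 1")
        if self.bead_diameter_px <= 0 or self.noise_sd <= 0:
            raise ParameterError("bead_diameter_px and noise_sd must be > 0")
        if self.bead_depth <= 0 or self.halo_amplitude < 0:
            raise ParameterError("bead_depth must be > 0, halo_amplitude >= 0")

    def tilt_angles(self) -> np.ndarray:
        lo, hi = self.tilt_range_deg
        return np.linspace(lo, hi, self.n_tilts)


@dataclass
class GroundTruth:
    """Known bead positions and footprint masks for every tilt."""

    centers: pd.DataFrame  # tilt_index, bead_id, y, x
    mask_labels: np.ndarray  # (n_tilts, ny, nx) int, bead_id + 1, 0 = bg
    params: SynthParams

    @property
    def masks(self) -> np.ndarray:
        return self.mask_labels > 0

    def bead_mask(self, tilt_index: int, bead_id: int) -> np.ndarray:
        return self.mask_labels[tilt_index] == bead_id + 1


def footprint_radius(r0: float, depth: float, contrast: float = 1.0) -> float:
    """Radius where the rendered deficit falls to one noise SD."""
    s = depth * contrast
    if s <= math.e:
        return r0
    return r0 * math.log(s) ** 0.25


def generate_tilt_series(params: SynthParams):
    """Render the scene; returns ``(TiltSeries, GroundTruth)``."""
    ny, nx = params.image_shape
    rng = np.random.default_rng(params.seed & 0x7FFFFFFF)
    angles = params.tilt_angles()
    r0 = params.bead_diameter_px / 2.0
    cy, cx = ny / 2.0, nx / 2.0

    # validate geometry before rendering anything
    bad = []
    for bead_id, (bx, by, bz) in enumerate(params.bead_positions_3d):
        for theta in np.deg2rad(angles):
            py = cy + by
            px = cx + bx * math.cos(theta) + bz * math.sin(theta)
            if not (r0 <= py <= ny - 1 - r0 and r0 <= px <= nx - 1 - r0):
                bad.append(bead_id)
                break
    if bad:
        raise ParameterError(
            f"beads {bad} project outside the field of view at some tilt"
        )

    data = np.empty((params.n_tilts, ny, nx), dtype=np.float32)
    labels = np.zeros((params.n_tilts, ny, nx), dtype=np.int16)
    rows = []
    texture_sigma = min(ny, nx) / 10.0
    win = int(math.ceil(3.2 * r0))

    for t, theta_deg in enumerate(angles):
        theta = math.radians(theta_deg)
        contrast = math.cos(theta) ** params.tilt_contrast_exponent
        img = rng.normal(0.0, params.noise_sd, size=(ny, nx))
        if params.texture_amplitude > 0:
            tex = ndimage.gaussian_filter(
                rng.standard_normal((ny, nx)), texture_sigma
            )
            sd = tex.std()
            if sd > 0:
                img += tex * (params.texture_amplitude * params.noise_sd / sd)

        r_fp = footprint_radius(r0, params.bead_depth, contrast)
        for bead_id, (bx, by, bz) in enumerate(params.bead_positions_3d):
            py = cy + by
            px = cx + bx * math.cos(theta) + bz * math.sin(theta)
            iy, ix = int(round(py)), int(round(px))
            ys = slice(max(iy - win, 0), min(iy + win + 1, ny))
            xs = slice(max(ix - win, 0), min(ix + win + 1, nx))
            yy = np.arange(ys.start, ys.stop)[:, None] - py
            xx = np.arange(xs.start, xs.stop)[None, :] - px
            r = np.hypot(yy, xx)
            deficit = (params.bead_depth * params.noise_sd * contrast
                       * np.exp(-((r / r0) ** 4)))
            ring_center = params.halo_radius_factor * r0
            halo = (params.halo_amplitude * params.noise_sd * contrast
                    * np.exp(-(((r - ring_center)
                                / (HALO_SIGMA_FACTOR * r0)) ** 2)))
            img[ys, xs] += halo - deficit
            labels[t, ys, xs][r <= r_fp] = bead_id + 1
            rows.append((t, bead_id, py, px))
        data[t] = img.astype(np.float32)

    centers = pd.DataFrame(rows, columns=["tilt_index", "bead_id", "y", "x"])
    series = TiltSeries(
        data=data,
        pixel_size_angstrom=params.pixel_size_angstrom,
        tilt_angles_deg=angles,
    )
    return series, GroundTruth(centers=centers, mask_labels=labels,
                               params=params)


def generate_aggregate_fixture(n_beads: int, overlap_px: float,
                               params: SynthParams):
    """A chain of beads with centers ``overlap_px`` apart along the tilt axis.

    Spacing below one bead diameter makes the true footprints one connected
    cluster (the aggregated-fiducial case); larger spacing is the negative
    control.  The chain runs along y so connectivity is tilt-invariant.
    """
    if n_beads < 2:
        raise ParameterError("an aggregate needs at least 2 beads")
    half = (n_beads - 1) / 2.0
    positions = [(0.0, (i - half) * overlap_px, 0.0) for i in range(n_beads)]
    return generate_tilt_series(
        dataclass_replace(params, bead_positions_3d=positions)
    )


def random_bead_positions(
    rng: np.random.Generator,
    n_beads: int,
    image_shape: Tuple[int, int],
    bead_diameter_px: float,
    angles_deg: Sequence[float] = (0.0,),
    z_extent_px: float = 0.0,
    min_separation_factor: float = 3.0,
    max_tries: int = 20000,
) -> List[Tuple[float, float, float]]:
    """Rejection-sample well-isolated bead positions.

    Enforces a minimum projected center separation of
    ``min_separation_factor * bead_diameter_px`` and a border margin of two
    diameters at every tilt angle, so beads stay isolated throughout the
    series.
    """
    ny, nx = image_shape
    cy, cx = ny / 2.0, nx / 2.0
    margin = 2.0 * bead_diameter_px
    min_sep = min_separation_factor * bead_diameter_px
    thetas = np.deg2rad(np.asarray(angles_deg, dtype=float))
    accepted: List[Tuple[float, float, float]] = []
    for _ in range(max_tries):
        if len(accepted) == n_beads:
            break
        y = rng.uniform(margin - cy, ny - 1 - margin - cy)
        x = rng.uniform(margin - cx, nx - 1 - margin - cx)
        z = rng.uniform(-z_extent_px, z_extent_px) if z_extent_px > 0 else 0.0
        px_all = x * np.cos(thetas) + z * np.sin(thetas)
        if np.any(px_all + cx < margin) or np.any(px_all + cx > nx - 1 - margin):
            continue
        ok = True
        for (ax, ay, az) in accepted:
            apx = ax * np.cos(thetas) + az * np.sin(thetas)
            d = np.hypot(px_all - apx, x * 0 + (y - ay))
            if np.min(d) < min_sep:
                ok = False
                break
        if ok:
            accepted.append((x, y, z))
    if len(accepted) < n_beads:
        raise ParameterError(
            f"could not place {n_beads} isolated beads in {image_shape}"
        )
    return accepted


def detection_fixture(seed: int, n_beads: int = 20,
                      image_shape: Tuple[int, int] = (512, 512),
                      tilt_deg: float = 0.0, **overrides):
    """Canonical single-tilt study fixture: isolated 10 nm beads at
    4.59 A/px, depth 10 noise SDs, rendered at the given tilt angle.

    ``tilt_deg`` exercises the tilt-contrast model (bead and halo amplitude
    scaled by ``cos(tilt)``): the bead layout is the zero-tilt layout for
    every angle, with 3D x positions back-compensated by ``1 / cos(tilt)``
    so the projected scene is identical and only the contrast changes.
    """
    base = SynthParams(image_shape=image_shape, n_tilts=1,
                       tilt_range_deg=(tilt_deg, tilt_deg), seed=seed,
                       **overrides)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 101]))
    positions = random_bead_positions(
        rng, n_beads, image_shape, base.bead_diameter_px, angles_deg=[0.0],
    )
    cos_t = math.cos(math.radians(tilt_deg))
    positions = [(x / cos_t, y, z) for (x, y, z) in positions]
    return generate_tilt_series(
        dataclass_replace(base, bead_positions_3d=positions)
    )


def multi_tilt_fixture(seed: int, n_beads: int = 12, n_tilts: int = 9,
                       image_shape: Tuple[int, int] = (512, 512),
                       tilt_range_deg: Tuple[float, float] = (-60.0, 60.0),
                       **overrides):
    """Multi-tilt study fixture with beads isolated at every angle."""
    base = SynthParams(image_shape=image_shape, n_tilts=n_tilts,
                       tilt_range_deg=tilt_range_deg, seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 202]))
    positions = random_bead_positions(
        rng, n_beads, image_shape, base.bead_diameter_px,
        angles_deg=base.tilt_angles(), z_extent_px=15.0,
        min_separation_factor=2.5,
    )
    return generate_tilt_series(
        dataclass_replace(base, bead_positions_3d=positions)
    )


def blank_noise_image(seed: int, image_shape: Tuple[int, int] = (512, 512),
                      **overrides):
    """A bead-free noise + texture image (false-positive testing)."""
    params = SynthParams(image_shape=image_shape, n_tilts=1,
                         tilt_range_deg=(0.0, 0.0), bead_positions_3d=(),
                         seed=seed, **overrides)
    series, _ = generate_tilt_series(params)
    return series.data[0]
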