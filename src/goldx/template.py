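"""Reduced (point-set) template for gold bead detection.

A fiducial in a defocused bright-field tilt image is a dark disk surrounded
by a bright defocus-halo fringe.  The reduced template represents this as two
signed point sets rather than a dense image: an inner set of offsets covering
a disk of radius ``r_in`` (the dark bead) and a thin outer ring of offsets at
the halo radius.  Between them lies an excluded gap annulus, which makes the
score tolerant to minor size and shape variations of individual beads.

Geometry defaults (relative to the bead radius ``r_in`` in pixels):
``r_gap = 1.3 r_in`` (inner edge of the ring), ring thickness
``t_out = max(1, round(0.2 r_in))``, and a nominal outer extent
``r_out = 1.6 r_in`` used for margins and exclusion distances.  These ratios
place the ring just outside a typical first defocus fringe; they are exposed
for fine-tuning but rarely need it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .errors import ParameterError

# ring geometry relative to the bead radius; see module docstring
GAP_FACTOR = 1.3
OUTER_FACTOR = 1.6
RING_THICKNESS_FACTOR = 0.2


@dataclass(frozen=True)
class ReducedTemplate:
    """Two disjoint signed point sets separated by a gap annulus.

    ``inner_points`` cover the dark bead disk (weight -1 in the rendered
    form), ``outer_points`` the bright halo ring (weight +1).  Offsets are
    integer ``(dy, dx)`` pairs sorted lexicographically.
    """

    inner_points: Tuple[Tuple[int, int], ...]
    outer_points: Tuple[Tuple[int, int], ...]
    r_in: float
    r_gap: float
    r_out: float
    scale_factor: float

    @property
    def span(self) -> int:
        """Half-width of the smallest centered square window holding every
        template point, never less than ``ceil(r_out)``."""
        reach = max(
            max(abs(dy), abs(dx))
            for dy, dx in self.inner_points + self.outer_points
        )
        return max(int(math.ceil(self.r_out)), reach)


def build_template(
    pixel_size_angstrom: float,
    bead_diameter_nm: float,
    scale_factor: float = 1.0,
) -> ReducedTemplate:
    """Scale the reduced template to the data.

    The only required physical inputs are the pixel size and the mean bead
    diameter; ``scale_factor`` is a manual fine-tune multiplier applied to
    all radii.

    Raises
    ------
    ParameterError
        If the bead radius comes out below 1.5 px — such beads span fewer
        than 3 pixels and cannot be detected; use a smaller pixel size or a
        larger bead diameter.
    """
    if pixel_size_angstrom <= 0 or bead_diameter_nm <= 0 or scale_factor <= 0:
        raise ParameterError("pixel size, bead diameter and scale must be > 0")
    r_in = scale_factor * (bead_diameter_nm * 10.0 / pixel_size_angstrom) / 2.0
    if r_in < 1.5:
        raise ParameterError(
            f"bead radius {r_in:.2f} px is below 1.5 px; the bead must span "
            "at least 3 pixels (decrease the pixel size or increase the bead "
            "diameter)"
        )
    r_gap = GAP_FACTOR * r_in
    r_out = OUTER_FACTOR * r_in
    t_out = max(1, round(RING_THICKNESS_FACTOR * r_in))
    ring_outer = r_gap + t_out

    k = int(math.ceil(ring_outer))
    offs = np.arange(-k, k + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    rsq = dy.astype(float) ** 2 + dx.astype(float) ** 2
    inner_sel = rsq <= r_in**2
    outer_sel = (rsq >= r_gap**2) & (rsq <= ring_outer**2)
    inner = sorted(zip(dy[inner_sel].tolist(), dx[inner_sel].tolist()))
    outer = sorted(zip(dy[outer_sel].tolist(), dx[outer_sel].tolist()))
    return ReducedTemplate(
        inner_points=tuple(inner),
        outer_points=tuple(outer),
        r_in=r_in,
        r_gap=r_gap,
        r_out=r_out,
        scale_factor=scale_factor,
    )


def render_template(template: ReducedTemplate, canvas_half_width: int) -> np.ndarray:
    """Render the template on a square canvas for visual validation.

    Returns an image of side ``2 * canvas_half_width + 1`` holding -1 at
    inner points, +1 at outer points and 0 elsewhere, template centered.
    """
    if canvas_half_width < math.ceil(template.r_out) + 1:
        raise ParameterError(
            f"canvas_half_width {canvas_half_width} too small for template "
            f"with r_out {template.r_out:.2f}"
        )
    side = 2 * canvas_half_width + 1
    img = np.zeros((side, side), dtype=np.float32)
    c = canvas_half_width
    for dy, dx in template.inner_points:
        img[c + dy, c + dx] = -1.0
    for dy, dx in template.outer_points:
        img[c + dy, c + dx] = 1.0
    return img


def point_kernels(template: ReducedTemplate) -> Tuple[np.ndarray, np.ndarray, int]:
    """Indicator kernels (inner, outer) on a common odd canvas.

    Returns ``(k_inner, k_outer, half_width)``; used by the scoring stage.
    """
    k = template.span
    side = 2 * k + 1
    k_in = np.zeros((side, side), dtype=float)
    k_out = np.zeros((side, side), dtype=float)
    for dy, dx in template.inner_points:
        k_in[k + dy, k + dx] = 1.0
    for dy, dx in template.outer_points:
        k_out[k + dy, k + dx] = 1.0
    return k_in, k_out, k
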