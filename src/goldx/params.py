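"""Tunable parameters for the fiducial-erasure pipeline, with defaults.

The two required physical inputs are the pixel size (A/px) and the mean
bead diameter (nm); everything else has defaults chosen for fully automated
operation and is exposed for the occasional fine-tuning pass (typically on
the zero-degree and maximal tilt only).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Union

from .errors import ParameterError
from .template import ReducedTemplate, build_template

POLARITIES = ("dark_beads", "bright_beads")


@dataclass
class GoldXParams:
    """All pipeline parameters.

    Attributes
    ----------
    pixel_size_angstrom : float
        Pixel size of the tilt images, A/px.
    bead_diameter_nm : float
        Mean gold bead diameter, nm (5-15 nm typical).
    scale_factor : float
        Manual fine-tune multiplier on the template radii.
    threshold_sd : float
        Score-map threshold in SDs above the mean score.
    erode_radius_px : int
        Disk radius for the spurious-peak erosion of the binary map.
    dilate_radius_px : int or None
        Disk radius for the halo-covering mask dilation; ``None`` derives a
        generous default from the template geometry.
    background_side_px : int or "auto"
        Side of the square background block patches are drawn from; "auto"
        picks a side large relative to the bead footprint.
    n_candidates : int
        Number of random background candidates ranked by flatness (RMSD).
    ring_width_px : int
        Width of the surround ring whose mean/RMS each patch is matched to.
    seed : int
        Master seed; all randomness is derived from it.
    polarity : str
        "dark_beads" (bright-field convention, default) or "bright_beads"
        for stacks stored with inverted contrast.
    """

    pixel_size_angstrom: float
    bead_diameter_nm: float
    scale_factor: float = 1.0
    threshold_sd: float = 5.0
    erode_radius_px: int = 1
    dilate_radius_px: Optional[int] = None
    background_side_px: Union[int, str] = "auto"
    n_candidates: int = 50
    ring_width_px: int = 3
    seed: int = 0
    polarity: str = "dark_beads"

    def __post_init__(self) -> None:
        if self.pixel_size_angstrom <= 0:
            raise ParameterError("pixel_size_angstrom must be > 0")
        if self.bead_diameter_nm <= 0:
            raise ParameterError("bead_diameter_nm must be > 0")
        if self.scale_factor <= 0:
            raise ParameterError("scale_factor must be > 0")
        if self.erode_radius_px < 1:
            raise ParameterError("erode_radius_px must be >= 1")
        if self.dilate_radius_px is not None and self.dilate_radius_px < 1:
            raise ParameterError("dilate_radius_px must be >= 1")
        if self.n_candidates < 1:
            raise ParameterError("n_candidates must be >= 1")
        if self.ring_width_px < 1:
            raise ParameterError("ring_width_px must be >= 1")
        if self.polarity not in POLARITIES:
            raise ParameterError(
                f"polarity must be one of {POLARITIES}, got {self.polarity!r}"
            )
        if (self.background_side_px != "auto"
                and (not isinstance(self.background_side_px, int)
                     or self.background_side_px < 4)):
            raise ParameterError(
                "background_side_px must be 'auto' or an integer >= 4"
            )

    def template(self) -> ReducedTemplate:
        return build_template(
            self.pixel_size_angstrom, self.bead_diameter_nm, self.scale_factor
        )

    def resolved_dilate_radius(self, template: ReducedTemplate) -> int:
        """Halo dilation radius: explicit value, or a generous geometric one."""
        if self.dilate_radius_px is not None:
            return self.dilate_radius_px
        return max(3, round(template.r_gap - template.r_in) + 2)

    def resolved_background_side(
        self, image_shape, template: ReducedTemplate
    ) -> int:
        """Auto background side: large relative to the bead footprint
        (8 footprints of diameter ``2 r_out``), floored at 64 px and capped
        at half the smaller image dimension."""
        if self.background_side_px != "auto":
            return int(self.background_side_px)
        side = max(int(round(8 * 2 * template.r_out)), 64)
        cap = min(image_shape) // 2
        return max(min(side, cap), 8)

    def to_dict(self) -> dict:
        return asdict(self)
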