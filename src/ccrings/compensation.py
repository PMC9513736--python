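"""Shadow/projection compensation of the en face CC angiogram.

Large superficial retinal vessels and lesion material attenuate both the
structural en face slab and the angiogram beneath them. Compensation inverts
the structural image and multiplies it pixelwise with the angiogram: where
the structural signal is weak (shadow), the inverted structural is strong and
boosts the angiogram back up. The product is min-max rescaled to the input
bit depth. A structurally flat product (e.g. structural saturated at the
intensity maximum) cannot be rescaled; it is returned as-is with a warning
rather than raising, so batch runs survive pathological inputs.
"""

from __future__ import annotations

import logging

import numpy as np

from .images import EnFaceImage, GeometryError

__all__ = ["invert_structural", "compensate_angiogram"]

log = logging.getLogger(__name__)


def invert_structural(structural: EnFaceImage) -> EnFaceImage:
    """Invert a structural en face image: out = I_max - in.

    Raises ``ValueError`` if the input is not of structural modality.
    """
    if structural.modality != "structural":
        raise ValueError(
            f"invert_structural expects a structural image, got {structural.modality!r}"
        )
    return structural.with_pixels(structural.i_max - structural.pixels)


def compensate_angiogram(
    angiogram: EnFaceImage, structural: EnFaceImage
) -> EnFaceImage:
    """Compensate the CC angiogram with the inverted structural image.

    The pixelwise product ``angiogram * (I_max - structural)`` is computed in
    floating point and min-max rescaled to the angiogram's full bit-depth
    range. Output modality is ``compensated``; grid and pitch are unchanged.
    """
    if angiogram.modality != "angiogram":
        raise ValueError(f"expected an angiogram, got {angiogram.modality!r}")
    if structural.modality != "structural":
        raise ValueError(f"expected a structural image, got {structural.modality!r}")
    if not angiogram.same_grid(structural):
        raise GeometryError(
            f"grid mismatch: angiogram {angiogram.shape} @ {angiogram.pixel_pitch_um} um "
            f"vs structural {structural.shape} @ {structural.pixel_pitch_um} um"
        )
    product = angiogram.pixels * (structural.i_max - structural.pixels)
    lo, hi = float(product.min()), float(product.max())
    if hi <= lo:
        log.warning(
            "compensation produced a flat product (min=max=%g); returning it unrescaled",
            lo,
        )
        out = np.clip(product, 0, angiogram.i_max)
    else:
        out = (product - lo) * (angiogram.i_max / (hi - lo))
    out = np.clip(out, 0.0, float(angiogram.i_max))
    return angiogram.with_pixels(out, modality="compensated")
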