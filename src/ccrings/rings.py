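"""Concentric ring ROIs around the perilesional dark halo.

Five 200-um-wide rings are grown outward from the edge of the dark halo (DH)
with a Euclidean distance map, mirroring the ImageJ "Distance Map" ROI
construction: ring k holds exactly the pixels whose center-to-center distance
d from the filled lesion region (MNV union DH) satisfies
(k-1)*width < d <= k*width. The rings therefore partition the 1000-um band
around the halo, never overlap the lesion itself, and are clipped (with a
warning) where they run off the scan.

The ring configuration is built once on the T1 visit and transferred
unchanged to T2 ("same size and position"); inputs are assumed co-registered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import EnFaceImage, GeometryError

__all__ = [
    "LesionMaskSet",
    "RingSet",
    "AnalysisMasks",
    "MarginReport",
    "validate_scan_margins",
    "build_rings",
    "build_analysis_masks",
    "transfer_rings",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LesionMaskSet:
    """Binary rasters delineating the MNV lesion, its dark halo, and large
    superficial retinal vessels (to be excluded as shadow artifacts)."""

    mnv_mask: np.ndarray
    halo_mask: np.ndarray
    vessel_mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mnv_mask, dtype=bool)
        h = np.asarray(self.halo_mask, dtype=bool)
        v = np.asarray(self.vessel_mask, dtype=bool)
        if not (m.shape == h.shape == v.shape):
            raise GeometryError("lesion masks must share one grid")
        object.__setattr__(self, "mnv_mask", m)
        object.__setattr__(self, "halo_mask", h)
        object.__setattr__(self, "vessel_mask", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mnv_mask.shape  # type: ignore[return-value]

    def lesion_region(self) -> np.ndarray:
        """Filled MNV-union-halo region the distance map grows from."""
        return ndimage.binary_fill_holes(self.mnv_mask | self.halo_mask)


@dataclass(frozen=True)
class RingSet:
    """Labeled raster of concentric rings: 0 = outside, 1..n_rings = R1..Rn."""

    label_map: np.ndarray
    ring_width_um: float
    n_rings: int
    pixel_pitch_um: float
    origin_masks: LesionMaskSet

    def ring_mask(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_rings:
            raise ValueError(f"ring index {k} outside 1..{self.n_rings}")
        return self.label_map == k

    def ring_areas_px(self) -> np.ndarray:
        """Pixel count of each ring, index 0 -> R1."""
        counts = np.bincount(self.label_map.ravel(), minlength=self.n_rings + 1)
        return counts[1 : self.n_rings + 1]


@dataclass(frozen=True)
class AnalysisMasks:
    """Per-ring effective analysis masks (ring minus vessel exclusions).

    ``flagged`` marks rings whose effective area fell below the floor; they
    are reported as missing downstream, not as zeros.
    """

    effective_masks: tuple[np.ndarray, ...]
    denominators_px: tuple[int, ...]
    flagged: tuple[bool, ...]
    pixel_pitch_um: float

    @property
    def n_rings(self) -> int:
        return len(self.effective_masks)


@dataclass(frozen=True)
class MarginReport:
    passed: bool
    min_margin_um: float
    required_um: float

    def __bool__(self) -> bool:
        return self.passed


def validate_scan_margins(
    mnv_mask: np.ndarray, pixel_pitch_um: float, min_margin_um: float = 1000.0
) -> MarginReport:
    """Check that every MNV pixel lies at least ``min_margin_um`` from every
    scan border (pixel-center to border distance).

    Eyes whose lesion comes closer than 1 mm to the scan edge were excluded
    from the study; the pipeline enforces the same rule.
    """
    mnv = np.asarray(mnv_mask, dtype=bool)
    if not mnv.any():
        raise ValueError("empty MNV mask: margins are undefined")
    rows, cols = np.nonzero(mnv)
    n_r, n_c = mnv.shape
    # distance from a pixel center to the nearest border, in pixel units
    margin_px = min(
        rows.min() + 0.5,
        cols.min() + 0.5,
        n_r - rows.max() - 0.5,
        n_c - cols.max() - 0.5,
    )
    margin_um = margin_px * pixel_pitch_um
    return MarginReport(margin_um >= min_margin_um, margin_um, min_margin_um)


def build_rings(
    masks: LesionMaskSet,
    pixel_pitch_um: float,
    ring_width_um: float = 200.0,
    n_rings: int = 5,
) -> RingSet:
    """Build the concentric ring label map from the dark-halo edge.

    The exact Euclidean distance transform is computed from the filled
    MNV-union-halo region; ring k is the half-open distance band
    ((k-1)*w, k*w]. Rings partially off-grid are clipped with a warning; a
    ring with no on-grid pixels raises :class:`GeometryError`.
    """
    if not masks.halo_mask.any():
        raise ValueError("empty halo mask: rings are anchored to the dark-halo edge")
    region = masks.lesion_region()
    dist_um = ndimage.distance_transform_edt(~region) * pixel_pitch_um
    label_map = np.zeros(masks.shape, dtype=np.int32)
    for k in range(1, n_rings + 1):
        band = (dist_um > (k - 1) * ring_width_um) & (dist_um <= k * ring_width_um)
        n_px = int(band.sum())
        if n_px == 0:
            raise GeometryError(f"ring R{k} lies entirely off-grid")
        label_map[band] = k
    # detect clipping: outermost band reaching the image border
    border = np.zeros(masks.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (label_map[border] > 0).any():
        clipped = sorted(set(int(v) for v in np.unique(label_map[border])) - {0})
        log.warning("rings %s reach the scan border and are clipped", clipped)
    return RingSet(label_map, ring_width_um, n_rings, pixel_pitch_um, masks)


def build_analysis_masks(
    rings: RingSet,
    masks: LesionMaskSet,
    min_area_px: int = 100,
) -> AnalysisMasks:
    """Subtract vessel exclusions from each ring and record denominators.

    Rings whose effective area falls below ``min_area_px`` are flagged (not
    failed); flagged rings are dropped pairwise from cohort statistics.
    """
    if rings.label_map.shape != masks.shape:
        raise GeometryError("ring label map and lesion masks must share one grid")
    eff, denom, flagged = [], [], []
    for k in range(1, rings.n_rings + 1):
        m = rings.ring_mask(k) & ~masks.vessel_mask
        n = int(m.sum())
        is_flagged = n < min_area_px
        if is_flagged:
            log.warning("ring R%d effective area %d px below floor %d; flagged", k, n, min_area_px)
        eff.append(m)
        denom.append(n)
        flagged.append(is_flagged)
    return AnalysisMasks(tuple(eff), tuple(denom), tuple(flagged), rings.pixel_pitch_um)


def transfer_rings(rings: RingSet, t2_image: EnFaceImage) -> RingSet:
    """Bind the fixed T1 ring configuration to the T2 visit.

    The label map is reused pixel-for-pixel (no re-derivation from T2 masks),
    matching the fixed-size, fixed-position transfer of the analysis ROIs.
    """
    if rings.label_map.shape != t2_image.shape:
        raise GeometryError(
            f"T2 grid {t2_image.shape} does not match ring grid {rings.label_map.shape}"
        )
    if not np.isclose(rings.pixel_pitch_um, t2_image.pixel_pitch_um):
        raise GeometryError("T2 pixel pitch differs from the ring configuration's")
    return rings
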