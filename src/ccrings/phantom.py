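"""Synthetic en face OCTA phantoms with known flow-deficit ground truth.

The study's inputs — a CC angiogram, the matching structural slab, and
manually drawn MNV / dark-halo / vessel masks for paired visits — are not
publicly available, so every downstream stage is exercised on phantoms:

* a bright type-1 MNV disc at the scan center, surrounded by a hypointense
  dark-halo annulus;
* a CC background of bright "flow" with dark deficit blobs placed zone by
  zone (five 200-um ring bands outward from the halo edge, plus the far
  background), each zone filled to a designed deficit area fraction;
* multiplicative lognormal speckle and vertical retinal-vessel stripes that
  attenuate both the angiogram and the structural image (the artifact the
  compensation stage removes);
* paired T1/T2 cohorts in which T2 reuses the T1 geometry, shifts each ring's
  deficit fraction by a designed delta (plus eye-level noise), and fragments
  deficits by a split factor — the reperfusion pattern reported after
  anti-VEGF loading (FD% down, deficits smaller and more numerous).

Blob placement is exact: each zone is filled until the realized deficit pixel
count equals round(fraction x zone area), trimming the last blob, so the
recorded ground-truth fractions are reliable oracles for the measurement
pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .images import EnFaceImage
from .rings import LesionMaskSet, build_rings

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "EyeRecord",
    "PhantomConfigError",
    "generate_phantom",
    "generate_paired_cohort",
    "split_deficits",
]

log = logging.getLogger(__name__)

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

# Table-style T1 per-ring deficit fractions: highest adjacent to the halo,
# decaying outward.
_DEFAULT_RING_FD = (0.5248, 0.5137, 0.5030, 0.4922, 0.4828)
# Designed T1->T2 reperfusion, percentage points per ring (negative = less
# deficit after treatment; smallest effect in R1).
_DEFAULT_DELTAS = (-2.02, -3.07, -3.57, -3.45, -3.18)


class PhantomConfigError(ValueError):
    """Phantom geometry cannot satisfy its margin/fit constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Design parameters of one synthetic eye/visit.

    Geometry defaults mirror a 3 x 3 mm, 500 x 500 px scan with a centered
    lesion; intensity defaults put flow/deficit on the bright/dark side of
    the Phansalkar operating range on an 8-bit scale.
    """

    grid_size_px: tuple[int, int] = (500, 500)
    scan_extent_mm: float = 3.0
    mnv_radius_um: float = 250.0
    halo_width_um: float = 250.0
    ring_fd_fraction: tuple[float, ...] = _DEFAULT_RING_FD
    background_fd_fraction: float = 0.45
    deficit_mean_area_um2: float = 360.0
    speckle_sigma: float = 0.1
    structural_speckle_sigma: float = 0.03
    shadow_strength: float = 0.3
    vessel_count: int = 2
    seed: int = 0
    # secondary knobs (not part of the core design surface)
    ring_width_um: float = 200.0
    vessel_width_um: float = 36.0
    zone_edge_gap_px: int = 1
    min_margin_um: float = 1000.0
    flow_level: float = 102.0
    deficit_level: float = 31.0
    mnv_level: float = 115.0
    halo_level: float = 26.0
    structural_level: float = 168.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_size_px", tuple(int(g) for g in self.grid_size_px))
        object.__setattr__(self, "ring_fd_fraction", tuple(float(f) for f in self.ring_fd_fraction))
        self.validate()

    @property
    def n_rings(self) -> int:
        return len(self.ring_fd_fraction)

    @property
    def pixel_pitch_um(self) -> float:
        return self.scan_extent_mm * 1000.0 / self.grid_size_px[1]

    def validate(self) -> None:
        if self.scan_extent_mm <= 0:
            raise PhantomConfigError("scan_extent_mm must be positive")
        if any(g < 8 for g in self.grid_size_px):
            raise PhantomConfigError("grid_size_px must be at least 8 x 8")
        for f in self.ring_fd_fraction + (self.background_fd_fraction,):
            if not 0.0 <= f <= 1.0:
                raise PhantomConfigError(f"deficit fraction {f} outside [0, 1]")
        if self.mnv_radius_um < 0 or self.halo_width_um < 0:
            raise PhantomConfigError("mnv_radius_um and halo_width_um must be >= 0")
        if self.deficit_mean_area_um2 <= 0:
            raise PhantomConfigError("deficit_mean_area_um2 must be positive")
        if self.speckle_sigma < 0 or self.structural_speckle_sigma < 0:
            raise PhantomConfigError("speckle sigmas must be >= 0")
        if not 0.0 <= self.shadow_strength <= 1.0:
            raise PhantomConfigError("shadow_strength must lie in [0, 1]")
        if self.vessel_count < 0:
            raise PhantomConfigError("vessel_count must be >= 0")
        half_extent_um = min(self.grid_size_px) * self.pixel_pitch_um / 2.0
        if self.mnv_radius_um > 0:
            # MNV edges at least min_margin from every scan border
            if self.mnv_radius_um + self.min_margin_um > half_extent_um:
                raise PhantomConfigError(
                    "MNV margin violated: mnv_radius_um + min_margin_um = "
                    f"{self.mnv_radius_um + self.min_margin_um:.0f} um exceeds the "
                    f"half scan extent {half_extent_um:.0f} um"
                )
        ring_reach = self.mnv_radius_um + self.halo_width_um + self.n_rings * self.ring_width_um
        if self.halo_width_um > 0 and ring_reach > half_extent_um:
            raise PhantomConfigError(
                f"rings do not fit: lesion + {self.n_rings} x {self.ring_width_um:.0f} um "
                f"rings reach {ring_reach:.0f} um, beyond the half scan extent "
                f"{half_extent_um:.0f} um"
            )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of one phantom: the no-flow mask, the realized deficit
    fraction and component count per ring zone, and the lesion masks."""

    deficit_mask: np.ndarray
    ring_truth_fractions: tuple[float, ...]
    component_count_per_ring: tuple[int, ...]
    mnv_mask: np.ndarray
    halo_mask: np.ndarray
    vessel_mask: np.ndarray
    ring_zone_map: np.ndarray  # 0 = background/lesion, 1..n = ring zones
    background_fraction: float

    def lesion_masks(self) -> LesionMaskSet:
        return LesionMaskSet(self.mnv_mask, self.halo_mask, self.vessel_mask)


@dataclass(frozen=True)
class CohortSpec:
    """A paired-visit synthetic cohort (defaults mirror the 30-eye study)."""

    n_eyes: int = 30
    t1_spec: PhantomSpec = field(default_factory=PhantomSpec)
    fd_percent_delta_per_ring: tuple[float, ...] = _DEFAULT_DELTAS
    split_factor: float = 1.25
    between_eye_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise ValueError("n_eyes must be >= 2")
        if self.split_factor < 1:
            raise ValueError("split_factor must be >= 1")
        if self.between_eye_sd < 0:
            raise ValueError("between_eye_sd must be >= 0")
        if len(self.fd_percent_delta_per_ring) != self.t1_spec.n_rings:
            raise ValueError("one FD% delta per ring is required")
        object.__setattr__(
            self, "fd_percent_delta_per_ring", tuple(float(d) for d in self.fd_percent_delta_per_ring)
        )


@dataclass(frozen=True)
class EyeRecord:
    """One synthetic eye: phantom triples at both visits plus designed deltas."""

    eye_id: str
    t1: tuple[EnFaceImage, EnFaceImage, PhantomTruth]
    t2: tuple[EnFaceImage, EnFaceImage, PhantomTruth]
    designed_delta_points: tuple[float, ...]
    realized_delta_points: tuple[float, ...]


# --------------------------------------------------------------------------
# geometry and placement helpers


@lru_cache(maxsize=64)
def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Disc pixel offsets sorted by center distance (for shape-preserving
    trimming of the final blob)."""
    ax = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    d2 = dy * dy + dx * dx
    keep = d2 <= radius * radius
    dy, dx, d2 = dy[keep], dx[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return dy[order], dx[order]


def _centered_distance_um(shape: tuple[int, int], pitch_um: float) -> np.ndarray:
    rows = (np.arange(shape[0]) - (shape[0] - 1) / 2.0)[:, None]
    cols = (np.arange(shape[1]) - (shape[1] - 1) / 2.0)[None, :]
    return np.hypot(rows, cols) * pitch_um


def _sample_radii(n: int, mean_area_px: float, rng: np.random.Generator) -> np.ndarray:
    r_mean = max(np.sqrt(mean_area_px / np.pi), 0.6)
    radii = np.rint(rng.normal(r_mean, 0.3 * r_mean, size=n)).astype(int)
    return np.clip(radii, 1, None)


def _stamp_batch(
    mask: np.ndarray,
    zone_lut: np.ndarray,
    zone_rows: np.ndarray,
    zone_cols: np.ndarray,
    n_blobs: int,
    mean_area_px: float,
    rng: np.random.Generator,
) -> int:
    """Stamp ``n_blobs`` discs (clipped to the zone) into ``mask``; return the
    number of newly set pixels."""
    n_r, n_c = mask.shape
    idx = rng.integers(0, len(zone_rows), size=n_blobs)
    radii = _sample_radii(n_blobs, mean_area_px, rng)
    placed = 0
    flat_mask = mask.reshape(-1)
    for radius in np.unique(radii):
        sel = radii == radius
        dy, dx = _disc_offsets(int(radius))
        rr = (zone_rows[idx[sel]][:, None] + dy[None, :]).ravel()
        cc = (zone_cols[idx[sel]][:, None] + dx[None, :]).ravel()
        ok = (rr >= 0) & (rr < n_r) & (cc >= 0) & (cc < n_c)
        flat = rr[ok] * n_c + cc[ok]
        flat = flat[zone_lut[flat]]
        flat = np.unique(flat)
        placed += int(np.count_nonzero(~flat_mask[flat]))
        flat_mask[flat] = True
    return placed


def _stamp_single_exact(
    mask: np.ndarray,
    zone_lut: np.ndarray,
    zone_rows: np.ndarray,
    zone_cols: np.ndarray,
    budget_px: int,
    mean_area_px: float,
    rng: np.random.Generator,
) -> int:
    """Stamp one disc, trimming its outermost new pixels to stay within
    ``budget_px`` newly set pixels. Returns pixels actually placed."""
    n_r, n_c = mask.shape
    i = int(rng.integers(0, len(zone_rows)))
    radius = int(_sample_radii(1, mean_area_px, rng)[0])
    dy, dx = _disc_offsets(radius)
    rr = zone_rows[i] + dy
    cc = zone_cols[i] + dx
    ok = (rr >= 0) & (rr < n_r) & (cc >= 0) & (cc < n_c)
    flat = rr[ok] * n_c + cc[ok]
    flat = flat[zone_lut[flat]]
    flat_mask = mask.reshape(-1)
    new = flat[~flat_mask[flat]]
    if len(new) > budget_px:
        new = new[:budget_px]  # offsets are distance-sorted: trim outer pixels
    flat_mask[new] = True
    return len(new)


def _trim_zone(
    mask: np.ndarray,
    zone_mask: np.ndarray,
    n_remove: int,
    rng: np.random.Generator,
) -> None:
    """Remove ``n_remove`` deficit pixels inside the zone, peeling component
    boundaries so blobs stay compact."""
    while n_remove > 0:
        boundary = mask & zone_mask & ~ndimage.binary_erosion(mask, structure=_STRUCTURE_8)
        cand = np.nonzero(boundary.reshape(-1))[0]
        if len(cand) == 0:
            cand = np.nonzero((mask & zone_mask).reshape(-1))[0]
        if len(cand) == 0:
            return
        take = min(n_remove, len(cand))
        pick = rng.choice(cand, size=take, replace=False)
        mask.reshape(-1)[pick] = False
        n_remove -= take


def _placement_zone(zone_mask: np.ndarray, target_px: int, gap_px: int) -> np.ndarray:
    """Zone eroded by ``gap_px`` so blobs stay clear of the zone boundary and
    never 8-connect across zones; falls back to the full zone when the eroded
    zone cannot hold the target."""
    if gap_px <= 0:
        return zone_mask
    eroded = ndimage.binary_erosion(zone_mask, structure=_STRUCTURE_8, iterations=gap_px)
    if eroded.any() and int(eroded.sum()) >= target_px:
        return eroded
    return zone_mask


def _fill_zone_to_target(
    mask: np.ndarray,
    zone_mask: np.ndarray,
    target_px: int,
    mean_area_px: float,
    rng: np.random.Generator,
    current_px: int | None = None,
    placement_mask: np.ndarray | None = None,
) -> None:
    """Add deficit blobs until exactly ``target_px`` pixels of ``zone_mask``
    are deficit. Blobs are stamped inside ``placement_mask`` (default: the
    zone itself)."""
    if placement_mask is None:
        placement_mask = zone_mask
    zone_rows, zone_cols = np.nonzero(placement_mask)
    area = int(zone_mask.sum())
    if area == 0 or len(zone_rows) == 0:
        return
    if current_px is None:
        current_px = int((mask & zone_mask).sum())
    remaining = target_px - current_px
    if remaining <= 0:
        return
    if target_px >= area:  # saturation
        mask[zone_mask] = True
        return
    zone_lut = placement_mask.reshape(-1)
    # bulk stage: aim below the gap each batch (overlap makes the per-blob
    # yield ~ mean_area x (1 - current density)), then finish exactly
    while remaining > 4 * mean_area_px:
        density = (target_px - remaining) / area
        eff = max(mean_area_px * (1.0 - density), 1.0)
        n = max(1, int(0.6 * remaining / eff))
        placed = _stamp_batch(mask, zone_lut, zone_rows, zone_cols, n, mean_area_px, rng)
        remaining -= placed
    if remaining < 0:  # rare bulk overshoot: shave component boundary pixels
        _trim_zone(mask, zone_mask, -remaining, rng)
        remaining = 0
    # exact stage: single blobs with trimming
    misses = 0
    while remaining > 0:
        placed = _stamp_single_exact(
            mask, zone_lut, zone_rows, zone_cols, remaining, mean_area_px, rng
        )
        remaining -= placed
        misses = misses + 1 if placed == 0 else 0
        if misses > 200:  # zone nearly saturated: finish with single pixels
            free = np.nonzero(zone_lut & ~mask.reshape(-1))[0]
            if len(free) < remaining:
                free = np.nonzero(zone_mask.reshape(-1) & ~mask.reshape(-1))[0]
            pick = rng.choice(free, size=remaining, replace=False)
            mask.reshape(-1)[pick] = True
            remaining = 0


# --------------------------------------------------------------------------
# phantom assembly


def _build_geometry(spec: PhantomSpec) -> tuple[LesionMaskSet, np.ndarray]:
    """Lesion masks (vessels excluded here) and the ring-zone label map."""
    shape = spec.grid_size_px
    pitch = spec.pixel_pitch_um
    d = _centered_distance_um(shape, pitch)
    mnv = d <= spec.mnv_radius_um
    halo = (d > spec.mnv_radius_um) & (d <= spec.mnv_radius_um + spec.halo_width_um)
    empty = np.zeros(shape, dtype=bool)
    masks = LesionMaskSet(mnv, halo, empty)
    if halo.any():
        rings = build_rings(masks, pitch, spec.ring_width_um, spec.n_rings)
        zone_map = rings.label_map
    else:
        zone_map = np.zeros(shape, dtype=np.int32)
    return masks, zone_map


def _make_vessels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Vertical stripes standing in for large superficial retinal vessels."""
    shape = spec.grid_size_px
    vessels = np.zeros(shape, dtype=bool)
    if spec.vessel_count == 0:
        return vessels
    width_px = max(1, int(round(spec.vessel_width_um / spec.pixel_pitch_um)))
    cols = rng.choice(shape[1] - width_px + 1, size=spec.vessel_count, replace=False)
    for c in cols:
        vessels[:, c : c + width_px] = True
    return vessels


def _zone_targets(spec: PhantomSpec, zone_map: np.ndarray, lesion: np.ndarray) -> list[tuple[np.ndarray, int]]:
    """(zone mask, target deficit pixel count) for each ring zone, then the
    background zone."""
    out = []
    for k in range(1, spec.n_rings + 1):
        zone = zone_map == k
        out.append((zone, int(round(spec.ring_fd_fraction[k - 1] * zone.sum()))))
    background = (zone_map == 0) & ~lesion
    out.append((background, int(round(spec.background_fd_fraction * background.sum()))))
    return out


def _place_deficits(
    spec: PhantomSpec,
    zone_map: np.ndarray,
    lesion: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    mask = np.zeros(spec.grid_size_px, dtype=bool)
    mean_area_px = spec.deficit_mean_area_um2 / spec.pixel_pitch_um**2
    for zone, target in _zone_targets(spec, zone_map, lesion):
        placement = _placement_zone(zone, target, spec.zone_edge_gap_px)
        _fill_zone_to_target(
            mask, zone, target, mean_area_px, rng, current_px=0, placement_mask=placement
        )
    return mask


def _truth_from_mask(
    deficit: np.ndarray,
    zone_map: np.ndarray,
    masks: LesionMaskSet,
    vessel_mask: np.ndarray,
    n_rings: int,
    background_zone: np.ndarray,
) -> PhantomTruth:
    fractions, counts = [], []
    for k in range(1, n_rings + 1):
        zone = zone_map == k
        n_zone = int(zone.sum())
        in_zone = deficit & zone
        fractions.append(float(in_zone.sum()) / n_zone if n_zone else float("nan"))
        _, n_comp = ndimage.label(in_zone, structure=_STRUCTURE_8)
        counts.append(int(n_comp))
    bg_n = int(background_zone.sum())
    bg_frac = float((deficit & background_zone).sum()) / bg_n if bg_n else float("nan")
    return PhantomTruth(
        deficit_mask=deficit,
        ring_truth_fractions=tuple(fractions),
        component_count_per_ring=tuple(counts),
        mnv_mask=masks.mnv_mask,
        halo_mask=masks.halo_mask,
        vessel_mask=vessel_mask,
        ring_zone_map=zone_map,
        background_fraction=bg_frac,
    )


def _render(
    spec: PhantomSpec,
    deficit: np.ndarray,
    masks: LesionMaskSet,
    vessel_mask: np.ndarray,
    rng: np.random.Generator,
) -> tuple[EnFaceImage, EnFaceImage]:
    """Render angiogram + structural images for a given truth configuration."""
    shape = spec.grid_size_px
    angio = np.full(shape, spec.flow_level, dtype=np.float64)
    angio[deficit] = spec.deficit_level
    angio[masks.halo_mask] = spec.halo_level
    angio[masks.mnv_mask] = spec.mnv_level
    struct = np.full(shape, spec.structural_level, dtype=np.float64)
    # the angiogram (a decorrelation signal) is noisier than the structural
    # slab, which benefits from volume averaging
    if spec.speckle_sigma > 0:
        angio *= np.exp(rng.normal(0.0, spec.speckle_sigma, shape))
    if spec.structural_speckle_sigma > 0:
        struct *= np.exp(rng.normal(0.0, spec.structural_speckle_sigma, shape))
    if spec.shadow_strength > 0 and vessel_mask.any():
        atten = 1.0 - spec.shadow_strength
        angio[vessel_mask] *= atten
        struct[vessel_mask] *= atten
    hi = float((1 << spec.bit_depth) - 1)
    angio = np.clip(np.rint(angio), 0, hi)
    struct = np.clip(np.rint(struct), 0, hi)
    pitch = spec.pixel_pitch_um
    return (
        EnFaceImage(angio, pitch, spec.bit_depth, "angiogram"),
        EnFaceImage(struct, pitch, spec.bit_depth, "structural"),
    )


def generate_phantom(
    spec: PhantomSpec,
    _rng: np.random.Generator | None = None,
    _geometry: tuple[LesionMaskSet, np.ndarray] | None = None,
    _render_images: bool = True,
) -> tuple[EnFaceImage | None, EnFaceImage | None, PhantomTruth]:
    """Generate one synthetic eye/visit: (angiogram, structural, truth).

    Deterministic for a fixed ``spec.seed``. The leading-underscore arguments
    let cohort generation reuse a derived RNG stream, a precomputed
    lesion/zone geometry, or skip image synthesis; they do not change the
    contract.
    """
    spec.validate()
    rng = _rng if _rng is not None else np.random.default_rng(spec.seed)
    masks, zone_map = _geometry if _geometry is not None else _build_geometry(spec)
    lesion = masks.mnv_mask | masks.halo_mask
    deficit = _place_deficits(spec, zone_map, lesion, rng)
    vessel_mask = _make_vessels(spec, rng)
    full_masks = LesionMaskSet(masks.mnv_mask, masks.halo_mask, vessel_mask)
    background_zone = (zone_map == 0) & ~lesion
    truth = _truth_from_mask(deficit, zone_map, full_masks, vessel_mask, spec.n_rings, background_zone)
    # rendering noise lives on a derived stream so the truth configuration is
    # identical whether or not images are synthesized
    render_seed = int(rng.integers(0, 2**31))
    if not _render_images:
        return None, None, truth
    angio, struct = _render(
        spec, deficit, full_masks, vessel_mask, np.random.default_rng(render_seed)
    )
    return angio, struct, truth


# --------------------------------------------------------------------------
# deficit splitting and paired cohorts


def split_deficits(
    deficit_mask: np.ndarray,
    factor: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Fragment deficit components so the expected component count scales by
    ``factor``, by removing one-pixel separating lines.

    Each component is cut perpendicular to its longer bounding-box axis at
    coordinate quantiles; pixel loss is the separators only (small relative to
    component area for components more than a few pixels wide). ``factor`` 1
    is the identity; components too small to cut are left intact.
    """
    if factor < 1:
        raise ValueError("split factor must be >= 1")
    mask = np.asarray(deficit_mask, dtype=bool).copy()
    if factor == 1:
        return mask
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else rng)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        return mask
    objects = ndimage.find_objects(labels)
    base = int(np.floor(factor))
    frac = factor - base
    extra = rng.random(n) < frac
    for i, slc in enumerate(objects, start=1):
        pieces = base + int(extra[i - 1])
        if pieces < 2:
            continue
        sub = labels[slc] == i
        rows, cols = np.nonzero(sub)
        ext_r = rows.max() - rows.min()
        ext_c = cols.max() - cols.min()
        coord = rows if ext_r >= ext_c else cols
        lo, hi = coord.min(), coord.max()
        if hi - lo < 2:  # nothing strictly between the extremes to cut at
            continue
        cuts = np.unique(
            np.clip(
                np.rint(np.quantile(coord, np.arange(1, pieces) / pieces)).astype(int),
                lo + 1,
                hi - 1,
            )
        )
        sel = np.isin(coord, cuts)
        rr = rows[sel] + slc[0].start
        cc = cols[sel] + slc[1].start
        mask[rr, cc] = False
    return mask


def _adjust_zone_to_target(
    mask: np.ndarray,
    zone_mask: np.ndarray,
    target_px: int,
    mean_area_px: float,
    rng: np.random.Generator,
    gap_px: int = 1,
) -> None:
    """Remove whole components / add blobs inside one zone until the zone's
    deficit pixel count equals ``target_px`` exactly."""
    in_zone = mask & zone_mask
    current = int(in_zone.sum())
    if current > target_px:
        labels, n = ndimage.label(in_zone, structure=_STRUCTURE_8)
        areas = np.bincount(labels.ravel())[1:]
        order = rng.permutation(n) + 1
        cum = np.cumsum(areas[order - 1])
        excess = current - target_px
        k = int(np.searchsorted(cum, excess) + 1)
        remove_ids = order[:k]
        lut = np.zeros(n + 1, dtype=bool)
        lut[remove_ids] = True
        mask[lut[labels]] = False
        current -= int(cum[k - 1])
    if current < target_px:
        placement = _placement_zone(zone_mask, target_px, gap_px)
        _fill_zone_to_target(
            mask, zone_mask, target_px, mean_area_px, rng,
            current_px=current, placement_mask=placement,
        )


def generate_paired_cohort(cohort: CohortSpec, render: bool = True) -> list[EyeRecord]:
    """Generate matched T1/T2 phantom pairs for every eye of a cohort.

    T2 reuses the eye's T1 geometry and masks; its deficit mask is the T1
    mask fragmented by ``split_factor`` and then adjusted zone by zone to the
    target fraction ``T1 realized + (delta + N(0, between_eye_sd)) / 100``
    (clamped to [0, 1] with a warning). Speckle is redrawn at T2. Per-eye
    seeds derive deterministically from ``cohort.seed``.

    ``render=False`` skips image synthesis (records carry ``None`` images),
    for ground-truth-mask studies that only need the masks.
    """
    spec = cohort.t1_spec
    geometry = _build_geometry(spec)
    _, zone_map = geometry
    lesion = geometry[0].mnv_mask | geometry[0].halo_mask
    background_zone = (zone_map == 0) & ~lesion
    mean_area_px = spec.deficit_mean_area_um2 / spec.pixel_pitch_um**2
    zone_masks = [zone_map == k for k in range(1, spec.n_rings + 1)]
    zone_areas = [int(z.sum()) for z in zone_masks]
    records: list[EyeRecord] = []
    for eye in range(cohort.n_eyes):
        ss = np.random.SeedSequence([int(cohort.seed) & 0x7FFFFFFF, eye])
        rng = np.random.default_rng(ss)
        eye_spec = replace(spec, seed=int(ss.generate_state(1)[0] & 0x7FFFFFFF))
        angio1, struct1, truth1 = generate_phantom(
            eye_spec, _rng=rng, _geometry=geometry, _render_images=render
        )
        # designed per-ring T2 targets
        noise = rng.normal(0.0, cohort.between_eye_sd, size=spec.n_rings)
        designed = np.asarray(cohort.fd_percent_delta_per_ring) + noise
        t2_frac = np.asarray(truth1.ring_truth_fractions) + designed / 100.0
        clipped = np.clip(t2_frac, 0.0, 1.0)
        if not np.allclose(clipped, t2_frac):
            log.warning("eye %d: T2 ring fractions clamped to [0, 1]", eye)
        t2_mask = split_deficits(truth1.deficit_mask, cohort.split_factor, rng)
        for k in range(spec.n_rings):
            target = int(round(clipped[k] * zone_areas[k]))
            _adjust_zone_to_target(
                t2_mask, zone_masks[k], target, mean_area_px, rng, spec.zone_edge_gap_px
            )
        # background: restore the T1 deficit load after splitting
        bg_target = int((truth1.deficit_mask & background_zone).sum())
        _adjust_zone_to_target(
            t2_mask, background_zone, bg_target, mean_area_px, rng, spec.zone_edge_gap_px
        )
        truth2 = _truth_from_mask(
            t2_mask, zone_map, truth1.lesion_masks(), truth1.vessel_mask, spec.n_rings, background_zone
        )
        render_seed2 = int(rng.integers(0, 2**31))
        if render:
            angio2, struct2 = _render(
                spec, t2_mask, truth1.lesion_masks(), truth1.vessel_mask,
                np.random.default_rng(render_seed2),
            )
        else:
            angio2 = struct2 = None
        realized = tuple(
            100.0 * (f2 - f1)
            for f1, f2 in zip(truth1.ring_truth_fractions, truth2.ring_truth_fractions)
        )
        records.append(
            EyeRecord(
                eye_id=f"eye{eye:03d}",
                t1=(angio1, struct1, truth1),
                t2=(angio2, struct2, truth2),
                designed_delta_points=tuple(designed),
                realized_delta_points=realized,
            )
        )
    return records
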