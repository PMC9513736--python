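"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (double loops, flood fill, textbook
formulas) and independent of the package's optimized code paths; tests freeze
expectations against them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ccrings import EnFaceImage, LesionMaskSet, PhantomSpec
from ccrings.binarize import PhansalkarParams, disc_footprint


# --------------------------------------------------------------------------
# naive Phansalkar: per-pixel double loop over the circular window


def naive_phansalkar_thresholds(
    normalized: np.ndarray, params: PhansalkarParams
) -> np.ndarray:
    rad = params.radius_px
    fp = disc_footprint(rad)
    padded = np.pad(normalized.astype(np.float64), rad, mode="symmetric")
    out = np.empty_like(normalized, dtype=np.float64)
    for i in range(normalized.shape[0]):
        for j in range(normalized.shape[1]):
            win = padded[i : i + 2 * rad + 1, j : j + 2 * rad + 1][fp]
            m = win.mean()
            s = win.std()
            out[i, j] = m * (
                1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1.0)
            )
    return out


@pytest.fixture
def naive_phansalkar():
    return naive_phansalkar_thresholds


# --------------------------------------------------------------------------
# iterative flood fill for component counting (8- or 4-connectivity)


def flood_fill_count(mask: np.ndarray, connectivity: int = 8) -> int:
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n = 0
    rows, cols = mask.shape
    for si, sj in zip(*np.nonzero(mask)):
        if seen[si, sj]:
            continue
        n += 1
        stack = [(si, sj)]
        seen[si, sj] = True
        while stack:
            i, j = stack.pop()
            for di, dj in nbrs:
                ii, jj = i + di, j + dj
                if 0 <= ii < rows and 0 <= jj < cols and mask[ii, jj] and not seen[ii, jj]:
                    seen[ii, jj] = True
                    stack.append((ii, jj))
    return n


@pytest.fixture
def flood_fill():
    return flood_fill_count


# --------------------------------------------------------------------------
# naive tie-corrected Friedman from the definitional formulas


def naive_friedman_chi2(values: np.ndarray) -> float:
    vals = np.asarray(values, dtype=float)
    n, k = vals.shape
    ranks = np.empty_like(vals)
    for i, row in enumerate(vals):
        for j, x in enumerate(row):
            less = np.sum(row < x)
            equal = np.sum(row == x)
            ranks[i, j] = less + (equal + 1) / 2.0
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in vals:
        for v in set(row.tolist()):
            t = np.sum(row == v)
            ties += t**3 - t
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0
    return max(chi2 / c, 0.0)


@pytest.fixture
def naive_friedman():
    return naive_friedman_chi2


# --------------------------------------------------------------------------
# common small inputs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_spec():
    """A small, quick phantom: 3 x 3 mm at 250 px (12 um pitch)."""
    return PhantomSpec(
        grid_size_px=(250, 250),
        mnv_radius_um=250.0,
        halo_width_um=250.0,
        deficit_mean_area_um2=1440.0,
        seed=7,
    )


@pytest.fixture
def circular_masks():
    """Circular MNV (250 um) + halo (outer radius 500 um) on the default
    500 x 500 / 6 um grid, no vessels."""
    shape = (500, 500)
    pitch = 6.0
    rows = (np.arange(shape[0]) - (shape[0] - 1) / 2.0)[:, None]
    cols = (np.arange(shape[1]) - (shape[1] - 1) / 2.0)[None, :]
    d = np.hypot(rows, cols) * pitch
    mnv = d <= 250.0
    halo = (d > 250.0) & (d <= 500.0)
    return LesionMaskSet(mnv, halo, np.zeros(shape, dtype=bool)), pitch


def make_image(pixels, pitch=6.0, bit_depth=8, modality="angiogram"):
    return EnFaceImage(np.asarray(pixels, dtype=float), pitch, bit_depth, modality)


@pytest.fixture
def image_factory():
    return make_image
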