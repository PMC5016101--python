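"""Shared raster geometry: integer disc footprints used by every stage.

A circular region of odd diameter ``d`` is the set of integer offsets whose
pixel-center distance from the region center is at most ``d/2``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=32)
def disc_offsets(diameter_px: int) -> np.ndarray:
    """Integer (dr, dc) offsets inside a disc of the given odd pixel diameter."""
    if diameter_px < 3 or diameter_px % 2 == 0:
        raise ValueError("diameter must be odd and >= 3")
    r = diameter_px // 2
    ys, xs = np.mgrid[-r : r + 1, -r : r + 1]
    keep = ys**2 + xs**2 <= (diameter_px / 2.0) ** 2
    out = np.stack([ys[keep], xs[keep]], axis=1)
    out.setflags(write=False)
    return out


@lru_cache(maxsize=32)
def disc_mask(diameter_px: int) -> np.ndarray:
    """Boolean d×d mask of the disc footprint (True inside)."""
    r = diameter_px // 2
    offs = disc_offsets(diameter_px)
    m = np.zeros((diameter_px, diameter_px), dtype=bool)
    m[offs[:, 0] + r, offs[:, 1] + r] = True
    m.setflags(write=False)
    return m


@lru_cache(maxsize=32)
def disc_overlap_deltas(diameter_px: int) -> frozenset[tuple[int, int]]:
    """Center deltas at which two discs of this diameter share >=1 pixel.

    This is the Minkowski difference D ⊖ D of the integer disc with itself,
    precomputed so disc–disc intersection is an O(1) set lookup.
    """
    offs = disc_offsets(diameter_px)
    deltas = offs[:, None, :] - offs[None, :, :]
    return frozenset(map(tuple, deltas.reshape(-1, 2).tolist()))


def discs_intersect(center_a, center_b, diameter_px: int) -> bool:
    d = (int(center_b[0] - center_a[0]), int(center_b[1] - center_a[1]))
    return d in disc_overlap_deltas(diameter_px)


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
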