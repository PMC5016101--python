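"""Peroxisome detection and region construction.

Actively importing peroxisomes are taken to be maxima of the Gaussian-smoothed
(σ = 2.0) confocal matrix-marker channel, with ImageJ Find-Maxima prominence
semantics: a candidate local maximum of value v is accepted unless a pixel
higher than v can be reached along a path whose values stay above
v − noise_tolerance. Around each accepted maximum a 19-px (380 nm) circular
region is placed; matched random control regions are uniform translations of
those discs within a 180-px radius, rejected while they touch any peroxisomal
disc or any matrix-marker signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ._geometry import disc_offsets, disc_overlap_deltas

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MaximumPoint:
    position: tuple[int, int]  # (row, col)
    value: float  # smoothed intensity at the maximum


@dataclass(frozen=True)
class CircularRegion:
    center: tuple[int, int]
    diameter_px: int = 19
    kind: str = "peroxisomal"  # "peroxisomal" | "random"
    source_maximum: MaximumPoint | None = None

    def pixel_coords(self) -> np.ndarray:
        """(k, 2) integer pixel coordinates of the disc."""
        return np.asarray(self.center, dtype=int) + disc_offsets(self.diameter_px)


def find_maxima(
    channel: np.ndarray,
    sigma: float = 2.0,
    noise_tolerance: float = 10.0,
) -> list[MaximumPoint]:
    """Accepted maxima of the smoothed channel, sorted by descending value.

    Plateaus (8-connected equal-valued candidate components) yield a single
    point at the rounded plateau centroid. Adding a constant to the image
    leaves the result unchanged: smoothing uses reflective boundaries and the
    tolerance acts on value differences only.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("channel must be 2-D")
    if sigma > 0:
        img = ndi.gaussian_filter(img, sigma, mode="reflect")

    # candidate pixels: no strictly-greater 8-neighbor
    mf = ndi.maximum_filter(img, footprint=_EIGHT, mode="constant", cval=-np.inf)
    cand = img >= mf  # maximum_filter includes self, so == in exact arithmetic
    # adjacent candidates are necessarily equal-valued -> components are plateaus
    labels, n_comp = ndi.label(cand, structure=_EIGHT)

    accepted: list[MaximumPoint] = []
    slices = ndi.find_objects(labels)
    gmin = float(img.min())
    gmax = float(img.max())
    for comp in range(1, n_comp + 1):
        sl = slices[comp - 1]
        inside = labels[sl] == comp
        rows, cols = np.nonzero(inside)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        v = img[rows[0], cols[0]]
        if rows.size == img.size:
            continue  # constant image: no maximum is defined
        # exact short-circuits: the global maximum has nothing higher to
        # reach; a candidate whose tolerance floor undercuts the image
        # minimum can reach every pixel, so any higher pixel rejects it
        if v < gmax and v - noise_tolerance < gmin:
            continue
        if v < gmax and _reachable_from_higher(img, rows, cols, v, noise_tolerance):
            continue
        centroid = (int(np.round(rows.mean())), int(np.round(cols.mean())))
        accepted.append(MaximumPoint(position=centroid, value=float(v)))
    accepted.sort(key=lambda m: (-m.value, m.position))
    return accepted


def _reachable_from_higher(
    img: np.ndarray, rows: np.ndarray, cols: np.ndarray, v: float, tol: float
) -> bool:
    """True if a pixel > v is 8-connected to the plateau through pixels > v − tol."""
    mask = img > v - tol
    if not mask[rows[0], cols[0]]:
        # tol == 0: the plateau itself is excluded; candidacy already
        # guarantees no strictly-higher neighbor, so nothing is reachable
        return False
    lab, _ = ndi.label(mask, structure=_EIGHT)
    comp_ids = np.unique(lab[rows, cols])
    for cid in comp_ids:
        if cid and img[lab == cid].max() > v:
            return True
    return False


def make_regions(
    maxima: list[MaximumPoint],
    image_shape: tuple[int, int],
    diameter_px: int = 19,
) -> list[CircularRegion]:
    """One peroxisomal region per maximum; discs crossing the border are dropped."""
    if diameter_px < 3 or diameter_px % 2 == 0:
        raise ValueError("diameter must be odd and >= 3")
    offs = disc_offsets(diameter_px)
    rmax = int(np.abs(offs).max())
    h, w = image_shape
    regions: list[CircularRegion] = []
    dropped = 0
    for m in maxima:
        r, c = m.position
        if r - rmax < 0 or c - rmax < 0 or r + rmax >= h or c + rmax >= w:
            dropped += 1
            continue
        regions.append(
            CircularRegion(center=(r, c), diameter_px=diameter_px, kind="peroxisomal",
                           source_maximum=m)
        )
    if dropped:
        logger.info("make_regions: dropped %d border-crossing regions", dropped)
    return regions


def build_exclusion_mask(
    matrix_channel: np.ndarray, sigma: float = 2.0, noise_tolerance: float = 10.0
) -> np.ndarray:
    """Pixels carrying matrix-marker signal, off-limits to random regions.

    The channel is smoothed at the detection scale and thresholded at the
    background median plus the detection noise tolerance.
    """
    sm = ndi.gaussian_filter(np.asarray(matrix_channel, dtype=float), sigma, mode="reflect")
    return sm > (np.median(sm) + noise_tolerance)


def make_random_regions(
    regions: list[CircularRegion],
    exclusion: np.ndarray,
    radius_px: float = 180.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> list[CircularRegion]:
    """Matched random control regions.

    Each peroxisomal region is translated to a uniform-random point within
    ``radius_px``; a candidate is resampled while its disc leaves the image,
    intersects any peroxisomal disc, or touches the exclusion mask. After
    ``max_tries`` rejections the region is logged and omitted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = exclusion.shape
    out: list[CircularRegion] = []
    failed = 0
    for reg in regions:
        d = reg.diameter_px
        offs = disc_offsets(d)
        rmax = int(np.abs(offs).max())
        overlap = disc_overlap_deltas(d)
        placed = False
        for _ in range(max_tries):
            rho = radius_px * np.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * np.pi)
            nr = int(round(reg.center[0] + rho * np.sin(phi)))
            nc = int(round(reg.center[1] + rho * np.cos(phi)))
            if nr - rmax < 0 or nc - rmax < 0 or nr + rmax >= h or nc + rmax >= w:
                continue
            if any(
                (p.center[0] - nr, p.center[1] - nc) in overlap
                for p in regions
                if p.diameter_px == d
            ):
                continue
            px = offs + (nr, nc)
            if exclusion[px[:, 0], px[:, 1]].any():
                continue
            out.append(
                CircularRegion(center=(nr, nc), diameter_px=d, kind="random",
                               source_maximum=reg.source_maximum)
            )
            placed = True
            break
        if not placed:
            failed += 1
    if failed:
        logger.info("make_random_regions: %d regions failed after %d tries each",
                    failed, max_tries)
    return out
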