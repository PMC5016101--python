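"""Pixel-wise Pearson colocalization per region with flip and random nulls.

Within each circular region the two STED channels' pixel values are
correlated over the disc support only. Two controls calibrate coincidental
correlation: re-computing after mirroring one channel's patch about the
vertical axis through the region center (flip control, sensitive to dense
but incongruent packing), and computing on the matched random regions away
from any matrix-marker signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._geometry import disc_mask
from .detection import CircularRegion
from .scene import ImageStack

logger = logging.getLogger(__name__)

COLOC_EDGES = np.linspace(-1.0, 1.0, 41)  # 40 bins on [-1, 1]

VARIANTS = ("real", "flip", "random")


@dataclass(frozen=True)
class RegionColoc:
    region_id: int
    pearson: float
    variant: str  # real | flip | random
    channel_labels: tuple[str, str] = ("", "")


@dataclass
class ColocResult:
    records: list[RegionColoc]
    medians: dict[str, float]
    histograms: dict[str, np.ndarray]  # counts per variant over COLOC_EDGES
    n_flagged: dict[str, int]
    edges: np.ndarray = field(default_factory=lambda: COLOC_EDGES.copy())


def extract_patch(channel: np.ndarray, region: CircularRegion) -> np.ndarray:
    """Square d×d patch around the region center (disc inscribed)."""
    r = region.diameter_px // 2
    r0, c0 = region.center
    patch = np.asarray(
        channel[r0 - r : r0 + r + 1, c0 - r : c0 + r + 1], dtype=float
    )
    if patch.shape != (region.diameter_px, region.diameter_px):
        raise ValueError("region disc crosses the image border")
    return patch


def region_pearson(
    patch_g: np.ndarray, patch_r: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson r over the disc pixels of two same-shape square patches.

    Returns NaN when either patch has zero variance on the disc (an undefined
    statistic; callers exclude and count these).
    """
    pg = np.asarray(patch_g, dtype=float)
    pr = np.asarray(patch_r, dtype=float)
    if pg.shape != pr.shape:
        raise ValueError("patches must share one shape")
    if mask is None:
        if pg.shape[0] != pg.shape[1] or pg.shape[0] % 2 == 0:
            raise ValueError("default disc mask needs a square odd-sized patch")
        mask = disc_mask(pg.shape[0])
    g = pg[mask]
    r = pr[mask]
    # all-equal test, not var == 0: the float mean of n identical values is
    # inexact for general n, so their variance can round to a positive number
    if np.all(g == g[0]) or np.all(r == r[0]):
        return float("nan")
    return float(stats.pearsonr(g, r).statistic)


def flip_patch(patch: np.ndarray) -> np.ndarray:
    """Mirror about the vertical axis through the patch center (column flip).

    The disc support is mirror-symmetric, so flipped disc pixels stay disc
    pixels; applying the flip twice is the identity.
    """
    return np.asarray(patch)[:, ::-1].copy()


def coloc_histograms(
    stack: ImageStack,
    regions: list[CircularRegion],
    ch1: int,
    ch2: int,
    random_regions: list[CircularRegion] | None = None,
) -> ColocResult:
    """Per-region Pearson values for real, flip and random variants, pooled.

    Zero-variance patches are excluded from histograms and medians with their
    counts logged per variant.
    """
    random_regions = random_regions or []
    labels = (stack.meta[ch1]["label"], stack.meta[ch2]["label"])
    img1 = np.asarray(stack.channels[ch1], dtype=float)
    img2 = np.asarray(stack.channels[ch2], dtype=float)

    records: list[RegionColoc] = []
    n_flagged = dict.fromkeys(VARIANTS, 0)

    def emit(rid: int, variant: str, value: float) -> None:
        if np.isnan(value):
            n_flagged[variant] += 1
        records.append(
            RegionColoc(region_id=rid, pearson=value, variant=variant, channel_labels=labels)
        )

    for i, reg in enumerate(regions):
        p1 = extract_patch(img1, reg)
        p2 = extract_patch(img2, reg)
        emit(i, "real", region_pearson(p1, p2))
        emit(i, "flip", region_pearson(p1, flip_patch(p2)))
    for i, reg in enumerate(random_regions):
        p1 = extract_patch(img1, reg)
        p2 = extract_patch(img2, reg)
        emit(i, "random", region_pearson(p1, p2))

    medians: dict[str, float] = {}
    histograms: dict[str, np.ndarray] = {}
    for variant in VARIANTS:
        vals = np.array(
            [r.pearson for r in records if r.variant == variant and np.isfinite(r.pearson)]
        )
        medians[variant] = float(np.median(vals)) if vals.size else float("nan")
        histograms[variant], _ = np.histogram(vals, bins=COLOC_EDGES)
        if n_flagged[variant]:
            logger.info(
                "coloc %s/%s %s: %d zero-variance regions excluded",
                *labels, variant, n_flagged[variant],
            )
    return ColocResult(
        records=records, medians=medians, histograms=histograms, n_flagged=n_flagged
    )
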