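"""Channel registration: acquisition drift and confocal↔STED chromatic shift.

Drift between repeated reference-channel (matrix marker) acquisitions is
found by exhaustive integer translation search over a ±18 px window, scoring
each offset by the overlap-normalized pixelwise product of the two images.
The chromatic offset between the confocal and STED optical paths is measured
from a multicolor-bead field as the mean displacement of matched
intensity-weighted bead centroids, with subpixel precision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as ndi_shift

from .scene import ImageStack, translate_with_zero_fill


@dataclass(frozen=True)
class CorrectionTransform:
    """Registration result: subpixel chromatic shift plus integer drift."""

    chromatic_shift_px: tuple[float, float] = (0.0, 0.0)
    drift_shift_px: tuple[int, int] = (0, 0)
    search_window_px: int = 18

    def __post_init__(self) -> None:
        if any(abs(s) > self.search_window_px for s in self.drift_shift_px):
            raise ValueError("drift outside the search window")


def _product_score(
    a: np.ndarray, b: np.ndarray, dr: int, dc: int, normalize: bool = False
) -> float:
    """Pixelwise product of a and b translated by (dr, dc), over the overlap.

    With ``normalize`` the sum is divided by the overlap pixel count. For
    zero-filled translated copies the plain sum is exact (Cauchy–Schwarz: it
    peaks strictly at the true shift), whereas overlap-normalization biases
    the argmax outward when the borders are dark — shrinking the overlap by a
    row raises the mean faster than a 1-px misalignment lowers the product.
    """
    h, w = a.shape
    ar = slice(max(0, -dr), h - max(0, dr))
    ac = slice(max(0, -dc), w - max(0, dc))
    br = slice(max(0, dr), h + min(0, dr))
    bc = slice(max(0, dc), w + min(0, dc))
    sub_a = a[ar, ac]
    if sub_a.size == 0:
        return -np.inf
    total = float(np.multiply(sub_a, b[br, bc], dtype=float).sum())
    return total / sub_a.size if normalize else total


def estimate_drift(
    ref_a: np.ndarray,
    ref_b: np.ndarray,
    window: int = 18,
    literal_minimum: bool = False,
    normalize: bool = False,
) -> tuple[int, int]:
    """Integer translation of ``ref_b`` relative to ``ref_a``.

    Searches all offsets in [-window, window]²; each offset scores the
    pixelwise product over the overlap region. By default the offset
    maximizing the score is returned (aligned nonnegative images maximize
    their product); ``literal_minimum=True`` instead selects the minimum as
    printed in the source procedure. ``normalize`` divides each score by the
    overlap pixel count (see :func:`_product_score` for why that is not the
    default). Ties break toward the smallest offset magnitude, then
    lexicographically.
    """
    a = np.asarray(ref_a, dtype=float)
    b = np.asarray(ref_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("reference images must share one shape")
    if window < 1:
        raise ValueError("window must be >= 1")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("reference images must be nonnegative")
    if not a.any() or not b.any():
        raise ValueError("no registration signal")

    best: tuple[int, int] | None = None
    best_key: tuple[float, int, int, int] | None = None
    sign = 1.0 if literal_minimum else -1.0  # minimize (sign * score)
    for dr, dc in itertools.product(range(-window, window + 1), repeat=2):
        score = _product_score(a, b, dr, dc, normalize=normalize)
        key = (sign * score, dr * dr + dc * dc, dr, dc)
        if best_key is None or key < best_key:
            best_key = key
            best = (dr, dc)
    assert best is not None
    return best


def _weighted_centroid(image: np.ndarray, peak: tuple[int, int], radius: int = 4) -> np.ndarray:
    """Background-subtracted intensity-weighted centroid around a peak."""
    h, w = image.shape
    r0, c0 = peak
    rs = slice(max(0, r0 - radius), min(h, r0 + radius + 1))
    cs = slice(max(0, c0 - radius), min(w, c0 + radius + 1))
    win = np.asarray(image[rs, cs], dtype=float)
    win = win - win.min()
    tot = win.sum()
    if tot <= 0:
        return np.array([float(r0), float(c0)])
    ys, xs = np.mgrid[rs, cs]
    return np.array([(ys * win).sum() / tot, (xs * win).sum() / tot])


def detect_bead_centroids(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Subpixel bead positions: smoothed maxima refined by local centroids."""
    from .detection import find_maxima

    img = np.asarray(image, dtype=float)
    tol = 0.2 * (img.max() - img.min())
    maxima = find_maxima(img, sigma=sigma, noise_tolerance=tol)
    return np.array([_weighted_centroid(img, m.position) for m in maxima]).reshape(-1, 2)


def estimate_chromatic_shift(
    bead_confocal: np.ndarray,
    bead_sted: np.ndarray,
    match_radius_px: float = 10.0,
    min_matches: int = 3,
) -> tuple[float, float]:
    """Mean displacement (STED − confocal) of matched bead centroids.

    Beads are matched by mutual nearest neighbors within ``match_radius_px``;
    fewer than ``min_matches`` matches is an error.
    """
    ca = detect_bead_centroids(bead_confocal)
    cb = detect_bead_centroids(bead_sted)
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("insufficient beads")
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    shifts = []
    for i in range(len(ca)):
        j = int(np.argmin(d[i]))
        if d[i, j] <= match_radius_px and int(np.argmin(d[:, j])) == i:
            shifts.append(cb[j] - ca[i])
    if len(shifts) < min_matches:
        raise ValueError("insufficient beads")
    mean = np.mean(shifts, axis=0)
    return float(mean[0]), float(mean[1])


def apply_correction(
    stack: ImageStack,
    t: CorrectionTransform,
    drift_channels: tuple[int, ...] = (),
    chromatic_channels: tuple[int, ...] | None = None,
) -> ImageStack:
    """Undo the measured shifts: integer zero-fill translation for drift,
    bilinear interpolation for the subpixel chromatic shift.

    ``chromatic_channels`` defaults to every STED-modality channel (the
    chromatic offset is between the confocal and STED optical paths).
    """
    if not all(np.isfinite(t.chromatic_shift_px)):
        raise ValueError("transform must be finite")
    if chromatic_channels is None:
        chromatic_channels = tuple(
            i for i, m in enumerate(stack.meta) if m.get("modality") == "sted"
        )
    out = stack.copy()
    ds = (-int(t.drift_shift_px[0]), -int(t.drift_shift_px[1]))
    for ch in drift_channels:
        out.channels[ch] = translate_with_zero_fill(out.channels[ch], ds)
    cs = (-t.chromatic_shift_px[0], -t.chromatic_shift_px[1])
    if cs != (0.0, 0.0):
        for ch in chromatic_channels:
            shifted = ndi_shift(
                np.asarray(out.channels[ch], dtype=float), cs, order=1, mode="constant"
            )
            out.channels[ch] = np.clip(shifted, 0.0, None)
    out.extra["applied_correction"] = {
        "chromatic_shift_px": list(t.chromatic_shift_px),
        "drift_shift_px": list(t.drift_shift_px),
        "drift_channels": list(drift_channels),
        "chromatic_channels": list(chromatic_channels),
    }
    return out
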