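"""Region-integrated intensity statistics.

Per cell (one image = one cell), the matrix-marker and protein intensities
integrated over each circular region form pairs (g_i, r_i); their Pearson
correlation summarizes how protein abundance tracks import activity.
Normalized intensity histograms (25 bins on [0, 1], each cell scaled by its
maximum peroxisomal integral) compare peroxisomal against random regions, and
a Gaussian fitted to the pooled histogram summarizes the distribution peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize, stats

from .detection import CircularRegion
from .scene import ImageStack

logger = logging.getLogger(__name__)

HIST_EDGES = np.linspace(0.0, 1.0, 26)  # bin width 0.04


@dataclass(frozen=True)
class RegionIntensityPair:
    region_id: int
    g: float  # integrated matrix-channel intensity
    r: float  # integrated protein-channel intensity
    kind: str


@dataclass(frozen=True)
class CellCorrelation:
    cell_id: str
    pearson_r: float
    n_regions: int


@dataclass
class IntensityHistogram:
    edges: np.ndarray
    counts: np.ndarray
    kind: str
    n_zero: int = 0
    n_clipped: int = 0

    def pooled_with(self, other: "IntensityHistogram") -> "IntensityHistogram":
        if self.kind != other.kind:
            raise ValueError("cannot pool histograms of different kinds")
        return IntensityHistogram(
            edges=self.edges,
            counts=self.counts + other.counts,
            kind=self.kind,
            n_zero=self.n_zero + other.n_zero,
            n_clipped=self.n_clipped + other.n_clipped,
        )


def integrate_regions(
    stack: ImageStack,
    regions: list[CircularRegion],
    matrix_ch: int,
    protein_ch: int,
) -> list[RegionIntensityPair]:
    """Sum both channels over each region's disc pixels."""
    g_img = np.asarray(stack.channels[matrix_ch], dtype=float)
    r_img = np.asarray(stack.channels[protein_ch], dtype=float)
    pairs = []
    for i, reg in enumerate(regions):
        px = reg.pixel_coords()
        pairs.append(
            RegionIntensityPair(
                region_id=i,
                g=float(g_img[px[:, 0], px[:, 1]].sum()),
                r=float(r_img[px[:, 0], px[:, 1]].sum()),
                kind=reg.kind,
            )
        )
    return pairs


def cell_correlation(pairs: list[RegionIntensityPair], cell_id: str = "") -> CellCorrelation:
    """Pearson correlation of the (g_i, r_i) pairs of one cell."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 region pairs")
    g = np.array([p.g for p in pairs])
    r = np.array([p.r for p in pairs])
    if np.all(g == g[0]) or np.all(r == r[0]):
        raise ValueError("degenerate intensity set")
    rho = stats.pearsonr(g, r).statistic
    return CellCorrelation(cell_id=cell_id, pearson_r=float(rho), n_regions=len(pairs))


def normalized_histogram(
    values, reference_max: float, kind: str = "peroxisomal"
) -> IntensityHistogram:
    """Bin values / reference_max into the fixed 25 bins on [0, 1].

    ``reference_max`` is the cell's maximum peroxisomal integral and is reused
    for that cell's random regions, so random values may exceed 1; they are
    kept in the top bin and counted in ``n_clipped``.
    """
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be nonnegative")
    norm = v / reference_max
    n_clipped = int((norm > 1.0).sum())
    if n_clipped:
        logger.info("normalized_histogram: %d values > 1 kept in top bin", n_clipped)
    counts, _ = np.histogram(np.clip(norm, 0.0, 1.0), bins=HIST_EDGES)
    return IntensityHistogram(
        edges=HIST_EDGES.copy(),
        counts=counts,
        kind=kind,
        n_zero=int((v == 0).sum()),
        n_clipped=n_clipped,
    )


def gaussian_peak(hist: IntensityHistogram) -> tuple[float, float]:
    """Location and width of a least-squares Gaussian fit to the histogram."""
    centers = 0.5 * (hist.edges[:-1] + hist.edges[1:])
    counts = np.asarray(hist.counts, dtype=float)
    nonzero = counts > 0
    if nonzero.sum() < 5:
        raise ValueError("need at least 5 nonzero bins for a Gaussian fit")

    def model(x, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    w = counts.sum()
    mu0 = float((centers * counts).sum() / w)
    s0 = float(np.sqrt(((centers - mu0) ** 2 * counts).sum() / w)) or 0.05
    try:
        popt, _ = optimize.curve_fit(
            model, centers, counts, p0=[counts.max(), mu0, s0], maxfev=10000
        )
    except RuntimeError as e:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Gaussian fit did not converge (p0={[counts.max(), mu0, s0]}): {e}")
    return float(popt[1]), float(abs(popt[2]))


def line_profile_fwhm(
    channel: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    pixel_size_nm: float = 20.0,
) -> float:
    """FWHM (nm) of the intensity profile sampled along a segment.

    Sampling is bilinear at 1-px steps; the baseline is the profile minimum
    and the half level sits midway between baseline and peak. Crossings are
    located by linear interpolation on both sides of the peak.
    """
    img = np.asarray(channel, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= img.shape[0] - 1 and 0 <= p[1] <= img.shape[1] - 1):
            raise ValueError("endpoints must lie inside the image")
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(np.ceil(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    coords = p0[:, None] * (1 - t) + p1[:, None] * t
    prof = ndi.map_coordinates(img, coords, order=1, mode="nearest")

    baseline = prof.min()
    peak_idx = int(np.argmax(prof))
    peak = prof[peak_idx]
    if peak <= baseline:
        raise ValueError("no peak")
    half = baseline + 0.5 * (peak - baseline)

    step = length / (n - 1)

    def cross(idx_range) -> float:
        prev = None
        for i in idx_range:
            if prof[i] < half:
                j = prev if prev is not None else i
                lo, hi = (i, j) if i < j else (j, i)
                frac = (half - prof[lo]) / (prof[hi] - prof[lo])
                return (lo + frac) * step
            prev = i
        raise ValueError("no peak")

    left = cross(range(peak_idx, -1, -1))
    right = cross(range(peak_idx, n))
    return abs(right - left) * pixel_size_nm


def compare_groups(groups: dict[str, list[float]]):
    """One-way ANOVA with Tukey HSD pairwise comparisons across conditions.

    Returns (F statistic, ANOVA p-value, tidy Tukey table).
    """
    import pandas as pd
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")
    if all(np.var(v) == 0 for v in arrays.values()) and len({v[0] for v in arrays.values()}) == 1:
        raise ValueError("degenerate groups: all values identical")
    f_stat, p = stats.f_oneway(*arrays.values())
    if not np.isfinite(p) and abs(f_stat) < 1e-12:
        # identical group means: between-group variance underflows to a tiny
        # negative value and scipy yields NaN; the exact answer is F=0, p=1
        f_stat, p = 0.0, 1.0
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    return float(f_stat), float(p), table
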