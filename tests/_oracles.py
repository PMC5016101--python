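"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the code paths (and where possible the libraries)
used by the package: pure-Python floods for maxima semantics, plain loops
for entropy thresholds, FFT correlation for drift, direct set enumeration
for geometry.
"""

from __future__ import annotations

import numpy as np

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_prominence_maxima(img: np.ndarray, tol: float) -> set[tuple[int, int]]:
    """Pure-Python flood oracle for Find-Maxima prominence semantics.

    A plateau (8-connected equal-value component with no higher neighbor) of
    value v is accepted unless a pixel > v is reachable through pixels
    > v − tol; accepted plateaus report their rounded centroid.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape

    def nbrs(r, c):
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    # candidate pixels: no strictly-higher neighbor
    cand = [[all(img[rr, cc] <= img[r, c] for rr, cc in nbrs(r, c)) for c in range(w)]
            for r in range(h)]

    seen = [[False] * w for _ in range(h)]
    accepted: set[tuple[int, int]] = set()
    for r0 in range(h):
        for c0 in range(w):
            if not cand[r0][c0] or seen[r0][c0]:
                continue
            v = img[r0, c0]
            # plateau = connected candidates of equal value
            plateau = [(r0, c0)]
            seen[r0][c0] = True
            stack = [(r0, c0)]
            while stack:
                r, c = stack.pop()
                for rr, cc in nbrs(r, c):
                    if cand[rr][cc] and not seen[rr][cc] and img[rr, cc] == v:
                        seen[rr][cc] = True
                        plateau.append((rr, cc))
                        stack.append((rr, cc))
            # flood through pixels > v - tol looking for anything > v
            visited = set(plateau)
            stack = list(plateau)
            reject = False
            while stack and not reject:
                r, c = stack.pop()
                for rr, cc in nbrs(r, c):
                    if (rr, cc) in visited or img[rr, cc] <= v - tol:
                        continue
                    if img[rr, cc] > v:
                        reject = True
                        break
                    visited.add((rr, cc))
                    stack.append((rr, cc))
            if len(plateau) == h * w:
                continue  # constant image: no maximum defined
            if not reject:
                rows = [p[0] for p in plateau]
                cols = [p[1] for p in plateau]
                accepted.add(
                    (int(np.round(np.mean(rows))), int(np.round(np.mean(cols))))
                )
    return accepted


def exhaustive_max_entropy_bin(patch: np.ndarray) -> int:
    """Exhaustive 256-candidate Kapur threshold search (the definition)."""
    p = np.asarray(patch, dtype=float)
    vmin, vmax = p.min(), p.max()
    scaled = np.round((p - vmin) / (vmax - vmin) * 255.0).astype(int)
    hist = np.bincount(scaled.ravel(), minlength=256).astype(float)
    prob = hist / hist.sum()
    objs = np.full(256, -np.inf)
    for t in range(256):
        pb = prob[: t + 1]
        pf = prob[t + 1 :]
        P1, P2 = pb.sum(), pf.sum()
        if P1 <= 0 or P2 <= 0:
            continue
        qb = pb[pb > 0] / P1
        qf = pf[pf > 0] / P2
        objs[t] = -(qb * np.log(qb)).sum() - (qf * np.log(qf)).sum()
    # lowest bin within float tolerance of the maximum (exact ties arise
    # from empty boundary bins, where adjacent cuts give identical partitions)
    return int(np.argmax(objs >= objs.max() - 1e-10))


def fft_drift(ref_a: np.ndarray, ref_b: np.ndarray, window: int) -> tuple[int, int]:
    """Cross-correlation-peak drift oracle (zero-padded FFT correlation)."""
    from scipy.signal import correlate

    a = np.asarray(ref_a, dtype=float)
    b = np.asarray(ref_b, dtype=float)
    cc = correlate(b, a, mode="full", method="fft")
    h, w = a.shape
    # displacement of b relative to a is the lag index minus (h-1, w-1)
    lags_r = np.arange(cc.shape[0]) - (h - 1)
    lags_c = np.arange(cc.shape[1]) - (w - 1)
    keep_r = np.abs(lags_r) <= window
    keep_c = np.abs(lags_c) <= window
    sub = cc[np.ix_(keep_r, keep_c)]
    idx = np.unravel_index(np.argmax(sub), sub.shape)
    return int(lags_r[keep_r][idx[0]]), int(lags_c[keep_c][idx[1]])


def enumerate_disc_pixels(center, diameter: int) -> set[tuple[int, int]]:
    """Direct enumeration of disc pixels: center distance <= d/2."""
    r0, c0 = center
    rad = diameter // 2
    out = set()
    for r in range(r0 - rad, r0 + rad + 1):
        for c in range(c0 - rad, c0 + rad + 1):
            if (r - r0) ** 2 + (c - c0) ** 2 <= (diameter / 2.0) ** 2:
                out.add((r, c))
    return out


def brute_patch_maxima(smoothed: np.ndarray, retain_frac: float,
                       mask: np.ndarray | None = None) -> set[tuple[int, int]]:
    """Brute-force scan: 8-neighborhood maximality plus the retention rule."""
    sm = np.asarray(smoothed, dtype=float)
    h, w = sm.shape
    gmax = sm[mask].max() if mask is not None else sm.max()
    out = set()
    for r in range(h):
        for c in range(w):
            if mask is not None and not mask[r, c]:
                continue
            v = sm[r, c]
            if v < retain_frac * gmax:
                continue
            ok = True
            for dr, dc in _NEIGH:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and sm[rr, cc] > v:
                    ok = False
                    break
            if ok:
                out.add((r, c))
    return out
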