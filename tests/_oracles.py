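"""Independent brute-force oracles the implementation is checked against."""

from collections import deque
from fractions import Fraction

import numpy as np

N_BINS = 256


def otsu_bruteforce(pixels: np.ndarray) -> float:
    """Exhaustive scan of all 256 candidate bins, exact rational arithmetic.

    Between-class variance for the split {bins < k} vs {bins >= k} is
    compared as the exact Fraction (S0*W1 - S1*W0)^2 / (W0*W1), which is
    proportional to w0*w1*(mu0 - mu1)^2 for fixed total count.  Lowest
    maximizing bin wins; a single-occupied-bin histogram has no valid
    split and yields the maximum intensity (empty foreground).
    """
    hist, _ = np.histogram(pixels, bins=N_BINS, range=(0.0, 1.0))
    hist = [int(h) for h in hist]
    occupied = [i for i, h in enumerate(hist) if h]
    if len(occupied) == 1:
        return float(np.max(pixels))

    total = sum(hist)
    total_s = sum(i * h for i, h in enumerate(hist))
    best_k, best_score = None, Fraction(-1)
    w0 = s0 = 0
    for k in range(1, N_BINS):
        w0 += hist[k - 1]
        s0 += (k - 1) * hist[k - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        s1 = total_s - s0
        score = Fraction((s0 * w1 - s1 * w0) ** 2, w0 * w1)
        if score > best_score:
            best_score, best_k = score, k
    return best_k / N_BINS


def flood_fill_label(mask: np.ndarray) -> list[dict]:
    """BFS 8-connected labeling; returns per-component area and centroid."""
    mask = np.asarray(mask)
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            queue = deque([(r, c)])
            seen[r, c] = True
            pixels = []
            while queue:
                pr, pc = queue.popleft()
                pixels.append((pr, pc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = pr + dr, pc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
            rows = [p[0] for p in pixels]
            cols = [p[1] for p in pixels]
            components.append(
                {
                    "area": len(pixels),
                    "centroid_row": sum(rows) / len(rows),
                    "centroid_col": sum(cols) / len(cols),
                }
            )
    return components


def roundsum_bruteforce(areas, mean_area: float) -> int:
    """Element-wise half-away-from-zero round of area ratios, then sum."""
    total = 0
    for a in areas:
        ratio = a / mean_area
        m = int(ratio)
        total += m + 1 if ratio - m >= 0.5 else m
    return total


def ols_normal_equations(x, y):
    """Closed-form OLS slope/intercept from the 2x2 normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
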