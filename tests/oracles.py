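"""Independent brute-force oracles used to cross-check the pipeline operators.

Each function here recomputes an operator's result from its definition with
naive loops/enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Connected-component labeling by explicit flood fill, raster-scan order."""
    H, W = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    labels = np.zeros((H, W), dtype=int)
    n = 0
    for y0 in range(H):
        for x0 in range(W):
            if mask[y0, x0] and labels[y0, x0] == 0:
                n += 1
                stack = [(y0, x0)]
                labels[y0, x0] = n
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = n
                            stack.append((ny, nx))
    return labels, n


def brute_tophat(image: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """White top-hat by exhaustive min/max loops with edge-clamped indexing."""
    H, W = image.shape
    offs = [(dy - footprint.shape[0] // 2, dx - footprint.shape[1] // 2)
            for dy in range(footprint.shape[0])
            for dx in range(footprint.shape[1])
            if footprint[dy, dx]]

    def clamp(v, hi):
        return min(max(v, 0), hi - 1)

    eroded = np.empty_like(image, dtype=float)
    for y in range(H):
        for x in range(W):
            eroded[y, x] = min(image[clamp(y + dy, H), clamp(x + dx, W)] for dy, dx in offs)
    opened = np.empty_like(image, dtype=float)
    for y in range(H):
        for x in range(W):
            opened[y, x] = max(eroded[clamp(y + dy, H), clamp(x + dx, W)] for dy, dx in offs)
    return image - opened


def otsu_exhaustive(values: np.ndarray) -> float:
    """Exhaustive threshold search maximizing between-class variance.

    Candidates are midpoints between consecutive distinct values; returns the
    candidate with maximal between-class variance (first on ties).
    """
    v = np.sort(np.unique(values))
    best_t, best_obj = None, -np.inf
    for a, b in zip(v[:-1], v[1:]):
        t = (a + b) / 2
        lo = values[values <= t]
        hi = values[values > t]
        w0, w1 = lo.size / values.size, hi.size / values.size
        obj = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if obj > best_obj:
            best_obj, best_t = obj, t
    return best_t


def between_class_variance(values: np.ndarray, t: float) -> float:
    lo = values[values <= t]
    hi = values[values > t]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0, w1 = lo.size / values.size, hi.size / values.size
    return w0 * w1 * (lo.mean() - hi.mean()) ** 2


def measure_by_loops(labels: np.ndarray, images: dict[str, np.ndarray], px_um: float):
    """Per-object area/centroid/mean/sum by explicit per-pixel accumulation."""
    out: dict[int, dict] = {}
    H, W = labels.shape
    for y in range(H):
        for x in range(W):
            lab = labels[y, x]
            if lab == 0:
                continue
            rec = out.setdefault(
                lab,
                {"n": 0, "sy": 0.0, "sx": 0.0, **{f"sum_{k}": 0.0 for k in images}},
            )
            rec["n"] += 1
            rec["sy"] += y
            rec["sx"] += x
            for k, img in images.items():
                rec[f"sum_{k}"] += img[y, x]
    for lab, rec in out.items():
        rec["area_um2"] = rec["n"] * px_um**2
        rec["centroid"] = (rec["sy"] / rec["n"], rec["sx"] / rec["n"])
        for k in images:
            rec[f"mean_{k}"] = rec[f"sum_{k}"] / rec["n"]
    return out


def quantile_gate_by_sort(means: dict[int, float], low_q: float, high_q: float) -> set[int]:
    """Excluded ids by sort-based linear-interpolation quantiles, strict rule."""
    ids = sorted(means)
    vals = np.array([means[i] for i in ids], dtype=float)
    order = np.sort(vals)
    n = len(order)

    def quant(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return order[lo] + (pos - lo) * (order[hi] - order[lo])

    low, high = quant(low_q), quant(high_q)
    return {i for i in ids if means[i] < low or means[i] > high}


def percentile_by_sort(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile by explicit sorting."""
    order = np.sort(np.asarray(values, dtype=float))
    pos = q / 100.0 * (order.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return float(order[lo] + (pos - lo) * (order[hi] - order[lo]))


def prominence_peaks(y: np.ndarray, min_prominence: float, min_distance: int) -> list[int]:
    """Peak detection from the prominence definition, by enumeration.

    A sample is a candidate local maximum if strictly higher than its
    neighbors (plateaus take the left edge of the flat top, matching
    lower-index tie-breaking).  Prominence: from the peak extend left/right
    until a strictly higher sample; the base on each side is the minimum over
    that window; prominence = peak - max(left_base, right_base).  Peaks
    closer than ``min_distance`` are resolved by keeping higher peaks first
    (ties toward lower index).
    """
    n = y.size
    candidates = []
    i = 1
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                candidates.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    kept = []
    for p in candidates:
        left = y[p]
        k = p - 1
        lmin = y[p]
        while k >= 0 and y[k] <= y[p]:
            lmin = min(lmin, y[k])
            k -= 1
        left_base = lmin if k >= 0 else min(y[: p + 1])
        k = p + 1
        rmin = y[p]
        while k < n and y[k] <= y[p]:
            rmin = min(rmin, y[k])
            k += 1
        right_base = rmin if k < n else min(y[p:])
        prom = y[p] - max(left_base, right_base)
        if prom >= min_prominence:
            kept.append(p)
    # distance selection: highest first, ties toward lower index
    order = sorted(kept, key=lambda p: (-y[p], p))
    selected: list[int] = []
    removed = set()
    for p in order:
        if p in removed:
            continue
        selected.append(p)
        for q in kept:
            if q != p and abs(q - p) < min_distance:
                removed.add(q)
    return sorted(selected)


def touching_ids_brute(labels: np.ndarray, mask: np.ndarray) -> set[int]:
    """Object ids overlapping or 8-adjacent to the mask, by pixel-pair loops."""
    H, W = labels.shape
    out = set()
    for y in range(H):
        for x in range(W):
            lab = labels[y, x]
            if lab == 0:
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < H and 0 <= nx < W and mask[ny, nx]:
                        out.add(int(lab))
    return out
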