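"""Independent reference implementations used only to check the package.

Each oracle takes the most literal route available — published conversion
matrices, naive exhaustive scans, all-pairs neighbor searches — and shares
no code with the implementation under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def reference_srgb_to_lab(rgb8: np.ndarray) -> np.ndarray:
    """Two-step sRGB→XYZ→Lab conversion with published matrices (D65)."""
    c = np.asarray(rgb8, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
    xyz = lin @ M.T
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def naive_otsu(L01: np.ndarray) -> float:
    """O(levels × pixels) exhaustive Otsu scan with exact integer compares."""
    levels = np.rint(np.asarray(L01, dtype=float).ravel() * 255).astype(int)
    N = levels.size
    best_k, best_num, best_den = None, 0, 0
    for k in range(255):
        mask = levels <= k
        n0 = int(mask.sum())
        if n0 == 0 or n0 == N:
            continue
        s0 = int(levels[mask].sum())
        s = int(levels.sum())
        num = s0 * N - s * n0
        sc_num, sc_den = num * num, n0 * (N - n0)
        if best_k is None or sc_num * best_den > best_num * sc_den:
            best_k, best_num, best_den = k, sc_num, sc_den
    if best_k is None:
        raise ValueError("constant raster")
    return (best_k + 0.5) / 255.0


def naive_dbscan(mask: np.ndarray, R: float, min_pxs: int):
    """All-pairs DBSCAN on the foreground pixels of a binary mask.

    Returns (coords, core, labels, candidates): per-foreground-pixel core
    flags, cluster labels (−1 noise), and for each border pixel the set of
    clusters it could legitimately join.
    """
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    n = len(coords)
    if n == 0:
        return coords, np.zeros(0, bool), np.zeros(0, int), {}
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    neigh = d2 <= R * R  # includes self
    core = neigh.sum(axis=1) >= min_pxs

    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for start in range(n):
        if not core[start] or labels[start] != -1:
            continue
        queue = deque([start])
        labels[start] = cluster
        while queue:
            i = queue.popleft()
            for j in np.flatnonzero(neigh[i] & core):
                if labels[j] == -1:
                    labels[j] = cluster
                    queue.append(j)
        cluster += 1

    candidates = {}
    for i in np.flatnonzero(~core):
        opts = {labels[j] for j in np.flatnonzero(neigh[i] & core)}
        if opts:
            candidates[i] = opts
    return coords, core, labels, candidates
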