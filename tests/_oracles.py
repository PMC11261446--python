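"""Independent brute-force oracles the production code must match.

These deliberately avoid the filtering/labeling machinery of the
implementation: thresholds are evaluated window by window from a padded
copy, and 3D labeling is a plain union-find over voxel neighbors.
"""

from __future__ import annotations

import numpy as np


def brute_phansalkar(image, radius, k=0.25, p=2.0, q=10.0, r=0.5):
    """Per-pixel windowed Phansalkar threshold, O(N·r²)."""
    img = np.asarray(image, dtype=float)
    padded = np.pad(img, radius, mode="reflect")
    out = np.zeros(img.shape, dtype=bool)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            win = padded[y : y + 2 * radius + 1, x : x + 2 * radius + 1]
            m = win.mean()
            s = win.std()
            t = m * (1.0 + p * np.exp(-q * m) + k * (s / r - 1.0))
            out[y, x] = img[y, x] < t
    return out


def brute_midgrey(image, radius):
    """Per-pixel windowed mean-of-extrema threshold."""
    img = np.asarray(image, dtype=float)
    padded = np.pad(img, radius, mode="reflect")
    out = np.zeros(img.shape, dtype=bool)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            win = padded[y : y + 2 * radius + 1, x : x + 2 * radius + 1]
            out[y, x] = img[y, x] < (win.max() + win.min()) / 2.0
    return out


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def union_find_labels(stack):
    """26-connected components of a boolean (t, y, x) stack.

    Returns an integer label volume (labels arbitrary but consistent).
    """
    m = np.asarray(stack, dtype=bool)
    coords = list(zip(*np.nonzero(m)))
    index = {c: i for i, c in enumerate(coords)}
    uf = _UnionFind(len(coords))
    offsets = [
        (dt, dy, dx)
        for dt in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dt, dy, dx) != (0, 0, 0)
    ]
    for c in coords:
        for dt, dy, dx in offsets:
            nb = (c[0] + dt, c[1] + dy, c[2] + dx)
            if nb in index:
                uf.union(index[c], index[nb])
    labels = np.zeros(m.shape, dtype=int)
    roots = {}
    for c in coords:
        root = uf.find(index[c])
        if root not in roots:
            roots[root] = len(roots) + 1
        labels[c] = roots[root]
    return labels


def partitions_equal(labels_a, labels_b):
    """True when two label volumes induce the same voxel partition."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if not np.array_equal(a > 0, b > 0):
        return False
    pairs = set(zip(a[a > 0].ravel(), b[b > 0].ravel()))
    # bijective label correspondence <=> same partition
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})
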