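"""Independent reference implementations used only to check the package.

These deliberately do NOT reuse the package's code paths: distances come
from the spherical law of cosines, and the density clustering is a direct
O(n^2) neighborhood-expansion DBSCAN.
"""

import numpy as np

EARTH_R = 6_371_000.0


def law_of_cosines_m(lat1, lon1, lat2, lon2):
    """Great-circle distance via the spherical law of cosines (degrees in)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2) - np.radians(lon1)
    c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return EARTH_R * np.arccos(np.clip(c, -1.0, 1.0))


def central_angle(coords_rad):
    """Pairwise central-angle matrix (radians) for (n, 2) lat/lon radians."""
    lat = coords_rad[:, 0]
    lon = coords_rad[:, 1]
    c = (np.sin(lat)[:, None] * np.sin(lat)[None, :]
         + np.cos(lat)[:, None] * np.cos(lat)[None, :]
         * np.cos(lon[:, None] - lon[None, :]))
    return np.arccos(np.clip(c, -1.0, 1.0))


def brute_force_dbscan(coords_rad, eps, min_samples, order_key=None):
    """O(n^2) DBSCAN: returns (labels, core_mask).

    Core point: at least min_samples points (self included) within eps.
    Clusters are connected components of core points under the eps graph;
    border points join the cluster of their core neighbor with the smallest
    ``order_key`` (defaults to index).
    """
    n = len(coords_rad)
    if n == 0:
        return np.empty(0, int), np.empty(0, bool)
    D = central_angle(coords_rad)
    within = D <= eps
    core = within.sum(axis=1) >= min_samples
    labels = np.full(n, -1, int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(within[j] & core):
                if labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    key = np.asarray(order_key) if order_key is not None else np.arange(n)
    for i in range(n):
        if core[i] or not within[i][core].any():
            continue
        cands = np.flatnonzero(within[i] & core)
        labels[i] = labels[cands[np.argmin(key[cands])]]
    return labels, core


def partitions_equal(a, b):
    """Partition equality up to label permutation (noise must match)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or ((a == -1) != (b == -1)).any():
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)
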