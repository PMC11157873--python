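"""Brute-force texture-matrix oracles: direct enumeration of voxel pairs,
runs, zones and dependence neighborhoods with plain Python loops."""

from __future__ import annotations

import numpy as np


def _inb(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def brute_glcm(levels, n_levels, distance, directions):
    """Symmetric co-occurrence counts by looping over every voxel pair."""
    P = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for p in np.ndindex(shape):
        if levels[p] <= 0:
            continue
        for d in directions:
            q = tuple(c + distance * o for c, o in zip(p, d))
            if _inb(shape, q) and levels[q] > 0:
                P[levels[p] - 1, levels[q] - 1] += 1
                P[levels[q] - 1, levels[p] - 1] += 1
    return P


def brute_runs(levels, n_levels, directions):
    """Run-length counts: walk every maximal same-level run per direction."""
    shape = levels.shape
    max_len = max(shape)
    P = np.zeros((n_levels, max_len))
    for d in directions:
        for p in np.ndindex(shape):
            if levels[p] <= 0:
                continue
            prev = tuple(c - o for c, o in zip(p, d))
            if _inb(shape, prev) and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = tuple(c + o for c, o in zip(p, d))
            while _inb(shape, q) and levels[q] == levels[p]:
                length += 1
                q = tuple(c + o for c, o in zip(q, d))
            P[levels[p] - 1, length - 1] += 1
    return P


def brute_zones(levels, n_levels):
    """Size-zone counts by flood-filling 26-connected equal-level sets."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    neigh = [d for d in np.ndindex(3, 3, 3) if d != (1, 1, 1)]
    zones = []
    for p in np.ndindex(shape):
        if levels[p] <= 0 or seen[p]:
            continue
        stack, size, lv = [p], 0, levels[p]
        seen[p] = True
        while stack:
            c = stack.pop()
            size += 1
            for d in neigh:
                q = tuple(ci + di - 1 for ci, di in zip(c, d))
                if _inb(shape, q) and not seen[q] and levels[q] == lv:
                    seen[q] = True
                    stack.append(q)
        zones.append((lv, size))
    max_size = max(s for _, s in zones)
    P = np.zeros((n_levels, max_size))
    for lv, s in zones:
        P[lv - 1, s - 1] += 1
    return P


def brute_dependence(levels, n_levels, alpha):
    """Dependence-size counts: each voxel plus its qualifying 26-neighbors."""
    shape = levels.shape
    neigh = [d for d in np.ndindex(3, 3, 3) if d != (1, 1, 1)]
    entries = []
    for p in np.ndindex(shape):
        if levels[p] <= 0:
            continue
        dep = 1
        for d in neigh:
            q = tuple(ci + di - 1 for ci, di in zip(p, d))
            if (_inb(shape, q) and levels[q] > 0
                    and abs(int(levels[q]) - int(levels[p])) <= alpha):
                dep += 1
        entries.append((levels[p], dep))
    max_dep = max(d for _, d in entries)
    P = np.zeros((n_levels, max_dep))
    for lv, dep in entries:
        P[lv - 1, dep - 1] += 1
    return P
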