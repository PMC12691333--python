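"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (explicit loops,
direct formulas) and share no code with the package, so agreement between
the two is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

import habikit as hk


@pytest.fixture(scope="session")
def small_cohort():
    """Six phantoms with the default three-habitat structure."""
    spec = hk.PhantomSpec(n_patients=6, seed=11, tumor_radius_range=(6.0, 9.0))
    volumes, clinical, truth = hk.generate_cohort(spec)
    return spec, volumes, clinical, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def entropy_bruteforce(values, mask, window, n_bins, eps):
    """Per-voxel neighbourhood entropy by explicit looping."""
    inside = mask.astype(bool)
    vals = values[inside]
    lo, hi = vals.min(), vals.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    out = {}
    nz, ny, nx = values.shape
    for z, y, x in zip(*np.nonzero(inside)):
        hist = np.zeros(n_bins)
        count = 0
        for dz in range(-window, window + 1):
            for dy in range(-window, window + 1):
                for dx in range(-window, window + 1):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx \
                            and inside[zz, yy, xx]:
                        b = np.searchsorted(edges, values[zz, yy, xx],
                                            side="right") - 1
                        hist[min(max(b, 0), n_bins - 1)] += 1
                        count += 1
        if count < 2:
            out[(z, y, x)] = 0.0
            continue
        p = hist / count
        out[(z, y, x)] = float(-(p * np.log2(p + eps)).sum())
    return out


def ch_bruteforce(x, labels):
    """Calinski-Harabasz by the definition, point by point."""
    x = np.asarray(x, float)
    labs = sorted(set(labels))
    k, n = len(labs), len(x)
    grand = x.mean(axis=0)
    b = w = 0.0
    for lab in labs:
        pts = x[np.asarray(labels) == lab]
        c = pts.mean(axis=0)
        b += len(pts) * ((c - grand) ** 2).sum()
        for p in pts:
            w += ((p - c) ** 2).sum()
    return (b / (k - 1)) / (w / (n - k))


def glcm_bruteforce(levels, mask, offset, n_levels):
    """Symmetric co-occurrence counts by enumerating every voxel pair."""
    mat = np.zeros((n_levels, n_levels))
    nz, ny, nx = levels.shape
    for z, y, x in zip(*np.nonzero(mask)):
        zz, yy, xx = z + offset[0], y + offset[1], x + offset[2]
        if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and mask[zz, yy, xx]:
            a, b = levels[z, y, x] - 1, levels[zz, yy, xx] - 1
            mat[a, b] += 1
            mat[b, a] += 1
    return mat


def glrlm_bruteforce(levels, mask, direction, n_levels):
    """Run-length counts by marching along every line."""
    d = np.array(direction)
    shape = np.array(levels.shape)
    runs = []
    visited = set()
    for start in zip(*np.nonzero(mask)):
        prev = tuple(np.array(start) - d)
        ok_prev = all(0 <= p < s for p, s in zip(prev, shape))
        if ok_prev and mask[prev] and levels[prev] == levels[start]:
            continue  # not a run start
        pos = np.array(start)
        length = 0
        lev = levels[start]
        while (all(0 <= p < s for p, s in zip(pos, shape))
               and mask[tuple(pos)] and levels[tuple(pos)] == lev):
            assert tuple(pos) not in visited
            visited.add(tuple(pos))
            length += 1
            pos = pos + d
        runs.append((lev, length))
    lmax = max(l for _, l in runs)
    mat = np.zeros((n_levels, lmax))
    for lev, length in runs:
        mat[lev - 1, length - 1] += 1
    return mat


def glszm_bruteforce(levels, mask, n_levels):
    """Zone counts by flood fill with 26-connectivity."""
    seen = np.zeros(levels.shape, bool)
    zones = []
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
            for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    nz, ny, nx = levels.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        lev = levels[start]
        stack, size = [start], 0
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in offs:
                zz, yy, xx = z + dz, y + dy, x + dx
                if (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                        and mask[zz, yy, xx] and not seen[zz, yy, xx]
                        and levels[zz, yy, xx] == lev):
                    seen[zz, yy, xx] = True
                    stack.append((zz, yy, xx))
        zones.append((lev, size))
    smax = max(s for _, s in zones)
    mat = np.zeros((n_levels, smax))
    for lev, size in zones:
        mat[lev - 1, size - 1] += 1
    return mat


def gldm_bruteforce(levels, mask, n_levels, alpha=0):
    """Dependence counts by explicit neighbour loops."""
    mat = np.zeros((n_levels, 27))
    nz, ny, nx = levels.shape
    for z, y, x in zip(*np.nonzero(mask)):
        dep = 0
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dz, dy, dx) == (0, 0, 0):
                        continue
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                            and mask[zz, yy, xx]
                            and abs(int(levels[zz, yy, xx])
                                    - int(levels[z, y, x])) <= alpha):
                        dep += 1
        mat[levels[z, y, x] - 1, dep] += 1
    return mat


def auc_pairs_bruteforce(scores, outcome):
    """AUC by counting all positive-negative pairs with half tie credit."""
    scores = np.asarray(scores, float)
    y = np.asarray(outcome)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def fisher_bruteforce(table):
    """Two-sided Fisher exact p by enumerating all tables with the margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return comb(r1, aa) * comb(r2, c1 - aa) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


def icc_bruteforce(a, b):
    """ICC(A,1) from the two-way ANOVA mean squares, one feature."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, k = len(a), 2
    data = np.stack([a, b], axis=1)
    grand = data.mean()
    ms_r = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - data.mean(axis=1, keepdims=True)
            - data.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    ms_e = sse / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))
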