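"""Texture-matrix feature families on discretized volumes.

All families use 3D neighbourhood conventions: GLCM over the 13 unique
distance-1 offsets (symmetric matrices, features averaged over offsets),
GLRLM over the corresponding 13 directions (features averaged), GLSZM zones
and GLDM dependences with 26-connectivity, NGTDM over the 26-neighbourhood.
Voxels outside the mask never pair with, run through, or count as neighbours
of masked voxels.

Degenerate-input conventions (kept so feature tables stay rectangular):
a single gray level makes GLCM Correlation 1 (perfect agreement limit) and
every inverse-difference feature 1; GLDM small-dependence emphases sum only
over dependence >= 1, since a dependence of 0 carries no neighbourhood.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVolume

__all__ = [
    "OFFSETS_13",
    "glcm_matrix", "glcm_features", "GLCM_FEATURES",
    "glrlm_matrix", "glrlm_features", "GLRLM_FEATURES",
    "glszm_matrix", "glszm_features", "GLSZM_FEATURES",
    "gldm_matrix", "gldm_features", "GLDM_FEATURES",
    "ngtdm_table", "ngtdm_features", "NGTDM_FEATURES",
]

_EPS = 1e-12

#: The 13 unique 3D offsets at Chebyshev distance 1 (one representative per
#: +/- pair of the 26-neighbourhood).
OFFSETS_13 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_OFFSETS_26 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


def _offset_slices(offset):
    src, dst = [], []
    for d in offset:
        if d >= 0:
            src.append(slice(0, None if d == 0 else -d))
            dst.append(slice(d, None))
        else:
            src.append(slice(-d, None))
            dst.append(slice(0, d))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "InverseVariance", "JointEnergy", "JointEntropy", "MaximumProbability",
    "SumAverage", "SumEntropy", "SumSquares",
)


def glcm_matrix(disc: DiscretizedVolume, offset) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts for one offset."""
    g = disc.n_levels
    src, dst = _offset_slices(offset)
    valid = disc.mask[src] & disc.mask[dst]
    a = disc.levels[src][valid] - 1
    b = disc.levels[dst][valid] - 1
    counts = np.bincount(a * g + b, minlength=g * g).reshape(g, g)
    return counts + counts.T


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    g = p.shape[0]
    i = np.arange(1, g + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = float((p * ii).sum())  # == mu_j by symmetry
    sig_i = float(np.sqrt((p * (ii - mu_i) ** 2).sum()))

    diff = np.abs(ii - jj)
    k_diff = np.arange(g, dtype=np.float64)
    p_diff = np.array([p[diff == k].sum() for k in range(g)])
    da = float((p_diff * k_diff).sum())
    ssum = ii + jj
    k_sum = np.arange(2, 2 * g + 1, dtype=np.float64)
    p_sum = np.array([p[ssum == k].sum() for k in range(2, 2 * g + 1)])

    if sig_i > 0:
        correlation = float(
            (p * (ii - mu_i) * (jj - mu_i)).sum() / (sig_i * sig_i)
        )
    else:
        correlation = 1.0  # single gray level: perfect-agreement convention

    off_diag = diff > 0
    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mu_i,
        "ClusterProminence": float((p * (ii + jj - 2 * mu_i) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu_i) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu_i) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff * np.log2(p_diff + _EPS)).sum()),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "Id": float((p / (1.0 + diff)).sum()),
        "Idm": float((p / (1.0 + diff ** 2)).sum()),
        "Idmn": float((p / (1.0 + diff ** 2 / g ** 2)).sum()),
        "Idn": float((p / (1.0 + diff / g)).sum()),
        "InverseVariance": float((p[off_diag] / diff[off_diag] ** 2).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((p_sum * k_sum).sum()),
        "SumEntropy": float(-(p_sum * np.log2(p_sum + _EPS)).sum()),
        "SumSquares": float((p * (ii - mu_i) ** 2).sum()),
    }


def glcm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """GLCM features averaged over the 13 unique distance-1 offsets."""
    acc: dict[str, float] = {}
    n_used = 0
    for offset in OFFSETS_13:
        counts = glcm_matrix(disc, offset)
        total = counts.sum()
        if total == 0:
            continue
        feats = _glcm_features_single(counts / total)
        for name, val in feats.items():
            acc[name] = acc.get(name, 0.0) + val
        n_used += 1
    if n_used == 0:
        raise ValueError("no co-occurring voxel pairs in any direction")
    return {name: acc[name] / n_used for name in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def glrlm_matrix(disc: DiscretizedVolume, direction) -> np.ndarray:
    """Run-length counts R[level-1, length-1] along one direction.

    A run is a maximal sequence of masked voxels of equal level spaced by
    exactly the direction vector; out-of-mask voxels break runs.  Voxels are
    grouped into lines by the (constant along a line) cross product of their
    position with the direction, then sorted by the projection onto it.
    """
    idx = np.nonzero(disc.mask)
    pos = np.stack(idx, axis=1).astype(np.int64)
    lv = disc.levels[idx].astype(np.int64)
    d = np.asarray(direction, dtype=np.int64)
    t = pos @ d
    line = np.cross(pos, d)
    order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
    t, lv, line = t[order], lv[order], line[order]

    if len(lv) == 0:
        raise ValueError("empty mask")
    same_line = np.all(line[1:] == line[:-1], axis=1)
    cont = same_line & (t[1:] - t[:-1] == d @ d) & (lv[1:] == lv[:-1])
    new_run = np.concatenate([[True], ~cont])
    run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    levels = lv[new_run]
    g = disc.n_levels
    lmax = int(lengths.max())
    return np.bincount(
        (levels - 1) * lmax + (lengths - 1), minlength=g * lmax
    ).reshape(g, lmax).astype(np.float64)


def _rlm_style_features(
    mat: np.ndarray, n_voxels: int, names: dict[str, str]
) -> dict[str, float]:
    """Shared emphasis/nonuniformity feature algebra for GLRLM and GLSZM.

    ``mat`` is counts indexed by (gray level - 1, size - 1); ``names`` maps
    the generic keys to the family's feature names (run vs zone vocabulary).
    """
    g, smax = mat.shape
    i = np.arange(1, g + 1, dtype=np.float64)[:, None]
    s = np.arange(1, smax + 1, dtype=np.float64)[None, :]
    n = mat.sum()
    if n == 0:
        raise ValueError("empty matrix")
    p = mat / n
    gl_marg = mat.sum(axis=1)
    sz_marg = mat.sum(axis=0)
    mu_i = (p * i).sum()
    mu_s = (p * s).sum()
    return {
        names["SE"]: float((mat / s ** 2).sum() / n),
        names["LE"]: float((mat * s ** 2).sum() / n),
        names["GLN"]: float((gl_marg ** 2).sum() / n),
        names["GLNN"]: float((gl_marg ** 2).sum() / n ** 2),
        names["SN"]: float((sz_marg ** 2).sum() / n),
        names["SNN"]: float((sz_marg ** 2).sum() / n ** 2),
        names["PCT"]: float(n / n_voxels),
        names["GLV"]: float((p * (i - mu_i) ** 2).sum()),
        names["SV"]: float((p * (s - mu_s) ** 2).sum()),
        names["ENT"]: float(-(p * np.log2(p + _EPS)).sum()),
        names["LGL"]: float((mat / i ** 2).sum() / n),
        names["HGL"]: float((mat * i ** 2).sum() / n),
        names["SLGL"]: float((mat / (i ** 2 * s ** 2)).sum() / n),
        names["SHGL"]: float((mat * i ** 2 / s ** 2).sum() / n),
        names["LLGL"]: float((mat * s ** 2 / i ** 2).sum() / n),
        names["LHGL"]: float((mat * s ** 2 * i ** 2).sum() / n),
    }


_GLRLM_NAMES = {
    "SE": "ShortRunEmphasis", "LE": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "SN": "RunLengthNonUniformity", "SNN": "RunLengthNonUniformityNormalized",
    "PCT": "RunPercentage", "GLV": "GrayLevelVariance", "SV": "RunVariance",
    "ENT": "RunEntropy", "LGL": "LowGrayLevelRunEmphasis",
    "HGL": "HighGrayLevelRunEmphasis", "SLGL": "ShortRunLowGrayLevelEmphasis",
    "SHGL": "ShortRunHighGrayLevelEmphasis",
    "LLGL": "LongRunLowGrayLevelEmphasis", "LHGL": "LongRunHighGrayLevelEmphasis",
}


def glrlm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """GLRLM features averaged over the 13 3D directions."""
    n_vox = disc.n_voxels
    acc: dict[str, float] = {}
    for direction in OFFSETS_13:
        feats = _rlm_style_features(
            glrlm_matrix(disc, direction), n_vox, _GLRLM_NAMES
        )
        for name, val in feats.items():
            acc[name] = acc.get(name, 0.0) + val
    return {name: acc[name] / len(OFFSETS_13) for name in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_GLSZM_NAMES = {
    "SE": "SmallAreaEmphasis", "LE": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "SN": "SizeZoneNonUniformity", "SNN": "SizeZoneNonUniformityNormalized",
    "PCT": "ZonePercentage", "GLV": "GrayLevelVariance", "SV": "ZoneVariance",
    "ENT": "ZoneEntropy", "LGL": "LowGrayLevelZoneEmphasis",
    "HGL": "HighGrayLevelZoneEmphasis", "SLGL": "SmallAreaLowGrayLevelEmphasis",
    "SHGL": "SmallAreaHighGrayLevelEmphasis",
    "LLGL": "LargeAreaLowGrayLevelEmphasis",
    "LHGL": "LargeAreaHighGrayLevelEmphasis",
}

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Zone counts Z[level-1, size-1]; zones are 26-connected equal-level
    components of the masked volume."""
    zones: list[tuple[int, int]] = []  # (level, size)
    for level in np.unique(disc.masked_levels):
        labeled, n = ndimage.label(
            (disc.levels == level) & disc.mask, structure=_STRUCT_26
        )
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((int(level), int(sz)) for sz in sizes)
    g = disc.n_levels
    smax = max(sz for _, sz in zones)
    mat = np.zeros((g, smax), dtype=np.float64)
    for level, sz in zones:
        mat[level - 1, sz - 1] += 1
    return mat


def glszm_features(disc: DiscretizedVolume) -> dict[str, float]:
    feats = _rlm_style_features(
        glszm_matrix(disc), disc.n_voxels, _GLSZM_NAMES
    )
    return {name: feats[name] for name in GLSZM_FEATURES}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity", "GrayLevelVariance",
    "DependenceEntropy", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def gldm_matrix(disc: DiscretizedVolume, alpha: int = 0) -> np.ndarray:
    """Dependence counts D[level-1, d] where d (0..26) is the number of
    26-neighbours within ``alpha`` gray levels of the centre."""
    dep = np.zeros(disc.levels.shape, dtype=np.int32)
    for offset in _OFFSETS_26:
        src, dst = _offset_slices(offset)
        ok = (
            disc.mask[src] & disc.mask[dst]
            & (np.abs(disc.levels[src] - disc.levels[dst]) <= alpha)
        )
        dep[src][...] = dep[src] + ok  # in-place on the view
    g = disc.n_levels
    lv = disc.levels[disc.mask] - 1
    d = dep[disc.mask]
    return np.bincount(lv * 27 + d, minlength=g * 27).reshape(g, 27).astype(
        np.float64
    )


def gldm_features(disc: DiscretizedVolume, alpha: int = 0) -> dict[str, float]:
    """GLDM features; small-dependence emphases sum over dependence >= 1
    (an isolated voxel has no neighbourhood to weight)."""
    mat = gldm_matrix(disc, alpha=alpha)
    g, dmax = mat.shape
    i = np.arange(1, g + 1, dtype=np.float64)[:, None]
    d = np.arange(0, dmax, dtype=np.float64)[None, :]
    n = mat.sum()
    p = mat / n
    pos = mat[:, 1:]
    dpos = d[:, 1:]
    gl_marg = mat.sum(axis=1)
    dp_marg = mat.sum(axis=0)
    return {
        "SmallDependenceEmphasis": float((pos / dpos ** 2).sum() / n),
        "LargeDependenceEmphasis": float((mat * d ** 2).sum() / n),
        "GrayLevelNonUniformity": float((gl_marg ** 2).sum() / n),
        "DependenceNonUniformity": float((dp_marg ** 2).sum() / n),
        "GrayLevelVariance": float(
            (p * (i - (p * i).sum()) ** 2).sum()
        ),
        "DependenceEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (pos / (i ** 2 * dpos ** 2)).sum() / n
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (pos * i ** 2 / dpos ** 2).sum() / n
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (mat * d ** 2 / i ** 2).sum() / n
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (mat * d ** 2 * i ** 2).sum() / n
        ),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity",
                  "Strength")


def ngtdm_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): occurrence counts and summed absolute deviations
    of the level from the mean of its masked 26-neighbourhood.

    Voxels with no masked neighbour are excluded.  Returns arrays of length
    N_g (levels 1..N_g; absent levels have n_i = 0).
    """
    mask = disc.mask.astype(np.float64)
    lv = disc.levels.astype(np.float64) * mask
    kernel = 27  # 3x3x3 box
    count = np.rint(
        ndimage.uniform_filter(mask, size=3, mode="constant", cval=0.0) * kernel
    ) - mask
    total = (
        ndimage.uniform_filter(lv, size=3, mode="constant", cval=0.0) * kernel
        - lv
    )
    valid = disc.mask & (count >= 1)
    nbr_mean = np.zeros(lv.shape)
    nbr_mean[valid] = total[valid] / count[valid]
    dev = np.abs(disc.levels[valid] - nbr_mean[valid])
    levels = disc.levels[valid]
    g = disc.n_levels
    n_i = np.bincount(levels - 1, minlength=g).astype(np.float64)
    s_i = np.bincount(levels - 1, weights=dev, minlength=g)
    return n_i, s_i


def ngtdm_features(disc: DiscretizedVolume) -> dict[str, float]:
    n_i, s_i = ngtdm_table(disc)
    n = n_i.sum()
    if n == 0:
        raise ValueError("no voxel has a masked neighbourhood")
    p_i = n_i / n
    present = p_i > 0
    g_present = int(present.sum())
    i = np.arange(1, disc.n_levels + 1, dtype=np.float64)

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6  # documented cap for flat regions

    if g_present > 1:
        ii = i[present][:, None]
        jj = i[present][None, :]
        pi = p_i[present][:, None]
        pj = p_i[present][None, :]
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum()
            / (g_present * (g_present - 1))
            * s_i.sum() / n
        )
        denom_busy = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        si = s_i[present][:, None]
        sj = s_i[present][None, :]
        complexity = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / n
        )
        s_total = s_i.sum()
        strength = (
            float(((pi + pj) * (ii - jj) ** 2).sum()) / s_total
            if s_total > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
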