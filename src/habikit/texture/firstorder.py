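"""First-order (histogram) features of masked intensities.

Conventions: percentiles use linear interpolation; IQR = P75 - P25; skewness
is m3 / m2^1.5 and kurtosis the non-excess Fisher-Pearson m4 / m2^2 (a normal
sample tends to 3); variance is the population (biased) moment.  Entropy and
Uniformity operate on the discretized gray levels, which the caller supplies
so the binning matches the texture families; standalone calls fall back to a
25-unit fixed bin width.  Degenerate (constant) regions return variance 0 and
NaN for skewness/kurtosis, keeping the feature table rectangular while
flagging the undefined moments.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize

__all__ = ["firstorder_features", "FIRSTORDER_FEATURES"]

FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

_EPS = 1e-12


def firstorder_features(
    values: np.ndarray,
    levels: np.ndarray | None = None,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """First-order feature set over masked voxel ``values`` (1D array).

    ``levels`` are the 1D discretized gray levels of the same voxels (used
    for Entropy and Uniformity); if omitted they are derived with a fixed
    25-unit bin width.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 voxels")
    if levels is None:
        disc = discretize(v.reshape(-1, 1, 1), np.ones((v.size, 1, 1), bool),
                          rule="width", bin_width=25.0)
        levels = disc.masked_levels
    counts = np.bincount(np.asarray(levels, dtype=np.int64))[1:]
    p = counts[counts > 0] / v.size

    mean = v.mean()
    m2 = ((v - mean) ** 2).mean()
    m3 = ((v - mean) ** 3).mean()
    m4 = ((v - mean) ** 4).mean()
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]

    return {
        "Energy": float((v ** 2).sum()),
        "TotalEnergy": float(voxel_volume * (v ** 2).sum()),
        "Entropy": float(-(p * np.log2(p + _EPS)).sum()),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((v ** 2).mean())),
        "Skewness": float(m3 / m2 ** 1.5) if m2 > 0 else float("nan"),
        "Kurtosis": float(m4 / m2 ** 2) if m2 > 0 else float("nan"),
        "Variance": float(m2),
        "Uniformity": float((p ** 2).sum()),
    }
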