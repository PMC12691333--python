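"""Gray-level discretization of masked intensities.

Texture-matrix families operate on integer gray levels 1..N_g.  Two rules are
supported: fixed bin width (levels anchored at the region minimum, the usual
choice for calibrated HU) and fixed bin count (for filter responses whose
scale is arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedVolume", "discretize"]


@dataclass
class DiscretizedVolume:
    """Integer gray levels on a mask: 0 outside, 1..n_levels inside."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    rule: str
    constant_region: bool = False

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(
    values: np.ndarray,
    mask: np.ndarray,
    rule: str = "width",
    bin_width: float = 25.0,
    n_bins: int = 32,
) -> DiscretizedVolume:
    """Discretize masked intensities into integer gray levels.

    ``rule="width"``: level(v) = floor((v - min) / bin_width) + 1, so N_g is
    determined by the region's range.  ``rule="count"``: ``n_bins`` equal-width
    bins over [min, max]; a constant region collapses to one level and is
    flagged.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    v = values[mask]
    lo, hi = float(v.min()), float(v.max())
    levels = np.zeros(values.shape, dtype=np.int32)

    if rule == "width":
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        lv = np.floor((v - lo) / bin_width).astype(np.int32) + 1
        ng = int(lv.max())
        levels[mask] = np.clip(lv, 1, ng)
        return DiscretizedVolume(levels, mask, ng, "width",
                                 constant_region=(ng == 1))
    if rule == "count":
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if hi <= lo:  # constant region: single level
            levels[mask] = 1
            return DiscretizedVolume(levels, mask, 1, "count",
                                     constant_region=True)
        edges = np.linspace(lo, hi, n_bins + 1)
        lv = np.clip(np.searchsorted(edges, v, side="right"), 1, n_bins)
        levels[mask] = lv.astype(np.int32)
        return DiscretizedVolume(levels, mask, n_bins, "count")
    raise ValueError(f"unknown discretization rule {rule!r}")
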