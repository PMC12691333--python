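"""Feature manifests and region-level extraction.

A :class:`FeatureManifest` declares the filter bank, the per-family feature
lists, and the shape features, and is the single source of truth for feature
names and counts.  The shipped ``default`` manifest (versioned JSON under
``habikit/data``) totals exactly 1218 features per region: 14 shape features
plus 14 filter images (original, LoG at sigma 1..5 mm, 8 wavelet subbands)
times 86 intensity/texture features.  A compact ``small`` manifest (original
filter only, 69 features) serves fast cohort-scale experiments.

Feature names follow the ``{filter}_{family}_{feature}`` convention, e.g.
``log.sigma.4.0.mm.3D_glcm_Idn`` or ``wavelet.LHH_glrlm_GrayLevelVariance``,
with a ``Sub{j}_`` prefix for habitat subregions, so published radscore
formulas evaluate against extracted tables verbatim.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ..io import TumorMask, VolumeImage, require_same_grid
from .discretize import discretize
from .filters import log_filter, wavelet_decompose
from .firstorder import firstorder_features
from .matrices import (
    glcm_features, gldm_features, glrlm_features, glszm_features,
    ngtdm_features,
)
from .shape import shape_features

__all__ = [
    "FeatureManifest", "load_manifest", "extract_region", "extract_patient",
    "extract_cohort",
]

logger = logging.getLogger(__name__)

_FAMILY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}


@dataclass(frozen=True)
class FeatureManifest:
    name: str
    version: int
    filters: tuple[str, ...]
    families: dict[str, tuple[str, ...]]
    shape: tuple[str, ...]
    discretization: dict
    wavelet: str = "coif1"

    @property
    def total_per_region(self) -> int:
        return len(self.shape) + len(self.filters) * sum(
            len(v) for v in self.families.values()
        )

    def feature_names(self, prefix: str = "") -> list[str]:
        names = [f"{prefix}original_shape_{f}" for f in self.shape]
        for filt in self.filters:
            for family, feats in self.families.items():
                names.extend(f"{prefix}{filt}_{family}_{f}" for f in feats)
        return names

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureManifest":
        m = cls(
            name=d["name"],
            version=int(d["version"]),
            filters=tuple(d["filters"]),
            families={k: tuple(v) for k, v in d["families"].items()},
            shape=tuple(d["shape"]),
            discretization=d["discretization"],
            wavelet=d.get("wavelet", "coif1"),
        )
        declared = d.get("total_per_region")
        if declared is not None and declared != m.total_per_region:
            raise ValueError(
                f"manifest declares {declared} features per region but "
                f"enumerates {m.total_per_region}"
            )
        return m


def load_manifest(name_or_path: str = "default") -> FeatureManifest:
    """Load a manifest by shipped name ("default", "small") or JSON path."""
    if name_or_path in ("default", "small"):
        text = (
            resources.files("habikit.data")
            .joinpath(f"manifest_{name_or_path}.json")
            .read_text()
        )
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return FeatureManifest.from_dict(json.loads(text))


def _crop_to_mask(image: VolumeImage, mask: np.ndarray, margin: int = 16):
    """Bounding-box crop (with margin) so filters run on a compact volume."""
    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - margin) for i in idx]
    hi = [min(s, int(i.max()) + margin + 1)
          for i, s in zip(idx, image.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image.values[sl], mask[sl]


def _filtered_volumes(values: np.ndarray, image: VolumeImage,
                      manifest: FeatureManifest):
    """Yield (filter_name, filtered_values) for every filter in the bank."""
    wavelet_bands = None
    vol = VolumeImage(values, image.spacing)
    for filt in manifest.filters:
        if filt == "original":
            yield filt, values
        elif filt.startswith("log.sigma."):
            sigma = float(filt.split(".sigma.")[1].split(".mm")[0])
            yield filt, log_filter(vol, sigma).values
        elif filt.startswith("wavelet."):
            if wavelet_bands is None:
                wavelet_bands = wavelet_decompose(values, manifest.wavelet)
            yield filt, wavelet_bands[filt.split(".", 1)[1]]
        else:
            raise ValueError(f"unknown filter {filt!r} in manifest")


def extract_region(
    image: VolumeImage,
    mask: TumorMask,
    manifest: FeatureManifest | None = None,
    prefix: str = "",
) -> dict[str, float]:
    """All manifest features for one region of one image.

    Filters are applied to the (cropped) image, each filtered volume is
    discretized under the manifest's rule for its class, and every family
    runs on the result.  Shape features are computed once from the mask.
    Regions under 8 voxels are processed but logged as low-confidence.
    """
    if manifest is None:
        manifest = load_manifest("default")
    require_same_grid(image, mask)
    if mask.n_voxels < 8:
        logger.warning(
            "region %s has only %d voxels; features are low-confidence",
            prefix or "<whole>", mask.n_voxels,
        )

    out: dict[str, float] = {}
    for fname, val in shape_features(mask).items():
        out[f"{prefix}original_shape_{fname}"] = val

    values, m = _crop_to_mask(image, mask.labels.astype(bool))
    disc_rules = manifest.discretization
    for filt, filtered in _filtered_volumes(values, image, manifest):
        rule = disc_rules["original"] if filt == "original" else disc_rules[
            "filtered"]
        disc = discretize(filtered, m, **rule)
        masked_vals = filtered[m]
        for family, feats in manifest.families.items():
            if family == "firstorder":
                computed = firstorder_features(
                    masked_vals, levels=disc.masked_levels,
                    voxel_volume=mask.voxel_volume,
                )
            else:
                computed = _FAMILY_FUNCS[family](disc)
            for f in feats:
                out[f"{filt}_{family}_{f}"] = computed[f]
    # Re-apply the prefix to non-shape names (shape already prefixed above).
    if prefix:
        out = {
            k if k.startswith(prefix) else f"{prefix}{k}": v
            for k, v in out.items()
        }
    expected = manifest.total_per_region
    if len(out) != expected:
        raise RuntimeError(
            f"extracted {len(out)} features, manifest declares {expected}"
        )
    return out


def extract_patient(
    image: VolumeImage,
    mask: TumorMask,
    habitat_map=None,
    manifest: FeatureManifest | None = None,
    regions: str = "whole",
) -> dict[str, float]:
    """Whole-tumor and/or per-habitat features for one patient.

    ``regions``: "whole", "habitats", or "both".  Habitat features carry a
    ``Sub{j}_`` prefix; a habitat absent in this patient contributes NaNs for
    its columns (the cohort-wide schema stays rectangular).
    """
    out: dict[str, float] = {}
    if regions in ("whole", "both"):
        out.update(extract_region(image, mask, manifest))
    if regions in ("habitats", "both"):
        if habitat_map is None:
            raise ValueError("habitat_map required for habitat regions")
        if manifest is None:
            manifest = load_manifest("default")
        for j in range(1, habitat_map.k + 1):
            prefix = f"Sub{j}_"
            region = habitat_map.region_mask(j)
            if region is None:
                for name in manifest.feature_names(prefix):
                    out[name] = float("nan")
            else:
                out.update(extract_region(image, region, manifest, prefix))
    return out


def extract_cohort(
    volumes,
    habitat_maps=None,
    manifest: FeatureManifest | None = None,
    regions: str = "whole",
    patient_ids=None,
) -> pd.DataFrame:
    """Feature table for a cohort: rows = patients, columns = named features."""
    rows = []
    for i, (image, mask) in enumerate(volumes):
        hmap = habitat_maps[i] if habitat_maps is not None else None
        rows.append(extract_patient(image, mask, hmap, manifest, regions))
    index = patient_ids if patient_ids is not None else range(len(rows))
    return pd.DataFrame(rows, index=index)
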