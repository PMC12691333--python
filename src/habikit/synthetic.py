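"""Seeded phantom cohorts with planted habitat structure.

Each phantom is an ellipsoidal "tumor" on a 1 mm isotropic grid, composited
from ``k_true`` spatially contiguous habitat populations.  Habitats differ in
mean attenuation (HU), attenuation spread, and texture correlation length, so
both voxel intensity and local entropy carry habitat signal — the two features
the habitat clustering stage uses.  Textures are Gaussian random fields:
white noise smoothed at the habitat's correlation length and rescaled to the
habitat's nominal voxel SD.

The binary outcome ("brain metastasis") is drawn from a logistic link on the
patient's true habitat volume fractions plus one subregional texture summary
(the realized voxel SD inside habitat 1).  This gives the subregional feature
set a true advantage over whole-tumor features, which is the contrast the
downstream models are meant to detect.  Clinical covariates are simulated
with realistic marginals but are independent of the outcome.

Determinism: one global seed is split into independent per-patient substreams
(`numpy.random.SeedSequence.spawn`), so identical ``(spec, seed)`` reproduces
the cohort bit-identically, including under per-patient parallel generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .io import TumorMask, VolumeImage

__all__ = [
    "HabitatParams",
    "PhantomSpec",
    "SyntheticTruth",
    "SegmentationPerturbation",
    "generate_cohort",
    "simulate_second_reader",
    "make_clinical_table",
    "TABLE1_VARIABLES",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HabitatParams:
    """One habitat population: mean HU, voxel SD (HU), correlation length (mm)."""

    mean_hu: float
    std_hu: float
    corr_length_mm: float


#: Default three-habitat parameterization: a low-attenuation "necrotic-like"
#: core population, an intermediate population, and an avidly enhancing one,
#: with distinct texture scales so entropy separates them even where HU alone
#: would not.
DEFAULT_HABITATS = (
    HabitatParams(mean_hu=20.0, std_hu=12.0, corr_length_mm=0.05),
    HabitatParams(mean_hu=60.0, std_hu=10.0, corr_length_mm=1.0),
    HabitatParams(mean_hu=105.0, std_hu=5.0, corr_length_mm=3.0),
)


@dataclass
class PhantomSpec:
    """Generation recipe for one phantom cohort.

    ``outcome_beta`` has length ``k_true + 1``: coefficients on the k habitat
    volume fractions followed by one on the habitat-1 texture summary (voxel
    SD, HU).  The logistic intercept is solved at generation time so the
    cohort-mean outcome probability equals ``prevalence_target``.
    """

    n_patients: int = 60
    k_true: int = 3
    habitat_params: tuple[HabitatParams, ...] = DEFAULT_HABITATS
    tumor_radius_range: tuple[float, float] = (8.0, 14.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    outcome_beta: tuple[float, ...] = (4.0, 0.0, -4.0, 2.0)
    prevalence_target: float = 0.35
    geometry: str = "voronoi"  # or "shells"
    mean_jitter_hu: float = 2.0
    std_jitter_rel: float = 0.15
    background_hu: float = -800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if len(self.habitat_params) != self.k_true:
            raise ValueError(
                f"habitat_params has {len(self.habitat_params)} entries, "
                f"expected k_true={self.k_true}"
            )
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must lie strictly in (0, 1)")
        if len(self.outcome_beta) != self.k_true + 1:
            raise ValueError(
                "outcome_beta must have k_true + 1 entries "
                "(habitat fractions then texture summary)"
            )
        if self.geometry not in ("voronoi", "shells"):
            raise ValueError(f"unknown habitat geometry {self.geometry!r}")
        # Separability guarantee: habitat mean HUs pairwise distinct by at
        # least twice the largest habitat SD.
        means = np.array([h.mean_hu for h in self.habitat_params], dtype=float)
        max_sd = max(h.std_hu for h in self.habitat_params)
        if self.k_true > 1:
            gaps = np.abs(means[:, None] - means[None, :])
            gaps[np.diag_indices_from(gaps)] = np.inf
            if gaps.min() < 2.0 * max_sd:
                raise ValueError(
                    "habitat mean HUs must differ pairwise by >= 2x the "
                    f"largest habitat SD ({2 * max_sd:.1f} HU); "
                    f"smallest gap is {gaps.min():.1f} HU"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["habitat_params"] = [asdict(h) for h in self.habitat_params]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["habitat_params"] = tuple(
            HabitatParams(**h) for h in d["habitat_params"]
        )
        for key in ("tumor_radius_range", "spacing", "outcome_beta"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort."""

    label_volumes: list[np.ndarray]  # 0 = background, 1..k = habitat
    habitat_fractions: np.ndarray  # (n_patients, k_true), rows sum to 1
    texture_summary: np.ndarray  # (n_patients,) realized habitat-1 voxel SD
    probability: np.ndarray  # (n_patients,) true P(outcome = 1)
    outcome: np.ndarray  # (n_patients,) binary
    intercept: float  # solved logistic intercept
    informative_features: tuple[str, ...] = ()

    @property
    def covariates(self) -> np.ndarray:
        """Link covariates: habitat fractions then texture summary."""
        return np.column_stack([self.habitat_fractions, self.texture_summary])


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _ellipsoid_mask(radii_mm: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Binary ellipsoid with the given semi-axes, padded by a 4-voxel margin."""
    half = np.ceil(radii_mm / spacing).astype(int) + 4
    shape = 2 * half + 1
    zz, yy, xx = np.meshgrid(
        *(np.arange(s) - h for s, h in zip(shape, half)), indexing="ij"
    )
    coords = np.stack([zz, yy, xx]) * spacing[:, None, None, None]
    r = np.sqrt(((coords / radii_mm[:, None, None, None]) ** 2).sum(axis=0))
    return r <= 1.0


def _normalized_radius(shape, radii_mm, spacing) -> np.ndarray:
    half = (np.array(shape) - 1) // 2
    zz, yy, xx = np.meshgrid(
        *(np.arange(s) - h for s, h in zip(shape, half)), indexing="ij"
    )
    coords = np.stack([zz, yy, xx]) * spacing[:, None, None, None]
    return np.sqrt(((coords / radii_mm[:, None, None, None]) ** 2).sum(axis=0))


def _habitat_labels(
    mask: np.ndarray,
    radii_mm: np.ndarray,
    spacing: np.ndarray,
    k: int,
    geometry: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partition the mask into k contiguous habitats (labels 1..k)."""
    labels = np.zeros(mask.shape, dtype=np.int16)
    if k == 1:
        labels[mask] = 1
        return labels
    if geometry == "shells":
        r = _normalized_radius(mask.shape, radii_mm, spacing)[mask]
        # Equal-volume concentric shells: habitat 1 innermost.
        edges = np.quantile(r, np.linspace(0, 1, k + 1)[1:-1])
        labels[mask] = np.searchsorted(edges, r, side="right") + 1
        return labels
    # Voronoi cells of k random interior seed points.
    idx = np.array(np.nonzero(mask)).T  # (n, 3) voxel coords
    r = _normalized_radius(mask.shape, radii_mm, spacing)
    interior = idx[r[tuple(idx.T)] <= 0.6]
    if len(interior) < k:
        interior = idx
    seeds = interior[rng.choice(len(interior), size=k, replace=False)]
    mm = idx * spacing  # distances in physical units
    d = np.linalg.norm(mm[:, None, :] - seeds[None, :, :] * spacing, axis=2)
    labels[tuple(idx.T)] = np.argmin(d, axis=1) + 1
    return labels


def _gaussian_random_field(
    shape, corr_length_vox: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD smooth noise field with the given correlation length (voxels)."""
    noise = rng.standard_normal(shape)
    if np.all(corr_length_vox <= 0.05):
        return noise
    field_ = ndimage.gaussian_filter(noise, sigma=corr_length_vox, mode="wrap")
    sd = field_.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return field_ / sd


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[VolumeImage, TumorMask, np.ndarray]:
    """One phantom: image, mask, and true habitat label volume."""
    spacing = np.asarray(spec.spacing, dtype=float)
    lo, hi = spec.tumor_radius_range
    for attempt in range(8):
        radii = rng.uniform(lo, hi, size=3)
        mask = _ellipsoid_mask(radii, spacing)
        if mask.sum() >= max(spec.k_true * 8, 27):
            break
        lo, hi = lo * 1.3, hi * 1.3
        logger.info("tumor too small for %d habitats; retrying with radius "
                    "range (%.1f, %.1f) mm", spec.k_true, lo, hi)
    else:
        raise ValueError("could not generate a tumor large enough for the "
                         f"requested {spec.k_true} habitats")

    labels = _habitat_labels(mask, radii, spacing, spec.k_true,
                             spec.geometry, rng)
    # Regenerate seeds if a habitat came out empty (possible only in the
    # degenerate case where interior sampling collapses).
    for _ in range(5):
        present = np.unique(labels[mask])
        if len(present) == spec.k_true:
            break
        labels = _habitat_labels(mask, radii, spacing, spec.k_true,
                                 spec.geometry, rng)

    values = np.full(mask.shape, spec.background_hu, dtype=np.float64)
    values += 30.0 * _gaussian_random_field(
        mask.shape, 1.0 / spacing, rng)  # lung-like background texture
    for j, hab in enumerate(spec.habitat_params, start=1):
        region = labels == j
        if not region.any():
            continue
        mean = hab.mean_hu + rng.normal(0.0, spec.mean_jitter_hu)
        std = hab.std_hu * rng.uniform(1.0 - spec.std_jitter_rel,
                                       1.0 + spec.std_jitter_rel)
        corr_vox = hab.corr_length_mm / spacing
        field_ = _gaussian_random_field(mask.shape, corr_vox, rng)
        values[region] = mean + std * field_[region]

    image = VolumeImage(values, tuple(spacing))
    tumor = TumorMask(mask.astype(np.uint8), tuple(spacing))
    return image, tumor, labels


def _solve_intercept(
    eta: np.ndarray, target: float, lo: float = -40.0, hi: float = 40.0
) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) == target."""

    def f(b0: float) -> float:
        return float(special.expit(b0 + eta).mean() - target)

    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"prevalence target {target} unattainable for this cohort"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def generate_cohort(
    spec: PhantomSpec,
) -> tuple[list[tuple[VolumeImage, TumorMask]], pd.DataFrame, SyntheticTruth]:
    """Generate a full phantom cohort.

    Returns the per-patient (image, mask) pairs, the clinical table, and the
    ground truth (habitat label volumes, fractions, outcome probabilities and
    draws).
    """
    root = np.random.SeedSequence(spec.seed)
    patient_seeds, aux_seed = root.spawn(spec.n_patients), root.spawn(1)[0]

    volumes: list[tuple[VolumeImage, TumorMask]] = []
    label_volumes: list[np.ndarray] = []
    fractions = np.zeros((spec.n_patients, spec.k_true))
    texture = np.zeros(spec.n_patients)
    for i, ss in enumerate(patient_seeds):
        rng = np.random.default_rng(ss)
        image, tumor, labels = _generate_phantom(spec, rng)
        volumes.append((image, tumor))
        label_volumes.append(labels)
        inside = labels[tumor.labels > 0]
        counts = np.bincount(inside, minlength=spec.k_true + 1)[1:]
        fractions[i] = counts / counts.sum()
        hab1 = image.values[labels == 1]
        texture[i] = hab1.std() if hab1.size > 1 else 0.0

    beta = np.asarray(spec.outcome_beta, dtype=float)
    covariates = np.column_stack([fractions, texture])
    eta = covariates @ beta
    b0 = _solve_intercept(eta, spec.prevalence_target)
    probability = special.expit(b0 + eta)
    aux_rng = np.random.default_rng(aux_seed)
    outcome = (aux_rng.uniform(size=spec.n_patients) < probability).astype(int)

    truth = SyntheticTruth(
        label_volumes=label_volumes,
        habitat_fractions=fractions,
        texture_summary=texture,
        probability=probability,
        outcome=outcome,
        intercept=b0,
        informative_features=tuple(
            [f"habitat_fraction_{j + 1}" for j in range(spec.k_true)]
            + ["habitat1_intensity_sd"]
        ),
    )
    clinical = make_clinical_table(spec, truth)
    return volumes, clinical, truth


# ---------------------------------------------------------------------------
# Second-reader simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationPerturbation:
    """Morphological perturbation emulating a second reader.

    ``grow_prob`` / ``shrink_prob`` are per-voxel probabilities of adding an
    outer-boundary voxel or removing an inner-boundary voxel, applied for
    ``iterations`` rounds with a 6-connected (face) structuring element.
    ``dice_floor`` is enforced by geometrically damping the probabilities and
    retrying when the perturbed mask falls below it.
    """

    grow_prob: float = 0.3
    shrink_prob: float = 0.3
    iterations: int = 1
    dice_floor: float = 0.85


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())


def simulate_second_reader(
    mask: TumorMask,
    perturb: SegmentationPerturbation = SegmentationPerturbation(),
    seed: int = 0,
) -> TumorMask:
    """Perturbed re-segmentation of ``mask`` with a guaranteed Dice floor."""
    base = mask.labels.astype(bool)
    struct = ndimage.generate_binary_structure(3, 1)
    rng = np.random.default_rng(seed)
    grow, shrink = perturb.grow_prob, perturb.shrink_prob
    for _ in range(12):
        out = base.copy()
        for _ in range(perturb.iterations):
            outer = ndimage.binary_dilation(out, struct) & ~out
            inner = out & ~ndimage.binary_erosion(out, struct)
            add = outer & (rng.uniform(size=out.shape) < grow)
            drop = inner & (rng.uniform(size=out.shape) < shrink)
            out = (out | add) & ~drop
        if out.sum() == 0:
            raise ValueError("perturbation emptied the mask")
        if _dice(base, out) >= perturb.dice_floor:
            return TumorMask(out.astype(np.uint8), mask.spacing, mask.origin,
                             mask.direction)
        grow, shrink = grow * 0.5, shrink * 0.5
    # Probabilities have been damped to near zero; the unperturbed mask
    # trivially satisfies the floor.
    return TumorMask(base.astype(np.uint8), mask.spacing, mask.origin,
                     mask.direction)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

#: Variable manifest mirroring the clinical characteristics table of an NSCLC
#: brain-metastasis cohort: demographics, serum tumor markers, stage, and
#: driver-mutation flags.
TABLE1_VARIABLES = (
    "age", "sex", "smoking", "tumor_type", "tumor_location",
    "CEA", "CA125", "CA72_4", "NSE", "SCC", "ProGRP", "Cyfra21_1",
    "T_stage", "N_stage", "M_stage",
    "gene_mutation", "EGFR", "ALK", "KRAS", "TP53",
)

#: Derived dichotomizations (strict > for marker cutoffs; >= for age).
DERIVED_VARIABLES = (
    "age_ge65", "N2_stage", "CEA_high", "CA125_high", "NSE_high",
    "ProGRP_high", "Cyfra21_1_high", "SCC_high",
)

_MARKER_CUTOFFS = {
    "CEA": 5.0, "CA125": 35.0, "NSE": 18.0, "ProGRP": 70.0,
    "Cyfra21_1": 2.08, "SCC": 2.0,
}


def make_clinical_table(spec: PhantomSpec, truth: SyntheticTruth) -> pd.DataFrame:
    """Simulated clinical covariates with realistic marginals.

    Covariates are independent of the synthetic outcome by construction (the
    outcome link uses only habitat composition), so the clinical model fitted
    downstream carries no true signal — the intended weakest baseline.
    """
    n = spec.n_patients
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 911]))

    def lognorm(median: float, sigma: float) -> np.ndarray:
        return np.exp(rng.normal(np.log(median), sigma, size=n))

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "age": np.clip(rng.normal(65.8, 9.0, size=n), 30, 92).round(1),
            "sex": rng.choice(["male", "female"], size=n, p=[0.59, 0.41]),
            "smoking": rng.uniform(size=n) < 0.47,
            "tumor_type": rng.choice(
                ["adenocarcinoma", "squamous"], size=n, p=[0.87, 0.13]),
            "tumor_location": rng.choice(
                ["peripheral", "central"], size=n, p=[0.86, 0.14]),
            "CEA": lognorm(5.6, 1.2).round(2),
            "CA125": lognorm(20.0, 1.0).round(2),
            "CA72_4": lognorm(4.2, 1.1).round(2),
            "NSE": lognorm(12.8, 0.35).round(2),
            "SCC": lognorm(1.0, 0.7).round(2),
            "ProGRP": lognorm(36.0, 0.4).round(2),
            "Cyfra21_1": lognorm(2.7, 0.8).round(2),
            "T_stage": rng.choice(["T1", "T2", "T3", "T4"], size=n,
                                  p=[0.20, 0.31, 0.24, 0.25]),
            "N_stage": rng.choice(["N0", "N1", "N2", "N3"], size=n,
                                  p=[0.30, 0.21, 0.32, 0.17]),
            "M_stage": rng.choice(["M0", "M1"], size=n, p=[0.48, 0.52]),
            "EGFR": rng.uniform(size=n) < 0.48,
            "ALK": rng.uniform(size=n) < 0.04,
            "KRAS": rng.uniform(size=n) < 0.10,
            "TP53": rng.uniform(size=n) < 0.10,
        }
    )
    df["gene_mutation"] = df[["EGFR", "ALK", "KRAS", "TP53"]].any(axis=1)

    df["age_ge65"] = df["age"] >= 65.0
    df["N2_stage"] = df["N_stage"] == "N2"
    for marker, cut in _MARKER_CUTOFFS.items():
        df[f"{marker}_high"] = df[marker] > cut  # strict >

    df["BM"] = truth.outcome.astype(int)
    return df
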