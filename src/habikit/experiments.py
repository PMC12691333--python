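"""Repeated-seed simulation experiments.

These are the package's headline numerical studies, each a thin loop over
the library: habitat-count recovery on phantoms with a known habitat count,
DeLong type-I-error calibration under a paired null, planted-feature
recovery through the selection pipeline, and the three-model AUC contrast
(clinical vs whole-tumor vs habitat) on cohorts whose outcome truly depends
on habitat composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import habitats as hb
from . import selection as sel
from . import stats as st
from .pipeline import RunConfig, analyze_cohort
from .synthetic import PhantomSpec, generate_cohort

__all__ = [
    "habitat_count_recovery",
    "delong_type_i_error",
    "lasso_recovery",
    "model_contrast",
    "ModelContrastResult",
]


def habitat_count_recovery(
    n_seeds: int = 20,
    n_patients: int = 20,
    k_true: int = 3,
    k_range=range(2, 7),
    base_seed: int = 0,
    **spec_overrides,
) -> dict:
    """Fraction of seeds where CH-based selection recovers the planted k.

    Each seed generates a fresh phantom cohort with ``k_true`` habitats,
    computes pooled (intensity, entropy) voxel features, and selects k by
    the Calinski-Harabasz argmax.
    """
    recovered = []
    k_stars = []
    for s in range(n_seeds):
        spec_kwargs = dict(n_patients=n_patients, k_true=k_true,
                           seed=base_seed + 1000 + s)
        spec_kwargs.update(spec_overrides)
        if k_true != 3 and "habitat_params" not in spec_kwargs:
            from .synthetic import DEFAULT_HABITATS, HabitatParams
            base = list(DEFAULT_HABITATS)
            while len(base) < k_true:
                last = base[-1]
                base.append(HabitatParams(last.mean_hu + 45.0, 9.0,
                                          last.corr_length_mm * 1.5))
            spec_kwargs["habitat_params"] = tuple(base[:k_true])
            spec_kwargs.setdefault(
                "outcome_beta", tuple([8.0] + [0.0] * (k_true - 1) + [0.25])
            )
        spec = PhantomSpec(**spec_kwargs)
        volumes, _, _ = generate_cohort(spec)
        fmaps = [hb.entropy_map(img, msk) for img, msk in volumes]
        pooled = hb.pool_cohort_features(fmaps)
        ks = hb.select_k(pooled.matrix, k_range=k_range,
                         seed=base_seed + 1000 + s)
        k_stars.append(ks.k_star)
        recovered.append(ks.k_star == k_true)
    return {
        "k_true": k_true,
        "k_stars": k_stars,
        "recovery_rate": float(np.mean(recovered)),
        "n_seeds": n_seeds,
    }


def delong_type_i_error(
    n_reps: int = 2000,
    n: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the paired AUC test under a null.

    Null construction: one latent signal drives the outcome; both score
    vectors are independent equally-noisy copies of it, so their true AUCs
    coincide while the scores stay correlated through the shared signal.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        signal = rng.standard_normal(n)
        y = (rng.uniform(size=n) < special.expit(1.5 * signal)).astype(int)
        if y.min() == y.max():
            y[rng.integers(n)] = 1 - y[0]
        a = signal + rng.standard_normal(n)
        b = signal + rng.standard_normal(n)
        if st.delong_test(a, b, y).p < alpha:
            rejections += 1
    return {
        "type_i_error": rejections / n_reps,
        "n_reps": n_reps,
        "n": n,
        "alpha": alpha,
    }


def lasso_recovery(
    n_seeds: int = 10,
    n: int = 200,
    n_features: int = 200,
    n_informative: int = 5,
    effect: float = 1.0,
    mrmr_top: int = 50,
    base_seed: int = 0,
) -> dict:
    """Planted-feature recovery through the correlation/mRMR/LASSO pipeline.

    Gaussian candidate features with ``n_informative`` of them entering a
    logistic outcome at coefficient ``effect``; recovery counts how many
    planted features survive to the final LASSO-selected set.
    """
    counts = []
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + 7000 + s)
        x = rng.standard_normal((n, n_features))
        informative = [f"f{j:03d}" for j in range(n_informative)]
        eta = effect * x[:, :n_informative].sum(axis=1)
        y = (rng.uniform(size=n) < special.expit(eta)).astype(int)
        table = pd.DataFrame(x, columns=[f"f{j:03d}" for j in
                                         range(n_features)])
        result = sel.select_features(table, y, mrmr_top=mrmr_top,
                                     seed=base_seed + 7000 + s)
        counts.append(len(set(result.selected) & set(informative)))
    return {
        "recovered_per_seed": counts,
        "median_recovered": float(np.median(counts)),
        "n_informative": n_informative,
    }


@dataclass
class ModelContrastResult:
    """Held-out AUCs of the three models across seeds."""

    auc: dict[str, list[float]]  # model -> per-seed validation AUC
    delong_z_training: list[float] = field(default_factory=list)
    reports: list = field(default_factory=list)

    def median_auc(self, model: str) -> float:
        return float(np.median(self.auc[model]))

    @property
    def ordering_holds(self) -> bool:
        return (
            self.median_auc("sub") > self.median_auc("voi")
            > self.median_auc("clin")
        )


def model_contrast(
    n_seeds: int = 10,
    n_patients: int = 120,
    base_seed: int = 0,
    manifest: str = "small",
    tumor_radius_range: tuple[float, float] = (6.0, 10.0),
    keep_reports: bool = False,
) -> ModelContrastResult:
    """Clinical vs whole-tumor vs habitat model contrast on phantom cohorts.

    For each seed a cohort with a habitat-linked outcome is generated and
    the full pipeline runs (habitat clustering, extraction, selection, model
    fits); the held-out validation AUCs of the three models are collected.
    """
    auc: dict[str, list[float]] = {"clin": [], "voi": [], "sub": []}
    zs: list[float] = []
    reports = []
    for s in range(n_seeds):
        config = RunConfig(
            phantom=dict(n_patients=n_patients,
                         tumor_radius_range=tumor_radius_range,
                         seed=base_seed + 300 + s),
            manifest=manifest,
            seed=base_seed + 300 + s,
        )
        report = analyze_cohort(config)
        for model in auc:
            auc[model].append(report.evaluation[f"{model}_validation"]["auc"])
        zs.append(report.delong["sub_vs_voi_training"]["z"])
        if keep_reports:
            reports.append(report)
    return ModelContrastResult(auc=auc, delong_z_training=zs,
                               reports=reports)
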