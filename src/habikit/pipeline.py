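"""End-to-end orchestration: simulate -> resample -> habitats -> extract ->
select -> fit -> evaluate -> report.

Two entry points:

* :func:`analyze_cohort` runs the whole analysis in memory on a generated
  cohort and returns the evaluation grid — the engine behind the experiment
  helpers and most tests.
* :func:`run_pipeline` is the disk-backed variant: every stage writes its
  artifacts under an output directory keyed by a config hash, stages resume
  from existing artifacts, and the final report is a deterministic JSON.

Leakage control: habitat clustering (pooled standardization + centroids),
feature selection and every model fit see only the training split;
validation patients are standardized and assigned with frozen training
parameters, and their outcomes enter only the final evaluation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import habitats as hb
from . import io as hio
from . import selection as sel
from . import stats as st
from .synthetic import PhantomSpec, generate_cohort
from .texture import extract_patient, load_manifest

__all__ = ["RunConfig", "RunReport", "analyze_cohort", "run_pipeline",
           "ingest_external"]

logger = logging.getLogger(__name__)
_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run (fully serializable)."""

    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    spacing_target: float = 1.0
    entropy_window: int = 1
    entropy_bins: int = 32
    entropy_eps: float = 1e-12
    k_range: tuple[int, int] = (2, 6)  # inclusive
    manifest: str = "small"
    r_max: float = 0.75
    mrmr_top: int = 50
    n_folds: int = 10
    split_ratio: float = 0.7
    seed: int = 17

    def phantom_spec(self) -> PhantomSpec:
        kwargs = dict(self.phantom)
        kwargs.setdefault("seed", self.seed)
        return PhantomSpec(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        if "phantom" in d:
            d["phantom"] = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["phantom"].items()
            }
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Deterministic summary of one run."""

    config_hash: str
    version: str
    k_star: int
    ch_by_k: dict[int, float]
    selection: dict[str, dict]
    evaluation: dict[str, dict]
    delong: dict[str, dict]
    n_training: int
    n_validation: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def report_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _eval_to_dict(ev: st.ModelEvaluation) -> dict:
    return {
        "auc": ev.auc, "ci": [ev.ci_low, ev.ci_high],
        "sensitivity": ev.sensitivity, "specificity": ev.specificity,
        "accuracy": ev.accuracy, "threshold": ev.threshold, "aic": ev.aic,
    }


def analyze_cohort(config: RunConfig, volumes=None, clinical=None,
                   truth=None) -> RunReport:
    """Run the full analysis in memory.

    When ``volumes``/``clinical`` are omitted a phantom cohort is generated
    from the config.  Returns the evaluation grid for the clinical,
    whole-tumor and habitat models on both splits, plus the habitat-count
    selection trace.
    """
    if volumes is None:
        volumes, clinical, truth = generate_cohort(config.phantom_spec())
    images = [v[0] for v in volumes]
    masks = [v[1] for v in volumes]

    # resample everything to the isotropic analysis grid
    resampled = [
        hio.resample_isotropic(img, msk, config.spacing_target)
        if not np.allclose(img.spacing, (config.spacing_target,) * 3)
        else (img, msk)
        for img, msk in zip(images, masks)
    ]
    images = [r[0] for r in resampled]
    masks = [r[1] for r in resampled]

    clinical = st.split_cohort(clinical, ratio=config.split_ratio,
                               seed=config.seed)
    is_train = (clinical["split"] == "training").values
    train_idx = np.nonzero(is_train)[0]
    valid_idx = np.nonzero(~is_train)[0]

    # --- habitats: fit on training voxels only -------------------------
    fmaps = [
        hb.entropy_map(images[i], masks[i], window=config.entropy_window,
                       n_bins=config.entropy_bins, eps=config.entropy_eps)
        for i in range(len(images))
    ]
    pooled = hb.pool_cohort_features([fmaps[i] for i in train_idx])
    lo, hi = config.k_range
    selection_k = hb.select_k(pooled.matrix, k_range=range(lo, hi + 1),
                              seed=config.seed)
    train_maps = hb.label_habitats(
        selection_k.best, pooled.patient_index,
        [fmaps[i] for i in train_idx], [masks[i] for i in train_idx],
    )
    habitat_maps: list = [None] * len(images)
    for j, i in enumerate(train_idx):
        habitat_maps[i] = train_maps[j]
    for i in valid_idx:
        habitat_maps[i] = hb.assign_to_centroids(
            pooled, selection_k.best, fmaps[i], masks[i]
        )

    # --- features -------------------------------------------------------
    manifest = load_manifest(config.manifest)
    rows = [
        extract_patient(images[i], masks[i], habitat_maps[i], manifest,
                        regions="both")
        for i in range(len(images))
    ]
    features = pd.DataFrame(rows, index=clinical.index)
    sub_cols = [c for c in features.columns if c.startswith("Sub")]
    voi_cols = [c for c in features.columns if not c.startswith("Sub")]

    y = clinical["BM"].astype(int).values
    y_tr, y_va = y[is_train], y[~is_train]
    feat_tr, feat_va = features[is_train], features[~is_train]
    # Impute absent-habitat NaNs with training column means.
    col_means = feat_tr.mean(axis=0)
    feat_tr = feat_tr.fillna(col_means)
    feat_va = feat_va.fillna(col_means)

    def _drop_degenerate(df: pd.DataFrame) -> pd.DataFrame:
        df = df.loc[:, df.notna().all(axis=0)]
        return df.loc[:, df.std(axis=0) > 1e-12]

    selections: dict[str, sel.SelectionResult] = {}
    models: dict[str, sel.RadscoreModel] = {}
    for tag, cols in (("voi", voi_cols), ("sub", sub_cols)):
        tbl = _drop_degenerate(feat_tr[cols])
        result = sel.select_features(
            tbl, y_tr, r_max=config.r_max, mrmr_top=config.mrmr_top,
            n_folds=config.n_folds, seed=config.seed,
        )
        selections[tag] = result
        models[tag] = sel.build_radscore(result, name=f"radscore_{tag}")

    # --- fit + evaluate -------------------------------------------------
    clin_model = st.fit_clinical_model(clinical[is_train])
    evaluation: dict[str, dict] = {}
    scores_by_model: dict[str, dict[str, np.ndarray]] = {}
    for tag, model in (("clin", None), ("voi", models["voi"]),
                       ("sub", models["sub"])):
        if tag == "clin":
            s_tr = clin_model.predict(clinical[is_train])
            s_va = clin_model.predict(clinical[~is_train])
        else:
            raw_tr = model.score(feat_tr)
            raw_va = model.score(feat_va)
            score_fit = st.fit_score_model(raw_tr, y_tr, name=tag)
            s_tr = score_fit.predict(raw_tr.reshape(-1, 1))
            s_va = score_fit.predict(raw_va.reshape(-1, 1))
        scores_by_model[tag] = {"training": s_tr, "validation": s_va}
        evaluation[f"{tag}_training"] = _eval_to_dict(
            st.evaluate_model(s_tr, y_tr))
        evaluation[f"{tag}_validation"] = _eval_to_dict(
            st.evaluate_model(s_va, y_va))

    delong = {}
    for cohort, yy in (("training", y_tr), ("validation", y_va)):
        cmp_ = st.delong_test(
            scores_by_model["sub"][cohort], scores_by_model["voi"][cohort], yy
        )
        delong[f"sub_vs_voi_{cohort}"] = {
            "auc_sub": cmp_.auc_a, "auc_voi": cmp_.auc_b,
            "z": cmp_.z, "p": cmp_.p,
        }

    return RunReport(
        config_hash=config.config_hash,
        version=_VERSION,
        k_star=selection_k.k_star,
        ch_by_k={int(k): float(v) for k, v in selection_k.ch_by_k.items()},
        selection={tag: s.to_dict() for tag, s in selections.items()},
        evaluation=evaluation,
        delong=delong,
        n_training=int(is_train.sum()),
        n_validation=int((~is_train).sum()),
    )


# ---------------------------------------------------------------------------
# Disk-backed pipeline
# ---------------------------------------------------------------------------

def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                               default=float))


def run_pipeline(config: RunConfig, out_dir) -> RunReport:
    """Disk-backed run: artifacts under ``out_dir``, resumable per stage.

    Stage artifacts are tied to the config hash; artifacts from a different
    configuration are regenerated rather than reused.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov_path = out / "provenance.json"
    if prov_path.exists():
        prov = json.loads(prov_path.read_text())
        if prov.get("config_hash") != config.config_hash:
            logger.info("config changed; clearing stale artifacts in %s", out)
            for p in out.rglob("*"):
                if p.is_file():
                    p.unlink()
    _write_json(out / "config.json", config.to_dict())
    _write_json(prov_path, {"config_hash": config.config_hash,
                            "version": _VERSION})

    cohort_dir = out / "cohort"
    clinical_path = cohort_dir / "clinical.csv"
    spec = config.phantom_spec()
    if clinical_path.exists():
        clinical = pd.read_csv(clinical_path, index_col=0)
        volumes = [
            (hio.read_volume(cohort_dir / f"img_{pid}.nii.gz"),
             hio.read_mask(cohort_dir / f"msk_{pid}.nii.gz"))
            for pid in clinical["patient_id"]
        ]
        truth = None
        logger.info("resumed cohort stage from %s", cohort_dir)
    else:
        cohort_dir.mkdir(exist_ok=True)
        volumes, clinical, truth = generate_cohort(spec)
        for pid, (img, msk), labels in zip(
            clinical["patient_id"], volumes, truth.label_volumes
        ):
            hio.write_volume(img, cohort_dir / f"img_{pid}.nii.gz")
            hio.write_mask(msk, cohort_dir / f"msk_{pid}.nii.gz")
            hio.write_volume(
                hio.VolumeImage(labels.astype(np.float64), img.spacing),
                cohort_dir / f"truth_{pid}.nii.gz",
            )
        clinical.to_csv(clinical_path)
        _write_json(cohort_dir / "spec.json", spec.to_dict())

    report_path = out / "report.json"
    report = analyze_cohort(config, volumes=volumes, clinical=clinical,
                            truth=truth)
    _write_json(report_path, report.to_dict())
    ch_table = pd.DataFrame(
        {"k": list(report.ch_by_k), "ch": list(report.ch_by_k.values())}
    )
    ch_table.to_csv(out / "ch_table.csv", index=False)
    grid = pd.DataFrame(report.evaluation).T
    grid.to_csv(out / "evaluation.csv")
    return report


def ingest_external(images_dir, masks_dir, clinical_csv) -> tuple[list, pd.DataFrame]:
    """Map an external deposit (per-patient image + mask volumes and one
    clinical CSV) into the standard cohort structure.

    Layout: ``<images_dir>/<patient_id>.nii.gz`` (or .nii/.nrrd) with
    matching file names under ``masks_dir``; the CSV needs ``patient_id``
    and ``BM`` columns, extra columns pass through.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    clinical = pd.read_csv(clinical_csv)
    if "patient_id" not in clinical or "BM" not in clinical:
        raise ValueError("clinical CSV must contain patient_id and BM columns")

    def _find(root: Path, pid: str) -> Path:
        for ext in (".nii.gz", ".nii", ".nrrd"):
            p = root / f"{pid}{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(
            f"no volume for patient {pid!r} under {root}"
        )

    volumes = []
    problems = []
    for pid in clinical["patient_id"].astype(str):
        try:
            img = hio.read_volume(_find(images_dir, pid))
            msk = hio.read_mask(_find(masks_dir, pid))
            hio.require_same_grid(img, msk)
            volumes.append((img, msk))
        except (FileNotFoundError, hio.GridMismatchError) as exc:
            problems.append(f"{pid}: {exc}")
    if problems:
        raise ValueError(
            "cohort reconciliation failed:\n" + "\n".join(problems)
        )
    return volumes, clinical
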