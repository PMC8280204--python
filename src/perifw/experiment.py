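"""Experiment orchestration: phantom cohort -> maps -> patches -> classifiers.

Two entry points:

* :func:`run_cohort_experiment` — streams phantom subjects in memory
  (generate, simulate DWI, fit maps, sample patches, discard volumes), then
  trains/cross-validates/tests the requested classifiers per input map.
  This is the benchmark driver.
* :func:`run_experiment` — the file-based staged pipeline behind the CLI:
  each stage reads its inputs from, and writes its outputs and a provenance
  marker to, the experiment directory; completed stages are skipped unless
  forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .cnn import (CLASSES, CnnClassifier, ModelConfig, balance_patches,
                  majority_vote, predict_patch_probs)
from .dwi import DWIVolume, load_dwi, load_mask, save_map
from .evaluate import (classification_metrics, confusion_counts,
                       cross_validate, mann_whitney_auc, roc_and_auc,
                       round_metrics)
from .freewater import FreeWaterConfig, fit_freewater, fw_corrected_scalars
from .gradients import GradientTable, default_gradient_table
from .patches import PatchSet, augment_patches, patch_budget, sample_patches
from .synthetic import SyntheticSubject, generate_cohort, make_cohort, simulate_dwi
from .tensor import MAP_KINDS, ScalarMap, fit_dti_wls, tensor_scalars
from .texture import TextureRfClassifier

__all__ = ["ExperimentConfig", "run_experiment", "run_cohort_experiment",
           "subject_scalar_maps", "subject_patches", "STAGES"]

logger = logging.getLogger(__name__)

#: patch windows reach at most half a window plus the augmentation shift
#: beyond an edema voxel, all in-plane
_MAP_MARGIN_VOX = 17


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, YAML-serializable."""

    outdir: str = "experiment"
    seed: int = 0
    n_train: tuple[int, int] = (20, 20)        # (glioblastoma, metastasis)
    n_test: tuple[int, int] = (5, 5)
    snr: float = 30.0
    overrides_by_class: dict = field(default_factory=dict)
    maps: tuple[str, ...] = ("FW-VF",)         # kinds or '+'-joined pairs
    classifiers: tuple[str, ...] = ("cnn",)    # cnn | gabor_rf | radiomic_rf
    cv_k: int = 5
    cv_level: str = "patch"
    n_aug: int = 1
    epochs: int = 30
    batch_size: int = 64
    freewater: dict = field(default_factory=dict)   # FreeWaterConfig overrides

    def __post_init__(self) -> None:
        self.n_train = tuple(self.n_train)
        self.n_test = tuple(self.n_test)
        self.maps = tuple(self.maps)
        self.classifiers = tuple(self.classifiers)
        for spec in self.maps:
            for kind in spec.split("+"):
                if kind not in MAP_KINDS:
                    raise ValueError(f"unknown map kind {kind!r}")
        for c in self.classifiers:
            if c not in ("cnn", "gabor_rf", "radiomic_rf"):
                raise ValueError(f"unknown classifier {c!r}")
        if sum(self.n_train) == 0:
            raise ValueError("empty training cohort")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d))


# -- map preparation ---------------------------------------------------------

def _map_fit_mask(subject_masks: dict[str, np.ndarray]) -> np.ndarray:
    """Voxels whose map values any admissible patch could touch: the edema
    dilated in-plane by a patch-plus-shift margin, inside the brain."""
    edema = subject_masks["edema"]
    size = (2 * _MAP_MARGIN_VOX + 1, 2 * _MAP_MARGIN_VOX + 1, 1)
    dilated = ndimage.maximum_filter(edema.astype(np.uint8), size=size) > 0
    return dilated & subject_masks["brain"]


def subject_scalar_maps(dwi: DWIVolume, masks: dict[str, np.ndarray],
                        kinds: set[str],
                        fw_config: FreeWaterConfig = FreeWaterConfig(),
                        ) -> dict[str, ScalarMap]:
    """Fit the requested scalar maps from a subject's DWI.

    Maps are fitted on the in-plane dilation of the edema (everything a
    patch footprint can reach); plain DTI scalars come from the WLS single
    tensor fit, FW-* maps from the bi-tensor free-water fit.
    """
    fit_mask = _map_fit_mask(masks)
    out: dict[str, ScalarMap] = {}
    if kinds & {"FA", "MD", "AX", "RAD"}:
        tensors = fit_dti_wls(dwi, fit_mask)
        out.update(tensor_scalars(tensors))
    if kinds & {"FW-VF", "FW-FA", "FW-AX", "FW-RAD"}:
        fw = fit_freewater(dwi, fit_mask, config=fw_config)
        out["FW-VF"] = fw.f
        out.update(fw_corrected_scalars(fw))
    return {k: v for k, v in out.items() if k in kinds}


def subject_patches(subject_maps: dict[str, ScalarMap],
                    masks: dict[str, np.ndarray], map_spec: str,
                    subject_id: str, label: str, seed: int,
                    n_aug: int = 0) -> PatchSet:
    """Budget-sized patch set for one subject and one map spec
    (single kind or '+'-joined combination), optionally shift-augmented."""
    kinds = map_spec.split("+")
    maps = [subject_maps[k] for k in kinds]
    n = patch_budget(masks["edema"])
    ps = sample_patches(maps, masks, n, seed=seed,
                        subject_id=subject_id, label=label)
    if n_aug > 0 and len(ps):
        ps = augment_patches(ps, maps, masks, n_aug=n_aug, seed=seed + 1)
    return ps


def _masks_of(subject: SyntheticSubject) -> dict[str, np.ndarray]:
    return {"brain": subject.brain, "tumor": subject.tumor,
            "edema": subject.edema}


def _make_classifier(name: str, map_spec: str, cfg: ExperimentConfig, seed: int):
    if name == "cnn":
        channels = len(map_spec.split("+"))
        return CnnClassifier(ModelConfig(
            input_shape=(16, 16, channels), epochs=cfg.epochs,
            batch_size=cfg.batch_size, seed=seed))
    if name == "gabor_rf":
        return TextureRfClassifier("gabor", seed=seed)
    if name == "radiomic_rf":
        return TextureRfClassifier("radiomic", seed=seed)
    raise ValueError(name)


def run_cohort_experiment(config: ExperimentConfig,
                          use_truth_maps: bool = False,
                          do_cv: bool = True,
                          gtab: GradientTable | None = None) -> dict:
    """In-memory experiment: returns a nested report dict.

    ``use_truth_maps=True`` skips DWI simulation and fitting and samples
    patches directly from the ground-truth FW-VF field (only valid for
    map spec 'FW-VF'); the default runs the full simulate-and-fit chain.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gtab = gtab or default_gradient_table()
    needed = {k for spec in cfg.maps for k in spec.split("+")}

    def collect(n_gbm, n_met, cohort_seed, augment):
        per_subject = []
        for subject in generate_cohort(n_gbm, n_met, seed=cohort_seed,
                                       overrides_by_class=cfg.overrides_by_class):
            masks = _masks_of(subject)
            if use_truth_maps:
                smap = {"FW-VF": subject.truth_f}
            else:
                dwi = simulate_dwi(subject, gtab=gtab, snr=cfg.snr,
                                   seed=subject.params.seed + 1)
                smap = subject_scalar_maps(
                    dwi, masks, needed, fw_config=FreeWaterConfig(**cfg.freewater))
            sets = {}
            for spec in cfg.maps:
                sets[spec] = subject_patches(
                    smap, masks, spec, subject.subject_id, subject.label,
                    seed=subject.params.seed + 2,
                    n_aug=cfg.n_aug if augment else 0)
            per_subject.append((subject.subject_id, subject.label, sets))
        return per_subject

    train_seed = int(rng.integers(2 ** 31))
    test_seed = int(rng.integers(2 ** 31))
    train_subjects = collect(*cfg.n_train, train_seed, augment=True)
    test_subjects = collect(*cfg.n_test, test_seed, augment=False) \
        if sum(cfg.n_test) else []

    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in cfg.__dict__.items()},
                    "maps": {}}
    for spec in cfg.maps:
        pooled = None
        for _, _, sets in train_subjects:
            pooled = sets[spec] if pooled is None else pooled.extend(sets[spec])
        pooled = balance_patches(pooled, seed=cfg.seed)
        block: dict = {"n_train_patches": len(pooled)}
        for clf_name in cfg.classifiers:
            entry: dict = {}
            if do_cv:
                cv = cross_validate(
                    pooled,
                    lambda fold: _make_classifier(clf_name, spec, cfg,
                                                  seed=cfg.seed + fold),
                    k=cfg.cv_k, seed=cfg.seed, level=cfg.cv_level)
                entry["cv"] = {
                    "mean": cv.mean_metrics,
                    "mean_rounded": round_metrics(cv.mean_metrics),
                    "folds": cv.fold_metrics,
                    "patch_auc": mann_whitney_auc(cv.pooled_scores,
                                                  cv.pooled_labels),
                }
                entry["_cv_scores"] = cv.pooled_scores
                entry["_cv_labels"] = cv.pooled_labels
            if test_subjects:
                clf = _make_classifier(clf_name, spec, cfg, seed=cfg.seed)
                clf.fit(pooled)
                preds, trues, scores = [], [], []
                for sid, label, sets in test_subjects:
                    ps = sets[spec]
                    if len(ps) == 0:
                        logger.warning("test subject %s has no patches", sid)
                        continue
                    probs = clf.predict_proba(ps)
                    vote = majority_vote(probs, subject_id=sid)
                    preds.append(vote.final_label)
                    trues.append(label)
                    scores.append(vote.gbm_vote_fraction)
                m = classification_metrics(confusion_counts(preds, trues))
                entry["test"] = {"metrics": m, "metrics_rounded": round_metrics(m),
                                 "n_subjects": len(trues),
                                 "subject_scores": scores,
                                 "subject_labels": trues,
                                 "subject_predictions": preds}
            block[clf_name] = entry
        report["maps"][spec] = block
    return report


# -- file-based staged pipeline (CLI backend) --------------------------------

STAGES = ("simulate", "fitmaps", "patches", "train", "crossval", "test", "report")


def _stage_dir(outdir: Path) -> Path:
    d = outdir / "stages"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _marker(outdir: Path, stage: str) -> Path:
    return _stage_dir(outdir) / f"{stage}.json"


def _write_marker(outdir: Path, stage: str, cfg: ExperimentConfig,
                  outputs: list[Path]) -> None:
    payload = {
        "stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "outputs": {str(p): _file_hash(p) for p in outputs if p.exists()},
    }
    _marker(outdir, stage).write_text(json.dumps(payload, indent=1))


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path}, produced by stage '{stage}'; "
            f"run that stage first")
    return path


def run_experiment(config: ExperimentConfig, stages: tuple[str, ...] | None = None,
                   force: bool = False) -> dict:
    """Run the staged pipeline under ``config.outdir``; returns the report.

    Completed stages (marker present) are skipped unless ``force``. The
    configuration is echoed into the experiment directory for provenance.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    for stage in stages or STAGES:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if _marker(outdir, stage).exists() and not force:
            logger.info("stage %s already complete; skipping", stage)
            continue
        logger.info("running stage %s", stage)
        _STAGE_FNS[stage](cfg, outdir)
    report_path = outdir / "report" / "report.json"
    return json.loads(report_path.read_text()) if report_path.exists() else {}


def _stage_simulate(cfg: ExperimentConfig, outdir: Path) -> None:
    rng = np.random.default_rng(cfg.seed)
    train_seed = int(rng.integers(2 ** 31))
    test_seed = int(rng.integers(2 ** 31))
    out = []
    for part, counts, seed in (("train", cfg.n_train, train_seed),
                               ("test", cfg.n_test, test_seed)):
        d = outdir / "cohort" / part
        manifest = make_cohort(d, counts[0], counts[1], seed=seed,
                               snr=cfg.snr,
                               overrides_by_class=cfg.overrides_by_class,
                               overwrite=True)
        out.append(d / "manifest.csv")
        logger.info("%s cohort: %d subjects", part, len(manifest))
    _write_marker(outdir, "simulate", cfg, out)


def _iter_manifest(outdir: Path, part: str, needed_by: str) -> pd.DataFrame:
    path = _require(outdir / "cohort" / part / "manifest.csv",
                    "simulate", needed_by)
    return pd.read_csv(path)


_SUFFIX = {"FW-VF": "fwvf", "FA": "fa", "MD": "md", "AX": "ax", "RAD": "rad",
           "FW-FA": "fwfa", "FW-AX": "fwax", "FW-RAD": "fwrad"}


def _stage_fitmaps(cfg: ExperimentConfig, outdir: Path) -> None:
    needed = {k for spec in cfg.maps for k in spec.split("+")}
    outputs = []
    for part in ("train", "test"):
        man = _iter_manifest(outdir, part, "fitmaps")
        d = outdir / "maps" / part
        d.mkdir(parents=True, exist_ok=True)
        for _, row in man.iterrows():
            base = Path(row.path_dwi).parent
            dwi = load_dwi(row.path_dwi, base / f"{row.subject_id}_dwi.bval",
                           base / f"{row.subject_id}_dwi.bvec")
            masks = {k: load_mask(row[f"path_{k}"])
                     for k in ("brain", "tumor", "edema")}
            smaps = subject_scalar_maps(
                dwi, masks, needed, fw_config=FreeWaterConfig(**cfg.freewater))
            for kind, smap in smaps.items():
                p = d / f"{row.subject_id}_{_SUFFIX[kind]}.nii.gz"
                save_map(smap.values, p, affine=dwi.affine, spacing=dwi.spacing)
                outputs.append(p)
    _write_marker(outdir, "fitmaps", cfg, outputs)


def _load_subject_maps(outdir: Path, part: str, sid: str,
                       kinds: set[str], masks) -> dict[str, ScalarMap]:
    import nibabel as nib
    out = {}
    for kind in kinds:
        p = _require(outdir / "maps" / part / f"{sid}_{_SUFFIX[kind]}.nii.gz",
                     "fitmaps", "patches")
        vals = np.asarray(nib.load(str(p)).dataobj, dtype=float)
        out[kind] = ScalarMap(values=vals, kind=kind, mask=masks["brain"])
    return out


def _stage_patches(cfg: ExperimentConfig, outdir: Path) -> None:
    needed = {k for spec in cfg.maps for k in spec.split("+")}
    outputs = []
    for part in ("train", "test"):
        man = _iter_manifest(outdir, part, "patches")
        d = outdir / "patches" / part
        d.mkdir(parents=True, exist_ok=True)
        for _, row in man.iterrows():
            masks = {k: load_mask(row[f"path_{k}"])
                     for k in ("brain", "tumor", "edema")}
            smaps = _load_subject_maps(outdir, part, row.subject_id, needed, masks)
            for spec in cfg.maps:
                ps = subject_patches(
                    smaps, masks, spec, row.subject_id, row.label,
                    seed=int(row.seed) + 2,
                    n_aug=cfg.n_aug if part == "train" else 0)
                stem = d / f"{row.subject_id}_{spec.replace('+', '_')}"
                ps.save(stem)
                ps.index_frame().to_csv(stem.with_suffix(".csv"), index=False)
                outputs.append(stem.with_suffix(".json"))
    _write_marker(outdir, "patches", cfg, outputs)


def _pooled_train_patches(cfg: ExperimentConfig, outdir: Path,
                          spec: str) -> PatchSet:
    man = _iter_manifest(outdir, "train", "train")
    pooled = None
    for _, row in man.iterrows():
        stem = outdir / "patches" / "train" / \
            f"{row.subject_id}_{spec.replace('+', '_')}"
        _require(stem.with_suffix(".json"), "patches", "train")
        ps = PatchSet.load(stem)
        pooled = ps if pooled is None else pooled.extend(ps)
    return balance_patches(pooled, seed=cfg.seed)


def _stage_train(cfg: ExperimentConfig, outdir: Path) -> None:
    outputs = []
    d = outdir / "models"
    d.mkdir(parents=True, exist_ok=True)
    for spec in cfg.maps:
        pooled = _pooled_train_patches(cfg, outdir, spec)
        for clf_name in cfg.classifiers:
            clf = _make_classifier(clf_name, spec, cfg, seed=cfg.seed)
            clf.fit(pooled)
            stem = d / f"{clf_name}_{spec.replace('+', '_')}"
            if clf_name == "cnn":
                clf.model.save(stem)
                clf.history.to_frame().to_csv(
                    stem.parent / (stem.name + "_history.csv"), index=False)
                outputs.append(stem.with_suffix(".npz"))
            else:
                import pickle
                with open(stem.with_suffix(".pkl"), "wb") as fh:
                    pickle.dump(clf, fh)
                outputs.append(stem.with_suffix(".pkl"))
    _write_marker(outdir, "train", cfg, outputs)


def _load_classifier(cfg: ExperimentConfig, outdir: Path, clf_name: str,
                     spec: str):
    stem = outdir / "models" / f"{clf_name}_{spec.replace('+', '_')}"
    if clf_name == "cnn":
        from .cnn import CnnModel
        _require(stem.with_suffix(".npz"), "train", "test")
        clf = CnnClassifier()
        clf.model = CnnModel.load(stem)
        return clf
    import pickle
    _require(stem.with_suffix(".pkl"), "train", "test")
    with open(stem.with_suffix(".pkl"), "rb") as fh:
        return pickle.load(fh)


def _stage_crossval(cfg: ExperimentConfig, outdir: Path) -> None:
    d = outdir / "report"
    d.mkdir(parents=True, exist_ok=True)
    outputs = []
    results = {}
    for spec in cfg.maps:
        pooled = _pooled_train_patches(cfg, outdir, spec)
        for clf_name in cfg.classifiers:
            cv = cross_validate(
                pooled,
                lambda fold: _make_classifier(clf_name, spec, cfg,
                                              seed=cfg.seed + fold),
                k=cfg.cv_k, seed=cfg.seed, level=cfg.cv_level)
            key = f"{clf_name}_{spec.replace('+', '_')}"
            p = d / f"cv_{key}.csv"
            cv.to_frame().to_csv(p, index=False)
            outputs.append(p)
            np.savez(d / f"cv_scores_{key}.npz", scores=cv.pooled_scores,
                     labels=cv.pooled_labels)
            results[key] = {"mean": cv.mean_metrics,
                            "mean_rounded": round_metrics(cv.mean_metrics)}
    (d / "crossval.json").write_text(json.dumps(results, indent=1))
    _write_marker(outdir, "crossval", cfg, outputs + [d / "crossval.json"])


def _stage_test(cfg: ExperimentConfig, outdir: Path) -> None:
    d = outdir / "report"
    d.mkdir(parents=True, exist_ok=True)
    man = _iter_manifest(outdir, "test", "test")
    results = {}
    outputs = []
    for spec in cfg.maps:
        for clf_name in cfg.classifiers:
            clf = _load_classifier(cfg, outdir, clf_name, spec)
            rows, preds, trues, scores = [], [], [], []
            for _, row in man.iterrows():
                stem = outdir / "patches" / "test" / \
                    f"{row.subject_id}_{spec.replace('+', '_')}"
                _require(stem.with_suffix(".json"), "patches", "test")
                ps = PatchSet.load(stem)
                if len(ps) == 0:
                    logger.warning("test subject %s has no patches",
                                   row.subject_id)
                    continue
                probs = clf.predict_proba(ps)
                vote = majority_vote(probs, subject_id=row.subject_id)
                preds.append(vote.final_label)
                trues.append(row.label)
                scores.append(vote.gbm_vote_fraction)
                rows.append({"subject_id": row.subject_id, "true": row.label,
                             "predicted": vote.final_label,
                             "n_patches": len(ps),
                             "votes_gbm": vote.votes[CLASSES[0]],
                             "votes_met": vote.votes[CLASSES[1]],
                             "gbm_vote_fraction": vote.gbm_vote_fraction,
                             "tie_broken": vote.tie_broken})
            key = f"{clf_name}_{spec.replace('+', '_')}"
            p = d / f"test_subjects_{key}.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            outputs.append(p)
            m = classification_metrics(confusion_counts(preds, trues))
            results[key] = {"metrics": m, "metrics_rounded": round_metrics(m),
                            "n_subjects": len(trues),
                            "subject_scores": scores,
                            "subject_labels": trues}
    (d / "test.json").write_text(json.dumps(results, indent=1))
    _write_marker(outdir, "test", cfg, outputs + [d / "test.json"])


def _stage_report(cfg: ExperimentConfig, outdir: Path) -> None:
    d = outdir / "report"
    d.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in cfg.__dict__.items()}}
    cv_path = d / "crossval.json"
    if cv_path.exists():
        report["crossval"] = json.loads(cv_path.read_text())
    test_path = d / "test.json"
    if test_path.exists():
        report["test"] = json.loads(test_path.read_text())
        # subject-level ROC per classifier/map from vote fractions
        rocs = {}
        for key, block in report["test"].items():
            scores = np.asarray(block["subject_scores"], dtype=float)
            labels = np.asarray(block["subject_labels"])
            if len(set(labels.tolist())) == 2:
                roc = roc_and_auc(scores, labels)
                roc.to_frame().to_csv(d / f"roc_subject_{key}.csv", index=False)
                rocs[key] = roc.auc
                _plot_roc(roc, d / f"roc_subject_{key}.png", key)
        report["subject_auc"] = rocs
    (d / "report.json").write_text(json.dumps(report, indent=1))
    _write_marker(outdir, "report", cfg, [d / "report.json"])


def _plot_roc(roc, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "fitmaps": _stage_fitmaps,
    "patches": _stage_patches,
    "train": _stage_train,
    "crossval": _stage_crossval,
    "test": _stage_test,
    "report": _stage_report,
}
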