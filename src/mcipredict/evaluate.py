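"""Metrics, cross-validation harnesses and the end-to-end experiment driver.

The positive class is the MCI converter (label +1) throughout:
sensitivity = correctly classified converters / all converters,
specificity = the same for non-converters.  AUC is the trapezoidal area
under the ROC built from the continuous classifier scores.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from mcipredict import preprocess, selection, synthetic
from mcipredict.cnn import (
    CnnConfig,
    build_cnn,
    classify_subject_by_patch_vote,
    extract_cnn_features,
    train_cnn,
)
from mcipredict.elm import CLASSIFIERS
from mcipredict.io import FeatureMatrix
from mcipredict.patches import extract_patch_set, sample_locations
from mcipredict.synthetic import SyntheticConfig

POSITIVE_GROUP = "MCIc"  # converter
NEGATIVE_GROUP = "MCInc"


# ---------------------------------------------------------------------------
# metrics


@dataclasses.dataclass
class EvalResult:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: np.ndarray  # (k, 2) columns (fpr, tpr), (0,0) .. (1,1)
    per_subject: pd.DataFrame
    flags: list[str] = dataclasses.field(default_factory=list)


def roc_curve_points(truth: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC points swept over distinct score thresholds (ties grouped)."""
    truth = np.asarray(truth)
    pos = truth > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    order = np.argsort(-np.asarray(scores, dtype=float), kind="mergesort")
    s_sorted = np.asarray(scores, dtype=float)[order]
    pos_sorted = pos[order]
    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(~pos_sorted)
    # keep only the last point of each tied-score run
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    tpr = tp / n_pos if n_pos else np.full(len(tp), np.nan)
    fpr = fp / n_neg if n_neg else np.full(len(fp), np.nan)
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def auc_trapezoid(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def compute_metrics(
    truth: Sequence[int],
    pred: Sequence[int],
    scores: Sequence[float],
    ids: Optional[Sequence[str]] = None,
) -> EvalResult:
    """Accuracy / sensitivity / specificity / trapezoidal AUC.

    ``truth`` and ``pred`` use {+1, -1}; single-class truth leaves
    sensitivity or specificity (and AUC) as NaN with a flag set.
    """
    truth = np.where(np.asarray(truth, dtype=float) > 0, 1, -1)
    pred = np.where(np.asarray(pred, dtype=float) > 0, 1, -1)
    scores = np.asarray(scores, dtype=float)
    if not (len(truth) == len(pred) == len(scores)):
        raise ValueError("truth, pred and scores must have equal length")
    flags: list[str] = []
    pos, neg = truth == 1, truth == -1
    accuracy = float((truth == pred).mean())
    if pos.any():
        sensitivity = float((pred[pos] == 1).mean())
    else:
        sensitivity, flags = np.nan, flags + ["no_positive_subjects"]
    if neg.any():
        specificity = float((pred[neg] == -1).mean())
    else:
        specificity, flags = np.nan, flags + ["no_negative_subjects"]
    if pos.any() and neg.any():
        points = roc_curve_points(truth, scores)
        auc = auc_trapezoid(points)
    else:
        points, auc = np.array([[0.0, 0.0], [1.0, 1.0]]), np.nan
    per_subject = pd.DataFrame(
        {
            "id": list(ids) if ids is not None else [str(i) for i in range(len(truth))],
            "truth": truth,
            "pred": pred,
            "score": scores,
        }
    )
    return EvalResult(accuracy, sensitivity, specificity, auc, points, per_subject, flags)


# ---------------------------------------------------------------------------
# per-fold trainable pipeline


@dataclasses.dataclass
class FusionConfig:
    """Dimensions of the PCA -> LASSO -> fusion chain."""

    p_c: int = 29  # PCA dims kept per patch (CNN branch)
    p_f: int = 150  # PCA dims kept for structural features
    l_c: int = 35  # LASSO-selected CNN features
    l_f: int = 40  # LASSO-selected structural features
    penalty: float = 0.1
    gamma: Optional[float] = None  # RBF width; None -> 1/d
    reg_C: float = 1.0
    refit_pca_per_fold: bool = True
    classifier: str = "elm"
    seed: int = 0


class FusionPipeline:
    """Standardize -> PCA -> LARS-LASSO -> fuse -> classifier, refit per fold.

    Holds the full cohort's raw per-subject inputs; ``fit`` only ever
    touches the rows named by ``train_idx`` (fold hygiene), which is
    recorded in ``last_fit_ids`` so tests can assert no leakage.
    """

    def __init__(
        self,
        subject_ids: Sequence[str],
        labels: Sequence[int],
        cnn_patch_features: Optional[np.ndarray] = None,  # (n, n_patches, D)
        struct_features: Optional[np.ndarray] = None,  # (n, F)
        cfg: FusionConfig | None = None,
    ):
        if cnn_patch_features is None and struct_features is None:
            raise ValueError("at least one feature source required")
        self.ids = [str(s) for s in subject_ids]
        self.labels = np.where(np.asarray(labels, dtype=float) > 0, 1, -1)
        self.cnn = None if cnn_patch_features is None else np.asarray(cnn_patch_features, float)
        self.struct = None if struct_features is None else np.asarray(struct_features, float)
        self.cfg = cfg or FusionConfig()
        self.last_fit_ids: list[str] = []
        self._global_pca_c = None
        self._global_pca_f = None
        if not self.cfg.refit_pca_per_fold:
            if self.cnn is not None:
                flat = self.cnn.reshape(-1, self.cnn.shape[2])
                self._global_pca_c = selection.fit_pca(flat, self.cfg.p_c)
            if self.struct is not None:
                self._global_pca_f = selection.fit_pca(self.struct, self.cfg.p_f)

    # -- branch transforms -------------------------------------------------

    def _cnn_block(self, idx: np.ndarray, fit: bool) -> np.ndarray:
        assert self.cnn is not None
        n, P, D = self.cnn.shape
        if fit and self.cfg.refit_pca_per_fold:
            self._pca_c = selection.fit_pca(self.cnn[idx].reshape(-1, D), self.cfg.p_c)
        elif fit:
            self._pca_c = self._global_pca_c
        reduced = selection.apply_pca(self._pca_c, self.cnn[idx].reshape(-1, D))
        per_subject = reduced.reshape(len(idx), P * self.cfg.p_c)
        if fit:
            fm = FeatureMatrix(
                per_subject,
                [self.ids[i] for i in idx],
                [f"c{j}" for j in range(per_subject.shape[1])],
            )
            std, self._scaler_c = selection.standardize(fm)
            self._sel_c = selection.lars_lasso_select(
                std, self.labels[idx], self.cfg.l_c, self.cfg.penalty
            )
            return std.values[:, self._sel_c.selected_indices]
        z = (per_subject - self._scaler_c.mean) / self._scaler_c.sd
        return z[:, self._sel_c.selected_indices]

    def _struct_block(self, idx: np.ndarray, fit: bool) -> np.ndarray:
        assert self.struct is not None
        if fit and self.cfg.refit_pca_per_fold:
            self._pca_f = selection.fit_pca(self.struct[idx], self.cfg.p_f)
        elif fit:
            self._pca_f = self._global_pca_f
        reduced = selection.apply_pca(self._pca_f, self.struct[idx])
        if fit:
            fm = FeatureMatrix(
                reduced,
                [self.ids[i] for i in idx],
                [f"f{j}" for j in range(reduced.shape[1])],
            )
            std, self._scaler_f = selection.standardize(fm)
            self._sel_f = selection.lars_lasso_select(
                std, self.labels[idx], self.cfg.l_f, self.cfg.penalty
            )
            return std.values[:, self._sel_f.selected_indices]
        z = (reduced - self._scaler_f.mean) / self._scaler_f.sd
        return z[:, self._sel_f.selected_indices]

    def _fused(self, idx: np.ndarray, fit: bool) -> np.ndarray:
        blocks = []
        if self.cnn is not None:
            blocks.append(self._cnn_block(idx, fit))
        if self.struct is not None:
            blocks.append(self._struct_block(idx, fit))
        return np.hstack(blocks)

    # -- harness interface -------------------------------------------------

    def fit(self, train_idx: Sequence[int]) -> "FusionPipeline":
        idx = np.asarray(train_idx, dtype=int)
        self.last_fit_ids = [self.ids[i] for i in idx]
        X = self._fused(idx, fit=True)
        kwargs = {}
        if self.cfg.classifier == "elm":
            kwargs = {"gamma": self.cfg.gamma, "reg_C": self.cfg.reg_C}
        elif self.cfg.classifier in ("svm",):
            kwargs = {"seed": self.cfg.seed}
        elif self.cfg.classifier == "rf":
            kwargs = {"seed": self.cfg.seed}
        self._clf = CLASSIFIERS[self.cfg.classifier](**kwargs)
        self._clf.fit(X, self.labels[idx])
        return self

    def decision(self, test_idx: Sequence[int]) -> np.ndarray:
        idx = np.asarray(test_idx, dtype=int)
        return self._clf.decision(self._fused(idx, fit=False))


# ---------------------------------------------------------------------------
# cross-validation harnesses


def loocv(pipeline: FusionPipeline) -> EvalResult:
    """Leave-one-out: n folds, each refitting the pipeline without the
    held-out subject."""
    n = len(pipeline.ids)
    if n < 2:
        raise ValueError("need >= 2 subjects for LOOCV")
    scores = np.empty(n)
    for i in range(n):
        train_idx = np.r_[np.arange(i), np.arange(i + 1, n)]
        if np.unique(pipeline.labels[train_idx]).size < 2:
            raise ValueError("a training fold lost one class entirely")
        pipeline.fit(train_idx)
        assert pipeline.ids[i] not in pipeline.last_fit_ids
        scores[i] = pipeline.decision([i])[0]
    pred = np.where(scores >= 0, 1, -1)
    return compute_metrics(pipeline.labels, pred, scores, ids=pipeline.ids)


def kfold_cv(pipeline: FusionPipeline, k: int = 10, seed: int = 0) -> EvalResult:
    """Stratified k-fold with per-fold refits; pooled per-subject scores."""
    n = len(pipeline.ids)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k == n:
        return loocv(pipeline)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(n)
    for train_idx, test_idx in skf.split(np.zeros(n), pipeline.labels):
        if np.unique(pipeline.labels[train_idx]).size < 2:
            raise ValueError("a training fold lost one class entirely")
        pipeline.fit(train_idx)
        scores[test_idx] = pipeline.decision(test_idx)
    pred = np.where(scores >= 0, 1, -1)
    return compute_metrics(pipeline.labels, pred, scores, ids=pipeline.ids)


# ---------------------------------------------------------------------------
# end-to-end experiment driver


@dataclasses.dataclass
class ExperimentConfig:
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    cnn: CnnConfig = dataclasses.field(default_factory=CnnConfig)
    fusion: FusionConfig = dataclasses.field(default_factory=FusionConfig)
    n_patches: int = 151
    min_distance: float = 2.0
    age_correction: bool = True
    histogram_match: bool = False
    ablations: tuple[str, ...] = ("fused", "cnn_only", "struct_only")
    cv: str = "loocv"  # or "kfold"
    k: int = 10
    seed: int = 0


@dataclasses.dataclass
class ExperimentResult:
    results: dict[str, EvalResult]
    artifacts: dict


def _prepare_volumes(cfg, records, volumes, mask):
    """Histogram matching + voxel-level age correction (NC-fit)."""
    artifacts = {}
    if cfg.histogram_match:
        template = synthetic.make_template(cfg.synthetic.volume_shape, cfg.synthetic.seed)
        volumes = [preprocess.match_histogram(v, template) for v in volumes]
    if cfg.age_correction:
        nc = [i for i, r in enumerate(records) if r.group == "NC"]
        model = preprocess.fit_age_correction(
            [volumes[i] for i in nc],
            [records[i].age for i in nc],
            reference_age=cfg.synthetic.reference_age,
        )
        volumes = [
            preprocess.apply_age_correction(model, v, r.age)
            for v, r in zip(volumes, records)
        ]
        artifacts["age_model_fit_groups"] = sorted({records[i].group for i in nc})
    return volumes, artifacts


def _subject_patch_features(model, volumes, locations) -> np.ndarray:
    """(n_subjects, n_patches, feature_dim) deep-feature tensor."""
    out = []
    for vol in volumes:
        patches = extract_patch_set(vol, locations)
        out.append(extract_cnn_features(model, patches).values)
    return np.stack(out)


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Full chain on a synthetic cohort.

    Preprocess -> age-correct -> sample locations once -> train CNN on
    AD/NC patches only -> extract MCI deep features -> per-ablation
    PCA/LASSO/classifier under the chosen CV scheme.  The CNN and the
    age-correction model are fit once, outside the CV loop, because
    neither ever sees MCI labels.
    """
    if cfg.cv not in ("loocv", "kfold"):
        raise ValueError(f"unknown cv scheme '{cfg.cv}'")
    records, volumes, mask = synthetic.generate_cohort(cfg.synthetic)
    volumes, artifacts = _prepare_volumes(cfg, records, volumes, mask)
    locations = sample_locations(
        mask, n=cfg.n_patches, min_distance=cfg.min_distance, seed=cfg.seed
    )
    artifacts["locations"] = locations

    # --- CNN trained on AD/NC patches only --------------------------------
    train_ids = [i for i, r in enumerate(records) if r.group in ("AD", "NC")]
    artifacts["cnn_training_groups"] = sorted({records[i].group for i in train_ids})
    patches, labels = [], []
    for i in train_ids:
        ps = extract_patch_set(volumes[i], locations)
        patches.extend(ps)
        labels.extend([1 if records[i].group == "AD" else 0] * len(ps))
    model = build_cnn(cfg.cnn)
    train_cnn(model, patches, labels)
    artifacts["cnn_log"] = list(model.training_log)

    # --- MCI deep + structural features -----------------------------------
    mci = [i for i, r in enumerate(records) if r.group in (POSITIVE_GROUP, NEGATIVE_GROUP)]
    mci_records = [records[i] for i in mci]
    mci_ids = [r.subject_id for r in mci_records]
    mci_labels = [1 if r.group == POSITIVE_GROUP else -1 for r in mci_records]
    cnn_feats = _subject_patch_features(model, [volumes[i] for i in mci], locations)

    struct = synthetic.generate_structural_features(cfg.synthetic, records)
    if cfg.age_correction:
        struct = preprocess.fit_and_apply_feature_age_correction(
            struct, records, reference_age=cfg.synthetic.reference_age
        )
    id_to_row = {s: i for i, s in enumerate(struct.subject_ids)}
    struct_mci = struct.values[[id_to_row[s] for s in mci_ids]]

    # --- per-ablation CV ---------------------------------------------------
    results = {}
    for ablation in cfg.ablations:
        fcfg = dataclasses.replace(cfg.fusion, seed=cfg.seed)
        pipeline = FusionPipeline(
            subject_ids=mci_ids,
            labels=mci_labels,
            cnn_patch_features=None if ablation == "struct_only" else cnn_feats,
            struct_features=None if ablation == "cnn_only" else struct_mci,
            cfg=fcfg,
        )
        if cfg.cv == "loocv":
            results[ablation] = loocv(pipeline)
        elif cfg.cv == "kfold":
            results[ablation] = kfold_cv(pipeline, k=cfg.k, seed=cfg.seed)
        else:
            raise ValueError(f"unknown cv scheme '{cfg.cv}'")
    return ExperimentResult(results=results, artifacts=artifacts)


# ---------------------------------------------------------------------------
# patch-vote protocol (CNN-only robustness comparison)


def run_patch_vote_comparison(cfg: ExperimentConfig) -> dict:
    """Two-arm patch-vote protocol on one synthetic cohort.

    Arm A: CNN trained on all AD/NC patches, patch-vote classifies a
    held-out MCI test half.  Arm B: CNN trained on the other MCI half's
    patches, evaluated on the same test half.  Returns both accuracies.
    """
    records, volumes, mask = synthetic.generate_cohort(cfg.synthetic)
    volumes, _ = _prepare_volumes(cfg, records, volumes, mask)
    locations = sample_locations(
        mask, n=cfg.n_patches, min_distance=cfg.min_distance, seed=cfg.seed
    )

    def patch_sets(indices):
        return {i: extract_patch_set(volumes[i], locations) for i in indices}

    adnc = [i for i, r in enumerate(records) if r.group in ("AD", "NC")]
    mci = [i for i, r in enumerate(records) if r.group in (POSITIVE_GROUP, NEGATIVE_GROUP)]
    rng = np.random.default_rng(cfg.seed)
    mci_pos = [i for i in mci if records[i].group == POSITIVE_GROUP]
    mci_neg = [i for i in mci if records[i].group == NEGATIVE_GROUP]
    rng.shuffle(mci_pos)
    rng.shuffle(mci_neg)
    test = mci_pos[: len(mci_pos) // 2] + mci_neg[: len(mci_neg) // 2]
    train_mci = [i for i in mci if i not in set(test)]

    cache = patch_sets(set(adnc) | set(mci))

    def train_and_vote(train_idx, positive_group):
        patches, labels = [], []
        for i in train_idx:
            ps = cache[i]
            patches.extend(ps)
            labels.extend([1 if records[i].group == positive_group else 0] * len(ps))
        model = build_cnn(cfg.cnn)
        train_cnn(model, patches, labels)
        correct = 0
        for i in test:
            vote = classify_subject_by_patch_vote(model, cache[i])
            truth = 1 if records[i].group == POSITIVE_GROUP else 0
            correct += int(vote == truth)
        return correct / len(test)

    return {
        "adnc_trained_accuracy": train_and_vote(adnc, "AD"),
        "mci_trained_accuracy": train_and_vote(train_mci, POSITIVE_GROUP),
        "n_test": len(test),
    }
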