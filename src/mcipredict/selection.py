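"""Standardization, PCA reduction, LARS-LASSO selection and fusion.

The sparse selector runs the least-angle-regression path for the LASSO
objective ``0.5 * ||y - D a||^2 + penalty * ||a||_1`` and stops once
``n_select`` distinct variables have entered the path, returning them
in entry order.  Labels are encoded {+1, -1}.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import lars_path

from mcipredict.io import FeatureMatrix


@dataclasses.dataclass
class Scaler:
    """Train-set column means/SDs, reapplied to test rows."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if fm.n_features != len(self.mean):
            raise ValueError("feature count mismatch with fitted scaler")
        values = (fm.values - self.mean) / self.sd
        return FeatureMatrix(values, list(fm.subject_ids), list(fm.feature_names))


def standardize(fm: FeatureMatrix) -> tuple[FeatureMatrix, Scaler]:
    """Zero-mean unit-variance columns; constant columns map to 0."""
    if fm.n_subjects < 2:
        raise ValueError("need >= 2 rows to standardize")
    mean = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) mapped to zero",
            stacklevel=2,
        )
        sd = np.where(constant, 1.0, sd)
    scaler = Scaler(mean=mean, sd=sd)
    return scaler.transform(fm), scaler


@dataclasses.dataclass
class PcaModel:
    mean: np.ndarray
    components: np.ndarray  # (original_dim, kept_dim), orthonormal columns
    kept_dim: int


def fit_pca(fm: FeatureMatrix | np.ndarray, kept_dim: int) -> PcaModel:
    """Top-``kept_dim`` principal components of the training matrix."""
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    n, d = X.shape
    if kept_dim > min(n, d):
        raise ValueError(f"kept_dim {kept_dim} exceeds min(n={n}, d={d})")
    solver = "full" if min(n, d) <= 600 else "randomized"
    p = PCA(n_components=kept_dim, svd_solver=solver, random_state=0)
    p.fit(X)
    return PcaModel(mean=p.mean_, components=p.components_.T, kept_dim=kept_dim)


def apply_pca(model: PcaModel, fm: FeatureMatrix | np.ndarray):
    """Project onto the kept components; returns the same container kind."""
    if isinstance(fm, FeatureMatrix):
        proj = (fm.values - model.mean) @ model.components
        names = [f"pc_{j}" for j in range(model.kept_dim)]
        return FeatureMatrix(proj, list(fm.subject_ids), names)
    return (np.asarray(fm, dtype=float) - model.mean) @ model.components


@dataclasses.dataclass
class LassoSelection:
    selected_indices: list[int]
    coefficients: np.ndarray
    penalty: float

    def __post_init__(self) -> None:
        idx = self.selected_indices
        if len(set(idx)) != len(idx):
            raise ValueError("selected indices must be unique")


def lars_lasso_select(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    n_select: int,
    penalty: float = 0.1,
) -> LassoSelection:
    """Run the LARS path for the LASSO and keep the first ``n_select``
    variables to enter, in entry order.

    The ``penalty`` sets the smallest regularization the path is allowed
    to reach; if the path ends (or the penalty floor is hit) before
    ``n_select`` variables have entered, an error is raised rather than
    returning a short selection.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, dtype=float)
    y = np.where(y > 0, 1.0, -1.0)  # {+1, -1} encoding
    n, d = X.shape
    if n_select > d:
        raise ValueError(f"cannot select {n_select} from {d} features")
    if np.unique(y).size < 2:
        raise ValueError("labels are all equal; selection is degenerate")
    if n_select == 0:
        return LassoSelection([], np.zeros(d), penalty)

    # sklearn's lasso objective is (1/2n)||y - Xw||^2 + alpha ||w||_1
    alpha_min = penalty / n
    _, _, coefs = lars_path(
        X,
        y,
        method="lasso",
        alpha_min=alpha_min,
        max_iter=max(8 * n_select + 16, 64),
        return_path=True,
    )
    entered: list[int] = []
    stop_step = coefs.shape[1] - 1
    for step in range(coefs.shape[1]):
        new = np.flatnonzero((coefs[:, step] != 0) & (coefs[:, step - 1] == 0) if step else coefs[:, step] != 0)
        for j in new:
            if j not in entered:
                entered.append(int(j))
        if len(entered) >= n_select:
            stop_step = step
            break
    if len(entered) < n_select:
        raise RuntimeError(
            f"LARS path ended after {len(entered)} entered variables; "
            f"cannot select {n_select} (n={n}, d={d}, penalty={penalty})"
        )
    return LassoSelection(entered[:n_select], coefs[:, stop_step].copy(), penalty)


def apply_selection(sel: LassoSelection, fm: FeatureMatrix) -> FeatureMatrix:
    values = fm.values[:, sel.selected_indices]
    names = [fm.feature_names[j] for j in sel.selected_indices]
    return FeatureMatrix(values, list(fm.subject_ids), names)


def build_fused_feature_vector(
    cnn_sel: FeatureMatrix | None, struct_sel: FeatureMatrix | None
) -> FeatureMatrix:
    """Row-wise concatenation, CNN-selected columns first.

    Either block may be omitted (single-feature ablations); subject
    order must agree when both are present.
    """
    blocks = [b for b in (cnn_sel, struct_sel) if b is not None]
    if not blocks:
        raise ValueError("at least one feature block required")
    if len(blocks) == 2 and blocks[0].subject_ids != blocks[1].subject_ids:
        raise ValueError("subject order mismatch between feature blocks")
    values = np.hstack([b.values for b in blocks])
    names = [n for b in blocks for n in b.feature_names]
    return FeatureMatrix(values, list(blocks[0].subject_ids), names)
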