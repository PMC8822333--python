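"""Cross-validated PLS-DA, VIP scoring, and the voxel selection rule.

The discriminant model codes diagnosis as +/-1 and fits NIPALS partial least
squares on mean-centered, unit-variance voxels. The component count is chosen
by stratified k-fold cross-validation maximizing balanced accuracy (ties go
to the smaller model), then the model is refit on all data.

Variable importance in projection for voxel j:

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ),
    SS_a = q_a^2 t_a' t_a

so that mean(VIP^2) = 1. Selection keeps voxels with VIP >= 2 and an
absolute percent mean GM difference > 2%, split by direction: lower GM in
MCI is the biological signal; higher GM in MCI is treated as artifact and
excluded from integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, DegenerateInputError, InputError


@dataclass
class PlsdaModel:
    """Fitted PLS-DA model on standardized predictors."""

    n_components: int
    weights: np.ndarray        # (p, A), unit-norm columns
    scores: np.ndarray         # (n, A)
    x_loadings: np.ndarray     # (p, A)
    y_loadings: np.ndarray     # (A,)
    cv_curve: dict[int, float] # candidate components -> mean CV balanced acc
    mean_: np.ndarray
    scale_: np.ndarray
    classes_: tuple[str, str]  # (negative, positive)


@dataclass
class VoxelSelection:
    """Per-voxel VIP / percent-difference scores and the selection buckets."""

    vip: np.ndarray
    pct_diff: np.ndarray           # positive = lower GM in cases
    selected_ids: np.ndarray       # VIP and pct criteria met, lower GM in MCI
    artifact_ids: np.ndarray       # criteria met but higher GM in MCI
    flagged_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    vip_min: float = 2.0
    pct_min: float = 2.0


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def _encode(y: np.ndarray, pos_label: str | None) -> tuple[np.ndarray, tuple[str, str]]:
    classes = np.unique(y)
    if classes.size != 2:
        raise InputError(f"exactly two classes required, got {list(classes)}")
    if pos_label is None:
        pos_label = "MCI" if "MCI" in classes else classes[1]
    if pos_label not in classes:
        raise InputError(f"pos_label {pos_label!r} not among classes {list(classes)}")
    neg = [c for c in classes if c != pos_label][0]
    coded = np.where(y == pos_label, 1.0, -1.0)
    return coded, (str(neg), str(pos_label))


def fit_plsda_cv(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 3,
    max_components: int = 5,
    pos_label: str | None = None,
    random_state: int = 0,
) -> PlsdaModel:
    """Fit PLS-DA choosing the component count by stratified k-fold CV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError("X must be (n_subjects, n_voxels) aligned with y")
    coded, classes = _encode(y, pos_label)

    n, p = X.shape
    min_fold_train = n - int(np.ceil(n / k_folds))
    limit = int(min(max_components, p, min_fold_train - 1))
    if limit < max_components:
        warnings.warn(
            f"max_components clipped from {max_components} to {limit} by data rank",
            stacklevel=2,
        )
    if limit < 1:
        raise DegenerateInputError("too few samples for even one component")

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=random_state)
    folds = list(skf.split(X, y))
    for _, test in folds:
        if np.unique(y[test]).size < 2:
            raise InputError("a CV fold is missing one class; reduce k_folds")

    cv_curve: dict[int, float] = {}
    fold_cache = []
    for train, test in folds:
        Xtr, mean, scale = _standardize(X[train])
        Xte = (X[test] - mean) / scale
        fold_cache.append((Xtr, coded[train], Xte, y[test]))
    for a in range(1, limit + 1):
        accs = []
        for Xtr, ytr, Xte, yte_labels in fold_cache:
            pls = PLSRegression(n_components=a, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls.fit(Xtr, ytr)
                pred = pls.predict(Xte).ravel()
            pred_labels = np.where(pred >= 0, classes[1], classes[0])
            accs.append(balanced_accuracy_score(yte_labels, pred_labels))
        cv_curve[a] = float(np.mean(accs))
    best = max(cv_curve, key=lambda a: (cv_curve[a], -a))

    Xs, mean, scale = _standardize(X)
    pls = PLSRegression(n_components=best, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, coded)
    return PlsdaModel(
        n_components=best,
        weights=pls.x_weights_,
        scores=pls.x_scores_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_.ravel(),
        cv_curve=cv_curve,
        mean_=mean,
        scale_=scale,
        classes_=classes,
    )


def compute_vip(model: PlsdaModel) -> np.ndarray:
    """Per-voxel VIP scores from a fitted PLS-DA model."""
    W = model.weights                       # (p, A), unit norm per component
    T = model.scores                        # (n, A)
    q = model.y_loadings                    # (A,)
    ss = q**2 * np.einsum("na,na->a", T, T)
    total = ss.sum()
    if total <= 0:
        raise DegenerateInputError("zero total explained sum of squares")
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 == 0, 1.0, wnorm2)
    return np.sqrt(p * ((W**2 / wnorm2) @ ss) / total)


def select_voxels(
    vip: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    vip_min: float = 2.0,
    pct_min: float = 2.0,
    pos_label: str = "MCI",
) -> VoxelSelection:
    """Apply the VIP and percent-difference rule, partitioned by direction.

    pct_diff_j = 100 * (mean_control_j - mean_case_j) / mean_control_j,
    positive when cases have lower gray matter. Voxels meeting both
    thresholds are selected when positive and binned as artifacts when
    negative. Voxels with a zero control mean are flagged and excluded.
    """
    X = np.asarray(X, dtype=float)
    vip = np.asarray(vip, dtype=float)
    if vip.shape[0] != X.shape[1]:
        raise InputError("VIP vector not aligned with X columns")
    y = np.asarray(y)
    case = y == pos_label
    if not case.any() or case.all():
        raise InputError("both classes required")
    mean_case = X[case].mean(axis=0)
    mean_ctrl = X[~case].mean(axis=0)
    flagged = np.flatnonzero(mean_ctrl == 0)
    if flagged.size:
        warnings.warn(
            f"{flagged.size} voxels have zero control mean; flagged and excluded",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (mean_ctrl - mean_case) / mean_ctrl
    pct[flagged] = np.nan
    meets = (vip >= vip_min) & (np.abs(pct) > pct_min) & ~np.isnan(pct)
    selected = np.flatnonzero(meets & (pct > 0))
    artifact = np.flatnonzero(meets & (pct < 0))
    return VoxelSelection(
        vip=vip,
        pct_diff=pct,
        selected_ids=selected,
        artifact_ids=artifact,
        flagged_ids=flagged,
        vip_min=vip_min,
        pct_min=pct_min,
    )


class PLSDAVoxelSelector(BaseEstimator):
    """sklearn-style selector: CV PLS-DA fit, VIP scoring, selection rule.

    After ``fit(X, y)`` the instance exposes ``model_``, ``vip_``,
    ``pct_diff_``, ``selected_ids_``, ``artifact_ids_`` and a boolean
    ``support_`` over columns; ``transform(X)`` keeps the selected voxels.
    """

    def __init__(
        self,
        vip_min: float = 2.0,
        pct_min: float = 2.0,
        k_folds: int = 3,
        max_components: int = 5,
        pos_label: str = "MCI",
        random_state: int = 0,
    ) -> None:
        self.vip_min = vip_min
        self.pct_min = pct_min
        self.k_folds = k_folds
        self.max_components = max_components
        self.pos_label = pos_label
        self.random_state = random_state

    def fit(self, X, y) -> "PLSDAVoxelSelector":
        X = np.asarray(X, dtype=float)
        self.model_ = fit_plsda_cv(
            X,
            y,
            k_folds=self.k_folds,
            max_components=self.max_components,
            pos_label=self.pos_label,
            random_state=self.random_state,
        )
        self.vip_ = compute_vip(self.model_)
        sel = select_voxels(
            self.vip_, X, y,
            vip_min=self.vip_min, pct_min=self.pct_min, pos_label=self.pos_label,
        )
        self.selection_ = sel
        self.pct_diff_ = sel.pct_diff
        self.selected_ids_ = sel.selected_ids
        self.artifact_ids_ = sel.artifact_ids
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[sel.selected_ids] = True
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.shape[1] != self.support_.shape[0]:
            raise InputError("X column count differs from the fitted data")
        return X[:, self.support_]

    def fit_transform(self, X, y) -> np.ndarray:
        return self.fit(X, y).transform(X)
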