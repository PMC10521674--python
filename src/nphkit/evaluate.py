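"""Segmentation evaluation and NPH prediction.

Covers the Dice overlap score, per-class volumes in mL, the Evans' index
(frontal-horn width A over maximal inner-skull width B, measured on
axial slices; >= 0.3 reads as hydrocephalic), per-slice group volume
profiles, fusion of the 4 volumetric with the 26 network features, and
the repeated stratified cross-validated linear SVM that scores NPH
prediction in precision/recall percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import InvariantError
from .netmetrics import NetworkFeatureVector
from .types import LabelVolume

EVANS_THRESHOLD = 0.3
VOLUMETRIC_FEATURE_NAMES = ("ventricle_ml", "subarachnoid_ml", "gray_white_ml", "total_ml")

#: labels contributing to "total brain volume" (skull and background excluded)
BRAIN_LABELS = (1, 2, 3, 4, 5)


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """2|X∩Y| / (|X|+|Y|); two empty masks count as perfect agreement."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise InvariantError(f"mask shapes differ: {x.shape} vs {y.shape}")
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(x, y).sum() / denom)


def class_volumes(seg: LabelVolume) -> dict[str, float]:
    """Per-class volume in mL plus the total over brain tissue classes."""
    vox_ml = seg.voxel_volume_mm3 / 1000.0
    counts = np.bincount(seg.labels.reshape(-1), minlength=max(seg.legend, default=0) + 1)
    out = {name: float(counts[lab] * vox_ml) if lab < counts.size else 0.0
           for lab, name in sorted(seg.legend.items())}
    out["total"] = float(sum(counts[l] for l in BRAIN_LABELS if l < counts.size) * vox_ml)
    return out


def volumetric_features(seg: LabelVolume) -> dict[str, float]:
    """The 4 volume features: ventricle, subarachnoid, gray-white, total (mL)."""
    vox_ml = seg.voxel_volume_mm3 / 1000.0
    counts = np.bincount(seg.labels.reshape(-1), minlength=7)
    return {
        "ventricle_ml": float(counts[1] * vox_ml),
        "subarachnoid_ml": float(counts[2] * vox_ml),
        "gray_white_ml": float(counts[3] * vox_ml),
        "total_ml": float(sum(counts[l] for l in BRAIN_LABELS) * vox_ml),
    }


@dataclass
class EvansMeasurement:
    """A = widest frontal-horn transverse span, B = widest inner-skull span (mm)."""

    A: float
    B: float

    def __post_init__(self):
        if not (0 < self.A <= self.B):
            raise InvariantError(f"Evans widths must satisfy 0 < A <= B, got A={self.A}, B={self.B}")

    @property
    def index(self) -> float:
        return self.A / self.B


def _max_transverse_width(mask: np.ndarray, spacing_x: float) -> float:
    """Max over axial (z) slices of the left-right voxel-centre span."""
    best = 0.0
    xs = np.any(mask, axis=1)  # (x, z): any voxel at this x in this slice
    for z in range(mask.shape[2]):
        col = np.flatnonzero(xs[:, z])
        if col.size:
            best = max(best, float((col[-1] - col[0]) * spacing_x))
    return best


def evans_index(ventricle: np.ndarray, inner_skull: np.ndarray,
                spacing: tuple[float, float, float]) -> EvansMeasurement:
    """Evans' measurement from binary masks on a shared grid.

    A is the maximal transverse (left-right) span of the ventricle mask
    restricted to the anterior half of the brain bounding box — the
    frontal horns; B is the maximal transverse span of the inner skull
    over all axial slices.  Spans are measured centre-to-centre, so the
    quantisation error is at most one voxel.
    """
    ventricle = np.asarray(ventricle).astype(bool)
    inner_skull = np.asarray(inner_skull).astype(bool)
    if ventricle.shape != inner_skull.shape:
        raise InvariantError("ventricle and inner-skull masks must share a grid")
    if not ventricle.any() or not inner_skull.any():
        raise InvariantError("Evans' index needs nonempty ventricle and skull masks")
    ys = np.flatnonzero(np.any(inner_skull, axis=(0, 2)))
    y_mid = (ys[0] + ys[-1]) / 2.0
    anterior = np.zeros_like(ventricle)
    anterior[:, int(np.ceil(y_mid)):, :] = True  # +y is anterior (RAS)
    horns = ventricle & anterior
    if not horns.any():
        raise InvariantError("no ventricle voxels in the anterior half")
    A = _max_transverse_width(horns, spacing[0])
    B = _max_transverse_width(inner_skull, spacing[0])
    return EvansMeasurement(A=max(A, spacing[0] * 1e-9), B=B)


def classify_evans(e: EvansMeasurement, threshold: float = EVANS_THRESHOLD) -> str:
    """Threshold rule: index >= 0.3 reads as NPH."""
    return "NPH" if e.index >= threshold else "non-NPH"


def slice_profiles(group: list[LabelVolume], class_label: int):
    """Per-axial-slice mean and sd (mL) of one class across subjects."""
    if not group:
        raise InvariantError("slice profile needs at least one subject")
    ref = group[0]
    for i, lab in enumerate(group[1:], start=1):
        if not ref.same_grid_as(lab):
            raise InvariantError(f"subject {i} is not on the common grid")
    vox_ml = ref.voxel_volume_mm3 / 1000.0
    per_subj = np.stack([
        (lab.labels == class_label).sum(axis=(0, 1)) * vox_ml for lab in group
    ])  # (n_subjects, n_slices)
    return per_subj.mean(axis=0), per_subj.std(axis=0)


@dataclass
class SubjectFeatures:
    """4 volumetric + 26 network features for one subject."""

    volumetric: dict[str, float]
    network: NetworkFeatureVector

    def __post_init__(self):
        if tuple(self.volumetric) != VOLUMETRIC_FEATURE_NAMES:
            raise InvariantError(f"volumetric features must be {VOLUMETRIC_FEATURE_NAMES}")
        if any(v < 0 for v in self.volumetric.values()):
            raise InvariantError("volumes must be nonnegative")
        total = self.volumetric["total_ml"]
        if any(total + 1e-9 < v for k, v in self.volumetric.items() if k != "total_ml"):
            raise InvariantError("total volume must dominate each component")

    @property
    def names(self) -> tuple[str, ...]:
        return VOLUMETRIC_FEATURE_NAMES + self.network.names

    def to_vector(self, mode: str = "fused") -> np.ndarray:
        return fuse_features(self.volumetric, self.network, mode=mode)


def fuse_features(vol: dict[str, float] | None, net: NetworkFeatureVector | None,
                  mode: str = "fused") -> np.ndarray:
    """Fixed-order feature vector: 4 volumetric then 26 network values.

    ``mode``: "fused" (30), "volumetric" (4, model-1), "network"
    (26, model-2).
    """
    if mode == "volumetric":
        if vol is None:
            raise InvariantError("volumetric mode needs volume features")
        return np.array([vol[k] for k in VOLUMETRIC_FEATURE_NAMES], dtype=float)
    if mode == "network":
        if net is None:
            raise InvariantError("network mode needs network features")
        return net.to_array()
    if mode == "fused":
        if vol is None or net is None:
            raise InvariantError("fused mode needs both feature groups")
        return np.concatenate([
            [vol[k] for k in VOLUMETRIC_FEATURE_NAMES], net.to_array()
        ])
    raise InvariantError(f"unknown feature mode {mode!r}")


@dataclass
class PredictionReport:
    """Train/test precision and recall, mean ± sd on the percent scale."""

    precision_train: tuple[float, float]
    precision_test: tuple[float, float]
    recall_train: tuple[float, float]
    recall_test: tuple[float, float]
    folds: int = 5
    iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("precision_train", "precision_test", "recall_train", "recall_test"):
            mean, sd = getattr(self, name)
            if not (0 <= mean <= 100 and 0 <= sd <= 100):
                raise InvariantError(f"{name} must be on the [0, 100] percent scale")

    def as_dict(self) -> dict:
        return {
            "precision_train_mean": self.precision_train[0],
            "precision_train_sd": self.precision_train[1],
            "precision_test_mean": self.precision_test[0],
            "precision_test_sd": self.precision_test[1],
            "recall_train_mean": self.recall_train[0],
            "recall_train_sd": self.recall_train[1],
            "recall_test_mean": self.recall_test[0],
            "recall_test_sd": self.recall_test[1],
            "folds": self.folds,
            "iterations": self.iterations,
            "seed": self.seed,
        }


class NPHPredictor(BaseEstimator, ClassifierMixin):
    """Linear SVM (L2 penalty) on standardised fused features.

    A thin sklearn estimator: StandardScaler + LinearSVC with
    configurable regularisation strength C (default 1.0).
    """

    def __init__(self, C: float = 1.0, max_iter: int = 10000):
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y):
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            LinearSVC(C=self.C, penalty="l2", max_iter=self.max_iter),
        )
        self.pipeline_.fit(np.asarray(X, dtype=float), np.asarray(y))
        self.classes_ = self.pipeline_.named_steps["linearsvc"].classes_
        return self

    def predict(self, X):
        return self.pipeline_.predict(np.asarray(X, dtype=float))


def cross_validated_svm(features: np.ndarray, labels: np.ndarray, folds: int = 5,
                        iterations: int = 100, seed: int = 0, C: float = 1.0,
                        positive=1) -> PredictionReport:
    """Repeated reshuffled stratified k-fold linear-SVM evaluation.

    Each iteration draws a fresh stratified split; train and test
    precision/recall (positive class = NPH) are pooled over all
    iterations x folds and reported as mean ± sd in percent.
    Deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvariantError("features must be (n_subjects, n_features) matching labels")
    for cls in np.unique(y):
        if (y == cls).sum() < folds:
            raise InvariantError(
                f"class {cls!r} has fewer than {folds} subjects; stratified "
                f"{folds}-fold CV is impossible"
            )
    yb = (y == positive).astype(int)
    if len(np.unique(yb)) < 2:
        raise InvariantError(
            f"positive label {positive!r} must be present alongside a negative class"
        )
    base = NPHPredictor(C=C)
    fold_seeds = np.random.SeedSequence(seed).generate_state(iterations) % (2**31)
    acc = {k: [] for k in ("p_tr", "p_te", "r_tr", "r_te")}
    for it in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(fold_seeds[it]))
        for tr, te in skf.split(X, yb):
            est = clone(base).fit(X[tr], yb[tr])
            pred_tr, pred_te = est.predict(X[tr]), est.predict(X[te])
            acc["p_tr"].append(precision_score(yb[tr], pred_tr, zero_division=0))
            acc["p_te"].append(precision_score(yb[te], pred_te, zero_division=0))
            acc["r_tr"].append(recall_score(yb[tr], pred_tr, zero_division=0))
            acc["r_te"].append(recall_score(yb[te], pred_te, zero_division=0))

    def stat(key):
        arr = np.asarray(acc[key]) * 100.0
        return float(arr.mean()), float(arr.std())

    return PredictionReport(
        precision_train=stat("p_tr"), precision_test=stat("p_te"),
        recall_train=stat("r_tr"), recall_test=stat("r_te"),
        folds=folds, iterations=iterations, seed=seed,
    )


def pca_2d(net_features: np.ndarray) -> np.ndarray:
    """Standardised 2-component PCA embedding of the network features."""
    X = np.asarray(net_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise InvariantError("PCA needs at least 3 subjects")
    Xs = StandardScaler().fit_transform(X)
    return PCA(n_components=2).fit_transform(Xs)
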