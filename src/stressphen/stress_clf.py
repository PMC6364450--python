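"""Stress severity classification from trait indicators.

Separate models are trained per stress factor (water, nitrogen, weeds) on
55-dimensional feature vectors: the 54 standardized indicator-statistic
values (canopy cover mean, volumetric estimate mean, height mean and
variance, 25 band means and variances) with days-after-sowing appended
unscaled.  Training uses stratified five-fold cross-validation on the
training rows; all dates of a randomly held-out 20% of boxes form an
independent test set.  Ordinal misclassification costs make adjacent
severity errors cheaper than two-level errors:

    cost = (1/N) * sum_ij CM_ij * w_ij

with the default 3x3 weight matrix [[0,1,2],[1,0,1],[2,1,0]] for the
nitrogen and weed factors (rows = actual, cols = predicted) and a uniform
0/1 matrix for the binary water factor.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .synthscene import (NITROGEN_LEVELS, WEED_LEVELS, TreatmentSpec)
from .traits import FEATURE_COLUMNS

WATER_CLASSES = ("Sufficient", "Drying")
NITROGEN_CLASSES = NITROGEN_LEVELS          # Low, Medium, High
WEED_CLASSES = WEED_LEVELS                  # None, Medium, High
STRESS_FACTORS = ("water", "nitrogen", "weeds")
CLASS_ORDERS = {"water": WATER_CLASSES, "nitrogen": NITROGEN_CLASSES,
                "weeds": WEED_CLASSES}

WATER_LABEL_BOUNDARY_DAS = 28  #: drought labels start after this day

#: ordinal cost weights for the 3-level factors (Low/None, Medium, High)
DEFAULT_COST_MATRIX = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
UNIFORM_BINARY_COST = np.array([[0, 1], [1, 0]], dtype=float)


@dataclasses.dataclass(frozen=True)
class StressLabels:
    """Per-date severity class for each of the three stress factors."""

    water: str
    nitrogen: str
    weeds: str

    def __post_init__(self) -> None:
        if self.water not in WATER_CLASSES:
            raise ValueError(f"unknown water class {self.water!r}")
        if self.nitrogen not in NITROGEN_CLASSES:
            raise ValueError(f"unknown nitrogen class {self.nitrogen!r}")
        if self.weeds not in WEED_CLASSES:
            raise ValueError(f"unknown weed class {self.weeds!r}")


def assign_labels(treatment: TreatmentSpec, das: int) -> StressLabels:
    """Target classes of a box at a given day after sowing.

    Nitrogen and weed labels follow the treatment; the water label is
    Sufficient for every box up to (and including) DAS 28 and Drying for
    water-limited boxes afterwards.
    """
    if treatment.water == "Limited" and das > WATER_LABEL_BOUNDARY_DAS:
        water = "Drying"
    else:
        water = "Sufficient"
    return StressLabels(water=water, nitrogen=treatment.nitrogen, weeds=treatment.weeds)


def cost_matrix_for(factor: str) -> np.ndarray:
    return UNIFORM_BINARY_COST if factor == "water" else DEFAULT_COST_MATRIX


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

FEATURE_DIM = len(FEATURE_COLUMNS) + 1  #: 54 scaled traits + DAS


class FeatureAssembler:
    """Standardize the 54 trait columns and append DAS unscaled.

    The scaler (per-column mean/std) and the imputation means are fitted
    on training rows only; absent values are imputed with the training
    mean, i.e. become 0 after scaling.  Component order is the fixed
    ``FEATURE_COLUMNS`` order with DAS last.
    """

    def __init__(self, columns: Sequence[str] = FEATURE_COLUMNS):
        self.columns = list(columns)
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, traits: pd.DataFrame) -> "FeatureAssembler":
        X = self._raw(traits)
        self.mean_ = np.nanmean(X, axis=0)
        self.mean_ = np.where(np.isnan(self.mean_), 0.0, self.mean_)
        self.std_ = np.nanstd(X, axis=0)
        self.std_ = np.where(self.std_ > 0, self.std_, 1.0)
        return self

    def transform(self, traits: pd.DataFrame) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("assembler not fitted")
        X = self._raw(traits)
        X = np.where(np.isnan(X), self.mean_, X)
        Xs = (X - self.mean_) / self.std_
        das = traits["das"].to_numpy(dtype=float)[:, None]
        return np.hstack([Xs, das])

    def _raw(self, traits: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns + ["das"] if c not in traits.columns]
        if missing:
            raise ValueError(f"trait table is missing required columns {missing}")
        return traits[self.columns].to_numpy(dtype=float)


def assemble_features(traits: pd.DataFrame, assembler: FeatureAssembler) -> np.ndarray:
    """(N, 55) feature matrix via a fitted assembler."""
    return assembler.transform(traits)


# ---------------------------------------------------------------------------
# Splitting and cross-validation
# ---------------------------------------------------------------------------


def split_boxes(box_ids: Sequence[str], fraction: float = 0.2,
                seed: int = 0) -> tuple[list[str], list[str]]:
    """Hold out round(fraction * n) whole boxes as the test set."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    boxes = sorted(set(map(str, box_ids)))
    if len(boxes) < 2:
        raise ValueError("need at least 2 boxes to split")
    n_test = int(round(fraction * len(boxes)))
    n_test = min(max(n_test, 1), len(boxes) - 1)
    rng = np.random.default_rng(seed)
    test = sorted(rng.choice(boxes, size=n_test, replace=False).tolist())
    train = [b for b in boxes if b not in test]
    return train, test


def default_model_factory():
    """Reference classifier: support-vector machine with quadratic kernel.

    Kernel and distance-based backends re-standardize their inputs
    internally (as the original statistics-toolbox presets do): the
    appended raw DAS component would otherwise dominate the kernel.
    """
    return make_pipeline(StandardScaler(),
                         SVC(kernel="poly", degree=2, coef0=1.0, C=1.0, gamma="scale"))


MODEL_FACTORIES: dict[str, Callable[[], object]] = {
    "svm_quadratic": default_model_factory,
    "decision_tree": lambda: DecisionTreeClassifier(random_state=0),
    "lda": lambda: LinearDiscriminantAnalysis(),
    "knn": lambda: make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5)),
    "bagged_trees": lambda: RandomForestClassifier(n_estimators=50, random_state=0),
    "subspace_discriminant": lambda: BaggingClassifier(
        LinearDiscriminantAnalysis(), n_estimators=30, max_features=0.5, random_state=0),
    "subspace_knn": lambda: make_pipeline(StandardScaler(), BaggingClassifier(
        KNeighborsClassifier(n_neighbors=5), n_estimators=30, max_features=0.5,
        random_state=0)),
    "boosted_trees": lambda: AdaBoostClassifier(
        DecisionTreeClassifier(max_depth=3), n_estimators=50, random_state=0),
}


def kfold_cv(features: np.ndarray, labels: np.ndarray, k: int = 5,
             model_factory: Callable[[], object] = default_model_factory,
             seed: int = 0, prescaled: bool = False,
             trait_frame: pd.DataFrame | None = None,
             columns: Sequence[str] = FEATURE_COLUMNS) -> dict:
    """Stratified k-fold cross-validation accuracy for one stress factor.

    Folds partition the observations (box-dates); ties in stratification
    are broken by a seeded shuffle.  When a trait frame is supplied the
    feature assembler is re-fitted on each fold's training part so that
    standardization never sees validation rows.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("a class is absent from the training data")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X_index = np.arange(len(labels))
    fold_acc = []
    fold_assign = np.empty(len(labels), dtype=int)
    for fold, (tr, va) in enumerate(skf.split(X_index, labels)):
        fold_assign[va] = fold
        if trait_frame is not None:
            asm = FeatureAssembler(columns).fit(trait_frame.iloc[tr])
            Xtr = asm.transform(trait_frame.iloc[tr])
            Xva = asm.transform(trait_frame.iloc[va])
        else:
            Xtr, Xva = features[tr], features[va]
        model = model_factory()
        model.fit(Xtr, labels[tr])
        fold_acc.append(float(np.mean(model.predict(Xva) == labels[va])))
    return {"fold_accuracies": fold_acc, "mean_accuracy": float(np.mean(fold_acc)),
            "fold_assignments": fold_assign}


def misclassification_cost(CM: np.ndarray, W: np.ndarray,
                           N: int | None = None) -> float:
    """Mean misclassification cost (1/N) sum_ij CM_ij w_ij."""
    CM = np.asarray(CM, dtype=float)
    W = np.asarray(W, dtype=float)
    if CM.shape != W.shape:
        raise ValueError("confusion and weight matrices must have the same shape")
    if N is None:
        N = int(CM.sum())
    if N == 0:
        raise ValueError("N must be > 0")
    return float((CM * W).sum() / N)


@dataclasses.dataclass
class EvalReport:
    """Test-set evaluation of one trained stress-factor model."""

    classes: tuple[str, ...]
    confusion: np.ndarray      #: rows = actual, cols = predicted
    accuracy: float
    cost: float

    @property
    def n(self) -> int:
        return int(self.confusion.sum())


def confusion_matrix(actual: np.ndarray, predicted: np.ndarray,
                     classes: Sequence[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    CM = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        CM[idx[str(a)], idx[str(p)]] += 1
    return CM


def evaluate(model, features: np.ndarray, labels: np.ndarray,
             classes: Sequence[str], W: np.ndarray | None = None) -> EvalReport:
    """Confusion matrix, accuracy and mean misclassification cost."""
    pred = model.predict(features)
    CM = confusion_matrix(np.asarray(labels), pred, classes)
    N = CM.sum()
    acc = float(np.trace(CM) / N) if N else float("nan")
    if W is None:
        W = np.ones((len(classes), len(classes))) - np.eye(len(classes))
    return EvalReport(classes=tuple(classes), confusion=CM, accuracy=acc,
                      cost=misclassification_cost(CM, W))


# ---------------------------------------------------------------------------
# End-to-end protocol
# ---------------------------------------------------------------------------

#: feature subsets of the modality ablation (DAS only in the +Time subset)
MODALITY_SUBSETS: dict[str, tuple[tuple[str, ...], bool]] = {
    "rgb": (("CanCov_mean",), False),
    "rgb_3d": (("CanCov_mean", "Height_mean", "Height_var", "VolEst_mean"), False),
    "hs": (tuple(c for c in FEATURE_COLUMNS if c.startswith("HS")), False),
    "rgb_3d_hs": (tuple(FEATURE_COLUMNS), False),
    "rgb_3d_hs_time": (tuple(FEATURE_COLUMNS), True),
}


def _merge_traits_labels(traits: pd.DataFrame, labels: pd.DataFrame,
                         drop_first_date: bool = True) -> pd.DataFrame:
    labels = labels.copy()
    # CSV round-trip: pandas parses the weed class "None" as NaN
    if "weeds" in labels.columns:
        labels["weeds"] = labels["weeds"].fillna("None")
    df = traits.merge(labels, on=["box_id", "das"], how="inner")
    if drop_first_date and len(df):
        df = df[df["das"] > df["das"].min()].reset_index(drop=True)
    return df


def run_classification(traits: pd.DataFrame, labels: pd.DataFrame, k: int = 5,
                       test_fraction: float = 0.2, seed: int = 0,
                       method: str = "svm_quadratic",
                       drop_first_date: bool = True) -> dict:
    """Full protocol: box-held-out split, per-factor CV and test evaluation.

    ``traits`` must carry box_id, das and the 54 trait columns; ``labels``
    box_id, das, water, nitrogen, weeds.  The first measurement date (day
    of sowing, no germinated plants) is dropped.  Returns a JSON-ready
    report with per-factor fold/mean CV accuracies, test accuracy,
    confusion matrix and mean misclassification cost.
    """
    if method not in MODEL_FACTORIES:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(MODEL_FACTORIES)}")
    factory = MODEL_FACTORIES[method]
    df = _merge_traits_labels(traits, labels, drop_first_date)
    train_boxes, test_boxes = split_boxes(df["box_id"], test_fraction, seed)
    dtrain = df[df["box_id"].isin(train_boxes)].reset_index(drop=True)
    dtest = df[df["box_id"].isin(test_boxes)].reset_index(drop=True)
    report: dict = {"method": method, "k": k, "seed": seed,
                    "train_boxes": train_boxes, "test_boxes": test_boxes,
                    "n_train": len(dtrain), "n_test": len(dtest), "factors": {}}
    for factor in STRESS_FACTORS:
        y_tr = dtrain[factor].to_numpy()
        cv = kfold_cv(None, y_tr, k=k, model_factory=factory, seed=seed,
                      trait_frame=dtrain)
        asm = FeatureAssembler().fit(dtrain)
        model = factory()
        model.fit(asm.transform(dtrain), y_tr)
        classes = CLASS_ORDERS[factor]
        present = tuple(c for c in classes if c in set(df[factor]))
        W_full = cost_matrix_for(factor)
        keep = [classes.index(c) for c in present]
        W = W_full[np.ix_(keep, keep)]
        rep = evaluate(model, asm.transform(dtest), dtest[factor].to_numpy(),
                       present, W)
        report["factors"][factor] = {
            "cv_fold_accuracies": cv["fold_accuracies"],
            "cv_mean_accuracy": cv["mean_accuracy"],
            "test_accuracy": rep.accuracy,
            "test_cost": rep.cost,
            "classes": list(present),
            "confusion_matrix": rep.confusion.tolist(),
        }
    return report


def modality_ablation(traits: pd.DataFrame, labels: pd.DataFrame, k: int = 5,
                      seed: int = 0, method: str = "svm_quadratic",
                      subsets: dict | None = None,
                      drop_first_date: bool = True) -> dict:
    """Cross-validation accuracy per feature-modality subset per factor.

    Subsets: RGB only (canopy cover), RGB+3D (+height, volume), HS only
    (25 band means and variances), all modalities, and all modalities
    plus time (DAS).
    """
    subsets = MODALITY_SUBSETS if subsets is None else subsets
    if any(len(cols) == 0 for cols, _ in subsets.values()):
        raise ValueError("empty feature subset")
    factory = MODEL_FACTORIES[method]
    df = _merge_traits_labels(traits, labels, drop_first_date)
    train_boxes, _ = split_boxes(df["box_id"], 0.2, seed)
    dtrain = df[df["box_id"].isin(train_boxes)].reset_index(drop=True)
    out: dict = {}
    for name, (cols, with_das) in subsets.items():
        out[name] = {}
        for factor in STRESS_FACTORS:
            y = dtrain[factor].to_numpy()
            if with_das:
                cv = kfold_cv(None, y, k=k, model_factory=factory, seed=seed,
                              trait_frame=dtrain, columns=cols)
                acc = cv["mean_accuracy"]
            else:
                acc = _cv_without_das(dtrain, y, cols, k, factory, seed)
            out[name][factor] = acc
    return out


def _cv_without_das(dtrain: pd.DataFrame, y: np.ndarray, cols, k, factory, seed) -> float:
    """CV on a subset with the DAS column removed from the vectors."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(np.arange(len(y)), y):
        asm = FeatureAssembler(cols).fit(dtrain.iloc[tr])
        Xtr = asm.transform(dtrain.iloc[tr])[:, :-1]
        Xva = asm.transform(dtrain.iloc[va])[:, :-1]
        model = factory()
        model.fit(Xtr, y[tr])
        accs.append(float(np.mean(model.predict(Xva) == y[va])))
    return float(np.mean(accs))


def majority_class_rate(labels: np.ndarray) -> float:
    """Accuracy of the best constant predictor (the chance level here)."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    return float(counts.max() / counts.sum())
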