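"""Deep-feature classification pipeline.

Backbone-agnostic feature extraction (with a deterministic, seeded stub
backbone so the whole pipeline runs offline without pretrained weights),
five univariate/multivariate feature-selection scorers (ANOVA F,
Kruskal-Wallis H, chi-squared, ReliefF, mRMR), three classical classifiers
(SVM, decision tree, k-NN) and ROC-based evaluation.

Feature selection is always computed on training data only inside
:func:`train_eval` — scores are never derived from held-out samples.
Ties everywhere break by lowest feature index, so every result is
reproducible from (data, seed) alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.feature_selection import chi2 as _sk_chi2, f_classif as _sk_f_classif
from sklearn.metrics import mutual_info_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.model_selection import train_test_split

from .errors import ConfigError, DegenerateInputError, InsufficientDataError
from .image_io import normalize_intensity, resize_image

__all__ = [
    "FeatureMatrix",
    "BackboneSpec",
    "FeatureScores",
    "EvalReport",
    "extract_deep_features",
    "anova_f_scores",
    "kruskal_wallis_scores",
    "chi2_scores",
    "relieff_scores",
    "mrmr_select",
    "roc_auc",
    "confusion_metrics",
    "train_eval",
]

#: sentinel score for an infinite F statistic (zero within-group variance,
#: unequal means); large, finite, and documented rather than inf
F_SENTINEL = 1e12


@dataclass
class FeatureMatrix:
    """Samples-by-features table with binary class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list = None
    sample_ids: list = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be 2D with one label per row")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains missing/non-finite entries")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if self.sample_ids is None:
            self.sample_ids = list(range(self.X.shape[0]))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def classes(self) -> np.ndarray:
        return np.unique(self.y)


def _require_two_classes(fm: FeatureMatrix, min_per_class: int = 2) -> None:
    classes, counts = np.unique(fm.y, return_counts=True)
    if classes.size != 2:
        raise InsufficientDataError(f"need exactly 2 classes, got {classes.size}")
    if counts.min() < min_per_class:
        raise InsufficientDataError(f"need >= {min_per_class} samples per class")


@dataclass
class BackboneSpec:
    """Identifies a feature-extraction backbone and its tap point.

    The package ships ``name='stub'`` — a seeded random projection followed
    by tanh — which honours the same contract as a pretrained CNN tap
    (fixed-length deterministic features per image).  Real backbones can be
    registered as plug-ins.
    """

    name: str = "stub"
    layer: str = "fc"
    input_size: tuple = (64, 64)
    preprocessing: str = "minmax"
    n_features: int = 128


@dataclass
class FeatureScores:
    method: str
    scores: np.ndarray
    ranking: np.ndarray
    selected_order: np.ndarray = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranking = np.asarray(self.ranking, dtype=int)
        if sorted(self.ranking.tolist()) != list(range(self.scores.size)):
            raise ValueError("ranking must be a permutation of feature indices")

    def top(self, k: int) -> np.ndarray:
        if self.selected_order is not None:
            return self.selected_order[:k]
        return self.ranking[:k]


def _rank_desc(scores: np.ndarray) -> np.ndarray:
    """Indices by descending score; ties broken by lowest feature index."""
    return np.lexsort((np.arange(scores.size), -scores))


# ---------------------------------------------------------------------------
# feature extraction


_BACKBONES = {}


def register_backbone(name: str, factory) -> None:
    """Register a backbone plug-in: factory(spec) -> callable(batch) -> features."""
    _BACKBONES[name] = factory


def _stub_backbone(spec: BackboneSpec):
    h, w = spec.input_size
    seed = zlib.crc32(f"{spec.name}/{spec.layer}".encode()) % (2**31)
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((h * w, spec.n_features)) / np.sqrt(h * w)
    bias = rng.standard_normal(spec.n_features) * 0.1

    def forward(batch: np.ndarray) -> np.ndarray:
        return np.tanh(batch.reshape(batch.shape[0], -1) @ W + bias)

    return forward


register_backbone("stub", _stub_backbone)


def preprocess_image(image: np.ndarray, spec: BackboneSpec) -> np.ndarray:
    """Resize to the backbone's input size and apply its normalization recipe."""
    img = resize_image(np.asarray(image, dtype=float), spec.input_size, "bilinear")
    if spec.preprocessing == "minmax":
        return normalize_intensity(img, "minmax")
    if spec.preprocessing == "zscore":
        return normalize_intensity(img, "zscore")
    if spec.preprocessing == "none":
        return img
    raise ConfigError(f"unknown preprocessing recipe {spec.preprocessing!r}")


def extract_deep_features(images, backbone: BackboneSpec,
                          preprocess: bool = True) -> FeatureMatrix:
    """One fixed-length feature vector per 2D image; deterministic per backbone.

    Labels are filled with zeros — callers attach real labels afterwards.
    """
    if backbone.name not in _BACKBONES:
        raise ConfigError(f"unknown backbone {backbone.name!r}")
    forward = _BACKBONES[backbone.name](backbone)
    batch = []
    for img in images:
        img = np.asarray(img, dtype=float)
        if preprocess:
            img = preprocess_image(img, backbone)
        elif img.shape != tuple(backbone.input_size):
            raise ConfigError(
                f"image shape {img.shape} != backbone input {tuple(backbone.input_size)}"
            )
        batch.append(img)
    X = forward(np.stack(batch))
    return FeatureMatrix(X=X, y=np.zeros(X.shape[0], dtype=int))


# ---------------------------------------------------------------------------
# feature-selection scorers


def anova_f_scores(fm: FeatureMatrix) -> FeatureScores:
    """One-way ANOVA F statistic per feature (between / within mean square)."""
    _require_two_classes(fm)
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = _sk_f_classif(fm.X, fm.y)
    # zero within-group variance with unequal means -> inf; map to sentinel
    f = np.where(np.isinf(f), F_SENTINEL, f)
    f = np.nan_to_num(f, nan=0.0)  # constant feature: no variance at all -> 0
    return FeatureScores(method="anova_f", scores=f, ranking=_rank_desc(f))


def kruskal_wallis_scores(fm: FeatureMatrix) -> FeatureScores:
    """Kruskal-Wallis H statistic per feature (rank-based, tie-corrected)."""
    _require_two_classes(fm)
    classes = fm.classes()
    groups = [fm.y == c for c in classes]
    scores = np.zeros(fm.n_features)
    for j in range(fm.n_features):
        col = fm.X[:, j]
        if np.unique(col).size == 1:
            scores[j] = 0.0
            continue
        try:
            h, _ = stats.kruskal(*[col[g] for g in groups])
        except ValueError:  # all values identical within scipy's check
            h = 0.0
        scores[j] = h
    return FeatureScores(method="kruskal_wallis", scores=scores,
                         ranking=_rank_desc(scores))


def chi2_scores(fm: FeatureMatrix) -> FeatureScores:
    """Chi-squared statistic on per-class feature sums (frequency-like features).

    Observed counts are the per-class sums of the feature; expected counts
    split the total in proportion to class size.  Features must be
    non-negative — shift or min-max scale them first if they are not.
    """
    _require_two_classes(fm, min_per_class=1)
    if (fm.X < 0).any():
        raise ValueError(
            "chi-squared scores require non-negative features; "
            "shift or min-max scale the matrix first"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        scores, _ = _sk_chi2(fm.X, fm.y)
    scores = np.nan_to_num(scores, nan=0.0)
    return FeatureScores(method="chi2", scores=scores, ranking=_rank_desc(scores))


def _range_normalize(X: np.ndarray) -> np.ndarray:
    rng_ = X.max(axis=0) - X.min(axis=0)
    rng_[rng_ == 0] = 1.0
    return (X - X.min(axis=0)) / rng_


def relieff_scores(fm: FeatureMatrix, k_neighbors: int = 10,
                   n_iterations: int = None, seed: int = 0) -> FeatureScores:
    """ReliefF feature weights.

    For each visited instance, find its ``k_neighbors`` nearest same-class
    (hits) and other-class (misses) neighbours by Manhattan distance on
    range-normalized features; weights are decremented by hit differences
    and incremented by miss differences, normalized by iterations and k.
    With ``n_iterations`` >= n_samples (or None) every instance is visited
    exactly once (exhaustive, deterministic); otherwise a seeded sample of
    instances is used.
    """
    _require_two_classes(fm)
    X = _range_normalize(fm.X)
    y = fm.y
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_neighbors + 1:
        raise ValueError(
            f"every class needs > k_neighbors={k_neighbors} samples for ReliefF"
        )
    if n_iterations is None or n_iterations >= n:
        visit = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        visit = rng.choice(n, size=n_iterations, replace=False)
    # pairwise Manhattan distances, chunked by visited instance
    w = np.zeros(p)
    for i in visit:
        d = np.abs(X - X[i]).sum(axis=1)
        d[i] = np.inf
        same = y == y[i]
        for is_hit in (True, False):
            sel = same if is_hit else ~same
            cand = np.where(sel)[0]
            # stable ordering: by (distance, index)
            order = cand[np.lexsort((cand, d[cand]))][:k_neighbors]
            diffs = np.abs(X[order] - X[i]).sum(axis=0)
            w += -diffs if is_hit else diffs
    w /= visit.size * k_neighbors
    return FeatureScores(method="relieff", scores=w, ranking=_rank_desc(w))


def _discretize(col: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros(col.size, dtype=int)
    bins = np.clip(((col - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    return bins


def _binned_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two discrete label vectors."""
    return float(mutual_info_score(a, b))


def mrmr_select(fm: FeatureMatrix, n_select: int, n_bins: int = 10) -> FeatureScores:
    """Greedy minimum-redundancy-maximum-relevance selection (MID criterion).

    Features are discretized into ``n_bins`` equal-width bins; relevance is
    the mutual information with the class label, redundancy the mean MI with
    already-selected features.  Each step picks
    ``argmax [I(f; y) - mean_s I(f; s)]``, ties to the lowest index.  A
    feature occupying a single bin has MI defined as 0.
    """
    _require_two_classes(fm, min_per_class=1)
    if n_select > fm.n_features:
        raise ValueError("n_select exceeds the number of features")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    disc = np.column_stack([_discretize(fm.X[:, j], n_bins) for j in range(fm.n_features)])
    relevance = np.array([_binned_mi(disc[:, j], fm.y) for j in range(fm.n_features)])
    selected = []
    remaining = list(range(fm.n_features))
    redundancy_sum = np.zeros(fm.n_features)
    while len(selected) < n_select:
        if selected:
            crit = relevance - redundancy_sum / len(selected)
        else:
            crit = relevance.copy()
        best = min(remaining, key=lambda j: (-crit[j], j))
        selected.append(best)
        remaining.remove(best)
        if remaining:
            for j in remaining:
                redundancy_sum[j] += _binned_mi(disc[:, j], disc[:, best])
    selected = np.array(selected, dtype=int)
    ranking = np.concatenate([selected, np.array(sorted(remaining), dtype=int)])
    return FeatureScores(method="mrmr", scores=relevance, ranking=ranking,
                         selected_order=selected)


# ---------------------------------------------------------------------------
# classification and evaluation


@dataclass
class EvalReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    roc_points: list
    confusion: dict
    split_seed: int
    selected_features: list = field(default_factory=list)
    undefined_metrics: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "f1": self.f1,
            "confusion": self.confusion, "split_seed": self.split_seed,
            "selected_features": [int(i) for i in self.selected_features],
            "undefined_metrics": self.undefined_metrics,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }


def roc_auc(scores, labels):
    """AUC by the Mann-Whitney pair-counting definition plus the ROC polyline.

    Ties between a positive and a negative score count one half.  The
    trapezoidal area under the returned ``roc_points`` equals the pair-count
    value exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("AUC undefined: one class absent")
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    auc = (ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    fpr, tpr, _ = roc_curve(labels, scores)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return float(auc), points


def confusion_metrics(confusion: dict) -> dict:
    """Accuracy, sensitivity, specificity, precision and F1 from TP/FP/FN/TN.

    Zero-denominator metrics are NaN and listed under ``undefined`` — never
    silently reported as 0.
    """
    tp, fp, fn, tn = (confusion[k] for k in ("TP", "FP", "FN", "TN"))
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    out = {
        "accuracy": (tp + tn) / total,
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "precision": ratio(tp, tp + fp, "precision"),
    }
    out["f1"] = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    out["undefined"] = undefined
    return out


_CLASSIFIERS = {
    "svm": lambda seed: SVC(kernel="rbf", C=1.0, random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(criterion="gini", random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(n_neighbors=5, metric="euclidean"),
}

_SELECTORS = {
    "anova_f": lambda fm, seed: anova_f_scores(fm),
    "kruskal_wallis": lambda fm, seed: kruskal_wallis_scores(fm),
    "chi2": lambda fm, seed: chi2_scores(
        FeatureMatrix(X=_range_normalize(fm.X), y=fm.y)),
    "relieff": lambda fm, seed: relieff_scores(fm, seed=seed),
    "mrmr": lambda fm, seed: mrmr_select(fm, n_select=fm.n_features),
}


def _decision_scores(clf, X):
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X)
    return clf.predict_proba(X)[:, 1]


def train_eval(fm: FeatureMatrix, classifier: str = "svm", selection: str = "none",
               k_features: int = None, test_fraction: float = 0.3,
               seed: int = 0) -> EvalReport:
    """Stratified holdout training and evaluation, fully seeded.

    ``selection`` names a scorer ('none' to keep all features); the scorer
    runs on the training split only, and the top ``k_features`` features by
    its ranking are kept.  The chi-squared scorer sees features min-max
    scaled on the training split (it requires non-negative input).
    """
    if classifier not in _CLASSIFIERS:
        raise ConfigError(f"unknown classifier {classifier!r}")
    if selection != "none" and selection not in _SELECTORS:
        raise ConfigError(f"unknown selection method {selection!r}")
    _require_two_classes(fm)
    X_tr, X_te, y_tr, y_te = train_test_split(
        fm.X, fm.y, test_size=test_fraction, random_state=seed, stratify=fm.y
    )
    if np.unique(y_tr).size < 2:
        raise InsufficientDataError("training split contains a single class")
    if selection == "none":
        keep = np.arange(fm.n_features)
    else:
        if k_features is None:
            raise ConfigError("k_features is required when selection != 'none'")
        if k_features > fm.n_features:
            raise ValueError("k_features exceeds the number of features")
        scores = _SELECTORS[selection](FeatureMatrix(X=X_tr, y=y_tr), seed)
        keep = scores.top(k_features)
    clf = _CLASSIFIERS[classifier](seed)
    clf.fit(X_tr[:, keep], y_tr)
    dscores = _decision_scores(clf, X_te[:, keep])
    auc, points = roc_auc(dscores, y_te)
    y_pred = clf.predict(X_te[:, keep])
    conf = {
        "TP": int(((y_pred == 1) & (y_te == 1)).sum()),
        "FP": int(((y_pred == 1) & (y_te == 0)).sum()),
        "FN": int(((y_pred == 0) & (y_te == 1)).sum()),
        "TN": int(((y_pred == 0) & (y_te == 0)).sum()),
    }
    m = confusion_metrics(conf)
    return EvalReport(
        auc=auc, accuracy=m["accuracy"], sensitivity=m["sensitivity"],
        specificity=m["specificity"], precision=m["precision"], f1=m["f1"],
        roc_points=points, confusion=conf, split_seed=seed,
        selected_features=list(map(int, keep)), undefined_metrics=m["undefined"],
    )
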