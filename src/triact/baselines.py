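"""Feature extraction and conventional comparison classifiers.

Each 128 x 3 window is summarized by 12 features: per-axis mean (3),
per-axis standard deviation (3), pairwise axis correlations (3),
magnitude mean (1), magnitude standard deviation (1), and the dominant
frequency of the mean-removed magnitude signal (1).

Three classifiers are provided with fixed hyperparameters:

* SVM — Gaussian kernel ``exp(-||u - v||^2 / s^2)`` with kernel scale
  s = 3 on z-scored features, one-vs-one multiclass;
* decision tree — Gini impurity, at most 5,000 splits;
* k-NN — Euclidean distance-weighted voting with 10 neighbors.

Features are standardized (z-scored) on the training folds only.  The
fold splits are the same block-wise splits used for the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from triact.evaluation import ConfusionMatrix
from triact.signal_io import DEFAULT_SAMPLE_RATE_HZ, Window

FEATURE_NAMES: tuple[str, ...] = (
    "mean_x", "mean_y", "mean_z",
    "std_x", "std_y", "std_z",
    "corr_xy", "corr_xz", "corr_yz",
    "mag_mean", "mag_std", "mag_dominant_freq_hz",
)

BASELINE_KINDS = ("svm", "dt", "knn")

SVM_KERNEL_SCALE = 3.0
DT_MAX_SPLITS = 5000
KNN_NEIGHBORS = 10


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the 0-by-convention rule for constant
    signals (0/0)."""
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def extract_features(
    window: Window | np.ndarray,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> np.ndarray:
    """The 12-feature vector of one window, in :data:`FEATURE_NAMES`
    order.  Deterministic."""
    values = window.values if isinstance(window, Window) else np.asarray(window)
    x, y, z = values[:, 0], values[:, 1], values[:, 2]
    mag = np.linalg.norm(values, axis=1)
    centered = mag - mag.mean()
    spectrum = np.abs(np.fft.rfft(centered))
    freqs = np.fft.rfftfreq(len(mag), d=1.0 / sample_rate_hz)
    if spectrum[1:].max() > 0:
        dom = float(freqs[1:][np.argmax(spectrum[1:])])
    else:
        dom = 0.0
    return np.array(
        [
            x.mean(), y.mean(), z.mean(),
            x.std(), y.std(), z.std(),
            _safe_corr(x, y), _safe_corr(x, z), _safe_corr(y, z),
            mag.mean(), mag.std(), dom,
        ]
    )


def extract_feature_table(
    windows: list[Window], sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
) -> np.ndarray:
    """(N, 12) feature matrix for a window list, in list order."""
    return np.array([extract_features(w, sample_rate_hz) for w in windows])


def _make_model(kind: str, rng_seed: int = 0) -> Pipeline:
    if kind == "svm":
        clf = SVC(kernel="rbf", gamma=1.0 / SVM_KERNEL_SCALE**2)
    elif kind == "dt":
        # S binary splits <=> S + 1 leaves
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=DT_MAX_SPLITS + 1,
            random_state=rng_seed,
        )
    elif kind == "knn":
        clf = KNeighborsClassifier(
            n_neighbors=KNN_NEIGHBORS, weights="distance", metric="euclidean"
        )
    else:
        raise ValueError(f"unknown baseline kind {kind!r}; use one of "
                         f"{BASELINE_KINDS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class BaselineResult:
    kind: str
    model: Pipeline
    fold_matrices: list[ConfusionMatrix]


def train_baseline(
    kind: str,
    features: np.ndarray,
    labels: np.ndarray | list[str],
    folds: list[tuple[np.ndarray, np.ndarray]],
    class_labels: tuple[str, ...],
    rng_seed: int = 0,
) -> BaselineResult:
    """Fit one conventional classifier under the shared fold splits.

    ``folds`` holds per-fold (train_indices, val_indices) into the
    feature rows — the same splits used for the network.  Returns a model
    fitted on all data plus one validation confusion matrix per fold.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    label_index = {lab: i for i, lab in enumerate(class_labels)}
    n_cls = len(class_labels)
    matrices = []
    for train_idx, val_idx in folds:
        model = _make_model(kind, rng_seed)
        knn_cap = None
        if kind == "knn" and len(train_idx) < KNN_NEIGHBORS:
            model.set_params(clf__n_neighbors=len(train_idx))
            knn_cap = len(train_idx)
        model.fit(features[train_idx], labels[train_idx])
        preds = model.predict(features[val_idx])
        counts = np.zeros((n_cls, n_cls), dtype=int)
        for t, p in zip(labels[val_idx], preds):
            counts[label_index[t], label_index[p]] += 1
        matrices.append(ConfusionMatrix(labels=class_labels, counts=counts))
        del knn_cap
    final = _make_model(kind, rng_seed)
    if kind == "knn" and len(labels) < KNN_NEIGHBORS:
        final.set_params(clf__n_neighbors=len(labels))
    final.fit(features, labels)
    return BaselineResult(kind=kind, model=final, fold_matrices=matrices)
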