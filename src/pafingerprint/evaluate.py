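"""Evaluation: PCA visualization, cluster separation, classification reports.

The headline comparison mirrors the study's qualitative contrast: PCA of
raw spectral features leaves species intermingled, while PCA of the
CNN-learned features shows well-separated clusters. Here the contrast is
quantified with the mean silhouette coefficient of the 2-D projections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix, silhouette_score

from .prototype import TrainedClassifier
from .synth import LabeledSignalSet

__all__ = [
    "ProjectionResult",
    "EvaluationReport",
    "pca_project",
    "silhouette",
    "evaluate",
]


class EvalError(ValueError):
    pass


@dataclass(frozen=True)
class ProjectionResult:
    """2-D (or n-D) PCA projection with explained-variance fractions."""

    coordinates: np.ndarray
    explained_variance_fractions: np.ndarray
    labels: tuple | None = None
    basis: str = "pca"
    degenerate: bool = False

    def to_text(self) -> str:
        lines = ["\t".join(
            [f"pc{i+1}" for i in range(self.coordinates.shape[1])]
            + (["label"] if self.labels is not None else [])
        )]
        for i, row in enumerate(self.coordinates):
            cells = [f"{v:.9g}" for v in row]
            if self.labels is not None:
                cells.append(str(self.labels[i]))
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class EvaluationReport:
    confusion: np.ndarray
    class_names: tuple[str, ...]
    accuracy: float
    per_class_recall: dict[str, float]
    silhouette_raw: float
    silhouette_learned: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_names": list(self.class_names),
                "confusion": self.confusion.tolist(),
                "accuracy": self.accuracy,
                "per_class_recall": self.per_class_recall,
                "silhouette_raw": self.silhouette_raw,
                "silhouette_learned": self.silhouette_learned,
            },
            indent=2,
        )


def pca_project(
    features, n_components: int = 2, labels=None
) -> ProjectionResult:
    """Mean-centered projection onto the top principal axes.

    Sign convention: each axis is flipped, if needed, so its
    largest-magnitude loading is positive — this makes the projection
    deterministic across backends. Zero-variance input returns a
    degenerate all-zero projection rather than raising.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        X = np.stack([np.asarray(f, dtype=float) for f in features])
    n, d = X.shape
    if n < n_components + 1:
        raise EvalError(f"need >= {n_components + 1} samples, got {n}")

    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 1e-300):
        return ProjectionResult(
            coordinates=np.zeros((n, n_components)),
            explained_variance_fractions=np.zeros(n_components),
            labels=tuple(labels) if labels is not None else None,
            degenerate=True,
        )

    k = min(n_components, d, n - 1)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    # fixed sign: largest-|loading| entry of each axis made positive
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            coords[:, i] *= -1.0
    if k < n_components:
        coords = np.hstack([coords, np.zeros((n, n_components - k))])
        evf = np.concatenate([pca.explained_variance_ratio_, np.zeros(n_components - k)])
    else:
        evf = pca.explained_variance_ratio_
    return ProjectionResult(
        coordinates=coords,
        explained_variance_fractions=np.asarray(evf, dtype=float),
        labels=tuple(labels) if labels is not None else None,
    )


def silhouette(coordinates, labels) -> float:
    """Mean silhouette coefficient (standard a/b definition, Euclidean)."""
    X = np.asarray(coordinates, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise EvalError("silhouette needs >= 2 classes")
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise EvalError(f"singleton class(es) {bad.tolist()} not allowed")
    return float(silhouette_score(X, y, metric="euclidean"))


def evaluate(
    classifier: TrainedClassifier, test_set: LabeledSignalSet
) -> EvaluationReport:
    """Confusion matrix + accuracy from the nearest-prototype predictions,
    plus silhouettes of the 2-D PCA of raw spectra vs learned features.

    "Raw" features are the unit-max-normalized magnitude-spectrum vectors
    on the classifier's input grid; "learned" features are f(x, q). Both
    PCAs are fit on the test samples only.
    """
    if len(test_set) == 0:
        raise EvalError("empty test set")
    unknown = set(test_set.class_names) - set(classifier.class_names)
    if unknown:
        raise EvalError(f"test classes {sorted(unknown)} unseen by classifier")

    X = np.stack([classifier.signal_to_input(s) for s in test_set.signals])
    y_true = np.array(test_set.labels)
    est = classifier.estimator
    y_pred = est.predict(X).astype(str)

    names = tuple(test_set.class_names)
    cm = confusion_matrix(y_true, y_pred, labels=list(names))
    acc = float(np.trace(cm) / cm.sum())
    recalls = {}
    for i, cname in enumerate(names):
        row = cm[i].sum()
        recalls[cname] = float(cm[i, i] / row) if row else float("nan")

    peak = np.abs(X).max(axis=1, keepdims=True)
    raw = np.where(peak > 0, X / np.where(peak > 0, peak, 1.0), X)
    learned = est.transform(X)
    try:
        sil_raw = silhouette(pca_project(raw).coordinates, y_true)
        sil_learned = silhouette(pca_project(learned).coordinates, y_true)
    except EvalError:
        # test set too small for a meaningful silhouette (singleton class
        # or fewer than 3 points); the classification metrics still stand
        sil_raw = sil_learned = float("nan")

    return EvaluationReport(
        confusion=cm,
        class_names=names,
        accuracy=acc,
        per_class_recall=recalls,
        silhouette_raw=sil_raw,
        silhouette_learned=sil_learned,
    )


def plot_projection(projection: ProjectionResult, path) -> None:
    """Optional PC1/PC2 scatter colored by class (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = projection.labels or tuple(["?"] * len(projection.coordinates))
    for cname in dict.fromkeys(labels):
        sel = [i for i, l in enumerate(labels) if l == cname]
        ax.scatter(
            projection.coordinates[sel, 0],
            projection.coordinates[sel, 1],
            s=12,
            label=str(cname),
        )
    evf = projection.explained_variance_fractions
    ax.set_xlabel(f"PC1 ({evf[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evf[1]:.0%})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
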