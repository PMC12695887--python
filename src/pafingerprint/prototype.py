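"""Prototype learning for robust PA-spectrum classification.

Each class y owns K prototype embeddings m_yj in the extractor's latent
space (K = 1 by default: one representative embedding per class). A sample
is assigned to the class of its nearest prototype under Euclidean
distance. For training, the class probability is the softmax of negative
distances,

    p(y | x) = exp(-||f(x,q) - m_y||) / sum_k exp(-||f(x,q) - m_k||),

and the loss combines cross-entropy with a prototype-pull term,

    CE = -log p(y | x),      PL = ||f(x,q) - m_y||^2,
    loss = CE + lambda * PL          (lambda = 0.1 by default).

Prototypes are trainable and updated jointly with the CNN parameters q.
The public estimator is :class:`PrototypeNetClassifier`, a scikit-learn
compatible classifier over pre-computed spectrum input vectors; the
module-level :func:`train` / :func:`predict` wrap it for
:class:`~pafingerprint.synth.LabeledSignalSet` pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import features as F
from .features import DEFAULT_INPUT_BAND, FeatureVector, ModelConfig, ModelState
from .signal import compute_spectrum
from .synth import LabeledSignalSet, PASignal

__all__ = [
    "PrototypeSet",
    "ClassProbabilities",
    "LossBreakdown",
    "TrainConfig",
    "TrainedClassifier",
    "PrototypeNetClassifier",
    "classify",
    "class_probabilities",
    "cross_entropy",
    "prototype_loss",
    "total_loss",
    "split_dataset",
    "train",
    "predict",
]

CE_EPSILON = 1e-12


class PrototypeError(ValueError):
    """Invalid prototype-learning input."""


@dataclass(frozen=True)
class PrototypeSet:
    """Per-class prototype embeddings m_yj, shape (C, K, D)."""

    prototypes: np.ndarray
    class_names: tuple[str, ...]
    K: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.prototypes, dtype=float)
        if m.ndim == 2:  # (C, D) convenience for K = 1
            m = m[:, None, :]
        if m.ndim != 3:
            raise PrototypeError("prototypes must have shape (C, K, D)")
        names = tuple(self.class_names)
        if len(names) < 2:
            raise PrototypeError("need >= 2 classes")
        if len(set(names)) != len(names):
            raise PrototypeError("class names must be unique")
        if m.shape[0] != len(names):
            raise PrototypeError("prototype count must match class count")
        if m.shape[1] != self.K:
            object.__setattr__(self, "K", m.shape[1])
        if not np.all(np.isfinite(m)):
            raise PrototypeError("prototypes must be finite")
        object.__setattr__(self, "prototypes", m)
        object.__setattr__(self, "class_names", names)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def dim(self) -> int:
        return self.prototypes.shape[2]


@dataclass(frozen=True)
class ClassProbabilities:
    probabilities: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size != len(self.class_names):
            raise PrototypeError("probability vector length must match classes")
        if np.any(p < 0) or abs(float(p.sum()) - 1.0) > 1e-9:
            raise PrototypeError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def top(self) -> str:
        return self.class_names[int(np.argmax(self.probabilities))]

    def as_dict(self) -> dict[str, float]:
        return {c: float(p) for c, p in zip(self.class_names, self.probabilities)}


@dataclass(frozen=True)
class LossBreakdown:
    ce: float
    pl: float
    lam: float
    total: float


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (lambda and the 80/20 split follow the
    study protocol; the optimizer settings are package defaults)."""

    lam: float = 0.1
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0
    K: int = 1
    warm_start_prototypes: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise PrototypeError("train_fraction must be in (0, 1)")
        if self.epochs < 0:
            raise PrototypeError("epochs must be >= 0")
        if self.lam < 0:
            raise PrototypeError("lambda must be >= 0")


def _feat_array(feature) -> np.ndarray:
    v = feature.values if isinstance(feature, FeatureVector) else np.asarray(feature, dtype=float)
    if not np.all(np.isfinite(v)):
        raise PrototypeError("feature must be finite")
    return v


def _class_distances(feats: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Euclidean distances (B, C): per class the min over its K prototypes."""
    diff = feats[:, None, None, :] - prototypes[None, :, :, :]  # (B, C, K, D)
    d = np.sqrt(np.sum(diff**2, axis=3))
    return d.min(axis=2)


def classify(feature, prototypes: PrototypeSet) -> tuple[str, float]:
    """Nearest-prototype rule: argmin over all C*K prototype distances.

    Ties break toward the lowest class index.
    """
    f = _feat_array(feature)
    if f.size != prototypes.dim:
        raise PrototypeError(
            f"feature dim {f.size} != prototype dim {prototypes.dim}"
        )
    d = _class_distances(f[None, :], prototypes.prototypes)[0]
    i = int(np.argmin(d))  # argmin returns the first (lowest-index) minimum
    return prototypes.class_names[i], float(d[i])


def class_probabilities(feature, prototypes: PrototypeSet) -> ClassProbabilities:
    """Distance softmax p(y|x) = exp(-d_y) / sum_k exp(-d_k), computed with
    a max-shift for numerical stability (shift-invariant in the distances)."""
    f = _feat_array(feature)
    if f.size != prototypes.dim:
        raise PrototypeError("feature/prototype dimension mismatch")
    d = _class_distances(f[None, :], prototypes.prototypes)[0]
    z = -d
    z -= z.max()
    e = np.exp(z)
    p = e / e.sum()
    return ClassProbabilities(probabilities=p, class_names=prototypes.class_names)


def cross_entropy(probabilities: ClassProbabilities, true_class: str) -> float:
    """CE = -log p(y|x), natural log, with p clamped at ``CE_EPSILON``."""
    if true_class not in probabilities.class_names:
        raise PrototypeError(f"unknown class {true_class!r}")
    i = probabilities.class_names.index(true_class)
    p = max(float(probabilities.probabilities[i]), CE_EPSILON)
    return -math.log(p)


def prototype_loss(feature, prototypes: PrototypeSet, true_class: str) -> float:
    """PL = ||f(x,q) - m_y||^2 to the true class's (nearest) prototype."""
    if true_class not in prototypes.class_names:
        raise PrototypeError(f"unknown class {true_class!r}")
    f = _feat_array(feature)
    if f.size != prototypes.dim:
        raise PrototypeError("feature/prototype dimension mismatch")
    y = prototypes.class_names.index(true_class)
    diff = f[None, :] - prototypes.prototypes[y]  # (K, D)
    return float(np.min(np.sum(diff**2, axis=1)))


def total_loss(ce: float, pl: float, lam: float = 0.1) -> LossBreakdown:
    """loss = CE + lambda * PL, exactly."""
    if ce < 0 or pl < 0 or lam < 0:
        raise PrototypeError("ce, pl and lambda must be non-negative")
    return LossBreakdown(ce=ce, pl=pl, lam=lam, total=ce + lam * pl)


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

def split_dataset(
    dataset: LabeledSignalSet,
    train_fraction: float = 0.8,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[LabeledSignalSet, LabeledSignalSet, dict]:
    """Seeded train/test split (default 80/20).

    Stratified splitting keeps per-class proportions; per-class train
    counts are ``round(n_c * train_fraction)`` clipped so both sides keep
    at least one sample. The assignment record maps signal index ->
    "train" | "test" and is reproducible from the seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise PrototypeError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    assignment = np.empty(n, dtype=object)

    if stratified:
        for cname in dataset.class_names:
            idx = np.array([i for i, s in enumerate(dataset.signals) if s.label == cname])
            if idx.size < 2:
                raise PrototypeError(
                    f"class {cname!r} has {idx.size} sample(s); stratified split needs >= 2"
                )
            perm = rng.permutation(idx)
            n_train = int(round(idx.size * train_fraction))
            n_train = min(max(n_train, 1), idx.size - 1)
            assignment[perm[:n_train]] = "train"
            assignment[perm[n_train:]] = "test"
    else:
        perm = rng.permutation(n)
        n_train = min(max(int(round(n * train_fraction)), 1), n - 1)
        assignment[perm[:n_train]] = "train"
        assignment[perm[n_train:]] = "test"

    tr = [s for s, a in zip(dataset.signals, assignment) if a == "train"]
    te = [s for s, a in zip(dataset.signals, assignment) if a == "test"]
    record = {
        "seed": seed,
        "train_fraction": train_fraction,
        "stratified": stratified,
        "assignment": list(assignment),
    }
    return (
        LabeledSignalSet(tr, list(dataset.class_names)),
        LabeledSignalSet(te, list(dataset.class_names)),
        record,
    )


# --------------------------------------------------------------------------
# The estimator
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _batch_loss_and_grads(state, protos, x, y_idx, lam):
    """Mean loss over a batch and gradients w.r.t. CNN params + prototypes.

    ``protos`` has shape (C, K, D); gradient flows through each sample's
    nearest within-class prototype (for K = 1 this is the class prototype).
    """
    feats, cache = F.forward_batch(state, x, want_cache=True)
    b, dim = feats.shape
    c, k, _ = protos.shape
    diff = feats[:, None, None, :] - protos[None, :, :, :]  # (B, C, K, D)
    d_all = np.sqrt(np.sum(diff**2, axis=3))  # (B, C, K)
    jmin = d_all.argmin(axis=2)  # (B, C)
    bi, ci = np.ogrid[:b, :c]
    d = d_all[bi, ci, jmin]  # (B, C)

    z = -d
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    rows = np.arange(b)
    ce = -np.log(np.clip(p[rows, y_idx], CE_EPSILON, None))
    diff_y = feats - protos[y_idx, jmin[rows, y_idx], :]
    pl = np.sum(diff_y**2, axis=1)
    loss = float(np.mean(ce + lam * pl))

    # dCE/dd_bc = (delta_{c,y} - p_bc); dd/dfeat = (feat - m_c*)/d
    dd = (np.eye(c)[y_idx] - p) / b  # (B, C), includes batch mean
    d_safe = np.maximum(d, 1e-12)
    unit = diff[bi, ci, jmin, :] / d_safe[..., None]  # (B, C, D)
    dfeat = np.einsum("bc,bcd->bd", dd, unit)
    dfeat += lam * 2.0 * diff_y / b

    dprotos = np.zeros_like(protos)
    contrib = -dd[..., None] * unit  # (B, C, D) gradient into the selected prototype
    np.add.at(dprotos, (ci.repeat(b, axis=0), jmin), contrib)
    pl_contrib = -lam * 2.0 * diff_y / b
    np.add.at(dprotos, (y_idx, jmin[rows, y_idx]), pl_contrib)

    grads = F.backward_batch(state, cache, dfeat)
    return loss, float(np.mean(ce)), float(np.mean(pl)), grads, dprotos, p


class PrototypeNetClassifier(ClassifierMixin, BaseEstimator):
    """Prototype-learning CNN classifier over spectrum input vectors.

    scikit-learn compatible: ``fit(X, y)`` on an (n_samples, n_bins)
    matrix of magnitude-spectrum vectors (already on a common grid),
    ``predict`` / ``predict_proba`` via the nearest-prototype rule and
    the distance softmax, ``transform`` to the learned D-dimensional
    embedding. Training minimises CE + lambda*PL with Adam, updating the
    CNN parameters q and the prototypes m_y jointly.

    Parameters
    ----------
    conv_kernels : tuple of (width, channels)
        Convolutional stages, each followed by ReLU and max-pooling.
    pool_width : int
        Max-pool width (= stride) after each conv stage.
    feature_dim : int
        Latent dimension D of the learned features and prototypes.
    lam : float
        Weight of the prototype loss (paper protocol value 0.1).
    n_prototypes_per_class : int
        K; one representative embedding per class by default.
    epochs, batch_size, learning_rate : training loop settings.
    normalize_input : bool
        Scale each input vector to unit maximum before the network.
    warm_start_prototypes : bool
        Initialize prototypes at the class means of the initial features
        instead of small random values.
    random_state : int
        Seed for initialization and batch shuffling; training is
        deterministic given the seed.
    """

    def __init__(
        self,
        conv_kernels=((9, 16), (5, 32)),
        pool_width=4,
        feature_dim=32,
        lam=0.1,
        n_prototypes_per_class=1,
        epochs=100,
        batch_size=16,
        learning_rate=1e-3,
        normalize_input=True,
        warm_start_prototypes=False,
        random_state=0,
    ):
        self.conv_kernels = conv_kernels
        self.pool_width = pool_width
        self.feature_dim = feature_dim
        self.lam = lam
        self.n_prototypes_per_class = n_prototypes_per_class
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.normalize_input = normalize_input
        self.warm_start_prototypes = warm_start_prototypes
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def _validate_X(self, X, fitted: bool):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_bins)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if fitted and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, classifier expects {self.n_features_in_}"
            )
        return X

    def fit(self, X, y):
        X = self._validate_X(X, fitted=False)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need >= 2 classes")
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_to_idx[c] for c in y])
        self.n_features_in_ = X.shape[1]

        cfg = ModelConfig(
            input_length=self.n_features_in_,
            conv_kernels=tuple(tuple(k) for k in self.conv_kernels),
            pool_width=self.pool_width,
            feature_dim=self.feature_dim,
            normalize_input=self.normalize_input,
            seed=self.random_state,
        )
        state = F.init_model(cfg)
        rng = np.random.default_rng(self.random_state)
        C, K, D = self.classes_.size, self.n_prototypes_per_class, self.feature_dim
        protos = rng.normal(0.0, 0.1, (C, K, D))
        if self.warm_start_prototypes:
            feats0, _ = F.forward_batch(state, X)
            for ci in range(C):
                protos[ci, :, :] = feats0[y_idx == ci].mean(axis=0)[None, :]

        all_params = dict(state.params)
        all_params["__protos__"] = protos
        opt = _Adam(all_params, self.learning_rate)

        n = X.shape[0]
        bs = min(self.batch_size, n)
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            ep_loss = ep_ce = ep_pl = 0.0
            correct = 0
            for start in range(0, n, bs):
                sel = order[start : start + bs]
                loss, ce, pl, grads, dprotos, p = _batch_loss_and_grads(
                    state, protos, X[sel], y_idx[sel], self.lam
                )
                if not math.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: ce={ce}, pl={pl}; "
                        "try a lower learning rate"
                    )
                grads["__protos__"] = dprotos
                opt.step(all_params, grads)
                # state.params and protos alias entries of all_params
                state.params = {k: v for k, v in all_params.items() if k != "__protos__"}
                protos = all_params["__protos__"]
                w = sel.size / n
                ep_loss += loss * w
                ep_ce += ce * w
                ep_pl += pl * w
                correct += int(np.sum(p.argmax(axis=1) == y_idx[sel]))
            history.append(
                {
                    "epoch": epoch,
                    "loss": ep_loss,
                    "ce": ep_ce,
                    "pl": ep_pl,
                    "lambda": self.lam,
                    "train_accuracy": correct / n,
                }
            )

        self.model_state_ = state
        self.prototypes_ = PrototypeSet(
            prototypes=protos,
            class_names=tuple(str(c) for c in self.classes_),
            K=K,
        )
        self.history_ = history
        return self

    def transform(self, X):
        """Learned features f(x, q), shape (n_samples, D)."""
        check_is_fitted(self, "model_state_")
        X = self._validate_X(X, fitted=True)
        feats, _ = F.forward_batch(self.model_state_, X)
        return feats

    def decision_function(self, X):
        """Negative distances to each class prototype (higher = closer)."""
        feats = self.transform(X)
        return -_class_distances(feats, self.prototypes_.prototypes)

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X):
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# Signal-level pipeline wrappers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainedClassifier:
    """Immutable trained artifact: extractor + prototypes + provenance.

    Separate sample types (washed cells vs whole blood) get separate
    instances of the same architecture; training one never mutates
    another.
    """

    estimator: PrototypeNetClassifier
    train_config: TrainConfig
    split_record: dict
    input_length: int
    input_band: tuple[float, float]
    class_names: tuple[str, ...]

    @property
    def history(self) -> list[dict]:
        return self.estimator.history_

    @property
    def prototypes(self) -> PrototypeSet:
        return self.estimator.prototypes_

    @property
    def model_state(self) -> ModelState:
        return self.estimator.model_state_

    def signal_to_input(self, signal: PASignal) -> np.ndarray:
        spec = compute_spectrum(signal)
        return F.spectrum_to_input(spec, self.input_length, self.input_band)


def signals_to_inputs(
    signals: list[PASignal],
    input_length: int = 512,
    band: tuple[float, float] = DEFAULT_INPUT_BAND,
) -> np.ndarray:
    """FFT + band-resample each signal into a network input matrix."""
    return np.stack(
        [F.spectrum_to_input(compute_spectrum(s), input_length, band) for s in signals]
    )


def train(
    dataset: LabeledSignalSet,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    input_band: tuple[float, float] = DEFAULT_INPUT_BAND,
) -> TrainedClassifier:
    """End-to-end training on a labeled signal set.

    Computes FFT spectra, maps them onto the network input band, splits
    80/20 (stratified, seeded), and fits a :class:`PrototypeNetClassifier`
    on the training portion. With ``epochs=0`` the returned parameters
    equal the seeded initialization.
    """
    tc = train_config or TrainConfig()
    mc = model_config or ModelConfig()
    if len(dataset.class_names) < 2:
        raise PrototypeError("need >= 2 classes to train")

    tr, te, record = split_dataset(
        dataset, tc.train_fraction, tc.stratified, tc.seed
    )
    X_tr = signals_to_inputs(tr.signals, mc.input_length, input_band)
    y_tr = np.array(tr.labels)

    est = PrototypeNetClassifier(
        conv_kernels=mc.conv_kernels,
        pool_width=mc.pool_width,
        feature_dim=mc.feature_dim,
        lam=tc.lam,
        n_prototypes_per_class=tc.K,
        epochs=tc.epochs,
        batch_size=tc.batch_size,
        learning_rate=tc.learning_rate,
        normalize_input=mc.normalize_input,
        warm_start_prototypes=tc.warm_start_prototypes,
        random_state=tc.seed,
    )
    est.fit(X_tr, y_tr)
    return TrainedClassifier(
        estimator=est,
        train_config=tc,
        split_record=record,
        input_length=mc.input_length,
        input_band=tuple(input_band),
        class_names=tuple(dataset.class_names),
    )


def predict(
    classifier: TrainedClassifier, signal: PASignal
) -> tuple[str, ClassProbabilities]:
    """Spectrum -> features -> nearest prototype for one signal."""
    x = classifier.signal_to_input(signal)[None, :]
    est = classifier.estimator
    label = str(est.predict(x)[0])
    proba = est.predict_proba(x)[0]
    probs = ClassProbabilities(
        probabilities=proba,
        class_names=tuple(str(c) for c in est.classes_),
    )
    return label, probs
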