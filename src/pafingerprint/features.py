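"""1-D CNN feature extractor for PA spectra.

The network maps a one-sided magnitude spectrum (resampled to a fixed
number of bins and scaled to unit maximum) to a D-dimensional embedding:

    x -> [conv -> ReLU -> max-pool] x n_layers -> flatten -> FC -> ReLU

Convolutional kernels stride along the frequency axis so each kernel picks
up a local spectral pattern; max-pooling distills the strongest local
responses; the fully connected layer with ReLU integrates them into the
learned feature f(x, q).

Implemented directly on numpy with hand-written backpropagation (see
:func:`forward_batch` / :func:`backward_batch`), which keeps the trainer
dependency-free and bit-deterministic for a given seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .signal import Spectrum
from .synth import MHZ

__all__ = [
    "ModelConfig",
    "ModelState",
    "FeatureVector",
    "init_model",
    "extract_features",
    "extract_features_batch",
    "forward_batch",
    "backward_batch",
    "feature_map_length",
    "spectrum_to_input",
    "save_model",
    "load_model",
    "DEFAULT_INPUT_BAND",
]

#: Default frequency band mapped onto the network input: the PA content of
#: cell and nanoparticle signals lives well below 12.5 MHz.
DEFAULT_INPUT_BAND = (0.0, 12.5 * MHZ)


class ModelConfigError(ValueError):
    """Inconsistent extractor configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Extractor architecture.

    ``conv_kernels`` is a sequence of (kernel_width, out_channels) pairs;
    each conv layer is followed by ReLU and a width-``pool_width`` max
    pool (stride = width, remainder dropped). ``feature_dim`` is the
    embedding size D. ``normalize_input`` scales each input vector to unit
    maximum (classification should key on spectral shape, not amplitude).
    """

    input_length: int = 512
    conv_kernels: tuple[tuple[int, int], ...] = ((9, 16), (5, 32))
    pool_width: int = 4
    feature_dim: int = 32
    activation: str = "relu"
    normalize_input: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_length < 1:
            raise ModelConfigError("input_length must be >= 1")
        if self.feature_dim < 2:
            raise ModelConfigError("feature_dim must be >= 2")
        if self.pool_width < 1:
            raise ModelConfigError("pool_width must be >= 1")
        if self.activation != "relu":
            raise ModelConfigError("only ReLU activation is supported")
        if not self.conv_kernels:
            raise ModelConfigError("need at least one conv layer")
        length = self.input_length
        for i, (w, ch) in enumerate(self.conv_kernels):
            if w < 1 or ch < 1:
                raise ModelConfigError(f"conv layer {i}: width/channels must be >= 1")
            if w > length:
                raise ModelConfigError(
                    f"conv layer {i}: kernel width {w} exceeds input length {length}"
                )
            length = (length - w + 1) // self.pool_width
            if length < 1:
                raise ModelConfigError(f"conv layer {i}: feature map vanishes")

    @property
    def flat_dim(self) -> int:
        """Flattened length entering the fully connected layer."""
        length = self.input_length
        ch = 1
        for w, c in self.conv_kernels:
            length = (length - w + 1) // self.pool_width
            ch = c
        return length * ch

    def to_dict(self) -> dict:
        return {
            "input_length": self.input_length,
            "conv_kernels": [list(k) for k in self.conv_kernels],
            "pool_width": self.pool_width,
            "feature_dim": self.feature_dim,
            "activation": self.activation,
            "normalize_input": self.normalize_input,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_kernels"] = tuple(tuple(k) for k in d["conv_kernels"])
        return cls(**d)


def feature_map_length(input_length: int, kernel_width: int, pool_width: int) -> int:
    """Closed-form output length of one conv(valid) + max-pool block."""
    return (input_length - kernel_width + 1) // pool_width


@dataclass
class ModelState:
    """Trainable parameters q of the extractor plus its config."""

    params: dict[str, np.ndarray]
    config: ModelConfig

    def digest(self) -> str:
        h = hashlib.sha256(json.dumps(self.config.to_dict(), sort_keys=True).encode())
        for key in sorted(self.params):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.params[key]).tobytes())
        return h.hexdigest()[:16]

    def copy(self) -> "ModelState":
        return ModelState({k: v.copy() for k, v in self.params.items()}, self.config)


@dataclass(frozen=True)
class FeatureVector:
    """A learned D-dimensional embedding of one spectrum."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def init_model(config: ModelConfig) -> ModelState:
    """He-initialized parameters, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    c_in = 1
    for i, (w, c_out) in enumerate(config.conv_kernels):
        fan_in = c_in * w
        params[f"conv{i}_w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, w))
        params[f"conv{i}_b"] = np.zeros(c_out)
        c_in = c_out
    fan_in = config.flat_dim
    params["fc_w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (config.feature_dim, fan_in))
    params["fc_b"] = np.zeros(config.feature_dim)
    return ModelState(params=params, config=config)


# --------------------------------------------------------------------------
# Forward / backward
# --------------------------------------------------------------------------

def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (B, C_in, L); w: (C_out, C_in, W) -> (B, C_out, L-W+1)
    win = np.lib.stride_tricks.sliding_window_view(x, w.shape[2], axis=2)
    return np.einsum("ocw,bciw->boi", w, win, optimize=True) + b[None, :, None]


def _conv1d_backward(x, w, dout):
    win = np.lib.stride_tricks.sliding_window_view(x, w.shape[2], axis=2)
    dw = np.einsum("boi,bciw->ocw", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2))
    dx = np.zeros_like(x)
    l_out = dout.shape[2]
    for k in range(w.shape[2]):
        dx[:, :, k : k + l_out] += np.einsum("oc,boi->bci", w[:, :, k], dout, optimize=True)
    return dx, dw, db


def _maxpool(x: np.ndarray, p: int):
    b, c, l = x.shape
    l_out = l // p
    xr = x[:, :, : l_out * p].reshape(b, c, l_out, p)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), idx


def _maxpool_backward(dout, idx, in_shape, p):
    b, c, l = in_shape
    l_out = dout.shape[2]
    dxr = np.zeros((b, c, l_out, p))
    bi, ci, li = np.ogrid[:b, :c, :l_out]
    dxr[bi, ci, li, idx] = dout
    dx = np.zeros(in_shape)
    dx[:, :, : l_out * p] = dxr.reshape(b, c, l_out * p)
    return dx


def forward_batch(state: ModelState, x: np.ndarray, want_cache: bool = False):
    """Features for a batch of input vectors.

    ``x`` has shape (B, input_length). Returns (features (B, D), cache);
    the cache carries the intermediates that :func:`backward_batch` needs.
    """
    cfg = state.config
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != cfg.input_length:
        raise ValueError(
            f"expected input of shape (B, {cfg.input_length}), got {x.shape}"
        )
    if cfg.normalize_input:
        peak = np.abs(x).max(axis=1, keepdims=True)
        x = np.where(peak > 0, x / np.where(peak > 0, peak, 1.0), x)
    h = x[:, None, :]  # (B, 1, L)
    cache = {"x0": h} if want_cache else None
    for i in range(len(cfg.conv_kernels)):
        w, b = state.params[f"conv{i}_w"], state.params[f"conv{i}_b"]
        z = _conv1d(h, w, b)
        a = np.maximum(z, 0.0)
        pooled, idx = _maxpool(a, cfg.pool_width)
        if want_cache:
            cache[f"in{i}"] = h
            cache[f"z{i}"] = z
            cache[f"a_shape{i}"] = a.shape
            cache[f"idx{i}"] = idx
        h = pooled
    flat = h.reshape(h.shape[0], -1)
    z_fc = flat @ state.params["fc_w"].T + state.params["fc_b"]
    feat = np.maximum(z_fc, 0.0)
    if want_cache:
        cache["pool_shape"] = h.shape
        cache["flat"] = flat
        cache["z_fc"] = z_fc
    return feat, cache


def backward_batch(state: ModelState, cache: dict, dfeat: np.ndarray) -> dict:
    """Gradients of a scalar loss w.r.t. every parameter, given dL/dfeatures."""
    cfg = state.config
    grads: dict[str, np.ndarray] = {}
    dz_fc = dfeat * (cache["z_fc"] > 0)
    grads["fc_w"] = dz_fc.T @ cache["flat"]
    grads["fc_b"] = dz_fc.sum(axis=0)
    dh = (dz_fc @ state.params["fc_w"]).reshape(cache["pool_shape"])
    for i in reversed(range(len(cfg.conv_kernels))):
        da = _maxpool_backward(dh, cache[f"idx{i}"], cache[f"a_shape{i}"], cfg.pool_width)
        dz = da * (cache[f"z{i}"] > 0)
        dh, dw, db = _conv1d_backward(cache[f"in{i}"], state.params[f"conv{i}_w"], dz)
        grads[f"conv{i}_w"] = dw
        grads[f"conv{i}_b"] = db
    return grads


# --------------------------------------------------------------------------
# Public single/batch extraction over Spectrum objects
# --------------------------------------------------------------------------

def _as_input_vector(spectrum, input_length: int) -> np.ndarray:
    if isinstance(spectrum, Spectrum):
        v = spectrum.magnitudes
    else:
        v = np.asarray(spectrum, dtype=float)
    if v.ndim != 1 or v.size != input_length:
        raise ValueError(f"spectrum length {v.size} != model input length {input_length}")
    if not np.all(np.isfinite(v)):
        raise ValueError("spectrum contains non-finite values")
    return v


def extract_features(state: ModelState, spectrum) -> FeatureVector:
    """Embed one spectrum (a :class:`Spectrum` on the model grid, or a raw
    magnitude vector of length ``input_length``)."""
    v = _as_input_vector(spectrum, state.config.input_length)
    feat, _ = forward_batch(state, v[None, :])
    src = spectrum.source if isinstance(spectrum, Spectrum) else ""
    return FeatureVector(values=feat[0], source=src)


def extract_features_batch(state: ModelState, spectra: list) -> list[FeatureVector]:
    """Batch version of :func:`extract_features`.

    Evaluates each member independently so results are bitwise equal to
    single-sample calls (batched BLAS reductions would reassociate sums).
    """
    for i, s in enumerate(spectra):
        try:
            _as_input_vector(s, state.config.input_length)
        except ValueError as e:
            raise ValueError(f"batch member {i}: {e}") from e
    return [extract_features(state, s) for s in spectra]


def spectrum_to_input(
    spectrum: Spectrum,
    input_length: int,
    band: tuple[float, float] = DEFAULT_INPUT_BAND,
) -> np.ndarray:
    """Resample a spectrum's magnitudes onto ``input_length`` uniform bins
    spanning ``band``; this is the canonical network input preparation."""
    lo, hi = band
    grid = np.linspace(lo, hi, input_length)
    return np.interp(grid, spectrum.frequencies, spectrum.magnitudes, left=0.0, right=0.0)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def save_model(state: ModelState, path) -> None:
    """Checkpoint = one .npz with parameters, config JSON and digest."""
    arrays = {f"param__{k}": v for k, v in state.params.items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(state.config.to_dict()).encode(), dtype=np.uint8
    )
    arrays["digest"] = np.frombuffer(state.digest().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> ModelState:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(json.loads(bytes(data["config_json"]).decode()))
        params = {
            k[len("param__"):]: data[k] for k in data.files if k.startswith("param__")
        }
        stored = bytes(data["digest"]).decode()
    state = ModelState(params=params, config=cfg)
    if state.digest() != stored:
        raise ValueError("checkpoint digest mismatch; file corrupt or altered")
    return state
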