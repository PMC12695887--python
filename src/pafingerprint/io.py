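"""On-disk formats: waveform text files, dataset manifests, spectra,
fingerprint libraries, template sets, and classifier archives.

Waveforms are two-column delimited text (``time_s``, ``amplitude_mV``)
with one header line; a dataset is a directory of waveform files plus a
JSON manifest recording class names and per-file label/seed/config digest.
Template sets round-trip to YAML or JSON. Trained classifiers persist as a
single ``.npz`` archive holding the extractor checkpoint, the prototype
matrix, and the config/split provenance as embedded JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import features as F
from .prototype import (
    PrototypeNetClassifier,
    PrototypeSet,
    TrainConfig,
    TrainedClassifier,
)
from .signal import FingerprintLibrary, SignalError, Spectrum
from .synth import LabeledSignalSet, PASignal, SpeciesTemplate

__all__ = [
    "write_signal",
    "read_signal",
    "write_dataset",
    "load_dataset",
    "write_spectrum",
    "read_spectrum",
    "write_library",
    "read_library",
    "write_templates",
    "read_templates",
    "save_classifier",
    "load_classifier",
]

MANIFEST_NAME = "manifest.json"


class ManifestError(ValueError):
    pass


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_signal(signal: PASignal, path) -> None:
    path = Path(path)
    t = signal.times
    with path.open("w") as fh:
        fh.write("time_s\tamplitude_mV\n")
        for ti, xi in zip(t, signal.samples):
            fh.write(f"{ti:.9e}\t{xi:.9e}\n")


def read_signal(path, label: str | None = None) -> PASignal:
    path = Path(path)
    data = np.loadtxt(path, skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ManifestError(f"{path}: expected two columns time_s, amplitude_mV")
    dt = np.diff(data[:, 0])
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ManifestError(f"{path}: time column must be uniform and increasing")
    return PASignal(
        samples=data[:, 1],
        sampling_rate=1.0 / float(dt[0]),
        label=label,
        provenance=str(path),
    )


def write_dataset(dataset: LabeledSignalSet, outdir, config_digest: str = "") -> Path:
    """One waveform file per signal plus a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, s in enumerate(dataset.signals):
        fname = f"signal_{i:05d}_{s.label}.tsv"
        write_signal(s, outdir / fname)
        files.append(
            {
                "file": fname,
                "label": s.label,
                "provenance": s.provenance,
                "digest": _file_digest(outdir / fname),
            }
        )
    manifest = {
        "class_names": list(dataset.class_names),
        "config_digest": config_digest,
        "files": files,
    }
    mpath = outdir / MANIFEST_NAME
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_dataset(manifest_path, verify: bool = True) -> LabeledSignalSet:
    mpath = Path(manifest_path)
    if mpath.is_dir():
        mpath = mpath / MANIFEST_NAME
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as e:
        raise ManifestError(f"{mpath}: corrupt manifest at line {e.lineno}: {e.msg}") from e
    root = mpath.parent
    signals = []
    for entry in manifest["files"]:
        fpath = root / entry["file"]
        if not fpath.exists():
            raise ManifestError(f"{mpath}: listed file missing: {entry['file']}")
        if verify and _file_digest(fpath) != entry["digest"]:
            raise ManifestError(f"{mpath}: digest mismatch for {entry['file']}")
        signals.append(read_signal(fpath, label=entry["label"]))
    return LabeledSignalSet(signals=signals, class_names=manifest["class_names"])


# --------------------------------------------------------------------------
# Spectra and libraries
# --------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("frequency_hz\tmagnitude\n")
        for f, m in zip(spectrum.frequencies, spectrum.magnitudes):
            fh.write(f"{f:.9e}\t{m:.9e}\n")


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if ln == 1 and line.startswith("frequency"):
            continue
        if not line.strip():
            continue
        parts = line.split()
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (IndexError, ValueError) as e:
            raise SignalError(f"{path}: malformed spectrum at line {ln}: {line!r}") from e
    if len(rows) < 2:
        raise SignalError(f"{path}: spectrum needs >= 2 rows")
    arr = np.array(rows)
    return Spectrum(arr[:, 0], arr[:, 1], source=str(path))


def write_library(library: FingerprintLibrary, path) -> None:
    payload = {
        "similarity_metric": library.similarity_metric,
        "frequencies_hz": library.grid.tolist(),
        "entries": [
            {"label": lab, "magnitudes": spec.magnitudes.tolist()}
            for lab, spec in library.entries
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_library(path) -> FingerprintLibrary:
    payload = json.loads(Path(path).read_text())
    grid = np.asarray(payload["frequencies_hz"], dtype=float)
    entries = [
        (e["label"], Spectrum(grid, np.asarray(e["magnitudes"], dtype=float),
                              normalization="unit-energy"))
        for e in payload["entries"]
    ]
    return FingerprintLibrary(
        entries=entries, similarity_metric=payload.get("similarity_metric", "cosine")
    )


def write_templates(templates: list[SpeciesTemplate], path) -> None:
    path = Path(path)
    payload = [t.to_dict() for t in templates]
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_templates(path) -> list[SpeciesTemplate]:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return [SpeciesTemplate.from_dict(d) for d in payload]


# --------------------------------------------------------------------------
# Classifier archives
# --------------------------------------------------------------------------

def save_classifier(classifier: TrainedClassifier, path) -> None:
    state = classifier.model_state
    arrays = {f"param__{k}": v for k, v in state.params.items()}
    arrays["prototypes"] = classifier.prototypes.prototypes
    meta = {
        "model_config": state.config.to_dict(),
        "train_config": asdict(classifier.train_config),
        "split_record": classifier.split_record,
        "input_length": classifier.input_length,
        "input_band": list(classifier.input_band),
        "class_names": list(classifier.class_names),
        "prototype_class_names": list(classifier.prototypes.class_names),
        "history": classifier.history,
        "extractor_digest": state.digest(),
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_classifier(path) -> TrainedClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        params = {
            k[len("param__"):]: data[k] for k in data.files if k.startswith("param__")
        }
        protos = data["prototypes"]

    cfg = F.ModelConfig.from_dict(meta["model_config"])
    state = F.ModelState(params=params, config=cfg)
    if state.digest() != meta["extractor_digest"]:
        raise ManifestError(f"{path}: extractor digest mismatch")
    tc = TrainConfig(**meta["train_config"])

    est = PrototypeNetClassifier(
        conv_kernels=cfg.conv_kernels,
        pool_width=cfg.pool_width,
        feature_dim=cfg.feature_dim,
        lam=tc.lam,
        n_prototypes_per_class=tc.K,
        epochs=tc.epochs,
        batch_size=tc.batch_size,
        learning_rate=tc.learning_rate,
        normalize_input=cfg.normalize_input,
        warm_start_prototypes=tc.warm_start_prototypes,
        random_state=tc.seed,
    )
    # restore fitted attributes without retraining
    est.classes_ = np.array(meta["prototype_class_names"])
    est.n_features_in_ = cfg.input_length
    est.model_state_ = state
    est.prototypes_ = PrototypeSet(
        prototypes=protos,
        class_names=tuple(meta["prototype_class_names"]),
        K=tc.K,
    )
    est.history_ = meta["history"]
    return TrainedClassifier(
        estimator=est,
        train_config=tc,
        split_record=meta["split_record"],
        input_length=meta["input_length"],
        input_band=tuple(meta["input_band"]),
        class_names=tuple(meta["class_names"]),
    )
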