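"""File formats: dataset TXT, model JSON, event logs, session reports, config.

All artifacts are plain text, schema-versioned, and embed the seed and a
hash of the generating configuration so that a run can be reproduced and an
artifact traced back to its settings.

Dataset TXT dialect (written by the generator, read by training):

.. code-block:: text

    # posewatch dataset v1
    # joint_set=center_shoulder,left_elbow,...
    # window=1
    # anchor=shoulder_mid
    # labels=both_arms_down,...
    # seed=1
    0.500000 0.512345 ... both_arms_down

one sample per line, features at 6 decimals, the final token is the label.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np

from .detectors import ClassifierBundle
from .neural import BackpropMLP, TrainingSet
from .monitor import AlarmEvent, AlarmStage

__all__ = [
    "write_dataset",
    "read_dataset",
    "save_bundle",
    "load_bundle",
    "write_events",
    "read_events",
    "config_hash",
    "read_config",
]

_DATASET_MAGIC = "# posewatch dataset v1"
_MODEL_SCHEMA = "posewatch.model.v1"


def config_hash(params: dict) -> str:
    """Stable short hash of a flat parameter mapping."""
    canon = json.dumps(
        {str(k): params[k] for k in sorted(params, key=str)}, sort_keys=True, default=str
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_dataset(
    path,
    dataset: TrainingSet,
    joint_set=None,
    window: int = 1,
    anchor: str = "",
    seed: Optional[int] = None,
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_DATASET_MAGIC + "\n")
        if joint_set is not None:
            fh.write("# joint_set=" + ",".join(str(j) for j in joint_set) + "\n")
        fh.write(f"# window={window}\n")
        if anchor:
            fh.write(f"# anchor={anchor}\n")
        fh.write("# labels=" + ",".join(dataset.labels) + "\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for row, label in zip(dataset.X, dataset.y):
            fh.write(" ".join(f"{v:.6f}" for v in row) + f" {label}\n")


def read_dataset(path):
    """Returns ``(TrainingSet, metadata dict)``; metadata holds the header."""
    path = Path(path)
    meta: dict = {}
    rows, labels = [], []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"{path}:{lineno}: expected features followed by a label")
        try:
            rows.append([float(v) for v in tokens[:-1]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed feature value") from exc
        labels.append(tokens[-1])
    if not rows:
        raise ValueError(f"{path}: dataset has no samples")
    declared = tuple(meta["labels"].split(",")) if "labels" in meta else ()
    ds = TrainingSet(X=np.asarray(rows), y=np.asarray(labels), labels=declared)
    meta.setdefault("window", "1")
    return ds, meta


def _mlp_to_dict(mlp: BackpropMLP) -> dict:
    return {
        "params": mlp.get_params(),
        "classes": [str(c) for c in mlp.classes_],
        "n_features_in": int(mlp.n_features_in_),
        "w_hidden": mlp.w_hidden_.tolist(),  # row-major: [input][hidden]
        "b_hidden": mlp.b_hidden_.tolist(),
        "w_out": mlp.w_out_.tolist(),
        "b_out": mlp.b_out_.tolist(),
        "n_epochs": int(mlp.n_epochs_),
        "converged": bool(mlp.converged_),
        "final_error": float(mlp.loss_curve_[-1]) if len(mlp.loss_curve_) else None,
    }


def _mlp_from_dict(doc: dict) -> BackpropMLP:
    mlp = BackpropMLP(**doc["params"])
    mlp.classes_ = np.asarray(doc["classes"])
    mlp.n_features_in_ = int(doc["n_features_in"])
    mlp.w_hidden_ = np.asarray(doc["w_hidden"], dtype=float)
    mlp.b_hidden_ = np.asarray(doc["b_hidden"], dtype=float)
    mlp.w_out_ = np.asarray(doc["w_out"], dtype=float)
    mlp.b_out_ = np.asarray(doc["b_out"], dtype=float)
    mlp.n_epochs_ = int(doc["n_epochs"])
    mlp.converged_ = bool(doc["converged"])
    mlp.loss_curve_ = np.asarray(
        [] if doc.get("final_error") is None else [doc["final_error"]]
    )
    return mlp


def save_bundle(path, bundle: ClassifierBundle, seed: Optional[int] = None) -> None:
    """Serialize a trained bundle; ``load_bundle(save_bundle(b))`` reproduces
    outputs bit-exactly (weights survive the JSON float round-trip)."""
    doc = {
        "schema": _MODEL_SCHEMA,
        "network": _mlp_to_dict(bundle.mlp),
        "joint_set": [str(j) for j in bundle.joint_set],
        "labels": list(bundle.labels),
        "anchor": bundle.anchor,
        "window": bundle.window,
        "confidence_threshold": bundle.confidence_threshold,
        "margin": bundle.margin,
        "seed": seed,
    }
    doc["config_hash"] = config_hash(
        {**doc["network"]["params"], "joint_set": doc["joint_set"], "window": bundle.window}
    )
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")


def load_bundle(path) -> ClassifierBundle:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != _MODEL_SCHEMA:
        raise ValueError(f"{path}: not a posewatch model file")
    return ClassifierBundle(
        mlp=_mlp_from_dict(doc["network"]),
        joint_set=tuple(doc["joint_set"]),
        labels=tuple(doc["labels"]),
        anchor=doc["anchor"],
        window=int(doc["window"]),
        confidence_threshold=float(doc["confidence_threshold"]),
        margin=float(doc["margin"]),
    )


def write_events(path, events) -> None:
    """JSON-lines event log, one alarm event per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for event in events:
            fh.write(event.to_json() + "\n")


def read_events(path) -> list:
    events = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        doc = json.loads(line)
        events.append(
            AlarmEvent(
                kind=doc["kind"],
                timestamp=float(doc["timestamp"]),
                from_stage=AlarmStage(doc["from_stage"]),
                to_stage=AlarmStage(doc["to_stage"]),
            )
        )
    return events


def read_config(path) -> dict:
    """Flat ``key = value`` config document; '#' comments; later keys win."""
    config: dict = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    return config
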