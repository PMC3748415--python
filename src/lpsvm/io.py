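"""Reading/writing delimited datasets and JSON model files.

Datasets are CSV (comma) or TSV (tab, chosen by file extension) with a
header row; samples are rows.  Labels come either from a final column
named ``label`` or from a separate single-column file.  Numeric -1/+1
labels are used as-is; any other pair of level names is mapped to +1/-1
in first-seen order and the mapping is persisted in the model file.

Models are stored as flat JSON.  Floats survive the JSON round trip
bit-exactly, so a reloaded model reproduces predictions exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset
from .model import FitOptions, LpSvmModel
from .synthetic import Scaler

__all__ = [
    "LabelCodec",
    "read_dataset",
    "write_dataset",
    "read_features",
    "save_model",
    "load_model",
]

LABEL_COLUMN = "label"


def _sep_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


@dataclass
class LabelCodec:
    """Mapping between raw label values and the internal -1/+1 coding."""

    positive: str
    negative: str

    def encode(self, raw: pd.Series) -> np.ndarray:
        values = raw.astype(str)
        unknown = set(values.unique()) - {self.positive, self.negative}
        if unknown:
            raise ValueError(f"unexpected label values: {sorted(unknown)}")
        return np.where(values == self.positive, 1.0, -1.0)

    def decode(self, coded: np.ndarray) -> list:
        return [self.positive if c > 0 else self.negative for c in np.asarray(coded)]

    @classmethod
    def infer(cls, raw: pd.Series) -> "LabelCodec":
        levels = list(dict.fromkeys(raw.astype(str)))
        if set(levels) <= {"-1", "1", "+1", "-1.0", "1.0"}:
            pos = next((l for l in levels if not l.startswith("-")), "1")
            neg = next((l for l in levels if l.startswith("-")), "-1")
            return cls(positive=pos, negative=neg)
        if len(levels) != 2:
            raise ValueError(
                f"column '{LABEL_COLUMN}' must have exactly two levels, "
                f"found {levels}"
            )
        return cls(positive=levels[0], negative=levels[1])


def read_dataset(path, label_path=None):
    """Load a delimited dataset.

    Returns ``(dataset, feature_names, codec)``.
    """
    frame = pd.read_csv(path, sep=_sep_for(path))
    if label_path is not None:
        labels_raw = pd.read_csv(label_path, sep=_sep_for(label_path)).iloc[:, 0]
        feat_frame = frame
    else:
        if LABEL_COLUMN not in frame.columns:
            raise ValueError(
                f"no column named '{LABEL_COLUMN}' in {path}; pass a separate "
                "label file instead"
            )
        labels_raw = frame[LABEL_COLUMN]
        feat_frame = frame.drop(columns=[LABEL_COLUMN])
    codec = LabelCodec.infer(labels_raw)
    labels = codec.encode(labels_raw)
    try:
        features = feat_frame.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric feature values in {path}: {exc}") from exc
    return Dataset(features, labels), list(feat_frame.columns), codec


def write_dataset(data: Dataset, path, feature_names=None) -> None:
    """Write samples x features plus a trailing ``label`` column."""
    names = feature_names or [
        f"f{j + 1:0{max(3, len(str(data.n_features)))}d}" for j in range(data.n_features)
    ]
    frame = pd.DataFrame(data.features, columns=names)
    frame[LABEL_COLUMN] = data.labels.astype(int)
    frame.to_csv(path, sep=_sep_for(path), index=False)


def read_features(path, expected_names: list[str]):
    """Load a feature-only file whose columns must match the model's.

    A stray ``label`` column is tolerated (and returned separately); any
    other mismatch is an error rather than silent truncation.
    """
    frame = pd.read_csv(path, sep=_sep_for(path))
    labels = None
    if LABEL_COLUMN in frame.columns:
        labels = frame[LABEL_COLUMN]
        frame = frame.drop(columns=[LABEL_COLUMN])
    if list(frame.columns) != list(expected_names):
        raise ValueError(
            f"feature columns of {path} do not match the model: expected "
            f"{len(expected_names)} columns {expected_names[:3]}..., got "
            f"{len(frame.columns)} columns {list(frame.columns)[:3]}..."
        )
    return frame.to_numpy(dtype=np.float64), labels


def save_model(
    path,
    model: LpSvmModel,
    opts: FitOptions,
    scaler: Scaler | None = None,
    feature_names: list[str] | None = None,
    codec: LabelCodec | None = None,
) -> None:
    """Serialize a fitted model (with its preprocessing) to flat JSON."""
    payload = {
        "format": "lpsvm-model",
        "version": 1,
        "p": model.p,
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "support_indices": model.support_indices.tolist(),
        "n_outer_iters": model.n_outer_iters,
        "converged": model.converged,
        "options": {
            k: (None if v == np.inf else v) for k, v in opts.__dict__.items()
        },
        "scaler": None
        if scaler is None
        else {"mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist()},
        "feature_names": feature_names,
        "label_map": None
        if codec is None
        else {"positive": codec.positive, "negative": codec.negative},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path):
    """Inverse of :func:`save_model`.

    Returns ``(model, opts, scaler, feature_names, codec)``.
    """
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "lpsvm-model":
        raise ValueError(f"{path} is not a model file")
    raw_opts = dict(payload["options"])
    if raw_opts.get("box_c") is None:
        raw_opts["box_c"] = np.inf
    opts = FitOptions(**raw_opts)
    weights = np.asarray(payload["weights"], dtype=np.float64)
    model = LpSvmModel(
        weights=weights,
        bias=float(payload["bias"]),
        p=float(payload["p"]),
        support_indices=np.asarray(payload["support_indices"], dtype=np.intp),
        n_outer_iters=int(payload["n_outer_iters"]),
        weight_trajectory=[],
        converged=bool(payload["converged"]),
        dual=None,
    )
    scaler = None
    if payload["scaler"] is not None:
        scaler = Scaler(
            mean_=np.asarray(payload["scaler"]["mean"], dtype=np.float64),
            scale_=np.asarray(payload["scaler"]["scale"], dtype=np.float64),
        )
    codec = None
    if payload["label_map"] is not None:
        codec = LabelCodec(**payload["label_map"])
    return model, opts, scaler, payload["feature_names"], codec
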