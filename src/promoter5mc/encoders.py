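"""Numeric encodings of candidate-site windows.

Two per-position encodings are provided, plus their concatenation:

* ``onehot`` — A=[1,0,0,0], C=[0,1,0,0], G=[0,0,1,0], T=[0,0,0,1], N=zeros.
* ``dpf`` — deoxynucleotide property and frequency: three chemical-property
  bits per position (ring structure: purine A/G; functional group: amino
  A/C; hydrogen bond: weak pair A/T) followed by the cumulative frequency
  of the position's base over the prefix ending there.
* ``fused`` — onehot followed by dpf, doubling the width.

All encodings map an L-nt window to 4L (or 8L for fused) values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_sequences import Sample

ENCODINGS = ("onehot", "dpf", "fused")

_ONEHOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}

# (ring structure, functional group, hydrogen bond); N degrades to all-zero.
_PROPERTIES = {
    "A": (1.0, 1.0, 1.0),
    "C": (0.0, 1.0, 0.0),
    "G": (1.0, 0.0, 0.0),
    "T": (0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0),
}


def _window_of(sample: Sample | str) -> str:
    window = sample.window if isinstance(sample, Sample) else str(sample).upper()
    for offset, base in enumerate(window):
        if base not in _ONEHOT:
            raise ValidationError(
                f"illegal character {base!r} at offset {offset} in window"
            )
    return window


def encode_one_hot(sample: Sample | str) -> np.ndarray:
    """One-hot encode a window into a 4L vector (positions concatenated)."""
    window = _window_of(sample)
    out = np.empty(4 * len(window))
    for k, base in enumerate(window):
        out[4 * k : 4 * k + 4] = _ONEHOT[base]
    return out


def encode_dpf(sample: Sample | str) -> np.ndarray:
    """Property-and-frequency encode a window into a 4L vector.

    Position k (1-based) contributes (x_k, y_k, z_k, lambda_k) where the
    first three are the chemical-property bits of the base and lambda_k is
    the number of occurrences of that same base among positions 1..k,
    divided by k.  lambda_1 is always 1; N positions count literal 'N'
    matches.
    """
    window = _window_of(sample)
    out = np.empty(4 * len(window))
    counts = {b: 0 for b in _PROPERTIES}
    for k, base in enumerate(window):
        counts[base] += 1
        out[4 * k : 4 * k + 3] = _PROPERTIES[base]
        out[4 * k + 3] = counts[base] / (k + 1)
    return out


def encode_fused(sample: Sample | str) -> np.ndarray:
    """Concatenation of the one-hot and dpf encodings (8L vector)."""
    return np.concatenate([encode_one_hot(sample), encode_dpf(sample)])


_ENCODER_FNS = {"onehot": encode_one_hot, "dpf": encode_dpf, "fused": encode_fused}


@dataclass
class FeatureMatrix:
    """n_samples x d matrix tagged with its encoding name and delta."""

    values: np.ndarray
    encoding: str
    delta: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.encoding not in ENCODINGS:
            raise ValidationError(f"unknown encoding {self.encoding!r}")
        expected = self.width(self.encoding, self.delta)
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValidationError(
                f"feature matrix width {self.values.shape} inconsistent with "
                f"encoding {self.encoding!r} at delta={self.delta} (expected {expected})"
            )

    @staticmethod
    def width(encoding: str, delta: int) -> int:
        length = 2 * delta + 1
        return 8 * length if encoding == "fused" else 4 * length

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def encode_batch(samples: list[Sample], encoding: str, delta: int | None = None) -> FeatureMatrix:
    """Encode samples row-wise into a FeatureMatrix (row order preserved).

    All samples must share the same delta; ``delta`` must be given for an
    empty batch so the matrix width is well defined.
    """
    if encoding not in ENCODINGS:
        raise ValidationError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")
    if samples:
        deltas = {s.delta for s in samples}
        if len(deltas) > 1:
            raise ValidationError(f"mixed delta values in batch: {sorted(deltas)}")
        delta = deltas.pop()
    elif delta is None:
        raise ValidationError("delta is required to encode an empty batch")
    fn = _ENCODER_FNS[encoding]
    width = FeatureMatrix.width(encoding, delta)
    values = (
        np.vstack([fn(s) for s in samples]) if samples else np.empty((0, width))
    )
    return FeatureMatrix(values=values, encoding=encoding, delta=delta)


def save_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a FeatureMatrix to CSV with a JSON sidecar holding its metadata."""
    path = Path(path)
    pd.DataFrame(matrix.values).to_csv(path, index=False, header=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"encoding": matrix.encoding, "delta": matrix.delta, "n": matrix.n_samples})
    )


def load_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if meta["n"] == 0:
        values = np.empty((0, FeatureMatrix.width(meta["encoding"], meta["delta"])))
    return FeatureMatrix(values=values, encoding=meta["encoding"], delta=meta["delta"])
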