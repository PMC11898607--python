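"""Tabular dataset I/O.

A dataset CSV has a header row with numeric feature columns, M annotator
label columns sharing a common prefix (``ann1 .. annM`` by default) and an
optional ground-truth column. Labels are integers in 1..G; every annotator
labels every unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class AnnotatedDataset:
    """Feature matrix plus the M annotator label sets and optional truth."""

    X: np.ndarray                       # (N, p)
    Y: np.ndarray                       # (N, M) labels in 1..G
    y_true: np.ndarray | None = None    # (N,) optional ground truth
    feature_names: list[str] | None = None
    annotator_names: list[str] | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.asarray(self.Y, dtype=int)
        if self.Y.ndim != 2 or self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("X and Y must agree on the number of units")
        if self.y_true is not None:
            self.y_true = np.asarray(self.y_true, dtype=int)
            if self.y_true.shape != (self.X.shape[0],):
                raise ValueError("ground truth length does not match X")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def M(self) -> int:
        return self.Y.shape[1]

    @property
    def G(self) -> int:
        top = int(self.Y.max())
        if self.y_true is not None:
            top = max(top, int(self.y_true.max()))
        return top


def _check_labels(values: pd.Series, column: str) -> np.ndarray:
    arr = values.to_numpy()
    as_int = np.asarray(arr, dtype=float)
    if not np.isfinite(as_int).all():
        bad = int(np.flatnonzero(~np.isfinite(as_int))[0])
        raise ValueError(f"missing or non-numeric label in column {column!r}, row {bad}")
    if np.any(as_int != np.round(as_int)):
        bad = int(np.flatnonzero(as_int != np.round(as_int))[0])
        raise ValueError(f"non-integer label {arr[bad]!r} in column {column!r}, row {bad}")
    out = as_int.astype(int)
    if np.any(out < 1):
        bad = int(np.flatnonzero(out < 1)[0])
        raise ValueError(f"label {out[bad]} out of range (classes are 1..G) in "
                         f"column {column!r}, row {bad}")
    return out


def read_dataset(path: str | Path, annotator_prefix: str = "ann",
                 truth_col: str = "truth",
                 feature_cols: list[str] | None = None) -> AnnotatedDataset:
    """Read an annotated dataset CSV.

    Columns starting with ``annotator_prefix`` are annotator labels, the
    ``truth_col`` column (if present) is the ground truth, and the remaining
    columns (or an explicit ``feature_cols`` list) are numeric features.
    G is inferred as the largest observed label.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    ann_cols = [c for c in df.columns if c.startswith(annotator_prefix)]
    if not ann_cols:
        raise ValueError(f"no annotator columns with prefix {annotator_prefix!r} "
                         f"in {path}")
    if feature_cols is None:
        feature_cols = [c for c in df.columns
                        if c not in ann_cols and c != truth_col]
    if not feature_cols:
        raise ValueError(f"no feature columns found in {path}")
    X = df[feature_cols].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values in the dataset")
    Y = np.column_stack([_check_labels(df[c], c) for c in ann_cols])
    y_true = _check_labels(df[truth_col], truth_col) if truth_col in df.columns else None
    return AnnotatedDataset(X=X, Y=Y, y_true=y_true,
                            feature_names=list(feature_cols),
                            annotator_names=ann_cols)


def write_dataset(ds: AnnotatedDataset, path: str | Path,
                  annotator_prefix: str = "ann", truth_col: str = "truth") -> None:
    """Write a dataset to CSV with full-precision floats (round-trips exactly)."""
    feature_names = ds.feature_names or [f"x{j + 1}" for j in range(ds.p)]
    ann_names = ds.annotator_names or [f"{annotator_prefix}{m + 1}" for m in range(ds.M)]
    df = pd.DataFrame(ds.X, columns=feature_names)
    for m, name in enumerate(ann_names):
        df[name] = ds.Y[:, m]
    if ds.y_true is not None:
        df[truth_col] = ds.y_true
    # pandas' default float formatting is the shortest repr that round-trips
    df.to_csv(path, index=False)
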