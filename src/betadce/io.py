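"""Delimited-text input, unit-variance standardization, and matrix output.

Matrices travel as TSV/CSV with a header row of feature names and a
label column (or a features-in-rows layout, transposed on read).
Standardization subtracts the per-feature mean and divides by the
population (divide-by-n) standard deviation; the fitted parameters are
returned so test data can be transformed with the *training* statistics
and never its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import CLASS_A, CLASS_B, FeatureMatrix

logger = logging.getLogger(__name__)

LABEL_COLUMN_DEFAULT = "label"


@dataclass(frozen=True)
class TableSpec:
    """How to read a labeled matrix from delimited text."""

    path: str | Path
    delimiter: Literal["tab", "comma"] = "tab"
    orientation: Literal["samples-in-rows", "features-in-rows"] = "samples-in-rows"
    label_column: str = LABEL_COLUMN_DEFAULT
    class_map: Mapping[str, str] | None = None  # observed label -> "A"/"B"


def _map_labels(raw: pd.Series, class_map: Mapping[str, str] | None) -> np.ndarray:
    observed = raw.astype(str)
    if class_map is None:
        levels = sorted(observed.unique())
        if len(levels) != 2:
            raise ValidationError(
                f"expected exactly 2 label values, found {len(levels)}: {levels}"
            )
        class_map = {levels[0]: CLASS_A, levels[1]: CLASS_B}
        logger.info("label mapping: %s", class_map)
    mapped = observed.map(dict(class_map))
    if mapped.isna().any():
        unknown = sorted(observed[mapped.isna()].unique())
        raise ValidationError(f"labels not covered by class_map: {unknown}")
    if set(mapped.unique()) != {CLASS_A, CLASS_B}:
        raise ValidationError("class_map must produce exactly the classes A and B")
    return mapped.to_numpy(dtype="U1")


def read_matrix(spec: TableSpec) -> FeatureMatrix:
    """Read and validate a labeled feature matrix from TSV/CSV.

    Non-numeric or missing cells are rejected with their row/column
    coordinates; a features-in-rows table is transposed (its first
    column must hold feature names and its label row is identified by
    ``label_column``).
    """
    sep = "\t" if spec.delimiter == "tab" else ","
    frame = pd.read_csv(spec.path, sep=sep, index_col=0, dtype=str)
    if spec.orientation == "features-in-rows":
        frame = frame.T
    if spec.label_column not in frame.columns:
        raise ValidationError(
            f"label column {spec.label_column!r} not found in {list(frame.columns)}"
        )
    labels = _map_labels(frame[spec.label_column], spec.class_map)
    data = frame.drop(columns=[spec.label_column])
    if data.columns.duplicated().any():
        dupes = sorted(data.columns[data.columns.duplicated()].unique())
        raise ValidationError(f"duplicate feature names: {dupes}")
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"missing or non-numeric cell at sample {data.index[row]!r}, "
            f"feature {data.columns[col]!r}"
        )
    return FeatureMatrix(
        values=numeric.to_numpy(dtype=np.float64),
        labels=labels,
        feature_names=tuple(str(c) for c in data.columns),
        sample_ids=tuple(str(i) for i in data.index),
    )


def write_matrix(matrix: FeatureMatrix, path: str | Path, delimiter: str = "tab") -> None:
    """Write a matrix as delimited text (samples in rows, label column last)."""
    sep = "\t" if delimiter == "tab" else ","
    frame = pd.DataFrame(
        matrix.values, index=list(matrix.sample_ids), columns=list(matrix.feature_names)
    )
    frame[LABEL_COLUMN_DEFAULT] = matrix.labels
    frame.index.name = "sample"
    frame.to_csv(path, sep=sep, float_format="%.10g")


@dataclass(frozen=True)
class Standardization:
    """Fitted per-feature means/SDs plus any dropped zero-variance features."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray  # population (divide-by-n) standard deviations
    dropped: tuple[str, ...]

    def transform(self, values: np.ndarray, feature_names: tuple[str, ...] | None = None) -> np.ndarray:
        """Apply the fitted transform; columns must match ``feature_names``."""
        values = np.atleast_2d(np.asarray(values, dtype=np.float64))
        if feature_names is not None and tuple(feature_names) != self.feature_names:
            idx = {f: j for j, f in enumerate(feature_names)}
            missing = [f for f in self.feature_names if f not in idx]
            if missing:
                raise ValidationError(f"test data lacks features: {missing}")
            values = values[:, [idx[f] for f in self.feature_names]]
        if values.shape[1] != len(self.feature_names):
            raise ValidationError("column count does not match fitted features")
        return (values - self.means) / self.sds


def standardize(matrix: FeatureMatrix) -> tuple[FeatureMatrix, Standardization]:
    """Scale every feature to mean 0, unit variance (population SD).

    Zero-variance features carry no neighbor information and would
    divide by zero, so they are dropped with a warning and listed in the
    returned parameters.
    """
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0)  # ddof=0
    keep = sds > 0
    dropped = tuple(
        name for name, ok in zip(matrix.feature_names, keep) if not ok
    )
    if not keep.any():
        raise ValidationError("all features have zero variance")
    if dropped:
        logger.warning("dropping zero-variance features: %s", list(dropped))
    kept_names = tuple(n for n, ok in zip(matrix.feature_names, keep) if ok)
    params = Standardization(
        feature_names=kept_names,
        means=means[keep],
        sds=sds[keep],
        dropped=dropped,
    )
    standardized = FeatureMatrix(
        values=(matrix.values[:, keep] - means[keep]) / sds[keep],
        labels=matrix.labels.copy(),
        feature_names=kept_names,
        sample_ids=matrix.sample_ids,
    )
    return standardized, params
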