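"""Labeled feature matrix for binary-class feature selection.

The :class:`FeatureMatrix` is the in-memory container shared by every
betadce component: real-valued samples-by-features data with a binary
class tag ("A" / "B") per sample.  Validation is strict because the
nearest-neighbor machinery downstream assumes finite values and at least
two samples per class (so every sample has a potential same-class
neighbor under the leave-one-out convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import FeatureLookupError, ValidationError

CLASS_A = "A"
CLASS_B = "B"


@dataclass(frozen=True)
class FeatureMatrix:
    """n samples x p features with binary labels.

    Parameters
    ----------
    values
        Real matrix of shape (n_samples, n_features); must be finite.
    labels
        Per-sample class tag, each either ``"A"`` or ``"B"``; at least
        two samples per class.
    feature_names
        p unique feature identifiers.
    sample_ids
        n unique sample identifiers; defaults to ``s0 .. s{n-1}``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x features matrix")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at sample {bad[0]}, feature {bad[1]}"
            )
        labels = np.asarray(self.labels, dtype=object)
        if labels.shape != (values.shape[0],):
            raise ValidationError("labels must have one entry per sample")
        bad_tags = sorted({str(x) for x in labels} - {CLASS_A, CLASS_B})
        if bad_tags:
            raise ValidationError(f"labels must be 'A' or 'B', got {bad_tags}")
        labels = labels.astype("U1")
        n_a = int(np.sum(labels == CLASS_A))
        n_b = int(np.sum(labels == CLASS_B))
        if n_a < 2 or n_b < 2:
            raise ValidationError(
                f"each class needs at least two samples (n_A={n_a}, n_B={n_b})"
            )
        names = tuple(str(f) for f in self.feature_names)
        if len(names) != values.shape[1]:
            raise ValidationError("feature_names length must match feature count")
        if len(set(names)) != len(names):
            raise ValidationError("feature_names must be unique")
        ids = tuple(str(s) for s in self.sample_ids) or tuple(
            f"s{i}" for i in range(values.shape[0])
        )
        if len(ids) != values.shape[0]:
            raise ValidationError("sample_ids length must match sample count")
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_ids must be unique")
        values.setflags(write=False)
        labels.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "sample_ids", ids)

    # -- basic shape accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_a(self) -> int:
        return int(np.sum(self.labels == CLASS_A))

    @property
    def n_b(self) -> int:
        return int(np.sum(self.labels == CLASS_B))

    @property
    def is_class_a(self) -> np.ndarray:
        """Boolean mask, True where the sample belongs to class A."""
        return self.labels == CLASS_A

    # -- feature addressing ----------------------------------------------------

    def feature_indices(self, subset: Iterable[str]) -> np.ndarray:
        """Column indices for the given feature ids (in the given order)."""
        index = {name: j for j, name in enumerate(self.feature_names)}
        cols = []
        for name in subset:
            if name not in index:
                raise FeatureLookupError(f"unknown feature id: {name!r}")
            cols.append(index[name])
        if not cols:
            raise ValidationError("feature subset must be non-empty")
        return np.asarray(cols, dtype=np.intp)

    def subset_values(self, subset: Iterable[str]) -> np.ndarray:
        """Columns of ``values`` restricted to ``subset``."""
        return self.values[:, self.feature_indices(subset)]

    def with_feature(self, name: str, column: Sequence[float]) -> "FeatureMatrix":
        """A new matrix with one extra feature appended (originals untouched)."""
        col = np.asarray(column, dtype=np.float64).reshape(-1, 1)
        if col.shape[0] != self.n_samples:
            raise ValidationError("appended column length must match sample count")
        return FeatureMatrix(
            values=np.hstack([self.values, col]),
            labels=self.labels.copy(),
            feature_names=self.feature_names + (name,),
            sample_ids=self.sample_ids,
        )
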