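"""Beta-posterior expectations and the cross-entropy subset objective.

The model: for a sample with K nearest neighbors of which K_a belong to
class A and K_b to class B, the probability P_A that the sample itself
belongs to A is treated as Beta(K_a + 1, K_b + 1) — the posterior of a
binomial proportion under a uniform prior.  Its mean,

    E[P_A] = (K_a + 1) / (K_a + K_b + 2),

is available in closed form, so no resampling is needed to score a
feature subset.  Each training sample gets its own optimized neighbor
count K (the value maximizing the expected probability of the sample's
true class), and a subset is scored by the class-balanced cross-entropy

    H = -(1/n_A) sum_{i in A} ln E_i - (1/n_B) sum_{i in B} ln E_i,

in nats; lower is better.  Because E shrinks toward 1/2 when K is small,
H penalizes neighborhoods that are pure only by chance — the
bias/variance trade-off that lets the objective reject redundant
features without cross-validation.

Conventions (all deterministic):

* Euclidean distance on the active feature subset defines neighbors.
* The query sample is excluded from its own neighbor set (leave-one-out).
* Exact distance ties break toward the lower sample index.
* Ties in the K optimization break toward the smallest K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateFeatureError, ValidationError
from .matrix import FeatureMatrix

Objective = Literal["true-class", "predicted-class"]


# ---------------------------------------------------------------------------
# Beta posterior moments
# ---------------------------------------------------------------------------

def _check_counts(k_a: int, k_b: int) -> tuple[int, int]:
    for k in (k_a, k_b):
        if isinstance(k, bool) or not float(k).is_integer():
            raise ValidationError(f"neighbor counts must be integers, got {k!r}")
        if k < 0:
            raise ValidationError(f"neighbor counts must be non-negative, got {k!r}")
    return int(k_a), int(k_b)


def beta_expectation(k_a: int, k_b: int) -> tuple[float, float]:
    """Expected class probabilities (E[P_A], E[P_B]) from neighbor counts.

    P_A ~ Beta(k_a + 1, k_b + 1), so E[P_A] = (k_a + 1) / (k_a + k_b + 2)
    and E[P_B] = 1 - E[P_A].  With no neighbors the prior mean (1/2, 1/2)
    is returned.
    """
    k_a, k_b = _check_counts(k_a, k_b)
    total = k_a + k_b + 2
    e_a = (k_a + 1) / total
    return e_a, 1.0 - e_a


def beta_variance(k_a: int, k_b: int) -> float:
    """Variance of the Beta(k_a + 1, k_b + 1) class-probability posterior.

    Used as the spread half of the bias/variance diagnostic: at a fixed
    count ratio the variance shrinks as the total neighbor count grows,
    which is why larger (equally biased) neighborhoods score better.
    """
    k_a, k_b = _check_counts(k_a, k_b)
    a, b = k_a + 1, k_b + 1
    return (a * b) / ((a + b) ** 2 * (a + b + 1))


# ---------------------------------------------------------------------------
# Neighbor profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborProfile:
    """Ordered neighbors of one sample on an active feature subset.

    ``ordered_neighbors`` lists the other n-1 sample indices by ascending
    Euclidean distance (ties toward the lower index); row K-1 of
    ``cumulative_class_counts`` holds (K_a, K_b) for the K nearest.
    """

    sample_index: int
    ordered_neighbors: np.ndarray
    cumulative_class_counts: np.ndarray  # shape (n-1, 2): columns (K_a, K_b)


@dataclass(frozen=True)
class SampleExpectation:
    """Optimized neighbor count and expected probability for one sample."""

    sample_index: int
    K: int
    K_a: int
    K_b: int
    E: float


@dataclass(frozen=True)
class SubsetEvaluation:
    """A feature subset with its cross-entropy H and per-sample detail."""

    subset: tuple[str, ...]
    H: float
    sample_K: np.ndarray
    sample_K_a: np.ndarray
    sample_K_b: np.ndarray
    sample_E: np.ndarray

    @property
    def per_sample(self) -> list[SampleExpectation]:
        return [
            SampleExpectation(
                sample_index=i,
                K=int(self.sample_K[i]),
                K_a=int(self.sample_K_a[i]),
                K_b=int(self.sample_K_b[i]),
                E=float(self.sample_E[i]),
            )
            for i in range(len(self.sample_K))
        ]


def _neighbor_order(values: np.ndarray) -> np.ndarray:
    """Stable leave-one-out neighbor ordering for every sample at once.

    Returns an (n, n-1) integer array; row i lists the other samples by
    ascending Euclidean distance on ``values``, exact ties broken toward
    the lower sample index (stable sort over an index-ordered key).
    """
    d2 = cdist(values, values, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)  # exclude self
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :-1]


def neighbor_profile(
    matrix: FeatureMatrix, subset: Iterable[str], sample_index: int
) -> NeighborProfile:
    """Neighbor ordering and cumulative class counts for one sample."""
    subset = tuple(subset)
    values = matrix.subset_values(subset)
    n = matrix.n_samples
    if not 0 <= sample_index < n:
        raise ValidationError(f"sample_index out of range: {sample_index}")
    order = _neighbor_order(values)[sample_index]
    neighbor_is_a = matrix.is_class_a[order]
    k_a = np.cumsum(neighbor_is_a)
    k_b = np.arange(1, n) - k_a
    return NeighborProfile(
        sample_index=sample_index,
        ordered_neighbors=order,
        cumulative_class_counts=np.column_stack([k_a, k_b]),
    )


def optimize_sample_k(
    profile: NeighborProfile, label: str, k_max: int | None = None
) -> SampleExpectation:
    """Pick the K in 1..k_max maximizing the true-class expected probability.

    E_true(K) = (K_c + 1) / (K + 2) where K_c counts same-class neighbors
    among the K nearest; ties go to the smallest K (the least assumption
    about the extent of the local neighborhood).
    """
    counts = profile.cumulative_class_counts
    n_neighbors = counts.shape[0]
    if n_neighbors == 0:
        raise ValidationError("neighbor profile is empty")
    k_max = n_neighbors if k_max is None else int(k_max)
    if not 1 <= k_max <= n_neighbors:
        raise ValidationError(f"k_max must be in 1..{n_neighbors}, got {k_max}")
    own_col = 0 if label == "A" else 1
    k_own = counts[:k_max, own_col]
    ks = np.arange(1, k_max + 1)
    e_true = (k_own + 1) / (ks + 2)
    best = int(np.argmax(e_true))  # first max -> smallest K
    return SampleExpectation(
        sample_index=profile.sample_index,
        K=int(ks[best]),
        K_a=int(counts[best, 0]),
        K_b=int(counts[best, 1]),
        E=float(e_true[best]),
    )


# ---------------------------------------------------------------------------
# Subset evaluation
# ---------------------------------------------------------------------------

def _evaluate_values(
    values: np.ndarray,
    is_a: np.ndarray,
    k_max: int | None,
    objective: Objective = "true-class",
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core: H plus per-sample (K, K_a, K_b, E) arrays."""
    n = values.shape[0]
    k_cap = n - 1 if k_max is None else min(int(k_max), n - 1)
    if k_cap < 1:
        raise ValidationError("k_max must be at least 1")
    order = _neighbor_order(values)  # (n, n-1)
    neighbor_is_a = is_a[order]  # (n, n-1)
    cum_a = np.cumsum(neighbor_is_a, axis=1)  # K_a for each prefix
    ks = np.arange(1, n)  # prefix lengths
    cum_own = np.where(is_a[:, None], cum_a, ks[None, :] - cum_a)
    e_true = (cum_own[:, :k_cap] + 1) / (ks[None, :k_cap] + 2)
    best = np.argmax(e_true, axis=1)  # first max -> smallest K
    rows = np.arange(n)
    k_opt = best + 1
    k_a = cum_a[rows, best]
    k_b = k_opt - k_a
    e_own = e_true[rows, best]
    if objective == "true-class":
        e_used = e_own
    elif objective == "predicted-class":
        # Literal winner-take-all reading: score each sample by the
        # expectation of its *predicted* class, max(E[P_A], E[P_B]).
        e_used = np.maximum(e_own, 1.0 - e_own)
    else:  # pragma: no cover - guarded by Literal type
        raise ValidationError(f"unknown objective: {objective!r}")
    log_e = np.log(e_used)
    h = -log_e[is_a].mean() - log_e[~is_a].mean()
    return float(h), k_opt, k_a, k_b, e_own


def evaluate_subset(
    matrix: FeatureMatrix,
    subset: Iterable[str],
    k_max: int | None = None,
    objective: Objective = "true-class",
) -> SubsetEvaluation:
    """Score a feature subset by the balanced nearest-neighbor cross-entropy.

    Parameters
    ----------
    matrix
        Validated feature matrix (standardize first if features are on
        different scales; see :func:`betadce.io.standardize`).
    subset
        Non-empty collection of feature ids.
    k_max
        Cap on the per-sample neighbor count scan; defaults to n - 1.
    objective
        ``"true-class"`` (default) scores each sample by the expected
        probability of its actual class, so misclassified samples pull H
        up; ``"predicted-class"`` scores by the winning class's
        expectation instead.

    Returns
    -------
    SubsetEvaluation
        With ``H`` in nats and per-sample optimized neighbor counts.
    """
    subset = tuple(subset)
    values = matrix.subset_values(subset)
    spans = np.ptp(values, axis=0)
    if np.any(spans == 0):
        dead = [subset[j] for j in np.flatnonzero(spans == 0)]
        raise DegenerateFeatureError(f"zero-variance feature(s) in subset: {dead}")
    h, k_opt, k_a, k_b, e_own = _evaluate_values(
        values, matrix.is_class_a, k_max, objective
    )
    return SubsetEvaluation(
        subset=subset,
        H=h,
        sample_K=k_opt,
        sample_K_a=k_a,
        sample_K_b=k_b,
        sample_E=e_own,
    )


def subset_entropy(
    matrix: FeatureMatrix,
    subset: Sequence[str],
    k_max: int | None = None,
    objective: Objective = "true-class",
) -> float:
    """H only — the fast path used by the epoch search."""
    values = matrix.subset_values(subset)
    spans = np.ptp(values, axis=0)
    if np.any(spans == 0):
        dead = [list(subset)[j] for j in np.flatnonzero(spans == 0)]
        raise DegenerateFeatureError(f"zero-variance feature(s) in subset: {dead}")
    return _evaluate_values(values, matrix.is_class_a, k_max, objective)[0]
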