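"""Epoch-wise wrapper search over feature subsets.

Epoch i evaluates every subset of i features drawn from the current
candidate pool and sorts them by the cross-entropy H.  The pool carried
into epoch i+1 is the first m unique features encountered while scanning
that sorted list, where m is the largest pool size whose next-epoch
subset count C(m, i+1) stays within the per-epoch evaluation budget N_e.
The search stops as soon as an epoch's best H fails to improve on the
previous epoch's best by more than the stopping ratio (default 0.95,
i.e. a 5% relative improvement is required to continue), or when the
pool cannot supply enough features, or at the configured epoch cap.

Everything is deterministic: subsets are sorted by (H, feature names)
and parallel evaluation only partitions independent subset scores, so
the result is identical for any worker count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from joblib import Parallel, delayed

from .core import Objective, subset_entropy
from .errors import SearchExhaustedError, ValidationError
from .matrix import FeatureMatrix

logger = logging.getLogger(__name__)

ReturnPolicy = Literal["global-best", "current-epoch-best"]
StopReason = Literal["stop-ratio", "pool-exhausted", "max-epochs"]


@dataclass(frozen=True)
class SearchConfig:
    """Tunables of the epoch search.

    Attributes
    ----------
    n_e
        Evaluation budget per epoch; caps the pool via C(m, i+1) <= N_e.
        Epoch 1 always scores every single feature regardless of the
        budget (the budget governs pools for epochs >= 2).
    stop_ratio
        Continue only while min_H(i) < stop_ratio * min_H(i-1); the
        default 0.95 demands a >5% relative improvement per epoch.
    k_max
        Per-sample neighbor-count cap passed to the evaluator
        (None = n - 1).
    max_epochs
        Safety bound on the number of epochs.
    return_policy
        ``"global-best"`` (default) returns the lowest-H subset seen in
        any epoch; ``"current-epoch-best"`` returns the terminal epoch's
        best, the literal one-epoch-lookback reading.
    threads
        Worker count for subset evaluation (joblib threads); results are
        independent of this value.
    """

    n_e: int = 100_000
    stop_ratio: float = 0.95
    k_max: int | None = None
    max_epochs: int = 20
    seed: int | None = None  # reserved for stochastic subsampling variants
    return_policy: ReturnPolicy = "global-best"
    objective: Objective = "true-class"
    threads: int = 1

    def __post_init__(self) -> None:
        if self.n_e < 1:
            raise ValidationError("n_e must be >= 1")
        if not 0.0 < self.stop_ratio <= 1.0:
            raise ValidationError("stop_ratio must lie in (0, 1]")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")


@dataclass(frozen=True)
class EpochResult:
    """One epoch: the sorted evaluations and the pool passed onward."""

    epoch_index: int
    evaluated: tuple[tuple[tuple[str, ...], float], ...]  # (subset, H) ascending
    min_H: float
    pool: tuple[str, ...]

    @property
    def best_subset(self) -> tuple[str, ...]:
        return self.evaluated[0][0]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the search: selected subset plus the full epoch trace."""

    selected: tuple[str, ...]
    trace: tuple[EpochResult, ...] = field(repr=False)
    stopped_reason: StopReason

    @property
    def min_H_trace(self) -> list[float]:
        """Per-epoch best H, for convergence plots."""
        return [epoch.min_H for epoch in self.trace]


def max_pool_size(i: int, n_e: int) -> int:
    """Largest m with C(m, i+1) <= n_e, the pool bound for epoch i.

    Computed with exact integer binomials grown incrementally, so it is
    overflow-safe for any budget.
    """
    if i < 1:
        raise ValidationError("epoch index must be >= 1")
    if n_e < 1:
        raise ValidationError("n_e must be >= 1")
    k = i + 1
    m = k  # C(k, k) = 1 <= n_e always
    binom = 1
    while True:
        # C(m+1, k) = C(m, k) * (m+1) / (m+1-k)
        nxt = binom * (m + 1) // (m + 1 - k)
        if nxt > n_e:
            return m
        m += 1
        binom = nxt


def _score_subsets(
    matrix: FeatureMatrix,
    subsets: list[tuple[str, ...]],
    config: SearchConfig,
) -> list[float]:
    if config.threads > 1 and len(subsets) > 1:
        return Parallel(n_jobs=config.threads, backend="threading")(
            delayed(subset_entropy)(matrix, s, config.k_max, config.objective)
            for s in subsets
        )
    return [
        subset_entropy(matrix, s, config.k_max, config.objective) for s in subsets
    ]


def run_epoch(
    matrix: FeatureMatrix,
    candidate_features: Sequence[str],
    i: int,
    config: SearchConfig,
) -> EpochResult:
    """Evaluate every size-i subset of the candidates and build the pool.

    Subsets are sorted ascending by H with ties broken lexicographically
    by feature names; the pool is the first max_pool_size(i, N_e) unique
    features encountered scanning the sorted list.
    """
    candidates = list(candidate_features)
    if len(candidates) < i:
        raise SearchExhaustedError(
            f"epoch {i} needs {i} candidate features, have {len(candidates)}"
        )
    subsets = [tuple(sorted(c)) for c in itertools.combinations(candidates, i)]
    scores = _score_subsets(matrix, subsets, config)
    ranked = sorted(zip(subsets, scores), key=lambda sh: (sh[1], sh[0]))
    m = max_pool_size(i, config.n_e)
    pool: list[str] = []
    seen: set[str] = set()
    for subset, _ in ranked:
        for name in subset:
            if name not in seen:
                seen.add(name)
                pool.append(name)
        if len(pool) >= m:
            break
    return EpochResult(
        epoch_index=i,
        evaluated=tuple(ranked),
        min_H=ranked[0][1],
        pool=tuple(pool[:m]),
    )


def select_features(
    matrix: FeatureMatrix, config: SearchConfig | None = None
) -> SelectionResult:
    """Run the epoch-wise search on a matrix and return the chosen subset.

    Epoch 1 scores all p single features; each later epoch i scores all
    size-i subsets of the pool inherited from epoch i-1.  Iteration ends
    when the relative improvement of the epoch's best H falls below
    1 - stop_ratio, the pool runs out, or max_epochs is reached.
    """
    config = config or SearchConfig()
    if matrix.n_features < 1:
        raise ValidationError("matrix has no features")
    candidates: Sequence[str] = matrix.feature_names
    trace: list[EpochResult] = []
    reason: StopReason = "max-epochs"
    for i in range(1, config.max_epochs + 1):
        epoch = run_epoch(matrix, candidates, i, config)
        trace.append(epoch)
        logger.info("epoch %d: evaluated %d subsets, min H = %.6f",
                    i, len(epoch.evaluated), epoch.min_H)
        if i > 1 and epoch.min_H >= config.stop_ratio * trace[-2].min_H:
            reason = "stop-ratio"
            break
        if i == config.max_epochs:
            reason = "max-epochs"
            break
        if len(epoch.pool) < i + 1:
            reason = "pool-exhausted"
            break
        candidates = epoch.pool
    if config.return_policy == "current-epoch-best":
        selected = trace[-1].best_subset
    else:
        best_epoch = min(trace, key=lambda e: (e.min_H, e.epoch_index))
        selected = best_epoch.best_subset
    return SelectionResult(selected=selected, trace=tuple(trace), stopped_reason=reason)
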