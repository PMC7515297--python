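"""XOR-like benchmark: synthetic generator and redundant-feature permutation test.

The generator emulates the benchmark's study conditions: 280 samples
(140 per class) on two real features, each class split equally over two
diagonally opposed isotropic Gaussian clusters so the classes cross in
an XOR pattern.  Each feature is then individually uninformative — any
per-feature filter, and any wrapper at epoch 1, sees pure noise — while
the pair is jointly discriminative, which is exactly the structure that
separates subset-level evaluation functions from marginal ones.

The permutation test measures how often an evaluator would *retain* an
appended label-independent feature: for each replicate a fresh redundant
column is appended, the 3-feature evaluation is compared against the
fixed 2-feature baseline, and the false discovery rate is the fraction
of replicates where the rule says "improved".  For the cross-entropy
evaluator the default rule mirrors the search's own retention condition
(the 3-feature H must undercut 95% of the baseline H); for
accuracy-type baselines (KNN leave-one-out, RBF-kernel SVM with
cross-validation) any strict accuracy increase counts as a discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Protocol, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .core import Objective, subset_entropy
from .errors import ValidationError
from .matrix import CLASS_A, CLASS_B, FeatureMatrix

logger = logging.getLogger(__name__)

DetectionRule = Literal["slack-0.95", "strict"]
RedundantMode = Literal["noise", "permuted-copy"]


@dataclass(frozen=True)
class XorConfig:
    """Geometry and size of the XOR-like dataset.

    Class A occupies clusters at (-1,-1) and (1,1); class B at (-1,1)
    and (1,-1).  Each cluster is an isotropic Gaussian with standard
    deviation ``sigma`` and receives ``n_per_class / 2`` samples.
    """

    n_per_class: int = 140
    centers_a: tuple[tuple[float, float], tuple[float, float]] = ((-1.0, -1.0), (1.0, 1.0))
    centers_b: tuple[tuple[float, float], tuple[float, float]] = ((-1.0, 1.0), (1.0, -1.0))
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2 or self.n_per_class % 2:
            raise ValidationError("n_per_class must be an even integer >= 2")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of the redundant-feature permutation test."""

    reps: int
    false_discoveries: int
    fdr: float
    rule: str
    baseline_value: float
    replicate_values: np.ndarray = field(repr=False)
    replicate_flags: np.ndarray = field(repr=False)


class SubsetEvaluator(Protocol):
    """Contract for pluggable evaluators in the permutation test.

    ``kind`` declares the direction: "loss" evaluators (lower is better,
    e.g. the cross-entropy H) versus "accuracy" evaluators.
    """

    kind: str

    def __call__(self, matrix: FeatureMatrix, subset: Sequence[str]) -> float: ...


def generate_xor(config: XorConfig | None = None) -> FeatureMatrix:
    """Draw the XOR-like training set: 2*n_per_class samples x 2 features."""
    config = config or XorConfig()
    rng = np.random.default_rng(config.seed)
    half = config.n_per_class // 2
    blocks, labels = [], []
    for tag, centers in ((CLASS_A, config.centers_a), (CLASS_B, config.centers_b)):
        for center in centers:
            blocks.append(
                np.asarray(center) + config.sigma * rng.standard_normal((half, 2))
            )
            labels.extend([tag] * half)
    return FeatureMatrix(
        values=np.vstack(blocks),
        labels=np.asarray(labels, dtype="U1"),
        feature_names=("f1", "f2"),
    )


def add_redundant_feature(
    matrix: FeatureMatrix,
    seed: int,
    mode: RedundantMode = "noise",
    name: str = "redundant",
) -> FeatureMatrix:
    """Append one label-independent feature.

    ``"noise"`` draws a fresh standard-normal column; ``"permuted-copy"``
    randomly permutes a copy of the first feature, destroying any joint
    structure while preserving its marginal distribution.
    """
    rng = np.random.default_rng(seed)
    if mode == "noise":
        column = rng.standard_normal(matrix.n_samples)
    elif mode == "permuted-copy":
        column = rng.permutation(matrix.values[:, 0])
    else:
        raise ValidationError(f"unknown redundant-feature mode: {mode!r}")
    return matrix.with_feature(name, column)


# ---------------------------------------------------------------------------
# Evaluators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaDCEEvaluator:
    """The cross-entropy objective itself (loss; lower is better)."""

    k_max: int | None = None
    objective: Objective = "true-class"
    kind: str = "loss"

    def __call__(self, matrix: FeatureMatrix, subset: Sequence[str]) -> float:
        return subset_entropy(matrix, subset, self.k_max, self.objective)


def knn_loocv_accuracy(
    matrix: FeatureMatrix,
    subset: Sequence[str],
    k_grid: Sequence[int] = tuple(range(1, 31)),
) -> float:
    """Best leave-one-out accuracy of a majority-vote KNN over a k grid.

    The neighbor ordering is computed once (ties toward the lower sample
    index) and reused for all grid points; majority-vote ties go to
    class A.  Grid points with k >= n are skipped.
    """
    if not len(k_grid):
        raise ValidationError("k_grid must be non-empty")
    values = matrix.subset_values(subset)
    n = matrix.n_samples
    valid = [int(k) for k in k_grid if 1 <= int(k) < n]
    if not valid:
        raise ValidationError(f"no valid k in grid for n={n}")
    d2 = cdist(values, values, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :-1]
    votes_a = np.cumsum(matrix.is_class_a[order], axis=1)  # (n, n-1)
    truth_a = matrix.is_class_a
    best = 0.0
    for k in valid:
        pred_a = votes_a[:, k - 1] * 2 >= k  # majority, ties -> A
        best = max(best, float(np.mean(pred_a == truth_a)))
    return best


@dataclass(frozen=True)
class KnnLoocvEvaluator:
    """Leave-one-out KNN accuracy with automatic k (accuracy; higher better)."""

    k_grid: tuple[int, ...] = tuple(range(1, 31))
    kind: str = "accuracy"

    def __call__(self, matrix: FeatureMatrix, subset: Sequence[str]) -> float:
        return knn_loocv_accuracy(matrix, subset, self.k_grid)


def svm_cv_accuracy(
    matrix: FeatureMatrix,
    subset: Sequence[str],
    folds: int = 5,
    c_grid: Sequence[float] = tuple(10.0 ** np.arange(-2, 4)),
    gamma_grid: Sequence[float] = tuple(10.0 ** np.arange(-3, 2)),
    seed: int = 0,
) -> float:
    """Best stratified k-fold accuracy of an RBF-kernel SVM over a C x gamma grid."""
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    values = matrix.subset_values(subset)
    y = (matrix.labels == CLASS_A).astype(int)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    grid = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(c_grid), "gamma": list(gamma_grid)},
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    grid.fit(values, y)
    return float(grid.best_score_)


@dataclass(frozen=True)
class SvmCvEvaluator:
    """Cross-validated RBF-SVM accuracy with grid-tuned C and gamma."""

    folds: int = 5
    c_grid: tuple[float, ...] = tuple(10.0 ** np.arange(-2, 4))
    gamma_grid: tuple[float, ...] = tuple(10.0 ** np.arange(-3, 2))
    seed: int = 0
    kind: str = "accuracy"

    def __call__(self, matrix: FeatureMatrix, subset: Sequence[str]) -> float:
        return svm_cv_accuracy(
            matrix, subset, self.folds, self.c_grid, self.gamma_grid, self.seed
        )


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _is_false_discovery(
    kind: str, rule: DetectionRule, baseline: float, value: float
) -> bool:
    if kind == "loss":
        if rule == "slack-0.95":
            return value < 0.95 * baseline
        return value < baseline
    # accuracy-type: any strict improvement retains the redundant feature
    return value > baseline


def permutation_fdr(
    matrix: FeatureMatrix,
    evaluator: SubsetEvaluator,
    reps: int = 1000,
    rule: DetectionRule = "slack-0.95",
    seed: int = 0,
    mode: RedundantMode = "noise",
    threads: int = 1,
) -> PermTestResult:
    """False discovery rate of an evaluator against appended redundant features.

    The 2-feature baseline is evaluated once; each replicate appends a
    fresh label-independent column (seeded; all replicate columns are
    drawn up-front from one stream so the result is independent of the
    execution order) and re-evaluates on all 3 features.  A replicate
    counts as a false discovery when the detection rule flags the
    3-feature evaluation as an improvement.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if rule not in ("slack-0.95", "strict"):
        raise ValidationError(f"unknown detection rule: {rule!r}")
    base_subset = list(matrix.feature_names)
    baseline = float(evaluator(matrix, base_subset))
    rng = np.random.default_rng(seed)
    if mode == "noise":
        columns = rng.standard_normal((reps, matrix.n_samples))
    elif mode == "permuted-copy":
        columns = np.stack(
            [rng.permutation(matrix.values[:, 0]) for _ in range(reps)]
        )
    else:
        raise ValidationError(f"unknown redundant-feature mode: {mode!r}")

    def one(column: np.ndarray) -> float:
        augmented = matrix.with_feature("redundant", column)
        return float(evaluator(augmented, base_subset + ["redundant"]))

    if threads > 1:
        from joblib import Parallel, delayed

        values = Parallel(n_jobs=threads, backend="threading")(
            delayed(one)(columns[r]) for r in range(reps)
        )
    else:
        values = [one(columns[r]) for r in range(reps)]
    values = np.asarray(values, dtype=np.float64)
    flags = np.asarray(
        [_is_false_discovery(evaluator.kind, rule, baseline, v) for v in values],
        dtype=bool,
    )
    count = int(flags.sum())
    logger.info(
        "permutation test: %d/%d false discoveries (baseline %.6f)",
        count, reps, baseline,
    )
    return PermTestResult(
        reps=reps,
        false_discoveries=count,
        fdr=count / reps,
        rule=rule,
        baseline_value=baseline,
        replicate_values=values,
        replicate_flags=flags,
    )
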