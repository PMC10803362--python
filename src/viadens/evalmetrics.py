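"""Detection evaluation: distance-based point matching, precision/recall/F, CV harness.

A detection is counted as a true positive when it can be paired one-to-one
with a ground-truth nucleus at Euclidean distance <= ``radius`` pixels
(default 20, the approximate nucleus radius). Among all maximum-cardinality
pairings the one with minimal total distance is used, so the result is
deterministic and independent of point order.
"""

from __future__ import annotations

import copy
import dataclasses
from collections.abc import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "MatchResult",
    "MetricSet",
    "FoldPlan",
    "CVResult",
    "match_points",
    "f_measure",
    "metric_set",
    "make_fold_plan",
    "cross_validate",
]

DEFAULT_RADIUS = 20.0


@dataclasses.dataclass(frozen=True)
class MatchResult:
    """One-to-one matching between predicted and ground-truth points."""

    tp: int
    fp: int
    fn: int
    #: (pred index, gt index, distance px) for every matched pair
    pairs: tuple[tuple[int, int, float], ...]

    @property
    def total_distance(self) -> float:
        return float(sum(d for _, _, d in self.pairs))


@dataclasses.dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f_measure: float


def _as_points(points) -> np.ndarray:
    """Coerce to an (n, 2) float array of (x, y) coordinates."""
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {arr.shape}")
    return arr


def match_points(pred, gt, radius: float = DEFAULT_RADIUS) -> MatchResult:
    """Match predictions to ground truth within ``radius`` pixels.

    Maximum-cardinality one-to-one matching; ties in cardinality are broken
    by minimal total paired distance. Unpaired predictions are false
    positives, unpaired ground-truth points false negatives.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pred = _as_points(pred)
    gt = _as_points(gt)
    n_pred, n_gt = len(pred), len(gt)
    if n_pred == 0 or n_gt == 0:
        return MatchResult(tp=0, fp=n_pred, fn=n_gt, pairs=())

    dist = cdist(pred, gt)
    feasible = dist <= radius
    # Infeasible assignments get a cost larger than any total feasible
    # distance, so minimizing total cost first maximizes the number of
    # feasible pairs, then minimizes their summed distance.
    big = radius * (min(n_pred, n_gt) + 1.0) + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(
        (int(i), int(j), float(dist[i, j]))
        for i, j in zip(rows, cols)
        if feasible[i, j]
    )
    tp = len(pairs)
    return MatchResult(tp=tp, fp=n_pred - tp, fn=n_gt - tp, pairs=pairs)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metric_set(m: MatchResult) -> MetricSet:
    """Precision, recall and F from match counts.

    The empty-vs-empty case (no predictions, no ground truth) is defined as
    perfect (1, 1, 1): no errors were made.
    """
    if m.tp + m.fp == 0:
        precision = 1.0 if m.fn == 0 else 0.0
    else:
        precision = m.tp / (m.tp + m.fp)
    if m.tp + m.fn == 0:
        recall = 1.0 if m.fp == 0 else 0.0
    else:
        recall = m.tp / (m.tp + m.fn)
    return MetricSet(precision=precision, recall=recall, f_measure=f_measure(precision, recall))


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Partition of patients into disjoint subsets plus a rotation schedule.

    ``folds[f]`` maps the role of each subset in fold ``f``: three (or
    n_folds - 2) subsets train, one validates (model selection), one tests.
    """

    subsets: tuple[tuple[object, ...], ...]
    folds: tuple[dict, ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def fold_ids(self, f: int) -> tuple[list, list, list]:
        """(train ids, val ids, test ids) for fold ``f``."""
        spec = self.folds[f]
        train = [pid for s in spec["train"] for pid in self.subsets[s]]
        val = list(self.subsets[spec["val"]])
        test = list(self.subsets[spec["test"]])
        return train, val, test


def make_fold_plan(
    patient_ids: Sequence,
    n_folds: int = 5,
    seed: int = 0,
    stratify_by: Mapping | None = None,
) -> FoldPlan:
    """Seeded partition into ``n_folds`` near-equal subsets with rotation.

    ``stratify_by`` optionally maps patient id -> label (e.g. specimen
    type); labels are balanced across subsets by round-robin within label.
    Fold f uses subset f as test, subset (f+1) mod n as validation, the
    rest as training.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    if stratify_by is not None:
        by_label: dict = {}
        for pid in order:
            by_label.setdefault(stratify_by[pid], []).append(pid)
        order = [pid for label in sorted(by_label, key=str) for pid in by_label[label]]
    subsets: list[list] = [[] for _ in range(n_folds)]
    for i, pid in enumerate(order):
        subsets[i % n_folds].append(pid)
    folds = tuple(
        {
            "test": f,
            "val": (f + 1) % n_folds,
            "train": tuple(s for s in range(n_folds) if s not in (f, (f + 1) % n_folds)),
        }
        for f in range(n_folds)
    )
    return FoldPlan(subsets=tuple(tuple(s) for s in subsets), folds=folds)


@dataclasses.dataclass(frozen=True)
class CVResult:
    per_fold: tuple[MetricSet, ...]
    mean: MetricSet
    sd: MetricSet


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def cross_validate(
    patches_by_patient: Mapping,
    config,
    plan: FoldPlan,
    detector_factory: Callable | None = None,
    radius: float = DEFAULT_RADIUS,
) -> CVResult:
    """Patient-grouped k-fold cross-validation of a point detector.

    ``patches_by_patient`` maps patient id -> list of rendered patches
    (objects with ``.image`` and ``.viable_points``). For each fold a
    detector is trained on the train subsets with per-epoch selection on
    the validation subset, then evaluated on the test subset by pooling
    tp/fp/fn over its patches. ``detector_factory(train, val, config)``
    must return a callable ``patch -> predicted PointSet``; by default the
    heatmap-regression detector from :mod:`viadens.detect` is trained.
    """
    if detector_factory is None:
        from .detect import trained_detector_factory

        detector_factory = trained_detector_factory

    for f in range(plan.n_folds):
        for pid in (pid for ids in plan.fold_ids(f) for pid in ids):
            if pid not in patches_by_patient:
                raise ValueError(f"patient {pid!r} in the fold plan has no patches")

    per_fold = []
    for f in range(plan.n_folds):
        train_ids, val_ids, test_ids = plan.fold_ids(f)
        train = [p for pid in train_ids for p in patches_by_patient[pid]]
        val = [p for pid in val_ids for p in patches_by_patient[pid]]
        test = [p for pid in test_ids for p in patches_by_patient[pid]]
        if not test:
            raise ValueError(f"fold {f} has zero test patches")
        fold_config = copy.deepcopy(config)
        detector = detector_factory(train, val, fold_config)
        tp = fp = fn = 0
        for patch in test:
            m = match_points(detector(patch), patch.viable_points, radius=radius)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        per_fold.append(metric_set(MatchResult(tp=tp, fp=fp, fn=fn, pairs=())))

    p_mean, p_sd = _mean_sd([m.precision for m in per_fold])
    r_mean, r_sd = _mean_sd([m.recall for m in per_fold])
    f_mean, f_sd = _mean_sd([m.f_measure for m in per_fold])
    return CVResult(
        per_fold=tuple(per_fold),
        mean=MetricSet(p_mean, r_mean, f_mean),
        sd=MetricSet(p_sd, r_sd, f_sd),
    )
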