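"""Double-loop cross-validated one-vs-rest SVM signature discovery.

Each (cyto)genetic subtype is treated as an independent binary task:
subtype vs all other samples.  One DLCV run draws a fresh stratified outer
k-fold of the cohort; on every outer-training set an inner stratified
cross-validation picks the signature size m* from a fixed grid, features
are ranked by the absolute Welch t statistic on the outer-training set
only, the top m* features are standardized (training parameters) and a
linear soft-margin SVM is fitted, and the held-out outer fold is scored.
Pooled confusion counts per run yield sensitivity/specificity/PPV/NPV/
accuracy; the report averages those per-run metrics over runs.  A feature's
selection frequency is the fraction of outer-training fits whose final
model contained it; the subtype signature is the set of features with
frequency >= tau, capped at the median m*.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import ExpressionMatrix, PipelineConfig, SampleAnnotation, SUBTYPES

logger = logging.getLogger("mirsig")

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add_predictions(self, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        self.tp += int(((y_true == 1) & (y_pred == 1)).sum())
        self.fp += int(((y_true == 0) & (y_pred == 1)).sum())
        self.tn += int(((y_true == 0) & (y_pred == 0)).sum())
        self.fn += int(((y_true == 1) & (y_pred == 0)).sum())


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Percent metrics from confusion counts.

    A zero-denominator ratio is returned as NaN (flagged undefined), never
    silently coerced to 0.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "accuracy": 100.0 * (c.tp + c.tn) / c.total,
    }


def rank_features(
    values: np.ndarray, y: np.ndarray, feature_ids: list[str]
) -> np.ndarray:
    """Feature indices ordered by decreasing |Welch t| between classes.

    Zero pooled-variance features with a nonzero mean gap rank first
    (statistic +inf); features identical in both classes get statistic 0.
    Ties break on feature_id lexicographic order.
    """
    y = np.asarray(y).astype(int)
    pos, neg = values[:, y == 1], values[:, y == 0]
    n1, n0 = pos.shape[1], neg.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs at least 2 samples for Welch ranking")
    gap = pos.mean(axis=1) - neg.mean(axis=1)
    se2 = pos.var(axis=1, ddof=1) / n1 + neg.var(axis=1, ddof=1) / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(gap) / np.sqrt(se2)
    t = np.where(se2 == 0, np.where(gap == 0, 0.0, np.inf), t)
    order = sorted(range(len(feature_ids)), key=lambda i: (-t[i], feature_ids[i]))
    return np.asarray(order, dtype=int)


@dataclass
class FoldModel:
    """One trained fold: selected features, scaler, linear SVM parameters."""

    feature_idx: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray
    intercept: float
    m_star: int | None = None

    def decision_function(self, values: np.ndarray) -> np.ndarray:
        z = (values[self.feature_idx, :].T - self.mean) / self.sd
        return z @ self.coef + self.intercept

    def predict(self, values: np.ndarray) -> np.ndarray:
        return (self.decision_function(values) > 0).astype(int)


def train_ovr_svm(
    values: np.ndarray,
    y: np.ndarray,
    feature_idx: np.ndarray,
    c: float = 1.0,
    class_weight: str | None = None,
) -> FoldModel:
    """Fit a linear SVM on standardized selected features (deterministic)."""
    feature_idx = np.asarray(feature_idx, dtype=int)
    if feature_idx.size == 0:
        raise ValueError("empty feature subset")
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x = values[feature_idx, :].T  # samples x features
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd
    clf = SVC(kernel="linear", C=c, class_weight=class_weight)
    clf.fit(z, y)
    return FoldModel(
        feature_idx=feature_idx,
        mean=mean,
        sd=sd,
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
    )


def inner_loop_select(
    values: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    feature_grid: tuple[int, ...],
    inner_folds: int,
    seed: int,
    c: float = 1.0,
    class_weight: str | None = None,
) -> tuple[int, dict[int, float]]:
    """Pick the signature size m* by inner stratified cross-validation.

    For each m in the grid (truncated to the feature count), features are
    ranked on each inner-training split and the top m are used to train and
    score the inner test split; m* maximizes the pooled inner-test accuracy.
    Ties go to the LARGEST m: once accuracy saturates the data cannot
    distinguish sizes, and the larger set is the more redundant, hence more
    robust to cross-platform feature loss.  If a class is too small for the
    requested fold count, the split is refolded with fewer folds (warned);
    below 2 usable folds it is an error.
    """
    y = np.asarray(y).astype(int)
    grid = [m for m in feature_grid if m <= values.shape[0]]
    if not grid:
        raise ValueError("feature grid empty after truncation to feature count")
    n_min = int(min((y == 1).sum(), (y == 0).sum()))
    folds = min(inner_folds, n_min)
    if folds < 2:
        raise ValueError("cannot build stratified inner folds: a class has <2 samples")
    if folds < inner_folds:
        logger.warning("inner folds reduced from %d to %d", inner_folds, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = {m: 0 for m in grid}
    total = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        order = rank_features(values[:, train_idx], y[train_idx], feature_ids)
        total += len(test_idx)
        for m in grid:
            model = train_ovr_svm(
                values[:, train_idx], y[train_idx], order[:m], c=c, class_weight=class_weight
            )
            pred = model.predict(values[:, test_idx])
            correct[m] += int((pred == y[test_idx]).sum())
    scores = {m: correct[m] / total for m in grid}
    best = max(scores.values())
    m_star = max(m for m in grid if scores[m] == best)
    return m_star, scores


def train_outer_fold(
    values: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    feature_ids: list[str],
    config: PipelineConfig,
    fold_seed: int,
) -> FoldModel:
    """Train one outer fold end to end (selection, ranking, fit).

    A pure function of the training rows and the fold seed: held-out
    samples cannot influence the model.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    m_star, _ = inner_loop_select(
        values[:, train_idx],
        y[train_idx],
        feature_ids,
        config.feature_grid,
        config.inner_folds,
        fold_seed,
        c=config.svm_c,
        class_weight=config.class_weight,
    )
    order = rank_features(values[:, train_idx], y[train_idx], feature_ids)
    model = train_ovr_svm(
        values[:, train_idx], y[train_idx], order[:m_star],
        c=config.svm_c, class_weight=config.class_weight,
    )
    model.m_star = m_star
    return model


@dataclass
class SubtypeSignature:
    """Selected miRNAs for one subtype with direction and stability."""

    subtype: str
    members: list[tuple[str, str, float]]  # (feature_id, direction, selection_frequency)

    def __post_init__(self) -> None:
        freqs = [q for _, _, q in self.members]
        if any(not 0 <= q <= 1 for q in freqs):
            raise ValueError("selection frequencies must lie in [0, 1]")
        if any(b > a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("members must be sorted by descending frequency")

    @property
    def size(self) -> int:
        return len(self.members)

    def feature_ids(self) -> list[str]:
        return [f for f, _, _ in self.members]


@dataclass
class DlcvReport:
    """Averaged per-run metrics, traces, and the chosen signature."""

    subtype: str
    n_runs: int
    mean_metrics: dict[str, float]
    per_run_metrics: dict[str, list[float]]
    pooled_confusion: ConfusionCounts
    selection_frequency: dict[str, float]
    m_star_values: list[int]
    chosen_signature: SubtypeSignature
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "subtype": self.subtype,
            "n_runs": self.n_runs,
            "rng_seed": self.rng_seed,
            "mean_metrics": self.mean_metrics,
            "per_run_metrics": self.per_run_metrics,
            "pooled_confusion": vars(self.pooled_confusion),
            "m_star_values": self.m_star_values,
            "selection_frequency": self.selection_frequency,
            "chosen_signature": [
                {"mirna": f, "direction": d, "frequency": q}
                for f, d, q in self.chosen_signature.members
            ],
        }


def signature_directions(
    x: ExpressionMatrix, a: SampleAnnotation, subtype: str
) -> dict[str, str]:
    """up/down per feature by the sign of (in-group - out-group) full-cohort mean."""
    y = a.binary_labels(subtype)
    gap = x.values[:, y == 1].mean(axis=1) - x.values[:, y == 0].mean(axis=1)
    return {f: ("up" if g >= 0 else "down") for f, g in zip(x.feature_ids, gap)}


def _subtype_seed_state(rng_seed: int, subtype: str, n: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(rng_seed), SUBTYPES.index(subtype)])
    return ss.generate_state(n) & 0x7FFFFFFF


def dlcv(
    x: ExpressionMatrix,
    a: SampleAnnotation,
    subtype: str,
    config: PipelineConfig,
) -> DlcvReport:
    """Run the full double-loop cross-validation for one subtype."""
    y = a.binary_labels(subtype)
    n_pos = int(y.sum())
    if n_pos < config.min_group_size:
        raise ValueError(
            f"subtype {subtype!r} has {n_pos} samples, below the minimum group size "
            f"{config.min_group_size}"
        )
    values = x.values
    n_fits = config.dlcv_runs * config.outer_folds
    seeds = _subtype_seed_state(config.rng_seed, subtype, config.dlcv_runs + n_fits)
    run_seeds, fold_seeds = seeds[: config.dlcv_runs], seeds[config.dlcv_runs :]

    counts = np.zeros(x.n_features, dtype=int)
    m_stars: list[int] = []
    per_run: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    pooled = ConfusionCounts()
    fit = 0
    for run in range(config.dlcv_runs):
        outer = StratifiedKFold(
            n_splits=config.outer_folds, shuffle=True, random_state=int(run_seeds[run])
        )
        run_counts = ConfusionCounts()
        for train_idx, test_idx in outer.split(np.zeros(len(y)), y):
            model = train_outer_fold(
                values, y, train_idx, x.feature_ids, config, int(fold_seeds[fit])
            )
            fit += 1
            pred = model.predict(values[:, test_idx])
            run_counts.add_predictions(y[test_idx], pred)
            counts[model.feature_idx] += 1
            m_stars.append(int(model.m_star))
        metrics = compute_metrics(run_counts)
        for m in METRIC_NAMES:
            per_run[m].append(metrics[m])
        pooled.tp += run_counts.tp
        pooled.fp += run_counts.fp
        pooled.tn += run_counts.tn
        pooled.fn += run_counts.fn

    freq_arr = counts / n_fits
    frequency = {f: float(q) for f, q in zip(x.feature_ids, freq_arr) if q > 0}
    directions = signature_directions(x, a, subtype)
    tau = config.selection_frequency_tau
    candidates = sorted(
        ((f, q) for f, q in frequency.items() if q >= tau),
        key=lambda fq: (-fq[1], fq[0]),
    )
    cap = int(statistics.median(m_stars))
    members = [(f, directions[f], q) for f, q in candidates[:cap]]
    signature = SubtypeSignature(subtype, members)

    mean_metrics = {
        m: float(np.nanmean(per_run[m])) if not all(math.isnan(v) for v in per_run[m]) else math.nan
        for m in METRIC_NAMES
    }
    return DlcvReport(
        subtype=subtype,
        n_runs=config.dlcv_runs,
        mean_metrics=mean_metrics,
        per_run_metrics=per_run,
        pooled_confusion=pooled,
        selection_frequency=frequency,
        m_star_values=m_stars,
        chosen_signature=signature,
        rng_seed=config.rng_seed,
    )


def dlcv_all(
    x: ExpressionMatrix,
    a: SampleAnnotation,
    config: PipelineConfig,
    subtypes: tuple[str, ...] = SUBTYPES,
) -> dict[str, DlcvReport]:
    """DLCV for every subtype meeting the minimum group size."""
    reports: dict[str, DlcvReport] = {}
    for st in subtypes:
        n_pos = int((a.subtype == st).sum())
        if n_pos < config.min_group_size:
            logger.warning(
                "skipping subtype %s: %d samples < minimum %d", st, n_pos, config.min_group_size
            )
            continue
        reports[st] = dlcv(x, a, st, config)
    return reports


def consolidate_signatures(
    signatures: dict[str, SubtypeSignature] | list[SubtypeSignature],
) -> dict:
    """De-duplicated union of signature members across subtypes.

    Each miRNA keeps its per-subtype direction entries; the union size is
    the number of distinct miRNAs.
    """
    if isinstance(signatures, dict):
        sigs = list(signatures.values())
    else:
        sigs = list(signatures)
    if not sigs:
        raise ValueError("no signatures to consolidate")
    union: dict[str, dict[str, dict]] = {}
    for sig in sigs:
        for f, d, q in sig.members:
            union.setdefault(f, {})[sig.subtype] = {"direction": d, "frequency": q}
    return {
        "union_size": len(union),
        "members": {f: union[f] for f in sorted(union)},
        "per_subtype_sizes": {sig.subtype: sig.size for sig in sigs},
    }
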