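"""Cross-platform validation of subtype signatures on an independent cohort.

The validation cohort typically comes from a different array platform, so
only part of each signature is measurable there.  Per subtype: intersect
the signature with the test platform's features (after miRNA-name
canonicalization), restrict both cohorts to the shared features,
standardize each cohort per feature within itself (absorbing additive
platform offsets), train the one-vs-rest SVM on the full training cohort,
and score every test sample.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, PipelineConfig, SampleAnnotation
from .dlcv import ConfusionCounts, SubtypeSignature, compute_metrics, train_ovr_svm

logger = logging.getLogger("mirsig")


def canonical_mirna(name: str) -> str:
    """Canonical miRNA name for cross-platform matching.

    Lowercases and strips whitespace and an organism prefix ("hsa-").  The
    star strand marker and -3p/-5p suffixes are preserved: miR-126 and
    miR-126* are distinct features.
    """
    s = str(name).strip().lower()
    s = re.sub(r"^hsa-", "", s)
    return s


@dataclass
class PlatformIntersection:
    """Which signature miRNAs are measurable on the test platform."""

    subtype: str
    requested: list[str]
    available: list[str]
    dropped: list[str]

    def __post_init__(self) -> None:
        if sorted(self.available + self.dropped) != sorted(self.requested):
            raise ValueError("available and dropped must partition requested")
        if set(self.available) & set(self.dropped):
            raise ValueError("available and dropped overlap")


def intersect_signature(
    sig: SubtypeSignature, platform_features: list[str]
) -> PlatformIntersection:
    """Exact-name intersection after canonicalization; deterministic."""
    platform = {canonical_mirna(f) for f in platform_features}
    available = [f for f in sig.feature_ids() if canonical_mirna(f) in platform]
    dropped = [f for f in sig.feature_ids() if canonical_mirna(f) not in platform]
    if not available:
        raise ValueError(
            f"signature for {sig.subtype!r} untestable on this platform: no shared miRNAs"
        )
    return PlatformIntersection(sig.subtype, sig.feature_ids(), available, dropped)


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mean) / sd


def cross_platform_validate(
    train_x: ExpressionMatrix,
    train_a: SampleAnnotation,
    test_x: ExpressionMatrix,
    test_a: SampleAnnotation,
    signatures: dict[str, SubtypeSignature],
    config: PipelineConfig,
    standardize: bool = True,
    min_test_positives: int = 5,
) -> dict[str, dict]:
    """Validate each subtype signature on the test cohort.

    Returns per subtype either a metrics dict (with the intersection
    bookkeeping) or a skip record with status "insufficient" (too few
    positive test samples) or "untestable" (no shared signature miRNAs).
    Subtypes are never silently scored or silently dropped.
    """
    results: dict[str, dict] = {}
    train_canon = {canonical_mirna(f): i for i, f in enumerate(train_x.feature_ids)}
    test_canon = {canonical_mirna(f): i for i, f in enumerate(test_x.feature_ids)}
    for subtype, sig in signatures.items():
        n_test_pos = int((test_a.subtype == subtype).sum())
        if n_test_pos < min_test_positives:
            logger.warning(
                "subtype %s skipped: %d positive test samples < %d",
                subtype, n_test_pos, min_test_positives,
            )
            results[subtype] = {
                "status": "insufficient",
                "n_test_positives": n_test_pos,
                "min_test_positives": min_test_positives,
            }
            continue
        try:
            inter = intersect_signature(sig, list(test_x.feature_ids))
        except ValueError:
            results[subtype] = {"status": "untestable", "n_shared_features": 0}
            continue
        shared = [f for f in inter.available if canonical_mirna(f) in train_canon]
        if not shared:
            results[subtype] = {"status": "untestable", "n_shared_features": 0}
            continue
        tr_idx = np.array([train_canon[canonical_mirna(f)] for f in shared])
        te_idx = np.array([test_canon[canonical_mirna(f)] for f in shared])
        tr_vals = train_x.values[tr_idx, :]
        te_vals = test_x.values[te_idx, :]
        if standardize:
            tr_vals = _standardize_rows(tr_vals)
            te_vals = _standardize_rows(te_vals)
        y_train = train_a.binary_labels(subtype)
        model = train_ovr_svm(
            tr_vals,
            y_train,
            np.arange(len(shared)),
            c=config.svm_c,
            class_weight=config.class_weight,
        )
        pred = model.predict(te_vals)
        counts = ConfusionCounts()
        counts.add_predictions(test_a.binary_labels(subtype), pred)
        results[subtype] = {
            "status": "scored",
            "metrics": compute_metrics(counts),
            "confusion": vars(counts),
            "n_shared_features": len(shared),
            "requested": inter.requested,
            "available": inter.available,
            "dropped": inter.dropped,
        }
    return results
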