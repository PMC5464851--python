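"""Core containers for the miRNA classification pipeline.

The pipeline operates on a log2-scale expression matrix (miRNAs in rows,
samples in columns) paired with a per-sample annotation carrying the
(cyto)genetic subtype label and optional clinical covariates.  Six AML
subtypes are modelled explicitly; everything else is pooled into ``other``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirsig")

#: Canonical subtype vocabulary: MLL/11q23 rearrangements, t(8;21)(q22;q22),
#: inv(16)(p13q22), t(15;17)(q21;q22), CEBPA double mutation, NPM1 mutation.
SUBTYPES: tuple[str, ...] = ("MLL", "t_8_21", "inv_16", "t_15_17", "CEBPA_dm", "NPM1")
OTHER = "other"
ALL_LABELS: tuple[str, ...] = SUBTYPES + (OTHER,)

#: Aliases from cytogenetic notation (as printed in clinical tables) to the
#: canonical tokens.  Lookup is case-insensitive on the stripped string.
SUBTYPE_ALIASES: dict[str, str] = {
    "mll": "MLL",
    "mll-r": "MLL",
    "mll-rearranged": "MLL",
    "11q23": "MLL",
    "11q23-rearranged": "MLL",
    "t(8;21)": "t_8_21",
    "t(8;21)(q22;q22)": "t_8_21",
    "t_8_21": "t_8_21",
    "inv(16)": "inv_16",
    "inv(16)(p13q22)": "inv_16",
    "inv_16": "inv_16",
    "t(15;17)": "t_15_17",
    "t(15;17)(q21;q22)": "t_15_17",
    "t_15_17": "t_15_17",
    "cebpa": "CEBPA_dm",
    "cebpa-dm": "CEBPA_dm",
    "cebpa.dm": "CEBPA_dm",
    "cepba.dm": "CEBPA_dm",  # spelling as printed in some tables
    "cebpa_dm": "CEBPA_dm",
    "cebpa double mutation": "CEBPA_dm",
    "npm1": "NPM1",
    "npm1-mut": "NPM1",
    "npm1 mutation": "NPM1",
    "other": OTHER,
}


def canonical_subtype(label: str) -> str:
    """Map a subtype string to the canonical vocabulary.

    Unknown labels map to ``other`` (with a warning at the call sites that
    read user files); the vocabulary is closed.
    """
    s = str(label).strip()
    if s in ALL_LABELS:
        return s
    return SUBTYPE_ALIASES.get(s.lower(), OTHER)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, features x samples.

    ``missing_mask`` is True where the value was undetected in the raw data
    (before any imputation); values under the mask may be non-finite.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.feature_ids), len(self.sample_ids))
        if self.values.shape != shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.missing_mask is None:
            self.missing_mask = np.zeros(shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != shape:
                raise ValueError("missing_mask shape does not match values")
        bad = ~np.isfinite(self.values) & ~self.missing_mask
        if bad.any():
            f, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value outside missing_mask at "
                f"({self.feature_ids[f]}, {self.sample_ids[s]})"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def subset_features(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
            self.missing_mask[idx, :],
        )

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
            self.values[:, idx],
            self.missing_mask[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Per-sample subtype labels plus optional covariates.

    Covariates are either continuous (float arrays, NaN = missing) or
    categorical (object arrays of strings; the tri-state convention
    present/absent/untested is just three category values).
    """

    sample_ids: list[str]
    subtype: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.subtype = np.asarray(self.subtype, dtype=object)
        if self.subtype.shape != (len(self.sample_ids),):
            raise ValueError("subtype length does not match sample_ids")
        for lab in self.subtype:
            if lab not in ALL_LABELS:
                raise ValueError(f"subtype {lab!r} outside closed vocabulary {ALL_LABELS}")
        for name, col in self.covariates.items():
            col = np.asarray(col)
            if col.shape != (len(self.sample_ids),):
                raise ValueError(f"covariate {name!r} length mismatch")
            self.covariates[name] = col

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: Sequence[int]) -> "SampleAnnotation":
        idx = np.asarray(idx, dtype=int)
        return SampleAnnotation(
            [self.sample_ids[i] for i in idx],
            self.subtype[idx],
            {k: v[idx] for k, v in self.covariates.items()},
        )

    def binary_labels(self, subtype: str) -> np.ndarray:
        """0/1 vector for a one-vs-rest task."""
        if subtype not in ALL_LABELS:
            raise ValueError(f"unknown subtype {subtype!r}")
        return (self.subtype == subtype).astype(int)


#: Default signature-size grid searched by the inner cross-validation loop.
DEFAULT_FEATURE_GRID: tuple[int, ...] = (1, 2, 3, 5, 8, 12, 18, 27, 40, 60)


@dataclass
class PipelineConfig:
    """Fixed constants of the analysis.

    Defaults are the study's stated constants: a 6-fold deviation filter,
    14 sample clusters, 100 double-loop cross-validation runs, a minimum
    subtype size of 10 for classification, and a 3-of-5-database consensus
    rule for target calls.
    """

    filter_fold_threshold: float = 6.0
    n_clusters: int = 14
    dlcv_runs: int = 100
    outer_folds: int = 3
    inner_folds: int = 5
    feature_grid: tuple[int, ...] = DEFAULT_FEATURE_GRID
    selection_frequency_tau: float = 0.5
    min_group_size: int = 10
    consensus_min_support: int = 3
    rng_seed: int = 0
    svm_c: float = 1.0
    class_weight: str | None = None  # None or "balanced"
    linkage_method: str = "ward_d"  # "ward_d" | "ward_d2"

    def __post_init__(self) -> None:
        if self.filter_fold_threshold <= 1:
            raise ValueError("filter_fold_threshold must exceed 1")
        for name in ("n_clusters", "dlcv_runs", "min_group_size", "consensus_min_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        grid = tuple(int(m) for m in self.feature_grid)
        if not grid or any(m <= 0 for m in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("feature_grid must be a strictly increasing positive sequence")
        self.feature_grid = grid
        if not 0 < self.selection_frequency_tau <= 1:
            raise ValueError("selection_frequency_tau must lie in (0, 1]")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.class_weight not in (None, "balanced"):
            raise ValueError("class_weight must be None or 'balanced'")
        if self.linkage_method not in ("ward_d", "ward_d2"):
            raise ValueError("linkage_method must be 'ward_d' or 'ward_d2'")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["feature_grid"] = list(self.feature_grid)
        return d


def effect_from_fold(fold: float) -> float:
    """log2 effect size corresponding to a linear fold change."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    return math.log2(fold)
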