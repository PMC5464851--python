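"""Synthetic miRNA cohorts with planted subtype signatures.

The generator emulates the structure of a 165-sample pediatric AML cohort
profiled on a ~664-miRNA array: six (cyto)genetic subtypes of fixed sizes
plus an ``other`` remainder, each subtype carrying a block of up/down
regulated signature miRNAs of the sizes reported for the real cohort
(37/14/17/14/18/5).  Values are Gaussian on the log2 scale: a per-miRNA
baseline shared by all samples, a signed subtype effect on signature
miRNAs, and i.i.d. measurement noise.  The lowest fraction of cells
(``missing_rate``) is "undetected" — left-censored at the detection limit
and imputed at the cohort floor, as Ct arrays censor low-abundance
transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .datatypes import ExpressionMatrix, SampleAnnotation, SUBTYPES

DEFAULT_GROUP_SIZES: dict[str, int] = {
    "MLL": 36,
    "t_8_21": 21,
    "inv_16": 17,
    "t_15_17": 12,
    "CEBPA_dm": 11,
    "NPM1": 11,
    "other": 57,
}

DEFAULT_SIGNATURE_SIZES: dict[str, int] = {
    "MLL": 37,
    "t_8_21": 14,
    "inv_16": 17,
    "t_15_17": 14,
    "CEBPA_dm": 18,
    "NPM1": 5,
}


@dataclass
class CohortDesign:
    """Parameters of one synthetic cohort.

    ``effect_log2`` defaults to log2(6): signature miRNAs sit one
    filter-threshold fold above or below their baseline in their own
    subtype.  ``direction_mix`` is the fraction of up-regulated members per
    signature.
    """

    n_features: int = 664
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    signature_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_SIZES)
    )
    effect_log2: float = math.log2(6.0)
    direction_mix: float = 0.5
    baseline_sd: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    allow_overlap: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for st in self.signature_sizes:
            if st not in SUBTYPES:
                raise ValueError(f"signature for unknown subtype {st!r}")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be nonnegative")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not self.allow_overlap and sum(self.signature_sizes.values()) > self.n_features:
            raise ValueError("disjoint signature sizes exceed n_features")
        if self.allow_overlap and max(self.signature_sizes.values(), default=0) > self.n_features:
            raise ValueError("a signature size exceeds n_features")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class GroundTruth:
    """What was planted: signature membership with directions, and labels."""

    planted_signatures: dict[str, list[tuple[str, str]]]
    sample_labels: list[str]

    def signature_features(self, subtype: str) -> list[str]:
        return [f for f, _ in self.planted_signatures[subtype]]


def _plant_signatures(
    design: CohortDesign, feature_ids: list[str], rng: np.random.Generator
) -> dict[str, list[tuple[str, str]]]:
    planted: dict[str, list[tuple[str, str]]] = {}
    order = [st for st in SUBTYPES if st in design.signature_sizes]
    if design.allow_overlap:
        pools = {
            st: rng.choice(design.n_features, size=design.signature_sizes[st], replace=False)
            for st in order
        }
    else:
        total = sum(design.signature_sizes[st] for st in order)
        chosen = rng.choice(design.n_features, size=total, replace=False)
        pools, at = {}, 0
        for st in order:
            k = design.signature_sizes[st]
            pools[st] = chosen[at : at + k]
            at += k
    for st in order:
        idx = np.sort(pools[st])
        n_up = int(round(design.direction_mix * len(idx)))
        up_pos = rng.permutation(len(idx))[:n_up]
        directions = np.full(len(idx), "down", dtype=object)
        directions[up_pos] = "up"
        planted[st] = [(feature_ids[i], d) for i, d in zip(idx, directions)]
    return planted


def generate_cohort(
    design: CohortDesign, truth: GroundTruth | None = None
) -> tuple[ExpressionMatrix, SampleAnnotation, GroundTruth]:
    """Draw one cohort; identical (design, seed) gives identical output.

    Pass an existing ``truth`` to draw an independent cohort sharing the
    same planted signature features and directions (a replication cohort).
    """
    rng = np.random.default_rng(design.rng_seed)
    n_feat, n_samp = design.n_features, design.n_samples
    feature_ids = [f"miR-{i + 1:04d}" for i in range(n_feat)]
    if truth is None:
        planted = _plant_signatures(design, feature_ids, rng)
    else:
        planted = {st: list(members) for st, members in truth.planted_signatures.items()}
        fset = set(feature_ids)
        for st, members in planted.items():
            for f, _ in members:
                if f not in fset:
                    raise ValueError(f"planted feature {f!r} absent from generated matrix")

    labels: list[str] = []
    for st, size in design.group_sizes.items():
        labels.extend([st] * size)
    sample_ids = [f"P{i + 1:03d}" for i in range(n_samp)]

    baseline = rng.normal(0.0, design.baseline_sd, size=n_feat)
    values = baseline[:, None] + rng.normal(0.0, design.noise_sd, size=(n_feat, n_samp))

    fidx = {f: i for i, f in enumerate(feature_ids)}
    label_arr = np.array(labels, dtype=object)
    for st, members in planted.items():
        cols = np.flatnonzero(label_arr == st)
        if cols.size == 0:
            continue
        for f, direction in members:
            sign = 1.0 if direction == "up" else -1.0
            values[fidx[f], cols] += sign * design.effect_log2

    # Undetected values are left-censored at the detection limit: the lowest
    # missing_rate fraction of cells falls below the limit and is imputed at
    # the cohort floor (the censoring threshold itself).  This mirrors how
    # low-abundance transcripts go undetected on Ct arrays; undetected cells
    # are never random high-abundance measurements.
    mask = np.zeros((n_feat, n_samp), dtype=bool)
    if design.missing_rate > 0:
        floor = float(np.quantile(values, design.missing_rate))
        mask = values < floor
        values = values.copy()
        values[mask] = floor

    x = ExpressionMatrix(feature_ids, sample_ids, values, mask)
    ann = SampleAnnotation(sample_ids, label_arr)
    return x, ann, GroundTruth(planted, labels)


def generate_paired_mrna(
    truth: GroundTruth,
    mirna: ExpressionMatrix,
    coupling: float = -1.0,
    n_targets_per_mirna: int = 3,
    noise_sd: float = 1.0,
    rng_seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Synthetic target-gene expression anti-coupled to signature miRNAs.

    Each target gene g of miRNA m follows expr(g) = coupling * expr(m) +
    Normal(0, noise_sd); coupling must be <= 0 (repression).
    """
    if coupling > 0:
        raise ValueError("coupling must be <= 0")
    if n_targets_per_mirna <= 0:
        raise ValueError("n_targets_per_mirna must be positive")
    rng = np.random.default_rng(rng_seed)
    fidx = mirna.feature_index()
    mirnas = sorted({f for members in truth.planted_signatures.values() for f, _ in members})
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    target_map: dict[str, list[str]] = {}
    for m in mirnas:
        if m not in fidx:
            continue
        profile = mirna.values[fidx[m], :]
        genes = [f"{m}_target{j + 1}" for j in range(n_targets_per_mirna)]
        target_map[m] = genes
        for g in genes:
            gene_ids.append(g)
            rows.append(coupling * profile + rng.normal(0.0, noise_sd, size=profile.shape))
    mrna = ExpressionMatrix(gene_ids, list(mirna.sample_ids), np.vstack(rows))
    return mrna, target_map


def generate_second_platform(
    x: ExpressionMatrix,
    keep_fraction: float = 0.6,
    shift_sd: float = 2.0,
    rng_seed: int = 0,
) -> ExpressionMatrix:
    """Re-measure a cohort on a partial platform with per-feature offsets.

    A uniform random floor(keep_fraction * n_features) subset of features is
    retained; each kept feature gains an additive Normal(0, shift_sd) batch
    offset shared by all samples.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if shift_sd < 0:
        raise ValueError("shift_sd must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    n_keep = int(math.floor(keep_fraction * x.n_features))
    if n_keep == 0:
        raise ValueError("keep_fraction leaves no features")
    keep = np.sort(rng.choice(x.n_features, size=n_keep, replace=False))
    out = x.subset_features(keep)
    offsets = rng.normal(0.0, shift_sd, size=n_keep) if shift_sd > 0 else np.zeros(n_keep)
    out.values = out.values + offsets[:, None]
    return out
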