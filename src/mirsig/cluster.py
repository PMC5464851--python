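"""Unsupervised structure: Ward clustering on Pearson distances, enrichment.

Samples are clustered agglomeratively on d = 1 - r, where r is the Pearson
correlation between sample profiles across (feature-centered) miRNAs, using
Ward's minimum-variance linkage.  Clusters are then examined for
over-representation of subtype labels and categorical covariates
(one-sided hypergeometric test) and for shifts in continuous covariates
such as age and white-blood-cell count (Wilcoxon rank-sum), with
Benjamini-Hochberg adjustment within each label family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SampleAnnotation


@dataclass
class ClusterResult:
    """Merge history, flat assignments at k, and the correlation matrix."""

    linkage_tree: np.ndarray  # scipy linkage matrix, (n-1) x 4
    assignments: np.ndarray  # per-sample cluster index in 1..k
    correlation_matrix: np.ndarray
    k: int
    sample_ids: list[str]

    def cluster_members(self, cluster: int) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.assignments) if c == cluster]


def pearson_distance(x: ExpressionMatrix) -> np.ndarray:
    """Sample-sample distance d(i,j) = 1 - Pearson r of profiles.

    Errors on a zero-variance sample profile (correlation undefined).
    """
    profiles = x.values.T  # samples x features
    sd = profiles.std(axis=1)
    if (sd == 0).any():
        s = x.sample_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"sample {s!r} has a zero-variance profile")
    r = np.corrcoef(profiles)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def ward_linkage(d: np.ndarray, method: str = "ward_d") -> np.ndarray:
    """Ward agglomeration of a distance matrix.

    ``ward_d`` applies the Lance-Williams minimum-variance update to the
    dissimilarities as given (R hclust's ward.D); ``ward_d2`` applies it to
    their squares (ward.D2).  scipy's ward operates on squared input, so
    ward_d is obtained by feeding sqrt(d) and squaring the merge heights;
    both conventions produce the same tree topology on the same input only
    up to the monotone transform, so cut partitions of ward_d match a
    direct Lance-Williams implementation on d.
    """
    if method not in ("ward_d", "ward_d2"):
        raise ValueError("method must be 'ward_d' or 'ward_d2'")
    condensed = squareform(d, checks=False)
    if method == "ward_d":
        z = linkage(np.sqrt(condensed), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    else:
        z = linkage(condensed, method="ward")
    return z


def ward_cluster(
    d: np.ndarray,
    k: int,
    sample_ids: list[str] | None = None,
    correlation_matrix: np.ndarray | None = None,
    method: str = "ward_d",
) -> ClusterResult:
    """Cut the Ward tree of a distance matrix into k flat clusters."""
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    z = ward_linkage(d, method=method)
    assignments = fcluster(z, t=k, criterion="maxclust")
    if correlation_matrix is None:
        correlation_matrix = 1.0 - d
    return ClusterResult(z, assignments, correlation_matrix, k, list(sample_ids))


def cluster_samples(
    x: ExpressionMatrix,
    k: int,
    center_features: bool = True,
    method: str = "ward_d",
) -> ClusterResult:
    """Full clustering stage: (center features,) Pearson distance, Ward, cut.

    Feature centering removes per-miRNA baseline abundance so that sample
    correlations reflect relative regulation rather than the shared
    abundance profile.
    """
    if center_features:
        x = ExpressionMatrix(
            list(x.feature_ids),
            list(x.sample_ids),
            x.values - x.values.mean(axis=1, keepdims=True),
            x.missing_mask,
        )
    d = pearson_distance(x)
    return ward_cluster(d, k, sample_ids=x.sample_ids, correlation_matrix=1.0 - d, method=method)


def feature_order(x: ExpressionMatrix, method: str = "ward_d") -> list[str]:
    """Heatmap row order: leaf order of the feature-feature correlation tree."""
    profiles = x.values
    sd = profiles.std(axis=1)
    keep = sd > 0
    r = np.corrcoef(profiles[keep])
    z = ward_linkage(np.clip(1.0 - r, 0, 2), method=method)
    kept_ids = [f for f, m in zip(x.feature_ids, keep) if m]
    ordered = [kept_ids[i] for i in leaves_list(z)]
    ordered += [f for f, m in zip(x.feature_ids, keep) if not m]
    return ordered


def cluster_enrichment(c: ClusterResult, a: SampleAnnotation) -> pd.DataFrame:
    """Per-cluster enrichment table.

    Categorical families (the subtype label and categorical covariates):
    one-sided hypergeometric tail P(X >= count_in_cluster) for each
    (cluster, level).  Continuous covariates: two-sided Wilcoxon rank-sum of
    in-cluster vs out-of-cluster values.  BH adjustment is applied within
    each family.
    """
    if list(c.sample_ids) != list(a.sample_ids):
        raise ValueError("cluster result and annotation are not sample-aligned")
    n = len(c.sample_ids)
    clusters = sorted(set(int(v) for v in c.assignments))
    rows: list[dict] = []

    families: dict[str, np.ndarray] = {"subtype": a.subtype}
    cont: dict[str, np.ndarray] = {}
    for name, col in a.covariates.items():
        if np.issubdtype(np.asarray(col).dtype, np.number):
            cont[name] = np.asarray(col, dtype=float)
        else:
            families[name] = np.asarray(col, dtype=object)

    for fam, labels in families.items():
        valid = np.array([lab is not None and str(lab) != "" for lab in labels])
        levels = sorted({str(lab) for lab, ok in zip(labels, valid) if ok})
        for level in levels:
            is_level = np.array([str(lab) == level for lab in labels]) & valid
            count_total = int(is_level.sum())
            for cl in clusters:
                in_cl = c.assignments == cl
                count_in = int((is_level & in_cl).sum())
                p = float(hypergeom.sf(count_in - 1, n, count_total, int(in_cl.sum())))
                rows.append(
                    {
                        "cluster": cl,
                        "family": fam,
                        "level": level,
                        "count_in_cluster": count_in,
                        "cluster_size": int(in_cl.sum()),
                        "count_total": count_total,
                        "n_total": n,
                        "p_value": min(p, 1.0),
                    }
                )
    for fam, valsf in cont.items():
        ok = np.isfinite(valsf)
        if not ok.any():
            logging.getLogger("mirsig").warning("covariate %r entirely missing; skipped", fam)
            continue
        for cl in clusters:
            in_cl = (c.assignments == cl) & ok
            out_cl = (c.assignments != cl) & ok
            if in_cl.sum() == 0 or out_cl.sum() == 0:
                continue
            stat = mannwhitneyu(valsf[in_cl], valsf[out_cl], alternative="two-sided")
            rows.append(
                {
                    "cluster": cl,
                    "family": fam,
                    "level": "(continuous)",
                    "count_in_cluster": int(in_cl.sum()),
                    "cluster_size": int((c.assignments == cl).sum()),
                    "count_total": int(ok.sum()),
                    "n_total": n,
                    "p_value": float(stat.pvalue),
                }
            )

    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["adjusted_p"] = np.nan
    for fam in table["family"].unique():
        sel = table["family"] == fam
        table.loc[sel, "adjusted_p"] = multipletests(
            table.loc[sel, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    # BH can only raise p-values
    table["adjusted_p"] = np.maximum(table["adjusted_p"], table["p_value"])
    return table.sort_values(["family", "level", "cluster"]).reset_index(drop=True)
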