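"""Consensus miRNA-target calls and inverse-correlation screening.

A (miRNA, gene) pair is called a target when at least ``min_support`` of
the prediction databases report it (the study used 3 of 5).  Called pairs
are then screened on paired expression data: a repressing miRNA should be
inversely correlated with its target, so each tested pair gets a rank
correlation across shared samples and a consistency flag (correlation < 0),
with Benjamini-Hochberg adjustment across tested pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


@dataclass
class TargetDatabaseSet:
    """Named prediction databases, each a set of (mirna_id, gene_id) pairs."""

    databases: dict[str, set[tuple[str, str]]]

    def __post_init__(self) -> None:
        for name, pairs in self.databases.items():
            self.databases[name] = {(str(m), str(g)) for m, g in pairs}

    @property
    def n_databases(self) -> int:
        return len(self.databases)

    @classmethod
    def from_tsv_files(cls, files: dict[str, str | Path]) -> "TargetDatabaseSet":
        """One two-column TSV (mirna_id, gene_id) per database."""
        dbs: dict[str, set[tuple[str, str]]] = {}
        for name, path in files.items():
            df = pd.read_csv(path, sep="\t", dtype=str)
            if df.shape[1] < 2:
                raise ValueError(f"database {name!r}: expected two columns")
            dbs[name] = set(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return cls(dbs)


@dataclass
class ConsensusCall:
    mirna_id: str
    gene_id: str
    support: int
    is_target: bool


def consensus_targets(
    dbs: TargetDatabaseSet, min_support: int = 3
) -> list[ConsensusCall]:
    """One call per distinct pair seen anywhere; is_target iff support >= min.

    Output sorted by (mirna, descending support, gene).
    """
    if not 1 <= min_support <= dbs.n_databases:
        raise ValueError(
            f"min_support {min_support} outside 1..{dbs.n_databases} databases"
        )
    support: dict[tuple[str, str], int] = {}
    for pairs in dbs.databases.values():
        for pair in pairs:
            support[pair] = support.get(pair, 0) + 1
    calls = [
        ConsensusCall(m, g, s, s >= min_support) for (m, g), s in support.items()
    ]
    calls.sort(key=lambda c: (c.mirna_id, -c.support, c.gene_id))
    return calls


def calls_to_frame(calls: list[ConsensusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mirna_id": c.mirna_id, "gene_id": c.gene_id, "support": c.support,
             "is_target": c.is_target}
            for c in calls
        ]
    )


def inverse_correlation(
    mirna_x: ExpressionMatrix,
    mrna_x: ExpressionMatrix,
    calls: list[ConsensusCall],
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate each called target pair across shared samples.

    Rank (Spearman) correlation by default; ``method="pearson"`` for the
    linear coefficient.  Pairs whose miRNA or gene is absent from the
    matrices are listed as untested.  Errors with fewer than 4 shared
    samples.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    shared = [s for s in mirna_x.sample_ids if s in set(mrna_x.sample_ids)]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; need at least 4")
    mi_pos = {s: i for i, s in enumerate(mirna_x.sample_ids)}
    mr_pos = {s: i for i, s in enumerate(mrna_x.sample_ids)}
    mi_cols = [mi_pos[s] for s in shared]
    mr_cols = [mr_pos[s] for s in shared]
    mi_idx = mirna_x.feature_index()
    mr_idx = mrna_x.feature_index()

    rows: list[dict] = []
    for call in calls:
        if not call.is_target:
            continue
        row: dict = {"mirna_id": call.mirna_id, "gene_id": call.gene_id,
                     "support": call.support}
        if call.mirna_id not in mi_idx or call.gene_id not in mr_idx:
            row.update(tested=False, correlation=np.nan, p_value=np.nan,
                       consistent=False)
        else:
            a = mirna_x.values[mi_idx[call.mirna_id], mi_cols]
            b = mrna_x.values[mr_idx[call.gene_id], mr_cols]
            if method == "spearman":
                r, p = spearmanr(a, b)
            else:
                r, p = pearsonr(a, b)
            row.update(tested=True, correlation=float(r), p_value=float(p),
                       consistent=bool(r < 0))
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["adjusted_p"] = np.nan
    tested = table["tested"].to_numpy(dtype=bool)
    if tested.any():
        table.loc[tested, "adjusted_p"] = multipletests(
            table.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return table
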