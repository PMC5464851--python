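"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and annotations travel as TSV; signatures and run
reports as JSON.  JSON output is canonical (sorted keys, fixed indent) so
that identical computations produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleAnnotation, canonical_subtype, ALL_LABELS

logger = logging.getLogger("mirsig")

MISSING_TOKEN = "NA"


def _validate_rectangular(path: Path) -> None:
    """Hard error, with the 1-based line number, on ragged TSV rows."""
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = n
            elif n != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} ({n} fields, expected {width})"
                )


def read_expression_matrix(
    path: str | Path,
    orientation: str = "features_in_rows",
    missing_token: str = MISSING_TOKEN,
) -> ExpressionMatrix:
    """Read a TSV expression matrix into features x samples orientation.

    The file has one header row and one identifier column; cells are numeric
    or ``missing_token``.  ``orientation`` says what the file's rows are.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[missing_token],
        keep_default_na=False, float_precision="round_trip",
    )
    for axis_ids, what in ((df.index, "row"), (df.columns, "column")):
        dup = axis_ids[axis_ids.duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicate {what} identifier: {dup[0]!r}")
    if orientation == "samples_in_rows":
        df = df.T
    values = df.to_numpy(dtype=float)
    mask = np.isnan(values)
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values, mask)


def write_expression_matrix(
    x: ExpressionMatrix,
    path: str | Path,
    missing_token: str = MISSING_TOKEN,
    mask_as_token: bool = True,
) -> None:
    """Write a matrix as TSV (features in rows).

    With ``mask_as_token`` (default) masked cells are written as the missing
    token; pass False to persist already-imputed values instead (the mask is
    then not recoverable from the file).
    """
    df = x.to_frame().astype(object)
    if mask_as_token:
        df = df.where(~x.missing_mask, other=missing_token)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation TSV (columns: sample_id, subtype, covariates...).

    Subtype strings outside the closed vocabulary (after alias mapping) fall
    back to ``other`` with a logged warning.
    """
    path = Path(path)
    _validate_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    if "subtype" not in df.columns:
        raise ValueError(f"{path}: missing required column 'subtype'")
    subtypes = []
    for raw in df["subtype"]:
        mapped = canonical_subtype(raw)
        if mapped == "other" and str(raw).strip().lower() not in ("other", ""):
            logger.warning("unknown subtype %r mapped to 'other'", raw)
        subtypes.append(mapped)
    covariates: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col in ("sample_id", "subtype"):
            continue
        raw = df[col].replace({"": np.nan, MISSING_TOKEN: np.nan})
        numeric = pd.to_numeric(raw, errors="coerce")
        if numeric.notna().sum() == raw.notna().sum() and raw.notna().any():
            covariates[col] = numeric.to_numpy(dtype=float)
        else:
            covariates[col] = df[col].to_numpy(dtype=object)
    return SampleAnnotation(list(df["sample_id"]), np.array(subtypes, dtype=object), covariates)


def write_annotation(a: SampleAnnotation, path: str | Path) -> None:
    data = {"sample_id": a.sample_ids, "subtype": list(a.subtype)}
    for name, col in a.covariates.items():
        data[name] = list(col)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def align_samples(
    x: ExpressionMatrix, a: SampleAnnotation
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Restrict matrix and annotation to their shared samples, in matrix order.

    Idempotent; errors on an empty intersection.
    """
    ann_pos = {s: i for i, s in enumerate(a.sample_ids)}
    keep_x = [i for i, s in enumerate(x.sample_ids) if s in ann_pos]
    if not keep_x:
        raise ValueError("no shared samples between expression matrix and annotation")
    dropped = (x.n_samples - len(keep_x)) + (a.n_samples - len(keep_x))
    if dropped:
        logger.info("align_samples: dropped %d unmatched sample entries", dropped)
    x2 = x.subset_samples(keep_x)
    a2 = a.subset([ann_pos[x.sample_ids[i]] for i in keep_x])
    return x2, a2


def write_json_report(obj, path: str | Path) -> None:
    """Canonical JSON: sorted keys, stable float repr, trailing newline."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default, allow_nan=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_signatures(signatures: Mapping[str, "object"], path: str | Path) -> None:
    """Signatures JSON: subtype -> [{mirna, direction, frequency}] ordered."""
    out = {}
    for subtype, sig in signatures.items():
        out[subtype] = [
            {"mirna": f, "direction": d, "frequency": q} for f, d, q in sig.members
        ]
    write_json_report(out, path)


def read_signatures(path: str | Path) -> dict[str, list[tuple[str, str, float]]]:
    raw = read_json(path)
    return {
        st: [(m["mirna"], m["direction"], float(m["frequency"])) for m in members]
        for st, members in raw.items()
    }
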