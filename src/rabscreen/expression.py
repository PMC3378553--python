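"""Expression matrices, sample annotations, tumour-group assignment, KNN
imputation.

Expression values are stored on the log2 scale throughout the package
(RMA-style one-value-per-gene summaries).  Linear-scale quantities such as
fold changes are always derived, never stored.  The in-memory container is a
:class:`pandas.DataFrame` with gene symbols as the index and sample
identifiers as columns; missing values are ``NaN``.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TISSUES", "STAGES", "GRADES", "FGFR3", "GROUPS", "TUMOR_GROUPS",
    "PATHWAY_GROUPS", "AnnotationError", "ExpressionError",
    "read_expression", "write_expression", "read_annotations",
    "validate_annotations", "assign_groups", "impute_knn",
]

TISSUES = ("normal_urothelium", "tumor", "cancer_cell_line", "nhu_culture")
STAGES = ("Ta", "T1", "T2_4", "NA")
GRADES = ("G1", "G2", "G3", "NA")
FGFR3 = ("mutated", "non_mutated", "NA")

#: The six analysis groups of the two-pathway model, plus the shared
#: normal-urothelium reference and the explicit "excluded" bucket.
TUMOR_GROUPS = ("TaG1G2_mut", "T1_mut", "T24_mut",
                "TaG3_nonmut", "T1_nonmut", "T24_nonmut")
GROUPS = TUMOR_GROUPS + ("normal", "excluded")

#: Tumour groups making up each progression pathway, in stage order.
PATHWAY_GROUPS = {
    "mutated": ("TaG1G2_mut", "T1_mut", "T24_mut"),
    "non_mutated": ("TaG3_nonmut", "T1_nonmut", "T24_nonmut"),
}

#: Same-stage group on the opposite pathway, for specificity testing.
OPPOSITE_GROUP = {
    "TaG1G2_mut": "TaG3_nonmut", "T1_mut": "T1_nonmut",
    "T24_mut": "T24_nonmut", "TaG3_nonmut": "TaG1G2_mut",
    "T1_nonmut": "T1_mut", "T24_nonmut": "T24_mut",
}


class ExpressionError(ValueError):
    """Raised for malformed expression matrices."""


class AnnotationError(ValueError):
    """Raised for invalid sample annotations."""


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of log2 expression values.

    First column holds gene symbols, the header row holds sample ids.
    Empty cells and the literal ``NA`` mark missing values.  Duplicate gene
    rows and non-numeric cells are errors (reported with coordinates).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ExpressionError(f"{path}: duplicate gene row {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ExpressionError(f"{path}: duplicate sample column {dup!r}")
    values = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in ("", "NA"):
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ExpressionError(
                    f"{path}: non-numeric cell {cell!r} at gene "
                    f"{raw.index[i]!r}, sample {col!r}") from None
    return pd.DataFrame(values, index=raw.index.rename("gene"),
                        columns=raw.columns)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as TSV; NaN becomes an empty cell."""
    matrix.to_csv(path, sep="\t", na_rep="", index_label="gene",
                  float_format="%.6g")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV and validate it.

    Expected columns: ``sample``, ``tissue``, ``stage``, ``grade``,
    ``fgfr3``.  Empty cells are read as ``NA``.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "tissue", "stage", "grade", "fgfr3"}
    if not required.issubset(ann.columns):
        raise AnnotationError(
            f"{path}: annotation TSV needs columns {sorted(required)}")
    for col in ("stage", "grade", "fgfr3"):
        ann[col] = ann[col].replace("", "NA")
    validate_annotations(ann)
    return ann


def validate_annotations(ann: pd.DataFrame) -> None:
    if ann["sample"].duplicated().any():
        dup = ann.loc[ann["sample"].duplicated(), "sample"].iloc[0]
        raise AnnotationError(f"duplicate sample id {dup!r}")
    vocab = {"tissue": TISSUES, "stage": STAGES, "grade": GRADES,
             "fgfr3": FGFR3}
    for col, allowed in vocab.items():
        bad = set(ann[col]) - set(allowed)
        if bad:
            raise AnnotationError(f"invalid {col} value(s): {sorted(bad)}")
    tumors = ann[ann["tissue"] == "tumor"]
    for col in ("stage", "grade", "fgfr3"):
        missing = tumors[tumors[col] == "NA"]
        if len(missing):
            raise AnnotationError(
                f"tumor sample {missing['sample'].iloc[0]!r} has missing "
                f"{col}")


def assign_groups(annotations: pd.DataFrame) -> pd.Series:
    """Map every annotated sample to an analysis group.

    The two-pathway model: FGFR3-mutated tumours follow
    TaG1G2 -> T1 -> T2-4 and FGFR3-non-mutated tumours follow
    TaG3 -> T1 -> T2-4.  TaG3 mutated and TaG1/G2 non-mutated tumours fit
    neither pathway and map to ``excluded`` (never dropped silently), as do
    cultured cell-line and NHU profiles.  Normal urothelium maps to
    ``normal``.
    """
    validate_annotations(annotations)

    def one(row: pd.Series) -> str:
        if row["tissue"] == "normal_urothelium":
            return "normal"
        if row["tissue"] != "tumor":
            return "excluded"
        stage, grade, fgfr3 = row["stage"], row["grade"], row["fgfr3"]
        if fgfr3 == "mutated":
            if stage == "Ta":
                return "TaG1G2_mut" if grade in ("G1", "G2") else "excluded"
            return {"T1": "T1_mut", "T2_4": "T24_mut"}[stage]
        if stage == "Ta":
            return "TaG3_nonmut" if grade == "G3" else "excluded"
        return {"T1": "T1_nonmut", "T2_4": "T24_nonmut"}[stage]

    groups = annotations.apply(one, axis=1)
    groups.index = annotations["sample"].to_numpy()
    groups.name = "group"
    return groups


def impute_knn(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing entries from the k nearest genes.

    For a gene with a missing value at sample *j*, the neighbours are the
    *k* complete genes (no missing values anywhere) closest in Euclidean
    distance computed over the target gene's observed samples; the imputed
    value is the mean of their values at sample *j*.  Ties in distance are
    broken by row order, making the result deterministic.  Observed entries
    are never modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.to_numpy(dtype=float, copy=True)
    missing = np.isnan(values)
    if not missing.any():
        return matrix.copy()
    all_missing = missing.all(axis=1)
    if all_missing.any():
        gene = matrix.index[np.flatnonzero(all_missing)[0]]
        raise ExpressionError(f"gene {gene!r} has no observed values")
    complete = ~missing.any(axis=1)
    n_complete = int(complete.sum())
    if n_complete < k:
        raise ExpressionError(
            f"k={k} exceeds the {n_complete} complete gene(s) available")
    complete_idx = np.flatnonzero(complete)
    complete_vals = values[complete_idx]
    out = values.copy()
    for i in np.flatnonzero(missing.any(axis=1)):
        obs = ~missing[i]
        # Euclidean distance over the target gene's observed samples
        diffs = complete_vals[:, obs] - values[i, obs]
        dist = np.sqrt((diffs ** 2).sum(axis=1))
        order = np.argsort(dist, kind="stable")[:k]
        neighbours = complete_vals[order]
        for j in np.flatnonzero(missing[i]):
            out[i, j] = neighbours[:, j].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
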