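"""Loaders for the reference tables bundled with the package.

These TSVs carry the published per-group fold-change and q-value
summaries of the bladder-cancer Rab screen (the per-pathway deregulation
tables, the Rab27 cluster table and the pathway-specificity
cross-comparison).  They serve as worked-example inputs and as frozen
expected values for the thresholding and set-arithmetic machinery; the
underlying per-sample expression data are not redistributable.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .expression import PATHWAY_GROUPS

__all__ = [
    "load_pathway_reference", "load_rab27_reference",
    "load_specificity_reference", "reference_group_table",
]

_FILES = {
    "non_mutated": "nonmutated_pathway_fcq.tsv",
    "mutated": "mutated_pathway_fcq.tsv",
}


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("rabscreen.data") / name) as p:
        return pd.read_csv(p, sep="\t", index_col=0)


def load_pathway_reference(pathway: str) -> pd.DataFrame:
    """Published FC / q-value summary for one pathway's deregulated genes.

    Rows are genes; columns are ``fc_<group>`` / ``q_<group>`` for the
    pathway's three stage groups.
    """
    if pathway not in _FILES:
        raise ValueError(f"pathway must be one of {sorted(_FILES)}")
    return _read(_FILES[pathway])


def load_rab27_reference() -> pd.DataFrame:
    """Published FC / q-values for the Rab27 cluster in all six groups."""
    return _read("rab27_cluster_fcq.tsv")


def load_specificity_reference() -> pd.DataFrame:
    """Published cross-pathway comparison for the five specific genes."""
    return _read("pathway_specific_fcq.tsv")


def reference_group_table(df: pd.DataFrame, group: str) -> pd.DataFrame:
    """Extract one group's ``fc`` / ``q_percent`` columns from a reference
    table, in the shape :func:`rabscreen.screen.call_deregulated` accepts."""
    if group not in {g for gs in PATHWAY_GROUPS.values() for g in gs}:
        raise ValueError(f"unknown tumour group {group!r}")
    out = df[[f"fc_{group}", f"q_{group}"]].copy()
    out.columns = ["fc", "q_percent"]
    return out
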