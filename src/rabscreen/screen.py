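"""Deregulation calls, pathway lists, cross-dataset validation, stromal
filtering and pathway-specificity testing.

A gene is called up-regulated in a tumour group when its fold change
against the normal-urothelium reference exceeds 1.5 with q-value < 5%,
and down-regulated when the fold change falls below 0.667 (= 1/1.5) with
q-value < 5%; both fold-change inequalities are strict.  Per-pathway gene
lists are unions over the pathway's three stage groups.  Because bulk
tumour profiles mix tumour and stromal cells, an up-regulated gene is
retained only if at least one pure cancer cell line expresses it at >= 2x
the cultured normal urothelial (NHU) level; down-regulated genes bypass
this filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sam import SamResult

__all__ = [
    "FC_UP", "FC_DOWN", "Q_MAX_PERCENT", "PathwayLists", "ScreenError",
    "call_deregulated", "pathway_union", "cross_dataset_validate",
    "stroma_filter", "pathway_specific",
]

FC_UP = 1.5
FC_DOWN = 0.667
Q_MAX_PERCENT = 5.0


class ScreenError(ValueError):
    """Raised for inconsistent deregulation calls (e.g. direction conflict)."""


@dataclass
class PathwayLists:
    """Up-/down-regulated gene sets per progression pathway."""

    up: dict[str, set[str]] = field(default_factory=dict)
    down: dict[str, set[str]] = field(default_factory=dict)

    def pathway_genes(self, pathway: str) -> set[str]:
        return self.up.get(pathway, set()) | self.down.get(pathway, set())

    def union(self) -> tuple[set[str], set[str]]:
        """(down, up) gene sets over all pathways."""
        down = set().union(*self.down.values()) if self.down else set()
        up = set().union(*self.up.values()) if self.up else set()
        return down, up

    def intersection(self) -> tuple[set[str], set[str]]:
        """(down, up) gene sets common to all pathways."""
        down = set.intersection(*map(set, self.down.values())) \
            if self.down else set()
        up = set.intersection(*map(set, self.up.values())) \
            if self.up else set()
        return down, up

    def direction(self, pathway: str, gene: str) -> str:
        if gene in self.up.get(pathway, set()):
            return "up"
        if gene in self.down.get(pathway, set()):
            return "down"
        return "none"


def _as_table(sam: SamResult | pd.DataFrame) -> pd.DataFrame:
    table = sam.table if isinstance(sam, SamResult) else sam
    missing = {"fc", "q_percent"} - set(table.columns)
    if missing:
        raise ValueError(f"result table missing columns {missing}")
    return table


def call_deregulated(sam: SamResult | pd.DataFrame, group: str = "",
                     fc_up: float = FC_UP, fc_down: float = FC_DOWN,
                     q_max: float = Q_MAX_PERCENT) -> pd.DataFrame:
    """Turn per-gene FC / q-values into direction calls.

    All inequalities are strict: up requires ``fc > fc_up`` and
    ``q < q_max``; down requires ``fc < fc_down`` and ``q < q_max``;
    everything else is ``none``.  Accepts a :class:`SamResult` or any
    DataFrame with ``fc`` and ``q_percent`` columns indexed by gene.
    """
    if not (0 < fc_down < 1 < fc_up):
        raise ValueError("thresholds must satisfy 0 < fc_down < 1 < fc_up")
    table = _as_table(sam)
    q_ok = table["q_percent"] < q_max
    direction = np.where(
        (table["fc"] > fc_up) & q_ok, "up",
        np.where((table["fc"] < fc_down) & q_ok, "down", "none"))
    out = pd.DataFrame({
        "gene": table.index, "group": group, "direction": direction,
        "fc": table["fc"].to_numpy(), "q_percent": table["q_percent"].to_numpy(),
    }).reset_index(drop=True)
    return out


def _called(calls: pd.DataFrame, direction: str) -> set[str]:
    return set(calls.loc[calls["direction"] == direction, "gene"])


def pathway_union(calls_by_group: dict[str, pd.DataFrame],
                  pathway_groups: dict[str, tuple[str, ...]],
                  ) -> PathwayLists:
    """Union of per-group calls into per-pathway up/down gene lists.

    A gene belongs to a pathway's list when it passes in at least one of
    the pathway's stage groups; appearing as up in one group and down in
    another within the same pathway is a conflict and raises
    :class:`ScreenError`.  The result is invariant to group ordering.
    """
    lists = PathwayLists()
    for pathway, groups in pathway_groups.items():
        up: set[str] = set()
        down: set[str] = set()
        for g in groups:
            if g not in calls_by_group:
                raise ScreenError(f"missing calls for group {g!r}")
            up |= _called(calls_by_group[g], "up")
            down |= _called(calls_by_group[g], "down")
        conflict = up & down
        if conflict:
            raise ScreenError(
                f"gene(s) {sorted(conflict)} are up in one group and down "
                f"in another within the {pathway} pathway")
        lists.up[pathway] = up
        lists.down[pathway] = down
    return lists


def cross_dataset_validate(calls: pd.DataFrame,
                           sam2: SamResult | pd.DataFrame,
                           genes_present2: set[str],
                           fc_up: float = FC_UP, fc_down: float = FC_DOWN,
                           q_max: float = Q_MAX_PERCENT) -> pd.DataFrame:
    """Validate first-dataset calls against a second, independent dataset.

    For a called gene present in dataset 2: *validated* when the second
    fold change passes the same-direction threshold, or when the second
    q-value passes with the fold change at least on the same side of 1;
    *discordant* when both thresholds pass in the opposite direction;
    otherwise *not_significant*.  Genes absent from dataset 2 are
    *untested*, as are genes with direction ``none``.
    """
    table2 = _as_table(sam2)
    out = calls.copy()
    status = []
    for _, row in calls.iterrows():
        gene, direction = row["gene"], row["direction"]
        if direction == "none" or gene not in genes_present2 \
                or gene not in table2.index:
            status.append("untested")
            continue
        fc2 = float(table2.loc[gene, "fc"])
        q2 = float(table2.loc[gene, "q_percent"])
        if direction == "up":
            same_fc, opp_fc = fc2 > fc_up, fc2 < fc_down
            same_side = fc2 > 1.0
        else:
            same_fc, opp_fc = fc2 < fc_down, fc2 > fc_up
            same_side = fc2 < 1.0
        if same_fc or (q2 < q_max and same_side):
            status.append("validated")
        elif opp_fc and q2 < q_max:
            status.append("discordant")
        else:
            status.append("not_significant")
    out["validation"] = status
    return out


def stroma_filter(up_genes: list[str], cell_lines: pd.DataFrame,
                  nhu: pd.DataFrame,
                  min_log2_ratio: float = 1.0) -> pd.DataFrame:
    """Flag up-regulated genes whose rise is attributable to stroma.

    A gene is *retained* when at least one cancer cell line expresses it
    at least ``min_log2_ratio`` log2 units (default 2-fold, inclusive)
    above the mean of the NHU reference columns; otherwise it is
    *stromal_flagged*.  Matrices are log2 genes x samples.
    """
    for gene in up_genes:
        if gene not in cell_lines.index:
            raise KeyError(f"gene {gene!r} missing from cell-line matrix")
        if gene not in nhu.index:
            raise KeyError(f"gene {gene!r} missing from NHU matrix")
    nhu_ref = nhu.loc[list(up_genes)].mean(axis=1)
    excess = cell_lines.loc[list(up_genes)].sub(nhu_ref, axis=0)
    retained = (excess >= min_log2_ratio).any(axis=1)
    return pd.DataFrame({
        "gene": list(up_genes),
        "status": np.where(retained.to_numpy(), "retained",
                           "stromal_flagged"),
        "max_log2_ratio": excess.max(axis=1).to_numpy(),
    })


def pathway_specific(lists: PathwayLists,
                     cross_sam: dict[str, SamResult | pd.DataFrame],
                     group_pathway: dict[str, str],
                     fc_up: float = FC_UP, fc_down: float = FC_DOWN,
                     q_max: float = Q_MAX_PERCENT,
                     ) -> dict[str, dict[str, set[str]]]:
    """Two-step pathway-specificity screen.

    Step 1 keeps the genes deregulated in exactly one pathway.  Step 2
    compares, per stage, the candidate's own tumour group against the
    same-stage group of the opposite pathway (``cross_sam`` maps the
    candidate-pathway group name to a SAM table oriented with that group
    as the comparison); the gene is *specific* when any such comparison
    passes the fold-change and q thresholds in the candidate's direction.
    ``group_pathway`` maps each group name in ``cross_sam`` to its pathway.
    """
    pathways = list(lists.up.keys() | lists.down.keys())
    specific: dict[str, dict[str, set[str]]] = {
        p: {"up": set(), "down": set()} for p in pathways}
    for pathway in pathways:
        others = [p for p in pathways if p != pathway]
        other_genes = set().union(
            *(lists.pathway_genes(p) for p in others)) if others else set()
        for direction in ("up", "down"):
            candidates = {
                g for g in getattr(lists, direction).get(pathway, set())
                if g not in other_genes}
            for group, sam in cross_sam.items():
                if group_pathway.get(group) != pathway:
                    continue
                table = _as_table(sam)
                for gene in candidates:
                    if gene not in table.index:
                        continue
                    fc = float(table.loc[gene, "fc"])
                    q = float(table.loc[gene, "q_percent"])
                    passes = (fc > fc_up if direction == "up"
                              else fc < fc_down) and q < q_max
                    if passes:
                        specific[pathway][direction].add(gene)
    return specific
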