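"""End-to-end orchestration of the deregulation screen.

One :func:`run_pipeline` call executes the full flow on a prepared study:
catalog -> group assignment -> KNN imputation -> per-group SAM against
the shared normal reference -> threshold calls -> per-pathway lists ->
optional second-dataset validation -> stromal filter -> pathway
specificity -> cluster enrichment -> marker correlation.  It writes one
TSV per stage plus a machine-readable manifest; a failure in any stage
aborts the run with the stage name and removes partial outputs.
"""
from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import load_catalog, load_default_catalog, restrict_to_platform
from .correlation import (DIFFERENTIATION_MARKERS, PROLIFERATION_MARKERS,
                          marker_association)
from .enrichment import enrich_all
from .expression import (OPPOSITE_GROUP, PATHWAY_GROUPS, TUMOR_GROUPS,
                         assign_groups, impute_knn, read_annotations,
                         read_expression)
from .sam import SamConfig, run_sam
from .screen import (FC_DOWN, FC_UP, Q_MAX_PERCENT, call_deregulated,
                     cross_dataset_validate, pathway_specific, pathway_union,
                     stroma_filter)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and panels for one pipeline run."""

    expression: Path
    annotations: Path
    out_dir: Path
    catalog: Path | None = None          # None -> bundled default catalog
    cell_lines: Path | None = None       # cell-line + NHU panel (optional)
    expression2: Path | None = None      # second dataset (optional)
    annotations2: Path | None = None
    fc_up: float = FC_UP
    fc_down: float = FC_DOWN
    q_max_percent: float = Q_MAX_PERCENT
    cluster_alpha: float = 0.01
    corr_alpha: float = 0.01
    knn_k: int = 10
    sam: SamConfig = field(default_factory=SamConfig)
    proliferation_markers: tuple = PROLIFERATION_MARKERS
    differentiation_markers: tuple = DIFFERENTIATION_MARKERS
    corr_group_a: str = "TaG1G2_mut"
    corr_group_b: str = "T24_nonmut"

    def __post_init__(self) -> None:
        for attr in ("fc_up", "q_max_percent", "cluster_alpha",
                     "corr_alpha"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if not 0 < self.fc_down < 1 < self.fc_up:
            raise ValueError("need 0 < fc_down < 1 < fc_up")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _group_samples(groups: pd.Series, matrix: pd.DataFrame
                   ) -> dict[str, list[str]]:
    cols = set(matrix.columns)
    return {g: [s for s in groups.index if groups[s] == g and s in cols]
            for g in groups.unique()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full screen; returns the manifest dictionary.

    Outputs written to ``config.out_dir``: ``sam_<group>.tsv``,
    ``calls.tsv``, ``pathway_lists.tsv``, ``stroma.tsv`` (when a
    cell-line panel is supplied), ``specific.tsv``,
    ``cluster_enrichment.tsv``, ``correlations.tsv`` and
    ``manifest.json``.  Identical config and inputs give a byte-identical
    bundle.
    """
    out_dir = Path(config.out_dir)
    tmp = Path(tempfile.mkdtemp(prefix="rabscreen_"))
    log: list[str] = []
    try:
        manifest = _run(config, tmp, log)
    except PipelineError:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        shutil.rmtree(tmp, ignore_errors=True)
        raise PipelineError("unknown", str(exc)) from exc
    out_dir.mkdir(parents=True, exist_ok=True)
    for item in sorted(tmp.iterdir()):
        shutil.copy2(item, out_dir / item.name)
    shutil.rmtree(tmp, ignore_errors=True)
    return manifest


def _stage(name: str, fn, log: list[str], *args, **kwargs):
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    return result


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _run(config: PipelineConfig, out: Path, log: list[str]) -> dict:
    catalog = _stage(
        "catalog",
        lambda: (load_catalog(config.catalog) if config.catalog
                 else load_default_catalog()), log)

    matrix = _stage("expression", read_expression, log, config.expression)
    ann = _stage("annotations", read_annotations, log, config.annotations)
    groups = _stage("groups", assign_groups, log, ann)
    log.append(f"groups: {groups.value_counts().to_dict()}")

    if matrix.isna().any().any():
        matrix = _stage("impute", impute_knn, log, matrix, config.knn_k)

    platform = _stage("platform", restrict_to_platform, log,
                      catalog, set(matrix.index))
    log.append(f"platform: {platform.n_present} of {len(catalog)} "
               f"catalog genes present")
    catalog_present = [g for g in matrix.index
                       if platform.is_present(g)]
    by_group = _group_samples(groups, matrix)
    normal = by_group.get("normal", [])
    if len(normal) < 2:
        raise PipelineError("groups", "need >= 2 normal reference samples")

    sam_results = {}
    for group in TUMOR_GROUPS:
        samples = by_group.get(group, [])
        if len(samples) < 2:
            log.append(f"sam[{group}]: skipped ({len(samples)} samples)")
            continue
        res = _stage(f"sam[{group}]", run_sam, log,
                     matrix.loc[catalog_present], normal, samples,
                     config.sam)
        sam_results[group] = res
        _write(res.table.reset_index(names="gene"),
               out / f"sam_{group}.tsv")

    calls_by_group = {
        g: call_deregulated(res, group=g, fc_up=config.fc_up,
                            fc_down=config.fc_down,
                            q_max=config.q_max_percent)
        for g, res in sam_results.items()}
    pathway_groups = {
        p: tuple(g for g in gs if g in calls_by_group)
        for p, gs in PATHWAY_GROUPS.items()}
    lists = _stage("pathway_union", pathway_union, log,
                   calls_by_group, pathway_groups)

    calls = pd.concat(calls_by_group.values(), ignore_index=True)
    if config.expression2 is not None:
        matrix2 = _stage("expression2", read_expression, log,
                         config.expression2)
        ann2 = _stage("annotations2", read_annotations, log,
                      config.annotations2)
        groups2 = _stage("groups2", assign_groups, log, ann2)
        if matrix2.isna().any().any():
            matrix2 = _stage("impute2", impute_knn, log, matrix2,
                             config.knn_k)
        by_group2 = _group_samples(groups2, matrix2)
        normal2 = by_group2.get("normal", [])
        present2 = set(matrix2.index)
        validated = []
        for g, sub in calls.groupby("group", sort=False):
            samples2 = by_group2.get(g, [])
            if len(normal2) >= 2 and len(samples2) >= 2:
                res2 = _stage(f"sam2[{g}]", run_sam, log, matrix2,
                              normal2, samples2, config.sam)
                validated.append(cross_dataset_validate(
                    sub, res2, present2, config.fc_up, config.fc_down,
                    config.q_max_percent))
            else:
                sub = sub.copy()
                sub["validation"] = "untested"
                validated.append(sub)
        calls = pd.concat(validated, ignore_index=True)
    else:
        calls["validation"] = "untested"
    _write(calls, out / "calls.tsv")

    union_down, union_up = lists.union()
    stromal_flagged: set[str] = set()
    if config.cell_lines is not None and union_up:
        panel = _stage("cell_lines", read_expression, log, config.cell_lines)
        nhu_cols = [c for c in panel.columns if c.upper().startswith("NHU")]
        line_cols = [c for c in panel.columns if c not in nhu_cols]
        if not nhu_cols:
            raise PipelineError("stroma", "panel has no NHU columns")
        up_present = sorted(g for g in union_up if g in panel.index)
        stroma = _stage("stroma", stroma_filter, log, up_present,
                        panel[line_cols], panel[nhu_cols])
        _write(stroma, out / "stroma.tsv")
        stromal_flagged = set(
            stroma.loc[stroma["status"] == "stromal_flagged", "gene"])
        log.append(f"stroma: {len(stromal_flagged)} of {len(up_present)} "
                   f"up-regulated genes flagged")
        for pw in lists.up:
            lists.up[pw] -= stromal_flagged

    cross_sams = {}
    group_pathway = {}
    for pw, gs in pathway_groups.items():
        for g in gs:
            opp = OPPOSITE_GROUP[g]
            own = by_group.get(g, [])
            other = by_group.get(opp, [])
            if len(own) >= 2 and len(other) >= 2:
                cross_sams[g] = _stage(
                    f"cross_sam[{g}]", run_sam, log,
                    matrix.loc[catalog_present], other, own, config.sam)
                group_pathway[g] = pw
    specific = _stage("specific", pathway_specific, log, lists,
                      cross_sams, group_pathway, config.fc_up,
                      config.fc_down, config.q_max_percent)
    spec_rows = [
        {"pathway": pw, "direction": direction, "gene": gene}
        for pw, dd in specific.items()
        for direction, genes in dd.items() for gene in sorted(genes)]
    _write(pd.DataFrame(spec_rows, columns=["pathway", "direction", "gene"]),
           out / "specific.tsv")

    dereg_by_group = {
        g: (_called_set(sub) - stromal_flagged)
        for g, sub in calls.groupby("group", sort=False)}
    enrichment = _stage("cluster_enrichment", enrich_all, log,
                        dereg_by_group, platform, config.cluster_alpha)
    _write(enrichment, out / "cluster_enrichment.tsv")

    lists_rows = [
        {"pathway": pw, "direction": direction, "gene": gene}
        for pw in lists.up
        for direction, genes in (("up", lists.up[pw]),
                                 ("down", lists.down[pw]))
        for gene in sorted(genes)]
    _write(pd.DataFrame(lists_rows,
                        columns=["pathway", "direction", "gene"]),
           out / "pathway_lists.tsv")

    corr_rows = []
    markers = tuple(config.proliferation_markers) + tuple(
        config.differentiation_markers)
    ga = by_group.get(config.corr_group_a, [])
    gb = by_group.get(config.corr_group_b, [])
    dereg_union = sorted((union_down | union_up) - stromal_flagged)
    if len(ga) >= 4 and len(gb) >= 4:
        for marker in markers:
            if marker not in matrix.index:
                log.append(f"correlate: marker {marker} absent, skipped")
                continue
            for gene in dereg_union:
                if gene not in matrix.index:
                    continue
                assoc = marker_association(
                    matrix.loc[gene], matrix.loc[marker], ga, gb,
                    gene=gene, marker=marker, alpha=config.corr_alpha)
                corr_rows.append(assoc.__dict__)
    _write(pd.DataFrame(corr_rows, columns=[
        "gene", "marker", "r_group_a", "r_group_b", "critical_r_a",
        "critical_r_b", "verdict"]), out / "correlations.tsv")

    manifest = {
        "version": __version__,
        "seed": config.sam.seed,
        "thresholds": {
            "fc_up": config.fc_up, "fc_down": config.fc_down,
            "q_max_percent": config.q_max_percent,
            "cluster_alpha": config.cluster_alpha,
            "corr_alpha": config.corr_alpha,
        },
        "sam": {"n_permutations": config.sam.n_permutations,
                "s0_mode": config.sam.s0_mode},
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (
                ("expression", config.expression),
                ("annotations", config.annotations),
                ("catalog", config.catalog),
                ("cell_lines", config.cell_lines),
                ("expression2", config.expression2),
                ("annotations2", config.annotations2))
            if p is not None
        },
        "groups": {g: len(s) for g, s in by_group.items()},
        "log": log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _called_set(calls: pd.DataFrame) -> set[str]:
    return set(calls.loc[calls["direction"] != "none", "gene"])
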