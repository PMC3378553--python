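"""Synthetic study generator with planted ground truth.

Emulates the statistical structure the screen assumes: log2-scale Gaussian
expression around gene-specific baselines, group-specific mean shifts
(planted fold changes), latent factors inducing marker co-expression,
stroma-only up-regulation (present in tumour profiles, absent from pure
cell lines), platform-absent genes, and missing values.  Default group
sizes mirror the primary study cohort: 4 normal urothelium samples and
152 tumours (28 TaG1G2 / 13 T1 / 9 T2-4 FGFR3-mutated; 3 TaG3 / 25 T1 /
63 T2-4 non-mutated; plus 2 TaG3-mutated and 9 TaG1G2-non-mutated tumours
that fit neither pathway and are assigned to no analysis group).

All randomness flows from the single ``seed`` through one named
generator; identical configs give bit-identical outputs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_study",
           "simulate_cell_lines", "DEFAULT_GROUP_SIZES", "CELL_LINES"]

DEFAULT_GROUP_SIZES = {
    "normal": 4, "TaG1G2_mut": 28, "T1_mut": 13, "T24_mut": 9,
    "TaG3_nonmut": 3, "T1_nonmut": 25, "T24_nonmut": 63,
}

#: The seven bladder-cancer cell lines of the in-vitro panel.
CELL_LINES = ("KK47", "MGHU3", "RT112", "RT4", "SCaBER", "SD48", "T24")

_GROUP_ANNOT = {
    "normal": ("normal_urothelium", "NA", "NA", "NA"),
    "TaG1G2_mut": ("tumor", "Ta", "G2", "mutated"),
    "T1_mut": ("tumor", "T1", "G3", "mutated"),
    "T24_mut": ("tumor", "T2_4", "G3", "mutated"),
    "TaG3_nonmut": ("tumor", "Ta", "G3", "non_mutated"),
    "T1_nonmut": ("tumor", "T1", "G3", "non_mutated"),
    "T24_nonmut": ("tumor", "T2_4", "G3", "non_mutated"),
    "excluded_TaG3_mut": ("tumor", "Ta", "G3", "mutated"),
    "excluded_TaG1G2_nonmut": ("tumor", "Ta", "G1", "non_mutated"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines one synthetic study.

    planted_effects entries are ``(gene, groups, log2_shift)``; latent
    factors are ``(name, {gene: loading}, groups)`` and add
    ``loading * z`` with a per-sample standard-normal factor score ``z``
    to every listed gene (shared scores create marker co-expression).
    """

    seed: int = 0
    genes: tuple[str, ...] = ()
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_excluded_tag3_mut: int = 2
    n_excluded_tag1g2_nonmut: int = 9
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5
    heteroscedastic: bool = False   # scatter grows with baseline, for s0
    planted_effects: tuple = ()
    latent_factors: tuple = ()
    stromal_genes: frozenset = frozenset()
    missing_rate: float = 0.0
    platform_absent: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        symbols = set(self.genes)
        for gene, _groups, shift in self.planted_effects:
            if gene not in symbols:
                raise ValueError(f"planted gene {gene!r} not in gene list")
            if not np.isfinite(shift):
                raise ValueError(f"non-finite shift for {gene!r}")
        for gene in self.stromal_genes:
            if gene not in symbols:
                raise ValueError(f"stromal gene {gene!r} not in gene list")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study."""

    fold_change: pd.DataFrame        # genes x groups, linear scale
    stromal: frozenset
    factor_loadings: dict            # factor -> {gene: loading}

    def true_direction(self, gene: str, group: str,
                       fc_up: float = 1.5, fc_down: float = 1 / 1.5) -> str:
        fc = float(self.fold_change.loc[gene, group])
        if fc > fc_up:
            return "up"
        if fc < fc_down:
            return "down"
        return "none"


def _sample_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    ids = []
    for group, n in config.group_sizes.items():
        for i in range(n):
            ids.append((f"{group}_{i + 1:03d}", group))
    for i in range(config.n_excluded_tag3_mut):
        ids.append((f"xTaG3mut_{i + 1:02d}", "excluded_TaG3_mut"))
    for i in range(config.n_excluded_tag1g2_nonmut):
        ids.append((f"xTaG1G2nm_{i + 1:02d}", "excluded_TaG1G2_nonmut"))
    return ids


def simulate_study(config: SimulationConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression matrix, sample annotations, ground truth).

    Expression = per-gene baseline + group shift + latent-factor
    contributions + N(0, noise_sd) on the log2 scale; missing entries are
    then injected completely at random at ``missing_rate``.
    """
    if not config.genes:
        raise ValueError("config.genes must be non-empty")
    for group, n in config.group_sizes.items():
        if group != "normal" and n < 2:
            warnings.warn(
                f"group {group!r} has {n} sample(s); two-group tests "
                f"against it will fail", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    samples = _sample_ids(config)
    m, n = len(genes), len(samples)
    gene_pos = {g: i for i, g in enumerate(genes)}

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=m)
    values = np.tile(baseline[:, None], (1, n))

    shift = np.zeros((m, len(config.group_sizes)))
    group_names = list(config.group_sizes)
    group_pos = {g: j for j, g in enumerate(group_names)}
    for gene, groups, log2_shift in config.planted_effects:
        for g in groups:
            shift[gene_pos[gene], group_pos[g]] += log2_shift
    # stroma-only up-regulation appears in every tumour profile
    tumour_groups = [g for g in group_names if g != "normal"]
    for gene in config.stromal_genes:
        for g in tumour_groups:
            shift[gene_pos[gene], group_pos[g]] += 1.5
    for j, (sid, group) in enumerate(samples):
        base_group = group if group in group_pos else None
        if base_group is not None:
            values[:, j] += shift[:, group_pos[base_group]]

    for name, loadings, groups in config.latent_factors:
        scores = rng.standard_normal(n)
        in_groups = np.array([g in groups for _, g in samples])
        for gene, loading in loadings.items():
            values[gene_pos[gene], in_groups] += \
                loading * scores[in_groups]

    if config.heteroscedastic:
        scale = config.noise_sd * (0.5 + 0.5 * (
            baseline - baseline.min()) / max(np.ptp(baseline), 1e-9))
        values += rng.standard_normal((m, n)) * scale[:, None]
    else:
        values += rng.normal(0.0, config.noise_sd, size=(m, n))

    if config.missing_rate > 0:
        mask = rng.random((m, n)) < config.missing_rate
        # never blank out an entire gene row
        full_rows = mask.all(axis=1)
        mask[full_rows, 0] = False
        values = np.where(mask, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                          columns=[sid for sid, _ in samples])
    if config.platform_absent:
        matrix = matrix.drop(index=[g for g in config.platform_absent
                                    if g in matrix.index])

    ann = pd.DataFrame(
        [(sid,) + _GROUP_ANNOT[group] for sid, group in samples],
        columns=["sample", "tissue", "stage", "grade", "fgfr3"])

    fc = pd.DataFrame(np.exp2(shift), index=pd.Index(genes, name="gene"),
                      columns=group_names)
    truth = SyntheticTruth(
        fold_change=fc, stromal=frozenset(config.stromal_genes),
        factor_loadings={name: dict(loadings)
                         for name, loadings, _ in config.latent_factors})
    return matrix, ann, truth


def simulate_cell_lines(config: SimulationConfig, truth: SyntheticTruth,
                        n_nhu: int = 3) -> pd.DataFrame:
    """Generate the in-vitro panel: 7 cancer cell lines + NHU replicates.

    Non-stromal genes planted up in any tumour group exceed the NHU mean
    by at least one log2 unit in at least one line; stromal genes show no
    cell-line elevation at all, so the stromal filter can catch them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = list(config.genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    cols = list(CELL_LINES) + [f"NHU_{i + 1}" for i in range(n_nhu)]
    m = len(genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=m)
    values = np.tile(baseline[:, None], (1, len(cols))) \
        + rng.normal(0.0, config.noise_sd, size=(m, len(cols)))

    tumour_fc = truth.fold_change.drop(columns=["normal"], errors="ignore")
    up_anywhere = (tumour_fc.to_numpy() > 1.0).any(axis=1)
    for i, gene in enumerate(genes):
        if gene in truth.stromal:
            # stromal cell types are absent from epithelial lines: the
            # signal driving the tumour up-shift is depressed here
            values[i, :len(CELL_LINES)] -= 1.0
            continue
        if up_anywhere[i] and tumour_fc.iloc[i].max() >= 1.5:
            line = int(rng.integers(0, len(CELL_LINES)))
            lift = np.log2(float(tumour_fc.iloc[i].max())) + 2.0
            values[i, line] += max(lift, 3.0)
    out = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                       columns=cols)
    if config.platform_absent:
        out = out.drop(index=[g for g in config.platform_absent
                              if g in out.index])
    return out
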