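"""Two-class unpaired SAM test with permutation-estimated q-values.

SAM (significance analysis of microarrays) scores each gene with a
regularised t-like *relative difference*

    d = (mean2 - mean1) / (s + s0),
    s = sqrt((1/n1 + 1/n2) * (SS1 + SS2) / (n1 + n2 - 2)),

where ``s`` is the gene-specific pooled scatter and ``s0`` is a small
exchangeability constant chosen to make the spread of ``d`` independent of
expression level.  Significance is assessed against random label
permutations: an asymmetric threshold (delta) sweep over observed versus
expected order statistics yields, for every call set, a
false-discovery-rate estimate

    FDR = pi0 * median_b #{permuted d beyond the cutoffs} / #called,

and each gene's q-value (reported in percent) is the smallest FDR among
the thresholds at which it is called.  Fold change is the geometric-mean
ratio ``2**(mean2 - mean1)`` since the input is log2 scale.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SamConfig", "SamResult", "relative_difference", "estimate_s0",
    "fold_change", "run_sam",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SamConfig:
    """Parameters of one SAM run.

    Defaults follow the standard two-class unpaired configuration: 100
    label permutations, automatic s0, fixed random seed, and no array-wise
    median centring.
    """

    n_permutations: int = 100
    s0_mode: str = "automatic"       # "automatic" | "fixed"
    s0_fixed: float = 0.0
    seed: int = 1234567
    median_center: bool = False      # honoured: centring is never applied

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.s0_mode not in ("automatic", "fixed"):
            raise ValueError("s0_mode must be 'automatic' or 'fixed'")
        if self.s0_fixed < 0:
            raise ValueError("s0_fixed must be non-negative")
        if self.median_center:
            raise NotImplementedError(
                "array median centring is deliberately not applied")


@dataclass
class SamResult:
    """Per-gene SAM output plus the fitted exchangeability constant."""

    table: pd.DataFrame  # columns: d, s, fc, q_percent
    s0: float
    n_permutations: int = 0

    def __post_init__(self) -> None:
        missing = {"d", "s", "fc", "q_percent"} - set(self.table.columns)
        if missing:
            raise ValueError(f"SamResult table missing columns {missing}")


def _pooled_stats(x1: np.ndarray, x2: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = x1.shape[1], x2.shape[1]
    num = x2.mean(axis=1) - x1.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return num, s


def relative_difference(
        x1: np.ndarray, x2: np.ndarray, s0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative difference d and pooled scatter s per gene.

    ``x1`` and ``x2`` are (genes x samples) arrays for the reference and
    comparison group.  ``d`` carries the sign of ``mean(x2) - mean(x1)``.
    With ``s0 = 0`` the statistic coincides with the classical
    pooled-variance two-sample t statistic.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    num, s = _pooled_stats(x1, x2)
    denom = s + s0
    # guard exact-zero denominators (identical constant groups)
    denom = np.where(denom == 0, _EPS, denom)
    return num / denom, s


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def estimate_s0(s: np.ndarray, d_at, n_windows: int = 10) -> float:
    """Automatic choice of the exchangeability constant s0.

    Candidates are 0 together with the 0,5,...,100 percentiles of the
    per-gene scatters ``s``.  For each candidate, genes are split by rank
    of ``s`` into ``n_windows`` equal windows; the spread of
    ``d = d_at(s0)`` inside each window is summarised by the median
    absolute deviation, and the candidate minimising the coefficient of
    variation of those window spreads is returned.  Ties (including a flat
    criterion, as with homoscedastic data) break toward the smaller
    candidate.
    """
    s = np.asarray(s, dtype=float)
    m = s.size
    if m < 2 * n_windows:
        raise ValueError(
            f"need at least {2 * n_windows} genes to form {n_windows} "
            f"scatter windows, got {m}")
    candidates = np.unique(np.concatenate(
        [[0.0], np.percentile(s, np.arange(0, 101, 5))]))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    best_s0, best_cv = 0.0, math.inf
    for s0 in candidates:
        d = np.asarray(d_at(float(s0)), dtype=float)
        spreads = np.array([_mad(d[w]) for w in windows])
        mean = spreads.mean()
        if mean == 0:
            continue
        cv = spreads.std(ddof=1) / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def fold_change(matrix: pd.DataFrame, group1: list[str],
                group2: list[str]) -> pd.Series:
    """Linear-scale fold change of group2 over group1 (the reference).

    Input is log2, so ``fc = 2**(mean_log2(group2) - mean_log2(group1))``
    — a ratio of geometric means.
    """
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    delta = matrix[list(group2)].mean(axis=1) - matrix[list(group1)].mean(axis=1)
    fc = np.exp2(delta)
    fc.name = "fc"
    return fc


def _permutation_indices(n: int, n1: int, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Distinct random group-1 index sets, identity excluded.

    When the label space is small enough, all distinct non-identity
    assignments are enumerated instead of sampled.
    """
    identity = tuple(range(n1))
    total = math.comb(n, n1)
    if total - 1 <= n_perm:
        combos = [c for c in itertools.combinations(range(n), n1)
                  if c != identity]
        return np.array(combos, dtype=np.intp)
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < n_perm:
        combo = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if combo == identity or combo in seen:
            continue
        seen.add(combo)
        out.append(combo)
    return np.array(out, dtype=np.intp)


def run_sam(matrix: pd.DataFrame, group1: list[str], group2: list[str],
            config: SamConfig | None = None) -> SamResult:
    """Run the two-class unpaired SAM test on a log2 expression matrix.

    ``group1`` is the reference (e.g. normal urothelium), ``group2`` the
    comparison group; both are lists of sample/column identifiers with at
    least two members.  The matrix must contain no missing values (impute
    first).  Repeated runs with an identical config and inputs are
    bit-identical.
    """
    config = config or SamConfig()
    for g, name in ((group1, "group1"), (group2, "group2")):
        if len(g) < 2:
            raise ValueError(f"{name} needs at least 2 samples")
    sub = matrix[list(group1) + list(group2)]
    if sub.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    x = sub.to_numpy(dtype=float)
    n1, n2 = len(group1), len(group2)
    m = x.shape[0]

    num, s = _pooled_stats(x[:, :n1], x[:, n1:])
    if config.s0_mode == "automatic":
        s0 = estimate_s0(
            s, lambda c: num / np.where(s + c == 0, _EPS, s + c))
    else:
        s0 = config.s0_fixed
    denom = np.where(s + s0 == 0, _EPS, s + s0)
    d = num / denom
    fc = np.exp2(num)

    rng = np.random.default_rng(config.seed)
    perms = _permutation_indices(n1 + n2, n1, config.n_permutations, rng)
    n_perm = perms.shape[0]
    d_perm = np.empty((n_perm, m))
    for b, g1_idx in enumerate(perms):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[g1_idx] = True
        num_b, s_b = _pooled_stats(x[:, mask], x[:, ~mask])
        d_perm[b] = num_b / np.where(s_b + s0 == 0, _EPS, s_b + s0)
    d_perm.sort(axis=1)

    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    dbar = d_perm.mean(axis=0)

    q25, q75 = np.percentile(d, [25, 75])
    pi0 = np.count_nonzero((d_perm > q25) & (d_perm < q75)) / (
        0.5 * n_perm * m)
    pi0 = float(np.clip(pi0, 0.0, 1.0))

    q_sorted = _q_values(d_sorted, dbar, d_perm, pi0)
    q = np.empty(m)
    q[order] = q_sorted

    table = pd.DataFrame(
        {"d": d, "s": s, "fc": fc, "q_percent": q}, index=sub.index)
    return SamResult(table=table, s0=float(s0), n_permutations=n_perm)


def _cut_arrays(d_sorted: np.ndarray, dbar: np.ndarray, j0: int,
                deltas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper/lower cutoffs for every delta.

    cutup(delta) is the smallest observed d in the upper half of the
    quantile-quantile plot whose excess d - dbar reaches delta; genes at or
    above it are called up.  cutlow mirrors this in the lower half.
    cutup is non-decreasing and cutlow non-increasing in delta.
    """
    m = d_sorted.size
    diffs = d_sorted - dbar
    cutup = np.full(deltas.size, np.inf)
    cutlow = np.full(deltas.size, -np.inf)

    up = np.arange(j0, m)
    if up.size:
        # sort upper genes by excess descending; prefix-min of d over that
        # order gives cutup for any delta by counting qualifying genes
        ud = diffs[up]
        o = np.argsort(-ud, kind="stable")
        excess_desc = ud[o]
        prefix_min_d = np.minimum.accumulate(d_sorted[up][o])
        k = np.searchsorted(-excess_desc, -deltas, side="right")
        has = k > 0
        cutup[has] = prefix_min_d[k[has] - 1]

    low = np.arange(0, j0)
    if low.size:
        ld = -diffs[low]  # deficit
        o = np.argsort(-ld, kind="stable")
        deficit_desc = ld[o]
        prefix_max_d = np.maximum.accumulate(d_sorted[low][o])
        k = np.searchsorted(-deficit_desc, -deltas, side="right")
        has = k > 0
        cutlow[has] = prefix_max_d[k[has] - 1]
    return cutup, cutlow


def _q_values(d_sorted: np.ndarray, dbar: np.ndarray,
              d_perm_sorted: np.ndarray, pi0: float) -> np.ndarray:
    """Delta-sweep q-values (percent) for genes in ascending-d order."""
    m = d_sorted.size
    j0 = int(np.searchsorted(dbar, 0.0))  # plot origin: first dbar >= 0
    deltas = np.unique(np.abs(d_sorted - dbar))
    cutup, cutlow = _cut_arrays(d_sorted, dbar, j0, deltas)

    n_called = (m - np.searchsorted(d_sorted, cutup, side="left")
                + np.searchsorted(d_sorted, cutlow, side="right"))

    # median permuted exceedance count per delta
    counts = np.empty((d_perm_sorted.shape[0], deltas.size))
    for b in range(d_perm_sorted.shape[0]):
        row = d_perm_sorted[b]
        counts[b] = (m - np.searchsorted(row, cutup, side="left")
                     + np.searchsorted(row, cutlow, side="right"))
    med_fp = np.median(counts, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_called > 0,
                       np.minimum(100.0, 100.0 * pi0 * med_fp
                                  / np.maximum(n_called, 1)),
                       np.inf)

    # cutup non-decreasing, cutlow non-increasing: the deltas calling a
    # gene form a prefix, so a prefix-min over FDR gives its q directly.
    pmin_fdr = np.minimum.accumulate(fdr)
    # last delta index where the gene is still called, per tail
    j_up = np.searchsorted(cutup, d_sorted, side="right") - 1
    j_low = np.searchsorted(-cutlow, -d_sorted, side="right") - 1
    j = np.maximum(j_up, j_low)
    q = np.full(m, 100.0)
    ok = j >= 0
    q[ok] = np.where(np.isfinite(pmin_fdr[j[ok]]), pmin_fdr[j[ok]], 100.0)

    # safety projection: q non-increasing as |d| grows within each tail
    # (the prefix construction already guarantees this within one tail's
    # own cutoffs; cross-tail calls near the origin can break it)
    if j0 < m:
        q[j0:] = np.minimum.accumulate(q[j0:])
    if j0 > 0:
        q[:j0] = np.minimum.accumulate(q[:j0][::-1])[::-1]
    return np.clip(q, 0.0, 100.0)
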