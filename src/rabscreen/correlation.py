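"""Marker-correlation association and small test utilities.

Deregulated genes are associated with a proliferation marker (MKI67) or
urothelial differentiation markers (the uroplakins, GRHL3, FOXA1) by
Pearson correlation computed separately in two reference tumour groups;
an association requires two-tailed p < alpha in *both* groups with a
consistent sign.  The two-tailed p-value of a correlation r on n samples
uses the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 degrees
of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MarkerAssociation", "PROLIFERATION_MARKERS", "DIFFERENTIATION_MARKERS",
    "pearson_r", "pearson_pvalue", "critical_r", "verdict_from_r",
    "marker_association", "welch_t",
]

PROLIFERATION_MARKERS = ("MKI67",)
DIFFERENTIATION_MARKERS = ("UPK1A", "UPK1B", "UPK2", "UPK3A", "UPK3B",
                           "GRHL3", "FOXA1")


@dataclass(frozen=True)
class MarkerAssociation:
    """Dual-group correlation verdict for one gene/marker pair."""

    gene: str
    marker: str
    r_group_a: float
    r_group_b: float
    critical_r_a: float
    critical_r_b: float
    verdict: str  # "correlated" | "inversely_correlated" | "none"


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has undefined correlation")
    return float(stats.pearsonr(x, y).statistic)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-tailed p of a Pearson correlation via the exact t transform."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0  # degenerate: perfectly linear
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def critical_r(n: int, alpha: float = 0.01, decimals: int = 3) -> float:
    """Smallest |r| on a 10^-decimals grid with two-tailed p strictly < alpha.

    Defined on the printed-precision grid rather than by inverting the t
    quantile, so that the returned threshold is exactly the smallest value
    that would be reported as significant at that precision.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    step = 10.0 ** (-decimals)
    for i in range(1, int(round(1.0 / step))):
        r = round(i * step, decimals)
        if pearson_pvalue(r, n) < alpha:
            return r
    return 1.0


def verdict_from_r(r_a: float, r_b: float, crit_a: float, crit_b: float,
                   require_sign_consistency: bool = True) -> str:
    """Dual-group association verdict from per-group r and critical values."""
    pass_a = abs(r_a) > crit_a
    pass_b = abs(r_b) > crit_b
    if not (pass_a and pass_b):
        return "none"
    if r_a > 0 and r_b > 0:
        return "correlated"
    if r_a < 0 and r_b < 0:
        return "inversely_correlated"
    return "none" if require_sign_consistency else (
        "correlated" if (r_a + r_b) > 0 else "inversely_correlated")


def marker_association(gene_expr, marker_expr, group_a: list,
                       group_b: list, gene: str = "gene",
                       marker: str = "marker", alpha: float = 0.01,
                       require_sign_consistency: bool = True,
                       ) -> MarkerAssociation:
    """Associate one gene with one marker across two reference groups.

    ``gene_expr`` and ``marker_expr`` are mappings (e.g. pandas Series
    indexed by sample id) of log2 expression; ``group_a`` / ``group_b``
    are sample-id lists with at least 4 members each.  The verdict is
    ``correlated`` / ``inversely_correlated`` only when |r| exceeds the
    group-specific critical value in both groups with a consistent sign.
    """
    for g, name in ((group_a, "group_a"), (group_b, "group_b")):
        if len(g) < 4:
            raise ValueError(f"{name} needs at least 4 samples")
    r_a = pearson_r(np.asarray([gene_expr[s] for s in group_a]),
                    np.asarray([marker_expr[s] for s in group_a]))
    r_b = pearson_r(np.asarray([gene_expr[s] for s in group_b]),
                    np.asarray([marker_expr[s] for s in group_b]))
    crit_a = critical_r(len(group_a), alpha)
    crit_b = critical_r(len(group_b), alpha)
    return MarkerAssociation(
        gene=gene, marker=marker, r_group_a=r_a, r_group_b=r_b,
        critical_r_a=crit_a, critical_r_b=crit_b,
        verdict=verdict_from_r(r_a, r_b, crit_a, crit_b,
                               require_sign_consistency))


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Welch (unequal-variance) t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both samples are constant")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)
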