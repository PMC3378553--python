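"""Cluster-level binomial enrichment of deregulated genes.

For one tumour group, let K of the N platform-present catalog genes be
deregulated, giving a background rate p0 = K/N.  A Rab cluster with n
platform-present members, k of them deregulated, is tested with the exact
one-sided binomial upper tail P(X >= k), X ~ Binomial(n, p0) — the same
construction as R's ``binom.test(k, n, p0, alternative="greater")``.
Clusters with p < 0.01 are flagged significant; no multiple-testing
correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .catalog import PlatformCatalog

__all__ = ["ClusterEnrichmentResult", "binomial_upper_tail",
           "enrich_cluster", "enrich_all"]

SIGNIFICANCE_ALPHA = 0.01


@dataclass(frozen=True)
class ClusterEnrichmentResult:
    """Binomial enrichment of one cluster in one tumour group."""

    cluster: str
    group: str
    k: int          # deregulated cluster genes
    n: int          # platform-present cluster genes
    K: int          # deregulated catalog genes in this group
    N: int          # platform-present catalog genes
    p0: float       # K / N
    p_value: float
    significant: bool


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact one-sided binomial tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def enrich_cluster(deregulated: set[str], cluster: str,
                   platform: PlatformCatalog, group: str = "",
                   alpha: float = SIGNIFICANCE_ALPHA,
                   ) -> ClusterEnrichmentResult:
    """Test one Rab cluster for enrichment of deregulated genes.

    ``deregulated`` is the set of deregulated catalog genes for the group
    (covering the whole platform-present catalog, any direction).  Genes in
    several clusters count in each cluster's k and n but once in K and N.
    """
    members = platform.cluster_present_members(cluster)
    n = len(members)
    if n == 0:
        raise ValueError(
            f"cluster {cluster!r} has no platform-present members")
    present = set(platform.present_symbols())
    dereg_present = set(deregulated) & present
    k = sum(1 for g in members if g in dereg_present)
    K = len(dereg_present)
    N = platform.n_present
    p0 = K / N
    p = binomial_upper_tail(k, n, p0)
    return ClusterEnrichmentResult(
        cluster=cluster, group=group, k=k, n=n, K=K, N=N, p0=p0,
        p_value=p, significant=p < alpha)


def enrich_all(deregulated_by_group: dict[str, set[str]],
               platform: PlatformCatalog,
               alpha: float = SIGNIFICANCE_ALPHA) -> pd.DataFrame:
    """Binomial enrichment for every cluster in every group.

    Returns one row per (cluster, group) with columns cluster, group, k,
    n, K, N, p0, p_value, significant.  Clusters with no platform-present
    members are skipped.
    """
    names = platform.catalog.cluster_names
    if len(set(names)) != len(names):
        raise ValueError("duplicate cluster names in catalog")
    rows = []
    for group, dereg in deregulated_by_group.items():
        for cluster in names:
            if not platform.cluster_present_members(cluster):
                continue
            rows.append(enrich_cluster(dereg, cluster, platform,
                                       group=group, alpha=alpha))
    return pd.DataFrame([r.__dict__ for r in rows])
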