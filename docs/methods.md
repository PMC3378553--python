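# Methods

## Study design emulated by the package

The screen asks whether members of a curated gene family — Rab GTPases
and the proteins that regulate them (GEFs, GAPs) or act downstream of
them (effectors) — are transcriptionally deregulated during bladder
cancer progression, and whether whole Rab clusters (a Rab plus its
interactors) are deregulated together. Tumours are stratified by the
two-pathway model of bladder carcinogenesis: *FGFR3*-mutated tumours
progress TaG1G2 → T1 → T2-4, *FGFR3*-non-mutated (carcinoma-in-situ-like)
tumours progress TaG3 → T1 → T2-4. TaG3 mutated and TaG1/G2 non-mutated
tumours fit neither pathway and are assigned to an explicit `excluded`
group. Every tumour group is compared with a shared normal-urothelium
reference.

## Gene catalog

The bundled catalog holds 284 genes: 61 Rab isoforms, 23 GEFs, 20 GAPs,
174 effectors and 6 general-machinery genes (GDI1/2, CHM/CHML,
RABGGTA/B) that act on all Rabs and belong to no cluster. Interactors
shared by several Rabs carry multiple cluster memberships and count in
each cluster, but only once in catalog-wide totals. The Rab27 cluster
membership is exact (RAB27A/B, MADD, TBC1D10A and 12 effectors including
RPH3A); interactor membership of the other clusters reproduces the
published per-cluster role counts using clearly-labelled synthetic
placeholder symbols (`SYNEF`/`SYNGEF`/`SYNGAP` prefixes), because the
full membership lists are not printed in a machine-readable form.
Platform restriction removes 15 named genes absent from the primary
array, leaving N = 269; absent genes are flagged, not deleted.

## SAM test

For reference group 1 (n₁ samples) and comparison group 2 (n₂ samples),
each gene is scored with the relative difference

    d = (x̄₂ − x̄₁) / (s + s₀),
    s = sqrt((1/n₁ + 1/n₂) · (SS₁ + SS₂) / (n₁ + n₂ − 2)).

With s₀ = 0 this is the pooled-variance t statistic. The
exchangeability constant s₀ is chosen automatically: candidates are 0
plus the 0,5,…,100 percentiles of the per-gene scatters s; genes are
split by rank of s into 10 equal windows; the spread of d within each
window is summarised by its median absolute deviation; the candidate
minimising the coefficient of variation of the window spreads wins,
with ties (e.g. perfectly homoscedastic data, where the criterion is
flat) broken toward the smaller candidate. Ten windows rather than a
finer grid keeps the estimator defined down to the 20-gene minimum
input the function accepts.

Significance uses random label permutations (default 100, all distinct,
identity excluded; every permutation is drawn from a single seeded
generator, default seed 1234567). Sorted permuted scores averaged over
permutations give the expected order statistics d̄ᵢ. For each threshold
delta, the upper cutoff is the smallest observed d above the plot
origin with dᵢ − d̄ᵢ ≥ delta (symmetrically for the lower cutoff); the
call set is everything beyond the cutoffs, and its estimated false
discovery rate is

    FDR = π₀ · median_b #{permuted d beyond the cutoffs} / #called,

with π₀ = #{permuted d inside the interquartile range of observed
d} / (0.5 · B · m), clamped to [0, 1]. A gene's q-value (percent,
clamped to [0, 100]) is the smallest FDR among the thresholds at which
it is called; because the cutoffs are monotone in delta this is a
prefix minimum, and a final projection enforces q non-increasing in |d|
within each tail. Repeated runs with equal seed are bit-identical.
Array-wise median centring is never applied. Fold change is reported as
2^(x̄₂−x̄₁), a ratio of geometric means, since all stored values are
log2; an arithmetic-mean variant is deliberately not offered to keep
one scale convention throughout.

## Thresholding, stroma, validation, specificity

Calls use strict inequalities: up if FC > 1.5 and q < 5%, down if
FC < 0.667 and q < 5%. Per-pathway lists are unions over the pathway's
three stage groups; a gene up in one group and down in another of the
same pathway raises an error rather than being resolved silently.

The stromal filter applies only to up-regulated genes (a bulk-tumour
rise can come from stromal cells; a fall in a mixed profile still
implies a fall in the dominant compartment): a gene is retained when at
least one cancer cell line exceeds the mean NHU level by ≥1 log2 unit
(inclusive, matching a drawn 2× threshold line). Stromal-flagged genes
are removed from the deregulated sets before pathway-specificity
testing and cluster enrichment — with this ordering the per-group
deregulated totals reproduce the published counts exactly.

Cross-dataset validation of a call requires, in the second dataset,
either a same-direction fold-change pass, or a q pass with the fold
change at least on the same side of 1; both thresholds passing in the
opposite direction is reported as `discordant` rather than silently
counted as a failure. Pathway specificity proceeds in two steps:
candidates are genes deregulated in exactly one pathway; a candidate is
specific when the SAM comparison of its own tumour group against the
same-stage group of the opposite pathway passes the same FC/q
thresholds in the same direction.

## Cluster enrichment

For one tumour group with K deregulated genes among the N
platform-present catalog genes, a cluster with n present members and k
deregulated members is tested with the exact binomial upper tail
P(X ≥ k), X ~ Bin(n, K/N) — the `binom.test(..., alternative =
"greater")` construction — significant at p < 0.01 with no
multiple-testing correction (none is part of the procedure being
reproduced). The general-machinery genes contribute to K and N but to
no cluster; multi-cluster genes contribute to each cluster's k and n
but once to K and N.

## Marker association

Pearson correlations are computed separately in the two largest
homogeneous groups (TaG1G2 mutated, n = 28; T2-4 non-mutated, n = 63).
Two-tailed p-values use the exact transform t = r√(n−2)/√(1−r²) with
n − 2 degrees of freedom. The decision threshold `critical_r(n, α)` is
defined as the smallest three-decimal |r| with p strictly below α: this
grid definition reproduces both working thresholds (0.479 at n = 28,
0.323 at n = 63), whereas inverting the t quantile and rounding gives
0.322 at n = 63. An association verdict requires |r| above the
group-specific critical value in **both** groups with consistent sign;
sign consistency is a package decision (the dual-p rule alone does not
require it) and can be switched off. A Welch unequal-variance t-test
utility supports marker-level group comparisons.

## Synthetic data generator

`simulate_study` produces log2 expression as per-gene baseline
(N(8, 1.5²) across genes) plus group-specific planted shifts, plus
latent-factor contributions (a per-sample standard-normal score shared
by the loaded genes — this is what creates marker co-expression), plus
i.i.d. N(0, noise_sd²) noise, with missing values injected completely
at random. Defaults mirror the emulated cohort: 4 normals and 152
tumours (28/13/9 mutated; 3/25/63 non-mutated; 2 + 9 pathway-misfit
tumours that assign to `excluded`), noise_sd = 0.5 — a typical per-gene
residual spread for RMA-summarised arrays. Stroma-only genes receive a
+1.5 log2 shift in every tumour profile but none in the cell-line
panel, where their values are depressed by 1 log2 unit relative to
baseline (the stromal cell types expressing them are absent from
epithelial lines); non-stromal planted up-genes exceed the NHU mean by
≥3 log2 units in one random line so the 2× filter separates the two
populations reliably at the default noise level. A heteroscedastic
option (scatter growing with baseline) exists to exercise s₀
estimation. All randomness flows from one seed; identical configs give
identical outputs, including the cell-line panel (derived from a child
seed).

What the generator does **not** emulate: batch effects, probe-level
noise, intensity-dependent variance by default, correlated gene blocks
beyond the explicit latent factors, and non-random missingness.
Passing tests on synthetic data therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to
real-array artefacts.

## Numerical and design choices

- Imputation (k-nearest genes, default k = 10, Euclidean distance over
  the target gene's observed samples, neighbour pool restricted to
  complete genes, ties broken by row order) runs on the full matrix
  before any group subsetting.
- Binomial tails and t distribution tails are delegated to scipy;
  the test suite checks them against independent oracles (term-by-term
  pmf summation with exact integer coefficients; numerical quadrature
  of the t density).
- Degenerate inputs fail loudly: empty catalogs, duplicate symbols or
  samples, all-missing gene rows, constant vectors in correlations,
  groups below the minimum size, clusters with no platform-present
  members.
- Problem sizes in the test suite: 284-gene simulations with the full
  cohort layout for calibration and recovery properties (20 seeds
  each), 30–100 permutations and ~50–70-gene studies for the
  end-to-end pipeline checks — small enough to run the whole suite in
  well under a minute while preserving the cohort's group structure.

## Known limitations

- The q-value algorithm follows the classic SAM delta-sweep; minor
  revisions between historical versions of the tool mean published
  q-values can be matched qualitatively, not bit-exactly.
- With only 4 reference samples, fold-change estimates are noisy and
  permutation-FDR estimates at the call margin are conservative;
  planted-recovery experiments at FC 2.0 and noise 0.5 recover roughly
  85–90% of planted genes at q < 5% (the acceptance suite measures
  this), with essentially no null calls.
- The catalog beyond the Rab27 cluster is count-faithful but
  membership-synthetic; analyses that depend on the identity of
  placeholder members are only meaningful with a user-supplied catalog.
- Paired, multiclass and survival SAM variants, local FDR, competitive
  gene-set tests and partial correlations are out of scope.
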