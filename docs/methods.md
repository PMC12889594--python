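# Methods

`plaqueomics` reimplements, as a tested library, the downstream analysis of
paired single-plaque spatial proteomics: quality control and detection-aware
differential abundance on DIA protein-group matrices, temporal trajectory
classification, planar-filtered co-expression network analysis with module,
hub and trait statistics, order-statistics consensus ranking across studies,
and gene-set overrepresentation. Everything runs on log2 intensities;
fold changes are differences of log2 values throughout.

## The paired-capture data model

The unit of observation is a laser-capture pair: one amyloid-plaque capture
and one adjacent non-plaque control from the same tissue section, sharing a
`pair_id` within a model-by-age stratum (e.g. 5xFAD at 3, 8 and 14 months).
Intensities are missing not at random: detection probability falls as latent
abundance drops below the instrument's effective limit. That left-censoring
is why detection *counts* carry signal (the G-test step), why imputation uses
a per-sample detection floor, and why network correlations are computed
pairwise-complete.

## Synthetic cohorts (the test substrate)

`simulate.generate_cohort` draws, per protein, a baseline from
N(`baseline_mean` = 20, `baseline_sd` = 2) on the log2 scale; per capture
pair, a shared offset from N(0, `pair_offset_sd` = 0.5 x `baseline_sd`)
modelling capture/loading effects (this is what gives the paired test its
power advantage, and what median normalization must remove); and residual
noise with SD `noise_sd` = 0.5. A fraction `frac_dap` = 0.05 of proteins is
elevated in plaque samples by `effect_size` = 2.0 log2 units, modulated by a
temporal class: early/constant proteins carry the full effect at every age;
late accumulators carry multipliers (0, 0.1, 1) across the first/middle/last
age; decliners carry (1, 0.5, 0). The late mid-age multiplier is kept below
the classification threshold so the planted label always agrees with the
noiseless classification rule. An amyloid-beta tracer protein carries a
plaque enrichment that strictly increases with age — (1.0, 2.5, 4.0) log2
units over three ages — and `n_tracer_followers` = 10 proteins share its
exact age profile so the tracer-correlation screen has planted positives.
`n_blocks` = 5 blocks of `block_size` = 20 proteins share a per-sample latent
factor giving pairwise correlation `block_rho` = 0.8 (a one-factor model:
noise = sd x (sqrt(rho) z_block + sqrt(1-rho) z_indiv)); the first
`plaque_linked_blocks` = 1 block additionally carries the plaque effect so
module-trait analysis has a planted positive. Detection is Bernoulli with
probability logistic((latent − `missing_midpoint`) x `missing_slope`)
(defaults 17.0 and 1.0, i.e. ~10-15% missingness concentrated at low
abundance); `missing_midpoint = -inf` disables censoring. A configurable
fraction (1%) of proteins carries contaminant-style `CON__KRT` identifiers.
All randomness flows from one `numpy` generator seeded by `seed`, so a
config reproduces its matrix bit-for-bit.

What the generator does *not* emulate: peptide/spectrum-level structure,
retention-time or ion-mobility effects, batch drift across acquisitions,
heavy-tailed or protein-specific noise, and biological covariance beyond the
one-factor blocks. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not performance on
any particular real acquisition.

## QC and normalization

Contaminant filtering is case-insensitive substring matching against a
user-supplied pattern list (shipped default: keratin/trypsin/`CON__`
patterns); proteins detected in fewer than 3 samples are dropped (a protein
at exactly 3 is kept). Median normalization shifts each sample additively so
its median observed intensity equals the grand median of pre-normalization
sample medians — scale-preserving rather than centering at zero. Because the
target is data-derived, normalization is invariant to per-sample offsets only
up to a common constant; downstream stages are unaffected since every
statistic uses within-stratum contrasts or correlations. Median
normalization assumes most proteins are unchanged between samples; cohorts
in which a large fraction of the proteome is plaque-shifted would bias the
plaque-sample medians, so the synthetic network cohorts keep planted
plaque-shifted proteins near 5% of the proteome, matching the differential
fraction the pipeline is designed around.

## Differential abundance (per model-by-age stratum)

1. **Detection G test.** Per protein, the 2x2 detected/missing by
   plaque/control table is tested with the likelihood-ratio statistic
   G = 2 sum O ln(O/E) (zero cells contribute zero), p from chi-square with
   1 df. Degenerate margins (all detected or all missing in both groups)
   return G = 0, p = 1 by convention rather than erroring. The test is
   two-sided.
2. **Conditional equalizing imputation.** Only when the G-test p < 0.05,
   missing cells in the group with *fewer* detections are imputed — each
   with that sample's minimum observed intensity across all proteins, the
   natural floor under left-censoring — in ascending sample-id order until
   detection counts are equal or no missing cells remain. The
   better-detected group is never modified, and missing values are never
   filled wholesale. The ordering rule is a deterministic, minimal
   realization of the stated goal (equal detections).
3. **Moderated paired t-test.** Per protein, paired log2 differences
   (pairs with a missing member are dropped; at least 3 complete pairs
   required, otherwise the protein is reported untested with a reason). The
   per-protein variance s2_g with d_g = n−1 df is shrunk toward a prior:
   s2_post = (d0 s2_0 + d_g s2_g)/(d0 + d_g), t = mean / sqrt(s2_post/n),
   df = d0 + d_g. The prior (d0, s2_0) is fitted once per comparison by the
   scaled-F method of moments on log s2_g (the classic empirical-Bayes
   variance-moderation fit; our implementation matches Bioconductor limma's
   `fitFDist` to 6 decimals on shared data, and reduces exactly to the
   classical paired t at d0 = 0). Both hyperparameters can be injected for
   testing.
4. **BH FDR** across tested proteins within the stratum (step-up, NaN
   p-values excluded from the test count).
5. **log2FC-z thresholding.** Fold changes are standardized (mean/SD,
   ddof 1) across all tested proteins of the comparison; a protein is a DAP
   iff q < 0.05 and |z| exceeds the species threshold — 2.5 for mouse
   comparisons, 2.0 for human. Direction follows the sign of the fold
   change.

The z-standardization uses mean/SD rather than a robust variant, and the
sample (ddof 1) SD; both choices are conventions the published description
leaves open, fixed here and exposed in one place.

**Tracer correlation screen.** Pearson R of every protein against the tracer
across plaque samples pooled over ages (pairwise-complete, minimum 6 shared
observations; a config switch pools all samples instead). Proteins with
R > 0.8 and the top 20 by R are reported.

## Temporal trajectories

For each DAP, mean log2 plaque abundance per age is baseline-normalized by
subtracting the earliest-age (3-month) mean. Proteins whose post-baseline
deltas point in opposite directions at 8 and 14 months are excluded, with a
tolerance: sub-threshold deltas (|Δ| <= `tol` = 0.1 log2 units) do not count
as a direction, so noise-level sign flips are not excluded. The remaining
proteins are classified by a deterministic rule with threshold `tau` = 0.5
log2 units: decline if Δ(14m) <= −tau; late if Δ(14m) >= tau and
Δ(8m) < tau; early/constant otherwise (including near-zero profiles). This
replaces manual, clustering-guided curation — which is not reproducible —
with a rule validated by planted-truth recovery (>= 95% over seeds); an
exploratory average-linkage mode (k = 3) is available but not the default.

## Co-expression network

**Input.** Proteins with >= 50% missingness are dropped; values are
median-centered per protein and conditions stay merged.

**Edge screen.** Pairwise-complete Pearson correlations among all proteins
(pairs with < 3 shared observations are skipped). The null pools |rho| from
`n_perm` rounds in which every protein's sample order is permuted
independently — a global null across pairs, chosen for tractability over
per-pair permutation. For a threshold t, FDR(t) = mean null count(|rho| >= t)
/ observed count(|rho| >= t); each edge's q is the minimum FDR over
thresholds at or below its |rho| (a reverse cumulative minimum, so q is
monotone in |rho|), and edges with q <= 0.05 are retained.

**Planar filtered network.** Retained edges are inserted in descending
|rho| order (ties broken lexicographically) and kept only if the graph
remains planar (incremental planarity testing), stopping at the planar
capacity 3(V−2). Planarity acts as a sparsity budget that keeps only the
locally strongest correlation structure.

**Modules.** Each connected component is a root. A subgraph with at least
2 x `min_size` nodes is split by its maximum-modularity partition (Louvain,
|rho| weights, seeded); the split is accepted when observed modularity
exceeds the 95th percentile of modularities on `n_null` random *planar*
graphs with the same node and edge count — random Apollonian (tetrahedral)
triangulations pruned to the observed edge count, with the observed weights
permuted. A planar null is essential: subgraphs of a planar network are
planar, and planarity alone induces locality that inflates modularity, so a
non-planar (degree-preserving rewiring) reference mis-calibrates the test —
on planted 5-block cohorts the planar null recovers blocks at ARI ~0.9 while
the rewiring null collapses to ~0.5. Accepted children recurse; modules
sized outside [`min_size` = 10, |V|/2] are excluded from reporting but keep
their place in the hierarchy.

**Hubs.** Within a module, a node's strength is the sum of |rho| to module
members. The null draws random same-node/same-edge-count graphs with the
observed weights permuted onto random edges, pooling strengths across nodes
and draws; a node is a hub when its empirical p < 0.05 (BH q reported
alongside). The pooled random-graph null (rather than rewiring the module
subgraph itself) is required for the test to have any power on homogeneous
degree sequences — a star's center is the unique hub, a regular ring has
none. A post-filter for hub export keeps hubs with |log2FC-z| > 1.5 and a
consistent direction across strata.

**DAP enrichment.** Modules are tested against proteins ranked by |log2FC-z|
with a weighted Kolmogorov-Smirnov running sum (hit weight = the statistic,
exponent 1). The p-value is the fraction of `n_perm` = 10,000 random
same-size member sets whose score reaches the observed one; BH across
modules. On random modules the p-values are uniform (KS-checked in the
tests).

**Module-trait.** The module eigengene is the first principal component
score of the standardized member-by-sample submatrix (members with >= 50%
missingness dropped; remaining gaps mean-imputed for the PCA only), scaled
to unit variance and sign-oriented to correlate non-negatively with the mean
member profile. Pearson correlation with the 0/1 plaque indicator, exact
t-based p, BH across modules; a module is trait-associated iff q < 0.05 and
|r| >= 0.4.

## Consensus ranking

Each study contributes ranks 1..M (average ranks for ties), normalized to
r = rank/M in (0, 1]. For a protein with sorted normalized ranks
r_1 <= ... <= r_N over the N studies where it appears, Q is the joint
probability that all N uniform order statistics fall below those values,
computed by the alternating recursion Q = N! V_N with
V_k = sum_i (−1)^(i−1) V_{k−i} r_{N−k+1}^i / i!. The recursion is evaluated
in exact rational arithmetic (Python `Fraction`), so the catastrophic
cancellation that plagues the floating-point form cannot occur for any
N <= 20; the result is clamped to (0, 1]. Proteins present in fewer than
`min_datasets` = 3 studies are reported separately as unrankable (an
alternative policy imputes worst-rank r = 1 for absent studies); Q is used
ordinally — consensus order is Q ascending, ties broken by mean normalized
rank then id — and no p-value is attached, since no null-rank calibration
is defined. Q over available datasets is not rescaled across differing N.

## Overrepresentation

One-sided Fisher's exact test per gene set (hypergeometric upper tail
P(X >= a)), fold enrichment (a/k)/(K/M), BH across sets; a set is reported
iff q < 0.01 and fold > 2. The background defaults to the proteins
quantified in the comparison — the conservative choice — not the whole
proteome. Gene sets are read from GMT files; there are no live database
queries.

## Numerical and determinism choices

Ties are broken lexicographically on protein id everywhere an order matters
(edge insertion, consensus ties, module child ordering), so every stage is
deterministic given its seed. Degenerate inputs have defined behavior:
degenerate G-test margins return (0, 1); constant fold-change vectors raise
rather than silently producing zeros; a zero posterior variance yields
infinite t (p = 0) unless the mean difference is also zero (t = 0, p = 1);
all-zero per-protein variances fall back to the classical t with a warning.
Problem sizes in the test suite and acceptance script (2,000-protein
single-age cohorts for the differential stage, 400-protein cohorts with
five 20-protein blocks for the network stage, 20 edge permutations and 60
module nulls, 10^5-10^6-draw Monte-Carlo oracles) were chosen as the
smallest sizes at which the planted effects are comfortably identifiable
under the stated noise model.

## Known limitations

The module-detection procedure is a documented stand-in for multiscale
clustering of the full MEGENA kind: it preserves the contract (hierarchical
modules on the PFN, significance against planar-network nulls, size
filters, hub significance) but not the exact algorithm, so module
boundaries on real data will differ from a MEGENA run. The edge-screen null
is global across pairs, which is slightly conservative for proteins with
unusual missingness patterns. Q-values from the consensus stage are not
calibrated probabilities across proteins with different N. The generator's
noise model is Gaussian with a single shared SD; real DIA noise is
intensity-dependent.
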