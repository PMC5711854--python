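# Methods notes

This note records the statistical conventions, default parameters and
design choices behind `microkit`, and what the synthetic cohorts do and do
not establish about real data.

## Data model and rarefaction

OTU tables are validated integer count matrices, samples × OTUs; the
BIOM-style TSV dialect (`#OTU ID` rows, trailing taxonomy column) is
transposed on read. Rarefaction subsamples each retained sample to a fixed
depth **without replacement** (multivariate hypergeometric draw, the QIIME 1
behaviour), default depth 9000 with 1000 permutations; permutation *k* uses
seed `seed + k`, and the averaged table (mean count over permutations, not
necessarily integral) is the default input to diversity metrics. Samples
below depth are dropped (or raise, by policy). Raw counts — not the
rarefied table — feed the Hellinger/RDA/WT-index path by default: the
Hellinger transform already normalises sequencing depth, so rarefying
first would only discard reads. A flag on the pipeline could route the
rarefied average there instead; we deliberately did not add one to keep the
two paths' contracts distinct.

## Diversity conventions

* Shannon entropy uses log base 2 (bits), matching QIIME 1.
* Faith's PD includes the path to the root (`PD_whole_tree` convention):
  the minimal subtree spanning observed leaves **and** the root.
* Bray–Curtis is computed on proportions by default, since the metric is
  depth-sensitive on raw counts; a raw-count mode exists for rarefied
  inputs where totals are equal by construction.
* PCoA is classical metric scaling of the double-centred −½D²; negative
  eigenvalues are clamped to zero and excluded from the
  proportion-explained denominator. No Lingoes/Cailliez correction is
  applied — Bray–Curtis matrices at these scales embed well enough, and the
  correction would change eigenvalue shares silently.
* Deviation from baseline: the reference profile is the mean proportion
  vector over a unit's samples with timepoint < 0, where the unit is the
  sample's group (default) or subject. Group centroids are the default
  because per-subject baselines confound subject noise with drift at small
  n per timepoint.

## RDA, key OTUs and the WT-index

With a single binary constraint, RDA's constrained subspace is the group
centroid-difference direction of the column-centred Hellinger matrix; the
constrained eigenvalue is the between-group sum of squares. "Explains more
than 10% of the variability" is operationalised per OTU as the R² of its
Hellinger column on the group indicator — the per-species goodness-of-fit
of the single constrained axis (the `vegan::goodness` analogue), the only
per-OTU "fraction of variability" with a clean definition here. Constant
columns get R² = 0. Enrichment direction (set *N* vs *M*) uses Hellinger
group means, consistent with the index operating on `A_ij`; zero
differences are excluded, and an empty *N* or *M* is an error because the
index is undefined.

LOOCV is honest: selection (variance explained *and* direction) is refit on
every training fold, and the held-out sample is scored with that fold's key
set; folds whose selection fails score 0 and are logged. A fixed-key-set
mode (`wt_index` with a stored `KeyOtuSet`) serves scoring new cohorts with
a previously derived index. AUC uses the midrank Mann–Whitney form, so ties
count 1/2. The CI is a stratified percentile bootstrap (resampling scores
within class, 1000 replicates, 95%); stratification guarantees both classes
in every replicate. Percentile intervals may exclude the point estimate in
edge cases; only `ci_low ≤ ci_high` is enforced.

## SparCC and networks

SparCC defaults: 20 estimation iterations, 10 exclusion iterations,
exclusion threshold 0.1 (the published algorithm's defaults). Each
estimation iteration draws fractions from Dirichlet(counts + 1), forms
`T_ij = var(log x_i/x_j)` from the sample covariance of log fractions, and
solves `M ω = t` with `M = ones + (p−2)·I`; basis variances are floored at
1e-12 and correlations clipped to [−1, 1]. Exclusion removes the strongest
|r| pair above threshold from the system (decrementing `M`, zeroing that
`T` entry) and stops if any diagonal would drop to 1. The reported matrix
is the elementwise median over estimation iterations, symmetrised with a
unit diagonal. At least 4 OTUs and 4 samples are required.

Permutation p-values shuffle every OTU's counts independently across
samples (destroying inter-OTU association, preserving marginals) and
recompute SparCC with 5 estimation iterations per permutation — the
reduced count triples throughput and only adds noise that is symmetric
between observed and permuted statistics. `p = (1 + #{|R_perm| ≥
|R_obs|}) / (n_perm + 1)`: the add-one keeps p strictly positive so the
strict `p < 0.05` edge rule remains meaningful. No multiple-testing
correction is applied to edge p-values — the thresholds are a published
convention, not an inference claim. Edges require strictly `p < 0.05` and
`|R| > 0.7`; isolated nodes stay in the node list.

Topology follows the Cytoscape NetworkAnalyzer conventions: the clustering
coefficient averages local clustering over **all** nodes with degree-<2
nodes contributing 0 (an exclude mode exists behind a flag);
characteristic path length averages shortest paths over connected pairs
only; centralization is Freeman's `Σ(deg_max − deg_i)/((n−1)(n−2))`;
eigenvector centrality is the principal adjacency eigenvector of the
largest connected component (ties broken by component size then node
order), made non-negative and max-normalised, zero elsewhere, on the
unweighted edge set — thresholded |R| > 0.7 edges are near-binary, so
weighting adds little (a weighted mode exists). KS comparisons use the
asymptotic two-sample statistic.

## Group statistics

Mann–Whitney U uses midranks, exact enumeration p when n1+n2 ≤ 12 without
ties, and the tie-corrected normal approximation (with continuity
correction) otherwise. FDR control is Benjamini–Hochberg step-up. Note the
step-up adjustment is *not* idempotent: re-adjusting adjusted values can
only move them up (`q'_(i) = min_{j≥i} (m/j) q_(j) ≥ q_(i)`); tests assert
the monotone/bounds properties and FDR control by simulation instead.

MANOVA on principal coordinates retains the smallest number of axes whose
cumulative share of positive eigenvalue mass reaches the variance target
(default 80% — the axis count is data-determined, not fixed) and tests
group separation with Pillai's trace (chosen over Wilks for robustness to
covariance heterogeneity; Wilks is available). With one retained axis
Pillai's trace is η² and its F approximation is exactly the one-way ANOVA
F, computed directly; exactly coincident group centroids (a degenerate
null) return statistic 0, p = 1. Taxon-level testing collapses counts to
relative abundance at the requested rank (greengenes-style `p__` prefixes
or positional lineage parsing; missing ranks pool into "Unclassified")
and BH-adjusts across all tested taxa.

## Synthetic cohorts

The generator draws per-sample basis log-abundances from a multivariate
normal (per-OTU baseline means spread with sd 2.0 on the natural-log scale
— giving the several-orders-of-magnitude rank-abundance unevenness typical
of 16S data — plus optional within-block correlation, block ρ on top of a
common per-OTU log-sd of 1.0), shifts planted OTUs' means by
`effect_log2fc·log 2` (default 2 log2 units) positively for
reference-enriched and contrast-enriched OTUs in their respective groups,
closes to proportions, and draws multinomial counts at the sample's depth
(fixed 9000 by default, optionally lognormal). Defaults mirror a mouse
cohort: 300 OTUs, 15 samples per group, 20 reference-enriched and 30
contrast-enriched planted OTUs.

Planted differential OTUs take above-median (half-normal) baseline
log-abundances. The pattern being emulated — tens of enriched/depleted
OTUs identified and ranked by ordination in real data — consists by
construction of taxa observable at the study's sequencing depth; an
"effect" planted on an OTU whose expected count is ~0 at depth 9000 is
invisible to any analysis and models nothing the original measurement
could contain.

`GroundTruth.expected_proportions` is the closed-form lognormal-mean basis
composition `exp(μ + σ²/2)`, normalised; empirical mean proportions
converge to it up to the (small, second-order) bias of a ratio expectation,
which the convergence test absorbs at moderate basis spread.

The longitudinal generator gives each subject an independent Gaussian
random walk on basis logs with per-group step sd scaled by √(day gap), so
drift accumulates with time and a larger-drift group deviates further from
its baseline centroid.

What the cohorts do **not** emulate: taxonomic structure (taxonomy strings
are attached only where tests need them), sequencing error and chimeras,
overdispersion beyond lognormal×multinomial (a Dirichlet-multinomial mode
was considered and left out: SparCC's own model is log-scale basis
correlation, which is the structure under test), phylogenetic signal in
abundances, and real cage/litter effects. Passing tests therefore
establish correctness of the algorithms under their own modelling
assumptions, not performance guarantees on real sequencing runs.

## Problem sizes and determinism

Library defaults keep the published resampling scales (1000 rarefaction
permutations, 1000 network permutations, 1000 bootstrap replicates). The
test suite and the demonstration scripts run reduced scales — e.g. 99–500
network permutations, 20–100 bootstrap replicates, 20-OTU null panels —
chosen so the whole suite completes in well under a minute of compute per
module while the Monte-Carlo tolerances stated in each test remain valid
at those sizes. Every stochastic operation takes an explicit integer seed;
derived seeds (rarefaction's `seed + k`, the pipeline's per-stage offsets)
are documented where they occur, and `run_full` writes no timestamps, so
identical configs reproduce outputs bit-for-bit.

## Known limitations

* RDA is implemented only for the single binary constraint the index
  needs; multi-factor or partial RDA is out of scope.
* SparCC's basis-variance solve is the published approximation; it can
  mis-estimate when many strong correlations exist (the exclusion loop
  mitigates, not eliminates, this).
* Exact Mann–Whitney enumeration is limited to n1+n2 ≤ 12; beyond that the
  normal approximation is used even for small unbalanced designs.
* The permutation scheme for edge p-values treats samples as exchangeable;
  longitudinal autocorrelation within subjects would inflate significance
  if such data were fed to it ungrouped.
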