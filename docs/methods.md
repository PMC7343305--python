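# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, the numerical conventions, what the synthetic
generator does and does not emulate, and the known limitations.

## Preprocessing

Samples are retained when they have at least 1,000 reads, complete
metadata (including tobacco-use information — samples missing it are
flagged rather than imputed), and match no exclusion predicate (the
standard analysis drops former smokers, leaving a clean never/current
contrast). Rarefaction draws without replacement from each sample's
reads — a multivariate hypergeometric draw, so rarefied counts never
exceed the originals and every retained row sums exactly to the target
depth (6,500 by default; 6,250 after genus stripping, compensating for
the removed reads). A single seeded draw is used rather than averaging
over rarefactions; the seed is a required argument wherever rarefaction
occurs.

**Presence** is relative abundance ≥ 1/5,000 (one read at the shallowest
retained depth). The boundary is inclusive; a `strict` flag switches to
a strict inequality for sensitivity analysis. Feature screens: the
"abundant" set is presence in ≥ 10% of samples; prevalence modelling
additionally drops near-universal features (present in more than a
configurable fraction of samples, default 1000/1066 ≈ 0.938), where a
prevalence ratio carries almost no information.

## Diversity

Alpha metrics are observed ASVs, Shannon entropy in **bits** (base-2
logarithm, the common amplicon-pipeline convention), and Faith's PD
including the stem path to the root (a flag excludes it). Alpha models
are OLS with age, sex and run always included; further covariates enter
by greedy forward selection only while AIC strictly decreases, and each
term's contribution is the leave-one-out drop in R². Residual normality
is reported as a Jarque-Bera p-value, a diagnostic rather than a gate.

Beta diversity: Bray-Curtis, unweighted UniFrac, and **unnormalized**
weighted UniFrac (the normalized variant is available by flag), all
computed through scikit-bio on rarefied counts.

**PERMANOVA (adonis)** partitions the Gower-centered matrix
G = −½·J·D²·J sequentially (Type-I): terms are fitted in the declared
order via cumulative hat-matrix projections, so adjustment covariates go
first and disease status last — its R² is the incremental, adjusted
share. Pseudo-F per term uses the final residual. Permutations shuffle
sample labels freely (no strata), and p-values include the observed
statistic: p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), with 9,999
permutations by default. A term that is fully collinear with earlier
terms contributes 0 df and 0 SS and gets no p-value rather than an
error; a single-level term is an error. R² across terms plus residual
sums to 1 by construction.

Dispersion uses permdisp with the spatial-centroid estimate and 999
permutations; Mantel tests default to Pearson (Spearman by flag) with
999 permutations. PCoA reports negative eigenvalues but excludes them
from the proportion-explained denominator; no Cailliez correction is
applied by default. Group-distance summaries report within- and
between-group means with percentile bootstrap 95% CIs, pairwise
permutational t-tests (between-group distances vs pooled within-group
distances, label-permutation null), pairwise PERMANOVA, and flag a group
"heterogeneous" when its mean within-distance exceeds its mean distance
to every other group.

## Differential signals

**Prevalence ratios.** Per feature, the presence indicator is modelled
by a Poisson GLM with log link on status plus covariates (age, sex, run,
smoking, community, teeth), with HC0 sandwich variance — the standard
robust-Poisson approximation to log-binomial regression whose
exponentiated status coefficient is the prevalence ratio. HC1 is
available by flag. Constant-presence features are skipped with a note;
Benjamini-Hochberg correction runs across features and q < 0.05 is the
significance line. With no covariates the estimator reduces exactly to
the ratio of group proportions, which the tests exploit as a closed-form
oracle.

**Modified ANCOM.** Counts are offset by one; for every ordered feature
pair the log-ratio is regressed by OLS on status plus the covariates,
and each feature's W is the fraction of its comparisons whose BH-
corrected status p-value falls below 0.05. The denominator is the number
of comparisons actually made (k−1, reduced when a constant log-ratio is
skipped; normalizing by k is available). BH pooling is per-feature by
default, with a global-pool mode behind a flag — the per-comparison
reading is the more conservative of the two plausible conventions.
Significance is W ≥ 0.8, set a priori. Direction is the sign of the mean
status coefficient over the feature's comparisons ("none" on an exact
tie). The pairwise step is vectorized: with a common design matrix the
pair coefficients are differences of per-feature coefficients and the
pair RSS comes from the residual cross-product matrix, so cost is
O(nk² ) in memory-friendly matrix ops rather than an explicit pair loop;
tests verify exact agreement with an independent per-pair OLS oracle.

## Variant niche analysis

Carriage states (A only / both / B only / neither) come from the same
≥ 1/5,000 presence rule applied to the two focal variants; "neither"
samples are excluded downstream. The display log-ratio ln(rel_B/rel_A)
maps single carriers to ±15 sentinels — presentation only; models always
use the categorical states. The multinomial logit fixes A-only as the
reference and adjusts for age, sex, run, teeth, community and the
relative abundances of the focal species and its congener; CIs are Wald
(profile CIs were not implemented), and coefficients with |β| > 15
raise a separation flag.

**Variance attribution** quantifies how much of the status community
signal the variant explains: two sequential PERMANOVA fits share the
covariates and end with status; the second inserts the carriage term
just before status. The reported proportion is
(R²_status,excl − R²_status,incl) / R²_status,excl — the share of the
adjusted status R² absorbed by the variant. It can be negative in noise
(reported and flagged, never clipped). Term order is configurable; the
proportion is invariant to relabeling which variant is called A.

Genus stripping removes the named features, re-rarefies to 6,250, and
recomputes all three beta metrics plus Mantel agreement against the
full-community distances on the shared samples. Richness across carriage
states uses pairwise two-sided rank-sum tests with BH correction on the
genus-stripped observed-ASV counts.

## SparCC networks

Basis correlations are estimated from log-ratio variances
t_ij = var(log x_i / x_j): under the sparsity assumption the basis
variances solve a linear system in the t row sums, and
r_ij = (w_i + w_j − t_ij) / (2√(w_i w_j)). The most correlated pair
above |r| = 0.1 is excluded and the system re-solved, up to 10
iterations (the original algorithm's defaults; both configurable), never
disconnecting a feature entirely. Fractions default to a single
pseudocount estimate (c+1)/(Σc+k); a Dirichlet-resampling mode (median
over draws) is available. Estimates are clamped to [−1, 1] with a
warning, symmetrized, and require ≥ 4 features (the system is
underdetermined below that).

Networks keep edges with |r| ≥ 0.3 (inclusive). Cluster extraction is
seed-and-follow: repeatedly seed at the most connected remaining node
(degree counts both signs; ties break lexicographically for
determinism) and follow positive edges transitively. Negative edges
between clusters are recorded; a singleton whose only link is one
negative edge into another cluster is flagged as a trimmed pendant
(clusters still partition the node set). Coexclusion candidates are
negatively linked pairs — directly or across negatively joined
clusters — whose sequences differ by at most one mismatch (Hamming
distance; candidate variant pairs are same-length ASVs).

## Synthetic data

The generator draws, per sample: covariates (smoking correlated with
case status — the central confounder), a carriage state from a
group-specific mixture, per-feature basis abundances
log a = log baseline + status·β + smoking·γ + niche shift + ε with
ε ~ N(0, σ²) (σ = 1, with an optional planted correlation between one
feature pair), then composition noise via a Dirichlet draw
(concentration 200) and a multinomial at a depth uniform on
[5,000, 20,000] — so rarefaction at 6,500 drops a realistic ~10%
minority. In single-carrier samples the absent variant has zero
Dirichlet mass, making it a structural zero: carriage classification is
exact and the present variant dominates by an infinite ratio, which
trivially satisfies the ≥50-fold dominance contract. The tree is a
random bifurcating topology with exponential(1) branch lengths and the
variant pair forced sister; their sequences differ at exactly one
position, so unweighted UniFrac is nearly insensitive to which variant a
sample carries — the niche signal must come from the correlated shift in
20 background ASVs, mirroring the single-nucleotide biology the analysis
targets.

The default preset (1,000 subjects, 250 ASVs) plants: two strongly
case-enriched common ASVs (log-fold change +1.6), 51 control-enriched
lower-prevalence ASVs with log-fold changes between ln 0.5 and ln 0.8
(targeting prevalence ratios around 0.7–0.9 — the effect scale is a
choice, as only the count and direction of such features are
constrained), carriage mixtures that marginalize to roughly
33/32/35% A-only/B-only/both with case enrichment of variant B, smoking
effects on 10 ASVs, and one basis correlation of 0.8. Baselines of the
planted features are pinned near the presence threshold so prevalence
effects are identifiable.

What the generator does **not** emulate: taxonomic block structure and
phylogenetic signal in abundances (the tree is independent of the
baseline), batch effects tied to sequencing run, zero-inflation beyond
the Dirichlet-multinomial, chimeras and denoising artifacts, and truly
compositional interactions among more than the planted pair. Passing
tests therefore demonstrate correctness of the statistical machinery and
recoverability of planted structure under realistic noise — not
performance on any real cohort.

## Numerical choices and problem sizes

Permutation p-values always include the observed statistic in numerator
and denominator. Hat matrices use the pseudoinverse; PERMANOVA term
ranks come from numerically determined matrix rank. The MD5 display
hash is computed on the uppercased sequence. Calibration tests run 200
null replicates per permutation test with 199 permutations each, and
the end-to-end checks use the full preset at 1,000 subjects; these sizes
give rejection-rate standard errors near 1.5% against the nominal 5%
level. The multinomial model is fitted by Newton iterations (tolerance
at statsmodels defaults); saturated fits agree with closed-form
cross-product ratios to 1e-6.

## Limitations

- PERMANOVA supports no permutation strata; stratified designs would
  need restricted permutations.
- The robust-Poisson approximation can yield fitted presence
  probabilities above 1 in extreme covariate corners; log-binomial ML is
  not attempted as a fallback.
- SparCC p-values (bootstrap) are out of scope; edges are thresholded on
  the point estimate, and rarefaction plus overdispersion attenuate
  estimated correlations below the basis value.
- Multinomial CIs are Wald; near-separated tables are flagged but not
  penalized/regularized.
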