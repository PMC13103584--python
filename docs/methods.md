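# Methods

## The design and its null space

The unit of inference is the genotype-matched pair: cultivar *i* grown in
region A and region B gives composites (A_i, B_i), and with n pairs the
only label permutations consistent with the design are the 2ⁿ within-pair
swaps. All primary p-values in this package are exact over that space:

* **p_pair** for a statistic T is `#{relabelings with T ≥ T_obs} / 2ⁿ`,
  identity included in numerator and denominator, so p_pair lives on the
  grid {k/2ⁿ} with floor 1/2ⁿ (0.0039 at n = 8). Ties count toward the
  numerator. The statistic is recomputed from scratch for every mask — at
  256 evaluations there is nothing to be gained from incremental updates,
  and full recomputation keeps arbitrary statistic functionals correct.
* The **exact sign test** and **McNemar's exact test** use the doubled
  smaller binomial tail capped at 1 (8/8 → 2/256 = 0.0078, 7/8 → 18/256 =
  0.0703, 7 discordant one-way → 2/128 = 0.0156). Zero deltas are dropped
  before the sign test (the standard exact-sign convention); concordant
  pairs are ignored by McNemar.
* **Wilcoxon signed-rank** enumerates all 2ⁿ sign assignments on midranks
  for n ≤ 25 (ties therefore need no asymptotic correction) and falls back
  to a tie-corrected normal approximation above. **Spearman** on paired
  deltas enumerates all n! rank orders for n ≤ 8.
* The **unrestricted Monte-Carlo p** over full label shuffles
  ((1 + exceedances)/(1 + n_perm), floor 1/1000 at 999 permutations) is
  reported as a descriptive reference only; it ignores the pairing and is
  never the primary inference.

Negating every delta (swapping region roles) leaves all two-sided p-values
unchanged; this antisymmetry is property-tested.

## Composite indices

VSI and NPI are equal-weight differences of mean z-scores over fixed,
disjoint variable sets (floral/fruity vs resinous/woody volatiles;
phenolic/alkaloid vs amino/nitrogenous analytes). Design choices:

* z-scoring uses the sample SD (n−1). The choice is irrelevant to
  sign-based inference and to any statistic invariant to common scaling.
* Volatile non-detects are stored as exact 0 (never imputed) and enter the
  z-scoring as 0. A feature with zero variance across the standardization
  set is an error, not a silent drop.
* The `Standardizer` stores fitted means/SDs, and transforming held-out
  composites uses only those stored parameters. Inside LOPO every
  standardizer (raw features and indices alike) is refit on the training
  fold; the leakage audit asserts that mutating held-out values changes no
  training-fold parameter.
* Feature names are matched after NFKC normalization, case-folding, and
  spelling out "β", so `β-Caryophyllene` and `beta-caryophyllene` refer to
  the same feature across input dialects. "Linalool oxide" is treated as a
  single named feature rather than a sum of isomers.

## Community statistics

All operate on a dissimilarity matrix (Bray–Curtis by default, computed on
total-sum-scaled genus tables; a CLR transform is available for
compositional sensitivity checks, with zeros replaced by half the smallest
nonzero relative abundance).

* **PCoA** is the eigendecomposition of the Gower-centered matrix.
  Negative eigenvalues are dropped (no Lingoes/Cailliez correction) and the
  negative-inertia fraction is reported, which keeps coordinates real and
  is the most common default.
* **PERMANOVA pseudo-R²** = SS_between/SS_total computed directly from
  squared dissimilarities with a one-factor region model. Cultivar is
  controlled by the permutation restriction itself, not by a model term —
  within-pair swaps never mix cultivars, so a cultivar main effect cancels
  from the comparison.
* **Dispersion** (betadisper analogue) measures each sample's distance to
  its group centroid in the full positive-eigenvalue PCoA space; the F of
  group means of those distances is the statistic. Labels are permuted
  *before* centroids are recomputed — the stricter choice; the spatial
  median variant is not implemented because the centroid version is
  deterministic and hand-checkable.
* **Procrustes m²** is the symmetric scaled residual (both configurations
  centered and scaled to unit trace, optimal rotation from the SVD), so
  m² ∈ [0, 1] and m² = 0 under any similarity transform. Axes are truncated
  to the smaller positive-axis count of the two ordinations. The permuted
  quantity is the concordance 1 − m², making the engine's upper tail
  correct.
* **db-RDA** regresses the positive PCoA axes on the standardized covariate
  matrix; R² is the fitted-to-total sum-of-squares ratio and the adjusted
  value uses the Ezekiel correction 1 − (1 − R²)(n − 1)/(n − p − 1). The
  pair-restricted null permutes response rows within pairs with covariates
  fixed. Covariates enter jointly (no selection).

## Core-taxa audit

Prevalence is the fraction of all composites (both regions pooled) with
nonzero relative abundance; typical abundance is the median. v1.0 core =
prevalence ≥ 70% and median ≥ 0.1%; 30–70% intermittent; < 30% transient.
Genera with core-level prevalence but sub-floor abundance are a definitional
gap and get their own explicit class (`high_prevalence_low_abundance`) —
silent coercion into "core" or "intermittent" would corrupt the audit.

The robustness grid varies prevalence 60–80% (5% steps) × abundance
0.05–0.20% (0.05% steps). Direction consistency is the per-genus fraction
of pairs sharing the modal delta sign, aggregated over the shortlist by
mean (median available). Rank concordance is the Spearman correlation of
|mean within-pair delta| ranks against the v1.0 ranks on the shortlist
*intersection* (union with absent-ranked-last is available by
configuration); under true labels this is 1 by construction, and it becomes
informative under the pair-restricted null, where swapped pairs negate
their delta column and the effect ranks reshuffle.

## LOPO validation

Each of the n folds holds out one pair (both composites) and trains a
random forest (200 trees by default, fixed seed) on the remaining 2(n−1)
samples; probabilities are pooled over all 2n out-of-fold predictions into
a single midrank AUC (per-fold AUC on 2 samples is degenerate). The exact
null reruns the loop for every within-pair relabeling with the classifier
seed held fixed, so the null isolates label structure from forest
stochasticity, and reports p = (1 + #{non-identity AUC ≥ observed})/2ⁿ —
the standard +1 adjustment, identical to counting the identity in both
numerator and denominator. Fold feature matrices (z-scores and index
values) are unsupervised and therefore label-independent; the null
consequently shares them across relabelings, which is exactly equivalent to
rebuilding them per relabeling.

**A symmetry worth knowing:** for a deterministic learner that treats the
two classes symmetrically, the all-pairs swap inverts every training label
consistently, so the inverted model classifies the relabeled truth exactly
as well as the observed model. On a perfectly separable panel both the
identity and the full swap reach AUC = 1.0, and the attainable floor of the
exact p is therefore 2/2ⁿ (= 0.0078 at n = 8), not 1/2ⁿ.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analyses assume,
with defaults chosen as the study conditions:

* 8 pairs, regions ("Menghai", "Puer"); deterministic, byte-identical
  regeneration under a fixed seed.
* **Volatiles**: latent log-Area% with between-pair SD 0.35 and
  within-composite SD 0.15; the floral set receives a region shift of
  `volatile_effect` × the between-composite SD (default 1.0); columns are
  renormalized to 100 after effects are applied, mirroring total-signal
  normalization. The sesquiterpene is a hurdle variable: detected with
  probability 7/8 per pair in region B and 0 in region A, log-normal Area%
  centered near 0.08 (≈ 0.05–0.13 range) when detected, exact 0 otherwise.
* **Non-volatiles**: additive means at realistic mg/g levels, pair SD 13%
  and analytic noise 3% of the mean. EGCG/caffeine shift up and EC/CG down
  by `stable_nonvolatile_effect` (default 0.8) × the between-composite SD —
  at these noise levels a 0.8-SD shift yields all-8-pairs-positive EGCG
  deltas in ≥ 95% of seeds, the calibration the generator is specified to
  achieve. The theanine shift is mean-zero with between-pair SD
  `contingent_sd`, producing sign-mixed deltas.
* **E-tongue**: 5 attributes; `missing_etongue` composites (default 1) are
  missing entirely, so complete-case pairing drops one pair (7/7 patterns).
* **Soil**: OM/TN/HN up, TK/urease down in region A by `soil_effect`
  (default 1.2) — a separate knob so the soil layer can be silenced
  independently in null calibrations.
* **Genus tables**: logistic-normal/multinomial model — per-genus
  baselines (SD 1.5 on the log scale), per-pair latent site factors shared
  across kingdoms and scaled by `cross_kingdom_rho` (default 0.6, which is
  what makes bacterial and fungal ordinations Procrustes-concordant),
  a `microbe_effect` log-fold region contrast (default 1.0) split evenly
  between up- and down-shifted genera on a random 20% subset, per-sample
  noise SD 0.25, and multinomial sampling at `depth` (default 50,000, above
  the package's reference rarefaction depths of 44,867/41,725) so every
  column sums exactly to depth.

It does **not** emulate: chromatograms or reads (no ASV inference),
taxonomic structure, overdispersion beyond the logistic-normal layer,
spatial or temporal autocorrelation, or any climate/soil process model.
Passing tests on synthetic cohorts therefore demonstrate correctness of the
inference machinery under the assumed structure, not robustness to real
amplicon artefacts.

## Numerical choices and problem sizes

* Exact-test p-values are ratios of integers (over 2ⁿ, 2^d, or n!); float
  comparisons in the engine use plain ≥, and the identity relabeling is the
  literal same computation as the observed statistic.
* PCoA retains eigenvalues above 1e-10 × the largest; CLR pseudocount is
  half the smallest nonzero relative abundance.
* Null-calibration tests use 500 seeds (rejection bounded by
  0.05 + 2·binomial SE); effect-recovery tests use 25–60 seeds with
  majority criteria. The acceptance script runs the LOPO null with a
  100-tree forest; the library default is 200 trees. These sizes are the
  package's own desk-scale choices.
* Degenerate inputs fail loudly: zero-variance features for z-scoring or
  dz, all-zero samples for Bray–Curtis, constant vectors for Spearman, and
  rank-deficient covariate matrices for db-RDA are errors naming the
  offender; all-zero delta vectors and zero-discordance McNemar return
  p = 1 with a degeneracy flag instead.

## Known limitations

* The e-tongue layer and hurdle detection are Bernoulli/Gaussian sketches;
  they support the missingness and detect/non-detect *mechanics*, not
  sensor physics.
* The dispersion test implements only the centroid variant; the db-RDA
  covariate set is user-specified with a pragmatic default (pH, OM, TN,
  sucrase, VSI, NPI).
* Whether genus tables for the core-taxa audit should be rarefied or
  total-sum-scaled is a configuration choice (both are supported); the
  pipeline default audits the unrarefied relative abundances.
* The package reports both paired t and Wilcoxon for every continuous
  contrast rather than choosing by a symmetry diagnostic; which one is
  "primary" is a reporting decision left to configuration.
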