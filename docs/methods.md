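# Methods

`cytostrat` re-implements, as a tested pipeline, a blood mass-cytometry
immunophenotyping analysis for lupus nephritis (LN): per-cell preprocessing
and clustering, a cytometric type-I-interferon (IFN-I) score, covarying
neighborhood differential abundance, K-means stratification of patients into
three immunologic groups (control-like G0, IFN-high G1, cytotoxic-enriched
G2), clinical association models, and a rule-based week-52 renal-response
classifier.  Because the real cohort is controlled-access, every stage is
exercised on a bundled synthetic-cohort generator with full ground truth;
this note records the models, the defaults, and the choices made where the
design was genuinely open.

## Synthetic cohort model

Each sample is a set of per-panel event tables drawn from a catalog of ~21
latent cell subsets across the T, B, myeloid, and NK lineages.  Four
overlapping panels share the canonical lineage markers (CD3, CD19, CD14,
CD56, CD11b, CD16) and add lineage-focused function markers; the IFN-induced
score markers live on the panels that would carry them in practice (MX1 on
T, ISG-15 on B, Siglec-1 on myeloid).

*Compositions.*  Within-lineage subset fractions are logistic-normal:
Gaussian noise (SD 0.3) on the additive-log-ratio scale around baseline
fractions, shifted by planted per-group log fold changes.  Three latent
per-sample factors (interferon tone, proliferation, cytotoxicity; loadings
~0.15–0.25) induce the correlated co-abundance blocks that the correlation
map stage targets.  A logistic-normal rather than a Dirichlet is used
precisely so that such correlations can be planted.

*Marker values.*  Per cell, Gaussian on the arcsinh scale around the
subset's template mean (default SD 0.35), plus planted per-group shifts
expressed in units of the marker's SD, plus batch effects.  Events are
inverse-transformed (`sinh(x)·cofactor`, negatives clipped at zero) so the
pipeline's own transform runs on raw-scale input; the clip is the only
deviation from an exact round trip.

*Planted groups.*  G0-like carries zero effects by construction.  G1-like:
+2 SD on all three score markers (between-sample SD 0.4) and roughly 2-fold
expansion of Ki67+ proliferating T/B/NK subsets.  G2-like: 2.2–2.5-fold
expansion of granzyme-B+ T subsets, CD21-low naive B cells and low-density
neutrophils, reduced CD21 on naive B cells, an intermediate and deliberately
more variable IFN shift (+1.2 SD, between-sample SD 0.8), and expanded
proliferating subsets.  With G0 planted as exactly control-like and the
three LN groups equally sized, the expected IFN-elevated fraction among LN
samples is ~2/3 (G1 and G2 essentially always elevated, G0-like essentially
never); a higher elevated fraction would require either unequal group sizes
or a non-control-like G0 and is not forced.

*Batch effects.*  Additive per-(batch, panel, marker) location shifts
(SD 0.15 on the arcsinh scale) and a mild multiplicative scale jitter
(±10 %) — the simplest model the batch-correction contract can verifiably
remove.

*Clinical coupling.*  NIH activity index is drawn around group means
11/8/4 (G2/G1/G0, SD 3, clipped to 0–24) and chronicity around 2.5/3/5
(SD 1.6, clipped to 0–12), reproducing the directional pattern of highest
activity in the cytotoxic group and highest chronic damage in the quiescent
group.  Proliferative histology probabilities are 0.85/0.65/0.35.  Complete
renal response follows a logistic model with a planted G2 log-odds offset of
ln 8.5; the intercept is solved numerically so the marginal
complete/partial/none rates are 28 %/24 %/48 %.  Week-52 UPCR, creatinine
and prednisone are generated consistently with the drawn category, so the
rule-based classifier reconstructs it exactly on evaluable patients
(baseline UPCR ≥ 1, 75 % of LN samples by default).  Covariates (age, sex,
ethnicity, race) are drawn independently of group, so adjusted models are
estimating a truly unconfounded effect.

*What the generator does not emulate:* spillover, bead normalization,
doublets, acquisition drift, non-Gaussian marker distributions
(e.g. zero-inflation), confounded demographics, or informative missingness.
Passing tests therefore demonstrate correctness of the analysis machinery
under a known truth, not robustness to every artifact of real CyTOF data.

## Preprocessing

* **Transform** — `asinh(x / cofactor)`, cofactor 5 (mass-cytometry
  convention), configurable and invertible.
* **QC** — a sample is dropped iff viability < 0.50 (strict), it has zero
  B cells, or > 90 % (strict) of its cells fall in one provisional cluster.
  The occupancy rule is evaluated on the lineage-level clustering of the
  pooled B-panel events; viability is an input column, since the markers
  that measure it are not simulated.
* **Batch correction** — iterative soft-anchor matching: k-means anchors on
  the pooled matrix, Gaussian responsibilities, per-anchor per-batch
  weighted location offsets subtracted until convergence, preceded by a
  global per-batch scale match toward the pooled SD.  Batches smaller than
  the anchor count fall back to global location matching (logged).  Cell
  and sample counts are never altered.  Correction runs per panel.
* **Clustering** — kNN graph (k = 15 default at desk scale; Euclidean on
  z-scored markers) with Leiden modularity optimization (resolution 1.0,
  fixed seed), clusters under 50 cells merged into the nearest centroid.
  Lineage labels by maximal mean z-scored canonical-marker expression with
  a minimum winning margin of 0.1 (otherwise "unassigned", excluded
  downstream).  Within each panel, the panel's focal lineage is reclustered
  on the full panel to define subsets.  At resolution 1.0 the subset level
  deliberately over-partitions relative to the planted catalog; finer
  partitions remain valid abundance features, and planted-partition
  recovery is assessed at a resolution matched to the planted granularity.

## Sample-level signatures

The IFN-I score per sample is the sum of three control-standardized
summaries: median MX1 and median ISG-15 over all cells of their carrying
panels, and median Siglec-1 over myeloid-lineage cells.  Summaries are
computed on arcsinh-transformed, batch-corrected values (the scale every
other analysis uses).  The reference stores control means and population
SDs (configurable to n−1); a sample is "IFN-elevated" iff its score
strictly exceeds the control-score mean + 3 SD — a property of the
reference cohort, recomputed whenever the reference changes, not a constant
of the method.  The score is invariant to any affine rescaling of raw
marker units applied consistently to cohort and reference.

Subset abundances are within-lineage proportions; lineages with zero cells
in a sample are missing, never zero.  The simplified 5-parameter signature
uses rectangular gates (default: 99th percentile of pooled control cells
per marker, since no printed gates exist): IFN-I score, Ki67+ % of T∪B
cells, granzyme-B+ Ki67− % of T cells, median CD21 in Ki67− B cells (also
reported negated), and CD14− CD16+ CD11b+ CD15hi % of myeloid-panel events.

## Neighborhood differential abundance

A symmetrized kNN graph over pooled cells is row-normalized into a
random-walk transition matrix; sample i's NAM row starts uniform over its
own cells and diffuses 3 steps (auto mode: stop when consecutive steps'
per-cell totals rank-correlate > 0.99).  Phenotype and NAM columns are
residualized on covariates by OLS with intercept.  The global statistic is
the squared multiple correlation of the residual phenotype with the leading
NAM principal components; p-values come from label permutations with the
add-one rule (never exactly 0).  Binary phenotypes are coded 0/1 and
treated numerically.

Numerical choices that differ from the most literal construction, made
because the literal one fails its own power contract:

* **PC count (auto)** — k is chosen to minimize the BIC of the regression
  of the residual phenotype on the leading PCs, and the selection is
  repeated inside every permutation so the global test stays calibrated
  (measured null rejection ≈ 0.05).  A variance-explained rule ignores the
  phenotype and tends to include noise PCs that dilute localization.
* **Per-cell coefficients** — correlations of the residual phenotype with
  the rank-k reconstruction of the NAM columns, not the raw columns: a
  single cell's raw neighborhood fractions are dominated by small-count
  kNN noise (per-cell correlations ~0.4 where the sample-level signal
  correlates at ~0.98), and the truncation removes it.
* **FDR mask** — threshold = smallest |coefficient| cutoff at which
  (1 + mean permuted exceedances) / observed exceedances ≤ q; the mask is
  inclusive at the threshold (matching the exceedance counts) and reported
  only when the global test is significant at 0.05, because the empirical
  FDR curve on strongly correlated columns dips below q by chance in a
  nontrivial fraction of null datasets.

## Stratification and anchoring

Features are subset proportions plus the IFN-I score, z-scored per feature;
samples missing any panel are dropped by default (mean-imputation is
available), zero-variance features are dropped with a warning.  K-means
(K = 3, k-means++, 50 restarts, fixed seed) clusters all timepoints in one
fit, so longitudinal samples are labeled by the same model as baseline
samples.  Semantic anchoring: G0 = cluster with the highest control
fraction (an exact tie is an error, not a guess); of the remaining two,
G1 = higher mean IFN-I score, ties broken toward G2 by the summed
granzyme-B+ subset proportions.  The anchoring evidence (control fraction,
mean IFN, mean granzyme-B signature per raw cluster) is recorded.  PCA is
centered with the sign convention that each PC's largest-|loading| feature
is positive.  One-vs-rest enrichment runs either as covariate-adjusted
per-subset linear models with BH FDR or through the neighborhood test with
a 0/1 phenotype.

## Clinical models

Renal response (week 52, evaluable iff baseline UPCR ≥ 1 g/g): complete =
UPCR < 0.5 and (creatinine ≤ 1.3 mg/dL or < 125 % of baseline) and
prednisone < 10 mg/d; partial = UPCR reduction > 50 % without the complete
UPCR criterion, (creatinine ≤ 1.3 or ≤ 125 % of baseline) and prednisone
≤ 15; otherwise none.  The creatinine rule is an OR of the two clauses (the
"if abnormal" reading is ambiguous); the complete arm uses strict < 125 %
and the partial arm ≤ 125 %, mirroring the printed asymmetry, and every
call carries a rule trace sufficient to reconstruct the decision.

Group comparisons: tie-corrected Kruskal–Wallis with Dunn's pairwise z
tests, BH-adjusted (the adjustment for Dunn is not specified upstream; BH
matches the rest of the pipeline).  Screens: pairwise-complete Spearman
with BH FDR.  Multivariable models: OLS / maximum-likelihood logistic with
Wald CIs; suspected separation triggers a flagged ridge-stabilized refit.
Elastic net: l1_ratio 0.5, penalty grid log-spaced 1e-3…1e1 on standardized
predictors, penalty chosen by 10-fold CV, coefficients averaged over 10
repeats with per-repeat fold shuffles; selection frequency = fraction of
repeats with a nonzero coefficient.  Longitudinal trends: linear mixed
model (value ~ time × group, random intercept per patient, REML, Wald
tests), falling back to OLS with a warning when there is no within-patient
replication or the random-effect variance degenerates.

## Determinism and problem sizes

All randomness flows from one master seed through per-stage SHA-256-derived
seeds recorded in the run manifest together with hashes of every output;
identical configs reproduce byte-identical runs.

Desk-scale defaults used by the test suite and the acceptance script (the
generator supports arbitrary sizes): 40 controls + 120 LN samples (40 per
planted group), 300 cells/sample/panel, 4 batches; end-to-end recovery
checked over 3 seeds; neighborhood-DA calibration over 100–150 null
replicates at 250 cells/sample and power over 20–30 replicates at 1,000
cells/sample; clinical-model recovery at n = 2,000 samples over 100
replicates.  At these sizes the full pipeline recovers the planted groups
at ARI ≥ 0.8 per seed, the null rejection rate sits at ~5 %, and the
planted response log-odds is recovered within a few percent.

## Known limitations

The batch model is location/scale only; nonlinear batch distortions are out
of scope.  The graph clustering is not a reproduction of any specific
published tool's embeddings or cluster numbering.  The per-cell FDR mask is
an empirical estimator on heavily correlated tests and is interpreted
jointly with the global permutation p-value, not alone.  Clinical
simulation draws covariates independently of group, so it cannot probe
confounding-correction behavior beyond calibration.  No survival analysis
and no imputation of missing clinical data beyond listwise deletion.
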