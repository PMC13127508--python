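# Methods

This note documents the models implemented in `pancstate`, the choices made
where the design was genuinely open, what the synthetic data do and do not
emulate, and the numerical conventions that make results reproducible.

## Quality control

Cells are kept only if they pass every active criterion:

- detected genes within `median ± k·1.4826·MAD` (k = 3), computed within
  each sample on the detected-gene count only;
- detected genes ≥ a floor (exocrine preset 150, tumor preset 500);
- mitochondrial %, ribosomal % and ambient-contamination fraction each
  strictly below their preset bounds (exocrine: 10 / 35 / 0.5; tumor:
  25 / 20 / 0.5).

Upper-threshold comparisons are exclusive-keep (a cell at exactly 25%
mitochondrial reads is removed under the tumor preset); the MAD scale
constant 1.4826 makes the estimate consistent with a normal SD.  The
removal report counts each criterion separately, so a cell failing several
criteria is counted under each; the distinct total is reported separately.
Ambient contamination is consumed as a per-cell scalar covariate — its
estimation is out of scope here.

Exocrine cluster selection retains clusters whose larger of the mean
acinar- or ductal-panel module score exceeds the best exclusion-panel mean
score by a margin (default 0); with no exclusion panels the baseline is 0,
so retention reduces to a positive exocrine score.

## Module scores and subtype assignment

A module score is the mean log-normalized expression of the module genes
minus the mean over expression-matched controls: genes are ranked by mean
expression and split into `n_bins` equal-size rank bins (default 24), and
each module gene contributes `n_ctrl` control genes (default 100) sampled
with replacement from its bin under a caller-supplied seed.  On matrices
with very few genes the bins collapse to near-singletons and the score
degenerates toward zero; callers working at toy scale should reduce
`n_bins` accordingly.

Normalization is `ln(1 + count / cell_total × 10⁴)`; natural log and the
10⁴ scale factor are conventional defaults recorded in config, not claims
about the emulated studies.

Subtypes come from the per-cell argmax over eight axis panels (two
ductal-core-like axes map to the single "Ductal" label; the axis→label
table is configuration).  Ties break by declared axis order and are
flagged.  The margin between the top two axes maps to four confidence
buckets at cut points 0.05 / 0.15 / 0.30 — the bucket names are fixed, the
cut points are defaults.

## TF activity

The published rank-enrichment activity algorithm is replaced by a weighted
signed Stouffer score, a deliberate design decision: per gene, expression
is z-scored across cells; per TF and cell the activity is
`Σ_t w_t·m_t·z_{t,c} / √(Σ_t w_t²)` over the regulon targets present in
the matrix (mode m ∈ {−1, +1}, weight w > 0), z-scaled per TF.  This
preserves the contract that matters downstream — signed, weighted,
regulon-driven, z-scaled, minimum regulon size 5 — while being exactly
testable against planted activity.  TFs with fewer than five present
targets are skipped; genes with (numerically) zero expression variance
contribute nothing.

When two regulon collections are merged, the first collection wins
(tf, target) conflicts; this merge rule is ours.

Residualization fits OLS of each TF's activity on an intercept, detected
genes, %mito, %ribo, contamination and PC1 of the log-normalized matrix
over the top 3,000 highly variable genes, keeping re-z-scaled residuals.
Constant covariates are dropped with a warning; an all-zero residual
vector stays zero and flags the TF as degenerate.  PC1's sign is fixed by
making its largest-magnitude gene loading positive.

## Hurdle association

Per gene with at least 25 expressing cells, detection (expr > 0) is fit by
maximum-likelihood logistic regression (Newton, 50-iteration cap) and the
continuous level among detected cells by OLS, both on
intercept + activity + covariates.  Categorical covariates expand to
first-level-reference indicators; numeric adjustment covariates are
z-scaled for conditioning (the activity column is passed through, so its
coefficient keeps its scale); collinear columns are dropped with a
warning, and a dropped activity column, non-convergence, or a degenerate
fit (exploding coefficients, as under quasi-separation) yields a
`fit_error` status rather than a silent estimate.  Genes whose detection
indicator is constant get `degenerate_detection`; the continuous part is
still fit when cells allow.  Covariate presets: exocrine
{subtype, donor, context, detected genes}; tumor
{cluster, sample, detected genes}.  Note that with one donor per sample
and donors nested in context, context indicators are collinear with donor
indicators and are dropped — the adjustment is unchanged.

Evidence combination: `z_i = sign(coef_i) · Φ⁻¹(1 − p_i/2)` clipped to
±10, `z_combined = (w_d z_d + w_c z_c)/√(w_d² + w_c²)` (equal weights in
the exocrine arm, 2:1 detection:continuous in the tumor arm), and
`p_combined` from the χ²(4 df) survival function at
`−2(ln p_det + ln p_cont)` (Fisher's method; 4 df is forced by two
components).  A missing component passes the other through; both missing
propagates missing.  The same combination is used in both arms.  BH FDRs
are step-up adjusted per component and for the combination; missing
p-values pass through.  RNK export writes gene and clipped combined z,
sorted descending, no header.

## Gene modules, genotype model

Module scores are regressed on residualized activity with donor, context,
detected genes, %mito, %ribo and contamination; the global model also
includes subtype (so associations hold with subtype constant — this is
what licenses the claim that module shifts are not mere composition
shifts), and stratified fits re-run the model within each subtype without
the subtype term.  BH FDR is computed jointly over the whole
module × stratum table; the multiplicity family is our choice.  Strata too
small for the design return flagged missing results.

The inverse normal transform uses mid-ranked ties and the Blom offset 3/8:
`y_i = Φ⁻¹((r_i − 3/8)/(n + 1/4))`.  The clone model fits
`expression ~ dose` with a REML random intercept per clone; a zero clone
variance or failed mixed fit falls back to OLS (flagged in the result).

## Embedding tuning

The structure space is a PCA (30 components) of per-batch mean-centered
log expression over 3,000 HVGs — batch centering is this package's
integration step, chosen as the simplest transformation that attenuates
additive batch shifts at the scale we operate on.  The axis space is a PCA
of the cell × axis score matrix (capped at axes − 1 components).  Both are
scaled to unit total variance so α is interpretable.  For
`combined(α) = [α·structure, (1−α)·axis]` on a grid (default 0, 0.1, …, 1),
the objective is mean subtype silhouette plus one minus mean batch
silhouette; the argmax wins, ties to the smaller α, and a term whose
labels are constant is dropped.  Silhouettes subsample to 3,000 cells
(seeded) on larger inputs.  The objective and grid formalize "balance
subtype separation against batch mixing"; they are this package's
instantiation.  Nonlinear 2-D layouts are visualization-only and outside
the tested surface.

## Trajectories

Pseudotime replaces principal-curve fitting with a centroid-MST
construction: Euclidean minimum spanning tree over cluster centroids in
the supplied PC space, root at the cluster with the highest fraction of
Acinar/Acinar_REG+ cells, lineages as root-to-leaf paths.  A cell's
pseudotime is the tree distance from the root to its cluster plus its
signed projection on the cluster's incoming edge direction (the root uses
its first outgoing edge), shifted to start at 0 per lineage.  Per-lineage
metrics: cell count, pseudotime range, and the ductal-like fraction in the
top pseudotime quintile minus the bottom quintile (quintiles are our
definition of early/late; the ductal-like label set is configurable).
Lineage redundancy is the Pearson correlation of pseudotime over jointly
assigned cells (missing below 10 shared cells).  Representative selection
z-scales the three metrics, averages them, picks the best, then greedily
maximizes `base − λ·max|redundancy with selected|` (λ = 1), which
guarantees an exact duplicate of an already-selected lineage is never
added while any distinct candidate scores higher.  Profiles bin min-max
scaled pseudotime into equal-width bins with per-bin subtype fractions and
an edge-truncated running-mean activity curve.

## Tumor families

Signature scores are mean log-normalized expression over each signature's
genes intersected with the expressed universe;
`p_classical = (Sig1+Sig6)/total`, `p_basal = (Sig2+Sig10)/total`.  The
classifier applies, in order: Classical (p_c ≥ 0.60 and p_b ≤ 0.30), Basal
(mirrored), Hybrid (both ≥ 0.30), else Unassigned.  Rule order matters
only on the measure-zero boundary set but must be deterministic; with
non-negative scores the two fractions are complementary and Unassigned is
reachable only for cells with zero total signal (kept defensively).

## Synthetic data: what it emulates, and what it does not

The exocrine generator draws negative-binomial counts
(`var = μ + φμ²`, φ = 0.5) with log-mean = gene baseline + subtype marker
boost (20 genes per subtype, +1.5) + shared family programs (15-gene
acinar and ductal-core programs, the stress state transitional with
partial doses of both) + a 30-gene progression program rising with true
pseudotime (+0.4 per stage) + regulon effect × activity × mode (100
targets, effect 0.5, 25% repressed) + donor batch shift (SD 0.1) + a
log-normal library factor (SD 0.3), followed by expression-dependent extra
dropout.  The TF's own transcript is forced sparse (< 10% detection)
independently of its activity — exactly the regime that motivates
activity inference.  Subtypes follow fixed proportions across three
contexts with two donors each; pseudotime is stage + uniform along
acinar → stress → ductal → (CFTRhi | MUC5B | injury) paths with an
Acinar → REG+ side branch.  %mito, %ribo and contamination are drawn with
mild library-size correlation.  The family programs are load-bearing:
without them all subtype centroids are mutually equidistant (marker-swap
geometry) and no centroid method could order them.

The tumor generator gives each of 15 samples a family-typical anchor on
the classical–basal continuum (classical/basal/intermediate in rotation)
with cells beta-scattered around it; signature genes follow a linear-rate
model (mean count ∝ latent loading), because log-additive boosts saturate
at the detection limit and compress observed score fractions toward 0.5.
Latent fractions map to true families through the same thresholds the
classifier uses.  Uniform, degenerate and beta continua are available for
partition checks.

Focused generators plant exactly what their estimators recover: Bernoulli
detection with a specified activity log-odds plus Gaussian positive
levels; module scores as `β·activity + noise`; clone expression on the
standardized (INT) scale as `dose effect × dose + clone intercept + noise`
(12 clones × 3 replicates, SDs 0.2) — planting on the INT scale avoids
the rank transform distorting the planted coefficient.

What passing these tests shows: the estimators are calibrated and recover
planted effects under NB noise, sparsity, batch shifts and technical
confounding of the magnitudes above.  What they do not show: robustness to
ambient-profile contamination mixtures, doublets, UMI saturation,
cross-platform batch effects, or misspecified regulons — none of which the
generator emulates.

## Numerical conventions

All randomness flows through `numpy.random.default_rng` from explicit
seeds; no global state.  PCA/SVD signs are fixed by the
largest-|loading|-positive convention.  Z-scaling treats columns with SD
below 1e-12 (relative to magnitude) as constant and maps them to zero
rather than amplifying float noise.  P-values are floored at the smallest
positive double so logs and BH stay finite.  Workflow outputs are written
with a fixed float format and outdir-relative provenance paths, making
reruns byte-identical.  Pipeline runs at desk scale default to 2,000 cells
and 1,500 genes (the tumor workflow enforces a ≥ 1,500-gene universe so
cells can clear the fixed 500-detected-genes QC floor); the acceptance
script uses 500–2,000 cells per check and 20–50 replicates for
Monte-Carlo summaries.

## Known limitations

- The activity score assumes roughly linear target responses on the
  z-scale; strongly nonlinear regulation would dilute it.
- Residualizing on expression PC1 can absorb real signal when the TF's
  program dominates global variance; in the simulated regime (structure
  dominated by subtype programs) the residualized score tracks truth more
  closely than the raw one, but this is data-dependent.
- Library-size normalization couples genes compositionally, so a strong
  planted regulon induces weak spurious associations at non-target genes;
  calibration holds under the independent-gene null but global FDR on
  compositionally coupled data is approximate.
- The centroid-MST pseudotime assumes cluster centroids trace the
  trajectory; it cannot represent within-cluster branching.
- The clone model's dose p-value is asymptotic (Wald on 12 clones);
  exact small-sample inference is not attempted.
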