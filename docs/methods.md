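# Methods

This note documents the models and procedures `ancestryqtl` implements,
the defaults it ships, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not emulate.

## Synthetic two-ancestry cohorts

The generator produces the inputs the analysis assumes rather than a
demographically realistic population.

**Genotypes.** Each haplotype is a latent standard-normal vector,
exchangeably correlated within an LD block and thresholded at the
allele-frequency quantile; dosage is the sum of two independent
haplotypes, giving hard 0/1/2 calls. Because thresholding attenuates
correlation, the latent within-block correlation is calibrated (via the
tetrachoric relation, at each block's mean MAF) so that the *dosage*
correlation matches the requested `within_block_r`. Allele frequencies
are specified per ancestry on a shared variant panel; ref/alt pairs
exclude strand-ambiguous A/T and C/G combinations, emulating a post-QC
imputation panel. Not modelled: imputation-dosage uncertainty,
recombination-distance-dependent LD decay, admixture, or the X
chromosome.

**Molecular traits.** trait = Σ β·dosage + covariate terms + N(0, σ²)
on a standardized scale, with age, sex, and batch as a reduced stand-in
for a real covariate set (age, sex, genotyping array, genotype PCs).
Ancestry-specific effects are planted by setting one ancestry's β to
zero. Missingness is MCAR at a configurable rate, except xenobiotic
metabolites, which additionally lose one whole batch of samples —
mimicking compounds absent from some platform runs. Real omics features
not emulated: heteroskedastic platform noise, shared latent factors
across features, and limit-of-detection censoring; tests passing on
these cohorts therefore validate the statistical machinery, not
robustness to those artifacts.

**Case-control GWAS.** A cohort of `n_cases + n_controls` individuals
is built by bootstrap-resampling rows of the genotype panel (preserving
LD and allele frequencies), case status is drawn from a logistic
liability with the requested per-variant log-odds, and each variant is
summarized by the score test (β = U/V, SE = V^−1/2), which matches the
per-variant logistic Wald z asymptotically. Monomorphic columns are
dropped.

## Omics QC

Proteomics runs seven ordered steps (platform filters → IQR outlier
masking → 65% call-rate for analytes and samples → 85% analyte →
85% sample → back-transformation → removal of non-human/untargeted
analytes); metabolomics runs eleven (volume normalization → sample and
metabolite missingness → batch-missingness association → minimum-value
imputation → non-informative removal → IQR outliers → 50-data-point
floor → PCA sample outliers → batch-median alignment →
back-transformation). Call rate is the fraction of non-missing values;
comparisons are strict `<`, so items exactly at a threshold are kept.
Minimum-value imputation applies only to non-xenobiotic metabolites —
xenobiotics are expected to be genuinely absent in many samples, and
imputing them would fabricate signal.

Thresholds that live in platform documentation rather than any public
method description (limit of detection, scale factors, replicate CVs,
the exact batch-missingness test) are exposed as configurable hooks
with conservative defaults: replicate CV ≤ 0.15 (active only when
replicate labels are supplied), batch-missingness Fisher test at
p < 10⁻³, PCA sample fence at mean ± 3 SD on PC1/PC2.

Two numerical choices make the flow well-behaved. First, both outlier
steps (IQR masking, PCA sample removal) iterate internally to a fixed
point — fences are recomputed after each masking round until nothing
new is flagged — so the step applied to its own output is a no-op.
Second, in metabolomics the imputation rule is maintained after
masking: masked cells of non-xenobiotic metabolites refill with the
surviving feature minimum, keeping that block complete. Even so,
reapplying the *entire* pipeline is guaranteed equivalent only when no
removal step changes the sample set between passes and the
batch-alignment shift does not re-expose borderline cells to the IQR
fences; the audit report (one record per step, telescoping counts)
makes any such cascade visible. Step order is part of the contract and
is recorded in the report; permuting steps is not equivalence-preserving.

## QTL mapping

The scan residualizes the transformed trait and all dosages on the
covariates (Frisch–Waugh–Lovell), which reproduces full per-pair OLS
exactly; tests hold it to a `statsmodels` OLS oracle at 10⁻⁸ relative.
p-values use the t distribution with n − k degrees of freedom rather
than the normal — indistinguishable at cohort-scale n, material at toy
n. Pairs with fewer than 30 complete observations are skipped and
reported; rank-deficient covariate designs are flagged, never silently
dropped. Trait transforms: proteomics log10 then z-score; metabolomics
median-normalized then log10; `none` for data already standardized.

The study-wide threshold is genome-wide 5×10⁻⁸ divided by the number of
principal components that cumulatively explain 95% of trait variance —
an effective number of independent features. The threshold is applied
to cis and trans alike by default; a cis-only 5×10⁻⁸ rule is available
as a reporting flag, since both conventions appear in practice.

Inflated features (significant hits on more chromosomes than a
per-dataset limit — defaults 5/3/7/3 for EUR-protein / AFR-protein /
EUR-metabolite / AFR-metabolite) are first rescued by pruning hits at
low-quality variants (MAF < 0.05 or call rate < 97%); a feature still
inflated afterwards is removed entirely. LD blocks are half-open
[start, end) on 1-based coordinates (BED input is shifted on read);
assignment is by binary search, with variants outside every block
assigned the sentinel −1 and counted separately. The sentinel variant
per feature × block is the smallest p, ties broken by |Z| then by
variant id. Dosage is coded to the minor allele within each ancestry;
cross-ancestry comparisons reconcile sign by allele matching.

## Ancestry specificity

The classifier works on the discovery-relative signed ratio
z_other/z_discovery: within [0.1, 10] the effect replicates within
ten-fold and is *shared*; outside — which includes every sign-discordant
pair, whose ratio is ≤ 0 — the QTL is *specific* to its discovery
ancestry. The reported ratio is always printed in the fixed z_afr/z_eur
orientation. An alternative reading that applies the ten-fold band to
|ratio| would call sign-discordant pairs with |ratio| ∈ [0.1, 10]
shared; the signed-ratio rule is adopted because the worked examples
(−0.452, −594, −0.289) are all ancestry-specific calls.

An intrinsic property of the rule worth knowing: when the companion
ancestry's true effect is zero, its z is standard normal, so the QTL is
mislabeled shared with probability P(N(0,1) > 0.1·z_disc) — about 26%
at z_disc = 6.5, about 2% at z_disc = 20. Recovery guarantees therefore
hold for strongly discovered QTLs; the planted benchmark uses discovery
z ≈ 20 and achieves ≥ 97% recovery with a specificity-by-MAF-bin
gradient (≈ 70% / 45% / 10% planted, recovered within sampling error).

The empirical-Bayes sharing model is a fixed-grid variant of
multivariate adaptive shrinkage: EM over mixture weights on a canonical
dictionary of 2×2 prior covariances on the z scale — null,
AFR-only/EUR-only, and correlated-shared with ρ ∈ {0.25, 0.5, 0.75, 1}
at scale multipliers {0.5, 1, 2} of a base prior variance 4 — with
noise covariance I. The dictionary is fixed (not data-driven) for
desk-scale determinism; posterior means shrink via mixture-weighted
Tweedie formulas, and a pair is *shared* when its posterior-mean ratio
is sign-concordant within [0.1, 10].

Power uses the noncentral t of the dosage-slope test:
λ½ = |β|·√(n·2·maf·(1−maf)/σ²), two-sided at α = FWER/nTests (defaults
0.05/10⁶). Residual variance defaults to 1 − explained fraction,
floored at 0.1. The fixed-noncentrality formula is marginally optimistic
by a fraction of a percent versus simulation (realized genotype
variance is random); tests compare at design points where the
approximation sits inside two Monte-Carlo standard errors.

## XWAS

Regional SNP heritability uses Haseman–Elston regression (closed-form
slope of trait cross-products on genetic relatedness) rather than a
REML fit; only the sign gates model training, and HE preserves the
sign at a fraction of the cost. Weights are trained on all variants
within ±1 Mb of each sentinel: elastic net (mixing 0.5, penalty path by
5-fold CV), top1 (best marginal variant), and BLUP (ridge with penalty
m(1−h²)/h²); the model with the best out-of-fold R² is refit on all
data. Unusable models (h² ≤ 0 or CV R² ≤ 0) are excluded from the
Bonferroni denominator, which always counts *actual* usable models.

The association statistic z = wᵀz_gwas/√(wᵀRw) uses in-sample LD and is
invariant to rescaling w; under the null with z_gwas ~ MVN(0, R) it is
standard normal (property-tested). Alleles are matched on
chr:pos:ref:alt; swapped ref/alt flips the z sign; strand-ambiguous
A/T and C/G variants are dropped with a report. Weights are restricted
to variants present in the GWAS — no summary-statistic imputation —
with dropped variants counted.

## Colocalization

Per-variant Wakefield log-ABFs, labf = ½log(se²/(se²+W)) +
½z²·W/(se²+W), feed the standard five-hypothesis sums with priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵; everything runs in log space (log-sum-exp;
the i≠j cross term via log1p), so |z| up to 100 cannot overflow.
Effect-prior SDs: 0.15 on the log-odds scale for the case-control GWAS
and 0.2 trait-SD for z-scaled molecular traits — the conventional
defaults. Decision rule PP.H4 > 0.8 on the ±1 Mb window around the
sentinel; when a feature has several regions the maximum PP.H4 is
taken. Only single-causal colocalization is implemented; results are
tagged `method="single-causal"` so downstream consumers can distinguish
them from multi-causal (credible-set) variants of the analysis, which
are out of scope here.

## Mendelian randomization

Instruments are study-wide-significant QTL variants that (1) sit
outside pleiotropic LD blocks — blocks associated with ≥ 6 proteins or
≥ 11 metabolites — unless in linkage equilibrium (r² < 0.8) with the
block's sentinel, an escape clause for genuinely independent signals
inside busy regions; (2) survive greedy LD clumping by ascending p at
r² ≤ 0.001 (strict conventional default, configurable); (3) have
F = (β/se)² > 10. One instrument gives the Wald ratio with first-order
delta SE (se_out/|β_exp|; the second-order form adding the
exposure-uncertainty term is available behind a flag and is strictly
larger); several give IVW, identical to weighted least squares through
the origin. A feature with no surviving instruments is reported as
such, not an error. Feature-level control is Benjamini–Hochberg FDR.
Heterogeneity statistics, MR-Egger, weighted-median and Steiger
filtering are out of scope.

## Evidence integration and replication

The triple rule nominates a feature when XWAS passes its Bonferroni
gate, colocalization passes PP.H4 > 0.8, and MR passes FDR < 0.05; a
feature missing any analysis keeps that flag unset and cannot be
nominated. The combined posterior treats the colocalization probability
as a prior with a linear-truncation floor of 0.05 (so absent coloc
evidence dampens but never vetoes) and converts the XWAS z to a
unit-information Wakefield Bayes factor, BF = exp(z²/4)/√2; posterior =
BF·π/(BF·π + 1 − π). This is an approximation in the spirit of
integrative posteriors built from TWAS and colocalization output, with
the prior function pluggable; it is not a reproduction of any specific
tool's prior.

Replication against an external study table assigns each
feature–variant pair exactly one of six categories: feature absent →
`no_feature`; no variant with LD r² ≥ 0.8 → `no_proxy`; otherwise the
best match (smallest external p, ties to higher r²) is `validated`
(p < 5×10⁻¹¹), `known` (p < 5×10⁻⁸), `replicated` (p < 0.05), or
`not_replicated`. The fixed thresholds are used as printed constants
regardless of the external study's own multiplicity scheme.

## Pipeline and problem sizes

The driver executes scan → threshold → annotation → specificity → XWAS
→ coloc → MR → integration, writes one tab-delimited table per stage,
and logs row counts plus SHA-256 of each output; a rerun with the same
config and seed is byte-identical. The bundled demo study uses 11 LD
blocks of 8 variants spaced 3 Mb apart (so a ±1 Mb window never spans
two blocks), 1 500 EUR / 600 AFR samples, planted QTL effects of 0.6
trait-SD per allele, and a 2 000/2 000 case-control GWAS with log-odds
0.35 at the three effector variants — sizes chosen so each validation
runs in seconds while every decision threshold is exercised with wide
margins. The specificity benchmark uses 180 features (60 per MAF bin)
at n = 1 500 per ancestry.

## Known limitations

- Synthetic LD is exchangeable within blocks; no distance decay, so
  fine-mapping resolution inside a block is not meaningful.
- The GWAS bootstrap reuses panel rows, slightly understating
  between-cohort sampling variation relative to two disjoint cohorts.
- Specificity recovery guarantees degrade at modest discovery z (see
  above) — an intrinsic property of the ten-fold Z-ratio rule, not of
  the implementation.
- The EB sharing model's fixed covariance grid cannot adapt to effect
  patterns far from the dictionary (e.g. strong negative cross-ancestry
  correlation).
- QC reapplication equivalence is conditional (see Omics QC); the audit
  report is the source of truth for what was removed and why.
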