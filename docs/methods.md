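# Methods

`grazescan` implements the computational stages of a landscape-genomics study
of a perennial forage crop sampled across environmental strata ("soil zones"):
population-structure inference, a redundancy-analysis (RDA) genome scan for
genotype–environment association (GEA), linkage-disequilibrium decay, and
phenotype statistics. A synthetic-data generator reproduces the statistical
structure those stages assume, so every stage is testable by parameter
recovery at desk scale.

## Synthetic data generator

The generator emulates a collection of `n_pops` populations (one per site,
sites assigned round-robin to four soil zones), each contributing
`n_per_pop` diploid genotypes.

**Ancestry.** Two ancestral gene pools diverged to a target FST in the
Balding–Nichols sense: per locus a common ancestral frequency p ~ U(0.1, 0.9)
is drawn and each pool draws its frequency from a Beta with mean p and
variance `fst·p(1−p)`. Per-population mean ancestry lies on a gradient
(linspace 0.15–0.9, shuffled across populations) and individuals draw their
sativa-pool proportion q from Beta(αm, α(1−m)) with concentration
`admixture_alpha = 30` (within-population SD ≈ 0.06–0.09, matching a
collection in which populations carry distinct but internally consistent
parentage levels). A neutral locus's per-individual allele frequency is
`q·p_A + (1−q)·p_B`.

**Environment.** Each predictor (soil K, P, S, pH, summer/winter extreme
temperature, precipitation) has a global mean, a between-zone SD and a
within-zone site SD, chosen at magnitudes typical of prairie soil tests and
climate normals. Environment is constant within a site.

**Adaptive loci.** `n_adaptive` loci (default 20) are planted whose *site*
allele frequency is `expit(logit(p_mid) + adaptive_slope · z)` where z is the
coupled predictor standardized over sites and p_mid the locus's mid-parent
frequency. The default slope of 1.5 log-odds per SD produces dosage–predictor
correlations of roughly 0.2–0.6 at n≈120 — a detectable but not trivial
signal. Coupling acts on site frequency, not individual fitness, which is
exactly the signal an allele-frequency–environment scan is designed to find.

**Linkage disequilibrium.** Block boundaries follow a Poisson process with
mean spacing `block_len_bp` along each chromosome. Loci within a block share
their pool allele frequencies and, per individual and chromosome copy, a
latent uniform that is refreshed per locus with probability
`block_refresh = 0.1`; dosage is the sum of the two copies. Marginally each
call remains Binomial(2, f); within a block the genotypic r² is ≈ 0.65 and
the probability of co-membership decays as exp(−d/block_len), so the mean-r²
curve crosses 0.2 near the block length. This construction is controllable
and desk-scale; it does not model recombination gradients, variable block
strength, or mutation, so LD results transfer to real data only at the level
of "decay length is recovered", not curve shape.

**Phenotypes** are affine in the sativa ancestry proportion plus Gaussian
noise, per trait (defaults mimic forage yield, fall height, days to flower in
growing degree days, regrowth and crude protein at realistic scales).

What the generator does *not* emulate: tetraploid dosage, selfing/pedigree
structure, genotyping error, departure from Hardy–Weinberg within pools, and
ascertainment bias of GBS SNP discovery. Passing recovery tests therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness to those violations.

## QC and imputation

MAF is computed on non-missing calls; loci with MAF < 5% are removed (strict
inequality; an exactly-5% locus is kept). Missingness gates remove loci then
individuals exceeding a 50% default. Remaining missing calls are replaced by
the locus mean dosage: for the centered-dosage statistics downstream (RDA,
LD, DAPC) the mean is the variance-minimizing single imputation, and it
conserves column means exactly. The admixture EM instead uses the
observed-data likelihood and skips missing cells, so it never sees imputed
values.

## Admixture model

The likelihood is the standard unlinked-loci admixture model:
`f_il = Σ_k Q_ik P_kl`, `log L = Σ_il [g_il·ln f_il + (2−g_il)·ln(1−f_il)]`
(binomial coefficient omitted — it shifts the likelihood by a constant and
cancels in every comparison across K and runs). Estimation is EM with
closed-form updates, accelerated by SQUAREM (Varadhan–Roland S3 step length)
with a safeguard that falls back to the plain double EM step whenever the
extrapolated point does not improve the likelihood, so the recorded
log-likelihood path is non-decreasing. `fit_admixture` returns the best of
`n_init` seeded restarts; K = 1 is closed-form. Defaults: `tol = 1e−6`,
`max_iter = 2000`; the recovery experiments use `tol = 1e−4, max_iter = 60`,
at which the K = 2 fits are fully converged (the overfitted K ≥ 3 fits keep
crawling along a ridge and are capped — only their likelihood *level* enters
the Evanno statistic, which is insensitive to that residual tail).

Model order is chosen by the Evanno second-difference statistic
`ΔK = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / SD(L(K))` over repeated
runs, defined for interior K only; K with zero run-to-run SD are excluded
with a warning. Multiple runs are combined CLUMPP-style: columns permuted
(exhaustively for K ≤ 6, greedily above) to match the first run, then
averaged and renormalized. Note one estimator subtlety verified during
development: under the two-pool study conditions (FST 0.3, 150 individuals,
1000 loci) the maximum-likelihood fit shows a mild "stretch" bias (fitted
pools less diverged than truth, Q̂ pushed toward the simplex corners), and
the mean |Q̂ − Q| of the ML estimate sits at ≈ 0.0497 — the information floor;
run-averaged consensus is marginally above it. The package therefore treats
the best-likelihood restart as the point estimate and the consensus as a
label-coherence device.

Parentage classification uses the strict rule "> threshold" (default 0.5):
a genotype exactly at the boundary goes to the non-focal (falcata) class.

## Nei distance, UPGMA, bootstrap

Nei's (1972) standard distance for biallelic loci:
`Jx = mean(x² + (1−x)²)`, `Jxy = mean(xy + (1−x)(1−y))`,
`I = Jxy/√(JxJy)`, `D = −ln I`, with I ≤ 0 capped at D = 10 (flagged) and
numerical overshoot above 1 clamped. UPGMA merges the closest pair with
size-weighted (classical arithmetic-average) distance updates; node height
is half the merge distance, so trees are ultrametric by construction; ties
break on the lowest (row, col) index pair. Bootstrap support resamples loci
with replacement, recomputes frequencies → distances → tree, and reports the
percentage of replicates containing each original clade.

## DAPC

Centered dosages → PCA (up to min(n−1, L, 60) components). K-means over
K = 1..max_k is scored with `BIC(K) = n·ln(WSS/n) + K·ln(n)`; the lowest BIC
wins. This WSS-based criterion behaves sensibly in the regime DAPC actually
operates in — a PC space of dimension close to n — where per-cluster
overfitting gains are small relative to the ln(n) penalty; in low-dimensional
spaces it would over-split (see tests for the regime used). The number of PCs
retained for the discriminant step maximizes held-out assignment accuracy
over stratified shuffle splits on a small grid; linear discriminant axes are
then fit on the retained PCs against the chosen clusters.

## RDA genome scan

Predictor screening first removes constant predictors, then greedily drops
the later-listed member of any pair with |r| > 0.7, then iteratively drops
the largest VIF above 5 (VIF = 1/(1−R²) of each predictor on the rest).

The scan: Y is the individuals × loci dosage matrix, column-centered and —
by default — column-standardized; X is the standardized site-level predictor
matrix broadcast to individuals (one soil test per site). B = (XᵀX)⁻¹XᵀY,
Y′ = XB, and the SVD of Y′ gives constrained axes (eigenvalues = squared
singular values/(n−1)), individual scores, and unit-norm locus loadings.

*Why scale Y:* dosage variance depends on allele frequency, so unscaled
loadings form a scale mixture across loci whose Mahalanobis distances have
heavier-than-χ² tails; in calibration experiments the realized false
discovery proportion at q < 0.01 was several times nominal. Standardizing
the columns makes loci exchangeable and restores calibration (measured
precision ≈ 99% at the default settings). `scale=False` reproduces plain
covariance RDA for cross-checks.

Axis retention (`broken_stick` default) keeps the leading axes through the
*last* one whose eigenvalue share exceeds the broken-stick expectation
`b_i = (1/p)Σ_{j≥i} 1/j`. Stopping at the first axis below expectation
instead would routinely retain only the dominant ancestry axis and discard
the diffuse multi-predictor environmental signal carried by later axes,
killing the scan's power; retain-through-last was adopted after that failure
mode was measured. `fixed:K` and `proportion:x` overrides exist.

The locus-loading cloud's robust center and scatter come from FAST-MCD
(support fraction 0.75, seeded), so genuinely adaptive loci — the
contamination — do not inflate the null covariance; classical moments are
available for transparent small-instance oracles. D² is the Mahalanobis
distance; the genomic inflation factor λ = median(D²)/median(χ²_K) rescales
the statistics (for K = 2 the null median is exactly 2·ln 2); p-values are
upper-tail χ²_K probabilities of D²/λ; q-values are Storey's (π₀ from a
cubic smoothing spline over a λ-grid, returned as 1.0 below 100 loci where
the spline is unstable) with BH as the simpler alternative; outliers are
loci with q < 0.01 (strict).

Outliers are assigned to every gene interval containing their position
(1-based inclusive, boundary positions inside; "Intergenic region"
otherwise) and to the environmental predictor of maximum |Pearson r| between
individual dosage and site predictor value (the population-frequency variant
of that correlation is not implemented; individual dosage uses all n points).

## LD decay

Genotypic r² (squared Pearson correlation of dosage vectors over shared
non-missing calls; phase-free) for same-chromosome pairs within a distance
cap; pairs with fewer than 10 shared calls or zero variance are skipped.
The decay curve is the mean r² per distance bin; the headline summary is the
midpoint of the first bin where the 3-bin moving-average curve drops below
r² = 0.2 (inf sentinel if never), with the mean distance among sub-threshold
pairs reported as a secondary statistic since the verbal definition is used
both ways in the literature. Distances are physical bp throughout; no
genetic map is assumed.

## Phenotype statistics

Growing degree days: daily `max(0, (Tmax+Tmin)/2 − 5 °C)`, accumulated from
the series start (accumulation start date is a free choice; the series start
is the default) to the flowering day inclusive. ANOVA is one-way fixed
effects on genotype values — deliberately simpler than a nested RCBD mixed
model with Satterthwaite df, which is out of scope here; the Tukey–Kramer
studentized-range test handles unbalanced groups, SEM = √(MSE/harmonic mean
n), and the compact letter display is built by the insert-and-absorb
algorithm (split every column containing a significantly different pair,
absorb subsets), so two groups share a letter iff they are not significantly
different at α. Membership regression is OLS of a trait on the ancestry
proportion with the slope t-test; a constant trait returns slope 0, R² 0,
p 1 by definition.

## Pipeline determinism

`run_all` derives each stage's seed by stable hashing of the stage name with
the global seed, so toggling one stage never shifts another stage's
randomness; TSVs are written with a fixed float format and reruns are
byte-identical. A manifest records config, seed, input hashes and outputs.

## Problem sizes used in the recovery experiments

Recovery experiments run at desk scale, chosen to keep each experiment in
the tens of seconds while leaving comfortable statistical margins: GEA
recovery/precision and null calibration average 10 generator seeds
(L = 2000 with 20 planted loci, and L = 5000 neutral, n = 120, 12 sites);
admixture recovery uses 10 seeds at n = 150, L = 1000 with 5 runs × K = 1..5;
LD recovery averages 5 seeds at 600 loci on one 400 kb chromosome with 5 kb
blocks; the Tukey letter-display oracle covers 100 random 4-group instances.

## Known limitations

- Diploid dosage coding throughout, inherited from the upstream SNP-calling
  convention; alfalfa is autotetraploid, so this is a biological
  simplification of the real system.
- The RDA scan is unconditioned (no ancestry covariate); in strongly
  structured data the inflation factor absorbs structure only in the bulk,
  and confounded loci can leak into the tails.
- Storey's π₀ is unstable below a few hundred loci (it falls back to BH
  behavior via π₀ = 1).
- UPGMA assumes a clock; bootstrap supports are clade frequencies under
  locus resampling, not posterior probabilities.
- The EM admixture point estimate carries the ML stretch bias described
  above when no near-pure individuals are present.
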