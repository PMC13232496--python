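# Methods

This note documents the models and procedures implemented in `damageqtl`,
the assumptions behind them, the defaults and the reasoning for the design
choices that were genuinely open.

## Tissue classification and the damage statistic

Images are read as 8-bit PNG/JPEG and normalised to [0, 1] per channel. The
supervised classifier (DTR) applies fixed RGB inequalities in the precedence
order green → yellow → necrotic and labels each plant pixel with the first
matching class. Two details are deliberate:

- *Strict inequalities, evaluated on normalised channels.* The thresholds are
  fractions of the 8-bit range (e.g. 90/255) and the green rule is
  scale-invariant, so normalisation is consistent with both.
- *Precedence.* The yellow and necrotic acceptance boxes overlap in
  R ∈ (90/255, 225/255), G ∈ (97/255, 213/255), B ∈ (18/255, 53/255); a fixed
  evaluation order makes classification single-valued. Pixels matching no
  rule are *unclassified* and excluded from the damage denominator, because
  the damage statistic is defined over green + yellow + necrotic pixels only.

Background handling: classification requires a plant mask, supplied as a
sidecar image or derived by a uniform-background chroma rule (a pixel is
background when every channel is within `tol`, default 2/255, of the
configured background colour). This presumes lightbox-style imaging with a
controlled backdrop; no general segmentation is attempted.

The unsupervised method (DQU) quantises the plant pixels with the median-cut
algorithm: starting from one box containing all pixels, the box whose widest
channel range is largest is split at the median of that channel until three
boxes exist or none is splittable. Deterministic tie-breaks: larger pixel
count, then lower box index; pixels equal to the median go to the lower box;
if the median equals the box maximum the split point moves below it so both
halves are non-empty. Cluster centroids (mean colours) are mapped to tissue
classes by the DTR rules; a centroid matching no rule falls back to the
nearest of three configurable class prototypes (Euclidean RGB distance, ties
broken by the fixed order green < yellow < necrotic). The default prototypes
are the centres of the synthetic generator's class colour boxes. The
cluster→class mapping is the one genuinely under-determined step of the DQU
pipeline and is therefore exposed as a parameter.

JPEG input is supported read-only; fixtures are always written as PNG because
lossy compression perturbs pixels adjacent to the classification thresholds.

## Synthetic images

`generate_plant_image` colours plant pixels by sampling from fixed closed
8-bit RGB boxes per class — green (40–76, 140–178, 64–76), yellow (178–216,
128–153, 77–127), necrotic (102–140, 77–102, 5–11) — each strictly interior
to its threshold rule's acceptance region with a margin of at least 5/255 on
every face and outside the other two classes' regions. Class counts are made
exact by largest-remainder apportionment, so the planted damage is an exact
rational number and the threshold classifier recovers it to machine identity
after a lossless PNG round trip. With `jitter=False` each class is a single
colour (the box centre): three distinct colours stay atomic under median-cut
splits, so quantisation recovers the planted counts exactly and DQU damage
equals DTR damage — the colour-separable regime.

With jitter (uniform sampling inside the boxes), DQU is *not* exact: with
only three clusters, median-cut splits fall inside the majority class for
mid-range compositions, producing one cluster that mixes green with damaged
tissue; its winner-take-all classification misassigns up to ~10% of pixels.
Agreement between the two methods is therefore correlation-level, and the
correlation over a set of images depends on the spread of true damage in
that set. The concordance fixtures draw total damage from
0.02 + 0.93·Beta(0.5, 0.5), a wide spread resembling a population
segregating for resistance (many nearly-healthy and heavily-damaged plants);
under these conditions the DQU–DTR Pearson correlation is ≈ 0.93–0.96.
Restricting damage to a narrow band (say 0.2–0.4) would lower the correlation
substantially — a property of three-cluster quantisation, not of the
generator. Passing tests therefore demonstrate exactness of DTR and
conditional (separable-colour) exactness plus rank-level agreement of DQU;
they say nothing about camera calibration, illumination drift, shadows or
leaf-shape effects, none of which the generator emulates.

## Insect survival

`NTS = 100 · living / total_infested`, reported to one decimal place. With
the standard infestation of 6 insects per plant the statistic is discrete
(0.0, 16.7, 33.3, 50.0, 66.7, 83.3, 100.0). The simulator draws living
counts as Binomial(6, survival probability) — independence between plants,
no overdispersion and no mortality structure over time.

## Mixed model, REML and Cullis heritability

The multi-trial model is

    y = Xβ + Z_g u_g + Z_gt u_gt + Z_b u_b + ε

with trial fixed (sum-to-zero contrasts next to an intercept, or next to the
full set of genotype dummies when genotype is fixed), and genotype,
genotype×trial and block (nested in trial) as independent normal random
effects. Genotype effects may carry a pedigree numerator relationship matrix
A, built by the recursive tabular method (`a_ij = (a_is + a_id)/2`,
`a_jj = 1 + a_sd/2`); parents appearing only as parents are auto-added as
founders. Residuals are homogeneous across trials, and no row/column spatial
effects are fitted. Both are deliberate simplifications: they keep REML
estimable from first principles and testable against closed forms, at the
cost of fidelity to software that models heterogeneous trial residuals and
spatial trends. Genotype-by-trial effects are only fitted by default when
they are separable from the residual (replication within trial × genotype);
with one replicate per trial only their sum is identified.

Estimation maximises the restricted log-likelihood with variances on the log
scale. A model with a single random term uses a one-dimensional profiled
likelihood over the variance ratio γ = σ²_g/σ²_e via an eigendecomposition
of Z G Zᵀ, optimised by bounded Brent search (log γ ∈ [−30, 30], absolute
tolerance 1e-12); this path reproduces the balanced-data ANOVA estimator
(MSG − MSE)/r to < 1e-6. Models with several components use Nelder–Mead on
the log variances (parameter tolerance 1e-10) with the restricted likelihood
evaluated by Cholesky factorisation of V. Variances are bounded below at
e⁻³⁰ times the data scale, so boundary estimates appear as effective zeros
rather than failures. Non-convergence is flagged on the results object, never
silently returned. A model with no random terms (genotype fixed, nothing
else) reduces to OLS.

Genotype predictions: BLUPs `û = σ²_g G Zᵀ P y` with prediction-error
covariance `C = σ²_g G − σ⁴_g G Zᵀ P Z G`, or BLUEs (GLS estimates of the
genotype dummies, reported at the average trial effect). Arithmetic genotype
means are available as a third, shrinkage-free estimator. Cullis
heritability is `H² = 1 − PEV̄/(2σ̂²_g)` where PEV̄ is the exact average of
`var(ĝ_i − ĝ_j)` over all genotype pairs, computed from C as
`2(q·tr C − ΣC)/(q(q−1))`; the result is clamped to [0, 1] and defined as 0
when σ̂²_g = 0. Per-trial quality control fits each trial alone with
genotype random and excludes trials with H² below the threshold (default
0.2) or failed convergence; the same H² formula is used per trial and across
trials. Trait correlations are Pearson on per-genotype values (BLUEs by
convention, since they carry no shrinkage), pairwise-complete over missing
values; a constant trait yields NaN, never a silent zero.

## Synthetic genotypes and phenotypes

Families emulate a crossing design in which several heterozygous sires are
each mated to one shared tester dam (defaults: four families of 70, 120, 120
and 29 progeny — 339 in total — with 5 parents riding along in the genotype
matrix). Each parent is heterozygous at an expected fraction of SNPs
(default 0.5, the most informative configuration for an F1 family); progeny
gametes follow a Markov recombination walk along each chromosome with a
constant recombination probability between adjacent SNPs (`recomb_rate`,
default 0.01 at the default 1-kb marker spacing; 0.5 makes markers
effectively unlinked). Missing genotypes are injected completely at random
in progeny only. This emulates diploid-coded biallelic dosages with tunable
LD decay; it does not simulate sequencing reads, genotyping error, phasing,
or polyploid dosage ambiguity.

Phenotypes follow `y = trial mean + Σ_k β_k·dosage_k + g + (g×t) + block + e`
with independent normal components at the specified variances and genotypes
assigned to blocks round-robin. Genotype effects are drawn i.i.d. (not
pedigree-correlated), so pedigree-A fits on simulated data test machinery,
not A-model recovery. The entry-mean heritability implied by a design is
`σ²_g / (σ²_g + σ²_gxt/t + σ²_e/(t·r))` for t trials and r replicates; the
realised squared correlation between planted effects and genotype means
converges to it (checked at 1000 genotypes within ±0.05).

## Marker QC, kinship, PCA, LD

Call rate is the fraction of non-missing genotypes per SNP; MAF is computed
on non-missing dosages; defaults MAF ≥ 0.01 and call rate ≥ 0.40. Only
biallelic records are read from VCF (multiallelic sites are excluded with a
logged reason), and the filter is idempotent. VanRaden relationships use
per-SNP mean imputation of missing dosages. PCA is the SVD of the centred
(mean-imputed) dosage matrix; requested components beyond the rank are
truncated with a warning.

LD is the squared Pearson correlation of dosage vectors (composite LD),
pairwise-complete over missing genotypes, for intra-chromosome pairs within
`max_dist` (default 100 kb). Dosage r² was chosen over haplotype r² because
the pipeline accepts unphased VCFs and the two agree under random mating.
Pair values are averaged in fixed 1-kb bins; the decay curve is an isotonic
(monotone non-increasing) regression on the bin means at bin midpoints, and
the decay distance is the linear interpolation of the first crossing below
r² = 0.2. The monotone fit guarantees a unique first crossing; a parametric
drift-expectation fit `E[r²] = 1/(1 + C·d)` is available as an option
(`method="sved"`) with the crossing solved analytically. If the curve starts
below the threshold the first bin midpoint is returned; if it never crosses,
the sentinel `None` signals persistence beyond the observed range. At n
individuals, null r² sits at the 1/(n−1) sampling floor, so decay distances
are only meaningful well above that floor.

## Association scan and QTL windows

The scan is a per-SNP ordinary linear model `y ~ intercept + covariates +
dosage` with a two-sided t-test on the dosage coefficient, implemented by
exact residualisation against the covariate space. It is plumbing for the
downstream machinery — a single-locus fixed-effects scan, not a multi-locus
or kinship-corrected GWAS — and its null calibration (uniform p-values) and
power on planted QTLs are what the tests establish. Zero-variance SNPs get
p = 1 with a warning. Significance uses −log₁₀ p > 6 with
Benjamini–Hochberg q-values computed over all tested SNPs; an empty result
is a valid outcome.

Windows of half-width 2, 5 and 10 kb are placed around each significant
association ([max(1, pos−w), pos+w], 1-based inclusive), merged per
chromosome when they overlap by ≥ 1 bp, and named prefix + chromosome with
an ordinal "-k" suffix when several windows share a prefix and chromosome
(ordered by start). Merging happens before naming; the prefix comes from the
member traits with total-damage (qTPD) taking precedence over necrotic
tissue (qNT). The ±10 kb window is treated as the canonical reported track.
BED export converts 1-based inclusive [s, e] to 0-based half-open (s−1, e);
the round trip is tested as an identity. Gene intersection is a plain ≥1-bp
overlap against a user-supplied 1-based inclusive interval table; no
sequence-level annotation is attempted.

## Problem sizes used in the checks

The variance-recovery and heritability checks run 50 simulated datasets of
500 genotypes × 2 trials (one replicate each); image checks use 50–120
images of ~1,200 plant pixels; scan calibration uses 10,000 SNPs × 200–300
individuals; power checks use 100 simulated populations of 300 progeny × 200
unlinked markers with the planted marker chosen as the most variable (an
uninformative marker cannot be mapped in principle). These sizes put
Monte-Carlo error well inside the asserted tolerances while keeping the full
suite fast.

## Known limitations

- Homogeneous residual variance across trials; no spatial row/column
  modelling; no heterogeneous genotype×trial covariance structures.
- The Nelder–Mead path for ≥ 2 variance components is robust but not
  gradient-fast; very large multi-component fits are out of scope.
- The scan does not correct for kinship beyond the supplied covariates;
  in structured populations its p-values are conservative or inflated
  depending on how much structure the covariates absorb.
- Median-cut DQU with three clusters is exact only for colour-separable
  images; on continuous colour variation its damage estimates carry
  composition-dependent error (see above).
- Tetraploid dosage models, read-level simulation and phasing/imputation are
  out of scope throughout.
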