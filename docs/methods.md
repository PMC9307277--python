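# Methods

`hybridmap` implements heritability estimation and additive + dominance
genome-wide association mapping for microbial (or other compositional)
abundance traits measured on a multi-line hybrid intercross, together with
the simulator used to validate every estimator by parameter recovery.

## Study design emulated by the simulator

The target design is a two-generation intercross among eight partially
inbred lines derived from two house-mouse subspecies pools
(*Mus musculus musculus* and *M. m. domesticus*): two lines from each of
four breeding stocks, eight G1 dam x sire pairings (each mating a
domesticus-like with a musculus-like line), and eight G2 sub-crosses chosen
so every G2 individual has one grandparent from each stock.  The default
cohort is 8 sub-crosses x 40 males = 320 individuals.

Founder lines are haplotype mosaics of subspecies backgrounds.  A chosen
fraction of markers is subspecies-diagnostic (fixed between the pools); the
remainder segregate at a shared frequency drawn uniformly on (0.1, 0.9).
Ancestry blocks have exponential lengths (default mean 10 cM) and block
states are assigned by marker-weighted stratified sampling, so each line's
realised diagnostic-allele fraction tracks its subspecies weight to within
roughly one block (comfortably inside +/-0.05).  Inbreeding is modelled as
per-marker identity by descent between a line's two haplotypes at rate F
(default 0.85, matching lines inbred past the 80% point); F = 1 yields zero
heterozygosity exactly.

Meiosis uses Haldane's model: crossover counts are Poisson(L/100) per
chromosome with uniform positions and no interference, and the map defaults
to 1 cM = 1 Mb when no genetic map is supplied.  The X chromosome is not
simulated: the mapping population is male and autosomal modelling avoids a
dosage-compensation model that would otherwise be arbitrary.

Abundance traits are generated per taxon on a latent log-abundance scale,

    latent = mu + a Xa + d Xd + pair + subcross + polygenic + residual,

with pair ~ N(0, sigma2_m), subcross ~ N(0, sigma2_s), polygenic ~
MVN(0, sigma2_g K) for the realised centred GRM K, and residual ~
N(0, sigma2_e).  The additive effect follows the classical convention:
`a` is half the distance between homozygote means (Xa in {1, 0, -1}), `d`
the heterozygote deviation from the homozygote midpoint (Xd in {0, 1}).
Latent vectors map through a softmax to a composition and counts are drawn
multinomially at a fixed sequencing depth (default 10,000), so the count
table is compositional: absolute bacterial load is deliberately not
modelled.  The truth record stores the latent traits, per-taxon
h2 = sigma2_g / (sigma2_g + sigma2_m + sigma2_s + sigma2_e), and causal
effects, which is what the recovery tests consume.

What the generator does *not* emulate: genotyping error, taxonomic
misassignment, overdispersion beyond multinomial sampling, phylogenetic
correlation among taxa, and X-linked or parent-of-origin effects.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to those real-data complications.

## Genotype QC and ancestry

QC removes individuals with call rate < 90%, then markers with
missingness > 10%, minor allele frequency < 5%, or Hardy-Weinberg exact-test
p < 1e-10 (in that order; the filter is idempotent).  The HWE test is the
exact conditional test: heterozygote counts with conditional probability at
or below the observed one are summed (standard p, not mid-p).  LD pruning
slides a 5-SNP window in 1-SNP steps and, while any surviving pair exceeds
r^2 = 0.9 (Pearson correlation of dosages over pairwise-complete
individuals), drops the lower-MAF member (tie: the later position) — the
window/step/r^2 values are conventional; the tie rule is ours and is fixed
for reproducibility.  Ancestry-informative markers require >= 10 calls per
subspecies panel, a differing major allele, and an allele-frequency
difference > 0.3; the hybrid index is the fraction of non-missing AIM allele
copies carrying the musculus-tagged allele.

## Traits

Counts are rarefied to 10,000 reads (samples below depth are dropped, not
resampled), mirroring per-level sample attrition.  Core taxa must exceed
25% prevalence with median non-zero relative abundance > 0.2% (ASV, genus)
or > 0.5% (family and coarser).  The mapping trait is the inverse logistic
transform exp(x)/(1+exp(x)) applied to the relative abundance itself; its
image is the narrow interval [0.5, 0.731], which is retained deliberately —
the transform is monotone, so it only rescales effect sizes.  Shannon
(natural log) and bias-corrected Chao1 are appended as diversity traits,
and Bray-Curtis dissimilarity is provided for community-level summaries
(scikit-bio supplies the index implementations).

## Relatedness

Two GRM flavours over dosage columns x_i (missing entries mean-imputed):
centred, K = (1/p) sum_i (x_i - mean)(x_i - mean)^T, and standardised,
which divides each term by the biased (1/n) marker variance — that
denominator convention makes trace(K) = n an exact identity, which the
tests assert.  Zero-variance markers contribute nothing to the centred GRM
and are excluded (with p adjusted) from the standardised one.  LOCO
variants drop one chromosome's markers and are used marker-wise in the scan
to avoid proximal contamination.

## Mixed-model engine

The REML criterion is

    l_R = -1/2 [ q log 2pi + log|V| + log|X'V^-1 X| - log|X'X| + y'Py ],

q = n - rank(X); the -log|X'X| term makes l_R exactly invariant to
invertible reparameterisations of the fixed design (a tested property).
Components are profiled on the residual scale and optimised over log
variance ratios.  Single-random-term models use an exact one-dimensional
profile after rotating onto an orthonormal basis of the orthogonal
complement of col(X) (97-point grid plus bounded Brent refinement,
tolerance 1e-10).  Multi-component models run Nelder-Mead from three fixed
starts (all ratios at 0.1, 1, 10) followed by an L-BFGS-B polish; ratios
are bounded in [e^-16, e^16] and components whose ratio pins at the lower
bound are reported as exact zeros with a boundary flag.  The reported
log-likelihood is always re-evaluated densely at the *reported* (clamped)
components, so it matches an independent log-det + quadratic-form
evaluation to machine precision.

Fixed-effect tests use ML likelihoods (REML values are not comparable
across fixed designs).  The restricted likelihood-ratio test for a variance
component on the boundary uses a parametric bootstrap: traits are simulated
from the fitted null model and both models refitted; p = (1 + #{sim >=
observed})/(n_sim + 1).  When the tested kernel is the only random term the
null refits are vectorised over simulations on a 322-point variance-ratio
grid (the observed statistic is pushed through the same grid so the
comparison is exchangeable); with nuisance terms present each simulation is
refitted individually.  Type-I error is verified to sit in [3%, 7%] at
nominal 5%.

## Heritability

Narrow-sense h2 fits {centred GRM, mating-pair-within-subcross, subcross,
residual} and reports sigma2_g over the component total; chip heritability
is the same model with the standardised GRM.  Note h2 is a variance-
component ratio, not a sample-variance ratio: it is comparable across
estimators because simulator truth and estimator use the same GRM
parameterisation.  Taxa whose genetic component pins at zero get h2 = 0 and
RLRT p = 1 without spending bootstrap samples.  The cospeciation module
computes Spearman's rho between per-genus h2 and externally supplied
cospeciation rates (exact genus-name matching, >= 5 shared genera) plus an
OLS of h2 on rate and median abundance with per-coefficient t-tests and the
overall F-test (statsmodels).

## Association scan

Per marker the full model is mu + a Xa + d Xd with mating pair and the
LOCO centred GRM as random effects; Xa is oriented to the within-cohort
major allele.  p_total is a 2-df LRT against the intercept-only model;
p_additive and p_dominance drop one term each (1 df).  Per-term LRTs (not
Wald) keep one testing framework throughout — a documented choice where
convention is silent.  The default approximate mode estimates the null
variance components once per chromosome by ML, whitens, and profiles the
residual *scale* per marker (statistic n log(RSS0/RSS1)); re-profiling the
scale keeps the mode consistent with exact per-marker refits within about
an order of magnitude in p at strong QTLs, and exactly calibrated under the
null.  Exact mode refits every marker and is intended for small problems or
spot checks.  Markers with missing genotypes fall back to the exact path on
the observed subset.

Genomic control converts p-values to 1-df chi-square statistics (1 df used
uniformly, including for the 2-df total test — the convention adopted
here), computes lambda_GC as the median over 0.4549, and deflates only when
lambda_GC > 1.05.  The effective number of traits is
Meff = 1 + (M-1)(1 - Var(lambda)/M) from the eigenvalues of the trait
correlation matrix (sample variance, M-1 denominator), and the study-wide
threshold is the Bonferroni genome-wide threshold divided by Meff.

## Architecture and regions

Dominance is summarised by d/|a|: dividing by |a| orients the ratio to the
higher-abundance allele, so +1 reads as complete dominance of the high
allele regardless of which allele is major.  Bins: < -1.25 underdominant;
[-1.25, -0.75] recessive; (-0.75, -0.25) partially recessive;
[-0.25, 0.25] additive; (0.25, 0.75) partially dominant; [0.75, 1.25]
dominant; > 1.25 overdominant.  The transgressive screen runs two Welch
tests (het vs each homozygote) at alpha = 0.05 each with no correction —
the criterion is a screen, not an inference, and the joint null rate is
near alpha^2.  PVE is the marginal R2 of the SNP fixed effects:
Var(X beta) / (Var(X beta) + sum sigma2_k + sigma2_e), where the kinship
component contributes sigma2_g times the mean GRM diagonal; collinear
marker columns are dropped left-to-right in position order.

Significant LD-pruned SNPs expand to the interval of the most distant
same-chromosome markers with r^2 > 0.9 in the *pre-pruning* genotype set;
intervals with a gap under 10 Mb (strict, counting bases between the
intervals) merge transitively.  Coordinates are 1-based inclusive
internally; BED converts at the boundary.  Interval-overlap permutation
places query intervals uniformly within their own chromosomes (lengths
preserved) and counts overlapping interval pairs (pair counting, not
base-pair counting — a documented choice); gene-set permutation draws
|hit| genes uniformly from the universe; both report
p = (1 + #{perm >= obs})/(n_perm + 1), and a Fisher exact p accompanies the
gene-set test.  Regions larger than 10 Mb can be excluded before
cross-study comparisons via `max_region_bp`.

## Pipeline and reproducibility

The `hybridmap` CLI exposes one subcommand per stage plus `run`, which
executes simulate -> qc -> grm -> traits -> heritability -> scan ->
architecture -> regions and writes a manifest with the seed and a config
hash.  All randomness flows from the single config seed through spawned
substreams, so a rerun with the same config is bit-identical.  The demo
configuration runs at reduced scale (5 chromosomes x 400 markers, 160
individuals, 20 taxa) and disables the bootstrap RLRT by default; the RLRT
itself is exercised at full cohort scale by the test suite.  Validation
problem sizes used by the tests and the acceptance script: n = 320
individuals on 2,000 markers for recovery/calibration checks, 100
replicates per heritability level, 400 x 300 for RLRT calibration, and 50
replicates for scan power — sizes chosen so each check has enough
replication to be stable while the whole suite stays desk-scale.

## Known limitations

Relative-abundance traits cannot separate a taxon's change from
compensating changes in the rest of the community; the inverse-logit
transform applied to proportions compresses trait variance; the
approximate scan mode shares variance components within a chromosome, so
its p-values at very strong signals differ (conservatively or liberally by
well under an order of magnitude) from exact refits; and the
parametric-bootstrap RLRT prices its p-value resolution at 1/(n_sim + 1).
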