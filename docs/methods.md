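# Methods

This note documents the statistical procedures mbqtl implements, the
assumptions behind them, the synthetic-data model used to validate them,
and the numerical and design choices that were genuinely open.

## Association model

For a taxon with nonzero abundance in at least 75% of subjects
(boundary inclusive), the per-SNP test is ordinary least squares on the
variance-stabilized scale:

    asin(sqrt(f_it)) = β · g_is + X_i γ + ε_it

`f_it` is subject *i*'s relative abundance of taxon *t* after rarefaction,
`g_is` the risk-allele dosage (0/1/2, missing dosages mean-imputed), and
`X_i` the adjustment set: antibiotics < 1 month, immunosuppressants
< 1 month, biopsy inflammation, age, gender, biopsy location, CD/UC
diagnosis, disease location, years since diagnosis, cohort membership
(all discrete covariates dummy-coded against a declared reference level)
and the first three principal components of the pooled, mean-imputed,
column-centered dosage matrix.  Constant and exactly collinear columns
are dropped (QR pivot test) so the design always has full column rank.
The reported p is the two-sided t-test on β.  Below the prevalence
threshold the test is a maximum-likelihood logistic regression of
presence/absence; separation or non-convergence is flagged and the
p-value reported missing rather than fabricated.

Robustness: before each linear test, subjects whose value of that feature
lies more than 3 interquartile ranges from the feature's *mean* are
excluded and the model refitted (`n_used` is recorded).  The rule is
implemented exactly as stated — with a single gross outlier the inflated
mean can also drag near-mean values outside the band; the tests document
this property rather than silently substituting the median.

The least-squares engine is a direct `lstsq` solve, cheap enough to run
the full SNP × taxon × cohort screen in seconds; the test suite holds it
to statsmodels OLS and to the explicit normal-equations solution at 1e-8.

## Preprocessing

* **Rarefaction** to an even depth (default 2,000 reads) by
  multivariate-hypergeometric subsampling without replacement; shallow
  samples are dropped, never upsampled.  At depth 2,000 a taxon at
  relative abundance 0.15% is detected with probability
  1 − (1 − 0.0015)^2000 ≈ 0.9503.
* **Taxonomy binning** from phylum to genus off Greengenes-style lineage
  strings; unnamed ranks bin under "unclassified ⟨parent⟩" so per-rank
  totals conserve each sample's depth exactly.
* **Redundancy collapse**: features sorted by mean abundance join the
  first cluster whose representative correlates at Pearson r strictly
  above 0.95; the representative (the most abundant founder) carries the
  cluster's abundance forward.  Zero-variance features stay singletons.
* **SNP filters**: minor allele frequency must strictly exceed 0.1
  (MAF at 0.1 is excluded), and call rate must reach 0.95.  The call-rate
  threshold is a QC convention, not a reported value, and is configurable.
* **Power transform**: functional-module abundances use a per-feature
  Yeo-Johnson transform with λ estimated by maximum likelihood, then
  centering.  For data ≫ 1 this approaches the Box-Cox log limit; the
  Yeo-Johnson form is used because module abundances can be exactly zero.

## Sign-concordance (MCC) screen

Effect magnitudes scale with a taxon's mean abundance and are not
comparable across cohorts, so reproducibility is judged on signs.  For a
SNP and a cohort pair, taxa with nominal p < 0.05 (strict) in at least
one of the two cohorts enter a 2×2 table of coefficient signs; the
Matthews correlation coefficient summarizes agreement, and is undefined
(SNP skipped) when a margin is zero or fewer than 3 taxa qualify.
Significance uses the two-sided Fisher exact test by default — the
sampling model treats the sign table as fixed-margin under independence —
with a sign-permutation alternative for small tables.  Permutation
p-values use the add-one rule and count ties fully ("conservative"),
which is guaranteed valid but superuniform on the coarse MCC lattice of a
small table; a `midp` tie rule (half-weight ties) is provided for
calibration studies and is approximately uniform once the lattice is
fine (~200 pairs).  One test per gene is kept (the SNP with most included
taxa; best-p optional), then BH-corrected across genes within each cohort
pair at FDR 0.25.  A gene significant in at least one pair counts as
conserved.

## Fine mapping of multi-variant loci

A locus's variants are combined by simple (uncapped) summation of
risk-allele dosages, raising the carrier fraction and hence power; the
shipped six-variant prototype locus is calibrated so one lead variant has
6.3% carriers while the aggregate has 21.8% (under Hardy-Weinberg and
independent variants: lead MAF 0.0320, five secondary variants at MAF
0.0179).  The aggregate dosage is tested against each taxon, against the
first three PCoA axes of a beta-diversity matrix (BH across the 3 axes),
and genome-wide via a Mantel test (Pearson, two-sided, label
permutation) of Manhattan genetic distance against unweighted UniFrac.
Weighted UniFrac uses the normalized variant (values in [0, 1]), the
common QIIME default.  PCoA is classical scaling with non-positive
eigenvalue axes discarded.

## Power analysis

`required_sample_size` inverts the noncentral-F power curve: power at
total size n is `P(F' > F_crit)` with df (u, n − u − 1), noncentrality
λ = f² · (u + v + 1) and `F_crit` the null 1 − α quantile — the R `pwr`
convention — root-found in n and rounded up to the smallest integer
meeting the target.  A Monte-Carlo companion (`monte_carlo_power`)
simulates the design with the signal column rescaled so the sample
noncentrality is exactly f²·n, and matches the analytic curve within MC
error.  With u = 19, f² = 0.013, α = 1.39 × 10⁻⁵ and power 0.80 the
computation gives n = 3,932 (verified independently against base R's
`pf`/`qf`).  The screen bookkeeping (163 loci × 22 taxa = 3,586 tests,
Bonferroni 1.39 × 10⁻⁵) is computed by `bonferroni_threshold`.  The power
target of 0.80 is an assumption — the convention — since no target is
part of the bookkeeping itself.

## Pathway enrichment

The rank-product statistic is the mean log-rank (the log geometric-mean
rank) of a pathway's gene–taxon tests among all tests, ascending ranks
with ties averaged — strictly monotone in the classical rank product but
overflow-free and normalized for pathway size.  By default every taxon
test of every pathway gene contributes ("all"); a best-test-per-gene mode
exists.  Significance is empirical against size-matched gene sets drawn
without replacement from the null-variant gene pool (default 100,000
draws; the pipeline's `all` mode uses 1,000), with add-one smoothing so
p is never 0.  Redundant pathway definitions are binned greedily
largest-first when |A∩B|/min(|A|,|B|) strictly exceeds 0.75, the largest
constituent representing the bin (Jaccard overlap is available).
Hypergeometric over-representation of a hit list uses the upper tail and
BH across categories.

## Host factors and the dysbiosis index

Covariate redundancy is measured by the max-symmetrized uncertainty
coefficient max(U(x|y), U(y|x)) with natural logs (the base cancels);
continuous covariates are discretized into equal-frequency quartiles
first.  Complete linkage on distance 1 − maxU cut at height 0.5
guarantees every within-cluster pair shares ≥ 50% of its information.

The host-factor network regresses each taxon's transformed abundance
jointly on all factors (dummy-coded covariates, cohort, age, duration,
plus an aggregate locus dosage when available); BH runs across all
factor × taxon tests, edges require q < 0.05, and a taxon enters the
network only with ≥ 4 significant edges.  Edge weight is |β| divided by
the taxon's mean relative abundance, making effects comparable between
rare and dominant taxa.

The MDI is log((Σ disease-associated + ε)/(Σ health-associated + ε)) per
subject.  The taxon lists ship as an editable YAML config (they derive
from a prior pediatric-CD study, not from this package); names match
feature ids or lineage substrings, and a family-level disease match
outranks an order-level health match (Veillonellaceae sits inside
Clostridiales).  ε defaults to half the smallest nonzero relative
abundance; the log form follows the index's source convention, with a
raw-ratio option.  The antibiotics test is MDI ~ antibiotics + locus
dosage, t-test on the antibiotics coefficient; a constant dosage column
is dropped, reducing to the simple regression.

## Synthetic cohorts

The generator emulates the target study design: three cohorts of
152/160/162 subjects (474 total), CD fractions 62.5%/14.3%/63.5%,
inflamed-biopsy fractions 31.5%/11.3%/53.1%, one cohort dominated by
pre-pouch-ileum biopsies, ages uniform on 18–75, a risk panel of 154 SNPs
plus a null pool with MAF > 0.1 (dosages Binomial(2, MAF), Hardy-Weinberg,
no LD — the analysis treats SNPs marginally), 22 dominant taxa with a
geometric-decay base composition holding 98% of the mass plus a rare
tail, and the six-variant aggregate locus described above.

Counts are Dirichlet-multinomial: planted SNP effects, covariate effects
and cohort offsets shift the arcsine-sqrt-transformed baseline (so the
downstream linear model is correctly specified; a raw-scale switch exists
for robustness testing), the inverse transform maps back to proportions,
rows are renormalized, a Dirichlet draw with concentration 200 adds
biological overdispersion, and a multinomial draw at the subject's depth
(uniform on 2,000–6,000) adds counting noise.  Cohort batch effects are
additive transformed-scale offsets, N(0, 0.1) truncated below at half the
taxon's transformed baseline: a batch effect may shift but never
annihilate a dominant taxon, since the emulated design has the same
dominant taxa present in every cohort and planted effects must remain
expressible wherever they are declared conserved.  `calibrate_beta`
converts a target Cohen f² into a planted β via a small null pilot
estimate of the transformed-scale variance.

What the generator does **not** emulate: read-level 16S sequencing
(chimeras, primer bias), linkage disequilibrium, population structure
beyond cohort offsets, and taxon–taxon ecological interactions beyond
compositional coupling.  Passing tests therefore demonstrate statistical
correctness of the pipeline under its own model assumptions, not
robustness to real-data artifacts such as batch-variable sequencing error
or LD-driven confounding.

## Validation scale and numerical choices

The parameter-recovery guarantee runs 100 replicates of a reduced but
faithful screen — 3 cohorts × 150 subjects, 8 SNPs, 22 dominant taxa,
one SNP carrying alternating-sign effects at per-taxon f² ≈ 0.05 on 12
taxa — and requires recovery (positive MCC, q < 0.25 in ≥ 1 cohort pair)
in ≥ 80% of replicates; 200 null replicates bound the mean
false-discovery proportion at 0.25.  Null-calibration suites check
uniformity (KS p > 0.01) of linear, logistic, Mantel, rank-product and
mid-p permutation-MCC p-values at 200–1,000 replicates each.  These sizes
keep the full suite within a routine CI run while leaving Monte-Carlo
standard errors well inside the asserted tolerances.

Numerical conventions: distance matrices are symmetrized and validated
(symmetry 1e-12, zero diagonal); PCoA discards non-positive eigenvalues;
all empirical p-values use add-one smoothing; BH q-values propagate
missing p as missing; every random procedure takes an explicit seed and
the full three-cohort fixture is bit-for-bit reproducible from one seed.

## Known limitations

* The MCC screen compares directions only; it cannot detect magnitude
  heterogeneity, and Fisher exact on tables with fewer than ~9 included
  taxa rarely reaches q < 0.25 regardless of agreement (discreteness).
* Mean imputation of missing dosages shrinks per-SNP variance slightly;
  complete-case analysis is available but reduces n.
* The 3×IQR-from-the-mean outlier rule can exclude entire features when
  one value dominates the mean; this is faithful to the stated rule.
* Logistic fallback tests lose power relative to the linear path and are
  primarily a guard against prevalence-driven artifacts.
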