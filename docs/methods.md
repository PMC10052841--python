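# Methods

`dipkit` evaluates a biallelic autosomal DIP (deletion/insertion
polymorphism) marker panel the way a forensic population-genetics study
does: per-locus forensic parameters with panel cumulatives, equilibrium
screening, kinship likelihood-ratio power, population structure and
distance summaries, and biogeographic-origin classification. This note
records the models, conventions and numerical choices.

## Genotype model and coding

Every autosomal DIP locus is biallelic (insertion `I` vs deletion `D`).
Genotypes are stored as insertion dosage g ∈ {0, 1, 2}, the count of `I`
alleles; missing calls are NaN. The coding makes allele frequency,
heterozygosity, HWE counts, PCA features and classifier features all
derive from one array. The deletion frequency is always 1 − p and is
never stored separately. Y-DIP and Amelogenin columns are parsed but
carried only as metadata; no statistic touches them. Missing data are
handled by pairwise deletion per computation — never imputed — except in
PCA and the classifiers, where per-locus mean imputation is the standard
practice for dosage features.

## Forensic parameters

With insertion frequency p, q = 1 − p, n diploids, observed
heterozygosity h and H = 1 − h:

- He = 2pq · 2n/(2n − 1) (the small-sample unbiased estimator; the
  uncorrected 2pq does not reproduce reference values at n ≈ 233).
- PIC = 1 − (p² + q²) − 2p²q².
- MP = Σ_g f_g² over **observed** genotype frequencies; PD = 1 − MP.
  Observed rather than HWE-expected frequencies are used because that is
  what forensic summary tools (STRAF) compute and what reference tables
  reflect.
- PE (trio) = h²(1 − 2hH²); TPI = 1/(2H), reported as +inf with a
  warning when h = 1.

Cumulative indices multiply across loci: CMP = Π MP, CPD = 1 − CMP,
CPE = 1 − Π(1 − PE). Floats underflow no earlier than ~1e−308, but
1 − CMP saturates to exactly 1.0 in binary floating point as soon as
CMP < 2⁻⁵³; report strings such as `0.9999…97297` therefore come from an
arbitrary-precision `decimal` path (80 digits), quantized to show five
significant digits of the complement. The float CMP is also returned in
log10 form.

## Equilibrium screening

**HWE.** The exact biallelic test conditions on the minor-allele count
and enumerates all heterozygote counts of matching parity; the two-sided
p-value sums probabilities ≤ that of the observed count (probability-
ordering tail, the SNP-exact-test convention). Probabilities are
computed from log-gamma, normalized over the enumerated support, so the
test is deterministic and exact to double precision. A relative slack of
1e−12 absorbs floating-point ties in the "no more likely" comparison.
Monomorphic loci return p = 1 by convention. This deterministic exact
test stands in for Markov-chain exact tests used by population-genetics
suites; for biallelic loci the tail definition is identical.

**LD.** Two-locus haplotype frequencies are estimated from unphased
genotypes by EM; the double heterozygote is the only ambiguous class and
is split between cis and trans phases each E-step (tolerance 1e−8 on the
log-likelihood, ≤ 1000 iterations). The test statistic is
G = 2(lnL_hap − lnL_independence). Significance comes from permuting one
locus's genotypes across individuals (seedable; p = (hits + 1)/(B + 1)),
with the chi-square(1) p-value always reported as the fast alternative;
the pipeline default uses chi-square and the CLI default 10 000
permutations. Bonferroni thresholds are α/m.

## Kinship likelihood ratios

Full siblings share 0/1/2 alleles IBD with probabilities
κ = (¼, ½, ¼). The single-locus LR against unrelatedness is

LR = κ₀ + κ₁·T₁(g₂ | g₁, p)/P(g₂ | p) + κ₂·1[g₁ = g₂]/P(g₂ | p),

with HWE genotype probabilities and the one-IBD transition kernel T₁
(the shared allele is one of g₁'s two alleles with equal probability;
the other is a population draw). Loci combine multiplicatively — the
panel is screened for LD — accumulated in log10 to avoid underflow at
57 loci. E[LR | unrelated] = 1 per locus holds analytically and is
asserted to 1e−12.

Sibling pairs are simulated through explicit parents (two HWE parents;
each child independently receives one uniformly chosen allele from each
parent) rather than by the κ-mixture shortcut, so the machinery extends
to other relationships; agreement of the simulated joint genotype
distribution with the enumerated κ-mixture law is a test. The power
study classifies a pair as sibling when LR ≥ limit (inclusive; ties at
the limit count as identified) for limits {1, 10, 100, 1000, 10000},
reporting accuracy (sibling pairs above the limit) and false-positive
ratio (unrelated pairs above it) over 1000 pairs per hypothesis by
default.

The study's per-locus frequency table is not public, so power-study
reference checks use a synthetic stand-in: 57 frequencies drawn
uniformly on [0.3283, 0.7146], the printed frequency range of the panel
(mean ≈ 0.52, close to the printed average insertion frequency 0.5045).
Across such draws the LR ≥ 1 sibling accuracy lands at 97.4–98.9% with
~2% false positives, bracketing the published 98.12% / 2.04%; the
acceptance check asserts the published value within three binomial
standard errors of a 1000-pair run. This validates the LR engine's
operating characteristics under realistic frequencies, not the exact
population-specific numbers.

## Population differentiation

**FST.** The Weir & Cockerham (1984) θ: per-locus variance components
a (among populations), b (among individuals within populations) and
c (within individuals) from sample sizes, allele frequencies and
observed heterozygosities, combined multi-locus as Σa/Σ(a+b+c).
Negative estimates are retained in reports and floored at 0 (with a
`clamped` flag) only when a matrix feeds MDS or NJ. AMOVA-based pairwise
FST flavors used by other software are near-identical for these designs;
published matrices are comparability anchors, not exact targets.

**DA.** Nei et al. (1983): DA = 1 − (1/L) Σ_l Σ_alleles √(x y), both
alleles entering the geometric mean.

**In.** Rosenberg's informativeness for assignment, natural log,
unweighted mean across K populations,
In = Σ_alleles(−p̄ ln p̄ + (1/K) Σ_i p_i ln p_i), with 0·ln 0 := 0;
bounded by ln K.

**AMOVA.** Allele-level nested ANOVA: each diploid contributes two 0/1
allele copies per locus (the within-individual level is collapsed into
the within-population component, matching the granularity of typical
reports). Sums of squares, degrees of freedom and the unequal-size
coefficients (n′, n″, n‴) accumulate locus by locus — missingness can
change the design per locus — and variance components come from the
expected mean squares. Percentages sum to 100 by construction;
Φ_ST, Φ_CT, Φ_SC are returned. A 2-level design (no grouping) and the
3-level groups/populations/within design are supported.

## Ordination and trees

**PCA** is an SVD of the column-centered, unscaled feature matrix —
dosages at the individual level, frequencies at the population level
(centering already removes the scale ambiguity that motivates scaling
for mixed units; dosage features share units). Sign convention: each
loading vector's first nonzero entry is made non-negative, so results
are reproducible across runs and BLAS builds. Explained percentages are
eigenvalue shares of total variance.

**Classical MDS** (Torgerson): double-center −½·J·D²·J, eigendecompose,
scale eigenvectors by √eigenvalue. Requires non-negative input (clamp
first); if fewer than the requested dimensions have positive eigenvalues
the rest are zero-filled with a warning. The reference study's MDS
algorithm (SPSS) is unknowable; classical metric scaling is the
canonical deterministic choice.

**Neighbor joining**: Saitou–Nei agglomeration with the Studier–Keppler
Q-criterion; exact Q-ties are broken by the lexicographically smallest
taxon pair, so the topology is invariant to input order. Negative branch
lengths are floored at 0 (flagged), the convention of mainstream tree
software. Trees are dendropy objects, exported as Newick at full
precision.

## Biogeographic-origin classification

Features are mean-imputed insertion dosages; labels are continents. A
stratified 75/25 holdout split (seeded) feeds four library classifiers —
random forest, XGBoost, SVM (RBF), decision tree — at library-default
hyperparameters; the published protocol states neither split nor
hyperparameters, and a single ~25% holdout is consistent with published
holdout totals. Confusion matrices are oriented rows = predicted,
columns = truth. Accuracy CIs are exact binomial (Clopper–Pearson),
computed from the integer trace and total, matching independent beta-
quantile evaluation to 1e−9.

## Synthetic data generator

A hierarchical Balding–Nichols model: ancestral insertion frequencies
uniform on [0.3, 0.72] by default (the realistic span for a DIP panel
selected for balanced frequencies; configurable), continental
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral value,
population frequencies likewise around their continent, genotypes HWE
binomial draws. Default structure: five continental groups with
continental FST 0.06–0.15 and within-continent FST 0.01–0.02, mimicking
human continental magnitudes. Frequencies are truncated to
[1e−4, 1−1e−4] so kinship LRs are defined everywhere.

What it emulates: FST-structured frequency divergence, HWE within
populations, LD-free loci, realistic per-locus frequency ranges. What it
does not: admixture clines, linkage, genotyping error, null alleles,
departures from HWE. Tests passing on this generator therefore validate
the estimators under their own model assumptions — parameter recovery,
calibration, geometry — not robustness to real-data artifacts.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep Monte-Carlo
error well inside the asserted tolerances: 600 loci / 150 diploids for
FST recovery (relative MC SE ≈ √(2/600) ≈ 5.8%), 300 loci for AMOVA and
HWE calibration, 1000 pairs for the kinship power study (binomial SE
≈ 0.44 points at 98%), 100k-pair reference runs where a high-replicate
oracle is needed. Statistical assertions use 3-standard-error bands.
All randomness flows through `numpy.random.default_rng` seeds recorded
in outputs; the pipeline manifest stores input hashes, parameters and
per-stage status, and re-running with the same seed reproduces every
output byte-for-byte (given fixed library versions for the classifier
stage).

## Known limitations

- Pairwise FST is the W&C estimator, not the AMOVA-distance flavor some
  packages report; values are comparable, not identical.
- The LD permutation test permutes genotypes (not alleles), testing
  genotypic association; the EM assumes HWE within each locus pair.
- The exact decimal CPD string depends on per-locus MP values computed
  as binary floats before conversion; digits beyond ~15 significant
  figures of each MP are not meaningful, though the displayed complement
  digits are stable.
- The classifier harness evaluates a single stratified holdout, not
  cross-validation; accuracy CIs condition on that split.
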