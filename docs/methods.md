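# Methods

This note records the models, rules and numerical choices behind
`assoctx`, and what the bundled simulator does and does not emulate.

## SNP calling from pileup summaries

Input is a per-accession, per-site table of quality-passing base counts
(the platform starts downstream of read alignment and base-quality
filtering; counts are defined as already Q20-filtered). Per accession and
site:

- depth ≤ 10 → missing (`min_depth_exclusive = 10`, read strictly: depth
  must be *in excess of* 10);
- base frequencies are taken over the sum of counts; bases at frequency
  ≥ `noise_freq = 0.2` contribute to the call;
- one contributing base → that base; two → the two-base IUPAC code
  (R/Y/S/W/K/M); zero or three-plus → missing. Three-base mixtures are not
  representable in the two-base alphabet and are conservatively treated as
  missing rather than as the top-two code.

Sites are retained when the missing fraction is **below** 0.25, distinct
non-missing call states number ≤ 3, and at least two states occur. Because
the panel is inbred/doubled-haploid, each call state is one fixed allele of
the marker, so "alleles" are counted as distinct call states (A and R are
different alleles). MAF is the frequency of the second most frequent state
among non-missing calls (ties report the tied frequency); association and
LD keep markers with MAF **strictly above** 0.01.

A marker is *hemi* when any observed state is an ambiguity code — one
allele of the polymorphism is a fixed two-base mixture produced by
homoeologous cross-mapping — and *simple* otherwise. Simple SNPs are
genome-assigned through the CDS model that hosts them; hemi-SNPs are
assigned only when present in the supplied linkage-evidence file (markers
mapped directly in a doubled-haploid linkage population), because the
polymorphism may otherwise reside in either homoeologue.

## Quantification

RPKM = count / ((CDS length/1000) × (total mapped reads/10⁶)). The
denominator is each accession's total reads aligned anywhere on the
reference. GEM analysis keeps genes with panel-mean RPKM strictly above
0.4, the mean taken over all panel accessions including zeros.

## Genotype encoding, structure, kinship, LD

Dosage encoding per marker: most frequent state → 0, alternate → 1; at
three-state markers where one state is the IUPAC union of the two resolved
bases (e.g. A, G, R), the union code is the mixed state and sits at 0.5. A
third state with no union relation (possible at hemi markers, e.g. {R, K,
G}) carries no defined dosage and is masked. Missing dosages are imputed
with the per-marker mean for PCA and kinship (preserves allele frequency)
and dropped pairwise elsewhere.

JC69 distance: d = −(3/4)·ln(1 − (4/3)p) with p the mismatch proportion
over sites non-missing in both accessions; p ≥ 0.75 is outside the model's
domain and is flagged as infinite. The dendrogram is average-linkage
(UPGMA) by default — the linkage criterion is a free choice here and is
configurable (any scipy method, or neighbor joining via scikit-bio).

The Q-matrix is a deliberately simple PCA-to-simplex admixture surrogate
(a stand-in for likelihood-based admixture estimation, which is out of
scope): mean-imputed, column-centred dosages are decomposed by SVD; k-means
clusters the top k−1 principal coordinates; each cluster's *archetype* is
the mean of its outer quartile of points along the direction away from the
global centre (a trimmed extreme — robust to single outliers while keeping
unadmixed accessions near the simplex vertices); accessions are projected
onto the simplex the archetypes span by constrained least squares. With
`k="auto"`, k is the largest eigengap among the first ten eigenvalues; a
weak eigengap triggers a warning. This surrogate recovers subpopulation
labels at ≥ 95% accuracy on Fst-0.1 two-population panels but its k
selection is not a likelihood criterion.

Kinship: K = GGᵀ/m over column-standardized, mean-imputed dosages
(zero-variance markers dropped with a warning), rescaled to mean diagonal
1 so that σ²g is on the trait-variance scale.

LD: markers restricted to genome-assigned, MAF > 0.01; one SNP per CDS
model drawn with a seeded generator (default seed 1) so a gene's many
linked SNPs contribute once; r² is the squared Pearson correlation of
dosages over pairwise-complete accessions — in inbred/DH material the
composite dosage correlation equals the haplotype r², so no haplotype EM is
needed. Means are over within-chromosome pairs only; chromosomes with
fewer than two retained sites are skipped with a warning.

## Mixed-model association

Null model y = Xβ + g + e with X = [1, Q minus its last column] (Q rows
sum to one, so one column is dropped against the intercept), g ~ N(0,
σ²g K), e ~ N(0, σ²e I). REML is profiled over δ = σ²e/σ²g on the
eigenbasis of K: a 81-point log₁₀ grid on [10⁻⁵, 10⁵] followed by bounded
golden-section refinement (xatol 10⁻⁶); a boundary optimum warns.
Pseudo-heritability is h² = 1/(1+δ).

Marker tests reuse the null variance structure across all markers
(P3D/EMMAX). Complete markers are tested in the whitened eigenbasis by
exact partial regression (Frisch–Waugh), vectorized across markers; markers
with missing calls drop those accessions only, grouped by missingness
pattern, with a Cholesky whitening of the subset covariance per pattern.
The test is a Wald t with n − rank(X) − 1 degrees of freedom (no
finite-sample Satterthwaite correction). Per-marker REML refits are
available behind `p3d=False`. With K = I and no Q the procedure reduces
exactly (to ~10⁻¹⁶) to OLS simple regression, which the tests verify.

GEM tests are fixed-effect OLS of trait on (RPKM, Q, intercept). The
reported slope is the structure-adjusted RPKM coefficient; the intercept is
anchored so the prediction line passes through the panel means (ȳ −
slope·x̄), making `intercept + slope × RPKM` a usable predictor for a new
accession without its Q row; r² is the full-model coefficient of
determination. Genomic control is applied to GEM scans (optional for SNP
scans behind a flag): λ = median(χ²₁(p))/0.45494; when λ > 1 the χ²
values are divided by λ and p recomputed, otherwise the scan is unchanged.
Bonferroni thresholds use the number of markers actually tested
post-filter — this is what reproduces the platform's printed −log₁₀ P
lines of 6.7 (256 397 SNPs) and 6.03 (53 889 GEMs). The FDR line is the
−log₁₀ of the largest Benjamini–Hochberg-passing p at q = 0.05 (infinite
flag when none pass). Manhattan tables order markers A1..A10 then C1..C9 by
gene-model order index; genome-assigned markers are dark, unassigned
hemi-SNPs are pale and plotted at both homoeologous model positions when a
partner exists (homoeologous "shadows").

## Take-one-out prediction

Default (full) mode re-estimates everything per round from the n−1
training accessions: Q, K, the REML null fit, the scan and the selection of
markers above that round's Bonferroni line. The held-out accession's trait
is predicted as the unweighted mean of per-marker predictions — per-state
allelic-effect means for SNPs (states unseen in training, including
missing, fall back to the training mean), the fitted line intercept +
slope × RPKM for GEMs. The unweighted mean was chosen over a multiple
regression combiner because peak markers are strongly collinear. Rounds
with no selected marker predict the training mean and are flagged.

Predictive power is the R² of the regression of predicted on observed. A
non-positive correlation is reported as R² = 0: predictions that fall back
to the training mean are weakly *anti*-correlated with the held-out value
by construction ((S − yᵢ)/(n−1)), and without this guard a scan with no
real signal would report R² ≈ 1 from that artefact alone. Fast mode fixes
the selected marker set (and Q/K) from the full-panel scan and only refits
per-marker effects per round; it agrees with full mode within R² ± 0.05 on
simulations but is not leakage-free in selection.

## The synthetic panel

Defaults are the study conditions of the platform being emulated: 383
inbred accessions; k = 2 subpopulations with Balding–Nichols drift
(ancestral frequencies Uniform(0.05, 0.95), Beta-drifted at Fst = 0.1);
80% of accessions unadmixed, 20% Dirichlet(1)-admixed; alleles drawn once
per accession (homozygous). Two subgenomes of 150 gene models each (spread
over A1–A10 and C1–C9, lengths 300–3000 b, 3 candidate sites per model)
are paired 1:1 as homoeologues.

Pileups: depth ~ Poisson(50); sequencing errors move reads uniformly onto
the other three bases at rate 0.005. Cross-mapping is modelled as a
property of the model pair: for 70% of pairs read mapping cannot separate
the homoeologues and a fraction `cross_mapping_rate` (default 0.3) of each
site's reads carries the homoeologous base (taken as fixed at the mirrored
position, divergent from the reference base at 70% of sites); the
remaining pairs map discriminately. This choice is what produces the
coexistence of hemi-SNPs (the majority, as in real *B. napus* panels) and
genome-assignable simple SNPs; a single global rate would make every
polymorphism hemi. The hemi fraction rises monotonically with the rate and
is zero (up to the error floor) when cross-mapping is off. A seeded 30% of
sites are marked as linkage-mapped (the genome-assignment evidence for
hemi-SNPs).

Expression: log-normal background RPKM (log-mean ~ N(1.5, 0.5), log-sd
0.8); 15% of genes near-silent (mean ≪ 0.4) to exercise the expression
filter. One C2 gene carries a biallelic expression variant with frequency
0.85/0.15 across the two subpopulations; carriers express at ~12 RPKM,
non-carriers at ~2 (log-sd 0.3), giving the bimodal, structure-correlated
abundance profile of an expression-mediated causal gene.

Trait: two major loci on A8 and C3 contribute 30% and 20% of trait
variance (effects scaled by realized dosage variance; causal sites drawn
from discriminately-mapped models with realized MAF in [0.2, 0.45], the
window widened if empty), plus the causal gene's RPKM with a negative slope
sized for 15% of variance. The residual is matched to the realized
genetic variance so the realized h² equals the target (0.65) to ±0.02.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium decay along chromosomes
(sites are exchangeable given structure, so the simulated genome-wide mean
r² is the null expectation ≈ 1/(n−1), far below real panels, and
association peaks have no spatial width), homoeologous exchange and
copy-number variation, read-level quality variation, and selection or
bottleneck histories. One consequence is quantitative: the SNP-based h²
estimate converges on the SNP-attributable variance fraction (0.50), not
the total simulated h² (0.65), because the expression-mediated component
is by design not encoded in any scored SNP — exactly the situation of an
expression-variant causal gene with no SNP association. The estimator
itself is unbiased on polygenic traits drawn from K (recovering h² = 0.8
± 0.1 in the test suite).

## Problem sizes used in tests and the acceptance script

Calibration uses 200 accessions × 10 000 markers (type-I error) and 3 000
genes (genomic control); recovery uses the full default panel (383
accessions, 300 models, ~900 candidate sites, ~650 tested markers) over
20 seeds, with take-one-out validation (full, leakage-free mode) on one
panel; the hemi-SNP mechanism sweep uses 100 accessions × 80 models at
four cross-mapping rates. These sizes keep a complete run in the
few-minute range on one CPU while leaving every statistical check
well-powered.

## Known limitations

- The Q-matrix estimator is a PCA surrogate, not a likelihood admixture
  model; its `auto` k (eigengap) can differ from likelihood-based k.
- P3D reuses one variance fit across markers; for markers of very large
  effect the exact per-marker REML (available behind a flag) is more
  conservative.
- Genomic control is scan-level and assumes a broadly null scan; with many
  true signals the median-based λ over-corrects slightly.
- The file formats are this artifact's own TSV/CSV dialects (documented in
  `assoctx.io`); they are not interchange formats of other GWAS tools.
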