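# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices, and the known limitations of `grnmap`.

## Genetic model and codings

All association machinery works on minor-allele counts g ∈ {0, 1, 2}
(missing = NaN), where "minor" is determined per site from the loaded
cohort, not from the VCF REF/ALT orientation. This makes additive effects
consistently oriented across sites regardless of how the source VCF was
polarised.

The single-locus design uses the classical F∞ parameterisation:

* additive code x = g − 1 ∈ {−1, 0, +1}, so the additive effect *a* is half
  the difference between the two homozygote means (trait units per
  minor-allele copy);
* dominance code z = +½ for heterozygotes, −½ for either homozygote, so the
  dominance effect *d* is the heterozygote deviation from the homozygote
  midpoint.

With a saturated three-class fit these definitions give closed forms
a = (ȳ₂ − ȳ₀)/2 and d = ȳ₁ − (ȳ₀ + ȳ₂)/2, which the tests verify exactly.

Three single-locus tests are reported per SNP and trait: the 2-df genotypic
effect *m* (genotype-as-factor vs covariates-only F test, with
R² = ΔSSE/SStot as the variance explained), and 1-df tests of *a* and *d*
(full-vs-reduced F, equivalent to the coefficient t tests). Adjusted
genotype-class means come from a cell-means fit with centred covariates, so
they stay on the trait scale.

## Population structure

Structure enters as fixed covariates (the Q-matrix columns, centred),
not as a kinship random effect. This is the least-squares test for
unrelated individuals; it controls mean confounding by subpopulation
membership but does not model residual relatedness. For panels with cryptic
relatedness a kinship mixed model would be the appropriate upgrade; that is
out of scope here and the simplification is deliberate and documented.

## Epistasis: the four-way decomposition

The two-locus model fits

    y ~ Q + x₁ + z₁ + x₂ + z₂ + x₁x₂ + x₁z₂ + z₁x₂ + z₁z₂

by OLS. The four product columns carry the A×A, A×D, D×A and D×D
interaction effects — interpretable respectively as allele×allele,
allele×genotype, genotype×allele and genotype×genotype interactions. D×A is
reported distinctly from A×D (locus order matters). Under exact 1:2:1⊗1:2:1
genotype proportions (HWE at allele frequency ½) the eight genetic columns
are mutually orthogonal; this is the orthogonal partition that the
unequal-frequency ("extended") model generalises, and OLS on the observed
design is that generalisation. Note the orthogonality is with respect to
1:2:1 weights, not uniform 3×3 cell counts.

Each interaction coefficient gets a 1-df full-vs-reduced F test; a joint
4-df test covers the interaction block. Degrees of freedom are taken from
matrix ranks, so empty or aliased cells never inflate the numerator df.
Coefficients whose columns are aliased by the observed cell pattern (e.g. a
duplicated SNP) are flagged non-estimable rather than reported as zero.

Occupancy rule: a pair is tested only if every marginal genotype class at
each locus has ≥ 3 individuals and ≥ 5 of the 9 two-locus cells are
occupied (both configurable). Pairs failing the rule are reported as
skipped with the reason, never silently dropped.

### Combination tables

For a significant pair, combination effect–frequency tables report each
allele/genotype combination's weighted mean phenotype deviation from the
grand mean and its frequency share:

* A×A — every individual contributes its 2×2 ordered allele pairings (one
  allele from each locus) with weight ¼ each;
* A×D / D×A — allele at one locus (weight ½ per copy) crossed with the full
  genotype at the other;
* D×D — plain genotype–genotype cell means with weight 1.

Each individual contributes total weight 1, so frequencies sum to 1 and the
frequency-weighted effects sum to 0 exactly on complete data; rows are
sorted by effect, descending. The ¼-per-ordered-pairing weighting is the
definition under which a combination's frequency approaches the product of
its allele frequencies at unlinked loci.

## Multiple testing

Benjamini–Hochberg step-up q-values are computed within each
(trait, effect-type) family; the family choice is configurable. A result is
flagged significant at p ≤ α and q ≤ FDR, defaults 0.01 and 0.1. A stricter
FDR ≤ 0.01 preset is available via config (the validator notes the
non-default value). The significance transform log₁₀(1/p) is provided for
reporting.

## LD decay

Pairwise LD is the composite genotypic r²: the squared Pearson correlation
of minor-allele counts over individuals with both calls present. This is
the standard choice for unphased diploid data; no phasing or D′ is
attempted. r² is symmetric and invariant to which allele is coded at either
locus.

The decay of r² with physical distance d is fitted with the Hill–Weir
sample-size-adjusted expectation, with C = ρ·d:

    E(r²) = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]

The curve starts near 0.45 at C = 0 and decays to the finite-sample floor
≈ 1/n. The single parameter ρ ≥ 0 (per bp) is estimated by least squares on
a log-ρ grid (400 points spanning 1e−12…1e3) followed by bounded scalar
minimisation (xatol 1e−13), which recovers a noiseless curve's ρ to better
than 1e−6 relative. If the boundary ρ → 0 fits at least as well (e.g. all
r² = 1), the fit reports ρ = 0 and the threshold crossing as +∞. The
crossing distance for a threshold (default r² = 0.1, reported with the
conventional significance note) is found by bracketing + Brent root
finding on the fitted monotone curve.

## Target discovery

Motif scanning is exact string matching (overlaps allowed). In both-strand
mode, reverse-complement matches are reported on the − strand; a motif that
is its own reverse complement (such as TCACGTGA) is reported once, forward
only, to avoid double counting. A hit's position is the 1-based upstream
offset of the motif base closest to the TSS (position 1 = base immediately
5′ of the TSS); positional windows are closed intervals, and window
fractions use all hits as the denominator. By default a gene "has the
motif" if its promoter carries at least one occurrence of any configured
motif (OR logic across motifs; configurable to a single motif) — the
combination rule across a primary motif and an alternative core motif is a
design choice, not an assertion about any particular dataset.

Hub co-expression is plain Pearson r against the hub profile, honoured
as-is even over as few as 3–4 conditions: selection uses the strict
threshold |r| > 0.8 with no significance attached, so r = 0.8 exactly is
excluded. The differential-expression screen (FC ≥ 2 or ≤ 0.5, q ≤ 0.10,
p ≤ 1e−3, boundaries inclusive) operates on supplied statistics; the DE
test itself and RNA-seq normalisation are out of scope.

## Layered network

Significant SNP pairs collapse to undirected gene edges (within-gene pairs
are dropped — no self-loops), keeping the supporting SNP-pair list and
traits. Layers are BFS distance from the hub capped at the configured
maximum (default 3): hub = 1, direct interactors = 2, everything else
reachable = 3. Genes unreachable from the hub are excluded and listed. Edge
classes (L1–L2, within-L2, L2–L3, within-L3) are a function of endpoint
layers only. The connectivity summary is the fraction of a declared gene
universe (hub excluded) placed in layer ≥ 2. Per-trait networks and a
pooled network (union of per-trait significant edges) are both available;
pooled-union semantics is the documented default.

## Synthetic-data generators

The generators produce data with the statistical structure the analysis
assumes, at the default study conditions: 435 unrelated individuals, ten
quantitative traits, a hub gene plus 53 candidate targets, four-tissue
expression, 2-kb promoters.

* **Genotypes**: two Bernoulli(MAF) haplotype vectors per SNP (HWE).
  Within an LD block, each non-anchor SNP copies the anchor's haplotype
  with probability ρ per haplotype, giving pairwise r² ≈ ρ² for equal MAFs
  and exactly 1 at ρ = 1; chaining 2-SNP blocks yields distance-decaying
  LD. This is haplotype copying, not coalescent simulation: it gives exact
  control of the r² = 1 case at the cost of realism in the site-frequency
  spectrum.
* **Phenotypes**: y = μ + Σaᵢxᵢ + Σdᵢzᵢ + Σ epistatic products + Qβ +
  N(0, σ²), i.e. exactly the estimation model — by construction the σ→0
  limit recovers planted coefficients to numerical precision, which the
  tests use as a generative-consistency check.
* **Expression**: hub profile standard normal; each target is
  r*·(standardised hub) + √(1−r*²)·noise, then shifted positive by a
  per-gene constant (shifting, not exponentiation, so planted Pearson
  correlations are preserved exactly in expectation). With only 4
  conditions the realised r is noisy around r*, which is faithful to how
  few-tissue correlation filters behave; exact-recovery tests use larger
  condition counts.
* **Promoters**: i.i.d. background at a given GC content with motifs
  written at exact offsets; the background is guaranteed free of spurious
  occurrences of any planted motif string or its reverse complement by
  redrawing collision windows.

The bundled demo plants per-trait genetic architectures (4 additive, 3
dominance, 5 hub–target and 3 target–target epistatic terms) with σ = 1;
interaction coefficients are drawn larger for genotype-level terms (D×D
1.8–2.4) than allele-level ones (A×A 1.0–1.5), mirroring the relative
magnitudes combination tables show, and trait SDs land near 2. Epistatic
terms are planted at SNPs with realised MAF ≥ 0.25: at low MAF the
interaction columns are strongly collinear with the main-effect columns
(e.g. cov(x₁x₂, x₁) = E[x₂]·var(x₁), large when E[x₂] is far from 0), which
inflates interaction standard errors several-fold and would make the
planted signal mostly non-identifiable at this panel size — a real feature
of the unequal-frequency design worth knowing when interpreting rare-variant
interaction scans. Single-SNP
R² values then span roughly 0.1%–15%. These are design choices for a
plausible demonstration, not claims about any real population. What passing
tests on these data show is that the estimators and tests are correct and
calibrated under the assumed model (independent unrelated individuals,
Gaussian residuals, fixed-effect structure); they do not establish
robustness to kinship, non-normal residuals, or ascertainment.

## Numerical choices and degenerate inputs

* All fits use `numpy.linalg.lstsq`; nested F tests use rank-based degrees
  of freedom; a perfect fit (zero residual) reports p = 0 for any improving
  comparison.
* Missing genotypes/phenotypes are handled complete-case per test; no
  imputation.
* Genotype classes below `min_class_n` (default 3) are excluded from the
  test; with two remaining classes only *a* is estimated (d non-estimable,
  reason-coded); with fewer, the SNP is skipped with a reason.
* Monomorphic SNPs are retained in the matrix but flagged, and association
  operations skip them.
* The common-SNP filter keeps MAF strictly > 0.10; SNPs at exactly 0.10 are
  removed.
* The SNP missing-data threshold (keep SNPs with ≤ 20% missing calls) is
  exposed as configuration for file-based runs.
* Determinism: all randomness flows from one root seed via named per-stage
  substreams (SHA-256 of "seed:stage", truncated below 2³¹); identical
  config + seed reproduces byte-identical output tables.

## Known limitations

* Fixed-effect structure adjustment only — no kinship/variance-component
  mixed model, no permutation p-values.
* Exact-string motif scanning only — no PWM scanning or motif discovery.
* Pairwise epistasis only, at desk scale (pair lists are capped and
  configurable); no haplotype-based or higher-order interaction tests.
* The combination-table "effect" column is the deviation of the weighted
  combination mean from the grand mean; the per-test interaction "effect"
  is the least-squares coefficient on the corresponding product column.
  Other software may scale these differently; the definitions here are the
  documented ones.
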