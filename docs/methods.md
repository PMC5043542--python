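# Methods

## The model

An inversion polymorphism is treated as a locus with 2 or 3 non-recombining
"arrangement" alleles (haplotype classes). Because crossover products are
inviable in heterokaryotypes, the arrangements behave as super-alleles: SNPs
inside the inverted region are in strong mutual LD, individuals form discrete
genotype clusters in a chromosome-wide PCA, and a pooled sequencing sample
shows elevated heterozygosity wherever the arrangements are strongly
differentiated. Recombination suppression is strongest at the breakpoints;
double crossovers and gene conversion ("gene flux") slowly exchange interior
sequence between arrangements, which erodes interior LD but not breakpoint
LD. All analyses in this package are built around these structural
consequences rather than around direct breakpoint observation, so they work
on SNP-chip-density genotype data.

## Synthetic data generator

`invkaryo.simulate` draws, per individual, two arrangement copies (one for
hemizygous females at a sex-linked locus) i.i.d. from the configured class
frequencies — random mating, hence Hardy–Weinberg genotype proportions in
truth. SNP columns are then generated conditional on the copies:

* **Diagnostic SNPs.** Each SNP inside the inversion is class-diagnostic with
  probability `breakpoint_divergence` (allele 1 marks one uniformly chosen
  target class). Diagnostic SNPs in the two breakpoint zones (each a
  `breakpoint_frac` = 0.15 share of the inversion length) are never
  perturbed.
* **Gene flux.** Interior diagnostic SNPs are exchanged independently per
  haplotype copy and SNP with probability `gene_flux_rate`: the copy adopts
  the allele of a uniformly drawn other class. This is deliberately not an
  explicit double-crossover model; independent per-SNP exchange is the
  simplest mechanism that reproduces the breakpoint-high / interior-low LD
  signature, which is all the downstream analyses consume.
* **Background SNPs.** Collinear SNPs (and non-diagnostic interior SNPs)
  carry short-range LD from a latent Gaussian AR(1) process per haplotype
  copy, thresholded at a per-SNP allele frequency drawn from U(0.1, 0.5).
  The latent correlation between adjacent SNPs is `exp(−d·λ)` with
  `λ = 1/100 kb`, so background `r² > 0.1` is essentially gone beyond
  ~200 kb — a background LD ceiling of the order observed on genotyped
  chromosomes, and safely below the ≥1 Mb span required of inversion
  blocks. Non-diagnostic SNPs falling inside a breakpoint zone are kept
  monomorphic: near-total recombination suppression leaves no shared
  polymorphism there, which reproduces the slight dip in diversity at
  breakpoints relative to the flux-exposed interior.
* **Defaults as study conditions.** 1000 individuals, 200 SNPs evenly spaced
  on a 20-Mb chromosome, a 10-Mb inversion at frequency 0.6/0.4, full
  breakpoint divergence, 5% interior flux, pooled coverage 247.5×. No
  quantitative gene-flux rate is established for this system; 0.05 is an
  arbitrary but documented choice that leaves interior LD clearly above the
  detection threshold while measurably below breakpoint LD.

Pooled read counts are Poisson depth × binomial allele sampling at the
pooled frequency (only the mean coverage is constrained by the emulated
design). Phenotypes are `y = a·X_add + d·X_dom + ε`; egg mortality is
per-egg Bernoulli with a logit-linear model in parental heterokaryotypy;
transmissions are per-parent binomials; aviary fitness is linear in the
frequency-sum predictor. Every generator derives independent substreams
from one seed (`SeedSequence.spawn`) and is bit-reproducible.

**What the generator does not emulate:** coalescent site-frequency spectra,
selection over generations, pedigree relatedness (individuals are
unrelated), genotyping error, and read-level artifacts. Passing recovery
tests therefore demonstrates correctness of the estimators under the assumed
structure, not robustness to everything real data can do.

## Detection and karyotyping

* **Blocks.** `detect_long_range_blocks` grows quasi-cliques on the
  thresholded `r²` matrix: seed at the SNP with the most partners above
  `r² = 0.1`, admit the candidate with the highest mean `r²` into the block
  among those connected to ≥ 80% of current members, stop when none
  qualifies, report clusters spanning > 1 Mb. The 80% connectivity rule
  tolerates interior gene flux while excluding stray background pairs; the
  1-Mb span floor sits far above the background LD range. Boundary SNPs are
  the first and last members by position, each reported with its maximal
  `r²` into the block.
* **PCA.** Full SVD of the mean-imputed, centered (optionally
  `√(2p(1−p))`-scaled) dosage matrix; deterministic, with each component's
  sign fixed so its largest-magnitude loading is positive. Hemizygous
  females enter with doubled dosage (0→0, 1→2) so they co-locate with the
  corresponding homozygous males.
* **Cluster calling.** k-means with deterministic initialization — PC1
  min/median/max for the biallelic k = 3 case; three farthest-point corners
  plus pairwise midpoints on PC1/PC2 for the triallelic k = 6 case. Any
  clusterer that reproduces truth on synthetic data would do; k-means with
  fixed starts keeps the output reproducible. Allele labels are assigned by
  descending frequency (A = major). A hemizygous female landing in a
  heterozygote cluster is impossible for a true single-copy carrier and is
  reported as a flagged no-call rather than silently relabeled.
* **Tag SNPs.** Candidates are block SNPs with `r² > 0.9` against the PC1
  (optionally PC2) scores; the panel takes the candidates nearest each end
  of the block, which maximizes physical span and covers both breakpoint
  regions when possible. The dosage→genotype vote map is learned from the
  PCA calls. Majority voting allows missing tags and returns no-call on
  exact ties (a deliberate choice; ties are not resolvable without an
  arbitrary preference); unanimity requires all tags present and agreeing.

## Window statistics

`H_p` uses read-count sums over 50-kb windows anchored at position 1;
trailing partial windows are retained and flagged. Windows with no reads are
missing, never zero. `ZH_p` standardizes over all defined windows
genome-wide by default (per-chromosome offered as an option) using the
sample (n−1) standard deviation — at genome scale the difference from the
population formula is negligible. MAC spectra bin minor-allele read
fractions into width-0.02 bins on [0, 0.5]; a "local maximum" is a bin
exceeding both neighbors and ≥ 1.5× the median bin count (an invented but
documented peak-calling rule; the ratio floor suppresses noise peaks in
flat spectra).

## Tests and models

* **HWE.** χ² against expectations from the same counts, `df = genotype
  classes − alleles`; the exact biallelic test enumerates heterozygote
  counts conditional on allele counts and sums probabilities no larger than
  the observed configuration's (minlike convention, like the binomial
  two-sided test used for segregation distortion). For sex-linked loci the
  default test uses diploid (male) classes only, since mixing hemizygotes
  changes the degrees of freedom.
* **QC.** Individuals with missing rate strictly > 0.05 are dropped, then
  SNPs with missing rate > 0.1, monomorphic SNPs, and exact-HWE deviants at
  a Bonferroni threshold of 0.05 / (SNPs tested). Filters are idempotent.
* **Association.** OLS of the (Z-transformed) response on `X_add + X_dom`
  (+ covariates); count-like fitness components are square-root transformed
  *then* Z-transformed. Logistic regression for egg mortality with Wald
  CIs; complete separation is flagged and the CI reported as unbounded.
  The emulated study's random-effect structures (pedigree relatedness,
  permanent environment, experiment) are replaced by fixed-effect models:
  synthetic individuals are unrelated, so the estimands are unchanged; this
  is the package's principal simplification and the reason its recovery
  targets transfer to real data only where relatedness is modest or modeled
  elsewhere.
* **Meta-analysis.** Inverse-variance fixed-effect pooling; Cochran's
  `Q = Σ wᵢ(βᵢ − β̂)²` on k−1 df. The "weighted mean effect" summary is the
  same pooled estimate with a Z-test — inverse-variance weights are an
  assumption, stated here, not a derived fact.
* **Permutations.** Genotype labels are permuted within sex strata, which
  preserves the per-stratum genotype multiset; because the additive/
  dominance coding depends only on that multiset, the implementation
  permutes the precomputed codes (mathematically identical, ~8× faster).
  Empirical P values use the (r+1)/(n+1) correction. Spike-in power adds
  the effect to the homozygote groups with opposite signs (additive) or to
  the heterozygotes (dominance) after each permutation, then refits.
* **Frequency dependence.** Per-aviary allele frequencies from called birds
  of the focal sex; each individual receives the sum of its two alleles'
  frequencies (biallelic heterozygotes get exactly 1, hemizygotes their
  single allele's frequency). A constant predictor (aviaries fixed for one
  arrangement) is a degenerate design and raises rather than returning a
  meaningless slope.

## Numerical choices and degenerate inputs

Composite `r²` is undefined (NaN, distinguishable from 0) for constant
vectors or < 2 complete pairs; missing genotypes are excluded pairwise
everywhere. Coordinates are 1-based inclusive (VCF convention); BED output
converts to 0-based half-open. Dosage recoding to the minor allele breaks
50/50 ties toward the alphabetically first allele. Multi-locus LD between
inversion loci is a χ² on the two-locus genotype-class table scaled to
squared Cramér's V — an `r²`-analogue validated against its own nulls
(identity → 1, independent loci → uniform P), since the exact estimator of
the classical multi-allelic treatment is not pinned down by the emulated
design.

## Problem sizes

The test suite and acceptance script run the detection chain at 1000
individuals × 200 SNPs (50–100 seeds), effect recovery at n = 2000
phenotypes and 100 000 eggs, calibration suites at 2000 replicates, and MAC
spectra at 12 000 sites — sizes chosen so every Monte-Carlo criterion is
decided by its statistics rather than by run-to-run noise, while the whole
suite completes in well under a minute of compute per module.

## Known limitations

Breakpoints are located only to SNP resolution (no read-pair/split-read
mapping); no imputation or phasing; the triallelic cluster geometry assumes
the three homozygote clusters are mutually farthest points in PC space,
which can fail if a rare arrangement recombines with the others; exact HWE
is biallelic only (the multi-allelic χ² covers the rest); fixed-effect
models understate uncertainty when strong pedigree structure exists in real
data.
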