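# Methods

`ailgxe` implements a gene–diet-interaction mapping pipeline for
multiparental mouse populations — specifically a four-founder advanced
intercross line (AIL) — together with the microbial/fungal community
detection and multi-omics candidate-gene funnel that accompany it.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic-data experiments do and do not demonstrate.

## Founder-haplotype reconstruction

Genotypes are biallelic marker calls (0/1/2 copies of the "1" allele) on a
genetic map.  After QC (minor allele frequency > 0.05, missing fraction
< 0.1, removal of markers monomorphic across the founders), a hidden Markov
model reconstructs each individual's founder diplotype.

* **State space.**  Ordered pairs of founder origins internally
  (16 states for 4 founders), reported as the 10 unordered diplotypes and as
  per-founder dosages (0–2, summing to 2).  The chain has one state per
  marker; reported positions are marker positions.
* **Transitions.**  Each haplotype switches founder independently between
  adjacent markers with probability `1 − exp(−G_eff·d/100)` for map distance
  `d` cM, landing uniformly on any founder (probability 1/4 each, including
  the current one).  `G_eff` defaults to the number of intercross
  generations; the true effective value in a finite AIL is somewhat lower
  (drift and shared ancestry reduce effective meioses — we measure ~14 for
  20 generations with 50 breeding pairs), but posterior accuracy is
  insensitive to this choice; marker density dominates.
* **Emissions.**  P(observed call | founder alleles of the diplotype) with
  each of the two allele reads flipped independently with probability
  ε (default 0.002).  Missing calls contribute likelihood 1 (marginalized,
  never imputed).
* **Numerics.**  Scaled forward–backward in linear space with per-marker
  normalization and an emission floor of 1e-300; posteriors are validated to
  sum to 1 and dosages to 2 to 1e-9.  On ≤5-marker instances the posteriors
  agree with exhaustive path enumeration to better than 1e-12.
* **Calibration.**  With error-free strain-private markers at array-like
  density (16 markers/cM), the posterior argmax matches the simulated truth
  at ≥99% of markers for a 20-generation AIL.  At 2 markers/cM accuracy
  drops to ~92% — boundary localization between recombination breakpoints is
  the limiting factor, since each private marker is informative for only one
  founder.

## Kinship and residualization

Kinship is the dosage cross-product `K_ij = (1/2L) Σ_l Σ_f d_ilf d_jlf`,
scaled so the mean diagonal is 1 — a Gram matrix, hence symmetric PSD.

Quantitative traits are Box-Cox transformed (λ maximizing the profile
likelihood on a grid over [−2, 2], step 0.01, with an automatic recorded
shift for non-positive values), then residualized in the linear mixed model

    y = Xβ + u + e,    u ~ N(0, σ²_g K),    e ~ N(0, σ²_e I)

with sex and diet as fixed effects.  REML profiles the heritability ratio
h = σ²_g/(σ²_g+σ²_e) using one eigendecomposition of K; when the profile is
flat (e.g. K = I, where h is unidentifiable) the smaller h wins, so a null
kinship never inflates σ²_g.  The residual is conditional,
`r = y − Xβ̂ − û` (BLUP subtracted), which equals `σ²_e V⁻¹(y − Xβ̂)` and is
therefore exactly orthogonal to the fixed-effect columns.  Binary traits use
a penalized-quasi-likelihood loop (logit link) whose variance components are
re-estimated each iteration on the working response by the same gaussian
REML machinery — a simplification that ignores the IRLS weight
heterogeneity in the variance step; `r` is the working residual on the
linear-predictor scale.

The variance partition reported per trait is incremental:
`fraction(diet) = [RSS(model without diet) − RSS(full)]/TSS`, likewise for
sex, and `fraction(kinship) = ĥ × remainder`.  It is tested for
non-negativity and additivity, not for equality with any published
partition.

**Proximal contamination.**  Because the causal locus contributes to K, the
BLUP absorbs part of a QTL's signal.  The attenuation is governed by the
causal chromosome's share of the kinship: with 5 chromosomes a planted QTL
of raw LOD ≈ 25 retains residual LOD ≈ 3–6 (marginal against a ~4.3
threshold), while with 10 chromosomes of the same marker density it retains
LOD ≈ 6–10.  The synthetic end-to-end study therefore uses a 10 × 100-marker
genome; the real mouse genome's 20 chromosomes sit past this regime.
Relative to a full mixed-model scan oracle the residual scan's peak LOD is
still roughly halved — peak location agrees to within a marker — which is
an inherent property of all-marker (non-LOCO) kinship with conditional
residuals, not of the implementation.  Leave-one-chromosome-out kinship
would remove the effect entirely but is not part of the emulated
procedure.

## Genome scans and significance

At every locus the residual trait is regressed on the founder dosages
(3 estimable contrasts + intercept) and evidence is

    LOD = (n/2)·log10(RSS₀/RSS₁).

The interaction scans compare `r ~ D + factor + D:factor` against
`r ~ D + factor` (df = 3(k−1) for a k-level factor); the factor main effect
is kept in the base model defensively even though it was residualized out.
The gaussian likelihood is also used for residualized binary traits (working
residuals treated as gaussian).  Scans are computed with batched gram-matrix
least squares (one `einsum`/batched-solve per scan); rank-deficient local
designs fall back to pseudo-inverse.

Permutation thresholds shuffle genotype rows against (r, factor) pairs —
r never separates from its factor — and take the 95th percentile
(linear/type-7 interpolation) of the genome-max and per-chromosome-max LOD
distributions from the same permutations.  n_perm < 100 is refused.
Calibration: on 200 null traits (n = 500, 10 × 20 markers, 200 permutations
each) the empirical family-wise error sits inside [0.02, 0.09].

QTL are called one per chromosome at the LOD argmax (leftmost tie wins),
tiered genome-wide vs chromosome-wide (a genome-wide call is excluded from
the suggestive tier).  The support interval is the maximal contiguous run
with LOD ≥ peak − 1.5, extended to the flanking marker positions; variance
explained is `1 − 10^(−2·LOD/n)`.  Founder allele effects at the peak are
least-squares coefficients under sum-to-zero contrasts; the high/low founder
bipartition is the exact 1-D 2-means split (all contiguous splits of the
sorted coefficients scored by within-group SS), with the boundary gap
reported.

## Fine-mapping

Within a QTL support interval the founder variant table is filtered in
order: (1) drop variants whose alternate allele all founders share;
(2) keep variants whose alt-carrier set equals the effect bipartition or its
complement (subset containment behind a flag — the published procedure's
manual inspection is automated as this strain-distribution-pattern match);
(3) drop synonymous variants and rank genes by best consequence tier —
missense/5'UTR/3'UTR above other genic consequences, intergenic excluded —
with ties broken by supporting-variant count then gene id.  Every step
updates a ledger whose counts telescope exactly; record order never affects
the report.

## Co-occurrence communities (FMC/FFC)

OTU tables are filtered to taxa with ≥10 reads in ≥25 samples (singletons
removed first; thresholds inclusive).  SparCC estimates basis correlations
from log-ratio variances: per estimation iteration the fractions are drawn
from a Dirichlet posterior (counts + 0.5, which also handles zeros), the
linear system for basis variances is solved, and the strongest pair above
|ρ| = 0.1 is excluded from the system for up to 10 rounds; the median over
20 iterations is reported.  P-values permute each taxon's counts across
samples independently (100 datasets, +1 smoothing); Benjamini–Hochberg
adjustment is applied across pairs.

The network adjacency is `a_ij = (0.5 + 0.5·ρ_ij)^β` with β = 4, and the
unsigned topological overlap
`T_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)` feeds average-linkage
clustering of 1 − T.  Modules are branches of the dendrogram: the top above
0.995 of the maximum merge height is discarded and branches completing
below 0.8 × that cut with ≥ min_size members (10 for bacterial, 5 for
fungal tables) and mean within-branch distance below the branch height are
kept; all other taxa are "unassigned".  A single flat cut near the root
provably chains unconnected taxa onto tight modules (average-linkage
chaining), which the two-level rule prevents.  EigenOTUs are the first
principal component of each module's standardized abundances, unit variance,
sign-aligned with the module mean profile.  Module–trait statistics report
Spearman correlations plus Wilcoxon (2-level) or Kruskal–Wallis (≥3-level)
p-values, BH-adjusted across modules within each trait.  Cross-domain
correlation concatenates two modules' member taxa over shared samples and
reruns SparCC, reporting the cross block.

**Compositional closure caveat.**  In small tables a strongly abundant
correlated block displaces every other taxon's fractions, so a second block
becomes genuinely anti-correlated with any trait coupled to the first; with
realistic table sizes background taxa dilute the effect.  Recovery
experiments therefore use the block-only tables they state, and the
trait-association experiment includes background taxa.

## Synthetic data

The generator supplies every input the pipeline consumes:

* **Founders and cross.**  Four inbred founders over a configurable map; a
  stated fraction of markers is strain-private (exactly one founder
  differs), the rest are monomorphic.  Breeding: F1 from randomly paired
  founders, then `generations` rounds (default 20) of random pairing among
  `breeding_pairs` couples (default 50).  Meiosis is Haldane: Poisson
  crossover counts (mean = map length in Morgans), uniform positions, no
  interference — the process whose Markov structure the HMM assumes.
  Observed genotypes flip each allele read with probability ε.
* **Phenotypes.**  Components (QTL founder effects with optional
  diet-specific vectors, polygenic draw with covariance K, diet/sex main
  effects, noise) are standardized and scaled to stated variance fractions;
  binary traits threshold the latent at a stated prevalence.  Realized
  fractions are returned.
* **Variants.**  VCF-style founder records with gene assignment and
  consequence labels; a configurable fraction is alt-in-all-founders, and a
  causal missense variant with a chosen strain pattern can be planted.
* **OTU tables.**  Log-normal basis abundances with equicorrelated planted
  blocks, multinomial counts at fixed depth (default 20,000 reads — sample
  sums close exactly), optional logistic coupling of one block's factor to a
  binary trait.  Depths for the SparCC validation experiments: the planted
  pair sits at median abundance at 20,000 reads; the null table matches a
  typical survey's reads-per-taxon ratio (~68, i.e. depth 3,400 at 50 taxa),
  the regime whose count noise sets the scale of spurious correlations.

What the generator does **not** emulate: linkage disequilibrium between
founder alleles at nearby markers (markers are independent given founder
origin), litter structure and non-random mating, selection or mutation
during the cross, taxonomic structure or phylogenetic signal in OTU tables,
and read-level sequencing artifacts.  Passing tests therefore show the
algorithms behave correctly on data satisfying their assumptions, not that
the assumptions hold for any particular real dataset.

## Validation experiment sizes

The experiments in `ailgxe.experiments` (run by `tests/test_acceptance.py`
and `scripts/acceptance.py`) use: FWER — 200 traits × 200 permutations
(100 traits in the script) on an n = 500, 10 × 20-marker cohort; additive
power/coverage — 50 (40) replicates at dosage-R² = 0.2; hidden association —
50 (30) replicates at interaction-R² = 0.1, n = 600, balanced diets;
heritability recovery — 50 exact-model draws at h² = 0.4, n = 800; SparCC —
50 taxa × 200 samples; module recovery — blocks of 20 + 15 taxa, 200
samples; end-to-end funnel — 20 (15) full studies with a planted causal
missense variant private to one founder.  These sizes were chosen so each
experiment's sampling noise is small relative to the property being
asserted while a full run stays in the minutes range on one core.

## Known limitations

* The interaction LOD's gaussian likelihood is an approximation for
  residualized binary traits.
* PQL working residuals are a first-order approximation for binary traits;
  variance components on the working response can be biased for extreme
  prevalences.
* No multi-QTL modelling, epistasis, or LOCO kinship; one peak per
  chromosome per trait/model (a flagged splitter is out of scope).
* SparCC assumes sparse true correlation; tables where most taxa are
  correlated (or very few taxa) violate its basis-variance system, and
  closure effects can make "null" taxa genuinely correlated.
* The consequence vocabulary is a fixed six-label set; unknown labels fall
  to the middle tier with a warning rather than failing.
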