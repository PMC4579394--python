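# Methods

## Scope and data model

The package operates on phased haplotype panels: an ordered legend of
biallelic sites (1-based positions, REF/ALT strings, SNP/INDEL class)
plus a haplotype-major 0/1 allele matrix. The same container carries
reference panels, study haplotypes, and merged panels. Genomic
intervals (regions, chunks) are half-open `[start, end)` in bp; sites
are 1-based, following VCF. Genetic maps are piecewise-linear
bp→cumulative-cM functions; outside the mapped range the cM value is
clamped to the nearest endpoint (constant extrapolation, i.e. local
rate zero). Legends may contain duplicate positions transiently — that
is how split multi-allelic records reach the harmonization filters,
which then remove and count them.

## The copying HMM

Imputation follows the Li–Stephens haplotype-copying family. For one
pre-phased study haplotype conditioned on K reference haplotypes:

* **States** — the reference haplotype being copied at each typed site.
* **Transitions** — across a gap of d cM, stay with probability
  `exp(−ρ/K)` with `ρ = 4·Ne·d/100`; otherwise pick a template uniformly
  (including the current one). `Ne` defaults to 20,000, the value
  conventionally used for European-ancestry imputation.
* **Emissions** — the observed allele equals the copied allele with
  probability 1−ε, where ε = θ/(2(θ+K)) and θ is the Watterson estimator
  `1/Σ_{i<K} 1/i`. ε is recomputed from the *selected* K (the HMM in use
  has K states), not from the full panel size. It can be overridden.
* **Inference** — forward–backward with per-site normalization of both
  messages; the posterior is invariant to the scaling strategy to well
  below 1e−9. An exhaustive path-enumeration oracle in the test suite
  confirms agreement to ~1e−15 on small instances.

Untyped sites do not enter the chain. At an untyped site the state
posterior is interpolated linearly in cM between the two flanking typed
sites (clamped to the boundary row outside the typed range, and to the
left row across zero-cM gaps); P(ALT) is then the emission mixture
`ε + (1−2ε)·Σ_k γ_k a_k`. This is the cheapest scheme consistent with
imputing every reference site from typed-site posteriors; it is a
documented choice of this package, not a claim about what any particular
published implementation does. The mixture is applied uniformly — a
site where every conditioning haplotype carries ALT yields exactly 1−ε,
and sites monomorphic in the panel need no special casing because the
formula is well defined for constant columns.

Typed sites report the same mixture at their own posterior row, so a
typed genotype is *re-estimated*, not echoed: rare alleles the panel
does not carry are shrunk toward the panel consensus. Two haploid
posteriors a, b combine independently (pre-phasing is trusted):
p₂ = ab, p₀ = (1−a)(1−b), p₁ = 1−p₀−p₂, dosage = a+b. Best-guess
alleles threshold at 0.5 with ties resolved to REF.

## Reference selection

Three strategies choose the conditioning set per study haplotype, per
chunk, from the typed sites of the buffered interval; all are
deterministic (ties break toward the lower reference index, chosen
indices are returned ascending, so saturated selection is bit-identical
to using the whole panel):

* **all** — no approximation.
* **hamming** — the classical k_hap heuristic: the k references with the
  smallest region-wide Hamming distance to the study haplotype.
* **tracts** — local sharing: at `anchors` evenly spaced typed sites
  (default 16), references are ranked by the length, in typed sites, of
  the contiguous exact-match run covering the anchor, and the top
  ⌈k/anchors⌉ per anchor are pooled; an oversized pool is trimmed by the
  maximum tract length over anchors, an undersized one topped up with
  the best remaining Hamming candidates. Tract length is scored in site
  counts (a cM-weighted variant would need only a different score
  vector; site counts keep the operation integer and map-free).

The rationale for tracts: a rare allele is typically carried on a long
shared haplotype segment around it; a reference sharing that segment may
still be globally distant and thus invisible to region-wide Hamming
ranking. Run-length recurrences make scoring O(K·T) per haplotype.

## Panel merging

Two phased panels are merged in three steps. (1) **Harmonize**:
duplicate-position records (multi-allelic encodings) are dropped and
counted per panel; shared positions with REF/ALT exchanged are fixed by
flipping the second panel's codes (counted, not dropped); shared
positions whose allele pairs still differ are dropped from both panels;
sites private to one panel whose minor-allele count there is exactly 1
(cross-panel singletons) are dropped. For shared sites the combined
panels determine allele counts, so the singleton rule only ever fires
on private sites. (2) **Reciprocal imputation**: every haplotype of
each panel is treated as a pre-phased haploid study sequence typed at
the shared sites, the other panel's private sites are imputed from it
per buffered chunk (3 Mb cores, ±250 kb buffers by default; core-only
results kept), and thresholded to best-guess alleles. (3) **Stack**
over the position-sorted union legend. The code verifies on every run
that observed alleles are byte-identical after merging and that the
inclusion–exclusion identities of the report hold
(`n_union = n_a_only + n_b_only + n_shared = kept_a + kept_b − shared`).

## Quality metrics

* **true r²** — squared Pearson correlation between dosage (0–2) and
  held-out truth genotypes (0/1/2). Undefined (NaN) when either vector
  is constant; undefined sites are counted and reported but excluded
  from bin means — substituting zeros would bias means, but see the
  caveat under *Evaluation design* below.
* **info (expected r²)** — from genotype-probability uncertainty alone:
  `1 − Σ(f_i − e_i²) / (2N·θ̂(1−θ̂))` with e = p₁+2p₂, f = p₁+4p₂,
  θ̂ = Σe/2N; defined as 1 when θ̂ ∈ {0,1}; clamped to [0,1].
* **MAF bins** — default edges {0.1%, 0.5%, 1%, 2%, 5%, 50%}, half-open
  `(lo, hi]`, covering the rare (<0.5–1%) and low-frequency (1–5%)
  ranges usually quoted; info-count tables use edges {0.4, 0.8, 1.0}
  so both common confidence thresholds are available. Accuracy curves
  bin by truth MAF; count tables default to imputed MAF (θ̂-based),
  since in a real study cohort only the imputed frequency is available.

## The synthetic generator

Real reference panels of this kind are managed-access, so evaluations
run on synthetic scenarios. Founder haplotypes are drawn with per-site
derived-allele frequencies from a 1/f spectrum truncated to
[1/(2·n_founders), 0.5]; panel haplotypes are copying mosaics of the
founders (template switches with probability `1 − exp(−switch_rate·d)`
per gap, d in cM; per-site allele flips at `mut_rate`). This produces
the two features the methods actually exploit — block-wise haplotype
sharing and a rare-skewed frequency spectrum — without demography,
selection, gene conversion, or realistic mutation processes. Passing
tests therefore demonstrate method behaviour under well-specified LD
structure, not performance on real cohorts: real panels add phasing
error, allele-frequency mismatch between panel and study populations,
and sequencing artefacts that the generator deliberately omits.

The standard scenario (the `SimConfig` defaults) is a 5 Mb region at a
uniform 1 cM/Mb with 5,000 sites, 60 founders, a 400-haplotype primary
reference, a 200-haplotype secondary reference, and 100 study
haplotypes; 20% of sites form the pseudo-array, preferring MAF ≥ 5%
(array-like common-variant ascertainment), and 10% of segregating
sites are removed from each reference legend (disjointly) to create
panel-private sites. Typed sites are drawn from the sites present in
both reference legends — array content is ascertained common variation,
and every harness requires typed sites to exist in the imputing panel.
Each reference panel also receives ~2% planted singletons at
monomorphic positions so the cross-panel singleton filter has work to
do. The approximation strategies are compared at k = 40 of 400
(preserving the published k_hap-to-panel ratio's spirit at desk scale);
the CLI default k_hap is 10,000 clipped to the panel size. All
generators are pure functions of (config, seed).

## Evaluation design

* **Pseudo-GWAS** — mask the study panel to its typed sites, impute all
  reference sites, score info everywhere and true r² wherever truth
  exists. Selection and the HMM see the whole scenario region as a
  single chunk in the library harnesses (at 5 Mb the region *is*
  roughly one buffered chunk); the CLI imputation path runs the full
  3 Mb / ±250 kb chunked workflow.
* **Leave-one-out** — drop each diploid sample from the panel in turn,
  impute it back from its typed sites, score against itself; a seeded
  subsample of samples can be evaluated for speed.
* **Panel-size scaling** — panels of 50, 200 and 800 haplotypes are
  *nested* (subsets of one mosaic set), and means are taken over the
  sites with defined r² in every panel. This matters: a small panel is
  monomorphic at many rare sites, those sites yield constant dosages
  and undefined r² and drop out of its mean, so a naive per-panel mean
  is computed over each panel's easy sites and can *decrease* with
  panel size purely through this selection effect. Fixing the site
  support isolates the real quantity of interest — copying accuracy as
  panel depth grows.
* **Calibration** — the info-vs-true-r² comparison is likewise made
  over the sites where both are defined; constant-dosage sites have
  info near 0 and no r² at all, and mixing site sets reverses the sign
  of the comparison spuriously.

## Numerical and degenerate-input conventions

Forward–backward normalizes per site (posteriors are scale-invariant);
zero-cM gaps give an identity-dominated transition and collapse
interpolation weights to the left row; best-guess ties go to REF;
`true_r2` clamps at 1 against floating-point overshoot; info is clamped
to [0,1]; selection never consumes randomness. Chunk cores tile the
region exactly, the last core may be short, and buffers clip to the
region bounds.

## Known limitations

* Unphased-study (diploid-pair) imputation, genotype-likelihood input,
  and MCMC phasing are out of scope; study haplotypes must be
  pre-phased.
* The tract-sharing algorithm is this package's concrete instantiation
  of local-sharing selection (anchors / per-anchor quotas / union); it
  targets the qualitative accuracy ordering, not bit-equality with any
  published tool.
* Only SNP/INDEL biallelic sites are supported: no BCF, structural
  variants, genotype likelihoods, or chromosome-X ploidy handling.
* The merge iterates pairwise for three or more panels and does not
  re-phase merged haplotypes.
* Info scores from few samples are noisy; the default scenarios use
  50–100 study samples, well below typical cohort sizes.
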