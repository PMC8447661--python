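# Methods

## The problem and the model

Sika deer and red deer exchange genes freely on farms; hybrid
provenance is established by genotyping loci at which the two species
are fixed for alternative alleles. Over `L` such loci an individual's
red-deer content is summarised by the hybrid index
`h = r / (2k)`, where `r` counts red-specific alleles and `k <= L` the
called loci. Under progressive backcrossing to sika with unlinked loci,
`E[h]` halves each generation (1, 0.5, 0.25, 0.125, 0), and `h` of a
generation-`g` backcross concentrates around its expectation with
variance on the order of `E[h](1-E[h])/L` plus a pedigree term, which
is what makes a 1 000-locus panel sufficient to read the generation
directly off `h`.

Differentiation is scored per site with the Weir & Cockerham (1984)
two-population θ. With sample sizes `n_i`, allele frequencies `p_i` and
observed heterozygote frequencies `h_i`:

```
n̄ = (n1+n2)/2          n_c = (2n̄ − (n1²+n2²)/(2n̄))
p̄ = (n1p1+n2p2)/(2n̄)   s² = Σ n_i (p_i − p̄)² / n̄      h̄ = (n1h1+n2h2)/(2n̄)
a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²/2 − h̄/4) / (n̄−1) ]
b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²/2 − (2n̄−1)/(4n̄) h̄ ]
c = h̄/2                θ = a/(a+b+c)
```

θ is undefined (flagged, excluded from screening) when both populations
are monomorphic for the same allele, can be slightly negative by
estimator construction, and evaluates to exactly 1 at a fixed
difference for any `n1, n2 ≥ 2` — the algebra makes `b = c = 0`
identically, which is why the screening threshold (θ > 0.95) admits
every truly diagnostic site regardless of cohort size. Hudson's
estimator is available as an alternative; Weir–Cockerham is the default
because it is what the standard per-site VCF tooling computes.

## Screening pipeline

Filters are per-site predicates applied to the post-QC cohort:

1. defined θ strictly above 0.95;
2. allele pair must be a single-bead ("type II") pair — A/C, A/G, T/C,
   T/G; A/T and C/G pairs are strand-ambiguous on the array chemistry
   and are removed. (The protocol prose calls the removed pairs
   "conversion" sites; operationally the rule is exactly this pair
   exclusion.);
3. flanking interference: no other post-QC cohort variant within
   ±50 bp on the same contig (window inclusive, focal site excluded) —
   judged against the full surviving variant list, not against
   screening survivors, so the rule is order-independent;
4. tiering: "fixed" when the red-specific allele has frequency 1 in red
   and 0 in sika among called genotypes, requiring a per-population
   call rate ≥ 0.9 at the site (the fixation judgement is meaningless
   on a handful of calls); "high_fst" otherwise;
5. deterministic ranking: fixed tier first, then θ descending, then
   combined expected heterozygosity ascending, then (contig, pos);
   ranking ties cannot depend on input order, so permuting the input
   yields the identical panel;
6. truncation to the target size (default 1000). Fewer survivors than
   the target is a warning, not an error.

Probe contexts are 51-mer sense-strand windows with the variant
bracketed at position 26 (`25 left + [ref/alt] + 25 right`); sites
within 25 bp of a contig edge are rejected. Candidate submissions
export four times the target so vendor-side attrition still leaves a
full panel; externally supplied designability scores below 0.6 drop a
record (0.6 itself is kept, unscored records pass with a flag).

## The simulator

`simcross` generates the study conditions rather than a generic
coalescent:

- **Reference populations.** Default sizes 250 sika / 206 red
  (discovery design); the validation driver uses 125/39/56/29/17.
  Background loci: per-population frequencies drawn from the
  Balding–Nichols beta model `Beta(p(1−F)/F, (1−p)(1−F)/F)` around an
  ancestral `p ~ U(0.05, 0.95)` with divergence `F = 0.1` by default
  (a moderate between-species background so that background loci are
  genuinely non-diagnostic). The uniform support excludes the extreme
  5% tails to avoid ancestrally monomorphic sites whose θ is undefined.
  Diagnostic loci are fixed for alternative alleles; a
  `residual_polymorphism` knob lets the red allele segregate at
  `1−ρ`/`ρ` instead, for studying imperfect diagnosticity (the study's
  observed F1 mean of 0.48 rather than 0.50 suggests some; no published
  parameter pins ρ, so the default is 0).
- **Placement.** Sites are placed uniformly without replacement,
  ≥ 60 bp from contig edges (probe margins) and > 50 bp apart, except
  for deliberately clustered decoy pairs placed 10–49 bp apart to
  exercise the flanking filter; further decoy classes are
  strand-ambiguous diagnostic sites and the low-Fst background itself.
- **Crossing.** Genotypes are Hardy–Weinberg draws within populations;
  offspring draw one allele per locus from a uniformly chosen parent
  per pool, loci unlinked. The real genomes differ in chromosome
  number, and linkage would widen the spread of `h` within a
  generation; neither is modelled — a documented limitation, and the
  reason simulated within-generation SDs are lower bounds.
- **Chip noise.** Symmetric per-allele flip with probability `e`
  (genotype survives as `Bin(g, 1−e) + Bin(2−g, e)`) plus independent
  missingness `m`. The validation driver uses `e = 0.01`,
  `m = 0.013` (a mean detection rate of ~98.7%, the scale reported for
  the real array). The real chip-vs-sequencing disagreement also
  contains sequencing-side and clustering errors that this symmetric
  model does not separate, so simulated agreement (~98%) sits above
  the real aggregate (~93.5%) — the package measures agreement, it
  does not claim to predict it.
- **Seeding.** One master seed; every stage derives a named substream
  (`SeedSequence([master_seed, crc32(name)])`), so runs are
  byte-identical given the seed and stages are independently stable.

Truth metadata records the frequencies used per site, the diagnostic
flag and red allele, and each individual's realized red-allele fraction
recomputed from its own genotypes — the analysis is validated against
realized truth, not against expectations.

## Statistical conventions

- QC boundaries follow the protocol wording literally: sites are
  *removed* when missing rate > 0.1, depth < 5X or quality < 30
  (absent depth/quality annotations skip the check, as for chip
  matrices); samples are removed when missingness is strictly > 10%.
  Array QC keeps sites with MAF > 0.05 and call rate > 95% (strict);
  a zero threshold disables the corresponding filter.
- HWE is a 1-df chi-square goodness-of-fit at the observed allele
  frequency, no continuity correction; monomorphic sites return P = 1
  by convention. The exact test was not used because the protocol
  names only "HWE (P < 0.01)" and the chi-square is calibrated at the
  panel's sample sizes (type-I error ≈ 0.01 at n = 100, verified by
  simulation in the test suite).
- **Wahlund caveat.** A species-diagnostic site necessarily fails HWE
  in a cohort that mixes the two species and their hybrids — the
  combined-cohort HWE screen would reject an ideal panel wholesale.
  The QC function therefore reports the HWE count alongside the
  MAF/call-rate Venn counts, and the validation driver presents
  survivors both with and without the HWE term. On real data the HWE
  screen belongs within a single population.
- MAF scope is configurable; the default is all samples of the given
  matrix (the published panel MAF range, 0.33–0.36, is not reproducible
  from fixed sites over the combined reference cohort, which would give
  ≈ 0.455 — the original computation's sample scope is unknowable from
  the text, so no attempt is made to match it).
- PCA mean-imputes missing calls per site, centers per site, does not
  scale variance, and projects on the leading singular vectors;
  component signs are arbitrary.
- IBS distance is `mean |g_i − g_j| / 2` over co-called sites; it is a
  metric on complete data, and pairs with no co-called site are
  flagged rather than zeroed.
- Neighbor joining is the Saitou–Nei Q-criterion agglomeration with
  deterministic first-minimum tie-breaking in node order; negative
  branch lengths are clamped to zero with the deficit moved to the
  sister branch. Bootstrap support (site resampling) is available but
  off by default.
- The generation classifier maps `h` to the nearest expected value in
  {0, 0.125, 0.25, 0.5, 1}; boundaries are the midpoints and an exact
  boundary value goes to the lower-ancestry class. A deterministic rule
  replaces the original study's random-forest classifier: with a
  one-dimensional, well-separated index the learned classifier reduces
  to thresholds anyway, and the rule is auditable.

## Problem sizes

The shipped drivers and acceptance script run at desk scale, chosen so
each statistic is measured well inside its Monte-Carlo tolerance: 519
discovery animals over 3 900 sites (1 500 eligible diagnostic + 600
decoys + 2 000 background), 2 000-individual backcross cohorts over
1 000 loci for the Mendelian means (SE of the cohort mean ≈ 0.02
percentage points), and 266 validation animals. The originating study
screened ~130 M variants; the pipeline is linear in sites and samples,
and nothing in the implementation assumes the desk-scale counts.

## Known limitations

- No linkage, recombination map, selection or demography; sex
  chromosomes are not modelled.
- The noise model is symmetric per-allele error; real array error is
  cluster-driven and genotype-dependent.
- Designability scoring is proprietary upstream; the pipeline consumes
  an externally supplied score column and cannot generate one.
- Multiallelic records are dropped, not split: the diagnostic-panel
  procedure is defined for biallelic SNPs.
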