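# Methods

## Polarization and site handling

Genotypes are read from VCF with multiallelic records decomposed into one
biallelic record per ALT allele (the shared `locus_id` preserves the joint
record for multi-allele F_ST). Derived-allele orientation is inferred from
a single outgroup individual genotyped at the same sites: homozygous
reference marks ALT as derived, homozygous for the record's ALT marks REF
as derived, and heterozygous or missing outgroup calls — as well as
homozygosity for a *different* ALT — leave the site unpolarized.
Unpolarized sites are excluded from every derived-allele statistic; this
trades a little data for unbiased polarity, since assigning a direction to
an ambiguous outgroup call would systematically misorient sites toward the
outgroup's error mode.

Load statistics use a complete-case rule per breed pair: a site
contributes only where both breeds reach the `min_called` threshold, which
defaults to all `2n` alleles (the same completeness rule the site
frequency spectra use). Sites fixed derived in the whole panel are kept;
they contribute to a pair's sums only through the partner breed's deficit.

Two published conventions exist for the conservation bins; both are
selectable and `methods` (moderate = `2 ≤ pp < 5`, high = `pp ≥ 5`) is the
default. Loss-of-function status is assigned from a fixed ten-category
SNPeff list. Heterozygosity is the *observed* heterozygote fraction (not
the Hardy–Weinberg expectation) because breed panels are inbred.

Coordinates: VCF in/out is 1-based, BED 0-based half-open, and all
internal interval arithmetic is 0-based half-open.

## The R statistic

The frequency-weighted form `L_{A∉B} = Σ f_A (1 − f_B)` is used because it
is the expectation of the one-chromosome-per-breed sampling scheme that
defines "derived in A, not observed in B" without an arbitrary detection
threshold; a strict presence/absence mode (`mode="presence"`) is available
for sensitivity analysis. `R²` uses observed homozygous-derived individual
fractions rather than `f²` because inbred panels violate Hardy–Weinberg —
the statistic is meant to contrast realized homozygous burdens.

Inference is a weighted delete-one block jackknife: contributing sites are
split, in genomic order, into `n_blocks = 50` contiguous blocks of
approximately equal *site counts* (not equal physical length — equal
information per block matters more than equal base pairs, and the spacing
of informative sites varies along the genome). With block sizes `m_j`,
`n = Σ m_j`, `h_j = n/m_j`, full-data estimate `θ` and leave-one-out
estimates `θ_(−j)`:

```
θ_J  = g θ − Σ_j (1 − m_j/n) θ_(−j)
τ_j  = h_j θ − (h_j − 1) θ_(−j)
var  = (1/g) Σ_j (τ_j − θ_J)² / (h_j − 1)
```

`Z = (R − 1)/SE` is referred to the standard normal, two-sided. The
Bonferroni family defaults to the number of breed pairs within one site
class (28 for eight breeds) and is exposed as a parameter. Masked
re-estimation drops sites inside the mask and re-partitions blocks over
the survivors so the configured block count is preserved.

Degenerate cases: `R(A, A)` is exactly 1 with SE 0 (every per-site term
cancels identically); a zero denominator sum raises rather than returning
infinity; a constant statistic across leave-one-out replicates yields
SE = 0 and a p-value of 1 at `R = 1`.

## Differentiation

`F_ST` is the Weir–Cockerham (1984) θ from allele counts, heterozygote
counts and sample sizes, with the a/b/c variance components summed over
alleles before forming the ratio. Negative per-site estimates are retained
in averages (truncation would bias the mean upward); sites where both
breeds are fixed for the same allele are undefined and excluded from the
focal breed's pairwise mean. `V_ST` uses population variances (ddof = 0)
so that identical within-breed distributions give exactly 0.

Stage-1 candidates require the derived allele at frequency ≥ 0.7 in the
focal breed *and* strictly the highest derived frequency among breeds (the
differentiation threshold alone would also admit sites where the focal
breed is the ancestral outlier), average pairwise `F_ST ≥ 0.7`, and
PhyloP ≥ 2 (either alignment). Both frequency rules are parameters. Gene
proximity is measured from the variant position to the nearest point of
the gene span, half-open arithmetic, with a 5,000 bp flank. Selection-
window merging selects the `⌈top_frac·N⌉` highest-CLR windows with ties at
the threshold all included, concatenates adjacent windows and merges runs
separated by ≤ 100 kb.

## Association models

Binary outcomes are fitted by OLS (linear probability model), not
logistic regression, to match standard `lm()` practice in the veterinary
literature this pipeline serves; coefficients are therefore on the risk
scale. Genotypes are coded additively as derived-allele counts so effect
signs align with risk-allele framing. Missing genotypes are handled
complete-case per model. The interaction models expand `genotype*age` and
`genotype*age*sex` factorially. Rank-deficient designs (e.g. a marker with
a single carrier, which makes `genotype` and `genotype:age` exactly
collinear) raise an error; the pipeline skips such markers with a warning.

The two-locus EM starts at linkage equilibrium — with only the
double-heterozygote cell phase-ambiguous the likelihood is well behaved
and the deterministic start keeps results reproducible — and stops when no
haplotype frequency moves by more than 1e-8 (hard limit 1,000 iterations).
`D′` and `r²` are invariant to allele-label swaps; averages over a marker
set are means over unordered pairs.

Incidence is first-claim counts per 10,000 dog-years at risk; per-dog
exposure accrues from max(insurance start, window start) to the first
claim, withdrawal or window end. Dogs insured entirely outside the window
contribute nothing; a genuinely inverted insurance interval is an input
error and raises.

## Synthetic data generator

The generator is a frequency-level Wright–Fisher simulation, not a
coalescent with recombination: every statistic in scope is per-site except
jackknife blocking, which only needs the emitted genome layout, so
per-site frequency trajectories are sufficient and keep full runs in
seconds. What it emulates: standing ancestral variation with a neutral
`1/x` frequency spectrum (discretized on a 200-point grid), independent
per-breed drift through configurable bottleneck epochs with deterministic
purifying selection (`Δp = −(s/2)p(1−p)` additive, `−s p²(1−p)`
recessive), binomial sampling of 20 diploids per breed, an outgroup
carrying the true ancestral allele (misassigned with probability ε,
default 0), and annotations whose PhyloP scores reproduce the class
labels. What it does not emulate: linkage between sites, genotyping error,
shared drift between related breeds, and realistic gene structure —
passing tests therefore demonstrate the statistics' behaviour under their
own model assumptions, not robustness to those real-data complications.

Default demography is two bottlenecks — Ne 1,000 for 100 generations
(domestication-scale contraction) then Ne 200 for 60 generations (breed
formation, roughly two centuries at a ~3-year generation time). The
heavily bottlenecked variant shrinks the second epoch to Ne 20 (10-fold).
Under these conditions the relaxed-selection scenario (`s = 0.01` at
highly conserved sites) produces a ~10% derived-allele excess in the
bottlenecked breed — the magnitude such a breed contrast should show —
while neutral classes stay at `R = 1` within the jackknife CI. Default
selection coefficients per class: synonymous 0, nonsynonymous 0.002, LoF
0.005, moderately conserved 0.002, highly conserved 0.01.

The cohort generator draws examination ages uniformly on 4.8–15.9 years
(n = 122 by default), affection from
`logistic(α + β_g·g + β_a·age + β_ga·g·age + β_s·sex)` with `α = −5.2`,
`β_a = 0.55` (≈50% affected by ~9.5 years — a late-onset profile), and
assigns severity grades among the affected by ordered empirical quantile
thresholds on the linear predictor, with proportions 0.696/0.228/0.076 so
the B1/B2/C mix matches a screened dachshund cohort (55/18/6 of 79
affected). Because the outcome is generated on the logistic scale and
fitted by OLS, planted coefficients are recovered in attenuated form; the
parameter-recovery tests compare against the generator's own large-sample
OLS value. Copy-number variants are normal around breed means (σ = 0.3)
with planted 2-copy shifts, clipped at zero.

Determinism: one integer-seeded `numpy` generator per entry point; equal
configs give byte-identical output files.

## Problem sizes

The bundled test-suite and acceptance runs use 5×10⁴ sites for neutral
calibration, 2.5×10⁴ sites per class for the selection-recovery scenario,
20 replicates for jackknife coverage, 50 replicates for interaction
recovery and 200 for null p-value calibration — sizes chosen so the whole
suite completes in well under a minute of simulation time while keeping
Monte-Carlo noise far below the tested effect sizes.

## Known limitations

- Free recombination between all sites; LD-based analyses (the two-locus
  EM aside) cannot be validated against the generator.
- The outgroup is a single pseudo-haploid individual; lineage sorting and
  outgroup polymorphism are not modelled beyond the flat error rate ε.
- OLS on binary outcomes yields heteroskedastic residuals; p-values are
  the conventional homoskedastic ones, matching the `lm()` practice being
  mirrored rather than a robust-variance refinement.
- `V_ST` assumes copy numbers are measured without breed-correlated bias.
- The pipeline's candidate stage treats decomposed multiallelic records
  independently; joint multi-allele F_ST is available through the counts
  API but not wired into the per-site scan table.
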