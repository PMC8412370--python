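# breedload

Population-genetic toolkit for quantifying **between-breed mutational load**
from multi-breed resequencing panels, prioritizing **high-frequency derived
candidate disease variants**, and testing candidate markers for
**case-control association with a late-onset disease** (myxomatous mitral
valve disease, MMVD, in dogs). A seed-reproducible synthetic-data generator
stands in for a full 160-genome study, so every stage is testable offline.

Intended users: researchers in canine (or other managed-population)
genomics who want the derived-allele load machinery, the multi-stage
variant-prioritization filters, and the MMVD association models as a
tested, composable library rather than a collection of one-off scripts.

## The statistics at the core

**Derived-allele load ratio.** For breeds *A* and *B*, with per-site derived
allele frequencies `f_A`, `f_B` (polarized against an outgroup), the
sharing sums are

```
L_{A∉B} = Σ_sites f_A (1 − f_B)        L_{B∉A} = Σ_sites f_B (1 − f_A)
R_{A/B} = L_{A∉B} / L_{B∉A}
```

Each term is the probability that one chromosome drawn from *A* is derived
while one drawn from *B* is ancestral, so `R = 1` when mutations have
accumulated at equal rates since the breeds split; `R > 1` means excess
derived load in *A*. The recessive-load variant `R²_{A/B}` replaces
frequencies with observed homozygous-derived individual fractions.
Standard errors come from a **weighted delete-one block jackknife** over 50
contiguous genomic blocks; significance is a two-sided normal test of
`Z = (R − 1)/SE`, with Bonferroni correction across breed pairs.

**Differentiation and prioritization.** Per-site Weir–Cockerham `F_ST`
(variance components summed over alleles for multi-allelic sites; negative
estimates retained), averaged over a focal breed's pairs; `V_ST =
(V_T − V_S)/V_T` for copy-number variants. Candidates are high-frequency
derived alleles (`avg pairwise F_ST ≥ 0.7`, derived frequency ≥ 0.7) at
conserved sites (PhyloP ≥ 2), refined by proximity (±5 kb) to curated
heart-function or downregulated gene lists, or by explicit region scans.
Selection-sweep post-processing merges the top 5% of composite likelihood
ratio windows into non-overlapping regions.

**Association.** All models are OLS (`lm`-style linear probability models
for binary status): univariate `status ~ genotype/age/sex`, factorial
`graded_status ~ genotype*age(*sex)` for late-onset interaction effects,
young-case/old-control subsampling, two-locus EM for `|D′|`/`r²` from
unphased genotypes, and across-breed regression of MMVD incidence (claims
per 10,000 dog-years at risk) on breed allele frequency.

## Worked example

Simulate a heavily bottlenecked breed (second bottleneck Ne = 20 for 60
generations versus Ne = 200 in the control) with purifying selection
`s = 0.01` against derived alleles at highly conserved sites, then compare
load per site class:

```python
from breedload import simulate
from breedload.load_stats import r_ab

cfg = simulate.SimulationConfig(
    seed=102,
    n_sites={"synonymous": 25_000, "high": 25_000},
    demography={
        "breed_a": simulate.TIGHT_BOTTLENECK_EPOCHS,
        "breed_b": simulate.DEFAULT_EPOCHS,
    },
)
study = simulate.simulate_breed_panels(cfg)
masks = study.class_masks()
for cls in ("synonymous", "high"):
    comp = r_ab(study.dataset, "breed_a", "breed_b", masks[cls], n_blocks=50)
    lo, hi = comp.ci95
    print(f"{cls:>11}  R = {comp.value:.3f}  95% CI [{lo:.3f}, {hi:.3f}]  "
          f"Z = {comp.z:+.2f}  p = {comp.p:.2e}  n = {comp.n_sites}")
```

prints

```
 synonymous  R = 1.029  95% CI [0.985, 1.073]  Z = +1.29  p = 1.98e-01  n = 25000
       high  R = 1.104  95% CI [1.062, 1.147]  Z = +4.83  p = 1.40e-06  n = 25000
```

The synonymous (neutral) class shows no significant deviation from `R = 1`,
while the bottlenecked breed carries ~10% more derived alleles at highly
conserved sites — the signature of relaxed purifying selection during a
breed bottleneck.

The same pipeline runs from the shell:

```sh
breedload simulate --out study/ --seed 102
breedload load-stats --vcf study/genotypes.vcf --outgroup study/outgroup.vcf \
    --breeds study/breed_map.tsv --annot study/annotations.tsv \
    --classes syn,nonsyn,lof,moderate,high --blocks 50 --out load.tsv
breedload assoc --cohort study/cohort.tsv --marker NEBL_3 --model "graded~genotype*age"
```

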