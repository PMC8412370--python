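"""Seed-reproducible synthetic inputs with the structure the analyses assume.

The generator emulates a multi-breed resequencing study: a shared ancestral
population contributes standing variation (derived-allele frequencies drawn
from a discretized neutral 1/x spectrum), each breed then drifts through its
own bottleneck history as a frequency-level Wright-Fisher process with
deterministic selection against derived alleles, and 20 diploids per breed
are sampled from the final frequencies.  An outgroup individual carries the
true ancestral allele (optionally mis-assigned with a configurable error
rate), so the polarization machinery is exercised end to end.  Site classes
(synonymous, nonsynonymous, loss-of-function, moderately and highly
conserved) differ only in their selection coefficients and in the PhyloP
scores written to the annotation table, which lets every downstream module
recover the planted structure.

Cohort simulation draws a late-onset disease: affection probability is
logistic in genotype, age, genotype x age and sex, and ACVIM-style grades
are assigned among the affected by ordered empirical thresholds on the
linear predictor.

A coalescent with recombination is deliberately not simulated: every
statistic in scope is per-site except jackknife blocking, which only needs
the emitted genome layout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_model
from .io_model import BreedPanel, PolarizedDataset, polarize

DEFAULT_CLASS_SITES = {
    "synonymous": 8_000,
    "nonsynonymous": 4_000,
    "lof": 1_000,
    "moderate": 4_000,
    "high": 4_000,
}

#: additive selection coefficients per site class (against the derived allele)
DEFAULT_SELECTION = {
    "synonymous": 0.0,
    "nonsynonymous": 0.002,
    "lof": 0.005,
    "moderate": 0.002,
    "high": 0.01,
}

CLASS_EFFECT = {
    "synonymous": "SYNONYMOUS_CODING",
    "nonsynonymous": "NON_SYNONYMOUS_CODING",
    "lof": "STOP_GAINED",
    "moderate": "INTERGENIC",
    "high": "INTERGENIC",
}

#: PhyloP (100-vertebrate) score ranges emitted per class
CLASS_PHYLOP = {
    "synonymous": (-1.0, 1.9),
    "nonsynonymous": (-1.0, 1.9),
    "lof": (-1.0, 1.9),
    "moderate": (2.0, 4.99),
    "high": (5.0, 9.5),
}

#: two-bottleneck default demography: a domestication-scale contraction
#: followed by a narrower breed-formation bottleneck (~60 generations at a
#: few hundred effective individuals); a heavily bottlenecked breed is
#: modelled by shrinking the second epoch's Ne (e.g. 10-fold)
DEFAULT_EPOCHS: tuple[tuple[int, int], ...] = ((1_000, 100), (200, 60))
TIGHT_BOTTLENECK_EPOCHS: tuple[tuple[int, int], ...] = ((1_000, 100), (20, 60))

DEFAULT_MARKER_FREQS = {
    "NEBL_1": 0.35,
    "NEBL_2": 0.45,
    "NEBL_3": 0.30,
    "NEBL_4": 0.40,
    "NEBL_5": 0.50,
    "NEBL_6": 0.25,
    "SORBS2": 0.0,
    "LPHN2": 0.03,
    "HDGFL1": 0.13,
    "HTR1F": 0.03,
}


@dataclass
class CohortConfig:
    """Late-onset disease cohort parameters (defaults mirror a dachshund
    screening cohort: n = 122, examination ages ~5-16 years, roughly 2/3
    affected with grade proportions ~70/23/8 among cases)."""

    n: int = 122
    age_range: tuple[float, float] = (4.8, 15.9)
    marker_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_FREQS)
    )
    baseline: float = -5.2  # logistic intercept alpha
    beta_genotype: float = 0.0
    beta_age: float = 0.55
    beta_interaction: float = 0.0  # genotype x age
    beta_sex: float = 0.0
    effect_marker: str = "NEBL_3"  # marker carrying the planted effect
    grade_proportions: tuple[float, float, float] = (0.696, 0.228, 0.076)


@dataclass
class CnvConfig:
    n_variants: int = 50
    n_shifted: int = 10  # variants with a planted between-breed shift
    baseline_copies: float = 2.0
    shift: float = 2.0
    sigma: float = 0.3


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic study. ``seed`` is mandatory."""

    seed: int
    breed_names: Sequence[str] = ("breed_a", "breed_b")
    samples_per_breed: int = 20
    n_sites: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SITES))
    selection: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SELECTION))
    dominance: str = "additive"  # or "recessive"
    demography: Mapping[str, Sequence[tuple[int, int]]] | None = None
    polarization_error: float = 0.0
    n_chromosomes: int = 5
    site_spacing: int = 1_000
    freq_grid: int = 200
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.dominance not in ("additive", "recessive"):
            raise ValueError(f"unknown dominance mode {self.dominance!r}")
        if not 0 <= self.polarization_error <= 1:
            raise ValueError("polarization_error must be a probability")
        for cls, n in self.n_sites.items():
            if n < 0:
                raise ValueError(f"negative site count for class {cls!r}")
        for breed, epochs in (self.demography or {}).items():
            for ne, gens in epochs:
                if ne < 2:
                    raise ValueError(f"Ne must be >= 2 (breed {breed!r})")

    def epochs_for(self, breed: str) -> Sequence[tuple[int, int]]:
        if self.demography and breed in self.demography:
            return self.demography[breed]
        return DEFAULT_EPOCHS

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "cnv" in raw:
            raw["cnv"] = CnvConfig(**raw["cnv"])
        if "demography" in raw and raw["demography"] is not None:
            raw["demography"] = {
                b: [tuple(e) for e in eps] for b, eps in raw["demography"].items()
            }
        if "breed_names" in raw:
            raw["breed_names"] = tuple(raw["breed_names"])
        return cls(**raw)


@dataclass
class SimulatedStudy:
    dataset: PolarizedDataset
    truth: pd.DataFrame  # per-site class label and true per-breed derived freqs
    outgroup: np.ndarray  # (n_sites, 2) outgroup allele indices
    config: SimulationConfig
    cohort: pd.DataFrame | None = None
    cnv: tuple[np.ndarray, list[str]] | None = None  # (matrix, breed labels)

    def class_masks(self) -> dict[str, np.ndarray]:
        return {
            cls: (self.truth["site_class"] == cls).to_numpy()
            for cls in pd.unique(self.truth["site_class"])
        }


# ---------------------------------------------------------------------------
# breed panels


def _ancestral_frequencies(rng: np.random.Generator, n: int, grid: int) -> np.ndarray:
    """Derived frequencies from a discretized neutral 1/x spectrum."""
    i = np.arange(1, grid)
    p = (1.0 / i) / (1.0 / i).sum()
    return rng.choice(i, size=n, p=p) / grid


def _selection_update(p: np.ndarray, s: np.ndarray, dominance: str) -> np.ndarray:
    """One generation of deterministic selection against the derived allele."""
    if dominance == "additive":
        dp = -(s / 2) * p * (1 - p)
    else:  # recessive
        dp = -s * p * p * (1 - p)
    return np.clip(p + dp, 0.0, 1.0)


def simulate_breed_panels(config: SimulationConfig) -> SimulatedStudy:
    """Simulate polarized breed panels plus truth, annotation and outgroup.

    Byte-identical outputs for identical configs (single integer-seeded
    generator; no platform-dependent state).
    """
    rng = np.random.default_rng(config.seed)
    classes = [c for c, n in config.n_sites.items() if n > 0]
    site_class = np.concatenate(
        [np.repeat(c, config.n_sites[c]) for c in classes]
    ).astype(object)
    n = len(site_class)
    if n == 0:
        raise ValueError("no sites configured")
    # interleave classes along the genome so jackknife blocks mix classes
    order = rng.permutation(n)
    site_class = site_class[order]
    s = np.array([config.selection.get(c, 0.0) for c in site_class])

    p0 = _ancestral_frequencies(rng, n, config.freq_grid)
    freqs: dict[str, np.ndarray] = {}
    panels: dict[str, BreedPanel] = {}
    for breed in config.breed_names:
        p = p0.copy()
        for ne, gens in config.epochs_for(breed):
            for _ in range(gens):
                p = _selection_update(p, s, config.dominance)
                p = rng.binomial(2 * ne, p) / (2 * ne)
        freqs[breed] = p
        derived_counts = rng.binomial(2, p[:, None], size=(n, config.samples_per_breed))
        panels[breed] = (breed, derived_counts)

    # genome layout: sites spread over chromosomes in genomic order
    per_chrom = int(np.ceil(n / config.n_chromosomes))
    chrom_idx = np.arange(n) // per_chrom
    chroms = np.array([f"chr{i + 1}" for i in chrom_idx], dtype=object)
    pos = (np.arange(n) % per_chrom) * config.site_spacing + 1

    # REF/ALT orientation: derived allele is ALT for ~half the sites
    derived_is_alt = rng.random(n) < 0.5
    ref = np.where(derived_is_alt, "A", "G").astype(object)
    alt = np.where(derived_is_alt, "G", "A").astype(object)

    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "vtype": "SNV",
            "locus_id": np.arange(n),
            "alt_index": 1,
            "n_alts": 1,
        }
    )

    breed_panels: dict[str, BreedPanel] = {}
    for breed, (name, derived_counts) in panels.items():
        alt_counts = np.where(derived_is_alt[:, None], derived_counts, 2 - derived_counts)
        sample_ids = [f"{name}_{i + 1:02d}" for i in range(config.samples_per_breed)]
        breed_panels[breed] = BreedPanel(name, sample_ids, alt_counts.astype(np.int16))

    # outgroup carries the ancestral allele, flipped with probability epsilon
    anc_is_ref = derived_is_alt  # ancestral allele index: 0 where derived=ALT
    og_allele = np.where(anc_is_ref, 0, 1)
    if config.polarization_error > 0:
        flip = rng.random(n) < config.polarization_error
        og_allele = np.where(flip, 1 - og_allele, og_allele)
    outgroup = np.column_stack([og_allele, og_allele]).astype(np.int16)

    pp_low = np.array([CLASS_PHYLOP[c][0] for c in site_class])
    pp_high = np.array([CLASS_PHYLOP[c][1] for c in site_class])
    phylop = pp_low + rng.random(n) * (pp_high - pp_low)
    annotations = pd.DataFrame(
        {
            "effect_category": [CLASS_EFFECT[c] for c in site_class],
            "phylop100": np.round(phylop, 3),
            "phylop46": np.round(phylop, 3),
            "phastcon_hit": False,
        }
    )

    dataset = PolarizedDataset(sites=sites, panels=breed_panels, annotations=annotations)
    dataset = polarize(dataset, outgroup)
    truth = pd.DataFrame({"site_class": site_class})
    for breed in config.breed_names:
        truth[f"true_freq_{breed}"] = freqs[breed]
    return SimulatedStudy(
        dataset=dataset, truth=truth, outgroup=outgroup, config=config
    )


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimulationConfig | CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate a case-control cohort in the standard phenotype-table schema.

    Affection is Bernoulli with P = logistic(alpha + b_g*g + b_a*age +
    b_ga*g*age + b_s*sex); the planted genotype effect attaches to
    ``effect_marker``.  Grades among the affected follow ordered empirical
    thresholds on the linear predictor.
    """
    if isinstance(config, SimulationConfig):
        cc = config.cohort
        seed = config.seed if seed is None else seed
    else:
        cc = config
        if seed is None:
            raise ValueError("seed required when passing a CohortConfig directly")
    rng = np.random.default_rng(seed)
    n = cc.n
    if n == 0:
        return pd.DataFrame(
            columns=COHORT_SCHEMA_COLUMNS + list(cc.marker_freqs)
        )
    age = rng.uniform(cc.age_range[0], cc.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n)
    genos = {
        m: rng.binomial(2, f, size=n).astype(float) for m, f in cc.marker_freqs.items()
    }
    g_eff = genos.get(cc.effect_marker, np.zeros(n))
    eta = (
        cc.baseline
        + cc.beta_genotype * g_eff
        + cc.beta_age * age
        + cc.beta_interaction * g_eff * age
        + cc.beta_sex * sex
    )
    p_aff = 1.0 / (1.0 + np.exp(-eta))
    status = rng.random(n) < p_aff
    graded = np.zeros(n, dtype=int)
    if status.any():
        eta_aff = eta[status]
        q1, q2 = np.quantile(
            eta_aff,
            [cc.grade_proportions[0], cc.grade_proportions[0] + cc.grade_proportions[1]],
        )
        g = np.ones(status.sum(), dtype=int)
        g[eta_aff > q1] = 2
        g[eta_aff > q2] = 3
        graded[status] = g
    df = pd.DataFrame(
        {
            "Id": [f"dog_{i + 1:03d}" for i in range(n)],
            "breed": "dachshund",
            "nationality": "Swedish",
            "sex": sex,
            "MMVD_status": status.astype(int),
            "graded_MMVD_status": graded,
            "age": np.round(age, 2),
        }
    )
    for m, g in genos.items():
        df[m] = g
    return df


COHORT_SCHEMA_COLUMNS = [
    "Id",
    "breed",
    "nationality",
    "sex",
    "MMVD_status",
    "graded_MMVD_status",
    "age",
]


# ---------------------------------------------------------------------------
# copy number


def simulate_cnv(
    config: SimulationConfig | CnvConfig,
    breed_names: Sequence[str] | None = None,
    samples_per_breed: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Copy-number matrix (variants x individuals) with planted breed shifts.

    The first ``n_shifted`` variants shift the first breed's mean copy
    number by ``shift`` copies; the rest share the baseline.  Values are
    normal around the breed mean (sigma) and clipped at zero.
    """
    if isinstance(config, SimulationConfig):
        cv = config.cnv
        breed_names = list(config.breed_names)
        samples_per_breed = config.samples_per_breed
        seed = config.seed if seed is None else seed
    else:
        cv = config
        if breed_names is None or samples_per_breed is None or seed is None:
            raise ValueError("breed_names, samples_per_breed and seed are required")
    rng = np.random.default_rng(seed)
    labels = [b for b in breed_names for _ in range(samples_per_breed)]
    n_ind = len(labels)
    means = np.full((cv.n_variants, n_ind), cv.baseline_copies)
    focal = np.array([lab == breed_names[0] for lab in labels])
    means[: cv.n_shifted, focal] += cv.shift
    cn = rng.normal(means, cv.sigma)
    return np.clip(cn, 0.0, None), labels


# ---------------------------------------------------------------------------
# file emission


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Emit VCF, outgroup VCF, breed map, annotation, truth (and cohort/CNV
    when present) as plain-text files; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ds = study.dataset
    paths = {}

    all_samples: list[str] = []
    mats = []
    breed_rows = []
    for breed, panel in ds.panels.items():
        all_samples.extend(panel.sample_ids)
        mats.append(panel.genotypes)
        breed_rows.extend((s, breed) for s in panel.sample_ids)
    geno = np.hstack(mats)
    paths["vcf"] = os.path.join(outdir, "genotypes.vcf")
    io_model.write_vcf(paths["vcf"], ds.sites, geno, all_samples)

    og_counts = np.where(study.outgroup[:, 0] == 0, 0, 2).reshape(-1, 1)
    paths["outgroup_vcf"] = os.path.join(outdir, "outgroup.vcf")
    io_model.write_vcf(paths["outgroup_vcf"], ds.sites, og_counts, ["outgroup"])

    paths["breed_map"] = os.path.join(outdir, "breed_map.tsv")
    pd.DataFrame(breed_rows, columns=["sample_id", "breed"]).to_csv(
        paths["breed_map"], sep="\t", index=False
    )

    ann = pd.concat(
        [ds.sites[["chrom", "pos", "ref", "alt"]].reset_index(drop=True), ds.annotations],
        axis=1,
    )
    paths["annotations"] = os.path.join(outdir, "annotations.tsv")
    ann.to_csv(paths["annotations"], sep="\t", index=False)

    truth = pd.concat(
        [ds.sites[["chrom", "pos"]].reset_index(drop=True), study.truth], axis=1
    )
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    truth.to_csv(paths["truth"], sep="\t", index=False)

    if study.cohort is not None:
        paths["cohort"] = os.path.join(outdir, "cohort.tsv")
        study.cohort.to_csv(paths["cohort"], sep="\t", index=False)
    if study.cnv is not None:
        cn, labels = study.cnv
        cnv_df = pd.DataFrame(cn, columns=[f"{b}_{i}" for i, b in enumerate(labels)])
        paths["cnv"] = os.path.join(outdir, "cnv.tsv")
        cnv_df.to_csv(paths["cnv"], sep="\t", index=False)
    return paths


def study_conditions(config: SimulationConfig) -> dict:
    """Echo of the generator parameterization for report headers."""
    return dataclasses.asdict(config)
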