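"""Genotype input, outgroup polarization, annotation and frequency summaries.

Genotypes are stored per breed as matrices of ALT-allele counts with one row
per (site, ALT allele) record: multiallelic VCF records are decomposed into
one biallelic record per ALT allele so that every downstream frequency or
load computation works on a simple 0/1/2 coding.  The original VCF record is
remembered through a shared ``locus_id`` so that joint multi-allele
differentiation can regroup the decomposed rows.

Polarity is resolved against an outgroup individual genotyped at the same
sites: a homozygous-reference outgroup marks the ALT allele as derived, a
homozygous-ALT outgroup marks the REF allele as derived, and heterozygous or
missing outgroup calls leave the site unpolarized (such sites are excluded
from all derived-allele statistics).

Coordinates follow the conventions of the file formats: VCF positions are
1-based, BED intervals 0-based half-open; internal interval arithmetic is
0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING = -1

#: polarity codes stored per decomposed site record
DERIVED_ALT = 1
DERIVED_REF = -1
UNPOLARIZED = 0

#: SNPeff effect categories treated as loss of function
LOF_CATEGORIES = frozenset(
    {
        "CODON_CHANGE_PLUS_CODON_DELETION",
        "CODON_CHANGE_PLUS_CODON_INSERTION",
        "CODON_DELETION",
        "CODON_INSERTION",
        "EXON_DELETED",
        "FRAME_SHIFT",
        "SPLICE_SITE_ACCEPTOR",
        "SPLICE_SITE_DONOR",
        "START_LOST",
        "STOP_GAINED",
    }
)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "locus_id", "alt_index", "n_alts"]


@dataclass(frozen=True)
class VariantSite:
    """One variant position as read from a VCF record (pre-decomposition)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_alleles: tuple[str, ...]
    vtype: str  # "SNV" or "INDEL"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("REF and ALT alleles must differ")


@dataclass
class BreedPanel:
    """Genotypes for one breed: ALT-allele counts, ``MISSING`` for no-calls."""

    breed: str
    sample_ids: list[str]
    genotypes: np.ndarray  # (n_sites, n_samples) int16

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.sample_ids):
            raise ValueError("genotype matrix must have one column per sample")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class SfsVector:
    """Unfolded site frequency spectrum over derived-allele counts 0..2n."""

    counts: np.ndarray
    n_chromosomes: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.n_chromosomes + 1:
            raise ValueError("SFS length must be 2n + 1")
        if (self.counts < 0).any():
            raise ValueError("SFS entries must be non-negative")

    @property
    def segregating(self) -> np.ndarray:
        """Entries for derived counts 1..2n-1 (the polymorphic classes)."""
        return self.counts[1:-1]


@dataclass(frozen=True)
class ConcordanceReport:
    power: float
    accuracy: float
    fdr: float


@dataclass
class PolarizedDataset:
    """Decomposed site table plus per-breed genotype panels.

    ``sites`` carries one row per (VCF record, ALT allele) with columns
    ``chrom, pos, ref, alt, vtype, locus_id, alt_index, n_alts``.
    ``polarity`` is per-row: +1 derived=ALT, -1 derived=REF, 0 unpolarized
    (also the initial state before :func:`polarize` runs).
    """

    sites: pd.DataFrame
    panels: dict[str, BreedPanel]
    polarity: np.ndarray = field(default=None)  # type: ignore[assignment]
    annotations: pd.DataFrame | None = None
    outgroup: np.ndarray | None = None  # (n_rows, 2) outgroup allele indices

    def __post_init__(self) -> None:
        if self.polarity is None:
            self.polarity = np.zeros(len(self.sites), dtype=np.int8)
        self.polarity = np.asarray(self.polarity, dtype=np.int8)
        n = len(self.sites)
        if len(self.polarity) != n:
            raise ValueError("polarity must match the site table")
        for panel in self.panels.values():
            if panel.genotypes.shape[0] != n:
                raise ValueError(f"panel {panel.breed!r} does not cover the site list")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def breeds(self) -> list[str]:
        return list(self.panels)

    def panel(self, breed: str) -> BreedPanel:
        try:
            return self.panels[breed]
        except KeyError:
            raise KeyError(f"unknown breed {breed!r}; have {sorted(self.panels)}") from None

    def variant_sites(self) -> Iterable[VariantSite]:
        """Yield joint (pre-decomposition) :class:`VariantSite` records."""
        for _, group in self.sites.groupby("locus_id", sort=True):
            first = group.iloc[0]
            yield VariantSite(
                chrom=str(first.chrom),
                pos=int(first.pos),
                ref_allele=str(first.ref),
                alt_alleles=tuple(group.sort_values("alt_index")["alt"]),
                vtype=str(first.vtype),
            )

    def subset_rows(self, mask: np.ndarray) -> "PolarizedDataset":
        """Row-filtered copy (sites, polarity, panels, annotations)."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        panels = {
            b: BreedPanel(b, p.sample_ids, p.genotypes[idx]) for b, p in self.panels.items()
        }
        return PolarizedDataset(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            panels=panels,
            polarity=self.polarity[idx],
            annotations=None
            if self.annotations is None
            else self.annotations.iloc[idx].reset_index(drop=True),
            outgroup=None if self.outgroup is None else self.outgroup[idx],
        )


# ---------------------------------------------------------------------------
# input


def read_breed_map(source) -> dict[str, str]:
    """Read a two-column TSV (sample_id, breed) into a mapping."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    cols = list(df.columns)
    if "sample_id" in cols and "breed" in cols:
        pairs = df[["sample_id", "breed"]].itertuples(index=False)
    elif len(cols) >= 2:
        pairs = df.iloc[:, :2].itertuples(index=False)
    else:
        raise ValueError("breed map needs columns (sample_id, breed)")
    return {s: b for s, b in pairs}


def _vtype(ref: str, alts: Iterable[str]) -> str:
    return "SNV" if len(ref) == 1 and all(len(a) == 1 for a in alts) else "INDEL"


def read_genotypes(vcf_source: str, breed_map: Mapping[str, str] | str) -> PolarizedDataset:
    """Read a VCF into a :class:`PolarizedDataset` with polarity unset.

    Multiallelic records are decomposed into one row per ALT allele; the
    genotype code for a row is the number of copies of that row's ALT allele,
    with any partially missing call treated as missing.
    """
    from cyvcf2 import VCF

    if isinstance(breed_map, str):
        breed_map = read_breed_map(breed_map)
    vcf = VCF(str(vcf_source))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in breed_map]
    if unknown:
        raise ValueError(f"samples absent from breed map: {', '.join(unknown)}")

    by_breed: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_breed.setdefault(breed_map[s], []).append(i)

    rows: list[tuple] = []
    geno_rows: list[np.ndarray] = []
    for locus_id, rec in enumerate(vcf):
        alts = list(rec.ALT)
        if not alts:
            continue
        gts = np.array([g[:2] for g in rec.genotypes], dtype=np.int16)
        missing = (gts < 0).any(axis=1)
        vtype = _vtype(rec.REF, alts)
        for alt_index, alt in enumerate(alts, start=1):
            counts = (gts == alt_index).sum(axis=1).astype(np.int16)
            counts[missing] = MISSING
            rows.append(
                (rec.CHROM, rec.POS, rec.REF, alt, vtype, locus_id, alt_index, len(alts))
            )
            geno_rows.append(counts)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    geno = (
        np.array(geno_rows, dtype=np.int16)
        if geno_rows
        else np.empty((0, len(samples)), dtype=np.int16)
    )
    panels = {
        breed: BreedPanel(breed, [samples[i] for i in cols], geno[:, cols])
        for breed, cols in by_breed.items()
    }
    return PolarizedDataset(sites=sites, panels=panels)


def read_outgroup(vcf_source: str) -> dict[tuple[str, int], tuple[int, int]]:
    """Read the first sample of an outgroup VCF as (chrom, pos) -> allele pair."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source))
    out: dict[tuple[str, int], tuple[int, int]] = {}
    for rec in vcf:
        a = rec.genotypes[0]
        out[(rec.CHROM, rec.POS)] = (int(a[0]), int(a[1]))
    return out


# ---------------------------------------------------------------------------
# polarization and summaries


def polarize(
    dataset: PolarizedDataset,
    outgroup_genotypes: Mapping[tuple[str, int], tuple[int, int]] | np.ndarray,
) -> PolarizedDataset:
    """Assign derived-allele orientation from an outgroup individual.

    The outgroup may be given as a mapping (chrom, pos) -> allele-index pair
    (as from :func:`read_outgroup`) or as an (n_rows, 2) array aligned with
    the decomposed site table.  Homozygous-reference marks ALT derived;
    homozygous for the row's ALT marks REF derived; anything else (het,
    missing, homozygous for another ALT) leaves the row unpolarized.
    Idempotent: re-polarizing with the same outgroup changes nothing.
    """
    n = dataset.n_sites
    if isinstance(outgroup_genotypes, np.ndarray):
        og = np.asarray(outgroup_genotypes, dtype=np.int16)
        if og.shape != (n, 2):
            raise ValueError("outgroup array must be (n_rows, 2)")
    else:
        og = np.full((n, 2), MISSING, dtype=np.int16)
        keys = list(zip(dataset.sites["chrom"], dataset.sites["pos"]))
        for i, key in enumerate(keys):
            got = outgroup_genotypes.get((str(key[0]), int(key[1])))
            if got is not None:
                og[i] = got

    alt_index = dataset.sites["alt_index"].to_numpy()
    polarity = np.zeros(n, dtype=np.int8)
    hom = og[:, 0] == og[:, 1]
    polarity[hom & (og[:, 0] == 0)] = DERIVED_ALT
    polarity[hom & (og[:, 0] == alt_index)] = DERIVED_REF
    return replace(dataset, polarity=polarity, outgroup=og)


def derived_genotypes(dataset: PolarizedDataset, breed: str) -> np.ndarray:
    """Per-individual derived-allele counts (MISSING preserved, unpolarized rows MISSING)."""
    g = dataset.panel(breed).genotypes
    pol = dataset.polarity[:, None]
    out = np.where(pol == DERIVED_ALT, g, np.where(pol == DERIVED_REF, 2 - g, MISSING))
    out = np.where(g == MISSING, MISSING, out)
    return out.astype(np.int16)


def derived_frequencies(
    dataset: PolarizedDataset, breed: str, min_called: int | None = None
) -> pd.DataFrame:
    """Per-site derived-allele frequency and homozygous-derived fraction.

    ``min_called`` is the minimum number of called *alleles* for a site to be
    usable; the default requires every individual in the panel to be called,
    mirroring the complete-data rule used for the site frequency spectra.
    """
    panel = dataset.panel(breed)
    if min_called is None:
        min_called = 2 * panel.n_samples
    der = derived_genotypes(dataset, breed)
    called = der != MISSING
    n_called = 2 * called.sum(axis=1)
    n_ind = called.sum(axis=1)
    dcount = np.where(called, der, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, dcount / np.maximum(n_called, 1), np.nan)
        homf = np.where(
            n_ind > 0, np.where(called, der == 2, False).sum(axis=1) / np.maximum(n_ind, 1), np.nan
        )
    usable = (n_called >= min_called) & (dataset.polarity != UNPOLARIZED)
    return pd.DataFrame(
        {
            "derived_freq": np.where(dataset.polarity != UNPOLARIZED, freq, np.nan),
            "n_called": n_called,
            "hom_derived_fraction": np.where(
                dataset.polarity != UNPOLARIZED, homf, np.nan
            ),
            "usable": usable,
        }
    )


def classify_sites(annotations: pd.DataFrame, convention: str = "methods") -> pd.DataFrame:
    """Boolean site-class table from an annotation frame.

    ``annotations`` needs ``effect_category`` plus ``phylop100``; classes are
    ``synonymous``, ``nonsynonymous``, ``lof`` (fixed 10-category SNPeff
    list) and the conservation bins ``moderate`` / ``high``.  Two published
    bin conventions exist for the conservation cutoffs; both are selectable:

    - ``methods``: moderate = 2 <= pp < 5, high = pp >= 5
    - ``results``: moderate = 2 < pp <= 5, high = pp > 5
    """
    if convention not in ("methods", "results"):
        raise ValueError(f"unknown convention {convention!r}; use 'methods' or 'results'")
    cat = annotations["effect_category"].astype(str)
    pp = pd.to_numeric(annotations["phylop100"], errors="coerce")
    if convention == "methods":
        moderate = (pp >= 2) & (pp < 5)
        high = pp >= 5
    else:
        moderate = (pp > 2) & (pp <= 5)
        high = pp > 5
    return pd.DataFrame(
        {
            "synonymous": cat.str.upper().str.contains("SYNONYMOUS_CODING")
            & ~cat.str.upper().str.contains("NON_SYNONYMOUS"),
            "nonsynonymous": cat.str.upper().str.contains("NON_SYNONYMOUS"),
            "lof": cat.str.upper().isin(LOF_CATEGORIES),
            "moderate": moderate.fillna(False),
            "high": high.fillna(False),
        }
    )


def heterozygosity(dataset: PolarizedDataset, breed: str) -> float:
    """Observed heterozygote fraction averaged over biallelic segregating sites.

    Segregation is judged in the entire dataset (all panels pooled); only
    biallelic records enter.  The observed (not HWE-expected) fraction is
    used because breed panels are inbred.
    """
    biallelic = (dataset.sites["n_alts"] == 1).to_numpy()
    all_g = np.hstack([p.genotypes for p in dataset.panels.values()])
    called = all_g != MISSING
    alt_present = (np.where(called, all_g, 0) > 0).any(axis=1)
    ref_present = ((all_g == 0) | (all_g == 1)).any(axis=1)
    seg = biallelic & alt_present & ref_present
    g = dataset.panel(breed).genotypes[seg]
    called = g != MISSING
    n_called = called.sum(axis=1)
    ok = n_called > 0
    if not ok.any():
        raise ValueError("no usable segregating biallelic sites")
    het_frac = (g == 1).sum(axis=1)[ok] / n_called[ok]
    return float(het_frac.mean())


def compute_sfs(
    dataset: PolarizedDataset, breed: str, require_complete: bool = True
) -> SfsVector:
    """Unfolded site frequency spectrum of derived-allele counts for one breed."""
    panel = dataset.panel(breed)
    n_chrom = 2 * panel.n_samples
    der = derived_genotypes(dataset, breed)
    called = der != MISSING
    polarized = dataset.polarity != UNPOLARIZED
    if require_complete:
        keep = polarized & called.all(axis=1)
    else:
        keep = polarized & called.any(axis=1)
    dcount = np.where(called, der, 0).sum(axis=1)[keep]
    counts = np.bincount(dcount, minlength=n_chrom + 1)
    return SfsVector(counts=counts, n_chromosomes=n_chrom)


def _variable(calls: pd.DataFrame) -> pd.Series:
    """Rows where both alleles are observed among called genotypes."""
    g = calls.to_numpy()
    called = g != MISSING
    alt = (np.where(called, g, 0) > 0).any(axis=1)
    ref = ((g == 0) | (g == 1)).any(axis=1)
    return pd.Series(alt & ref, index=calls.index)


def concordance_metrics(wgs_calls: pd.DataFrame, array_calls: pd.DataFrame) -> ConcordanceReport:
    """Power, genotype accuracy and FDR of WGS calls against array truth.

    Both frames are genotype codes (0/1/2, MISSING) indexed by site with one
    column per sample.  Power is the fraction of array-variable sites that
    are variable in WGS; accuracy the fraction of identical overlapping
    genotype calls; FDR the fraction of array-interrogated sites that are
    variable in WGS but not on the array.
    """
    shared_sites = wgs_calls.index.intersection(array_calls.index)
    shared_samples = wgs_calls.columns.intersection(array_calls.columns)
    if len(shared_sites) == 0 or len(shared_samples) == 0:
        raise ValueError("no overlapping sites/samples between call sets")

    array_var = _variable(array_calls)
    wgs_var = _variable(wgs_calls)
    var_sites = array_var[array_var].index
    detected = var_sites.intersection(wgs_var[wgs_var].index)
    power = len(detected) / len(var_sites) if len(var_sites) else float("nan")

    w = wgs_calls.loc[shared_sites, shared_samples].to_numpy()
    a = array_calls.loc[shared_sites, shared_samples].to_numpy()
    both = (w != MISSING) & (a != MISSING)
    accuracy = float((w[both] == a[both]).mean()) if both.any() else float("nan")

    interrogated = array_calls.index
    wgs_only = wgs_var.reindex(interrogated, fill_value=False) & ~array_var
    fdr = float(wgs_only.sum() / len(interrogated))
    return ConcordanceReport(power=float(power), accuracy=accuracy, fdr=fdr)


# ---------------------------------------------------------------------------
# annotation I/O and VCF emission


ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "effect_category",
    "phylop100",
    "phylop46",
    "phastcon_hit",
]


def read_annotations(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {', '.join(missing)}")
    return df


def attach_annotations(dataset: PolarizedDataset, annotations: pd.DataFrame) -> PolarizedDataset:
    """Left-join annotations onto the decomposed site table by chrom/pos/ref/alt."""
    key = ["chrom", "pos", "ref", "alt"]
    sites = dataset.sites[key].copy()
    sites["chrom"] = sites["chrom"].astype(str)
    ann = annotations.copy()
    ann["chrom"] = ann["chrom"].astype(str)
    merged = sites.merge(ann, on=key, how="left", validate="many_to_one")
    merged["phastcon_hit"] = merged["phastcon_hit"].fillna(False).astype(bool)
    return replace(dataset, annotations=merged.drop(columns=key))


def write_vcf(
    path: str,
    sites: pd.DataFrame,
    genotype_matrix: np.ndarray,
    sample_ids: list[str],
) -> None:
    """Emit a minimal plain-text VCF of biallelic records.

    ``genotype_matrix`` holds ALT-allele counts (MISSING for no-call), one
    row per site row in ``sites`` (columns ``chrom, pos, ref, alt``).
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        chroms = sites["chrom"].to_numpy()
        poss = sites["pos"].to_numpy()
        refs = sites["ref"].to_numpy()
        alts = sites["alt"].to_numpy()
        for i in range(len(sites)):
            gts = "\t".join(gt_str[int(g)] for g in genotype_matrix[i])
            fh.write(f"{chroms[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def validate_dataset(dataset: PolarizedDataset) -> list[str]:
    """Return human-readable warnings for suspicious dataset states."""
    issues = []
    if (dataset.polarity == UNPOLARIZED).all():
        issues.append("dataset is entirely unpolarized; run polarize() first")
    n_panel_sizes = {b: p.n_samples for b, p in dataset.panels.items()}
    if len(set(n_panel_sizes.values())) > 1:
        issues.append(f"unequal panel sizes: {n_panel_sizes}")
    for msg in issues:
        warnings.warn(msg, stacklevel=2)
    return issues
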