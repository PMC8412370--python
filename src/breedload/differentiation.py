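"""Per-site differentiation and multi-stage candidate-variant prioritization.

F_ST between breed pairs uses the Weir & Cockerham (1984) theta estimator
computed from allele counts and heterozygote counts; for multi-allelic sites
the a/b/c variance components are summed over alleles before forming the
ratio, and negative estimates are retained (not truncated) so that averages
over pairs stay unbiased.  Differentiation of one breed against the rest of
the panel is the mean of its pairwise estimates ("average pairwise F_ST").

Copy-number variants use V_ST = (V_T - V_S) / V_T, where V_T is the pooled
copy-number variance of the two breeds and V_S the size-weighted mean of the
within-breed variances (population variances, ddof=0).

Candidate prioritization proceeds in stages: high-frequency derived alleles
at differentiated, conserved sites (stage 1), then proximity to curated gene
lists in a coding or regulatory mode, or membership in an explicit genomic
region.  Each surviving candidate accumulates a provenance trail of the
rules it passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_model import MISSING, PolarizedDataset, derived_frequencies

GENE_FLANK = 5_000  # bp up/downstream counted as "near" a gene


class AlleleCounts(NamedTuple):
    """Per-population summary for one site.

    allele_counts: observed count of each allele among called chromosomes
    het_counts: number of heterozygous individuals carrying each allele
    n: number of called diploid individuals
    """

    allele_counts: np.ndarray
    het_counts: np.ndarray
    n: int


def allele_counts_from_genotypes(genotype_pairs: np.ndarray, n_alleles: int) -> AlleleCounts:
    """Summarize an (n_individuals, 2) allele-index matrix; MISSING rows dropped."""
    g = np.asarray(genotype_pairs)
    called = (g >= 0).all(axis=1)
    g = g[called]
    ac = np.bincount(g.ravel(), minlength=n_alleles)
    het = g[:, 0] != g[:, 1]
    het_counts = np.zeros(n_alleles, dtype=int)
    for k in range(n_alleles):
        het_counts[k] = int(((g == k).any(axis=1) & het).sum())
    return AlleleCounts(ac.astype(float), het_counts.astype(float), int(called.sum()))


def wc_fst(counts_a: AlleleCounts, counts_b: AlleleCounts) -> float:
    """Weir & Cockerham (1984) two-population theta for one site.

    Variance components are summed over alleles; returns NaN when both
    populations are monomorphic for the same allele (the estimator is
    undefined there).  Negative estimates are returned as-is.
    """
    n_i = np.array([counts_a.n, counts_b.n], dtype=float)
    if (n_i < 1).any():
        return float("nan")
    r = 2.0
    n_alleles = len(counts_a.allele_counts)
    p_ik = np.vstack(
        [
            counts_a.allele_counts / (2 * counts_a.n),
            counts_b.allele_counts / (2 * counts_b.n),
        ]
    )
    h_ik = np.vstack(
        [counts_a.het_counts / counts_a.n, counts_b.het_counts / counts_b.n]
    )
    # both populations fixed for the same allele -> estimator undefined
    if np.array_equal(p_ik[0], p_ik[1]) and np.all((p_ik[0] == 0) | (p_ik[0] == 1)):
        return float("nan")

    nbar = n_i.mean()
    if nbar <= 1:
        return float("nan")
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    num = 0.0
    den = 0.0
    for k in range(n_alleles):
        pbar = float((n_i * p_ik[:, k]).sum() / (r * nbar))
        s2 = float((n_i * (p_ik[:, k] - pbar) ** 2).sum() / ((r - 1) * nbar))
        hbar = float((n_i * h_ik[:, k]).sum() / (r * nbar))
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    if den == 0:
        return float("nan")
    return float(num / den)


def _counts_for_breed(dataset: PolarizedDataset, breed: str, row: int) -> AlleleCounts:
    """Biallelic per-row counts (0/1/2 coding) as an :class:`AlleleCounts`."""
    g = dataset.panel(breed).genotypes[row]
    called = g != MISSING
    g = g[called]
    alt = int(g.sum())
    n = int(called.sum())
    het = float((g == 1).sum())
    return AlleleCounts(
        np.array([2 * n - alt, alt], dtype=float),
        np.array([het, het], dtype=float),
        n,
    )


def pairwise_fst_table(
    dataset: PolarizedDataset, breeds: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-site Weir-Cockerham F_ST for every breed pair.

    Decomposed rows are treated as biallelic (that ALT vs everything else);
    returns a frame with one column per pair label ``"A|B"``.
    """
    import itertools

    breeds = list(breeds) if breeds is not None else dataset.breeds
    n = dataset.n_sites
    out = {}
    for a, b in itertools.combinations(breeds, 2):
        vals = np.empty(n)
        for i in range(n):
            vals[i] = wc_fst(_counts_for_breed(dataset, a, i), _counts_for_breed(dataset, b, i))
        out[f"{a}|{b}"] = vals
    return pd.DataFrame(out)


def avg_pairwise_fst(pairwise: pd.DataFrame, focal_breed: str) -> pd.Series:
    """Mean of the focal breed's pairwise F_ST values (defined pairs only)."""
    cols = [c for c in pairwise.columns if focal_breed in c.split("|")]
    if not cols:
        raise ValueError(f"no pairwise columns involve breed {focal_breed!r}")
    return pairwise[cols].mean(axis=1, skipna=True)


def vst(
    copy_numbers: np.ndarray,
    breed_labels: Sequence[str] | np.ndarray,
    pair: tuple[str, str],
) -> float:
    """V_ST for one copy-number variant and one breed pair.

    V_ST = (V_T - V_S)/V_T with population variances (ddof=0); V_S weights
    the within-breed variances by sample size.  NaN when V_T = 0.
    """
    cn = np.asarray(copy_numbers, dtype=float)
    labels = np.asarray(breed_labels)
    a, b = pair
    xa = cn[labels == a]
    xb = cn[labels == b]
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 individuals per breed for V_ST")
    pooled = np.concatenate([xa, xb])
    v_t = float(pooled.var(ddof=0))
    if v_t == 0:
        return float("nan")
    v_s = (len(xa) * xa.var(ddof=0) + len(xb) * xb.var(ddof=0)) / (len(xa) + len(xb))
    return float((v_t - v_s) / v_t)


def avg_pairwise_vst(
    copy_numbers: np.ndarray, breed_labels: Sequence[str], focal_breed: str
) -> float:
    """Mean V_ST of the focal breed against every other breed, one variant."""
    others = [b for b in dict.fromkeys(breed_labels) if b != focal_breed]
    vals = [vst(copy_numbers, breed_labels, (focal_breed, b)) for b in others]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# candidate prioritization


@dataclass
class CandidateVariant:
    """One prioritized site with its filter provenance."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    focal_breed: str
    derived_freqs: dict[str, float]
    avg_pairwise_fst: float
    phylop100: float
    phylop46: float
    effect_category: str = ""
    gene_context: tuple[str, int] | None = None  # (gene, distance in bp)
    filter_provenance: list[str] = field(default_factory=list)


def stage1_candidates(
    dataset: PolarizedDataset,
    pairwise: pd.DataFrame,
    focal_breed: str,
    fst_min: float = 0.7,
    freq_min: float = 0.7,
    phylop_min: float = 2.0,
    require_top_freq: bool = True,
) -> list[CandidateVariant]:
    """High-frequency derived, differentiated, conserved sites in one breed.

    Keeps sites where the derived allele reaches frequency >= ``freq_min``
    in the focal breed (and, by default, is strictly the highest derived
    frequency among breeds), average pairwise F_ST >= ``fst_min``, and
    PhyloP (100-vertebrate or 46-mammal) >= ``phylop_min``.  Idempotent:
    running the filter on its own output changes nothing.
    """
    if dataset.annotations is None:
        raise ValueError("dataset has no annotations; attach them first")
    freq = {b: derived_frequencies(dataset, b) for b in dataset.breeds}
    focal = freq[focal_breed]
    afst = avg_pairwise_fst(pairwise, focal_breed)
    pp100 = pd.to_numeric(dataset.annotations["phylop100"], errors="coerce")
    pp46 = pd.to_numeric(dataset.annotations["phylop46"], errors="coerce")
    conserved = (pp100 >= phylop_min) | (pp46 >= phylop_min)

    keep = (
        focal["usable"]
        & (focal["derived_freq"] >= freq_min)
        & (afst >= fst_min)
        & conserved.fillna(False)
    )
    if require_top_freq:
        others = [b for b in dataset.breeds if b != focal_breed]
        if others:
            other_max = pd.concat(
                [freq[b]["derived_freq"] for b in others], axis=1
            ).max(axis=1)
            keep &= focal["derived_freq"] > other_max

    out: list[CandidateVariant] = []
    sites = dataset.sites
    for i in np.flatnonzero(keep.to_numpy()):
        out.append(
            CandidateVariant(
                chrom=str(sites["chrom"].iat[i]),
                pos=int(sites["pos"].iat[i]),
                ref=str(sites["ref"].iat[i]),
                alt=str(sites["alt"].iat[i]),
                focal_breed=focal_breed,
                derived_freqs={
                    b: float(freq[b]["derived_freq"].iat[i]) for b in dataset.breeds
                },
                avg_pairwise_fst=float(afst.iat[i]),
                phylop100=float(pp100.iat[i]) if np.isfinite(pp100.iat[i]) else float("nan"),
                phylop46=float(pp46.iat[i]) if np.isfinite(pp46.iat[i]) else float("nan"),
                effect_category=str(dataset.annotations["effect_category"].iat[i]),
                filter_provenance=["stage1"],
            )
        )
    return out


def _gene_distance(pos: int, start0: int, end0: int) -> int:
    """Distance from a 1-based position to a 0-based half-open gene span."""
    p0 = pos - 1
    if start0 <= p0 < end0:
        return 0
    return start0 - p0 if p0 < start0 else p0 - end0 + 1


def read_gene_bed(source) -> pd.DataFrame:
    bed = pd.read_csv(source, sep="\t", header=None, comment="#", dtype={0: str})
    bed = bed.iloc[:, :4]
    bed.columns = ["chrom", "start", "end", "gene"]
    return bed


def prioritize_by_gene(
    candidates: Iterable[CandidateVariant],
    gene_intervals: pd.DataFrame,
    gene_list: Sequence[str],
    mode: str,
    flank: int = GENE_FLANK,
) -> list[CandidateVariant]:
    """Keep candidates near listed genes, under a coding or regulatory rule.

    ``mode='coding'`` requires PhyloP_100vertebrates > 5 and proximity
    (within ``flank`` bp of the gene span) to a curated heart-function gene;
    ``mode='regulatory'`` requires PhyloP_100vertebrates or
    PhyloP_46mammals >= 2 and proximity to a downregulated gene.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    if mode not in ("coding", "regulatory"):
        raise ValueError(f"unknown mode {mode!r}")
    listed = gene_intervals[gene_intervals["gene"].isin(genes)]
    out: list[CandidateVariant] = []
    for cand in candidates:
        if mode == "coding":
            if not (np.isfinite(cand.phylop100) and cand.phylop100 > 5):
                continue
        else:
            ok100 = np.isfinite(cand.phylop100) and cand.phylop100 >= 2
            ok46 = np.isfinite(cand.phylop46) and cand.phylop46 >= 2
            if not (ok100 or ok46):
                continue
        near = listed[listed["chrom"].astype(str) == cand.chrom]
        best: tuple[str, int] | None = None
        for row in near.itertuples(index=False):
            d = _gene_distance(cand.pos, int(row.start), int(row.end))
            if d <= flank and (best is None or d < best[1]):
                best = (str(row.gene), d)
        if best is None:
            continue
        cand.gene_context = best
        cand.filter_provenance = list(cand.filter_provenance) + [
            f"{mode}:{best[0]}"
        ]
        out.append(cand)
    return out


from .io_model import LOF_CATEGORIES  # noqa: E402

CODING_EFFECTS = {"SYNONYMOUS_CODING", "NON_SYNONYMOUS_CODING"} | set(LOF_CATEGORIES)


def region_scan(
    candidates: Iterable[CandidateVariant],
    interval: tuple[str, int, int],
) -> list[CandidateVariant]:
    """Conserved non-coding candidates inside a 1-based half-open interval.

    Used to widen the search around a gene of interest (e.g. a 1-Mb window
    centred on a candidate locus).  The end coordinate is exclusive.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValueError("malformed interval")
    out = []
    for cand in candidates:
        if cand.chrom != str(chrom) or not (start <= cand.pos < end):
            continue
        if cand.effect_category.upper() in CODING_EFFECTS:
            continue
        ok100 = np.isfinite(cand.phylop100) and cand.phylop100 >= 2
        ok46 = np.isfinite(cand.phylop46) and cand.phylop46 >= 2
        if not (ok100 or ok46):
            continue
        cand.filter_provenance = list(cand.filter_provenance) + [
            f"region:{chrom}:{start}-{end}"
        ]
        out.append(cand)
    return out


def candidates_to_frame(candidates: Iterable[CandidateVariant]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "focal_breed": c.focal_breed,
            "effect_category": c.effect_category,
            "phylop100": c.phylop100,
            "phylop46": c.phylop46,
            "avg_pairwise_fst": c.avg_pairwise_fst,
            "gene": c.gene_context[0] if c.gene_context else "",
            "gene_distance": c.gene_context[1] if c.gene_context else np.nan,
            "provenance": ";".join(c.filter_provenance),
        }
        for b, f in c.derived_freqs.items():
            row[f"ref_freq_{b}"] = 1 - f  # reference-allele frequency per breed
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# selection-window merging


@dataclass(frozen=True)
class SelectionWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    max_clr: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")


def merge_selection_windows(
    window_scores: pd.DataFrame,
    top_frac: float = 0.05,
    window_size: int = 10_000,
    join_dist: int = 100_000,
) -> list[SelectionWindow]:
    """Top-scoring tiled windows merged into candidate selection regions.

    Selects the ceil(top_frac * N) highest composite-likelihood-ratio
    windows (ties at the threshold all included), concatenates adjacent
    selected windows, then merges concatenated runs separated by at most
    ``join_dist`` bp.  Output is sorted, non-overlapping and idempotent
    under re-merging.
    """
    if window_scores.empty:
        raise ValueError("empty window score table")
    df = window_scores.copy()
    if "end" not in df.columns:
        df["end"] = df["start"] + window_size
    k = int(np.ceil(top_frac * len(df)))
    threshold = np.sort(df["clr"].to_numpy())[::-1][k - 1]
    sel = df[df["clr"] >= threshold].sort_values(["chrom", "start"])

    out: list[SelectionWindow] = []
    for chrom, grp in sel.groupby("chrom", sort=True):
        cur_s = cur_e = None
        cur_max = -np.inf
        for row in grp.itertuples(index=False):
            s, e, clr = int(row.start), int(row.end), float(row.clr)
            if cur_s is None:
                cur_s, cur_e, cur_max = s, e, clr
            elif s - cur_e <= join_dist:
                cur_e = max(cur_e, e)
                cur_max = max(cur_max, clr)
            else:
                out.append(SelectionWindow(str(chrom), cur_s, cur_e, cur_max))
                cur_s, cur_e, cur_max = s, e, clr
        if cur_s is not None:
            out.append(SelectionWindow(str(chrom), cur_s, cur_e, cur_max))
    return out


def windows_to_mask(windows: Iterable[SelectionWindow]):
    from .load_stats import MaskSet

    return MaskSet([(w.chrom, w.start, w.end) for w in windows])
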