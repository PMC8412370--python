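"""Derived-allele load comparison between breed pairs.

The central statistic contrasts how many derived (new) mutations one breed
carries that a second breed lacks.  For a set of polarized sites with
derived-allele frequencies ``f_A`` and ``f_B`` the sharing sums are

    L_{A notin B} = sum_sites f_A * (1 - f_B)
    L_{B notin A} = sum_sites f_B * (1 - f_A)

and ``R_A/B = L_{A notin B} / L_{B notin A}``.  Each per-site term is the
probability that one chromosome drawn from A carries the derived allele
while one chromosome drawn from B carries the ancestral allele, so R is the
ratio of expected private derived-mutation counts under one-allele-per-breed
sampling.  Under equal accumulation rates since the breeds split, R = 1.

The recessive-load variant R^2 replaces allele frequencies with the observed
fraction of individuals homozygous for the derived allele, contrasting the
probabilities that one breed is homozygous derived while the other is not.
Observed rather than Hardy-Weinberg-expected homozygote fractions are used
because breed panels are inbred.

Standard errors come from a weighted delete-one block jackknife over
contiguous genomic blocks (50 by default), with significance assessed as a
two-sided normal test of Z = (R - 1) / SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io_model import PolarizedDataset, derived_frequencies, derived_genotypes

DEFAULT_N_BLOCKS = 50


@dataclass
class JackknifeResult:
    """Weighted delete-one jackknife summary for one statistic."""

    point: float
    leave_one_out: np.ndarray
    block_weights: np.ndarray  # number of sites removed per block
    se: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.point - 1.959964 * self.se, self.point + 1.959964 * self.se)


@dataclass
class LoadComparison:
    """R or R^2 for one breed pair and site class, with jackknife inference."""

    breed_a: str
    breed_b: str
    site_class: str
    statistic_kind: str  # "R" or "R2"
    L_a_not_b: float
    L_b_not_a: float
    value: float
    se: float
    z: float
    p: float
    n_sites: int
    p_bonf: float | None = None
    jackknife: JackknifeResult | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.value - 1.959964 * self.se, self.value + 1.959964 * self.se)


@dataclass
class MaskSet:
    """Normalized genomic intervals, 0-based half-open."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        norm: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            norm.setdefault(str(chrom), []).append((int(start), int(end)))
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted(norm):
            ivs = sorted(norm[chrom])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        self.intervals = merged

    def contains(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Membership of 0-based positions in the mask."""
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0)
        hit = np.zeros(len(pos0), dtype=bool)
        for c, s, e in self.intervals:
            hit |= (chrom == c) & (pos0 >= s) & (pos0 < e)
        return hit

    @classmethod
    def from_bed(cls, source) -> "MaskSet":
        import pandas as pd

        bed = pd.read_csv(source, sep="\t", header=None, comment="#", dtype={0: str})
        return cls([(r[0], int(r[1]), int(r[2])) for r in bed.itertuples(index=False)])


# ---------------------------------------------------------------------------
# sharing sums


def sharing_sums(
    freqs_a: np.ndarray,
    freqs_b: np.ndarray,
    site_subset: np.ndarray | None = None,
    mode: str = "frequency",
) -> tuple[float, float, int]:
    """Derived-allele sharing sums (L_{A notin B}, L_{B notin A}, n_sites).

    ``mode='frequency'`` (default) uses the frequency-weighted terms
    f_A (1 - f_B); ``mode='presence'`` replaces each frequency with a 0/1
    presence indicator for sensitivity analysis.
    """
    fa = np.asarray(freqs_a, dtype=float)
    fb = np.asarray(freqs_b, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError("frequency vectors must align")
    if site_subset is not None:
        fa = fa[site_subset]
        fb = fb[site_subset]
    if fa.size == 0:
        raise ValueError("empty site subset")
    if mode == "presence":
        fa = (fa > 0).astype(float)
        fb = (fb > 0).astype(float)
    elif mode != "frequency":
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.sum(fa * (1 - fb))), float(np.sum(fb * (1 - fa))), int(fa.size)


# ---------------------------------------------------------------------------
# weighted block jackknife


def partition_blocks(n_sites: int, n_blocks: int) -> list[np.ndarray]:
    """Split ``n_sites`` genomically ordered sites into contiguous,
    approximately equal-count blocks."""
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_sites < n_blocks:
        raise ValueError(f"fewer usable sites ({n_sites}) than blocks ({n_blocks})")
    return list(np.array_split(np.arange(n_sites), n_blocks))


def weighted_block_jackknife(
    n_sites: int,
    statistic_fn: Callable[[np.ndarray | None], float],
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> JackknifeResult:
    """Weighted delete-one block jackknife over contiguous site blocks.

    ``statistic_fn(keep_indices)`` evaluates the statistic on a subset of
    sites (``None`` means all sites).  Blocks hold approximately equal
    numbers of contributing sites; leave-one-out estimates are combined with
    weights proportional to the number of sites each block removes, using
    the weighted delete-one jackknife variance

        h_j   = n / m_j
        tau_j = h_j * theta - (h_j - 1) * theta_(-j)
        var   = (1/g) * sum_j (tau_j - theta_J)^2 / (h_j - 1)

    with theta_J = g*theta - sum_j (1 - m_j/n) theta_(-j).
    """
    blocks = partition_blocks(n_sites, n_blocks)
    theta = float(statistic_fn(None))
    all_idx = np.arange(n_sites)
    loo = np.empty(len(blocks))
    weights = np.empty(len(blocks))
    for j, block in enumerate(blocks):
        keep = np.delete(all_idx, block)
        loo[j] = statistic_fn(keep)
        weights[j] = len(block)
    g = len(blocks)
    n = float(n_sites)
    h = n / weights
    theta_j = g * theta - np.sum((1 - weights / n) * loo)
    tau = h * theta - (h - 1) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1)) / g
    return JackknifeResult(point=theta, leave_one_out=loo, block_weights=weights, se=float(np.sqrt(var)))


# ---------------------------------------------------------------------------
# R and R^2


def _usable_mask(
    dataset: PolarizedDataset,
    breed_a: str,
    breed_b: str,
    site_class: np.ndarray | str | None,
    min_called: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise complete-case mask plus derived frequencies for both breeds."""
    fa = derived_frequencies(dataset, breed_a, min_called)
    fb = derived_frequencies(dataset, breed_b, min_called)
    mask = (fa["usable"] & fb["usable"]).to_numpy()
    if site_class is not None:
        if isinstance(site_class, str):
            from .io_model import classify_sites

            if dataset.annotations is None:
                raise ValueError("dataset has no annotations; attach them first")
            classes = classify_sites(dataset.annotations)
            if site_class not in classes.columns:
                raise ValueError(f"unknown site class {site_class!r}")
            class_mask = classes[site_class].to_numpy()
        else:
            class_mask = np.asarray(site_class, dtype=bool)
        mask &= class_mask
    return mask, fa["derived_freq"].to_numpy(), fb["derived_freq"].to_numpy()


def _ratio_comparison(
    dataset: PolarizedDataset,
    breed_a: str,
    breed_b: str,
    site_class,
    values_a: np.ndarray,
    values_b: np.ndarray,
    mask: np.ndarray,
    kind: str,
    n_blocks: int,
    mode: str,
) -> LoadComparison:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("empty site subset for load comparison")
    va = values_a[idx]
    vb = values_b[idx]
    if mode == "presence":
        va = (va > 0).astype(float)
        vb = (vb > 0).astype(float)
    t_ab = va * (1 - vb)
    t_ba = vb * (1 - va)
    L_ab = float(t_ab.sum())
    L_ba = float(t_ba.sum())
    if L_ba == 0:
        raise ValueError("ratio undefined: denominator sharing sum is zero")

    def stat(keep: np.ndarray | None) -> float:
        if keep is None:
            return L_ab / L_ba
        denom = t_ba[keep].sum()
        if denom == 0:
            return np.nan
        return t_ab[keep].sum() / denom

    jk = weighted_block_jackknife(idx.size, stat, n_blocks=n_blocks)
    z = (jk.point - 1.0) / jk.se if jk.se > 0 else np.inf * np.sign(jk.point - 1.0) if jk.point != 1 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return LoadComparison(
        breed_a=breed_a,
        breed_b=breed_b,
        site_class=site_class if isinstance(site_class, str) else "custom",
        statistic_kind=kind,
        L_a_not_b=L_ab,
        L_b_not_a=L_ba,
        value=jk.point,
        se=jk.se,
        z=float(z),
        p=p,
        n_sites=int(idx.size),
        jackknife=jk,
    )


def r_ab(
    dataset: PolarizedDataset,
    breed_a: str,
    breed_b: str,
    site_class: np.ndarray | str | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    min_called: int | None = None,
    mode: str = "frequency",
) -> LoadComparison:
    """Additive-load ratio R_A/B with weighted block-jackknife inference.

    R(A, A) = 1 exactly and R(A, B) * R(B, A) = 1 exactly, for any class.
    """
    mask, fa, fb = _usable_mask(dataset, breed_a, breed_b, site_class, min_called)
    return _ratio_comparison(
        dataset, breed_a, breed_b, site_class, fa, fb, mask, "R", n_blocks, mode
    )


def r2_ab(
    dataset: PolarizedDataset,
    breed_a: str,
    breed_b: str,
    site_class: np.ndarray | str | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    min_called: int | None = None,
) -> LoadComparison:
    """Recessive-load ratio R^2_A/B built from homozygous-derived fractions."""
    mask, _, _ = _usable_mask(dataset, breed_a, breed_b, site_class, min_called)
    fa = derived_frequencies(dataset, breed_a, min_called)["hom_derived_fraction"].to_numpy()
    fb = derived_frequencies(dataset, breed_b, min_called)["hom_derived_fraction"].to_numpy()
    return _ratio_comparison(
        dataset, breed_a, breed_b, site_class, fa, fb, mask, "R2", DEFAULT_N_BLOCKS if n_blocks is None else n_blocks, "frequency"
    )


def masked_r_ab(
    dataset: PolarizedDataset,
    breed_a: str,
    breed_b: str,
    site_class: np.ndarray | str | None = None,
    mask: MaskSet | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    min_called: int | None = None,
) -> LoadComparison:
    """R_A/B after removing sites in masked genomic regions.

    Blocks are re-partitioned over the surviving sites so the configured
    block count is preserved.  An empty mask reproduces :func:`r_ab`.
    """
    if mask is None or not mask.intervals:
        return r_ab(dataset, breed_a, breed_b, site_class, n_blocks, min_called)
    pos0 = dataset.sites["pos"].to_numpy() - 1  # VCF 1-based -> 0-based
    hit = mask.contains(dataset.sites["chrom"].to_numpy(), pos0)
    if hit.all():
        raise ValueError("mask removes every site")
    keep_class, fa, fb = _usable_mask(dataset, breed_a, breed_b, site_class, min_called)
    keep = keep_class & ~hit
    return _ratio_comparison(
        dataset, breed_a, breed_b, site_class, fa, fb, keep, "R", n_blocks, "frequency"
    )


def bonferroni(p_values: Sequence[float] | np.ndarray, family_size: int) -> np.ndarray:
    """Bonferroni correction: min(1, p * family_size)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if family_size < p.size:
        raise ValueError("family_size must be at least the number of tests")
    return np.minimum(1.0, p * family_size)


def all_pairs_load_table(
    dataset: PolarizedDataset,
    site_classes: dict[str, np.ndarray],
    statistic: str = "R",
    n_blocks: int = DEFAULT_N_BLOCKS,
    family_size: int | None = None,
    min_called: int | None = None,
):
    """LoadComparison for every unordered breed pair in every site class.

    The Bonferroni family defaults to the number of breed pairs within one
    site class (28 for 8 breeds); p_bonf is filled in on each comparison.
    """
    import itertools

    import pandas as pd

    breeds = dataset.breeds
    pairs = list(itertools.combinations(breeds, 2))
    family = family_size if family_size is not None else len(pairs)
    fn = r_ab if statistic == "R" else r2_ab
    rows = []
    for cls_name, cls_mask in site_classes.items():
        comps = [
            fn(dataset, a, b, cls_mask, n_blocks=n_blocks, min_called=min_called)
            for a, b in pairs
        ]
        p_bonf = bonferroni([c.p for c in comps], family)
        for comp, (a, b), pb in zip(comps, pairs, p_bonf):
            comp.site_class = cls_name
            comp.p_bonf = float(pb)
            lo, hi = comp.ci95
            rows.append(
                {
                    "breed_a": a,
                    "breed_b": b,
                    "site_class": cls_name,
                    "statistic": statistic,
                    "L_a_not_b": comp.L_a_not_b,
                    "L_b_not_a": comp.L_b_not_a,
                    "value": comp.value,
                    "se": comp.se,
                    "ci_low": lo,
                    "ci_high": hi,
                    "z": comp.z,
                    "p": comp.p,
                    "p_bonf": comp.p_bonf,
                    "n_sites": comp.n_sites,
                }
            )
    return pd.DataFrame(rows)
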