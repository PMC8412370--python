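"""Case-control association of candidate markers with a late-onset disease.

All model fits are ordinary least squares (a linear probability model when
the outcome is the binary disease status), matching standard ``lm()`` usage
in veterinary epidemiology; genotypes enter additively as derived-allele
counts (0/1/2).  For a late-onset disease like myxomatous mitral valve
disease the module also supports genotype x age (x sex) interaction models
and young-case / old-control subsampling, which removes carriers that are
simply too young to show signs yet.

Two-locus linkage disequilibrium (|D'| and r^2) is estimated from unphased
diploid genotypes by an EM algorithm that iteratively resolves the phase of
double heterozygotes, and across-breed association regresses breed-level
disease incidence (claims per 10,000 dog-years at risk) on breed allele
frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

COHORT_COLUMNS = [
    "Id",
    "breed",
    "nationality",
    "sex",
    "MMVD_status",
    "graded_MMVD_status",
    "age",
]


@dataclass
class RegressionResult:
    outcome: str
    terms: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    adj_r2: float
    r2: float
    n: int

    def __getitem__(self, term: str) -> float:
        return self.coefficients[term]


@dataclass
class LdPair:
    marker_a: str
    marker_b: str
    d_prime: float
    r2: float
    hap_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab)
    n: int


@dataclass(frozen=True)
class IncidenceRecord:
    breed: str
    first_claims: int
    dyar: float

    @property
    def incidence(self) -> float:
        return 10_000 * self.first_claims / self.dyar


# ---------------------------------------------------------------------------
# cohort I/O


def read_cohort(
    tsv_source,
    marker_alleles: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Read a phenotype/genotype cohort table.

    The schema mirrors the standard cohort layout: ``Id, breed, nationality,
    sex (0 female / 1 male), MMVD_status (0/1), graded_MMVD_status (0-3 for
    ACVIM stages A/B1/B2/C), age`` plus one column per marker.  Marker
    genotypes may be numeric derived-allele counts or letter pairs (e.g.
    "AG"); letter pairs require ``marker_alleles`` mapping marker ->
    (ancestral, derived) allele.  Rows violating the grade/status invariant
    are reported as warnings, not dropped.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype={"Id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {', '.join(missing)}")
    markers = [c for c in df.columns if c not in COHORT_COLUMNS]
    for m in markers:
        col = df[m]
        if col.dtype == object:
            if marker_alleles is None or m not in marker_alleles:
                # try numeric strings before giving up
                num = pd.to_numeric(col, errors="coerce")
                if num.notna().sum() == 0 and col.notna().any():
                    raise ValueError(
                        f"marker {m!r} holds letter genotypes but no allele definition given"
                    )
                df[m] = num
            else:
                anc, der = marker_alleles[m]
                df[m] = col.map(
                    lambda s, anc=anc, der=der: _letters_to_count(s, anc, der, m)
                )
    bad = df[(df["MMVD_status"] == 0) & (df["graded_MMVD_status"] > 0)]
    bad = pd.concat([bad, df[(df["MMVD_status"] == 1) & (df["graded_MMVD_status"] == 0)]])
    for _, row in bad.iterrows():
        warnings.warn(
            f"record {row['Id']}: graded status {row['graded_MMVD_status']} "
            f"inconsistent with status {row['MMVD_status']}",
            stacklevel=2,
        )
    if (df["age"] <= 0).any():
        warnings.warn("cohort contains non-positive ages", stacklevel=2)
    return df


def _letters_to_count(value, ancestral: str, derived: str, marker: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().replace("/", "")
    if s in ("", "NA", "."):
        return np.nan
    if len(s) != 2:
        raise ValueError(f"marker {marker!r}: malformed genotype {value!r}")
    count = 0
    for a in s:
        if a == derived:
            count += 1
        elif a != ancestral:
            raise ValueError(
                f"marker {marker!r}: allele {a!r} not in ({ancestral}, {derived})"
            )
    return float(count)


# ---------------------------------------------------------------------------
# regression models


def _result_from_fit(fit, outcome: str, terms: list[str]) -> RegressionResult:
    return RegressionResult(
        outcome=outcome,
        terms=terms,
        coefficients={k: float(v) for k, v in fit.params.items()},
        std_errors={k: float(v) for k, v in fit.bse.items()},
        t_values={k: float(v) for k, v in fit.tvalues.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        adj_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        n=int(fit.nobs),
    )


def ols_fit(records: pd.DataFrame, outcome: str, terms: Sequence[str]) -> RegressionResult:
    """OLS of an outcome on main-effect/interaction terms (complete-case).

    ``terms`` follow patsy syntax, e.g. ``["genotype", "age"]`` or
    ``["genotype*age"]``; binary outcomes are fitted as a linear probability
    model, not logistic.
    """
    formula = f"{outcome} ~ " + " + ".join(terms)
    used = set([outcome])
    for t in terms:
        for piece in t.replace("*", ":").split(":"):
            used.add(piece.strip())
    cols = [c for c in used if c in records.columns]
    data = records[cols].dropna()
    model = smf.ols(formula, data=data)
    if data.shape[0] <= model.exog.shape[1]:
        raise ValueError("more model terms than observations")
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = model.fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        result = _result_from_fit(fit, outcome, list(terms))
    if np.var(model.endog) == 0:  # degenerate constant outcome: define R^2 = 0
        result.r2 = 0.0
        result.adj_r2 = 0.0
    return result


def interaction_models(
    records: pd.DataFrame, marker: str, include_sex: bool = False
) -> RegressionResult:
    """Graded-status ~ genotype * age (* sex) full factorial model.

    The marker column is renamed ``genotype`` in the fitted formula so that
    coefficient names are stable across markers.  Errors if the marker is
    monomorphic in the cohort.
    """
    data = records.rename(columns={marker: "genotype"})
    geno = data["genotype"].dropna()
    if geno.nunique() < 2:
        raise ValueError(f"marker {marker!r} is not segregating in these records")
    terms = ["genotype*age*sex"] if include_sex else ["genotype*age"]
    return ols_fit(data, "graded_MMVD_status", terms)


def young_case_old_control(
    records: pd.DataFrame,
    case_age_max: float,
    control_age_min: float,
    marker: str,
) -> tuple[pd.DataFrame, RegressionResult]:
    """Status ~ genotype on young cases plus old controls.

    Keeps affected dogs examined before ``case_age_max`` and healthy dogs
    examined after ``control_age_min``; tightening both thresholds never
    adds records (nested subsamples).
    """
    if case_age_max <= 0 or control_age_min < 0:
        raise ValueError("age thresholds must be positive")
    cases = records[(records["MMVD_status"] == 1) & (records["age"] < case_age_max)]
    controls = records[(records["MMVD_status"] == 0) & (records["age"] > control_age_min)]
    if cases.empty or controls.empty:
        raise ValueError(
            f"empty group: {len(cases)} cases < {case_age_max}y, "
            f"{len(controls)} controls > {control_age_min}y"
        )
    subset = pd.concat([cases, controls]).rename(columns={marker: "genotype"})
    return subset, ols_fit(subset, "MMVD_status", ["genotype"])


def group_allele_freq(
    records: pd.DataFrame,
    marker: str,
    group_filter: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
) -> float:
    """Derived-allele frequency of a marker within a filtered subgroup."""
    if group_filter is None:
        sub = records
    elif callable(group_filter):
        sub = records[group_filter(records)]
    else:
        sub = records[group_filter]
    geno = sub[marker].dropna()
    if geno.empty:
        raise ValueError("no called genotypes in group")
    return float(geno.sum() / (2 * len(geno)))


# ---------------------------------------------------------------------------
# two-locus LD via EM


def ld_em(
    records: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LdPair:
    """|D'| and r^2 between two markers from unphased diploid genotypes.

    Haplotype frequencies are estimated by EM starting from linkage
    equilibrium; only double heterozygotes have ambiguous phase.  Alleles
    are labelled by derived ("A"/"B") vs ancestral; both LD measures are
    invariant to swapping the labels at either locus.
    """
    g = records[[marker_a, marker_b]].dropna().to_numpy(dtype=int)
    if g.shape[0] == 0:
        raise ValueError("no complete genotype pairs")
    ga, gb = g[:, 0], g[:, 1]
    if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2:
        raise ValueError("both markers must be segregating")
    n = g.shape[0]
    pa = ga.sum() / (2 * n)
    pb = gb.sum() / (2 * n)

    # genotype-pair counts; phase is ambiguous only for the (1, 1) cell
    counts = np.zeros((3, 3))
    for i, j in zip(ga, gb):
        counts[i, j] += 1
    n_dh = counts[1, 1]

    # haplotype-count contributions that do not involve double heterozygotes
    base = np.zeros(4)  # AB, Ab, aB, ab
    contrib = {
        (0, 0): (0, 0, 0, 2),
        (0, 1): (0, 0, 1, 1),
        (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1),
        (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0),
        (2, 1): (1, 1, 0, 0),
        (2, 2): (2, 0, 0, 0),
    }
    for (i, j), add in contrib.items():
        base += counts[i, j] * np.asarray(add, dtype=float)

    h = np.array(
        [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)], dtype=float
    )
    total = 2.0 * n
    for _ in range(max_iter):
        # P(phase AB/ab | double het) given current haplotype frequencies
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new_counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new_h = new_counts / total
        if np.max(np.abs(new_h - h)) < tol:
            h = new_h
            break
        h = new_h
    else:
        raise RuntimeError("EM did not converge")

    p_ab = h[0]
    d = p_ab - pa * pb
    if d >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = d * d / denom if denom > 0 else 0.0
    return LdPair(marker_a, marker_b, float(d_prime), float(r2), h, n)


def average_ld(records: pd.DataFrame, markers: Sequence[str]) -> tuple[float, float]:
    """Mean |D'| and r^2 over all unordered marker pairs."""
    import itertools

    pairs = [ld_em(records, a, b) for a, b in itertools.combinations(markers, 2)]
    if not pairs:
        raise ValueError("need at least two markers")
    return (
        float(np.mean([p.d_prime for p in pairs])),
        float(np.mean([p.r2 for p in pairs])),
    )


# ---------------------------------------------------------------------------
# incidence


def incidence_rate(
    claims_table: pd.DataFrame,
    exposure_table: pd.DataFrame,
    window: tuple[float, float],
) -> list[IncidenceRecord]:
    """Per-breed first-claim incidence per 10,000 dog-years at risk.

    ``exposure_table`` has one row per dog (``dog_id, breed, insure_start,
    insure_end`` as decimal years) and ``claims_table`` one row per claim
    (``dog_id, claim_date``).  Exposure accrues from max(insurance start,
    window start) until the first claim, withdrawal, or window end --
    whichever comes first; repeat claims are ignored.
    """
    w_start, w_end = window
    first_claim = (
        claims_table.groupby("dog_id")["claim_date"].min()
        if not claims_table.empty
        else pd.Series(dtype=float)
    )
    per_breed_claims: dict[str, int] = {}
    per_breed_dyar: dict[str, float] = {}
    for row in exposure_table.itertuples(index=False):
        start = max(float(row.insure_start), w_start)
        end = min(float(row.insure_end), w_end)
        claim = first_claim.get(row.dog_id, np.inf)
        claimed = start <= claim <= end
        stop = min(end, claim)
        if stop < start:
            if end < w_start or start > w_end:
                continue  # insured entirely outside the window
            raise ValueError(f"negative exposure interval for dog {row.dog_id}")
        per_breed_dyar[row.breed] = per_breed_dyar.get(row.breed, 0.0) + (stop - start)
        if claimed:
            per_breed_claims[row.breed] = per_breed_claims.get(row.breed, 0) + 1
    return [
        IncidenceRecord(breed, per_breed_claims.get(breed, 0), dyar)
        for breed, dyar in sorted(per_breed_dyar.items())
    ]


def incidence_regression(
    incidence_by_breed: Mapping[str, float],
    allele_freq_by_breed: Mapping[str, float],
    drop_breed: str | None = None,
) -> RegressionResult:
    """OLS of breed MMVD incidence on breed allele frequency.

    ``drop_breed`` supports leave-one-breed-out sensitivity re-tests.
    """
    breeds = [
        b
        for b in incidence_by_breed
        if b in allele_freq_by_breed and b != drop_breed
    ]
    if len(breeds) < 3:
        raise ValueError("need at least three breeds with both incidence and frequency")
    data = pd.DataFrame(
        {
            "incidence": [incidence_by_breed[b] for b in breeds],
            "freq": [allele_freq_by_breed[b] for b in breeds],
        }
    )
    return ols_fit(data, "incidence", ["freq"])
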