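"""Cohort regression models, LD estimation and incidence analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from breedload import simulate
from breedload.association import (
    group_allele_freq,
    incidence_rate,
    incidence_regression,
    interaction_models,
    ld_em,
    ols_fit,
    read_cohort,
    young_case_old_control,
)


@pytest.fixture
def cohort_file(tmp_path, null_cohort):
    path = tmp_path / "cohort.tsv"
    null_cohort.to_csv(path, sep="\t", index=False)
    return path


class TestReadCohort:
    def test_round_trip(self, cohort_file, null_cohort):
        df = read_cohort(cohort_file)
        assert len(df) == len(null_cohort)
        assert df["NEBL_1"].equals(null_cohort["NEBL_1"])

    def test_schema_error_names_column(self, tmp_path):
        bad = pd.DataFrame({"Id": ["a"], "breed": ["x"]})
        path = tmp_path / "bad.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="MMVD_status"):
            read_cohort(path)

    def test_letter_genotypes_converted(self, tmp_path):
        df = pd.DataFrame(
            {
                "Id": ["d1", "d2", "d3"],
                "breed": "dachshund",
                "nationality": "Swedish",
                "sex": [0, 1, 0],
                "MMVD_status": [1, 0, 1],
                "graded_MMVD_status": [2, 0, 1],
                "age": [9.0, 8.0, 11.0],
                "NEBL_1": ["AG", "AA", "GG"],
            }
        )
        path = tmp_path / "letters.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = read_cohort(path, marker_alleles={"NEBL_1": ("A", "G")})
        assert out["NEBL_1"].tolist() == [1.0, 0.0, 2.0]

    def test_grade_status_inconsistency_warns(self, tmp_path):
        df = pd.DataFrame(
            {
                "Id": ["d1"],
                "breed": "dachshund",
                "nationality": "Swedish",
                "sex": [0],
                "MMVD_status": [0],
                "graded_MMVD_status": [2],
                "age": [9.0],
            }
        )
        path = tmp_path / "warn.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="inconsistent"):
            read_cohort(path)


class TestOlsFit:
    def test_exact_line(self):
        data = pd.DataFrame({"y": [2.0, 4.0, 6.0, 8.0], "x": [1.0, 2.0, 3.0, 4.0]})
        res = ols_fit(data, "y", ["x"])
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_outcome(self):
        data = pd.DataFrame({"y": [1.0] * 6, "x": [1, 2, 3, 4, 5, 6]})
        res = ols_fit(data, "y", ["x"])
        assert res.coefficients["x"] == pytest.approx(0.0, abs=1e-12)
        assert res.adj_r2 == 0.0

    def test_binary_outcome_is_linear_probability(self, null_cohort):
        """OLS on 0/1 status equals OLS on the same values as floats."""
        data = null_cohort.rename(columns={"NEBL_1": "genotype"})
        as_int = ols_fit(data, "MMVD_status", ["genotype"])
        data_f = data.assign(MMVD_status=data["MMVD_status"].astype(float))
        as_float = ols_fit(data_f, "MMVD_status", ["genotype"])
        assert as_int.coefficients == as_float.coefficients

    def test_rank_deficiency_errors(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="rank"):
            ols_fit(data, "y", ["x"])

    def test_age_predicts_late_onset_status(self, null_cohort):
        """The generator's planted age effect is recovered by status ~ age."""
        res = ols_fit(null_cohort, "MMVD_status", ["age"])
        assert res.coefficients["age"] > 0
        assert res.p_values["age"] < 0.01


class TestInteractionModels:
    def test_full_factorial_terms(self, null_cohort):
        res = interaction_models(null_cohort, "NEBL_3", include_sex=True)
        expected = {
            "Intercept",
            "genotype",
            "age",
            "sex",
            "genotype:age",
            "genotype:sex",
            "age:sex",
            "genotype:age:sex",
        }
        assert set(res.coefficients) == expected

    def test_monomorphic_marker_errors(self, null_cohort):
        with pytest.raises(ValueError, match="segregating"):
            interaction_models(null_cohort, "SORBS2")

    def test_planted_interaction_recovered_within_2se(self):
        """Seeded parameter recovery for the genotype x age effect."""
        cc = simulate.CohortConfig(n=400, beta_interaction=0.12, beta_genotype=-1.0)
        # OLS on a logistic-generated outcome attenuates the coefficient, so
        # the recoverable target is the generator's large-sample OLS value
        target = attenuated_expectation(cc)
        hits = 0
        for seed in range(50):
            cohort = simulate.simulate_cohort(cc, seed=1000 + seed)
            res = interaction_models(cohort, "NEBL_3")
            beta = res.coefficients["genotype:age"]
            se = res.std_errors["genotype:age"]
            if beta - 2 * se < target < beta + 2 * se:
                hits += 1
        assert hits >= 45


def attenuated_expectation(cc, n_large=200_000, seed=77):
    """Large-sample OLS interaction coefficient implied by the generator."""
    cohort = simulate.simulate_cohort(
        simulate.CohortConfig(**{**cc.__dict__, "n": n_large}), seed=seed
    )
    res = interaction_models(cohort, cc.effect_marker)
    return res.coefficients["genotype:age"]


class TestYoungCaseOldControl:
    def test_nested_subsets(self, null_cohort):
        sizes = []
        for case_max, ctrl_min in [(10, 8), (9, 9), (8, 10), (7, 11)]:
            subset, _ = young_case_old_control(null_cohort, case_max, ctrl_min, "NEBL_2")
            sizes.append(len(subset))
        assert sizes == sorted(sizes, reverse=True)

    def test_identity_thresholds(self, null_cohort):
        subset, res = young_case_old_control(null_cohort, np.inf, 0, "NEBL_2")
        assert len(subset) == len(null_cohort)
        plain = ols_fit(
            null_cohort.rename(columns={"NEBL_2": "genotype"}), "MMVD_status", ["genotype"]
        )
        for term, beta in plain.coefficients.items():
            assert res.coefficients[term] == pytest.approx(beta)

    def test_empty_group_errors(self, null_cohort):
        with pytest.raises(ValueError, match="empty group"):
            young_case_old_control(null_cohort, 0.1, 8, "NEBL_2")


class TestGroupAlleleFreq:
    def test_arithmetic(self):
        df = pd.DataFrame({"m": [2, 2, 2, 2, 0, 0, 0, 0, 0, 0]})
        assert group_allele_freq(df, "m") == pytest.approx(0.4)
        assert group_allele_freq(df, "m", df["m"] == 0) == 0.0

    def test_empty_group_errors(self):
        df = pd.DataFrame({"m": [1.0]})
        with pytest.raises(ValueError):
            group_allele_freq(df, "m", df["m"] > 5)

    def test_case_control_contrast(self):
        cc = simulate.CohortConfig(n=300, beta_genotype=1.5, effect_marker="NEBL_1")
        cohort = simulate.simulate_cohort(cc, seed=5)
        cases = group_allele_freq(cohort, "NEBL_1", cohort["MMVD_status"] == 1)
        controls = group_allele_freq(cohort, "NEBL_1", cohort["MMVD_status"] == 0)
        assert cases > controls


class TestLdEm:
    def test_marker_with_itself(self, null_cohort):
        pair = ld_em(null_cohort, "NEBL_1", "NEBL_1")
        assert pair.d_prime == pytest.approx(1.0)
        assert pair.r2 == pytest.approx(1.0)
        assert pair.hap_freqs.sum() == pytest.approx(1.0)

    def test_independent_markers_near_zero_r2(self):
        cc = simulate.CohortConfig(n=500)
        cohort = simulate.simulate_cohort(cc, seed=8)
        pair = ld_em(cohort, "NEBL_1", "NEBL_5")
        assert pair.r2 < 0.02

    def test_counting_oracle_without_double_heterozygotes(self):
        # phase is unambiguous: haplotypes countable directly
        df = pd.DataFrame(
            {"a": [0, 0, 1, 2, 2, 1], "b": [0, 2, 2, 0, 2, 1]}
        )
        df = df[~((df["a"] == 1) & (df["b"] == 1))]
        pair = ld_em(df, "a", "b")
        haps = []
        for ga, gb in df.itertuples(index=False):
            if ga == 1:
                haps += [(1, gb // 2), (0, gb // 2)]
            elif gb == 1:
                haps += [(ga // 2, 1), (ga // 2, 0)]
            else:
                haps += [(ga // 2, gb // 2)] * 2
        counts = pd.Series(haps).value_counts(normalize=True)
        assert pair.hap_freqs[0] == pytest.approx(counts.get((1, 1), 0.0), abs=1e-9)
        assert pair.hap_freqs[3] == pytest.approx(counts.get((0, 0), 0.0), abs=1e-9)

    def test_label_swap_invariance(self, null_cohort):
        pair = ld_em(null_cohort, "NEBL_1", "NEBL_2")
        flipped = null_cohort.assign(NEBL_1=2 - null_cohort["NEBL_1"])
        pair_f = ld_em(flipped, "NEBL_1", "NEBL_2")
        assert pair.r2 == pytest.approx(pair_f.r2, abs=1e-9)
        assert pair.d_prime == pytest.approx(pair_f.d_prime, abs=1e-9)

    def test_not_segregating_errors(self, null_cohort):
        with pytest.raises(ValueError, match="segregating"):
            ld_em(null_cohort, "NEBL_1", "SORBS2")


class TestIncidence:
    def exposure(self, rows):
        return pd.DataFrame(rows, columns=["dog_id", "breed", "insure_start", "insure_end"])

    def test_rate_arithmetic(self):
        exp = self.exposure(
            [(f"d{i}", "ckcs", 2011.0, 2015.0) for i in range(1000)]
        )
        claims = pd.DataFrame({"dog_id": ["d0", "d1"], "claim_date": [2015.0, 2015.0]})
        recs = incidence_rate(claims, exp, (2011.0, 2015.0))
        assert recs[0].first_claims == 2
        assert recs[0].dyar == pytest.approx(4000.0)
        assert recs[0].incidence == pytest.approx(5.0)

    def test_first_claim_only_and_truncated_exposure(self):
        exp = self.exposure([("d1", "ckcs", 2011.0, 2016.0)])
        claims = pd.DataFrame(
            {"dog_id": ["d1", "d1"], "claim_date": [2013.0, 2014.0]}
        )
        recs = incidence_rate(claims, exp, (2011.0, 2016.0))
        assert recs[0].first_claims == 1
        assert recs[0].dyar == pytest.approx(2.0)  # accrual stops at first claim

    def test_outside_window_excluded(self):
        exp = self.exposure([("late", "ckcs", 2020.0, 2022.0), ("d1", "ckcs", 2011.0, 2016.0)])
        recs = incidence_rate(pd.DataFrame(columns=["dog_id", "claim_date"]), exp, (2011.0, 2016.0))
        assert len(recs) == 1
        assert recs[0].dyar == pytest.approx(5.0)

    def test_negative_interval_errors(self):
        exp = self.exposure([("odd", "ckcs", 2015.0, 2012.0)])
        with pytest.raises(ValueError, match="odd"):
            incidence_rate(pd.DataFrame(columns=["dog_id", "claim_date"]), exp, (2011.0, 2016.0))


class TestIncidenceRegression:
    def test_exact_slope_recovery(self):
        freqs = {b: f for b, f in zip("abcde", [0.1, 0.2, 0.3, 0.4, 0.5])}
        incidence = {b: 10 + 200 * f for b, f in freqs.items()}
        res = incidence_regression(incidence, freqs)
        assert res.coefficients["freq"] == pytest.approx(200.0)

    def test_leave_one_out_flips_planted_outlier(self):
        # association driven entirely by one extreme breed
        rng = np.random.default_rng(12)
        freqs = {f"b{i}": 0.2 + 0.01 * rng.standard_normal() for i in range(8)}
        incidence = {b: 50 + 5 * rng.standard_normal() for b in freqs}
        freqs["ckcs"] = 1.0
        incidence["ckcs"] = 400.0
        with_out = incidence_regression(incidence, freqs)
        without = incidence_regression(incidence, freqs, drop_breed="ckcs")
        assert with_out.p_values["freq"] < 0.001
        assert without.p_values["freq"] > 0.05

    def test_too_few_breeds_errors(self):
        with pytest.raises(ValueError):
            incidence_regression({"a": 1.0, "b": 2.0}, {"a": 0.1, "b": 0.2})

    def test_constant_incidence_zero_slope(self):
        freqs = {b: f for b, f in zip("abcd", [0.1, 0.2, 0.3, 0.4])}
        incidence = {b: 5.0 for b in freqs}
        res = incidence_regression(incidence, freqs)
        assert res.coefficients["freq"] == pytest.approx(0.0, abs=1e-10)
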