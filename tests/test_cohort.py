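import numpy as np
import pandas as pd
import pytest

from lipidval import cohort, models
from lipidval.exceptions import ParameterError, SchemaError
from tests.conftest import make_labelled_cohort


class TestGenerateCohort:
    def test_returns_exactly_n_records(self):
        df = cohort.generate_cohort(cohort.CohortSpec(n=1099, seed=0))
        assert len(df) == 1099
        assert df["id"].is_unique

    def test_dbp_mean_within_sampling_error(self):
        spec = cohort.CohortSpec(n=1099, seed=42)
        df = cohort.generate_cohort(spec)
        tol = 3 * spec.dbp_sd / np.sqrt(spec.n)
        assert abs(df["dbp"].mean() - 70.4) < tol

    def test_moment_recovery_all_marginals(self):
        spec = cohort.CohortSpec(n=20_000, seed=7)
        df = cohort.generate_cohort(spec)
        targets = {
            "age": (spec.age_mean, spec.age_sd),
            "bmi": (spec.bmi_mean, spec.bmi_sd),
            "metabolic_age": (spec.metage_mean, spec.metage_sd),
            "dbp": (spec.dbp_mean, spec.dbp_sd),
            "sbp": (spec.sbp_mean, spec.sbp_sd),
        }
        for col, (m, s) in targets.items():
            se_mean = s / np.sqrt(spec.n)
            se_sd = s / np.sqrt(2 * spec.n)
            assert abs(df[col].mean() - m) < 3 * se_mean, col
            assert abs(df[col].std(ddof=1) - s) < 3 * se_sd, col
        assert abs(df["male"].mean() - spec.male_prob) < 3 * np.sqrt(
            spec.male_prob * (1 - spec.male_prob) / spec.n
        )

    def test_degenerate_variance_returns_means(self):
        spec = cohort.CohortSpec(
            n=1, age_sd=1e-6, bmi_sd=1e-6, metage_sd=1e-6,
            dbp_sd=1e-6, sbp_sd=1e-6, seed=9,
        )
        row = cohort.generate_cohort(spec).iloc[0]
        assert row["age"] == pytest.approx(spec.age_mean, abs=1e-3)
        assert row["bmi"] == pytest.approx(spec.bmi_mean, abs=1e-3)
        assert row["metabolic_age"] == pytest.approx(spec.metage_mean, abs=1e-3)
        assert row["dbp"] == pytest.approx(spec.dbp_mean, abs=1e-3)

    def test_same_seed_byte_identical(self, tmp_path):
        spec = cohort.CohortSpec(n=300, seed=17)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        cohort.write_cohort(cohort.generate_cohort(spec), a)
        cohort.write_cohort(cohort.generate_cohort(spec), b)
        assert a.read_bytes() == b.read_bytes()

    def test_bounds_respected(self):
        df = cohort.generate_cohort(cohort.CohortSpec(n=5000, seed=3))
        assert df["age"].between(20, 40).all()
        assert (df["bmi"] > 12).all()
        assert (df["dbp"] > 35).all()
        assert (df["metabolic_age"] > 0).all()

    def test_eq3_plus_noise_mode_tracks_proxy(self):
        spec = cohort.CohortSpec(n=5000, metage_mode="eq3_plus_noise",
                                 metage_noise_sd=1e-6, seed=4)
        df = cohort.generate_cohort(spec)
        proxy = models.impute_metabolic_age(df["age"], df["bmi"], df["male"])
        assert np.allclose(df["metabolic_age"], proxy, atol=1e-4)

    def test_copula_correlation_recovered(self):
        # dbp-sbp: bounds are far in the tails, so the latent copula
        # correlation should be realised almost unattenuated
        corr = np.eye(5)
        corr[3, 4] = corr[4, 3] = 0.5
        spec = cohort.CohortSpec(n=20_000, corr=corr, seed=8)
        df = cohort.generate_cohort(spec)
        r = np.corrcoef(df["dbp"], df["sbp"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)
        # heavily truncated margins attenuate but preserve the sign
        corr2 = np.eye(5)
        corr2[0, 1] = corr2[1, 0] = 0.5
        df2 = cohort.generate_cohort(cohort.CohortSpec(n=20_000, corr=corr2,
                                                       seed=8))
        assert 0.2 < np.corrcoef(df2["age"], df2["bmi"])[0, 1] < 0.5

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"n": 0}, "n"),
            ({"male_prob": 1.5}, "male_prob"),
            ({"age_sd": 0.0}, "age_sd"),
            ({"isco_probs": (0.5,) * 10}, "isco_probs"),
            ({"metage_mode": "lookup"}, "metage_mode"),
        ],
    )
    def test_invalid_spec_names_offending_field(self, kwargs, match):
        with pytest.raises(ParameterError, match=match):
            cohort.CohortSpec(**kwargs)


class TestEligibility:
    def _roster(self, n_clean=1099, codes=()):
        df = cohort.generate_cohort(cohort.CohortSpec(n=n_clean + len(codes),
                                                      seed=21))
        df = df.copy()
        for i, code in enumerate(codes):
            df.loc[i, "icd10_codes"] = code
        return df

    def test_study_flow_worked_example(self):
        # 1105 screened, 5 hypercholesterolemia diagnoses + 1 pregnancy
        roster = self._roster(1099, ["E78"] * 5 + ["Z34"])
        eligible, log = cohort.apply_eligibility(roster)
        assert len(eligible) == 1099
        assert len(log) == 6
        assert (log["reason"].str.startswith("icd10:")).all()

    def test_age_boundary_rule(self):
        df = self._roster(2)
        df.loc[0, "age"] = 41.0
        eligible, log = cohort.apply_eligibility(df)
        assert len(eligible) == len(df) - 1
        assert log.iloc[0]["reason"] == "age"

    def test_prefix_matching_against_default_set(self):
        # brute-force check: only codes starting with an excluded prefix drop
        rules = cohort.EligibilityRules()
        codes = ["E11", "E78", "E780", "E0", "E03", "F500", "N04", "Z34",
                 "Z3", "I10", "F5", ""]
        expected_excluded = {
            c for c in codes
            if any(c.startswith(p) for p in rules.excluded_icd10_prefixes)
        }
        df = self._roster(0, codes)
        _, log = cohort.apply_eligibility(df, rules)
        flagged = {r.split(":", 1)[1] for r in log["reason"]}
        assert flagged == expected_excluded

    def test_medication_rule_and_reason_precedence(self):
        df = self._roster(3)
        df.loc[0, "lipid_meds"] = "statin"
        df.loc[1, "icd10_codes"] = "E03"
        df.loc[1, "lipid_meds"] = "statin"  # icd10 reason wins
        eligible, log = cohort.apply_eligibility(df)
        assert len(eligible) == 1
        reasons = dict(zip(log["id"], log["reason"]))
        assert reasons[df.loc[0, "id"]] == "medication:statin"
        assert reasons[df.loc[1, "id"]] == "icd10:E03"

    def test_idempotent(self):
        roster = self._roster(50, ["E78", "Z34"])
        once, _ = cohort.apply_eligibility(roster)
        twice, log2 = cohort.apply_eligibility(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.empty

    def test_empty_roster_rejected(self):
        with pytest.raises(ParameterError):
            cohort.apply_eligibility(pd.DataFrame())


class TestSimulateOutcomes:
    def test_calibrated_prevalence_matches_mean_risk(self):
        df = make_labelled_cohort(20_000, seed=31)
        p = models.predicted_probability(models.NONHDL_MODEL, df)
        assert abs(df["y_nonhdl"].mean() - p.mean()) < 0.01

    def test_saturated_negative_drift_gives_all_zero(self):
        df = cohort.generate_cohort(cohort.CohortSpec(n=200, seed=32))
        sim = cohort.OutcomeSimSpec(true_model=models.NONHDL_MODEL,
                                    drift_intercept=-50.0, seed=1)
        out = cohort.simulate_outcomes(df, sim)
        assert out["y_nonhdl"].sum() == 0

    def test_missing_predictor_raises_schema_error(self):
        df = cohort.generate_cohort(cohort.CohortSpec(n=20, seed=33))
        sim = cohort.OutcomeSimSpec(true_model=models.NONHDL_MODEL, seed=1)
        with pytest.raises(SchemaError, match="dbp"):
            cohort.simulate_outcomes(df.drop(columns=["dbp"]), sim)

    def test_deterministic_given_seed(self):
        df = cohort.generate_cohort(cohort.CohortSpec(n=500, seed=34))
        sim = cohort.OutcomeSimSpec(true_model=models.NONHDL_MODEL, seed=9)
        a = cohort.simulate_outcomes(df, sim)
        b = cohort.simulate_outcomes(df, sim)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_drift_slope_rejected(self):
        with pytest.raises(ParameterError, match="drift_slope"):
            cohort.OutcomeSimSpec(true_model=models.NONHDL_MODEL,
                                  drift_slope=0.0)


class TestCsvRoundtrip:
    def test_cohort_roundtrip_preserves_values(self, tmp_path):
        df = make_labelled_cohort(100, seed=41)
        path = tmp_path / "cohort.csv"
        cohort.write_cohort(df, path)
        back = cohort.read_cohort(path)
        assert list(back.columns) == list(df.columns)
        assert np.allclose(back["metabolic_age"], df["metabolic_age"])
        assert (back["icd10_codes"] == "").all()
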