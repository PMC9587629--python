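import numpy as np
import pandas as pd
import pytest

from chestpain_cea.cohort import (DEFAULT_TRIAGE_FRACTIONS, CohortSpec,
                                  generate_cohort, hospital_spec,
                                  primary_care_spec, read_cohort,
                                  summarize_cohort, write_cohort)


class TestGenerateCohort:
    def test_empty_cohort(self):
        records = generate_cohort(primary_care_spec(n=0, seed=1))
        assert len(records) == 0

    def test_same_seed_identical(self):
        a = generate_cohort(primary_care_spec(n=500, seed=9))
        b = generate_cohort(primary_care_spec(n=500, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = summarize_cohort(generate_cohort(primary_care_spec(n=2000, seed=1)))
        b = summarize_cohort(generate_cohort(primary_care_spec(n=2000, seed=2)))
        assert a != b

    def test_hospital_records_have_costs_and_no_triage(self):
        records = generate_cohort(hospital_spec(n=50, seed=4))
        assert (records["triage"] == "not_applicable").all()
        assert records["cost_eur"].notna().all()

    def test_primary_records_carry_triage_class(self):
        records = generate_cohort(primary_care_spec(n=50, seed=4))
        assert records["triage"].isin(["rule_out", "observation",
                                       "rule_in"]).all()
        assert records["cost_eur"].isna().all()
        assert (records["los_hours"] >= 0).all()

    def test_primary_marginals_at_large_n(self):
        """At n = 10^5 every calibrated marginal sits within 3 MC SEs."""
        n = 100_000
        spec = primary_care_spec(n=n, seed=1)
        s = summarize_cohort(generate_cohort(spec))

        def se_p(p):
            return np.sqrt(p * (1 - p) / n)

        assert abs(s.p_admit - 0.132) < 3 * se_p(0.132)
        for frac, target in zip(s.triage_fractions, DEFAULT_TRIAGE_FRACTIONS):
            assert abs(frac - target) < 3 * se_p(target)
        assert abs(s.event_rate_30d - 5 / 1485) < 3 * se_p(5 / 1485)
        # lognormal LOS moments
        assert abs(s.los_mean_h - 3.4) < 3 * 0.740 / np.sqrt(n)
        assert s.los_sd_h == pytest.approx(0.740, rel=0.05)

    def test_hospital_los_mean_at_large_n(self):
        n = 50_000
        s = summarize_cohort(generate_cohort(hospital_spec(n=n, seed=2)))
        assert abs(s.los_mean_h - 22.3) < 3 * 22.010 / np.sqrt(n)
        # gamma cost mean, CV 0.5
        assert abs(s.mean_cost_eur - 1483) < 3 * (0.5 * 1483) / np.sqrt(n)

    def test_degenerate_sd_gives_point_mass(self):
        records = generate_cohort(primary_care_spec(n=20, seed=1,
                                                    los_sd_h=0.0))
        assert (records["los_hours"] == 3.4).all()

    def test_event_counts_binomial_across_seeds(self):
        """Events over n = 1485 at rate 5/1485 average five per cohort."""
        n, rate, n_seeds = 1485, 5 / 1485, 40
        counts = []
        for seed in range(n_seeds):
            rec = generate_cohort(primary_care_spec(n=n, seed=seed))
            counts.append((rec["event_30d"] != "none").sum())
        mean = np.mean(counts)
        se = np.sqrt(n * rate * (1 - rate) / n_seeds)
        assert abs(mean - 5.0) < 3 * se

    def test_invalid_triage_fractions_rejected(self):
        with pytest.raises(ValueError):
            primary_care_spec(n=1, seed=1, triage_fractions=(0.5, 0.5, 0.5))

    def test_hospital_spec_requires_cost(self):
        with pytest.raises(ValueError):
            CohortSpec(setting="hospital", n=1, seed=1, los_mean_h=22.3,
                       los_sd_h=22.0, event_rate_30d=0.002)


class TestSummaries:
    def test_single_admitted_record(self):
        rec = generate_cohort(primary_care_spec(n=1, seed=3)).assign(
            admitted=True)
        assert summarize_cohort(rec).p_admit == 1.0

    def test_empty_summary_sentinel(self):
        s = summarize_cohort(pd.DataFrame())
        assert s.empty and s.n == 0

    def test_concatenation_equals_weighted_combination(self):
        a = generate_cohort(primary_care_spec(n=3000, seed=5))
        b = generate_cohort(primary_care_spec(n=1000, seed=6))
        combined = summarize_cohort(pd.concat([a, b], ignore_index=True))
        merged = summarize_cohort(a).combine(summarize_cohort(b))
        assert merged.n == combined.n
        assert merged.p_admit == pytest.approx(combined.p_admit)
        assert merged.los_mean_h == pytest.approx(combined.los_mean_h)
        assert merged.los_sd_h == pytest.approx(combined.los_sd_h)
        for x, y in zip(merged.triage_fractions, combined.triage_fractions):
            assert x == pytest.approx(y)

    def test_triage_fractions_within_99pc_ci(self):
        n = 10_000
        s = summarize_cohort(generate_cohort(primary_care_spec(n=n, seed=7)))
        for frac, target in zip(s.triage_fractions, DEFAULT_TRIAGE_FRACTIONS):
            half = 2.576 * np.sqrt(target * (1 - target) / n)
            assert target - half < frac < target + half


class TestIO:
    def test_round_trip_with_sidecar(self, tmp_path):
        spec = hospital_spec(n=30, seed=8)
        records = generate_cohort(spec)
        path = tmp_path / "cohort.csv"
        write_cohort(records, path, spec)
        back = read_cohort(path)
        assert len(back) == 30
        assert (tmp_path / "cohort.csv.meta.json").exists()
        pd.testing.assert_series_equal(back["los_hours"],
                                       records["los_hours"], atol=1e-9)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"x": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_cohort(path)
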