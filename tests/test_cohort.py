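"""Cohort assembly: endpoint rule, eligibility, indicators, averaging, summary."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from prosmark.cohort import (
    ExclusionReason,
    average_spots,
    assemble_dataset,
    derive_bf_endpoint,
    derive_indicators,
    eligibility_filter,
    read_cohort_csv,
    run_concordance,
    summarize_cohort,
    write_cohort_csv,
)

from conftest import make_record


class TestBFEndpoint:
    def test_confirmed_rise_fails_at_index_value(self):
        rec = make_record(psa_days_values=((60, 0.25), (90, 0.30)))
        t, e = derive_bf_endpoint(rec)
        assert e and t == pytest.approx(60 / 365.25)

    def test_pre_six_week_value_cannot_qualify(self):
        rec = make_record(
            psa_days_values=((30, 0.25), (90, 0.30), (150, 0.35))
        )
        t, e = derive_bf_endpoint(rec)
        assert e and t == pytest.approx(90 / 365.25)

    def test_unconfirmed_rise_is_censored_at_last_contact(self):
        rec = make_record(
            psa_days_values=((60, 0.25), (90, 0.15)), last_contact_days=400
        )
        t, e = derive_bf_endpoint(rec)
        assert not e and t == pytest.approx(400 / 365.25)

    def test_confirmation_need_not_be_adjacent(self):
        rec = make_record(
            psa_days_values=((60, 0.25), (90, 0.1), (200, 0.4))
        )
        t, e = derive_bf_endpoint(rec)
        assert e and t == pytest.approx(60 / 365.25)

    def test_boundary_42_days_inclusive(self):
        rec = make_record(psa_days_values=((42, 0.2), (120, 0.25)))
        t, e = derive_bf_endpoint(rec)
        assert e and t == pytest.approx(42 / 365.25)

    def test_values_after_confirmed_failure_do_not_change_endpoint(self):
        base = ((60, 0.25), (150, 0.30))
        rec1 = make_record(psa_days_values=base)
        rec2 = make_record(psa_days_values=base + ((240, 0.05), (300, 9.0)))
        assert derive_bf_endpoint(rec1) == derive_bf_endpoint(rec2)


class TestEligibility:
    def test_gleason_4_5_kept(self):
        kept, _ = eligibility_filter(
            [make_record(gleason=(4, 5),
                         psa_days_values=((90, 0.05), (180, 0.05), (270, 0.05)))]
        )
        assert len(kept) == 1

    def test_pattern5_excluded_with_reason(self):
        _, excl = eligibility_filter([make_record(gleason=(5, 4))])
        assert excl[0][1] == ExclusionReason.GLEASON_PATTERN5

    def test_single_psa_excluded(self):
        _, excl = eligibility_filter(
            [make_record(gleason=(3, 3), psa_days_values=((90, 0.05),))]
        )
        assert excl[0][1] == ExclusionReason.SINGLE_PSA

    def test_malformed_gleason_raises(self):
        with pytest.raises(ValueError, match="Gleason"):
            eligibility_filter([make_record(gleason=(2, 3))])


class TestIndicators:
    @pytest.mark.parametrize(
        "gleason,flags,pattern,nonloc",
        [
            ((3, 4), {"pR1": True}, 3, True),
            ((4, 3), {}, 4, False),
            ((3, 3), {"pN1": True}, 3, True),
            ((4, 5), {"pT3": True}, 4, True),
        ],
    )
    def test_grouping_and_disjunction(self, gleason, flags, pattern, nonloc):
        ind = derive_indicators(make_record(gleason=gleason, **flags))
        assert ind["primary_pattern"] == pattern
        assert ind["non_localized"] is nonloc


class TestSpotAveraging:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["subject_id", "biomarker", "spot_index", "value"]
        )

    def test_mean_over_non_missing(self):
        tab = self._table(
            [("S1", "B1", 1, 20.0), ("S1", "B1", 2, 30.0),
             ("S1", "B1", 3, np.nan), ("S1", "B1", 4, 40.0)]
        )
        assert average_spots(tab).loc["S1", "B1"] == pytest.approx(30.0)

    def test_all_missing_gives_nan(self):
        tab = self._table([("S1", "B1", k, np.nan) for k in range(4)])
        assert np.isnan(average_spots(tab).loc["S1", "B1"])

    def test_single_spot_identity(self):
        tab = self._table([("S1", "B1", 1, 17.0)])
        assert average_spots(tab).loc["S1", "B1"] == 17.0

    def test_duplicate_keys_raise(self):
        tab = self._table([("S1", "B1", 1, 1.0), ("S1", "B1", 1, 2.0)])
        with pytest.raises(ValueError, match="duplicate"):
            average_spots(tab)

    def test_permutation_invariance(self):
        rows = [("S1", "B1", k, v) for k, v in enumerate([1.0, 5.0, 9.0])]
        a = average_spots(self._table(rows))
        b = average_spots(self._table(rows[::-1]))
        assert a.loc["S1", "B1"] == b.loc["S1", "B1"]


def _cohort_with_marginals():
    """Cohort reproducing the printed category counts: Gleason 50/63/34/8/5
    and 67 non-localized of 160."""
    records = []
    gleason_counts = [((3, 3), 50), ((3, 4), 63), ((4, 3), 34), ((4, 4), 8),
                      ((4, 5), 5)]
    i = 0
    for gl, cnt in gleason_counts:
        for _ in range(cnt):
            records.append(
                make_record(
                    subject_id=f"S{i:03d}", gleason=gl, pR1=(i < 67),
                    psa_days_values=((90, 0.05), (180, 0.05)),
                )
            )
            i += 1
    return records


class TestSummary:
    def test_printed_percentages(self):
        ds = assemble_dataset(_cohort_with_marginals())
        s = summarize_cohort(ds).set_index(["variable", "category"])
        assert s.loc[("Combined Gleason score", "3+3"), "pct"] == 31.3
        assert s.loc[("Combined Gleason score", "3+4"), "pct"] == 39.4
        assert s.loc[("Combined Gleason score", "4+3"), "pct"] == 21.3
        assert s.loc[("Combined Gleason score", "4+4"), "pct"] == 5.0
        assert s.loc[("Combined Gleason score", "4+5"), "pct"] == 3.1
        assert s.loc[("Primary Gleason pattern", "3"), "n"] == 113
        assert s.loc[("Primary Gleason pattern", "3"), "pct"] == 70.6
        assert s.loc[("Non-localized tumor indicator", "1"), "n"] == 67
        assert s.loc[("Non-localized tumor indicator", "1"), "pct"] == 41.9

    def test_categorical_blocks_sum_to_100(self):
        ds = assemble_dataset(_cohort_with_marginals())
        s = summarize_cohort(ds)
        for var in ("Combined Gleason score", "Primary Gleason pattern"):
            block = s[s["variable"] == var]
            assert block["pct"].astype(float).sum() == pytest.approx(100.0, abs=0.2)


class TestConcordance:
    def test_identical_runs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = run_concordance(x, x)
        assert out["correlation"] == pytest.approx(1.0)
        assert out["crosstab_pct"].loc["run1_observed", "run2_observed"] == 100.0

    def test_independent_runs_near_zero(self):
        rng = np.random.default_rng(0)
        out = run_concordance(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(out["correlation"]) < 0.05

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        out = run_concordance(x, y)
        # direct textbook formula
        r = (((x - x.mean()) * (y - y.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert out["correlation"] == pytest.approx(r)

    def test_missingness_crosstab_and_small_n(self):
        a = np.array([1.0, np.nan, 3.0, np.nan])
        b = np.array([1.5, 2.0, np.nan, np.nan])
        out = run_concordance(a, b)
        tab = out["crosstab_pct"]
        assert tab.loc["run1_observed", "run2_observed"] == 25.0
        assert tab.loc["run1_missing", "run2_missing"] == 25.0
        assert np.isnan(out["correlation"])  # < 3 doubly observed

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            run_concordance(np.ones(3), np.ones(4))


def test_cohort_csv_round_trip(tmp_path):
    recs = [
        make_record(subject_id="A", gleason=(3, 4), pT3=True),
        make_record(subject_id="B", gleason=(4, 4),
                    psa_days_values=((60, 0.25), (150, 0.3))),
    ]
    recs[1].preop_psa = None
    path = tmp_path / "cohort.csv"
    write_cohort_csv(recs, path)
    back = read_cohort_csv(path)
    assert len(back) == 2
    assert back[0].subject_id == "A" and back[0].pT3
    assert back[1].preop_psa is None
    assert back[1].psa_series == recs[1].psa_series
    assert derive_bf_endpoint(back[1]) == derive_bf_endpoint(recs[1])
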