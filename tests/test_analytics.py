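"""Cohort aggregation, odds ratios, logistic regression and longitudinal
summaries."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from transportnlp import (
    DataError,
    NoteResult,
    PatientRecord,
    TwoByTwo,
    YearRateRow,
    aggregate_by_patient,
    clean_note,
    fit_logistic_adjusted,
    interevent_intervals,
    mean_mentions_per_flagged,
    odds_ratio,
    prevalence,
    single_mention_share,
    term_frequency,
    two_by_two,
    yearly_rates,
)
from transportnlp.matcher import MentionMatch

from conftest import make_note


def _patient(pid, events=(), first=date(2018, 1, 1), total=3, **demo):
    defaults = dict(age_band="18-<60", sex="Male", race="White",
                    ethnicity="Non-Hispanic or Latino")
    defaults.update(demo)
    return PatientRecord(
        patient_id=pid,
        first_encounter_date=first,
        total_notes=total,
        mention_events=tuple(events),
        **defaults,
    )


def _result(note_id, pid, when, flagged):
    mention = MentionMatch(
        note_id=note_id, patient_id=pid, sentence_index=0, span=(0, 5),
        matched_phrase="no ride", transport_term_label="ride",
        need_term_label="no", direction="need_first",
    )
    return NoteResult(
        note_id=note_id, patient_id=pid, encounter_date=when,
        mentions=(mention,) if flagged else (),
    )


class TestAggregateByPatient:
    def _demo(self, pids):
        return pd.DataFrame(
            {
                "patient_id": pids,
                "age_band": ["18-<60"] * len(pids),
                "sex": ["Female"] * len(pids),
                "race": ["White"] * len(pids),
                "ethnicity": ["Non-Hispanic or Latino"] * len(pids),
                "first_encounter_date": ["2018-01-01"] * len(pids),
            }
        )

    def test_two_flagged_dates_become_two_events(self):
        notes = [
            clean_note(make_note("t", note_id=f"n{i}", patient_id="p1"))
            for i in range(3)
        ]
        results = [
            _result("n0", "p1", date(2019, 1, 1), True),
            _result("n1", "p1", date(2020, 1, 1), True),
            _result("n2", "p1", date(2020, 6, 1), False),
        ]
        (rec,) = aggregate_by_patient(results, notes, self._demo(["p1"]))
        assert rec.mention_events == (date(2019, 1, 1), date(2020, 1, 1))
        assert rec.total_notes == 3 and rec.flagged

    def test_unflagged_patient(self):
        notes = [clean_note(make_note("t", note_id="n0", patient_id="p1"))]
        results = [_result("n0", "p1", date(2019, 1, 1), False)]
        (rec,) = aggregate_by_patient(results, notes, self._demo(["p1"]))
        assert not rec.flagged and rec.mention_events == ()

    def test_unknown_patient_in_results_rejected(self):
        notes = [clean_note(make_note("t", note_id="n0", patient_id="p1"))]
        results = [_result("nX", "ghost", date(2019, 1, 1), True)]
        with pytest.raises(DataError, match="ghost"):
            aggregate_by_patient(results, notes, self._demo(["p1"]))


class TestPrevalenceAndMeans:
    def test_cohort_scale_prevalence_rounds_to_published_rate(self):
        patients = [
            _patient(f"f{i}", events=[date(2020, 1, 1)]) for i in range(726)
        ] + [_patient(f"u{i}") for i in range(118518 - 726)]
        assert prevalence(patients).percent == "0.6%"

    def test_zero_and_full_prevalence(self):
        cold = [_patient("a"), _patient("b")]
        hot = [_patient("a", events=[date(2020, 1, 1)])]
        assert prevalence(cold).percent == "0.0%"
        assert prevalence(hot).percent == "100.0%"

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            prevalence([])

    def test_mention_distribution_summary(self):
        # event-count distribution: 1x566, 2x97, 3x30, 4x13, 5x5, 6x7,
        # 7x3, 8x2, 9x3 -> 1033 events over 726 patients
        dist = {1: 566, 2: 97, 3: 30, 4: 13, 5: 5, 6: 7, 7: 3, 8: 2, 9: 3}
        patients = []
        i = 0
        for k, n in dist.items():
            for _ in range(n):
                events = [date(2019, 1, 1) + timedelta(days=30 * j) for j in range(k)]
                patients.append(_patient(f"p{i}", events=events))
                i += 1
        assert round(mean_mentions_per_flagged(patients), 2) == 1.42
        assert round(100 * single_mention_share(patients), 1) == 78.0


class TestTermFrequency:
    def test_grouping_counts_notes_and_patients(self):
        mentions = [
            MentionMatch(
                note_id=f"n{i}", patient_id="p1", sentence_index=0, span=(0, 4),
                matched_phrase="no ride", transport_term_label="ride",
                need_term_label="no", direction="need_first",
            )
            for i in range(2)
        ]
        table = term_frequency(mentions)
        assert table.iloc[0].tolist() == ["no ride", 2, 1]

    def test_empty_mentions(self):
        assert term_frequency([]).empty

    def test_sorted_by_hits_then_alphabetical(self):
        def m(phrase, nid):
            return MentionMatch(
                note_id=nid, patient_id=nid, sentence_index=0, span=(0, 4),
                matched_phrase=phrase, transport_term_label="ride",
                need_term_label="no", direction="need_first",
            )

        table = term_frequency(
            [m("b phrase", "1"), m("a phrase", "2"), m("b phrase", "3"),
             m("a phrase", "4"), m("c phrase", "5")]
        )
        assert table["phrase"].tolist() == ["a phrase", "b phrase", "c phrase"]


class TestOddsRatio:
    def test_published_age_band_estimate_and_ci(self):
        res = odds_ratio(TwoByTwo(a=125, b=10837, c=204, d=59015))
        assert round(res.estimate, 2) == 3.34
        assert res.ci_low == pytest.approx(2.67, abs=0.01)
        assert res.ci_high == pytest.approx(4.17, abs=0.01)

    def test_symmetric_table_is_null(self):
        assert odds_ratio(TwoByTwo(1, 1, 1, 1)).estimate == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table,expected",
        [
            (TwoByTwo(441, 68044, 285, 49747), 1.13),  # female vs male
            (TwoByTwo(218, 19685, 204, 59015), 3.20),  # 70-<80 vs 18-<60
            (TwoByTwo(179, 28255, 204, 59015), 1.83),  # 60-<70 vs 18-<60
            (TwoByTwo(1, 5040, 612, 90087), 0.03),     # Asian vs White
        ],
    )
    def test_published_unadjusted_estimates(self, table, expected):
        assert round(odds_ratio(table).estimate, 2) == expected

    def test_zero_cell_gets_haldane_correction_and_flag(self):
        res = odds_ratio(TwoByTwo(0, 10, 5, 10))
        assert res.degenerate
        assert np.isfinite(res.estimate) and res.ci_low < res.estimate < res.ci_high

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_reference_swap_reciprocity(self, cells):
        a, b, c, d = cells
        fwd = odds_ratio(TwoByTwo(a, b, c, d)).estimate
        rev = odds_ratio(TwoByTwo(c, d, a, b)).estimate
        assert fwd * rev == pytest.approx(1.0)

    def test_two_by_two_construction(self):
        patients = (
            [_patient(f"a{i}", events=[date(2020, 1, 1)], age_band=">=80") for i in range(3)]
            + [_patient(f"b{i}", age_band=">=80") for i in range(7)]
            + [_patient(f"c{i}", events=[date(2020, 1, 1)]) for i in range(2)]
            + [_patient(f"d{i}") for i in range(8)]
        )
        t = two_by_two(patients, "age_band", ">=80", "18-<60")
        assert (t.a, t.b, t.c, t.d) == (3, 7, 2, 8)


class TestLogisticRegression:
    def test_one_factor_model_equals_cross_product_ratio(self):
        rng = np.random.default_rng(7)
        patients = []
        for i in range(2000):
            exposed = bool(rng.random() < 0.4)
            p = 0.25 if exposed else 0.1
            flagged = rng.random() < p
            patients.append(
                _patient(
                    f"p{i}",
                    events=[date(2020, 1, 1)] if flagged else (),
                    age_band=">=80" if exposed else "18-<60",
                )
            )
        t = two_by_two(patients, "age_band", ">=80", "18-<60")
        crude = odds_ratio(t).estimate
        (adj,) = fit_logistic_adjusted(patients, ["age_band"])
        assert adj.estimate == pytest.approx(crude, abs=1e-6)

    def test_missing_levels_excluded_per_declared_policy(self):
        patients = [
            _patient("p1", events=[date(2020, 1, 1)], race="Declined or missing"),
            _patient("p2", race="White"),
            _patient("p3", events=[date(2020, 1, 1)], race="Black"),
            _patient("p4", race="Black"),
            _patient("p5", events=[date(2020, 1, 1)], race="White"),
            _patient("p6", race="White"),
        ]
        results = fit_logistic_adjusted(patients, ["race"])
        assert [r.label for r in results] == ["race=Black"]


class TestLongitudinal:
    @pytest.mark.parametrize(
        "total,need,rate", [(2542, 76, 3.0), (5276, 260, 4.9)]
    )
    def test_published_yearly_rates(self, total, need, rate):
        assert YearRateRow(2016, total, need).rate_percent == rate

    def test_yearly_rates_restricted_to_flagged_patients(self):
        patients = [
            _patient("f1", events=[date(2019, 3, 1)]),
            _patient("u1"),
        ]
        results = [
            _result("n1", "f1", date(2019, 3, 1), True),
            _result("n2", "f1", date(2019, 5, 1), False),
            _result("n3", "u1", date(2019, 6, 1), False),  # not flagged patient
        ]
        (row,) = yearly_rates(patients, results)
        assert (row.year, row.total_notes, row.need_count) == (2019, 2, 1)
        assert row.rate_percent == 50.0

    def test_yearly_numerators_sum_to_flagged_notes(self):
        patients = [_patient("f1", events=[date(2019, 3, 1), date(2020, 4, 1)])]
        results = [
            _result("n1", "f1", date(2019, 3, 1), True),
            _result("n2", "f1", date(2020, 4, 1), True),
            _result("n3", "f1", date(2020, 8, 1), False),
        ]
        rows = yearly_rates(patients, results)
        assert sum(r.need_count for r in rows) == 2

    def test_no_flagged_patients_empty_table(self):
        assert yearly_rates([_patient("u1")], []) == []

    def test_single_patient_interval_arithmetic(self):
        first = date(2020, 1, 1)
        rec = _patient(
            "p1",
            events=[first + timedelta(days=10), first + timedelta(days=14)],
            first=first,
        )
        (row,) = interevent_intervals([rec])
        assert row.event_count == 2 and row.n_patients == 1
        assert row.between_median == 4
        assert row.from_first_median == 10

    def test_group_median_of_pooled_gaps(self):
        first = date(2020, 1, 1)
        recs = [
            _patient(
                f"p{i}",
                events=[first, first + timedelta(days=gap)],
                first=first,
            )
            for i, gap in enumerate([2, 4, 100])
        ]
        (row,) = interevent_intervals(recs)
        assert row.between_median == 4
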