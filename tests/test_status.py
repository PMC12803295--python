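"""Completion/error classification, streaks and UpSet combination counts."""

import datetime as dt
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from studyqc import status as stx
from studyqc.schema import example_schema


def status_frame(statuses, site="MCC1-A", visit="baseline", form="imaging"):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(statuses))],
            "site_id": site,
            "cohort": "TKA",
            "visit": visit,
            "form_id": form,
            "status": statuses,
        }
    )


class TestClassifyForm:
    @pytest.mark.parametrize(
        "value, n_flags, applicable, expect",
        [
            (2, 0, True, stx.COMPLETE_NO_ERROR),
            (2, 2, True, stx.COMPLETE_WITH_ERROR),
            (0, 0, True, stx.INCOMPLETE),
            (1, 3, True, stx.INCOMPLETE),  # unverified counts as incomplete, flags irrelevant
            (None, 0, True, stx.UNKNOWN),
            (2, 0, False, stx.NOT_COLLECTED),
        ],
    )
    def test_quadrant_assignment(self, value, n_flags, applicable, expect):
        assert stx.classify_form(value, n_flags, applicable) == expect

    def test_out_of_range_status_warns_and_is_unknown(self):
        with pytest.warns(UserWarning, match="outside"):
            assert stx.classify_form(7, 0, True) == stx.UNKNOWN

    def test_partition_is_total(self, statuses):
        assert set(statuses["status"]) <= set(stx.STATUSES)
        assert not statuses[["subject_id", "visit", "form_id"]].duplicated().any()


class TestQuadrantPercentages:
    def test_hand_enumeration(self):
        frame = status_frame(
            [stx.COMPLETE_NO_ERROR] * 5 + [stx.COMPLETE_WITH_ERROR] * 2 + [stx.INCOMPLETE] * 2 + [stx.UNKNOWN]
        )
        assert stx.quadrant_percentages(frame) == {
            stx.COMPLETE_NO_ERROR: 50.0,
            stx.COMPLETE_WITH_ERROR: 20.0,
            stx.INCOMPLETE: 20.0,
            stx.UNKNOWN: 10.0,
        }

    def test_all_complete(self):
        frame = status_frame([stx.COMPLETE_NO_ERROR] * 4)
        assert stx.quadrant_percentages(frame) == {
            stx.COMPLETE_NO_ERROR: 100.0,
            stx.COMPLETE_WITH_ERROR: 0.0,
            stx.INCOMPLETE: 0.0,
            stx.UNKNOWN: 0.0,
        }

    def test_design_excluded_leaves_denominator(self):
        frame = status_frame([stx.COMPLETE_NO_ERROR, stx.NOT_COLLECTED, stx.NOT_COLLECTED])
        assert stx.quadrant_percentages(frame)[stx.COMPLETE_NO_ERROR] == 100.0

    def test_empty_selection_is_defined(self, statuses):
        assert stx.quadrant_percentages(statuses, sites=["nowhere"]) == {}

    def test_sum_is_100_on_simulated_selections(self, statuses):
        rng = np.random.default_rng(0)
        sites = statuses["site_id"].unique().tolist()
        visits = statuses["visit"].unique().tolist()
        forms = statuses["form_id"].unique().tolist()
        for _ in range(20):
            sel_sites = list(rng.choice(sites, size=rng.integers(1, len(sites) + 1), replace=False))
            sel_visits = list(rng.choice(visits, size=rng.integers(1, len(visits) + 1), replace=False))
            sel_forms = list(rng.choice(forms, size=rng.integers(1, len(forms) + 1), replace=False))
            result = stx.quadrant_percentages(statuses, sel_sites, sel_visits, sel_forms)
            if result:
                assert sum(result.values()) == pytest.approx(100.0, abs=0.21)


class TestStreaks:
    def make_statuses(self, per_form):
        rows = []
        for (visit, form), status in per_form.items():
            rows.append(
                {"subject_id": "s1", "site_id": "MCC1-A", "cohort": "TKA", "visit": visit, "form_id": form,
                 "status": status}
            )
        return pd.DataFrame(rows)

    @pytest.fixture
    def schema_(self):
        return example_schema()

    def test_all_due_complete_no_flags(self, schema_):
        baseline = dt.date(2025, 1, 1)
        as_of = dt.date(2025, 1, 20)  # only baseline and post-op due
        per_form = {("baseline", f): stx.COMPLETE_NO_ERROR for f in stx.DEFAULT_PRIMARY_FORMS}
        per_form.update({("post-op", f): stx.COMPLETE_NO_ERROR for f in stx.DEFAULT_PRIMARY_FORMS})
        result = stx.classify_streak(self.make_statuses(per_form), "TKA", schema_, baseline, as_of)
        assert result == stx.STREAK_NO_ERRORS

    def test_one_flagged_form_makes_streak_with_errors(self, schema_):
        baseline, as_of = dt.date(2025, 1, 1), dt.date(2025, 1, 20)
        per_form = {("baseline", f): stx.COMPLETE_NO_ERROR for f in stx.DEFAULT_PRIMARY_FORMS}
        per_form.update({("post-op", f): stx.COMPLETE_NO_ERROR for f in stx.DEFAULT_PRIMARY_FORMS})
        per_form[("baseline", "qst")] = stx.COMPLETE_WITH_ERROR
        result = stx.classify_streak(self.make_statuses(per_form), "TKA", schema_, baseline, as_of)
        assert result == stx.STREAK_WITH_ERRORS

    def test_missing_due_form_makes_incomplete_streak(self, schema_):
        baseline, as_of = dt.date(2025, 1, 1), dt.date(2025, 1, 20)
        per_form = {("baseline", f): stx.COMPLETE_NO_ERROR for f in stx.DEFAULT_PRIMARY_FORMS}
        per_form.update({("post-op", f): stx.COMPLETE_NO_ERROR for f in stx.DEFAULT_PRIMARY_FORMS})
        del per_form[("baseline", "imaging")]  # 3/4 due forms complete
        result = stx.classify_streak(self.make_statuses(per_form), "TKA", schema_, baseline, as_of)
        assert result == stx.STREAK_INCOMPLETE

    def test_future_visits_never_penalize(self, schema_):
        baseline, as_of = dt.date(2025, 1, 1), dt.date(2025, 1, 2)  # only baseline due
        per_form = {("baseline", f): stx.COMPLETE_NO_ERROR for f in stx.DEFAULT_PRIMARY_FORMS}
        result = stx.classify_streak(self.make_statuses(per_form), "TKA", schema_, baseline, as_of)
        assert result == stx.STREAK_NO_ERRORS

    def test_streaks_partition_subjects(self, study, statuses, records):
        table = stx.streak_table(statuses, records, study.schema, study.config.as_of)
        assert not table["subject_id"].duplicated().any()
        assert set(table["streak"]) <= {stx.STREAK_NO_ERRORS, stx.STREAK_WITH_ERRORS, stx.STREAK_INCOMPLETE}
        baselines = stx.baseline_dates(records, study.schema)
        assert len(table) == len(baselines)


def brute_force_combinations(membership, tracked):
    """Oracle: enumerate all 2^k subsets and count exact matches per site."""
    counts = {}
    for site, group in membership.groupby("site_id"):
        for subset in product([False, True], repeat=len(tracked)):
            n = int((group[list(tracked)] == pd.Series(dict(zip(tracked, subset)))).all(axis=1).sum())
            if n:
                counts[(site, subset)] = n
    return counts


class TestCombinationCounts:
    def test_hand_example(self):
        membership = pd.DataFrame(
            {"subject_id": ["s1", "s2", "s3"], "site_id": "X", "A": [True, True, True], "B": [True, True, False]}
        )
        combos = (
            membership.groupby(["site_id", "A", "B"], as_index=False).agg(count=("subject_id", "size"))
        )
        lookup = {(r.A, r.B): r.count for r in combos.itertuples()}
        assert lookup == {(True, True): 2, (True, False): 1}

    def test_exclusive_counts_match_brute_force(self, study, statuses, records):
        tracked = tuple(f.form_id for f in study.schema.forms)[:6]
        membership = stx.upset_membership_matrix(
            statuses, records, study.schema, study.config.as_of, "late", tracked
        )
        combos = stx.combination_counts(statuses, records, study.schema, study.config.as_of, "late", tracked)
        oracle = brute_force_combinations(membership, tracked)
        ours = {(r.site_id, tuple(getattr(r, f) for f in tracked)): r.count for r in combos.itertuples()}
        assert ours == oracle

    @pytest.mark.parametrize("anchor", ["early", "late"])
    def test_partition_and_marginal_identities(self, study, statuses, records, anchor):
        membership = stx.upset_membership_matrix(statuses, records, study.schema, study.config.as_of, anchor)
        combos = stx.combination_counts(statuses, records, study.schema, study.config.as_of, anchor)
        assert combos["count"].sum() == len(membership)  # exclusive subsets partition the stratum
        marginals = stx.marginal_counts(combos)
        tracked = [c for c in membership.columns if c not in ("subject_id", "site_id")]
        for row in marginals.itertuples():
            direct = int(membership.loc[membership["site_id"] == row.site_id, row.form_id].sum())
            assert row.count == direct

    def test_unknown_anchor_rejected(self, study, statuses, records):
        with pytest.raises(ValueError, match="anchor"):
            stx.combination_counts(statuses, records, study.schema, study.config.as_of, "middle")


@given(
    bits=st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()), min_size=1, max_size=40)
)
def test_combination_identities_random_matrices(bits):
    """Exclusive counts sum to n and marginals equal subset-sums on random
    membership matrices (3 forms, enumerable by brute force)."""
    tracked = ["f1", "f2", "f3"]
    membership = pd.DataFrame(bits, columns=tracked)
    membership.insert(0, "subject_id", [f"s{i}" for i in range(len(bits))])
    membership.insert(1, "site_id", "X")
    combos = membership.groupby(["site_id", *tracked], as_index=False).agg(count=("subject_id", "size"))
    assert combos["count"].sum() == len(membership)
    oracle = brute_force_combinations(membership, tracked)
    assert sum(oracle.values()) == len(membership)
    for form in tracked:
        marginal = combos.loc[combos[form], "count"].sum()
        assert marginal == membership[form].sum()


class TestCellCodes:
    def test_colors_follow_statuses(self, statuses, flags):
        codes = stx.cell_codes(statuses, flags)
        mapping = dict(zip(codes["status"], codes["color"]))
        assert mapping[stx.COMPLETE_NO_ERROR] == "blue"
        assert mapping[stx.COMPLETE_WITH_ERROR] == "green"
        assert mapping[stx.NOT_COLLECTED] == "yellow"
        green = codes[codes["color"] == "green"]
        assert (green["tooltip"] != "").all()
        assert (codes.loc[codes["color"] == "blue", "tooltip"] == "").all()
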