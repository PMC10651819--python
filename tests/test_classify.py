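"""Cutoff derivation, marker flagging, categories, transitions, survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from frailtykit import (
    CohortValidationError,
    classify,
    classify_cohort,
    derive_cutoffs,
    flag_positive,
    survival_rate,
    track_transitions,
)
from frailtykit.classify import DEFAULT_ORIENTATION, HIGHER, LOWER
from frailtykit.metrics import CRITERIA


def make_panels(values, criterion="td", sex="female", timepoint="baseline"):
    """Panels with one varying criterion; the others held constant at 1."""
    rows = []
    for i, v in enumerate(values):
        row = {"animal_id": f"x{i:03d}", "timepoint": timepoint, "sex": sex}
        for crit in CRITERIA:
            row[crit] = 1.0
        row[criterion] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def count_below_oracle(values, p=0.2):
    """Brute-force sort-and-count: how many values fall strictly below the
    linearly interpolated order-statistic quantile at index (n-1)*p."""
    s = sorted(values)
    h = (len(s) - 1) * p
    lo = int(np.floor(h))
    frac = h - lo
    cutoff = s[lo] + frac * (s[lo + 1] - s[lo]) if frac > 0 else s[lo]
    return sum(1 for v in values if v < cutoff)


class TestDeriveCutoffs:
    def test_interpolated_quantile_on_1_to_10(self):
        cuts = derive_cutoffs(make_panels(range(1, 11)))
        td = cuts.set_index("criterion").loc["td"]
        assert td["cutoff"] == pytest.approx(2.8)
        assert td["n_used"] == 10

    def test_interpolated_quantile_on_tens(self):
        cuts = derive_cutoffs(make_panels([10, 20, 30, 40, 50]))
        assert cuts.set_index("criterion").loc["td", "cutoff"] == pytest.approx(18.0)

    def test_degenerate_equal_values_flag_nobody(self):
        panels = make_panels([7.0] * 8)
        cuts = derive_cutoffs(panels)
        assert cuts.set_index("criterion").loc["td", "cutoff"] == 7.0
        cls = classify_cohort(panels, cuts)
        assert not cls["td_positive"].any()

    def test_fi_cutoff_stored_on_negated_scale(self):
        panels = make_panels([0.1, 0.2, 0.3, 0.4, 0.5], criterion="fi")
        cuts = derive_cutoffs(panels)
        fi = cuts.set_index("criterion").loc["fi"]
        assert fi["orientation"] == HIGHER
        # oriented values are -0.5..-0.1; 20th percentile = -0.42
        assert fi["cutoff"] == pytest.approx(-0.42)

    def test_too_few_reference_animals_names_sex_and_criterion(self):
        with pytest.raises(CohortValidationError, match="sex 'female', criterion"):
            derive_cutoffs(make_panels([1, 2, 3]))

    def test_all_missing_criterion_is_an_error(self):
        panels = make_panels(range(1, 11))
        panels["vrw"] = np.nan
        with pytest.raises(CohortValidationError, match="vrw"):
            derive_cutoffs(panels)


class TestFlagPositive:
    def test_strictly_below_cutoff_is_positive(self):
        panels = make_panels(range(1, 11))
        cuts = derive_cutoffs(panels)
        row = panels.iloc[1].copy()  # td = 2 < 2.8
        assert flag_positive(row, cuts)["td"] is True

    def test_value_at_cutoff_is_not_positive(self):
        panels = make_panels(range(1, 11))
        cuts = derive_cutoffs(panels)
        row = panels.iloc[0].copy()
        row["td"] = 2.8
        assert flag_positive(row, cuts)["td"] is False

    def test_higher_is_frailer_orientation_hand_check(self):
        cuts = pd.DataFrame(
            [{"sex": "female", "criterion": c,
              "cutoff": -0.35 if c == "fi" else 0.0,
              "orientation": DEFAULT_ORIENTATION[c], "n_used": 10}
             for c in CRITERIA]
        )
        row = {"animal_id": "x", "timepoint": "baseline", "sex": "female",
               **{c: 1.0 for c in CRITERIA}}
        row["fi"] = 0.40  # oriented -0.40 < -0.35 → positive
        assert flag_positive(row, cuts)["fi"] is True
        row["fi"] = 0.30  # oriented -0.30 >= -0.35 → negative
        assert flag_positive(row, cuts)["fi"] is False

    def test_missing_criterion_counts_negative_with_warning(self, caplog):
        panels = make_panels(range(1, 11))
        cuts = derive_cutoffs(panels)
        row = panels.iloc[1].copy()
        row["vrw"] = np.nan
        with caplog.at_level("WARNING"):
            markers = flag_positive(row, cuts)
        assert markers["vrw"] is False
        assert "vrw" in caplog.text

    def test_unknown_sex_is_an_error(self):
        cuts = derive_cutoffs(make_panels(range(1, 11)))
        row = {"animal_id": "x", "sex": "male", **{c: 1.0 for c in CRITERIA}}
        with pytest.raises(CohortValidationError, match="male"):
            flag_positive(row, cuts)


class TestClassify:
    def test_enumerated_rule(self):
        expected = ["robust", "robust", "prefrail", "frail", "frail", "frail", "frail"]
        assert [classify(t) for t in range(7)] == expected

    @pytest.mark.parametrize("bad", [-1, 7, 2.5, "two"])
    def test_invalid_tally_rejected(self, bad):
        with pytest.raises(CohortValidationError):
            classify(bad)

    @given(st.integers(0, 5))
    def test_monotone_never_toward_robust(self, tally):
        order = {"robust": 0, "prefrail": 1, "frail": 2}
        assert order[classify(tally + 1)] >= order[classify(tally)]


class TestPercentileCoverage:
    def test_exactly_20_of_100_distinct_fall_below(self, rng):
        values = rng.permutation(np.arange(1.0, 101.0))
        panels = make_panels(values)
        cuts = derive_cutoffs(panels)
        cls = classify_cohort(panels, cuts)
        assert int(cls["td_positive"].sum()) == 20

    @pytest.mark.parametrize("n", [5, 9, 10, 21, 37, 50, 99, 100, 137, 200])
    def test_matches_sort_and_count_oracle(self, n, rng):
        values = rng.normal(100, 20, size=n)
        assert len(set(values)) == n  # tie-free
        panels = make_panels(values)
        cls = classify_cohort(panels, derive_cutoffs(panels))
        assert int(cls["td_positive"].sum()) == count_below_oracle(values)


class TestInvariances:
    def test_cutoffs_ignore_adult_animals(self, rng):
        """Adding non-reference animals to the pipeline input must not
        change the cutoff table (it is derived from Old baseline only)."""
        from frailtykit.report import select_reference_panels

        old = make_panels(rng.uniform(40, 120, size=12))
        old["group"] = "old_vehicle"
        adult = make_panels(rng.uniform(100, 160, size=10))
        adult["animal_id"] = ["ad" + i for i in adult["animal_id"]]
        adult["group"] = "adult"
        cuts_old_only = derive_cutoffs(select_reference_panels(old))
        cuts_with_adults = derive_cutoffs(
            select_reference_panels(pd.concat([old, adult], ignore_index=True))
        )
        pd.testing.assert_frame_equal(cuts_old_only, cuts_with_adults)

    def test_orientation_flip_leaves_classifications_unchanged(self, rng):
        values = rng.uniform(10, 50, size=20)
        panels = make_panels(values, criterion="vrw")
        panels[["ws", "gft", "td", "fi", "dbw"]] = rng.uniform(
            1, 2, size=(20, 5)
        )
        base_cls = classify_cohort(panels, derive_cutoffs(panels))

        flipped = panels.copy()
        flipped["vrw"] = -flipped["vrw"]
        orientation = dict(DEFAULT_ORIENTATION, vrw=HIGHER)
        flip_cls = classify_cohort(
            flipped, derive_cutoffs(flipped, orientation=orientation), orientation
        )
        pd.testing.assert_frame_equal(base_cls, flip_cls)


class TestTransitions:
    @staticmethod
    def _cls(pairs, timepoint):
        return pd.DataFrame(
            [{"animal_id": a, "timepoint": timepoint, "category": c} for a, c in pairs],
            columns=["animal_id", "timepoint", "category"],
        )

    def test_direct_count(self):
        baseline = self._cls([("a", "robust"), ("b", "robust"), ("c", "prefrail")],
                             "baseline")
        endpoint = self._cls([("a", "robust"), ("b", "frail"), ("c", "robust")],
                             "endpoint")
        tm = track_transitions(baseline, endpoint)
        assert tm.counts.loc["robust", "robust"] == 1
        assert tm.counts.loc["robust", "frail"] == 1
        assert tm.counts.loc["prefrail", "robust"] == 1
        assert tm.counts.to_numpy().sum() == 3 and tm.lost.sum() == 0
        assert tm.fraction_robust_declined() == pytest.approx(0.5)
        assert tm.fraction_improved() == pytest.approx(1.0)

    def test_identical_classifications_are_diagonal(self):
        pairs = [("a", "robust"), ("b", "prefrail"), ("c", "frail")]
        tm = track_transitions(self._cls(pairs, "baseline"), self._cls(pairs, "endpoint"))
        assert np.trace(tm.counts.to_numpy()) == 3
        assert tm.counts.to_numpy().sum() == 3

    def test_death_goes_to_lost_and_totals_conserve(self):
        baseline = self._cls([("a", "robust"), ("b", "frail")], "baseline")
        endpoint = self._cls([("a", "robust")], "endpoint")
        tm = track_transitions(baseline, endpoint)
        assert tm.lost["frail"] == 1
        assert tm.total == 2
        frame = tm.to_frame()
        assert frame["count"].sum() == 2

    def test_endpoint_orphan_is_an_error(self):
        baseline = self._cls([("a", "robust")], "baseline")
        endpoint = self._cls([("a", "robust"), ("z", "frail")], "endpoint")
        with pytest.raises(CohortValidationError, match="z"):
            track_transitions(baseline, endpoint)

    @given(st.lists(st.sampled_from(["robust", "prefrail", "frail"]),
                    min_size=1, max_size=30),
           st.data())
    def test_conservation_property(self, baseline_cats, data):
        baseline = self._cls(
            [(f"m{i}", c) for i, c in enumerate(baseline_cats)], "baseline"
        )
        survivors = [
            (f"m{i}", data.draw(st.sampled_from(["robust", "prefrail", "frail"])))
            for i in range(len(baseline_cats))
            if data.draw(st.booleans())
        ]
        tm = track_transitions(baseline, self._cls(survivors, "endpoint"))
        assert tm.total == len(baseline_cats)
        # row totals: classified-at-both plus lost per baseline category
        for cat in ("robust", "prefrail", "frail"):
            expected = sum(1 for c in baseline_cats if c == cat)
            assert tm.counts.loc[cat].sum() + tm.lost[cat] == expected


class TestSurvival:
    def test_rates(self):
        animals = pd.DataFrame(
            [{"animal_id": f"m{i}", "sex": "female", "group": "old_vehicle",
              "alive_at_endpoint": i >= 2} for i in range(20)]
        )
        assert survival_rate(animals, "old_vehicle", "female") == pytest.approx(90.0)
        animals["alive_at_endpoint"] = True
        assert survival_rate(animals, "old_vehicle", "female") == 100.0
        animals["alive_at_endpoint"] = False
        assert survival_rate(animals, "old_vehicle", "female") == 0.0

    def test_empty_cell_is_an_error(self):
        animals = pd.DataFrame(
            [{"animal_id": "m0", "sex": "female", "group": "adult",
              "alive_at_endpoint": True}]
        )
        with pytest.raises(CohortValidationError, match="old_pdx"):
            survival_rate(animals, "old_pdx", "male")
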