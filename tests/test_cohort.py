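"""Per-person assembly, truncation, and Table-style summaries."""

import datetime

import numpy as np
import pandas as pd
import pytest

import thyrodose as td
from conftest import make_person


class TestPersonRecordValidation:
    def test_birth_after_epoch_rejected(self):
        with pytest.raises(ValueError, match="closed cohort"):
            make_person(birth_date=datetime.date(1990, 1, 1))

    def test_noncontiguous_residences_rejected(self):
        with pytest.raises(ValueError, match="not contiguous"):
            make_person(
                residences=(
                    td.Residence("L1", 0, 100),
                    td.Residence("L2", 150, td.FOLLOWUP_DAYS),
                )
            )

    def test_history_must_cover_followup(self):
        with pytest.raises(ValueError, match="ends at day"):
            make_person(residences=(td.Residence("L1", 0, 100),))


class TestPersonDose:
    def test_single_residence_reduces_to_pathway_calls(self, depmap, params):
        person = make_person()
        r = td.person_dose(person, depmap, params)
        t = float(td.FOLLOWUP_DAYS)
        dep = depmap["L1"]
        assert r.d_milk == pytest.approx(td.milk_iodine_dose(dep, t, params.milk))
        assert r.d_inh == pytest.approx(td.inhalation_dose(dep, params.inhalation))
        assert r.d_ext == pytest.approx(
            td.external_dose(dep, "F", t, params.external), rel=1e-12
        )
        assert r.d_cs_ing == pytest.approx(
            td.cs_ingestion_dose(dep, "F", t, params.cs_ingestion), rel=1e-12
        )

    def test_additivity_of_components(self, depmap, params):
        r = td.person_dose(make_person(sex="M"), depmap, params)
        assert r.d_total == pytest.approx(
            r.d_milk + r.d_inh + r.d_ext + r.d_cs_ing, rel=1e-10
        )

    def test_splitting_a_residence_changes_nothing(self, depmap, params):
        whole = make_person()
        split = make_person(
            residences=(
                td.Residence("L1", 0, 4000),
                td.Residence("L1", 4000, td.FOLLOWUP_DAYS),
            )
        )
        a = td.person_dose(whole, depmap, params)
        b = td.person_dose(split, depmap, params)
        for comp in td.cohort.COMPONENTS:
            assert getattr(b, comp) == pytest.approx(getattr(a, comp), rel=1e-10)

    def test_moving_to_higher_deposition_raises_protracted_dose(self, depmap, params):
        stay = make_person()
        move = make_person(
            residences=(
                td.Residence("L1", 0, 2000),
                td.Residence("L2", 2000, td.FOLLOWUP_DAYS),
            )
        )
        a = td.person_dose(stay, depmap, params)
        b = td.person_dose(move, depmap, params)
        assert b.d_ext > a.d_ext
        assert b.d_cs_ing > a.d_cs_ing
        # acute iodine pathways keyed to the epoch residence: unchanged
        assert b.d_milk == pytest.approx(a.d_milk)
        assert b.d_inh == pytest.approx(a.d_inh)
        # freeze mode ignores the move entirely
        frozen = td.person_dose(move, depmap, params, freeze_epoch_residence=True)
        for comp in td.cohort.COMPONENTS:
            assert getattr(frozen, comp) == pytest.approx(getattr(a, comp), rel=1e-10)

    def test_truncation_monotonicity(self, depmap, params):
        long = td.person_dose(make_person(), depmap, params)
        short = td.person_dose(make_person(followup_day=3000), depmap, params)
        for comp in td.cohort.COMPONENTS:
            assert getattr(short, comp) <= getattr(long, comp)

    def test_followup_ending_at_epoch_gives_zero_dose(self, depmap, params):
        person = make_person(
            residences=(td.Residence("L1", 0, 0),), followup_day=0, end_reason="death"
        )
        r = td.person_dose(person, depmap, params)
        assert r.d_total == 0.0

    def test_unknown_location_names_person(self, params):
        person = make_person()
        with pytest.raises(KeyError, match="person P1.*L1"):
            td.person_dose(person, {}, params)


class TestCohortDoses:
    def test_single_person_matches_person_dose(self, depmap, params):
        person = make_person()
        df = td.cohort_doses([person], depmap, params)
        r = td.person_dose(person, depmap, params)
        assert len(df) == 1
        assert df.loc[0, "d_total"] == pytest.approx(r.d_total, rel=1e-12)

    def test_order_invariance(self, depmap, params):
        people = [
            make_person(person_id=f"P{i}", sex="M" if i % 2 else "F")
            for i in range(5)
        ]
        a = td.cohort_doses(people, depmap, params)
        b = td.cohort_doses(list(reversed(people)), depmap, params)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_total_matches_independent_recomputation(self, depmap, params):
        cfg = td.ScenarioConfig(seed=11, n_persons=1000, n_locations=10)
        dep, cohort = td.generate_scenario(cfg)
        dm = {d.location_id: d for d in dep}
        df = td.cohort_doses(cohort, dm, params)
        expected = np.mean(
            [td.person_dose(p, dm, params).d_total for p in cohort]
        )
        assert df["d_total"].mean() == pytest.approx(expected, rel=1e-12)

    def test_empty_cohort_rejected(self, depmap, params):
        with pytest.raises(ValueError):
            td.cohort_doses([], depmap, params)


class TestSummarize:
    def test_constant_input_collapses_all_statistics(self):
        df = pd.DataFrame(
            {
                "person_id": ["a", "b", "c"],
                "sex": ["F", "F", "F"],
                "d_milk": 0.5,
                "d_inh": 0.5,
                "d_ext": 0.5,
                "d_cs_ing": 0.5,
                "d_total": 2.0,
            }
        )
        with pytest.warns(UserWarning, match="sex 'M'"):
            summary = td.summarize(df)
        row = summary[(summary.sex == "F") & (summary.component == "d_total")].iloc[0]
        for stat in ("mean", "median", "p5", "p95", "min", "max"):
            assert row[stat] == 2.0

    def test_two_values(self):
        df = pd.DataFrame(
            {
                "person_id": ["a", "b"],
                "sex": ["M", "M"],
                "d_milk": [1.0, 3.0],
                "d_inh": 0.0,
                "d_ext": 0.0,
                "d_cs_ing": 0.0,
                "d_total": [1.0, 3.0],
            }
        )
        with pytest.warns(UserWarning):
            s = td.summarize(df)
        row = s[(s.sex == "M") & (s.component == "d_milk")].iloc[0]
        assert row["mean"] == 2.0
        assert row["min"] == 1.0
        assert row["max"] == 3.0

    def test_percentiles_match_sort_based_oracle(self):
        rng = np.random.default_rng(42)
        totals = np.exp(rng.normal(0.5, 0.7, size=10_000))
        df = pd.DataFrame(
            {
                "person_id": [f"p{i}" for i in range(len(totals))],
                "sex": "F",
                "d_milk": 0.0,
                "d_inh": 0.0,
                "d_ext": 0.0,
                "d_cs_ing": totals,
                "d_total": totals,
            }
        )
        with pytest.warns(UserWarning):
            s = td.summarize(df)
        row = s[(s.sex == "F") & (s.component == "d_total")].iloc[0]
        # type-7: linear interpolation between order statistics
        x = np.sort(totals)
        for q, col in ((0.05, "p5"), (0.95, "p95")):
            h = (len(x) - 1) * q
            lo = int(np.floor(h))
            expected = x[lo] + (h - lo) * (x[lo + 1] - x[lo])
            assert row[col] == pytest.approx(expected, rel=1e-12)

    def test_quantile_ordering_and_mean_bounds(self, depmap, params):
        cfg = td.ScenarioConfig(seed=3, n_persons=400, n_locations=10)
        dep, cohort = td.generate_scenario(cfg)
        dm = {d.location_id: d for d in dep}
        s = td.summarize(td.cohort_doses(cohort, dm, params))
        assert (s["min"] <= s["p5"]).all()
        assert (s["p5"] <= s["median"]).all()
        assert (s["median"] <= s["p95"]).all()
        assert (s["p95"] <= s["max"]).all()
        assert ((s["mean"] >= s["min"]) & (s["mean"] <= s["max"])).all()

    def test_mean_total_is_sum_of_component_means(self, depmap, params):
        cfg = td.ScenarioConfig(seed=5, n_persons=300, n_locations=8)
        dep, cohort = td.generate_scenario(cfg)
        dm = {d.location_id: d for d in dep}
        s = td.summarize(td.cohort_doses(cohort, dm, params))
        for sex in ("F", "M"):
            g = s[s.sex == sex].set_index("component")["mean"]
            assert g["d_total"] == pytest.approx(
                g["d_milk"] + g["d_inh"] + g["d_ext"] + g["d_cs_ing"], rel=1e-10
            )


class TestCumulativeCurves:
    def test_grid_zero_gives_zero(self, depmap, params):
        curves = td.cumulative_curves([make_person()], depmap, params, [0])
        assert (curves["mean_mGy"] == 0.0).all()

    def test_final_point_matches_summary_means(self, depmap, params):
        cfg = td.ScenarioConfig(seed=9, n_persons=60, n_locations=5)
        dep, cohort = td.generate_scenario(cfg)
        dm = {d.location_id: d for d in dep}
        curves = td.cumulative_curves(cohort, dm, params, [0, 5000, td.FOLLOWUP_DAYS])
        summary = td.summarize(td.cohort_doses(cohort, dm, params))
        final = curves[curves.day == td.FOLLOWUP_DAYS]
        for _, row in final.iterrows():
            expected = summary[
                (summary.sex == row.sex) & (summary.component == row.component)
            ].iloc[0]["mean"]
            assert row.mean_mGy == pytest.approx(expected, rel=1e-10, abs=1e-14)

    def test_curves_monotone(self, depmap, params):
        grid = [0, 365, 2000, 6000, td.FOLLOWUP_DAYS]
        curves = td.cumulative_curves(
            [make_person(), make_person(person_id="P2", sex="M")],
            depmap,
            params,
            grid,
        )
        for (sex, comp), g in curves.groupby(["sex", "component"]):
            values = g.sort_values("day")["mean_mGy"].to_numpy()
            assert (np.diff(values) >= -1e-15).all()

    def test_iodine_curve_flat_after_first_year(self, depmap, params):
        grid = [365, 2000, td.FOLLOWUP_DAYS]
        curves = td.cumulative_curves([make_person()], depmap, params, grid)
        milk = curves[curves.component == "d_milk"].sort_values("day")
        values = milk["mean_mGy"].to_numpy()
        assert values[-1] - values[0] < 1e-3 * values[-1]

    def test_non_monotone_grid_rejected(self, depmap, params):
        with pytest.raises(ValueError, match="increasing"):
            td.cumulative_curves([make_person()], depmap, params, [0, 100, 100])
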