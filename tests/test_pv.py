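"""Disproportionality analysis: dedup, rollups, ROR arithmetic, screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrpv.errors import UnknownTermError, ZeroCellError
from mrpv.faers import ReportDatabase, ReportRecord, deduplicate
from mrpv.signal import (
    ContingencyTable,
    DisproportionalityScreen,
    control_validation,
    describe,
    rollup_events,
    ror,
    screen,
)
from mrpv.simulate import generate_report_db, headline_pv_scenario, pv_null_scenario


class TestDeduplicate:
    def test_highest_version_survives(self, tiny_records):
        out = deduplicate(tiny_records)
        by_case = {r.caseid: r for r in out}
        assert by_case[1].version == 2 and by_case[1].primaryid == 12
        assert len(out) == 4

    def test_identity_when_no_shared_caseids(self, tiny_records):
        unique = [r for r in tiny_records if r.primaryid != 12]
        assert deduplicate(unique) == sorted(unique, key=lambda r: r.primaryid)

    def test_tie_broken_by_primaryid(self):
        recs = [
            ReportRecord(5, 9, 1, [("d", "PS")], ["x"]),
            ReportRecord(8, 9, 1, [("d", "PS")], ["x"]),
        ]
        assert deduplicate(recs)[0].primaryid == 8

    def test_generated_duplicate_contract(self):
        from dataclasses import replace

        scenario = replace(pv_null_scenario(seed=1, n_reports=1000), duplicate_rate=0.2)
        db = generate_report_db(scenario)
        assert db.deduplicate().n_reports == 1000 - 200


class TestRollup:
    def test_set_collapse_at_hlgt(self, small_hierarchy, tiny_db):
        sets = rollup_events(tiny_db, small_hierarchy, "HLGT")
        # PTs 0 and 1 share the HLT/HLGT chain in the generated tree
        assert sets[12] == {small_hierarchy.rollup(sorted(small_hierarchy.pts())[0], "HLGT")}

    def test_smq_scope_membership(self, small_hierarchy, tiny_db):
        narrow = rollup_events(tiny_db, small_hierarchy, "smq_test", scope="narrow")
        broad = rollup_events(tiny_db, small_hierarchy, "smq_test", scope="broad")
        # report 21 carries only the third PT: broad case but not narrow case
        assert narrow[21] == frozenset()
        assert broad[21] == {"smq_test"}
        n_narrow = sum(bool(s) for s in narrow.values())
        n_broad = sum(bool(s) for s in broad.values())
        assert n_broad >= n_narrow

    def test_unknown_pt_raises(self, small_hierarchy):
        db = ReportDatabase.from_records(
            [ReportRecord(1, 1, 1, [("d", "PS")], ["not_a_term"])]
        )
        with pytest.raises(UnknownTermError):
            rollup_events(db, small_hierarchy, "SOC")


class TestROR:
    def test_hand_computed_example(self):
        res = ror(ContingencyTable(10, 90, 100, 9900))
        assert res.ror == pytest.approx(11.0)
        se = np.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert se == pytest.approx(0.3482, abs=2e-4)
        assert res.ci_low == pytest.approx(5.56, abs=0.01)
        assert res.ci_high == pytest.approx(21.77, abs=0.01)
        assert res.is_signal  # a >= 3 and ci_low > 1

    def test_symmetric_table(self):
        res = ror(ContingencyTable(50, 50, 50, 50))
        assert res.ror == pytest.approx(1.0)
        assert np.log(res.ci_low) == pytest.approx(-np.log(res.ci_high))

    def test_min_case_gate(self):
        res = ror(ContingencyTable(2, 10, 10, 10_000))
        assert res.ci_low > 1 and not res.is_signal

    def test_zero_cell_handling(self):
        with pytest.raises(ZeroCellError):
            ror(ContingencyTable(0, 10, 10, 10))
        res = ror(ContingencyTable(0, 10, 10, 10), correction="haldane")
        assert res.ror == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_swap_reciprocal_property(self, a, b, c, d):
        direct = ror(ContingencyTable(a, b, c, d))
        swapped = ror(ContingencyTable(c, d, a, b))
        assert swapped.ror == pytest.approx(1.0 / direct.ror)
        assert swapped.ci_low == pytest.approx(1.0 / direct.ci_high)

    @given(a=st.integers(2, 300), b=st.integers(1, 300),
           c=st.integers(1, 300), d=st.integers(1, 300))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_in_a(self, a, b, c, d):
        lo = ror(ContingencyTable(a - 1, b, c, d)).ror
        hi = ror(ContingencyTable(a, b, c, d)).ror
        assert hi > lo

    def test_against_generic_oracle(self, rng):
        from statsmodels.stats.contingency_tables import Table2x2

        for _ in range(25):
            a, b, c, d = rng.integers(1, 400, size=4)
            ours = ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            oracle = Table2x2(np.array([[a, b], [c, d]]))
            lo, hi = oracle.oddsratio_confint(0.05)
            assert ours.ror == pytest.approx(oracle.oddsratio, abs=1e-9)
            assert ours.ci_low == pytest.approx(lo, abs=1e-9)
            assert ours.ci_high == pytest.approx(hi, abs=1e-9)


class TestScreen:
    def test_cells_sum_to_stratum_size(self):
        scenario = pv_null_scenario(seed=6, n_reports=5000)
        db = generate_report_db(scenario)
        dedup = db.deduplicate()
        res = screen(db, scenario.hierarchy, ["glp1_ra"], level="SOC")
        for r in res.results:
            assert r.a + r.b + r.c + r.d == dedup.n_reports

    def test_ps_role_defines_target_margin(self, small_hierarchy, tiny_db):
        # drugA appears as concomitant on report 21; that report must stay
        # in the comparator margin
        res = screen(tiny_db, small_hierarchy, ["drugA"], level="SOC",
                     correction="haldane", min_cases=1)
        assert all(r.a + r.b == 2 for r in res.results)  # two PS-drugA cases

    def test_empty_stratum_not_evaluable(self, small_hierarchy, tiny_db):
        res = screen(
            tiny_db, small_hierarchy, ["drugB"], level="SOC",
            stratum={"indication": "weight_loss"},
        )
        assert all(not r.evaluable for r in res.results)
        assert res.n_tests == 0

    def test_model_front_end_summary(self, small_hierarchy, tiny_db):
        model = DisproportionalityScreen(tiny_db, small_hierarchy)
        res = model.fit(["drugA"], level="SOC", correction="haldane", min_cases=1)
        text = res.summary()
        assert "event sets tested" in text and "SOC" in text

    def test_stratified_planting_confined_to_stratum(self):
        """The headline design: a suicide-SMQ signal planted only for the
        weight-loss indication appears there and not in the glucose stratum."""
        scenario = headline_pv_scenario(seed=7, n_reports=120_000)
        db = generate_report_db(scenario)
        wl = screen(db, scenario.hierarchy, ["glp1_ra"], level="SMQ",
                    event_sets=["suicide_self_harm"],
                    stratum={"indication": "weight_loss"}).results[0]
        gl = screen(db, scenario.hierarchy, ["glp1_ra"], level="SMQ",
                    event_sets=["suicide_self_harm"],
                    stratum={"indication": "glucose_lowering"}).results[0]
        assert wl.is_signal
        assert wl.ror > gl.ror
        assert not gl.is_signal


class TestControlsAndDescribe:
    def test_positive_and_negative_controls(self):
        scenario = headline_pv_scenario(seed=3, n_reports=120_000)
        db = generate_report_db(scenario)
        report = control_validation(
            db,
            scenario.hierarchy,
            {
                "venlafaxine": {"suicide_self_harm": True, "mood_disorders": True},
                "sitagliptin": {"suicide_self_harm": False},
            },
        )
        assert report.passed

    def test_empty_control_map(self, small_hierarchy, tiny_db):
        assert control_validation(tiny_db, small_hierarchy, {}).checks == []

    def test_failed_control_warns(self, small_hierarchy, tiny_db):
        with pytest.warns(UserWarning, match="control validation failed"):
            report = control_validation(
                tiny_db, small_hierarchy, {"drugA": {"smq_test": True}},
            )
        assert not report.passed

    def test_describe_counts_by_construction(self, tiny_db):
        out = describe(tiny_db)
        assert out["n_reports"] == 4  # after dedup
        sex = out["sex"]
        assert int(sex.loc["F", "count"]) == 1
        assert int(sex.loc["M", "count"]) == 2
        assert sex["pct"].sum() <= 100.0 + 1e-9


def test_planted_ci_coverage():
    """95% Wald interval for a planted PT-level OR achieves nominal coverage."""
    from mrpv.evaluation import pv_ci_coverage_study

    out = pv_ci_coverage_study(n_seeds=1000, ror_true=2.0, n_reports=10_000, seed=2)
    assert 0.93 <= out["coverage"] <= 0.97
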