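"""The residual-mortality cascade: attribution, conservation, interaction."""

import numpy as np
import pandas as pd
import pytest

from averted.cascade import (
    BurdenProfile,
    aggregate_package,
    cascade_order,
    project,
    read_burden,
    round_half_up,
    run_cascade,
    single_impact,
    write_burden,
)
from averted.errors import ConfigError, DegenerateBaselineError
from averted.scenarios import EffectivenessEntry, Intervention, Scenario


def eff(e, af=1.0, cause="pneumonia"):
    return EffectivenessEntry(cause=cause, effectiveness=e, affected_fraction=af)


def iv(id, klass, effects, c0=0.0, sub=None):
    return Intervention(
        id=id, name=id, intervention_class=klass, baseline_coverage=c0,
        effects=tuple(effects), subcomponent_of=sub,
    )


def burden_one_cause(deaths=1000.0, cause="pneumonia"):
    return BurdenProfile(
        year=2011, live_births=100_000.0,
        child_deaths_by_cause={cause: deaths},
    )


class TestSingleImpact:
    def test_no_scaleup_averts_nothing(self):
        averted, residual = single_impact(1000.0, eff(0.8, 0.5), 0.3, 0.3)
        assert averted == 0.0
        assert residual == 1000.0

    def test_full_scaleup_from_zero_equals_effectiveness(self):
        averted, _ = single_impact(1000.0, eff(0.5, 1.0), 0.0, 1.0)
        assert averted == pytest.approx(500.0)

    def test_residual_counterfactual_normalisation(self):
        averted, residual = single_impact(1000.0, eff(0.8, 0.5), 0.25, 0.90)
        assert averted == pytest.approx(1000 * (0.4 * 0.65) / (1 - 0.4 * 0.25))
        assert averted == pytest.approx(288.9, abs=0.05)
        assert residual == pytest.approx(1000.0 - averted)

    def test_coverage_loss_reported_as_negative(self):
        averted, _ = single_impact(1000.0, eff(0.5, 1.0), 0.6, 0.2)
        assert averted < 0

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(DegenerateBaselineError):
            single_impact(1000.0, eff(1.0, 1.0), 1.0, 1.0)


class TestCascade:
    def test_empty_package_leaves_baseline_untouched(self):
        burden = burden_one_cause()
        sc = Scenario("s", 2011, 2015, {})
        entries, residual = run_cascade(burden, sc, [], 2015)
        assert entries.empty
        assert residual.child_total == burden.child_total

    def test_single_intervention_matches_single_impact(self):
        burden = burden_one_cause()
        cat = [iv("a", "curative", [eff(0.6, 0.8)], c0=0.2)]
        sc = Scenario("s", 2011, 2015, {"a": 0.9})
        entries, residual = run_cascade(burden, sc, cat, 2015)
        expected, _ = single_impact(1000.0, eff(0.6, 0.8), 0.2, 0.9)
        assert entries["averted"].sum() == pytest.approx(expected)
        assert residual.child_total == pytest.approx(1000.0 - expected)

    def test_sequential_residual_algebra_for_two_interventions(self):
        e1, e2, d = 0.4, 0.5, 1000.0
        burden = burden_one_cause(d)
        cat = [
            iv("vaccine", "preventive", [eff(e1)]),
            iv("case_mgmt", "curative", [eff(e2)]),
        ]
        sc = Scenario("s", 2011, 2015, {"vaccine": 1.0, "case_mgmt": 1.0})
        entries, _ = run_cascade(burden, sc, cat, 2015)
        total = entries["averted"].sum()
        assert total == pytest.approx(d * (1 - (1 - e1) * (1 - e2)))
        # dropping the preventive intervention inflates the curative one
        entries_solo, _ = run_cascade(
            burden, Scenario("s", 2011, 2015, {"case_mgmt": 1.0}), [cat[1]], 2015
        )
        with_upstream = entries[entries["intervention_id"] == "case_mgmt"][
            "averted"
        ].sum()
        without_upstream = entries_solo["averted"].sum()
        assert without_upstream > with_upstream

    def test_preventive_interventions_run_before_curative(self):
        cat = [
            iv("t1", "curative", [eff(0.5)]),
            iv("p1", "preventive", [eff(0.5)]),
        ]
        assert [x.id for x in cascade_order(cat)] == ["p1", "t1"]

    def test_subcomponent_ordered_after_parent_and_cycles_rejected(self):
        cat = [
            iv("sub", "preventive", [eff(0.5)], sub="parent"),
            iv("parent", "curative", [eff(0.5)]),
        ]
        assert [x.id for x in cascade_order(cat)] == ["parent", "sub"]
        bad = [
            iv("a", "preventive", [eff(0.5)], sub="b"),
            iv("b", "preventive", [eff(0.5)], sub="a"),
        ]
        with pytest.raises(ConfigError, match="cycle"):
            cascade_order(bad)

    def test_total_averted_invariant_to_catalogue_order(self, baseline, catalogue):
        _, burden, _ = baseline
        sc = Scenario("s", 2011, 2015, {x.id: 0.9 for x in catalogue})
        forward, _ = run_cascade(burden, sc, catalogue, 2015)
        shuffled = catalogue[::-1]
        backward, _ = run_cascade(burden, sc, shuffled, 2015)
        assert forward["averted"].sum() == pytest.approx(
            backward["averted"].sum(), rel=1e-9
        )
        # but the attribution across interventions changes
        fwd = forward.groupby("intervention_id")["averted"].sum()
        bwd = backward.groupby("intervention_id")["averted"].sum()
        assert not np.allclose(fwd.sort_index(), bwd.sort_index())

    def test_conservation_per_pool_and_year(self, baseline, catalogue):
        _, burden, _ = baseline
        sc = Scenario("s", 2011, 2015, {x.id: 0.9 for x in catalogue})
        ledger, _ = project(sc, burden, catalogue)
        ledger.check_conservation(rel_tol=1e-9)

    def test_raising_one_target_never_hurts(self, baseline, catalogue):
        _, burden, _ = baseline
        base_targets = {x.id: 0.6 for x in catalogue}
        bumped = dict(base_targets, ors=0.9)
        lo, res_lo = run_cascade(
            burden, Scenario("s", 2011, 2015, base_targets), catalogue, 2015
        )
        hi, res_hi = run_cascade(
            burden, Scenario("s", 2011, 2015, bumped), catalogue, 2015
        )
        averted_lo = lo[lo["intervention_id"] == "ors"]["averted"].sum()
        averted_hi = hi[hi["intervention_id"] == "ors"]["averted"].sum()
        assert averted_hi >= averted_lo
        assert res_hi.under5_total <= res_lo.under5_total


class TestProjection:
    def test_null_scenario_is_flat(self, baseline, catalogue):
        _, burden, _ = baseline
        sc = Scenario("null", 2011, 2015, {})
        _, traj = project(sc, burden, catalogue)
        assert traj["u5mr"].nunique() == 1
        assert traj["u5mr"].iloc[0] == pytest.approx(burden.u5mr)

    def test_scaleup_trajectories_non_increasing(self, baseline, catalogue):
        _, burden, _ = baseline
        sc = Scenario("sc2", 2011, 2015, {x.id: 0.9 for x in catalogue})
        _, traj = project(sc, burden, catalogue)
        assert (np.diff(traj["nmr"]) <= 1e-9).all()
        assert (np.diff(traj["u5mr"]) <= 1e-9).all()

    def test_perfect_package_eliminates_under5_mortality(self):
        burden = BurdenProfile(
            year=2011, live_births=1000.0,
            neonatal_deaths_by_cause={"sepsis": 10.0},
            child_deaths_by_cause={"diarrhea": 20.0, "pneumonia": 5.0},
        )
        cat = [
            iv("fix", "preventive",
               [eff(1.0, 1.0, c) for c in ("sepsis", "diarrhea", "pneumonia")]),
        ]
        sc = Scenario("all", 2011, 2015, {"fix": 1.0})
        _, traj = project(sc, burden, cat)
        assert traj["u5mr"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_u5mr_is_a_cohort_probability(self):
        burden = BurdenProfile(
            year=2011, live_births=1000.0,
            neonatal_deaths_by_cause={"sepsis": 35.0},
            child_deaths_by_cause={"diarrhea": 66.0},
        )
        q_neo = 35.0 / 1000.0
        q_child = 66.0 / (1000.0 - 35.0)
        assert burden.u5mr == pytest.approx(
            (1 - (1 - q_neo) * (1 - q_child)) * 1000
        )
        assert burden.nmr == pytest.approx(35.0)


class TestAggregation:
    def test_single_intervention_total_equals_its_entry(self, baseline):
        _, burden, _ = baseline
        cat = [iv("only", "curative", [eff(0.5, 1.0, "diarrhea")])]
        sc = Scenario("s", 2011, 2015, {"only": 0.9})
        ledger, _ = project(sc, burden, cat)
        agg = aggregate_package(ledger, cat)
        assert agg["total"] == pytest.approx(
            ledger.cumulative_by_intervention()["only"]
        )

    def test_subcomponents_excluded_from_total(self, baseline):
        _, burden, _ = baseline
        cat = [
            iv("parent", "preventive", [eff(0.5, 1.0, "sepsis")]),
            iv("child_comp", "curative", [eff(0.5, 1.0, "sepsis")], sub="parent"),
        ]
        sc = Scenario("s", 2011, 2015, {"parent": 0.9, "child_comp": 0.9})
        ledger, _ = project(sc, burden, cat)
        agg = aggregate_package(ledger, cat)
        cum = ledger.cumulative_by_intervention()
        assert cum["child_comp"] > 0
        assert agg["total"] == pytest.approx(cum["parent"])
        # conservation still counts the subcomponent's attributed deaths
        ledger.check_conservation()

    def test_unknown_subset_id_rejected(self, baseline):
        _, burden, _ = baseline
        cat = [iv("only", "curative", [eff(0.5, 1.0, "diarrhea")])]
        sc = Scenario("s", 2011, 2015, {"only": 0.9})
        ledger, _ = project(sc, burden, cat)
        with pytest.raises(Exception, match="unknown"):
            aggregate_package(ledger, cat, subsets={"bad": ["nope"]})

    def test_half_up_rounding(self):
        assert round_half_up(57.75, 1) == 57.8
        assert round_half_up(65.65, 1) == 65.7
        assert round_half_up(0.05, 1) == 0.1


def test_burden_csv_roundtrip(tmp_path, baseline):
    _, burden, _ = baseline
    path = tmp_path / "burden.csv"
    write_burden(burden, path)
    back = read_burden(path)
    assert back.live_births == burden.live_births
    assert back.neonatal_deaths_by_cause == pytest.approx(
        burden.neonatal_deaths_by_cause
    )
    assert back.child_deaths_by_cause == pytest.approx(burden.child_deaths_by_cause)
    assert back.maternal_deaths == pytest.approx(burden.maternal_deaths)
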