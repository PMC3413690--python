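"""Abridged life tables: construction, Chiang columns, transformations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from averted.errors import InfeasibleError, SchemaError, ValidationError
from averted.life_tables import (
    RADIX,
    AbridgedLifeTable,
    FertilitySchedule,
    apply_maternal_adjustment,
    apply_under5_reduction,
    life_expectancy_at_birth,
    read_life_table,
    write_life_table,
)

from conftest import make_constant_hazard_table, make_uniform_table


def two_row_table(first_deaths=RADIX):
    return AbridgedLifeTable(
        age_start=[0.0, 1.0],
        width=[1.0, np.inf],
        deaths=[first_deaths, RADIX - first_deaths],
    )


class TestConstruction:
    def test_everyone_dies_in_first_interval(self):
        lt = two_row_table()
        assert lt.survivors_at_start[1] == 0.0
        assert lt.death_probability[0] == 1.0

    def test_radix_conservation_enforced(self):
        with pytest.raises(ValidationError, match="radix"):
            AbridgedLifeTable(
                age_start=[0.0, 1.0], width=[1.0, np.inf], deaths=[99_000.0, 0.0]
            )

    def test_noncontiguous_rows_name_offender(self, tmp_path):
        path = tmp_path / "lt.csv"
        pd.DataFrame(
            {
                "age_start": [0.0, 2.0, 5.0],
                "width": [1.0, 3.0, np.nan],
                "deaths_per_100k": [50_000.0, 25_000.0, 25_000.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="row 1"):
            read_life_table(path)

    def test_negative_deaths_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            AbridgedLifeTable(
                age_start=[0.0, 1.0],
                width=[1.0, np.inf],
                deaths=[-10.0, RADIX + 10.0],
            )

    def test_synthetic_baseline_parses_and_is_monotone(self, baseline, tmp_path):
        lt, _, _ = baseline
        path = tmp_path / "lt.csv"
        write_life_table(lt, path)
        back = read_life_table(path)
        l = back.survivors_at_start
        assert (np.diff(l) <= 1e-9).all()
        assert l[0] == RADIX
        np.testing.assert_allclose(back.deaths, lt.deaths, rtol=1e-9)
        # writer appends the derived Chiang columns
        cols = pd.read_csv(path).columns
        assert {"l", "q", "L", "T", "e"} <= set(cols)

    def test_default_separation_fractions(self, baseline):
        lt, _, _ = baseline
        assert lt.a_x[0] == 0.3
        assert lt.a_x[1] == 0.4
        assert lt.a_x[2] == 0.5


class TestLifeExpectancy:
    def test_all_deaths_in_first_interval_gives_half_year(self):
        lt = AbridgedLifeTable(
            age_start=[0.0, 1.0], width=[1.0, np.inf], deaths=[RADIX, 0.0],
            a_x=[0.5, np.nan],
        )
        assert life_expectancy_at_birth(lt) == pytest.approx(0.5)

    def test_uniform_deaths_give_midrange(self):
        # brute-force oracle: sum of f_i * (i + 0.5) over 100 one-year bins
        lt = make_uniform_table(n=100, a_x=0.5)
        oracle = sum((1 / 100) * (i + 0.5) for i in range(100))
        assert oracle == pytest.approx(50.0)
        assert life_expectancy_at_birth(lt) == pytest.approx(50.0, abs=1e-9)

    def test_constant_hazard_closed_form(self):
        m = 0.02
        lt = make_constant_hazard_table(m=m, width=0.1, n=2000)
        assert life_expectancy_at_birth(lt) == pytest.approx(1.0 / m, rel=0.01)

    def test_e0_equals_mean_age_at_death(self, baseline):
        # telescoping identity: T(0) = sum_i d_i * (x_i + a_i * n_i)
        lt, _, _ = baseline
        h = lt.age_start.copy()
        h[:-1] += lt.a_x[:-1] * lt.width[:-1]
        h[-1] += lt.terminal_expectancy
        assert life_expectancy_at_birth(lt) == pytest.approx(
            float(np.sum(lt.deaths * h)) / RADIX, rel=1e-12
        )


@st.composite
def random_tables(draw):
    n = draw(st.integers(min_value=3, max_value=12))
    raw = draw(
        st.lists(
            st.floats(min_value=0.01, max_value=1.0), min_size=n, max_size=n
        )
    )
    deaths = np.array(raw) / np.sum(raw) * RADIX
    age_start = np.concatenate(([0.0, 1.0], 5.0 * np.arange(1, n - 1)))
    width = np.concatenate(([1.0, 4.0], np.full(n - 3, 5.0), [np.inf]))
    return AbridgedLifeTable(age_start=age_start, width=width, deaths=deaths)


class TestUnder5Reduction:
    def test_zero_averted_is_identity(self, baseline):
        lt, _, _ = baseline
        out = apply_under5_reduction(lt, 0.0, 0.0)
        np.testing.assert_allclose(out.deaths, lt.deaths, rtol=1e-12)

    def test_averting_everything_clears_under5(self, baseline):
        lt, _, _ = baseline
        out = apply_under5_reduction(
            lt, lt.deaths[0], lt.deaths[1], infant_share_of_child=0.0
        )
        assert out.death_probability[0] == 0.0
        assert out.death_probability[1] == 0.0
        assert out.deaths[2:].sum() == pytest.approx(RADIX, rel=1e-12)

    def test_averting_infant_deaths_raises_e0(self, baseline):
        lt, _, _ = baseline
        out = apply_under5_reduction(lt, 1000.0, 0.0)
        assert life_expectancy_at_birth(out) > life_expectancy_at_birth(lt)

    def test_overshoot_reports_interval(self, baseline):
        lt, _, _ = baseline
        with pytest.raises(InfeasibleError, match=r"\[1,5\)"):
            apply_under5_reduction(
                lt, 0.0, lt.deaths[1] * 2 + 10, infant_share_of_child=0.0
            )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(random_tables(), st.floats(min_value=0.0, max_value=1.0))
    def test_radix_conserved_and_survivorship_monotone(self, lt, frac):
        out = apply_under5_reduction(
            lt, frac * lt.deaths[0] * 0.5, frac * lt.deaths[1] * 0.5,
            infant_share_of_child=0.0,
        )
        assert out.deaths.sum() == pytest.approx(RADIX, rel=1e-9)
        assert (np.diff(out.survivors_at_start) <= 1e-9).all()

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(random_tables())
    def test_dominance_moving_deaths_older_raises_e0(self, lt):
        # moving a positive chunk of under-5 deaths strictly older
        if lt.deaths[0] < 1.0:
            return
        out = apply_under5_reduction(lt, lt.deaths[0] * 0.5, 0.0)
        assert life_expectancy_at_birth(out) > life_expectancy_at_birth(lt)


class TestMaternalAdjustment:
    def test_zero_is_identity(self, baseline):
        lt, _, fert = baseline
        out = apply_maternal_adjustment(lt, 0.0, fert)
        np.testing.assert_allclose(out.deaths, lt.deaths, rtol=1e-12)

    def test_degenerate_schedule_targets_single_interval(self, baseline):
        lt, _, _ = baseline
        fert = FertilitySchedule(age_start=[20.0], width=[5.0], rate=[0.2])
        out = apply_maternal_adjustment(lt, 100.0, fert)
        i20 = lt.interval_index(20.0)
        changed = np.nonzero(~np.isclose(out.deaths, lt.deaths))[0]
        assert i20 in changed
        # removals happen only in the fertile interval; additions only older
        assert (changed >= i20).all()
        assert out.deaths[i20] == pytest.approx(lt.deaths[i20] - 100.0)
        assert out.deaths.sum() == pytest.approx(RADIX, rel=1e-9)

    def test_maternal_gain_smaller_than_infant_gain(self, baseline):
        lt, _, fert = baseline
        e0 = life_expectancy_at_birth(lt)
        gain_maternal = (
            life_expectancy_at_birth(apply_maternal_adjustment(lt, 100.0, fert)) - e0
        )
        gain_infant = (
            life_expectancy_at_birth(apply_under5_reduction(lt, 100.0, 0.0)) - e0
        )
        assert 0 < gain_maternal < gain_infant
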