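"""Abridged period life tables and transformations on them.

A life table here is a static (non-dynamic) abridged table following a
hypothetical cohort of 100,000 live births: each age interval records the
number of cohort deaths falling in it.  From the death column the usual
columns of the Chiang construction are derived: survivors at the start of
the interval (l), the conditional probability of dying in it (q), person-
years lived in it (L), cumulative person-years above its start (T) and
remaining life expectancy (e).  Life expectancy at birth is e(0) = T(0)/l(0).

Person-years in an interior interval of width n use the separation fraction
a_x — the average fraction of the interval lived by those dying in it:

    L = n * l(x + n) + a_x * n * d(x)

The terminal interval is open-ended; its person-years are closed with a
user-configurable remaining expectancy for those reaching it (default 5
years), equivalent to L = l / m with m = 1 / expectancy.

Two transformations model intervention impacts: removing under-5 deaths
(split between the [0,1) and [1,5) intervals) and removing maternal deaths
(spread over the reproductive ages in proportion to age-specific fertility).
Both conserve the radix by moving the saved individuals' deaths to older
intervals in proportion to the baseline death distribution there — i.e. the
conditional mortality schedule above the affected ages is left unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InfeasibleError, SchemaError, ValidationError

RADIX = 100_000.0

#: Default separation fractions: early-infant deaths cluster near birth.
DEFAULT_A0 = 0.3
DEFAULT_A1_4 = 0.4
DEFAULT_A_INTERIOR = 0.5

#: Default remaining expectancy for those entering the open terminal interval.
DEFAULT_TERMINAL_EXPECTANCY = 5.0

_REL_TOL_RADIX = 1e-6


def default_separation_fractions(age_start: np.ndarray, width: np.ndarray) -> np.ndarray:
    """Standard abridged-table a_x defaults: 0.3 for [0,1), 0.4 for [1,5),
    0.5 for other interior intervals.  The terminal entry is unused and set
    to NaN."""
    a = np.full(len(age_start), DEFAULT_A_INTERIOR)
    if len(a) and age_start[0] == 0.0 and width[0] <= 1.0:
        a[0] = DEFAULT_A0
    for i in range(len(a)):
        if age_start[i] == 1.0 and width[i] == 4.0:
            a[i] = DEFAULT_A1_4
    a[-1] = np.nan
    return a


@dataclass(frozen=True)
class AbridgedLifeTable:
    """Abridged life table as deaths per 100,000 live births.

    Parameters
    ----------
    age_start, width
        Contiguous age intervals; the last width must be ``inf`` (open
        terminal interval) and the first start must be 0.
    deaths
        Deaths per 100,000 births in each interval; must sum to the radix.
    a_x
        Separation fractions per interval (terminal entry ignored).  If
        omitted, standard abridged defaults are used.
    terminal_expectancy
        Remaining life expectancy assumed for those who reach the terminal
        interval (years).
    """

    age_start: np.ndarray
    width: np.ndarray
    deaths: np.ndarray
    a_x: np.ndarray | None = None
    terminal_expectancy: float = DEFAULT_TERMINAL_EXPECTANCY

    def __post_init__(self) -> None:
        age_start = np.asarray(self.age_start, dtype=float)
        width = np.asarray(self.width, dtype=float)
        deaths = np.asarray(self.deaths, dtype=float)
        object.__setattr__(self, "age_start", age_start)
        object.__setattr__(self, "width", width)
        object.__setattr__(self, "deaths", deaths)
        if not (len(age_start) == len(width) == len(deaths)) or len(age_start) < 1:
            raise ValidationError("life table columns must be non-empty and equal length")
        if age_start[0] != 0.0:
            raise ValidationError("first interval must start at age 0")
        if not np.isinf(width[-1]):
            raise ValidationError("final interval must be open-ended (width inf)")
        if np.isinf(width[:-1]).any():
            raise ValidationError("only the final interval may be open-ended")
        if (width[:-1] <= 0).any():
            raise ValidationError("interval widths must be positive")
        for i in range(1, len(age_start)):
            expected = age_start[i - 1] + width[i - 1]
            if not np.isclose(age_start[i], expected, atol=1e-9):
                raise SchemaError(
                    f"row {i}: interval starts at {age_start[i]} but previous "
                    f"interval ends at {expected} (non-contiguous)"
                )
        if (deaths < 0).any():
            bad = int(np.argmax(deaths < 0))
            raise ValidationError(f"row {bad}: negative death count {deaths[bad]}")
        total = deaths.sum()
        if abs(total - RADIX) > _REL_TOL_RADIX * RADIX:
            raise ValidationError(
                f"deaths sum to {total:.6f}, not the radix {RADIX:.0f}"
            )
        if self.a_x is None:
            a = default_separation_fractions(age_start, width)
        else:
            a = np.asarray(self.a_x, dtype=float).copy()
            if len(a) != len(age_start):
                raise ValidationError("a_x length mismatch")
            interior = a[:-1]
            filled = np.isnan(interior)
            if filled.any():
                defaults = default_separation_fractions(age_start, width)[:-1]
                interior[filled] = defaults[filled]
            if ((interior <= 0) | (interior >= 1)).any():
                raise ValidationError("interior a_x must lie in (0, 1)")
            a[-1] = np.nan
        object.__setattr__(self, "a_x", a)
        if not self.terminal_expectancy > 0:
            raise ValidationError("terminal expectancy must be positive")

    # ----- derived Chiang columns -------------------------------------

    @property
    def n_intervals(self) -> int:
        return len(self.age_start)

    @property
    def survivors_at_start(self) -> np.ndarray:
        """l(x): cohort members alive at the start of each interval."""
        l = RADIX - np.concatenate(([0.0], np.cumsum(self.deaths[:-1])))
        return np.clip(l, 0.0, None)

    @property
    def death_probability(self) -> np.ndarray:
        """q(x): probability of dying in the interval given survival to x."""
        l = self.survivors_at_start
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(l > 0, self.deaths / np.where(l > 0, l, 1.0), 0.0)
        return np.clip(q, 0.0, 1.0)

    @property
    def person_years(self) -> np.ndarray:
        """L(x): person-years lived in each interval."""
        l = self.survivors_at_start
        d = self.deaths
        L = np.empty(self.n_intervals)
        n = self.width[:-1]
        l_next = l[1:] if self.n_intervals > 1 else np.array([])
        if self.n_intervals > 1:
            L[:-1] = n * l_next + self.a_x[:-1] * n * d[:-1]
        L[-1] = l[-1] * self.terminal_expectancy
        return L

    @property
    def cumulative_person_years(self) -> np.ndarray:
        """T(x): person-years lived above the start of each interval."""
        return np.cumsum(self.person_years[::-1])[::-1]

    @property
    def expectancy(self) -> np.ndarray:
        """e(x): remaining life expectancy at the start of each interval
        (NaN once nobody survives)."""
        l = self.survivors_at_start
        T = self.cumulative_person_years
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(l > 0, T / np.where(l > 0, l, 1.0), np.nan)

    # ----- convenience -------------------------------------------------

    def interval_index(self, start: float, width: float | None = None) -> int:
        for i in range(self.n_intervals):
            if np.isclose(self.age_start[i], start) and (
                width is None or np.isclose(self.width[i], width)
            ):
                return i
        raise KeyError(f"no interval starting at {start}")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the derived columns appended."""
        return pd.DataFrame(
            {
                "age_start": self.age_start,
                "width": self.width,
                "deaths_per_100k": self.deaths,
                "a_x": self.a_x,
                "l": self.survivors_at_start,
                "q": self.death_probability,
                "L": self.person_years,
                "T": self.cumulative_person_years,
                "e": self.expectancy,
            }
        )

    def with_deaths(self, deaths: np.ndarray) -> "AbridgedLifeTable":
        return replace(self, deaths=np.asarray(deaths, dtype=float))


@dataclass(frozen=True)
class FertilitySchedule:
    """Age-specific fertility rates (births per woman-year) on age bands
    inside the reproductive span [10, 55)."""

    age_start: np.ndarray
    width: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        age_start = np.asarray(self.age_start, dtype=float)
        width = np.asarray(self.width, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "age_start", age_start)
        object.__setattr__(self, "width", width)
        object.__setattr__(self, "rate", rate)
        if not (len(age_start) == len(width) == len(rate)):
            raise ValidationError("fertility schedule columns must align")
        if (rate < 0).any():
            raise ValidationError("fertility rates must be non-negative")
        if (age_start < 10.0).any() or (age_start + width > 55.0).any():
            raise ValidationError("fertility schedule must lie within [10, 55)")

    @property
    def total_fertility_rate(self) -> float:
        return float(np.sum(self.rate * self.width))

    def weight_on(self, start: float, end: float) -> float:
        """Integral of the fertility rate over the overlap with [start, end)."""
        lo = np.maximum(self.age_start, start)
        hi = np.minimum(self.age_start + self.width, end)
        overlap = np.clip(hi - lo, 0.0, None)
        return float(np.sum(self.rate * overlap))


# ---------------------------------------------------------------------------
# I/O — CSV schema: age_start,width,deaths_per_100k[,a_x]; terminal width
# empty or "inf".  The writer appends the derived columns l,q,L,T,e.
# ---------------------------------------------------------------------------


def read_life_table(path, terminal_expectancy: float = DEFAULT_TERMINAL_EXPECTANCY) -> AbridgedLifeTable:
    """Read an abridged life table from its CSV schema."""
    df = pd.read_csv(path)
    required = {"age_start", "width", "deaths_per_100k"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"life table CSV missing columns: {sorted(missing)}")
    width = pd.to_numeric(df["width"], errors="coerce").to_numpy(dtype=float)
    width[np.isnan(width)] = np.inf  # empty terminal width encodes the open interval
    a_x = None
    if "a_x" in df.columns:
        a_x = pd.to_numeric(df["a_x"], errors="coerce").to_numpy(dtype=float)
    return AbridgedLifeTable(
        age_start=df["age_start"].to_numpy(dtype=float),
        width=width,
        deaths=df["deaths_per_100k"].to_numpy(dtype=float),
        a_x=a_x,
        terminal_expectancy=terminal_expectancy,
    )


def write_life_table(lt: AbridgedLifeTable, path) -> None:
    lt.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scalar summaries
# ---------------------------------------------------------------------------


def life_expectancy_at_birth(lt: AbridgedLifeTable) -> float:
    """e(0) = T(0) / l(0) in years."""
    l0 = lt.survivors_at_start[0]
    if l0 <= 0:
        raise ValidationError("life expectancy undefined: zero radix")
    return float(lt.cumulative_person_years[0] / l0)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------


def _redistribute_older(
    deaths: np.ndarray, baseline: np.ndarray, above_index: int, amount: float
) -> None:
    """Add `amount` deaths to intervals strictly after `above_index`,
    proportionally to the *baseline* deaths there (terminal interval takes
    everything if no baseline deaths remain above)."""
    if amount == 0.0:
        return
    weights = baseline[above_index + 1 :].copy()
    total = weights.sum()
    if total <= 0:
        deaths[-1] += amount
        return
    deaths[above_index + 1 :] += amount * weights / total


def apply_under5_reduction(
    lt: AbridgedLifeTable,
    neonatal_deaths_averted: float,
    child_deaths_averted: float,
    *,
    infant_share_of_child: float = 0.5,
) -> AbridgedLifeTable:
    """Remove averted under-5 deaths from the table, conserving the radix.

    ``neonatal_deaths_averted`` (per 100,000 births) is removed from the
    [0,1) interval.  ``child_deaths_averted`` covers months 1–59:
    ``infant_share_of_child`` of it falls in [0,1) (months 1–11) and the
    rest in [1,5).  The saved children die later: their deaths are added to
    the intervals above age 5 proportionally to the baseline death
    distribution there.
    """
    if neonatal_deaths_averted < 0 or child_deaths_averted < 0:
        raise ValidationError("averted counts must be non-negative")
    if not 0.0 <= infant_share_of_child <= 1.0:
        raise ValidationError("infant_share_of_child must lie in [0, 1]")
    i0 = lt.interval_index(0.0)
    i1 = lt.interval_index(1.0)
    removed0 = neonatal_deaths_averted + infant_share_of_child * child_deaths_averted
    removed1 = (1.0 - infant_share_of_child) * child_deaths_averted
    tol = 1e-9 * RADIX
    if removed0 > lt.deaths[i0] + tol:
        raise InfeasibleError(
            f"interval [0,1): averting {removed0:.1f} exceeds the "
            f"{lt.deaths[i0]:.1f} deaths recorded there"
        )
    if removed1 > lt.deaths[i1] + tol:
        raise InfeasibleError(
            f"interval [1,5): averting {removed1:.1f} exceeds the "
            f"{lt.deaths[i1]:.1f} deaths recorded there"
        )
    d = lt.deaths.copy()
    d[i0] = max(d[i0] - removed0, 0.0)
    d[i1] = max(d[i1] - removed1, 0.0)
    _redistribute_older(d, lt.deaths, i1, removed0 + removed1)
    return lt.with_deaths(d)


def apply_maternal_adjustment(
    lt: AbridgedLifeTable,
    maternal_deaths_averted: float,
    fert: FertilitySchedule,
) -> AbridgedLifeTable:
    """Remove averted maternal deaths from the reproductive-age intervals.

    The averted count (per 100,000 births) is split across life-table
    intervals in proportion to the age-specific fertility integrated over
    each interval, then each interval's removed deaths are moved to strictly
    older intervals in proportion to the baseline death distribution there.
    """
    if maternal_deaths_averted < 0:
        raise ValidationError("averted count must be non-negative")
    if maternal_deaths_averted == 0:
        return lt
    ends = np.where(np.isinf(lt.width), np.inf, lt.age_start + lt.width)
    weights = np.array(
        [fert.weight_on(s, e) for s, e in zip(lt.age_start, ends)]
    )
    total_w = weights.sum()
    if total_w <= 0:
        raise ValidationError("fertility schedule assigns no weight to any interval")
    removal = maternal_deaths_averted * weights / total_w
    tol = 1e-9 * RADIX
    d = lt.deaths.copy()
    for i in np.nonzero(removal)[0]:
        if removal[i] > lt.deaths[i] + tol:
            raise InfeasibleError(
                f"interval starting {lt.age_start[i]:.0f}: averting "
                f"{removal[i]:.1f} exceeds the {lt.deaths[i]:.1f} deaths there"
            )
        d[i] -= removal[i]
        _redistribute_older(d, lt.deaths, int(i), float(removal[i]))
    return lt.with_deaths(d)
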