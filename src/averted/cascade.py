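"""The deaths-averted engine: a cause-specific residual-mortality cascade.

Each intervention removes a share of the cause-specific deaths left over by
the interventions applied before it.  For one intervention acting on a pool
of ``deaths`` with effectiveness E, affected fraction AF, baseline coverage
c0 and scaled-up coverage ct,

    averted = deaths * E*AF*(ct - c0) / (1 - E*AF*c0)

— the residual-counterfactual normalisation: the recorded baseline deaths
are those occurring *despite* baseline coverage, so the deaths that would
occur with no coverage at all are deaths / (1 - E*AF*c0), of which the
coverage increment removes E*AF*(ct - c0).  Equivalently each intervention
multiplies the pool by (1 - E*AF*ct) / (1 - E*AF*c0); the product over a
package is therefore order-invariant, while the attribution of averted
deaths to individual interventions depends on the cascade order.

The cascade order follows the class rule — preventive interventions are
scaled up before curative (treatment) ones — with catalogue order within a
class, and subcomponents placed directly after their parent so they act
only on the parent's residual.  Removing an upstream intervention for a
cause therefore inflates the deaths averted attributed to the remaining
downstream interventions for that cause (e.g. dropping a pneumonia vaccine
leaves more pneumonia cases for case management to treat).

Mortality rates from a (possibly residual) burden profile:

    NMR  = neonatal deaths / live births * 1000
    q_n  = neonatal deaths / births;  q_c = child deaths / (births - neonatal)
    U5MR = (1 - (1 - q_n)(1 - q_c)) * 1000

U5MR is a cohort probability so that neonatal survivors form the
denominator of the 1–59-month risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DegenerateBaselineError,
    ValidationError,
)
from .scenarios import (
    CURATIVE,
    PREVENTIVE,
    Intervention,
    Scenario,
    coverage_path,
)

NEONATAL = "neonatal"
CHILD = "child"  # 1-59 months
MATERNAL = "maternal"

_CONS_TOL = 1e-9


@dataclass(frozen=True)
class BurdenProfile:
    """Annual births plus cause-specific death counts for one year."""

    year: int
    live_births: float
    neonatal_deaths_by_cause: dict[str, float] = field(default_factory=dict)
    child_deaths_by_cause: dict[str, float] = field(default_factory=dict)
    maternal_deaths: float = 0.0

    def __post_init__(self) -> None:
        if self.live_births <= 0:
            raise ValidationError("live births must be positive")
        for pool in (self.neonatal_deaths_by_cause, self.child_deaths_by_cause):
            for cause, count in pool.items():
                if count < 0:
                    raise ValidationError(f"negative deaths for cause {cause!r}")
        if self.maternal_deaths < 0:
            raise ValidationError("negative maternal deaths")

    @property
    def neonatal_total(self) -> float:
        return float(sum(self.neonatal_deaths_by_cause.values()))

    @property
    def child_total(self) -> float:
        return float(sum(self.child_deaths_by_cause.values()))

    @property
    def under5_total(self) -> float:
        return self.neonatal_total + self.child_total

    @property
    def nmr(self) -> float:
        """Neonatal deaths per 1000 live births."""
        return self.neonatal_total / self.live_births * 1000.0

    @property
    def u5mr(self) -> float:
        """Under-5 deaths per 1000 live births (cohort probability)."""
        q_neo = self.neonatal_total / self.live_births
        survivors = self.live_births - self.neonatal_total
        q_child = self.child_total / survivors if survivors > 0 else 1.0
        return (1.0 - (1.0 - q_neo) * (1.0 - min(q_child, 1.0))) * 1000.0


def read_burden(path) -> BurdenProfile:
    """CSV schema: ``year,live_births,cause,period,deaths`` with period in
    {neonatal, child, maternal}."""
    df = pd.read_csv(path)
    year = int(df["year"].iloc[0])
    births = float(df["live_births"].iloc[0])
    neo, child, maternal = {}, {}, 0.0
    for row in df.itertuples(index=False):
        if row.period == NEONATAL:
            neo[row.cause] = neo.get(row.cause, 0.0) + float(row.deaths)
        elif row.period == CHILD:
            child[row.cause] = child.get(row.cause, 0.0) + float(row.deaths)
        elif row.period == MATERNAL:
            maternal += float(row.deaths)
        else:
            raise ValidationError(f"unknown period {row.period!r}")
    return BurdenProfile(year, births, neo, child, maternal)


def write_burden(burden: BurdenProfile, path) -> None:
    rows = [
        {"year": burden.year, "live_births": burden.live_births, "cause": c,
         "period": NEONATAL, "deaths": d}
        for c, d in burden.neonatal_deaths_by_cause.items()
    ] + [
        {"year": burden.year, "live_births": burden.live_births, "cause": c,
         "period": CHILD, "deaths": d}
        for c, d in burden.child_deaths_by_cause.items()
    ] + [
        {"year": burden.year, "live_births": burden.live_births,
         "cause": MATERNAL, "period": MATERNAL, "deaths": burden.maternal_deaths}
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Single-intervention arithmetic
# ---------------------------------------------------------------------------


def single_impact(deaths: float, eff, c0: float, ct: float) -> tuple[float, float]:
    """Deaths averted and residual for one intervention on one death pool.

    ct < c0 (coverage loss) yields a negative averted count — i.e. added
    deaths — rather than an error, so misconfigured scenarios stay visible.
    """
    if deaths < 0 or c0 < 0 or ct < 0:
        raise ValidationError("deaths and coverages must be non-negative")
    k = eff.effectiveness * eff.affected_fraction
    denom = 1.0 - k * c0
    if denom <= 1e-12:
        raise DegenerateBaselineError(
            "E*AF*c0 = 1: all preventable deaths already removed at baseline"
        )
    averted = deaths * k * (ct - c0) / denom
    return averted, deaths - averted


# ---------------------------------------------------------------------------
# Cascade over an ordered package
# ---------------------------------------------------------------------------


def cascade_order(catalogue: list[Intervention]) -> list[Intervention]:
    """Deterministic package order: preventive before curative, catalogue
    order within a class, each subcomponent directly after its parent."""
    by_id = {iv.id: iv for iv in catalogue}
    for iv in catalogue:
        seen, cur = set(), iv
        while cur.subcomponent_of is not None:
            if cur.id in seen:
                raise ConfigError(f"subcomponent cycle involving {iv.id!r}")
            seen.add(cur.id)
            parent = by_id.get(cur.subcomponent_of)
            if parent is None:
                raise ConfigError(
                    f"{cur.id}: unknown parent {cur.subcomponent_of!r}"
                )
            cur = parent
    class_rank = {PREVENTIVE: 0, CURATIVE: 1}
    mains = [iv for iv in catalogue if iv.subcomponent_of is None]
    index = {iv.id: i for i, iv in enumerate(catalogue)}
    ordered = sorted(
        mains, key=lambda iv: (class_rank[iv.intervention_class], index[iv.id])
    )
    out: list[Intervention] = []
    for main in ordered:
        out.append(main)
        subs = [iv for iv in catalogue if iv.subcomponent_of == main.id]
        out.extend(sorted(subs, key=lambda iv: index[iv.id]))
    return out


def _pools(burden: BurdenProfile) -> dict[tuple[str, str], float]:
    pools = {(NEONATAL, c): d for c, d in burden.neonatal_deaths_by_cause.items()}
    pools.update({(CHILD, c): d for c, d in burden.child_deaths_by_cause.items()})
    pools[(MATERNAL, MATERNAL)] = burden.maternal_deaths
    return pools


def _to_burden(pools: dict[tuple[str, str], float], like: BurdenProfile, year: int) -> BurdenProfile:
    return BurdenProfile(
        year=year,
        live_births=like.live_births,
        neonatal_deaths_by_cause={
            c: max(d, 0.0) for (p, c), d in pools.items() if p == NEONATAL
        },
        child_deaths_by_cause={
            c: max(d, 0.0) for (p, c), d in pools.items() if p == CHILD
        },
        maternal_deaths=max(pools.get((MATERNAL, MATERNAL), 0.0), 0.0),
    )


def run_cascade(
    burden: BurdenProfile,
    scenario: Scenario,
    catalogue: list[Intervention],
    year: int,
) -> tuple[pd.DataFrame, BurdenProfile]:
    """Apply the ordered package to the burden at one year's coverage.

    Returns the ledger entries for the year — one row per (intervention,
    period, cause) with the deaths averted attributed to it — and the
    residual burden.  Conservation holds exactly: for every pool, baseline
    deaths = residual + sum of attributed averted deaths.
    """
    order = cascade_order(catalogue)
    pools = _pools(burden)
    rows = []
    for iv in order:
        c0 = iv.baseline_coverage
        ct = coverage_path(scenario, iv)[year]
        for eff in iv.effects:
            for (period, cause), deaths in list(pools.items()):
                if cause != eff.cause:
                    continue
                averted, residual = single_impact(deaths, eff, c0, ct)
                pools[(period, cause)] = residual
                rows.append(
                    {
                        "year": year,
                        "intervention_id": iv.id,
                        "period": period,
                        "cause": cause,
                        "averted": averted,
                    }
                )
    entries = pd.DataFrame(
        rows, columns=["year", "intervention_id", "period", "cause", "averted"]
    )
    return entries, _to_burden(pools, burden, year)


@dataclass(frozen=True)
class AvertedLedger:
    """Per-(intervention, year) deaths averted plus residual burdens."""

    entries: pd.DataFrame  # year, intervention_id, period, cause, averted
    residuals: dict[int, BurdenProfile]
    baseline: BurdenProfile
    order: tuple[str, ...]

    def cumulative_by_intervention(self) -> pd.Series:
        """Deaths averted summed over all years and pools, by intervention."""
        if self.entries.empty:
            return pd.Series(dtype=float)
        return self.entries.groupby("intervention_id")["averted"].sum()

    def check_conservation(self, rel_tol: float = _CONS_TOL) -> None:
        """Assert baseline = residual + attributed averted per pool/year."""
        base = _pools(self.baseline)
        for year, residual in self.residuals.items():
            res = _pools(residual)
            sub = self.entries[self.entries["year"] == year]
            for key, base_deaths in base.items():
                period, cause = key
                attributed = sub[
                    (sub["period"] == period) & (sub["cause"] == cause)
                ]["averted"].sum()
                scale = max(abs(base_deaths), 1.0)
                if abs(base_deaths - (res.get(key, 0.0) + attributed)) > rel_tol * scale:
                    raise ValidationError(
                        f"conservation violated for {key} in {year}"
                    )


def project(
    scenario: Scenario,
    baseline: BurdenProfile,
    catalogue: list[Intervention],
    years: range | None = None,
) -> tuple[AvertedLedger, pd.DataFrame]:
    """Year-by-year projection of the scenario against a static baseline.

    The baseline burden is non-dynamic: each year's cascade starts from the
    same baseline counts at that year's interpolated coverage.  Returns the
    ledger (all years) and a trajectory frame with columns ``year, nmr,
    u5mr``.
    """
    if years is None:
        years = scenario.years
    if years.start < scenario.start_year or years[-1] > scenario.end_year:
        raise ValidationError("projection years outside scenario range")
    all_entries, residuals, traj = [], {}, []
    for year in years:
        entries, residual = run_cascade(baseline, scenario, catalogue, year)
        all_entries.append(entries)
        residuals[year] = residual
        traj.append({"year": year, "nmr": residual.nmr, "u5mr": residual.u5mr})
    ledger = AvertedLedger(
        entries=pd.concat(all_entries, ignore_index=True)
        if all_entries
        else pd.DataFrame(columns=["year", "intervention_id", "period", "cause", "averted"]),
        residuals=residuals,
        baseline=baseline,
        order=tuple(iv.id for iv in cascade_order(catalogue)),
    )
    return ledger, pd.DataFrame(traj)


# ---------------------------------------------------------------------------
# Package aggregation and reporting helpers
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), as printed report tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def share_pct(part: float, total: float, ndigits: int = 1) -> float:
    """Percentage share, half-up rounded to one decimal by default."""
    if total == 0:
        raise ValidationError("share undefined: zero total")
    return round_half_up(100.0 * part / total, ndigits)


def package_total(report: pd.DataFrame, averted_col: str = "averted") -> float:
    """Total deaths averted excluding subcomponent rows."""
    main = report[~report["is_subcomponent"].astype(bool)]
    return float(main[averted_col].sum())


def subset_subtotal(
    report: pd.DataFrame, ids: list[str], averted_col: str = "averted"
) -> float:
    known = set(report["intervention_id"])
    unknown = set(ids) - known
    if unknown:
        raise ValidationError(f"unknown intervention ids in subset: {sorted(unknown)}")
    return float(
        report[report["intervention_id"].isin(ids)][averted_col].sum()
    )


def aggregate_package(
    ledger: AvertedLedger,
    catalogue: list[Intervention],
    subsets: dict[str, list[str]] | None = None,
) -> dict:
    """Cumulative per-intervention deaths averted with package totals.

    Returns ``{"report": DataFrame, "total": float, "subsets": {name:
    {"subtotal", "share_pct"}}}``.  The total excludes subcomponent rows
    (their impact is already nested inside their parent's package effect);
    shares are half-up rounded to one decimal.
    """
    by_id = {iv.id: iv for iv in catalogue}
    cum = ledger.cumulative_by_intervention()
    rows = []
    for iv in catalogue:
        rows.append(
            {
                "intervention_id": iv.id,
                "name": iv.name,
                "baseline_coverage": iv.baseline_coverage,
                "averted": float(cum.get(iv.id, 0.0)),
                "is_subcomponent": iv.subcomponent_of is not None,
            }
        )
    report = pd.DataFrame(rows)
    total = package_total(report)
    out = {"report": report, "total": total, "subsets": {}}
    for name, ids in (subsets or {}).items():
        for iid in ids:
            if iid not in by_id:
                raise ValidationError(f"subset {name!r} names unknown id {iid!r}")
        subtotal = subset_subtotal(report, ids)
        out["subsets"][name] = {
            "subtotal": subtotal,
            "share_pct": share_pct(subtotal, total) if total else float("nan"),
        }
    return out
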