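"""Run configuration, the projection/equity pipelines and report files.

Three report surfaces mirror how scale-up analyses are usually presented:

* ``cmd_project`` — yearly NMR / U5MR trajectories per scenario, with the
  MDG-4 reference line (U5MR < 68 per 1000 live births);
* ``cmd_equity`` — yearly life expectancy at birth and Gini of age at
  death per scenario, obtained by pushing each year's averted deaths
  through the life table;
* ``cmd_report`` — a deaths-averted package table per scenario: one row
  per intervention, totals excluding subcomponents, named-subset
  subtotals and shares.

CSVs are the contract surface; plots are conveniences.  All percentages in
CSVs are written to one decimal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cascade as _cascade
from .cascade import (
    AvertedLedger,
    BurdenProfile,
    aggregate_package,
    project,
    read_burden,
    round_half_up,
    share_pct,
)
from .errors import ConfigError
from .gini import distribution_from_life_table, gini
from .life_tables import (
    AbridgedLifeTable,
    FertilitySchedule,
    apply_maternal_adjustment,
    apply_under5_reduction,
    life_expectancy_at_birth,
    read_life_table,
)
from .scenarios import Intervention, Scenario, build_scenarios, read_catalogue
from .synthetic import GeneratorConfig, make_baseline, make_catalogue, table2_fixture

logger = logging.getLogger("averted")

MDG4_U5MR = 68.0  # per 1000 live births


@dataclass
class RunConfig:
    """Paths and parameters for one reporting run.

    With no input paths set, an Ethiopia-like baseline and catalogue are
    generated from ``seed``; otherwise the CSV inputs are read.
    """

    out_dir: str | Path = "results"
    seed: int = 0
    v: float = 2.0
    start_year: int = 2011
    end_year: int = 2015
    life_table_path: str | None = None
    burden_path: str | None = None
    catalogue_path: str | None = None
    effects_path: str | None = None
    scenario_config_path: str | None = None
    scenario_name: str | None = None  # restrict to one scenario

    def __post_init__(self) -> None:
        if not self.end_year > self.start_year:
            raise ConfigError("years must be well-ordered (end > start)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


@dataclass(frozen=True)
class RunInputs:
    life_table: AbridgedLifeTable
    burden: BurdenProfile
    fertility: FertilitySchedule | None
    catalogue: list[Intervention]
    scenarios: list[Scenario]


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def default_scenario_set(
    catalogue: list[Intervention],
    baseline: BurdenProfile,
    start_year: int,
    end_year: int,
) -> list[Scenario]:
    """The three canonical scale-up shapes on an arbitrary catalogue.

    sc1: each intervention moves halfway from baseline to 90% (a partial,
    government-target-like scale-up); sc2: all interventions to 90%;
    sc3: 90% for the five interventions averting most deaths under sc2,
    all others frozen at baseline.
    """
    mains = [iv for iv in catalogue if iv.subcomponent_of is None]
    sc1_targets = {
        iv.id: iv.baseline_coverage + 0.5 * (0.9 - iv.baseline_coverage)
        for iv in mains
    }
    sc2_targets = {iv.id: 0.9 for iv in mains}
    config = [
        {"name": "sc1", "start_year": start_year, "end_year": end_year,
         "targets": sc1_targets},
        {"name": "sc2", "start_year": start_year, "end_year": end_year,
         "targets": sc2_targets},
    ]
    sc1, sc2 = build_scenarios(catalogue, config)
    ledger, _ = project(sc2, baseline, catalogue)
    cum = ledger.cumulative_by_intervention()
    ranked = [
        iid for iid in cum.sort_values(ascending=False).index
        if iid in {iv.id for iv in mains}
    ]
    top5 = ranked[:5]
    (sc3,) = build_scenarios(
        catalogue,
        [{"name": "sc3", "start_year": start_year, "end_year": end_year,
          "targets": {iid: 0.9 for iid in top5}}],
    )
    return [sc1, sc2, sc3]


def load_inputs(config: RunConfig) -> RunInputs:
    """Read the run inputs from files, generating synthetic ones where no
    paths are configured.  Logs input checksums and the seed."""
    if config.life_table_path or config.burden_path:
        if not (config.life_table_path and config.burden_path):
            raise ConfigError("life table and burden must be supplied together")
        lt = read_life_table(config.life_table_path)
        burden = read_burden(config.burden_path)
        fert = None
        logger.info(
            "inputs: life_table=%s burden=%s",
            _sha256(config.life_table_path),
            _sha256(config.burden_path),
        )
    else:
        gen = GeneratorConfig(seed=config.seed)
        lt, burden, fert = make_baseline(gen)
        logger.info("inputs: synthetic baseline, seed=%d", config.seed)
    if config.catalogue_path:
        if not config.effects_path:
            raise ConfigError("catalogue CSV requires its effects CSV")
        catalogue = read_catalogue(config.catalogue_path, config.effects_path)
        logger.info(
            "catalogue=%s effects=%s",
            _sha256(config.catalogue_path),
            _sha256(config.effects_path),
        )
    else:
        catalogue = make_catalogue(GeneratorConfig(seed=config.seed))
    if config.scenario_config_path:
        scenarios = build_scenarios(catalogue, config.scenario_config_path)
    else:
        scenarios = default_scenario_set(
            catalogue, burden, config.start_year, config.end_year
        )
    if config.scenario_name:
        scenarios = [s for s in scenarios if s.name == config.scenario_name]
        if not scenarios:
            raise ConfigError(f"no scenario named {config.scenario_name!r}")
    for s in scenarios:
        logger.info("scenario %s: %d targets over %d-%d",
                    s.name, len(s.targets), s.start_year, s.end_year)
    return RunInputs(lt, burden, fert, catalogue, scenarios)


# ---------------------------------------------------------------------------
# Equity pipeline: averted deaths -> life table -> e(0) and Gini
# ---------------------------------------------------------------------------


def infant_share_of_child_deaths(lt: AbridgedLifeTable, burden: BurdenProfile) -> float:
    """Share of 1-59-month deaths falling in [0,1), inferred from the
    baseline table: post-neonatal [0,1) deaths vs [1,5) deaths."""
    neo_per_100k = burden.nmr * 100.0
    pnn0 = max(lt.deaths[lt.interval_index(0.0)] - neo_per_100k, 0.0)
    d1 = lt.deaths[lt.interval_index(1.0)]
    total = pnn0 + d1
    return pnn0 / total if total > 0 else 0.5


def life_table_for_residual(
    lt: AbridgedLifeTable,
    baseline: BurdenProfile,
    residual: BurdenProfile,
    fert: FertilitySchedule | None = None,
    infant_share: float | None = None,
) -> AbridgedLifeTable:
    """Apply one year's averted deaths (baseline minus residual) to the
    baseline life table, rescaled to the 100,000-birth radix."""
    if infant_share is None:
        infant_share = infant_share_of_child_deaths(lt, baseline)
    per_100k = 100_000.0 / baseline.live_births
    neo = max(baseline.neonatal_total - residual.neonatal_total, 0.0) * per_100k
    child = max(baseline.child_total - residual.child_total, 0.0) * per_100k
    out = apply_under5_reduction(
        lt, neo, child, infant_share_of_child=infant_share
    )
    if fert is not None:
        mat = max(baseline.maternal_deaths - residual.maternal_deaths, 0.0) * per_100k
        if mat > 0:
            out = apply_maternal_adjustment(out, mat, fert)
    return out


def equity_trajectory(
    lt: AbridgedLifeTable,
    burden: BurdenProfile,
    fert: FertilitySchedule | None,
    scenario: Scenario,
    catalogue: list[Intervention],
    v: float = 2.0,
) -> pd.DataFrame:
    """Yearly e(0) and Gini of age at death under the scenario.

    Each year's life table reflects that year's residual mortality (period
    perspective, non-dynamic), so the trajectory tracks the phase-in of
    coverage.  Columns: ``year, scenario, e0_years, gini``.
    """
    ledger, _ = project(scenario, burden, catalogue)
    share = infant_share_of_child_deaths(lt, burden)
    rows = []
    for year in scenario.years:
        lt_y = life_table_for_residual(
            lt, burden, ledger.residuals[year], fert, infant_share=share
        )
        rows.append(
            {
                "year": year,
                "scenario": scenario.name,
                "e0_years": life_expectancy_at_birth(lt_y),
                "gini": gini(distribution_from_life_table(lt_y), v),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Commands (the CLI wraps these thinly)
# ---------------------------------------------------------------------------


def _ensure_out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _plot(fig, path: Path) -> None:
    fig.savefig(path, dpi=150, bbox_inches="tight")


def cmd_project(config: RunConfig) -> dict[str, Path]:
    """Write per-scenario NMR/U5MR trajectories and the MDG-4 figure."""
    inputs = load_inputs(config)
    frames = []
    for scenario in inputs.scenarios:
        ledger, traj = project(scenario, inputs.burden, inputs.catalogue)
        logger.info("cascade order (%s): %s", scenario.name, ", ".join(ledger.order))
        traj = traj.assign(
            scenario=scenario.name, mdg4_met=traj["u5mr"] < MDG4_U5MR
        )
        frames.append(traj[["year", "scenario", "nmr", "u5mr", "mdg4_met"]])
    table = pd.concat(frames, ignore_index=True)
    out = _ensure_out(config)
    csv_path = out / "mortality_trajectories.csv"
    table.to_csv(csv_path, index=False, float_format="%.3f")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharex=True)
    for name, sub in table.groupby("scenario"):
        axes[0].plot(sub["year"], sub["nmr"], marker="o", label=name)
        axes[1].plot(sub["year"], sub["u5mr"], marker="o", label=name)
    axes[0].set_ylabel("NMR (per 1000 live births)")
    axes[1].set_ylabel("U5MR (per 1000 live births)")
    axes[1].axhline(MDG4_U5MR, ls=":", color="grey", label="MDG 4 (68)")
    for ax in axes:
        ax.set_xlabel("year")
        ax.legend(fontsize=8)
    fig_path = out / "mortality_trajectories.png"
    _plot(fig, fig_path)
    plt.close(fig)
    return {"csv": csv_path, "figure": fig_path}


def cmd_equity(config: RunConfig) -> dict[str, Path]:
    """Write per-scenario yearly e(0) and Gini, plus the figure."""
    inputs = load_inputs(config)
    frames = [
        equity_trajectory(
            inputs.life_table, inputs.burden, inputs.fertility,
            scenario, inputs.catalogue, v=config.v,
        )
        for scenario in inputs.scenarios
    ]
    table = pd.concat(frames, ignore_index=True)
    out = _ensure_out(config)
    csv_path = out / "equity_trajectories.csv"
    table.to_csv(csv_path, index=False, float_format="%.4f")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharex=True)
    for name, sub in table.groupby("scenario"):
        axes[0].plot(sub["year"], sub["e0_years"], marker="o", label=name)
        axes[1].plot(sub["year"], sub["gini"], marker="o", label=name)
    axes[0].set_ylabel("life expectancy at birth (years)")
    axes[1].set_ylabel("Gini of age at death")
    for ax in axes:
        ax.set_xlabel("year")
        ax.legend(fontsize=8)
    fig_path = out / "equity_trajectories.png"
    _plot(fig, fig_path)
    plt.close(fig)
    return {"csv": csv_path, "figure": fig_path}


def package_report_frame(
    ledger: AvertedLedger,
    catalogue: list[Intervention],
    scenario: Scenario,
    subsets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Deaths-averted table for one scenario: one row per intervention,
    coverage as percentages to one decimal, a totals row excluding
    subcomponents, and one row per named subset with its share."""
    agg = aggregate_package(ledger, catalogue, subsets=subsets)
    report = agg["report"].copy()
    by_id = {iv.id: iv for iv in catalogue}
    report["target_coverage_pct"] = [
        round_half_up(100.0 * scenario.target_for(by_id[iid]))
        for iid in report["intervention_id"]
    ]
    report["baseline_coverage_pct"] = [
        round_half_up(100.0 * c) for c in report["baseline_coverage"]
    ]
    rows = report[
        ["intervention_id", "name", "baseline_coverage_pct",
         "target_coverage_pct", "averted", "is_subcomponent"]
    ].copy()
    total_row = {
        "intervention_id": "total", "name": "Total (excl. subcomponents)",
        "baseline_coverage_pct": float("nan"), "target_coverage_pct": float("nan"),
        "averted": agg["total"], "is_subcomponent": False,
    }
    extra = [total_row]
    for name, info in agg["subsets"].items():
        extra.append(
            {
                "intervention_id": f"subset:{name}",
                "name": f"Subset {name} ({info['share_pct']:.1f}%)",
                "baseline_coverage_pct": float("nan"),
                "target_coverage_pct": float("nan"),
                "averted": info["subtotal"], "is_subcomponent": False,
            }
        )
    return pd.concat([rows, pd.DataFrame(extra)], ignore_index=True)


def cmd_report(config: RunConfig) -> dict[str, Path]:
    """Write one deaths-averted package table per scenario."""
    inputs = load_inputs(config)
    out = _ensure_out(config)
    paths: dict[str, Path] = {}
    # rank by the all-90% scenario if present, else by the first scenario
    by_name = {s.name: s for s in inputs.scenarios}
    rank_scenario = by_name.get("sc2", inputs.scenarios[0])
    ledger_rank, _ = project(rank_scenario, inputs.burden, inputs.catalogue)
    cum = ledger_rank.cumulative_by_intervention()
    mains = {iv.id for iv in inputs.catalogue if iv.subcomponent_of is None}
    top5 = [i for i in cum.sort_values(ascending=False).index if i in mains][:5]
    for scenario in inputs.scenarios:
        ledger, _ = project(scenario, inputs.burden, inputs.catalogue)
        frame = package_report_frame(
            ledger, inputs.catalogue, scenario, subsets={"top_five": top5}
        )
        path = out / f"package_report_{scenario.name}.csv"
        frame.to_csv(path, index=False, float_format="%.1f")
        paths[scenario.name] = path
    return paths


def fixture_passthrough_report(out_dir) -> dict:
    """Aggregate the packaged printed deaths-averted table.

    Recomputes, per scenario column: the package total over non-
    subcomponent rows, the top-five subtotal, and the top-five share of
    the *printed* total (the published shares use the printed totals row).
    The known gap between the first column's row sum and its printed total
    is reported, never reconciled.  Writes ``table2_aggregation.csv`` and
    returns the figures.
    """
    fx = table2_fixture()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    result: dict = {"printed_totals": fx.printed_totals}
    for sc in ("sc1", "sc2", "sc3"):
        frame = fx.frame_for(sc)
        computed = _cascade.package_total(frame)
        top5 = _cascade.subset_subtotal(frame, list(fx.TOP_FIVE))
        printed = fx.printed_totals[sc]
        share = share_pct(top5, printed)
        result[sc] = {
            "computed_total": computed,
            "printed_total": printed,
            "row_sum_minus_printed": computed - printed,
            "top_five_subtotal": top5,
            "top_five_share_pct": share,
        }
        rows.append({"scenario": sc, **result[sc]})
    pd.DataFrame(rows).to_csv(out / "table2_aggregation.csv", index=False)
    (out / "table2_aggregation.json").write_text(json.dumps(result, indent=2))
    return result
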