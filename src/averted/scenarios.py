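"""Interventions, scale-up scenarios and yearly coverage trajectories.

A scenario names target coverage levels at its end year for a subset of an
intervention catalogue; coverage moves from the intervention's baseline at
the start year to the target by linear interpolation, one value per
calendar year.  Interventions absent from a scenario's target map stay at
baseline throughout.  Coverage is stored as fractions in [0, 1];
percentages appear only at the I/O boundary.

Subcomponent interventions (e.g. labor and delivery management inside
institutional delivery) inherit their parent's scenario target unless the
scenario sets one explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, ValidationError

PREVENTIVE = "preventive"
CURATIVE = "curative"


@dataclass(frozen=True)
class EffectivenessEntry:
    """Cause-specific impact of an intervention.

    effectiveness: fraction of the cause's deaths prevented at full
    coverage among those the intervention can reach; affected_fraction:
    share of the cause's deaths it can in principle reach.
    """

    cause: str
    effectiveness: float
    affected_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ValidationError(f"effectiveness {self.effectiveness} outside [0,1]")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValidationError(
                f"affected fraction {self.affected_fraction} outside [0,1]"
            )


@dataclass(frozen=True)
class Intervention:
    id: str
    name: str
    intervention_class: str  # preventive | curative
    delivery_level: str = "community"  # community | outreach | facility
    baseline_coverage: float = 0.0
    effects: tuple[EffectivenessEntry, ...] = ()
    subcomponent_of: str | None = None

    def __post_init__(self) -> None:
        if self.intervention_class not in (PREVENTIVE, CURATIVE):
            raise ValidationError(
                f"{self.id}: class must be preventive or curative, "
                f"got {self.intervention_class!r}"
            )
        if not 0.0 <= self.baseline_coverage <= 1.0:
            raise ValidationError(f"{self.id}: coverage outside [0,1]")
        object.__setattr__(self, "effects", tuple(self.effects))


@dataclass(frozen=True)
class Scenario:
    """Named coverage-target set over a span of calendar years."""

    name: str
    start_year: int
    end_year: int
    targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.end_year > self.start_year:
            raise ValidationError("end_year must exceed start_year")
        for iid, t in self.targets.items():
            if not 0.0 <= t <= 1.0:
                raise ValidationError(f"target for {iid} outside [0,1]")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def target_for(self, intervention: Intervention) -> float:
        return self.targets.get(intervention.id, intervention.baseline_coverage)


def interpolate_coverage(
    c0: float, c1: float, y0: int, y1: int, t: int | float
) -> float:
    """Linear interpolation of coverage between (y0, c0) and (y1, c1)."""
    if not (y0 <= t <= y1):
        raise ValidationError(f"year {t} outside scale-up window [{y0}, {y1}]")
    if y1 == y0:
        return float(c1)
    return float(c0 + (c1 - c0) * (t - y0) / (y1 - y0))


def coverage_path(scenario: Scenario, intervention: Intervention) -> dict[int, float]:
    """Coverage fraction for every calendar year of the scenario."""
    c0 = intervention.baseline_coverage
    c1 = scenario.target_for(intervention)
    return {
        y: interpolate_coverage(c0, c1, scenario.start_year, scenario.end_year, y)
        for y in scenario.years
    }


def _inherit_subcomponent_targets(
    targets: dict[str, float], catalogue: list[Intervention]
) -> dict[str, float]:
    out = dict(targets)
    for iv in catalogue:
        if iv.subcomponent_of and iv.id not in out and iv.subcomponent_of in out:
            out[iv.id] = out[iv.subcomponent_of]
    return out


def build_scenarios(catalogue: list[Intervention], config) -> list[Scenario]:
    """Build scenarios from a config mapping (or a JSON/YAML file path).

    Config shape: ``{"scenarios": [{"name", "start_year", "end_year",
    "targets": {id: fraction}}, ...]}`` (a bare list is also accepted).
    Every target id must exist in the catalogue; subcomponents without an
    explicit target inherit their parent's.
    """
    if isinstance(config, (str, Path)):
        config = _load_config(config)
    entries = config["scenarios"] if isinstance(config, dict) else config
    ids = {iv.id for iv in catalogue}
    scenarios = []
    for entry in entries:
        unknown = set(entry.get("targets", {})) - ids
        if unknown:
            raise ConfigError(
                f"scenario {entry.get('name')!r}: unknown intervention ids "
                f"{sorted(unknown)}"
            )
        scenarios.append(
            Scenario(
                name=entry["name"],
                start_year=int(entry["start_year"]),
                end_year=int(entry["end_year"]),
                targets=_inherit_subcomponent_targets(
                    {k: float(v) for k, v in entry.get("targets", {}).items()},
                    catalogue,
                ),
            )
        )
    return scenarios


def _load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_scenarios(scenarios: list[Scenario], path) -> None:
    payload = {
        "scenarios": [
            {
                "name": s.name,
                "start_year": s.start_year,
                "end_year": s.end_year,
                "targets": dict(s.targets),
            }
            for s in scenarios
        ]
    }
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Catalogue I/O — CSV pair: interventions + effects
# ---------------------------------------------------------------------------


def read_catalogue(interventions_csv, effects_csv) -> list[Intervention]:
    """Read the catalogue CSV pair.

    ``interventions_csv``: ``id,name,class,level,baseline_coverage,
    subcomponent_of``; ``effects_csv``: ``id,cause,effectiveness,
    affected_fraction``.
    """
    ivs = pd.read_csv(interventions_csv)
    effs = pd.read_csv(effects_csv)
    by_id: dict[str, list[EffectivenessEntry]] = {}
    for row in effs.itertuples(index=False):
        by_id.setdefault(row.id, []).append(
            EffectivenessEntry(
                cause=row.cause,
                effectiveness=float(row.effectiveness),
                affected_fraction=float(row.affected_fraction),
            )
        )
    catalogue = []
    for row in ivs.itertuples(index=False):
        sub = getattr(row, "subcomponent_of", None)
        if pd.isna(sub) or sub == "":
            sub = None
        catalogue.append(
            Intervention(
                id=row.id,
                name=row.name,
                intervention_class=row[2],  # "class" is keyword-mangled by itertuples
                delivery_level=row[3],
                baseline_coverage=float(row.baseline_coverage),
                effects=tuple(by_id.get(row.id, ())),
                subcomponent_of=sub,
            )
        )
    known = {iv.id for iv in catalogue}
    for iv in catalogue:
        if iv.subcomponent_of and iv.subcomponent_of not in known:
            raise ConfigError(
                f"{iv.id}: subcomponent_of names unknown intervention "
                f"{iv.subcomponent_of!r}"
            )
    return catalogue


def write_catalogue(catalogue: list[Intervention], interventions_csv, effects_csv) -> None:
    pd.DataFrame(
        [
            {
                "id": iv.id,
                "name": iv.name,
                "class": iv.intervention_class,
                "level": iv.delivery_level,
                "baseline_coverage": iv.baseline_coverage,
                "subcomponent_of": iv.subcomponent_of or "",
            }
            for iv in catalogue
        ]
    ).to_csv(interventions_csv, index=False)
    pd.DataFrame(
        [
            {
                "id": iv.id,
                "cause": e.cause,
                "effectiveness": e.effectiveness,
                "affected_fraction": e.affected_fraction,
            }
            for iv in catalogue
            for e in iv.effects
        ]
    ).to_csv(effects_csv, index=False)
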