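"""Generate the synthetic Ethiopia-like 2011 baseline and write it to CSV.

Produces the abridged life table, the cause-specific burden profile, the
fertility schedule and the 14-intervention catalogue that the later
analysis steps consume, and prints the headline baseline indicators.
"""

import argparse
from pathlib import Path

import pandas as pd

from averted.cascade import write_burden
from averted.gini import distribution_from_life_table, gini
from averted.life_tables import life_expectancy_at_birth, write_life_table
from averted.scenarios import write_catalogue
from averted.synthetic import (
    NEONATAL_CAUSES,
    GeneratorConfig,
    make_baseline,
    make_catalogue,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/baseline"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = GeneratorConfig(seed=args.seed)
    lt, burden, fert = make_baseline(cfg)
    catalogue = make_catalogue(cfg)

    write_life_table(lt, args.out / "life_table.csv")
    write_burden(burden, args.out / "burden.csv")
    write_catalogue(catalogue, args.out / "catalogue.csv", args.out / "effects.csv")
    pd.DataFrame(
        {"age_start": fert.age_start, "width": fert.width, "rate": fert.rate}
    ).to_csv(args.out / "fertility.csv", index=False)

    tail = sum(
        d for c, d in burden.child_deaths_by_cause.items() if c in NEONATAL_CAUSES
    )
    share = (burden.neonatal_total + tail) / burden.under5_total
    print(f"baseline written to {args.out} (seed {args.seed})")
    print(f"  live births / year          : {burden.live_births:,.0f}")
    print(f"  U5MR                        : {burden.u5mr:.1f} per 1000 live births")
    print(f"  NMR                         : {burden.nmr:.1f} per 1000 live births")
    print(f"  neonatal-cause share of U5  : {share:.1%}")
    print(f"  life expectancy at birth    : {life_expectancy_at_birth(lt):.1f} y")
    print(f"  Gini of age at death (v=2)  : "
          f"{gini(distribution_from_life_table(lt), 2.0):.3f}")
    print(f"  interventions in catalogue  : "
          f"{sum(1 for iv in catalogue if iv.subcomponent_of is None)} "
          f"(+{sum(1 for iv in catalogue if iv.subcomponent_of)} subcomponent)")


if __name__ == "__main__":
    main()
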