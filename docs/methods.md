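# Methods

## Model overview and assumptions

The package projects the effect of scaling up coverage of a package of
child-health interventions between a start and an end year. Four
assumptions shape everything downstream:

* **Static epidemiology.** The baseline burden (annual live births,
  cause-specific neonatal and 1–59-month death counts, maternal deaths)
  is held fixed across projection years; only coverage changes. Each
  year's cascade therefore starts from the same baseline counts at that
  year's interpolated coverage, and cumulative "deaths averted by the end
  year" is the sum of the yearly averted counts.
* **Non-dynamic life tables.** The life table is a period table for a
  hypothetical cohort of 100,000 births; there is no cohort-component
  projection, migration or feedback from saved children onto future
  births. This keeps life-expectancy and inequality calculations simple
  and transparent, at the cost of ignoring population dynamics.
* **Full implementation.** Target coverage means the intervention is
  delivered with its stated effectiveness to the covered fraction; health
  system quality, access and utilisation frictions are outside the model.
* **Independent intervention effects within a cause.** Interventions
  interact only through the residual cascade (each acts on what the ones
  before it left), not through synergies or herd effects.

## The lives-saved cascade

For one intervention on a pool of `D` cause-specific deaths with
effectiveness `E`, affected fraction `AF`, baseline coverage `c0` and
current-year coverage `ct`:

    averted = D * E*AF*(ct - c0) / (1 - E*AF*c0)

The denominator is the residual-counterfactual normalisation: baseline
deaths are the deaths occurring despite baseline coverage, so the
no-coverage counterfactual is `D / (1 - E*AF*c0)` and the coverage
increment removes `E*AF*(ct - c0)` of it. `E*AF*c0 = 1` is rejected as a
degenerate baseline. Coverage loss (`ct < c0`) produces a negative
averted count rather than an error, keeping the algebra total and making
misconfigured scenarios visible in reports.

Equivalently the intervention multiplies the pool by
`(1 - E*AF*ct) / (1 - E*AF*c0)`. Because these multipliers commute, the
package-total deaths averted is invariant to the cascade order; only the
attribution across interventions depends on it. The order is
deterministic and recorded in the ledger: preventive interventions before
curative ones (the class-level rule the scale-up tradition uses), catalogue
order within a class, and each subcomponent immediately after its parent
so it acts only on the parent's residual. Subcomponent rows are excluded
from package totals (their effect is nested in the parent's package), but
their attributed deaths still count in the conservation identity
`baseline = residual + sum of attributed averted`, which holds to 1e-9
relative per cause, period and year.

Rates from a burden profile: `NMR = neonatal deaths / births * 1000`, and
U5MR as a cohort probability,
`U5MR = (1 - (1 - q_n)(1 - q_c)) * 1000` with `q_n = neonatal/births`
and `q_c = child(1-59m) / (births - neonatal)`, so neonatal survivors form
the denominator of the later-childhood risk and no deaths are
double-counted.

## Coverage scenarios

Coverage is a fraction in [0, 1], interpolated linearly from the baseline
at the start year to the scenario target at the end year, evaluated once
per calendar year. Interventions absent from a scenario's target map stay
at baseline. Subcomponents inherit their parent's target unless the
scenario sets one explicitly — both representations (inherited and
explicit subcomponent coverage) are expressible. Percentages appear only
at the I/O boundary, formatted to one decimal with half-up rounding.

## Life tables

Abridged tables carry deaths per 100,000 births over contiguous intervals
(0, 1–4, then 5-year bands) with exactly one open terminal interval.
Derived columns follow the standard abridged construction: survivors
`l`, conditional death probability `q`, person-years
`L = n*l(x+n) + a_x*n*d(x)` with separation fraction `a_x`, cumulative
person-years `T`, and `e = T/l`. Defaults `a_0 = 0.3`, `a_{1-4} = 0.4`
and 0.5 elsewhere reflect the early-infancy clustering of deaths; all are
overridable per interval. The open terminal interval is closed with a
configurable remaining expectancy for those reaching it (default 5 years,
i.e. `L = l/m` with `m` the implied constant hazard) — a knob, because
"standard methods" underdetermine the closure. A useful identity
(tested): `e(0)` equals the mean of the age-at-death distribution with
representative ages `x + a_x*n` (terminal: start + terminal expectancy),
which is also exactly the distribution handed to the Gini statistic, so
the two outcome measures are internally consistent.

Intervention impacts enter as death removals. Under-5: the neonatal
averted count is removed from [0,1); the 1–59-month count is split
between [0,1) and [1,5) by an `infant_share_of_child` parameter, which
the pipeline infers from the baseline table and burden (post-neonatal
[0,1) deaths versus [1,5) deaths — about 0.51 on the default baseline)
rather than defaulting blindly. Maternal: averted deaths are allocated to
reproductive-age intervals in proportion to age-specific fertility
integrated over each interval. In both cases the saved individuals'
deaths are redistributed to strictly older intervals in proportion to the
baseline death distribution there — the minimal assumption that the
conditional mortality schedule above the affected ages is unchanged — so
the radix is conserved exactly and survivorship stays monotone. Averting
more deaths than an interval contains raises an infeasibility error
naming the interval.

## Gini of age at death

Groups `(h_i, f_i)` (age at death, proportion) are merged on ties and
ranked best-off first; with `s_i` the mass of better-off groups, the
fractional rank is `R_i = s_i + f_i/2`. The implementation computes the
extended Gini as

    G(v) = 1 - (v/mu) * sum_i f_i h_i w_i,
    w_i  = ((s_i + f_i)^v - s_i^v) / (v * f_i),

where `w_i` is the rank weight integrated exactly over the group's span
of the rank axis. At `v = 2`, `w_i` reduces identically to the midpoint
rank `R_i`, and `G(2)` equals the pairwise-difference Gini
`sum_{ij} f_i f_j |h_i - h_j| / (2 mu)` — verified against an explicit
double-loop oracle to 1e-10 over a thousand random distributions. The
exact integration (rather than plugging `R_i^{v-1}` directly) is a
deliberate choice: the plain midpoint form is not monotone in `v` for
coarse distributions, while the integrated form keeps the whole family
well-behaved — `G(1) = 0`, `G` non-decreasing in `v`, `G` in [0, 1] — and
is indistinguishable at the defining `v = 2` case. `v` defaults to 2
everywhere. A zero mean age at death (all deaths at age 0) leaves the
coefficient undefined and raises an error.

## Synthetic baseline generator

The generator emulates an Ethiopia-like 2011 baseline: U5MR 101 and NMR
35 per 1000 live births, infant mortality 68.5, life expectancy at birth
59.3 years, total fertility 3.9, maternal mortality ratio 590 per
100,000 births, and 3,150,000 annual live births (chosen so baseline
under-5 deaths land near 318,000 a year, the scale reported for the
setting). Cause fractions of under-5 deaths default to neonatal causes
38%, diarrhea 22%, pneumonia 12%, malaria 7%, measles 2%, other 19%.

Neonatal *period* deaths (NMR) and neonatal-*cause* deaths (the 38%) are
distinct quantities: with U5MR 101 and NMR 35 the period share is 34.7%,
so the generator places the excess neonatal-cause deaths (~3.4 per 1000
births) in the 1–59-month pool as post-neonatal sepsis. Both the rate
targets and the cause split then hold simultaneously, mirroring how the
two statistics are reported from different sources in practice.

The life table puts 6,850 deaths per 100,000 in [0,1) and 3,250 in
[1,5) (from the IMR/U5MR targets); adult mortality above age 5 follows a
Gompertz-like hazard (log-slope 0.09 per year) with mild seeded
lognormal jitter (sd 0.03) per 5-year band, whose overall level is then
calibrated by root-finding so e(0) hits the target exactly. The exact
adult shape is a free choice — only its level is identified by e(0) —
and different seeds give different but equally calibrated tables. All
draws come from named `numpy` generator streams derived from the single
config seed; there is no global random state, and a fixed seed reproduces
byte-identical outputs.

The intervention catalogue mirrors a standard 14-intervention
child-survival package (institutional delivery, ORS, pneumonia case
management, breastfeeding promotion, neonatal-infection management,
antimalarials, pneumococcal and measles vaccines, zinc, insecticide-
treated materials, postnatal care, kangaroo care, PMTCT, improved water)
plus one nested subcomponent (labor and delivery management under
institutional delivery). The cause map is fixed; effectiveness values are
drawn uniformly from the configured range (default [0.2, 0.8]), affected
fractions from [0.5, 1], baseline coverages from [0, 0.8]. For n ≥ 4 the
catalogue always contains a preventive/curative pair sharing a cause, so
the downstream-inflation interaction is exercisable by construction.

What the generator does *not* emulate: real effectiveness evidence (the
draws are synthetic, so projected magnitudes are not comparable to
published scale-up estimates, only directions and structure are), HIV-
specific mortality, seasonality, sub-national heterogeneity, and any
feedback of intervention scale-up on fertility or births. Passing tests
show the machinery is correct and the qualitative pattern (lower
mortality, higher e(0), lower Gini under scale-up) is robust — not that
the synthetic magnitudes match any real program.

Because generated baseline coverages are random, the analysis drivers'
default scenario set attaches structural rather than historical targets:
sc1 moves every intervention halfway from baseline to 90%, sc2 takes all
to 90%, sc3 takes the five interventions averting most deaths under sc2
to 90% and freezes the rest. The published table's actual coverages and
targets are exercised through the packaged verbatim fixture instead,
which also preserves (and surfaces) the known inconsistency that its
first scenario column sums 5,900 above its printed total.

## Numerical choices and degenerate inputs

* Radix conservation after every life-table transformation: exact to
  1e-9 relative; construction tolerates 1e-6 relative on input.
* Conservation of deaths in the cascade: 1e-9 relative per pool.
* Interpolated coverage paths are affine: second differences are checked
  to 1e-12.
* Half-up decimal rounding (via `decimal`) for printed percentages, one
  decimal place.
* Empty pools, zero-coverage changes and null scenarios are identities;
  zero radix and zero mean age raise explicit errors rather than NaN.
* Gompertz-level calibration uses Brent root-finding on [1e-8, 1] with
  xtol 1e-12; the bracket is guaranteed by the monotone dependence of
  e(0) on the hazard level.
* Problem sizes: trajectories run 5 years × ≤15 interventions; oracle
  suites use 1,000 random distributions and a 2,000-interval fine grid —
  everything completes in seconds.

## Known limitations

Static burden and non-dynamic life tables (no demographic feedback);
no uncertainty propagation on effectiveness or coverage; no costing; the
maternal adjustment treats averted maternal deaths per 100,000 *births*
as directly removable from the birth-cohort life table, a simplification
of the underlying population structure; and the terminal-interval closure
is a stated convention, not an estimate.
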