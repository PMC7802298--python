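# Methods notes

## Data model

The unit of observation is the *system-year*: one health system's
participation in one program year (2016 or 2017) of the health-plan-run
mailed FIT outreach. The packaged table holds 27 system-years across 17
systems (13 in 2016, 14 in 2017, 10 in both). The completion rate is
screened members divided by kits mailed, kept as an exact rational
(`fractions.Fraction`) throughout; percentages printed in reports are
derived, never stored.

Three case views feed the configurational analyses:

* **first participation** — each system's earliest year (17 cases). The
  program's "year 1" sample counts 17 cases although only 13 systems
  participated in calendar 2016, so year 1 is per-system program year
  one, not calendar 2016. This is a documented reconstruction exposed
  as a named view (`first_participation_view`), not a hard-coded
  filter; it also reproduces the 11/6 success split.
* **year 2** — the 2017 records of the 10 two-year systems.
* **change** — the 10 two-year systems, outcome = year-2 rate strictly
  above year-1 rate (exact rational comparison; ties count as
  unchanged).

## Calibration

The outcome is dichotomized at 19%: success iff rate ≥ 0.19. The
comparison is ≥ (not >) because a system printing exactly 19.0%
(20/105) is treated as a success; it is configurable
(`CalibrationSpec`). The 19% value sits at the tertile boundary of both
analysis samples: `tertile_threshold` puts the lowest `n//3` cases
(`+1` when `n % 3 == 2`, the integer partition nearest to thirds with
ties toward a smaller lowest tertile) below the boundary and returns
the open-closed interval between the largest low and smallest high
value — (15.2%, 19.05%] for the 17-case view, (18.6%, 24.3%] for the
10-case year-2 view, both containing 19%. Any threshold inside the
interval induces the same split. Fewer than three distinct values, or
no boundary with distinct values, is a degenerate-calibration error.

The default factor coding has 8 factors: the five adaptation
indicators, system size, FIT type (OC-Auto/OC-Light vs other), and
prior-research participation. Size is three-level {1, 2–4, ≥5} by
default — a 5-clinic system belongs to the largest class — with a
binary single/multi coding available; the year-1 pathway encodings use
the derived binary `multi_clinic` factor appended to the default
coding. The original analysis's exact 8-factor set is not recoverable;
candidate continuous variables (kits mailed, adaptation count,
participation length) are excluded from the default set because no
calibration rule exists for them. Codings are fully overridable and the
effective coding is echoed into every report.

## Configurational engine

Scoring uses exact rationals: a configuration (conjunction of
factor-level literals, each factor at most once, order ≤ 5 by default)
has consistency |X∧Y|/|X| and coverage |X∧Y|/|Y|. Thresholds are
converted from their decimal notation to exact fractions (0.95 →
19/20), so "≥ 95%" never suffers a floating-point artifact. A
configuration matching no case has *undefined* (not zero, not NaN)
consistency; a table without positives has undefined coverage and an
empty MSC set.

**MSC enumeration.** A minimally sufficient condition meets the
consistency threshold and the coverage floor while no proper
sub-conjunction does. The published procedure describes
complexity-ordered redundancy pruning without a formal rule; this
engine adopts the standard sub-conjunction minimality criterion, which
is directly oracle-testable (the test suite compares against an
independent exhaustive brute force on randomized tables).

**Relaxation.** Search starts at 100% consistency and drops in 5-point
steps until MSCs emerge; the model object's `fit()` keeps relaxing past
that point if the MSCs found cannot be assembled into any model
clearing both model floors, stopping at the 80% model-consistency
floor. Exhausting thresholds is a reported no-solution outcome, not an
exception.

**Model assembly.** All subsets of the MSC list up to 5 pathways are
scored on the *union* of matched cases (a case covered twice counts
once — this is what makes "9/9 consistency, 9/11 coverage" arithmetic
cohere). Subsets containing a redundant disjunct (one pathway's
matched-positive set inside another's) are discarded. Models must reach
≥ 80% consistency and ≥ 70% coverage; ranking is consistency desc,
coverage desc, fewer pathways, then lexical literal order, making
output byte-deterministic.

**Contradictions.** Cases identical on every factor but with mixed
outcomes are grouped and reported with every result; no 100%-consistent
pathway can cover them. Under the default coding the 17-case view
contains two such pairs (S4/S9 and S13/S17). The original report
narrates a single contradictory pair; its unstated factor set evidently
separated one of the two. The engine reports whatever the configured
coding implies.

## Reproduction choices and known divergences

* **Coverage floor vs single-case pathways.** The nominal 15% MSC
  coverage floor excludes any single-case pathway in both the 17-case
  (1/11 ≈ 9%) and change (1/7 ≈ 14.3%) analyses, yet the published
  models contain n=1 pathways in both. The floor therefore cannot have
  bound the final printed pathways. The package keeps 0.15 as the
  default but the change-analysis runner lowers it to 0.10 so a pathway
  covering one of seven improvers is admissible; with that floor the
  engine's own search assembles exactly the published three-pathway
  change model (5/5 consistency, 5/7 coverage).
* **Year-1 mailed-return pathway.** The narrative places "mailed return
  with no other adaptations" among multi-clinic systems, but the only
  success it can cover is a single-clinic system. The default encoding
  drops the size conjunct (coverage 9/11 = 82%, matching print); the
  multi-clinic variant is computed and reported alongside (it covers
  8/11). Model-level consistency of the printed four pathways under our
  encoding is 9/12, not the printed 9/9, because the size-free
  mailed-return pathway also matches three non-successes; coverage is
  unaffected.
* **Year-2 model.** The published year-2 model (coverage 86%, incentive
  pathway n=2) is not reproducible from the printed data: three
  two-year systems used incentives in 2017 and all succeeded, so every
  faithful encoding of "incentive" covers three cases and the
  two-pathway model covers 7/7. It is reported informationally, never
  asserted.
* **Non-OC mean mailing size.** The pooled mean of printed kit counts
  for non-OC systems is 1077/7 ≈ 153.9 (prints 154), not the published
  153; the cell is reported informationally.
* **Rounding.** Printed percentages use half-away-from-zero rounding on
  exact rationals; this reproduces every overall cell (e.g. the 2017
  median 24.505% → 25%, and 22.515% → 23% in the scrubbing range).

## Regression

Weighted least squares (statsmodels `WLS`) of the completion rate on
the adaptation count, weights = kits mailed, pooling both program years
(27 observations; a per-year option exists). The slope's p-value is the
classical two-sided t test on n − 2 degrees of freedom; the source
analysis does not name its procedure, and with unit (equal) weights the
fit reduces exactly to OLS (property-tested). Rates enter as
proportions so the slope (0.0398, printing 0.04) reads as ~4 percentage
points per adaptation.

## Synthetic data

`PlantedStructure` generates binary condition tables from a known DNF:
independent Bernoulli factors at configurable prevalences (default 0.5,
with an optional pairwise-copy correlation knob, default off, since
real adaptations co-occur), outcome = DNF truth value, then symmetric
outcome flips with probability `noise_rate` (the program gives no error
model; symmetric flipping is the neutral choice). An exhaustive
full-factorial layout supports exact-recovery tests: on noise-free
factorials whose disjuncts all clear the coverage floor, the top
assembled model equals the planted DNF (the MSCs of such a table are
its prime implicants). Default `n_cases=32` reflects the small-n regime
of system-level implementation data (tens of cases, not thousands).

What the generator does *not* emulate: continuous screening rates (it
targets the post-dichotomization layer), confounding between size, FIT
type and adaptations, or year-over-year dependence. Passing recovery
tests therefore demonstrate engine correctness, not robustness of the
substantive findings to those real-data features.

## Limitations

Tiny case counts make configurational results sensitive to the factor
coding; exhaustive subset assembly is exponential in the MSC count and
pathway cap (fine at these scales, capped at 5 pathways). All
observational caveats of the underlying program data apply: no control
systems, confounded size/FIT-type/adaptation choices, claims-based
outcome ascertainment.
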