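# Methods

## Compartmental model

The drug model is a linear two-compartment system with central
(`C1`, volume `V1 = 3.12` L) and peripheral (`C2`, `V2 = 1.65` L)
blood pools exchanging at flow `Qb = 0.12` L/day, and first-order
elimination (`K = 0.0368` day⁻¹) from the peripheral pool. A third,
intestinal compartment carries MAdCAM-1, suppressed algebraically by
the peripheral concentration through a Hill effect with baseline
`M0 = 2.23e-2` mg/L, maximum fractional suppression `Emax = 0.956`,
Hill coefficient `gamma = 0.3512` and half-effect concentration
`E50 = 0.093` mg/L. All times are days and concentrations mg/L.

Two unit conventions in the source constants are internally
inconsistent as printed (`Qb` in "L/g", `K` in "g⁻¹"); the only
dimensionally coherent reading of the rate equations is `Qb` in L/day
and `K` in day⁻¹, which also gives an elimination half-life
ln 2 / K ≈ 18.8 days, squarely inside the 14–21-day range reported for
this antibody. The package adopts that reading. Likewise the effect
equation is implemented as a pointwise algebraic map `M(t) = f(C2(t))`
(no lag): MAdCAM-1 is treated as directly and instantaneously
controlled by peripheral drug.

Assumptions worth keeping in mind: each compartment is perfectly
mixed; doses are instantaneous concentration jumps in `C1`; there is no
target-mediated disposition, no inter-individual variability and no
feedback from the intestine onto the kinetics.

### Dosing

The standard regimen is 300 mg IV at weeks 0, 2 and 6, then every
8 weeks through week 52 (weeks are converted at 7 days/week). A dose
adds `dose_mg / V1` to `C1` at the nearest grid point not after the
event time. The week-0 event is special-cased to set `C1(0) = 60` mg/L
directly — the initial condition the model is calibrated to — rather
than 300/3.12 ≈ 96 mg/L; both behaviours are expressible in the config
(`c1_increment` vs `dose_mg` entries).

### Numerics

The forward solver is explicit Euler with default step `h = 0.01` day,
chosen so the discretisation error (first order in `h`) sits far below
the resolution of any clinical observation: against the exact
eigendecomposition solution of the linear system the Euler trajectory
stays within 0.1% relative error over a full year, and the test suite
checks the error halves when `h` halves. The closed-form solution
handles a (numerically) repeated eigenvalue by falling back to the
matrix exponential. With `K = 0` the symmetric exchange terms cancel
exactly, so `V1·C1 + V2·C2` is conserved to machine precision even in
the Euler update — a structural check the tests exploit. Elimination-
rate fitting (`fit_elimination_rate`) runs Levenberg–Marquardt least
squares on log K against the closed form, so it is fast and cannot
leave the positive half-line.

## Permeability

Apparent permeability of the 4 kDa FITC-dextran probe (FD4) is
`Pm = Qt·δm/(S·t·C0)` with chamber defaults `S = 0.017` cm²,
`C0 = 1e4` pmol/cm³, `δm = 2.175e-3` cm. `Pm` is kept in cm²/s
internally; `pm_to_table_units` scales by 1e6 for display. TEER enters
as validated raw data only — no equation links it to the model — so it
participates solely in the statistics module.

## Concentration links

The links are empirical regressions of *Roseburia* relative abundance
(`Cb`) and permeability (`Pm`) on the logarithm of the central
concentration `C1` expressed in mg/mL. The logarithm is natural: at
the 0.06 mg/mL initial condition the permeability link then reproduces
the observed pre-treatment cohort mean (0.883×10⁻⁶ cm²/s) to 0.2%,
whereas a base-10 reading misses by about 7%. This choice is encoded
in a test.

Fitting is ordinary least squares of the response on ln C1
(statsmodels), with the coefficient of determination computed against
the mean-only null. A two-point fit is reported as r² = 1 exactly.
Inversion is closed-form (`exp((y − intercept)/slope)`). Negative
permeability predictions — possible below `exp(−intercept/slope)` ≈
2.5×10⁻¹² mg/mL, far outside the calibrated range — are clamped to
zero with a warning rather than raised, since the link is an empirical
line, not a mechanism. When a link is composed with a trajectory, the
mg/L output is divided by 1000 at the interface, and non-positive grid
points are masked as NaN and reported, never silently dropped.

Which concentrations anchored the original three-phase regression
(pre-dose troughs vs the 60 mg/L initial value) is not recoverable
from the published summaries, so the fitted r² values of the original
curve fits are not asserted anywhere; `fit_link` is exposed so any
anchoring convention can be tested.

## Clinical statistics

Cohort summaries report mean, median, sample standard deviation
(n − 1 denominator), minimum and maximum; a single-value column is
flagged and its std reported as 0. The paired t-test works on
differences with n − 1 degrees of freedom; a constant nonzero shift
(zero-variance differences) yields a signed infinite statistic with
p = 0, and identical lists raise a degenerate-test error. Pearson
correlations are tested via t = r√(n−2)/√(1−r²) on n − 2 df.

Score–histology correlations pool the per-patient, per-phase
(activity score, RHI) pairs across the three time points within each
disease group: 7 UC patients × 3 phases = 21 PMS/RHI pairs, 4 CD
patients × 3 phases = 12 HBI/RHI pairs. This pooling convention
reproduces both reference coefficients (0.751 and 0.651) exactly to
three decimals, and is therefore the convention the report uses. The
CD correlation is significant at 0.011 only one-tailed (two-tailed
0.022), so the report always prints both tails and flags the
discrepancy rather than silently choosing one.

No multiple-testing correction is applied (none is standard for a
pilot cohort of this size, and the report is descriptive).

## Synthetic cohorts

The generator emulates the study conditions: 11 patients (7 UC, 4 CD)
with three phases, declining activity scores and RHI, rising TEER,
falling FD4 permeability and rising *Roseburia*. Defaults are the
observed per-phase summaries: activity-score and RHI means/stds
computed from the built-in patient table; TEER means (12.27, 18.12,
18.36) Ω·cm² with stds (3.15, 7.23, 4.86); permeability means (0.883,
0.814, 0.735)×10⁻⁶ cm²/s with stds (0.451, 0.446, 0.552)×10⁻⁶.
*Roseburia* per-phase values are not published numerically, so its
default means are derived by chaining the two links (invert the
permeability link at each phase-mean permeability, evaluate the
abundance link there), giving an increasing sequence ≈ (0.0266,
0.0277, 0.0289); a 20% coefficient of variation is assumed as the
modelling choice for its spread.

Positive endpoints are drawn from truncated normals whose parent
mean/sd are solved (scale-invariantly, in std units) so the truncated
distribution has exactly the configured mean and sd — "matching the
printed mean/std" is taken literally. The activity score and RHI are
drawn through a Gaussian copula, scaled to the phase mean/sd, rounded
to integers and floored at zero. Because the pooled (across-phase)
correlation mixes within-phase noise with the systematic co-movement
of the phase means, the latent copula correlation is solved from the
pooled-variance decomposition so that the pooled score–RHI Pearson
correlation hits the configured target (default 0.75) in expectation;
a target needing |latent ρ| > 1 raises an explicit infeasibility
error. The small biases introduced by rounding and flooring are
measured in the tests (they stay within sampling noise at n = 2000)
rather than corrected.

One global seed governs everything; each patient draws from a spawned
substream keyed by patient index, so enlarging a cohort never
reshuffles earlier patients. What the generator does **not** emulate:
per-patient longitudinal autocorrelation beyond the phase means,
heavy tails or skew in TEER/permeability (only the first two moments
are matched), any dependence between the barrier endpoints and the
scores, or sequence-level microbiome structure. Tests passing on
synthetic cohorts therefore certify the pipeline's correctness and
stability, not distributional claims about real patients.

## Problem sizes

The moment-recovery checks run at n = 2000 patients, large enough that
three standard errors is a few percent of each mean; pipeline
stability is exercised over 100 seeds at the study size n = 11; solver
oracle comparisons span 364 days at h = 0.01 (36 401 grid points).

## Known limitations

- The kinetic model has no absorption phase, no target-mediated
  clearance and no covariates; it is a descriptive, not population,
  model. Under the full multi-dose schedule it accumulates drug more
  than published trough data suggest late in maintenance.
- The links are two-parameter empirical lines fitted to three phase
  means; they should not be extrapolated far below ~10⁻³ mg/mL.
- Raw per-patient TEER/permeability values are not published, so those
  endpoints can only be validated against summary statistics.
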