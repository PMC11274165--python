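# vedolink

Compartmental pharmacokinetics/pharmacodynamics of intravenous
vedolizumab coupled to gut-barrier readouts, plus the clinical
statistics pipeline of a three-phase inflammatory bowel disease (IBD)
cohort.

Vedolizumab is an anti-α4β7-integrin antibody that blocks lymphocyte
homing to the gut endothelium. This package is for modellers and
clinical researchers who want to (i) simulate the drug's blood
concentrations and its suppression of the adhesion molecule MAdCAM-1
under a multi-dose schedule, (ii) propagate those concentrations into
predicted intestinal permeability and *Roseburia* abundance through
empirical log-linear links, and (iii) reproduce the paired-test /
correlation analysis of an 11-patient ulcerative colitis (UC) /
Crohn's disease (CD) cohort observed before treatment (t0), at 24
weeks (t1) and at 52 weeks (t2).

## The model

Two blood compartments exchange drug at flow rate $Q_b$; elimination is
first order (rate $K$) from the peripheral compartment:

$$\frac{dC_1}{dt} = \frac{Q_b}{V_1}(C_2 - C_1), \qquad
  \frac{dC_2}{dt} = \frac{Q_b}{V_2}(C_1 - C_2) - K C_2 .$$

The intestinal MAdCAM-1 concentration responds to the peripheral drug
level through a Hill (Emax) effect:

$$M = M_0\left(1 - \frac{E_{\max}\, C_2^{\gamma}}{E_{50}^{\gamma} + C_2^{\gamma}}\right).$$

Defaults: $Q_b = 0.12$ L/day, $V_1 = 3.12$ L, $V_2 = 1.65$ L,
$K = 0.0368$ day⁻¹, $M_0 = 2.23\times10^{-2}$ mg/L, $E_{\max} = 0.956$,
$\gamma = 0.3512$, $E_{50} = 0.093$ mg/L. The standard regimen is
300 mg IV at weeks 0, 2, 6, then every 8 weeks through week 52, with
the week-0 bolus setting $C_1(0) = 60$ mg/L.

Two empirical log-linear links map the central concentration $C_1$
(in mg/mL, natural log) to clinical observables:

$$C_b = -0.5750\times10^{-3}\,\ln C_1 + 2.4967\times10^{-2}
  \quad (\textit{Roseburia } \text{relative abundance}),$$
$$P_m = 0.0370\times10^{-6}\,\ln C_1 + 0.9885\times10^{-6}
  \quad (\text{FD4 permeability, cm}^2/\text{s}).$$

Apparent permeability itself comes from Ussing-chamber FD4 flux:
$P_m = Q_t\,\delta_m / (S\,t\,C_0)$.

## Worked example

```python
import numpy as np
from vedolink import (simulate, DoseEvent, link_time_course,
                      PKParameters, PDParameters,
                      fixture_cohort, run_study_analysis)

pk, pdp = PKParameters(), PDParameters()
traj = simulate(pk, pdp, [DoseEvent(time=0.0, c1_increment=60.0)],
                t_end=364.0, h=0.01)
course = link_time_course(traj)
```

Printing a few grid points of the single-bolus run:

```
  day    C1 [mg/L]   C2 [mg/L]   M [mg/L]      Cb        Pm [cm^2/s]
    0      60.000       0.000   2.23e-02   0.02658    8.844e-07
   14      42.395      24.679   3.61e-03   0.02678    8.716e-07
   56      26.286      19.242   3.82e-03   0.02706    8.539e-07
  182       7.197       5.274   5.14e-03   0.02780    8.059e-07
  364       1.109       0.812   7.77e-03   0.02888    7.367e-07
```

The drug decays from its 60 mg/L bolus to ~1 mg/L over a year while
MAdCAM-1 collapses from its baseline 2.23×10⁻² mg/L within days and
slowly relaxes back as drug is consumed. The linked permeability falls
from 0.884×10⁻⁶ to 0.737×10⁻⁶ cm²/s — bracketing the observed cohort
means at t0 (0.883×10⁻⁶) and t2 (0.735×10⁻⁶) — while *Roseburia*
abundance rises in parallel.

The clinical pipeline on the built-in 11-patient cohort:

```python
report = run_study_analysis(fixture_cohort())
```

```
UC: r = 0.751 over 21 PMS/RHI pairs (two-tailed p = 8.7e-05)
CD: r = 0.651 over 12 HBI/RHI pairs (one-tailed p = 0.011)
RHI t0 vs t2: t = 5.61, df = 10, p = 2.3e-04
```

Disease-activity scores (Partial Mayo Score for UC, Harvey–Bradshaw
Index for CD) correlate positively with the Robarts Histopathological
Index, and histology improves strongly over the year of treatment.

The same stages are available from a shell:

```sh
vedolink simulate --out out/            # trajectory.csv with Cb/Pm columns
vedolink analyze  --out out/            # report.yaml on the built-in cohort
vedolink generate --seed 42 --out out/  # seeded synthetic cohort.csv
vedolink fit-link --input pairs.csv --out out/
```

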