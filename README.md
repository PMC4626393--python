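# cohortbump

Automatic detection of **local birth-cohort effects** in age-period
mortality tables, for epidemiologists and biostatisticians working with
cancer-registry style data (deaths and person-years tabulated by 5-year
age group and calendar period).

Classical age-period-cohort displays make cohort effects hard to spot:
a cohort born in year *c* runs along the diagonal *p − a = c* of the
Lexis table, and a short-lived excursion confined to a few birth years
is easily lost in the age and period trends. `cohortbump` models the
log mortality rate as a smooth varying coefficient over the age-period
plane plus an explicit Gaussian bump on the cohort diagonal, so a local
cohort effect becomes a single testable parameter.

## Model

Deaths in cell *(a, p)* with exposure *z<sub>a,p</sub>* person-years are

&nbsp;&nbsp;&nbsp;&nbsp;*d<sub>a,p</sub>* ~ Poisson(*z<sub>a,p</sub>* λ<sub>a,p</sub>),&nbsp;&nbsp;
log λ<sub>a,p</sub> = β₀(*a*, *p*)

with the varying coefficient

&nbsp;&nbsp;&nbsp;&nbsp;β₀(*a*, *p*) = **θ**′**x**(*a*, *p*) + β<sub>c</sub> φ(*p − a*; μ<sub>c</sub>, σ<sub>c</sub>²),

where **x**(*a*, *p*) is the 16-term tensor product of cubic
polynomials in (scaled) age and period — it absorbs age trends, period
trends and *global* (gradual) cohort trends — and φ is the normal
density in birth year, centred at μ<sub>c</sub> with width σ<sub>c</sub>.
For fixed (μ<sub>c</sub>, σ<sub>c</sub>), (**θ**, β<sub>c</sub>) are
estimated by Poisson maximum likelihood with offset log *z*; the bump
location itself is chosen by minimising the profile deviance −2ℓ̂ over a
grid of integer (μ<sub>c</sub>, σ<sub>c</sub>) candidates. The cohort
effect is reported as the relative risk

&nbsp;&nbsp;&nbsp;&nbsp;RR(*c*) = exp(β<sub>c</sub> φ(*c*; μ<sub>c</sub>, σ<sub>c</sub>²)),

which peaks at exp(β<sub>c</sub> / (σ<sub>c</sub>√(2π))) on the diagonal
*c = μ<sub>c</sub>*. A Wald z-test of β<sub>c</sub> = 0 gives the
significance of the effect, and the effect counts as **local** only
when σ<sub>c</sub> is at most 5% of the observed birth-year span —
a wide best-fitting bump means the Gaussian column is merely helping
the polynomials fit a global trend.

## Worked example

Simulate a registry-like table (17 five-year age groups × 11 periods,
10⁶ person-years per cell) with an elevated cohort planted at birth
year 1950, width 4, β<sub>c</sub> = 4.3, then run the detector:

```sh
cohortbump simulate --kind bump-positive --seed 7 --out sim.csv
cohortbump detect --input sim.csv --mu-grid 1930:1970 --sigma-grid 1:10 --out results/
```

prints

```
wrote 187 cells to sim.csv (23743 deaths)
best bump: mu_c=1949, sigma_c=3; beta_c=3.1605 (SE 0.2656, z=11.90, p=1.16e-32); local (sigma_c/span=0.023); extreme RR=1.52
```

Reading the output: the profile-deviance search put the bump at birth
year 1949 with width 3 — one grid step off the planted (1950, 4), the
expected sampling scatter at these exposures. The Wald test rejects
β<sub>c</sub> = 0 overwhelmingly (z = 11.9), the width is 2.3% of the
130-year birth span so the effect is classified local, and the cohort's
mortality peaks at 1.52 times the smooth background — close to the
planted peak of exp(4.3/(4√(2π))) ≈ 1.54. `results/` contains
`fit.json` (full coefficient table with SEs, z- and p-values),
`grid.csv` (deviance at every candidate bump), `rr_curve.csv` (RR by
birth year) and `surface.csv` (fitted Lexis surface of rates per
100 000 person-years).

The same analysis from Python, scikit-learn style:

```python
import numpy as np
import cohortbump as cb

table = cb.read_table("sim.csv")
det = cb.CohortBumpDetector(mu_grid=np.arange(1930, 1971),
                            sigma_grid=np.arange(1, 11))
det.fit(np.column_stack([table.ages, table.periods]),
        table.deaths, exposure=table.person_years)
det.mu_c_, det.sigma_c_, det.beta_c_, det.beta_c_p_, det.is_local_
```

Estimators follow sklearn conventions (`get_params`/`set_params`,
`clone`, fitted attributes with trailing underscores), so they compose
with sklearn tooling; `cb.fit_ml`, `cb.grid_search` and `cb.detect`
offer the same functionality on `AgePeriodTable` objects.

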