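# cardioage

Correlation-weighted ODE modelling of premature cardiovascular aging.

Immunosenescence and biochemical decline leave measurable traces — monocyte
and NK-cell surface markers (CD14, CD16, CD56, HLA-DR), antioxidant and renal
markers (SOD, GFR, cystatin C), inflammation (CRP) — and these interact with
clinical and behavioural factors (BMI, education, physical activity,
hypertension, prior infarction).  `cardioage` implements a compact modelling
chain for studying such interactions in elderly cohorts, aimed at
biostatisticians and modellers who want a reproducible, testable version of
the correlation-weighted aging ODE:

1. **Synthetic cohorts** (`cardioage.cohort`) — Gaussian-copula generation of
   patient tables with the study's exact composition (n = 52: 30 CVD /
   22 non-CVD, 18 men / 34 women) and a *planted* correlation structure
   across continuous, binary and ordinal variables, because the original
   patient data are private.
2. **Pearson screening** (`cardioage.screen`) — the cross-block correlation
   matrix between clinical/social factors and a biomarker block, and
   selection of the top-k pairs by |r|.  The six published coefficient sets
   (immunological & biochemical blocks × all / CVD / non-CVD cases) ship as
   fixtures.
3. **The aging model** (`cardioage.model`) — the ODE

   &nbsp;&nbsp;&nbsp;&nbsp;dA/dt = Σᵢ aᵢ·xᵢ(t)·yᵢ(t),&nbsp;&nbsp; i = 1…6,

   with aᵢ the Pearson coefficients, xᵢ a social factor, yᵢ a biomarker,
   time-varying factors built by the documented grid recurrence, and the
   exact quadrature reference solution.
4. **Integrators & error analysis** (`cardioage.solvers`,
   `cardioage.errors`) — classical RK4, two-step Adams–Bashforth and backward
   Euler against the exact solution; maximum-error reports and empirical
   convergence orders.  Because the right-hand side is state-independent,
   RK4 is provably composite-Simpson quadrature — an identity the test suite
   exploits as an oracle.

## Worked example

Plant the published CVD-group immunological correlation structure in a large
synthetic cohort, screen it back out, then compare the three solvers on the
corresponding model:

```python
from cardioage import (CohortSpec, correlation_from_pairs, default_catalog,
                       fixture_set, generate_cohort, pearson_matrix,
                       select_top_pairs, run_experiment)

catalog = default_catalog()
planted = [(p.social, p.biomarker, p.coefficient)
           for p in fixture_set(1, "B").pairs]
spec = CohortSpec(n_total=5000, n_cvd=2885, n_non_cvd=2115,
                  n_male=1731, n_female=3269, seed=42,
                  target_correlation=correlation_from_pairs(catalog, planted))
cohort = generate_cohort(spec, calibrate=True)

matrix = pearson_matrix(cohort.df, catalog.by_role("clinical_social"),
                        catalog.by_role("immunological"))
for pair in select_top_pairs(matrix, k=6).pairs:
    print(f"{pair.social:>5s} x {pair.biomarker:<7s} r = {pair.coefficient:+.3f}")

report = run_experiment(1, "B")
print("ranking:", report.ranking)
for method, err in sorted(report.errors.items()):
    print(f"max |exact - {method}|: {err:.3e}")
```

Output:

```
  BMI x HLA.DR  r = +0.486
    E x HLA.DR  r = +0.431
 PICS x CD14    r = +0.392
    E x CD56    r = +0.376
   AH x CD16    r = +0.375
  CHD x IPGF    r = +0.366
ranking: ['rk4', 'ab2', 'backward_euler']
max |exact - ab2|: 2.038e-06
max |exact - backward_euler|: 2.594e-03
max |exact - rk4|: 2.776e-17
```

The screen recovers all six planted pairs (coefficients slightly off their
targets: finite-sample noise at n = 5000 plus residual threshold attenuation
on the binary factors).  In the solver comparison RK4 is exact to rounding —
with linearly-growing factors the integrand is piecewise quadratic, which
Simpson integrates exactly — backward Euler carries its first-order
`(dt/2)·(f(T) − f(0))` error, and a correctly indexed AB2 sits in between at
second order.

## Command line

```bash
cardioage run-all --seed 1 --out-dir runs/demo        # full pipeline
cardioage generate-cohort --out cohort.csv --seed 1
cardioage screen --cohort cohort.csv --problem 1 --case B --out-prefix scr
cardioage report --problem 2 --case C --out report.json
cardioage solve --problem 1 --case A --method rk4 --out series.csv
```

`run-all` writes the cohort, six screening matrices and interaction sets,
six solved series, six error reports, a combined error table and a log that
echoes every configuration flag, the seed and the config hash.  Runs with the
same configuration are byte-identical; a failed run leaves its partial
outputs quarantined in `<out>.partial`.

Key switches (flags or YAML config): `--profile {fine_dx,coarse_dx}` (grid
reading), `--increment-rule {unit,step_index}` (trajectory recurrence),
`--ab2-start {rk4,forward_euler}`, `--trajectory-mode {recurrence,external}`.
Defaults and their rationale: [docs/methods.md](docs/methods.md).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Recomputes, from scratch under the default configuration, the maximum
absolute errors of the three integrators against the exact reference for the
published experiments (immunological and biochemical models, cases A–C) and
writes them as JSON keyed by target id.
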