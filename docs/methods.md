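# Methods

## The model

Premature cardiovascular aging is represented by a scalar state `A(t)` whose
rate is a fixed linear combination of pairwise interactions between
clinical/social factors `x_i` and biomarkers `y_i`:

    dA/dt = Σ_{i=1..k} a_i · x_i(t) · y_i(t),        k = 6 by default.

The weights `a_i` are Pearson correlation coefficients — either screened from
a cohort table (`cardioage.screen`) or taken from the six published
coefficient sets shipped as fixtures (two biomarker blocks — immunological
and biochemical — crossed with three patient cases: all, with CVD, without
CVD).  The right-hand side never references `A`: the ODE is a quadrature
problem in disguise, and that single fact drives most of the numerical
behaviour documented below.

Assumptions inherited from the source formulation and kept deliberately:

* linear (Pearson) association is an adequate interaction measure;
* the six largest-|r| cross-block pairs define the model; no p-value or
  multiplicity filtering is applied;
* the factors evolve on a shared deterministic time grid (below); biology
  enters only through the coefficients and the trajectory construction.

## Trajectories

Each factor named by the interaction set is tabulated on a uniform grid of
`N` steps of size `dt` by the recurrence

    P(0) = 1,    P(n) = P(n-1) + i·dx .

The increment symbol `i` is undefined in the source; both readings are
implemented (`increment_rule`):

* `"unit"` — `i = 1`, giving linear growth `P(n) = 1 + n·dx` (**default**);
* `"step_index"` — `i = n`, giving `P(n) = 1 + dx·n(n+1)/2`.

The unit rule is the default because the step-index rule inflates every
factor ~50-fold over the unit interval (at `dx = 0.01`), which drives all
method errors 3–7 orders of magnitude above every published error value;
under the unit rule the backward-Euler errors land inside the published
band.  The "zero initial conditions" of the source apply to the aging state
(`A(0) = 0`), not to the factors, whose boundary value is 1 — otherwise every
product would vanish and all methods would be trivially exact.

Externally supplied trajectories (a CSV with one column per factor) replace
the recurrence via `trajectory_mode="external"`, for users holding real
longitudinal data.

### Grid profiles

The two published parameter statements conflict: the running text says
`dx = (1-0)/100 = 0.01` with `N = 100`, the modelling-parameters table says
`dx = 0.001` with `N = 1000`.  Both satisfy `dx = (b-a)/N`, so `N` counts
`dx`-increments, while the number of *time* steps is `(b-a)/dt = 100` under
either reading.  Shipped profiles:

| profile     | dt   | dx    | time steps | interval |
|-------------|------|-------|------------|----------|
| `fine_dx`   | 0.01 | 0.001 | 100        | [0, 1]   |
| `coarse_dx` | 0.01 | 0.01  | 100        | [0, 1]   |

`fine_dx` (the table reading) is the default: with unit increments it
reproduces the magnitude regime of the published error tables (backward-Euler
errors 2.1–2.8·10⁻³ against printed 2.7–4.2·10⁻³).

## The reference ("exact") solution

Because the rhs is state-independent, the exact solution is the time integral
of the rhs.  Trajectories are continued piecewise-linearly between nodes, so
each per-step integrand is a product of two linear functions — a quadratic —
and the reference accumulates its closed-form integral step by step
(`reference="integral"`, default).  Two lower-fidelity readings of the source
formulation are retained for comparison:

* `"product"` — `A_n = dt·n·rhs_n`, the literal closed form printed in the
  source; it solves the ODE only when the rhs is time-constant.  Under this
  reference the model discrepancy `t·f(t) − ∫f` dominates every method
  equally and the method comparison loses meaning.
* `"cumulative_left"` — the left-Riemann accumulation
  `A_{n+1} = A_n + dt·rhs_n`, the finite-difference reading of the same
  closed form.

## Integrators

All three schemes reduce to quadrature rules:

* **RK4** — one step is Simpson's rule over `[t_n, t_{n+1}]`; the half-step
  rhs comes from linearly interpolated trajectories (interpolate the factors,
  then multiply).  The two middle stages coincide exactly (`k2 = k3`).  With
  unit-rule trajectories the interpolation is exact and the integrand is
  quadratic, so RK4 agrees with the reference to rounding (~10⁻¹⁶); its
  theoretical fourth order is observable in the closed-form-rhs convergence
  suite, where stages are evaluated analytically.
* **AB2** — `A_{i+1} = A_i + dt·(3/2·f_i − 1/2·f_{i-1})`, first step by one
  RK4 step (default) or forward Euler (`ab2_start`).
* **Backward Euler** — `A_{i+1} = A_i + dt·f_{i+1}`; state-independence makes
  the implicit equation explicit, so no iteration is performed (and stiffness
  machinery would be pointless).

Empirical convergence orders on `f(t) = e^t` over `dt ∈ {0.02, 0.01, 0.005}`
recover the textbook 4 / 2 / 1.  The source labels backward Euler as
second-order and Adams–Bashforth as first-order; the implemented formulas
outrank the labels, and the estimated orders are reported instead.

### The 3/2 signature, and why the published AB errors are irreproducible

In all six published experiments the Adams–Bashforth maximum error equals
exactly 1.5× the backward-Euler error, to every printed digit.  That ratio is
an algebraic identity under one specific implementation: if the reference is
the left-Riemann accumulation and the AB update reads *both* stencil points
one step late (`1.5·f_{i+1} − 0.5·f_i`), then the error telescopes to
`1.5·dt·(f_0 − f_n)` versus `dt·(f_0 − f_n)` for backward Euler — for any
trajectory data whatsoever.  `solve_ab2(variant="shifted")` implements that
update and reproduces the law bit-exactly; it is *not* a correct integrator
and is never the default.

A corollary: a correctly indexed AB2 has error ≈ `(5/12)·dt²·(f'(T) − f'(0))`
while backward Euler has ≈ `(dt/2)·(f(T) − f(0))`; for the trajectory family
`f(t) = S(1 + χt)²` their ratio is at most `(5/3)·dt ≈ 1/60` at `dt = 0.01`.
Demanding both errors inside `[10⁻³, 10⁻²]` on the same grid is therefore
unsatisfiable; the corresponding acceptance test is left red by design.

The per-case published values themselves scale with `f_N − f_0`, which under
the recurrence is a fixed multiple of the coefficient sum — but the printed
values do not follow any such common rule across cases (the authors state the
factor values "were read from the statistical database", which is private).
Exact per-case reproduction is consequently impossible; the pipeline
reproduces the method ranking, the backward-Euler magnitude band, and the
structural 3/2 law.

## Synthetic cohorts

The generator emulates the published composition exactly (counts are
assigned and shuffled, never sampled): 52 patients, 30/22 CVD split, 18/34
sex split, truncated-normal ages (means 82.9/81.5, sd 10.0, floor 60).
Correlation structure is planted through a Gaussian copula: latent normals
with the target correlation matrix, transformed per variable —

* continuous with a printed laboratory range: truncated-normal quantile
  transform, mean at the range centre, `sd = range/8` (±4σ truncation, so
  <10⁻⁴ of mass is clipped and sample moments stay within 2% of nominal);
* continuous without a range: affine, mean 1.0, sd 0.2 (normalised units);
* binary: threshold at the prevalence quantile (default 0.5);
* ordinal (education, alcohol, physical activity): three uniform levels.

No marginal summaries are published, so these marginals are conventions, not
reconstructions.  Thresholding attenuates planted correlations (for a
balanced binary against a continuous variable by φ(0)/0.5 ≈ 0.798); by
default this is left visible, and `calibrate=True` divides the latent
correlations by the analytic attenuation factors to hit observed targets.
Non-positive-semidefinite targets are rejected; `repair_psd=True` projects
onto the nearest valid correlation matrix (eigenvalue clipping with diagonal
rescaling).

What a green test does **not** establish: the generator produces no missing
data, no exclusion-criteria structure, no longitudinal correlation, and no
realistic marginal shapes for the immunological markers — it validates the
pipeline's statistical plumbing, not the biology.  At the study's n = 52,
screening is dominated by sampling noise: the planted-structure recovery rate
at n = 52 is reported but deliberately not asserted, mirroring the fragility
of top-|r| selection at that sample size.

## Numerical choices

* Pearson matrices: two-pass centred products; constant columns yield NaN
  (flagged, warned, excluded from selection) — NaN never wins a ranking.
* Top-k selection: rank by |r| descending, signed r retained; ties break
  lexicographically by (social, biomarker).
* Maximum error: over all N+1 nodes, endpoints included.
* Ties in the method ranking are declared (all-zero coefficient sets) when
  the error spread is ≤ 1e-15.
* Degenerate inputs: `N = 0` grids return the bare initial value; `dx = 0`
  gives constant-one trajectories; empty cohorts (n = 0) are valid tables.
* Convergence slopes: least-squares fit of log(max error) on log(dt); a
  method whose errors are all below 1e-14 is reported "exact" (rounding
  noise has no order).
* Cohort CSVs are written with 17 significant digits so save → load is a
  cell-exact identity.

## Known limitations

* The published per-case error values cannot be matched (private data; see
  the 3/2 analysis above).  Honest recomputations under the documented
  defaults are what the acceptance script reports.
* RK4's grid-mode accuracy is floor-limited by trajectory interpolation; on
  step-index trajectories it degrades to second order (noted in reports via
  the configuration flags echoed into every output).
* Screening reproduces only the top-6 published entries per case; the full
  published correlation matrices are shown only as figures and are not
  reconstructable.
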