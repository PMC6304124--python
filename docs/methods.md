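# Methods

## Model

`activedrop` analyses a two-dimensional droplet of an *active*, growing
Darcy fluid (a minimal continuum picture of a carcinoma spreading in an
epithelial monolayer) embedded in a passive, non-growing Darcy fluid.
Inside the droplet the force balance and mass conservation read

    grad p = -beta v + alpha v/|v|,        div v = k,

with `beta` the friction against the substrate (proportional to tissue
viscosity), `alpha` the magnitude of the active traction (independent of
speed, aligned with the local velocity), and `k` the uniform net growth
rate.  The surrounding tissue obeys plain Darcy flow, `grad p' = -beta' v'`,
`div v' = 0`.  At the interface the radial velocities are continuous and the
pressure jump equals the Laplace pressure with surface tension `gamma`.
Inertia, in-plane viscous shear, interfacial bending stiffness, nutrient
limitation and mode coupling are all outside the model.

Dimensionless variables: lengths are scaled by the capillary length at which
growth balances surface tension — `l = (2 gamma/(beta k))^(1/3)` for
exponential growth (times by `1/k`), and `l = (gamma/(beta nu))^(1/2)` for a
radius growing linearly at interface speed `nu` (times by `l/nu`, so the
dimensionless interface speed is 1).  The coordinates of every analytic
result are `alpha` (activity over the reference `beta*l*k`, resp.
`beta*nu`), `phi = beta'/beta`, and `r0` (radius over `l`).

## Dispersion relation

Linearizing around the circular base flow (`v_rho = rho/2` inside,
`r0^2/(2 rho)` outside) with an interface perturbation
`delta r ~ f_n(t) e^{i n theta}` gives the instantaneous growth rate

    sigma_n(r0) = [ (phi-1)(n-1) - n(n^2-1)/r0^3 + Lambda_n(x) ]
                  / ( 2 (phi + 1 + Lambda_n(x) - n x) ),       x = 2 alpha / r0,

valid in the low-activity regime `alpha < r0/2`.  The linearized active term
turns the interior pressure perturbation into a solution of
`P'' + P'/rho - n^2 P/(rho(rho - 2 alpha)) = 0`; the branch analytic at the
origin is a degree-`n` polynomial with coefficients
`a_j = (-1)^j C(n,j)^2 / C(2n-1,j)`, and

    Lambda_n(x) = n x - 1 + n * [sum_j a_j x^j] / [sum_j (n-j) a_j x^j].

Structural identities (all asserted in the test-suite) pin the algebra:

* `Lambda_n(0) = 0` and `Lambda_1(x) = 0` (a rigid translation is neutral,
  `sigma_1 = 0` identically);
* `Lambda_2(x) = x(3x-4)/(2x-3)` in closed form;
* `Lambda_n(1) = n - 1` exactly — the interior polynomial vanishes at the
  turning circle `rho = 2 alpha`;
* at `alpha = 0` the rate reduces to Paterson's radial viscous-fingering
  result (with source strength `Q = pi r0^2`) plus the correction
  `1/(phi+1)` from growth inside the fingers.

Activity enters destabilizingly: wherever `sigma_n >= 0`, increasing `alpha`
cannot lower it (property-tested).  Deep in the stable regime (small `r0`,
large `n`) `sigma_n` can dip slightly with `alpha`, because the activity
correction also shrinks the positive denominator; the blanket statement
"`sigma` increases with `alpha`" holds across the fingering-relevant radii
(`r0 >~ 5`, `n <= 8` verified on a grid) and from the positive side always.

### Numerical evaluation of `Lambda_n`

The coefficient sums alternate in sign; for large `n` with `x` near 1 the
terms exceed the result by many orders of magnitude.  `lambda_mode` runs a
float Horner pass that tracks the largest intermediate term and falls back
to exact `fractions.Fraction` arithmetic whenever the estimated cancellation
exceeds ~1e-10 relative (or the coefficients overflow double range, which
happens for `n` of several hundred).  The two paths are property-tested
against each other on their overlap.  `lambda_mode_exact` exposes the
rational path directly for oracle-grade use.  `Lambda_n` is defined on the
closed interval `x in [0, 1]`: the endpoint is the exact, continuous limit
`n - 1` and is needed for marginal-activity linear growth (below);
`lambda_mode(0, x)` is 0 by convention and mode `n = 0` is rejected by
`sigma` (an area perturbation conflicts with the imposed growth).

## Onset of fingering

Mode 2 destabilizes first; `critical_radius` finds the smallest root of
`sigma_2(r0) = 0` with positive slope by scanning a 400-point geometric grid
from the validity floor `max(0.01, 2 alpha (1+1e-6))` to `1e6` and polishing
with Brent's method (`xtol = 1e-9`).  A droplet already unstable at the
floor is reported with `regime_valid=False` instead of being dropped — its
true onset lies in the high-activity region the theory does not cover.  For
`phi < 1` the passive droplet is unconditionally stable and fingering needs
a minimum activity; because the valid-onset region is a *window* in `alpha`
(at large activity the root meets the floor again), `min_activity_for_onset`
first scans a geometric `alpha` grid for an interior point and then bisects
the window's lower edge to `1e-6`.

For mid-range tissue parameters (`l ~ 27 um`) the dimensionless onset radii
of a few capillary lengths correspond to ~10-100 um; this soft consistency
check is logged, not asserted.

## Growth kinetics and mode selection

`KineticsSpec` carries the kinetics pair actually used by the theory:

* **exponential** (constant `k`): `dt/dr = 2/r`, `sigma` as above;
* **linear** (constant interface speed): the local growth rate is
  `k(t) = 2 nu / r0(t)` (uniform in space, decaying in time), the flow is
  quasi-static, and in linear-growth units

      sigma_n(r0) = [ (phi-1)(n-1) - n(n^2-1)/r0^2 + Lambda_n(alpha) ]
                    / ( r0 (phi + 1 + Lambda_n(alpha) - n alpha) ),

  with `dt/dr = 1`.  The activity argument is radius-independent, so
  activity never fades under linear growth; the low-activity condition
  becomes `alpha < 1`, and `alpha = 1` is accepted as the marginal,
  continuously attained boundary case.

`destabilization_radius` gives `R_n` (closed forms where available: the
passive exponential case and all linear-growth cases are polynomial roots),
`amplitude_gain` integrates `zeta_n(r0) = exp int_{R_n}^{r0} sigma_n dt` by
adaptive quadrature in `log r` (`epsrel 1e-10`, checked against a 1e5-point
trapezoid oracle), and `dominant_mode` takes the integer argmax of
`log zeta_n` — physical modes are integers; gains are compared in log space
to avoid overflow.  The mode cap defaults to three times the applicable
asymptotic estimate (minimum 64); for large caps the search narrows a
geometric grid iteratively (the gain profile is smooth in `n`) and finishes
exhaustively, and hitting the cap raises rather than silently truncating.
Ties break toward the smaller mode.  A continuous-`n` treatment is
deliberately not the default: at `alpha = 0` the rate is polynomial in `n`
and extends trivially, while a gamma-function extension of `Lambda_n` adds
nothing the integer search needs.

### Asymptotic finger counts

With `c ~ 0.0595` the smaller root of `3c = 3 + ln c` (`solve_c`, bisected
to 1e-14; the larger root `c = 1` is structurally excluded):

* exponential, `phi > 1`: `n_d ~ (c(phi-1))^(1/2) r0^(3/2)` — activity drops
  out; confirmed numerically to three digits at `r0 = 10^3`;
* exponential, `phi = 1`: `n_d ~ [(alpha/2)^2 + (alpha/2)^(1/2)]^(1/2) r0^(1/2)`,
  confirmed within ~12% over two decades *provided the whole history lies
  strictly inside the low-activity regime*.  For activities so large that
  low modes are already unstable at the floor `r = 2 alpha` (e.g.
  `alpha = 2`), the aggregated gains plateau and the dominant mode
  saturates instead of following the square-root law — the scaling
  studies here therefore use `alpha = 0.5`;
* exponential, `phi < 1`: no asymptotic count — destabilized modes
  restabilize as activity fades relative to the stabilizing viscosity
  mismatch (`None` is returned);
* linear: `n_d ~ (c(alpha+phi-1))^(1/2) r0`.  The `c^(1/2)` prefactor is
  this package's own result: it follows from the identical maximization
  that yields the `phi > 1` exponential law, and the direct numerical
  argmax converges to `c^(1/2) ~ 0.244` (0.245 at `r0 = 800`,
  `alpha = phi = 1`).  A widely quoted form of this law carries a bare
  `c ~ 0.06` instead; the acceptance suite records that discrepancy
  honestly rather than adopting either number by fiat.

## Droplet shapes

`synthesize_shape` superposes every mode destabilized by the final radius:

    r(theta) = r0 + sum_n  A0 * zeta_n(r0) * cos(n theta + phase_n),

with a common initial amplitude `A0 = 0.2` (about 2 um at mid-range
parameters) and one uniform random phase per mode, drawn in ascending `n`
from `numpy.random.default_rng(seed)` and held fixed — phases are assigned
once at destabilization, the minimal reading of "a random phase difference
between each mode".  Equal seeds give bit-identical contours; different
seeds change phases only.  The linear ansatz conserves area to first order
(the sampled perturbation has zero mean on the uniform 2048-point angular
grid).  Shapes whose perturbation exceeds 30% of the radius (or dip to
non-positive radius) are emitted with a warning, not refused — finite
fingers drawn from linear theory are illustrative.  The predicate
`kinetics_matching` (`4 beta nu^3 = gamma k^2`, relative tolerance 1e-9)
identifies the interface speed at which the exponential and linear
capillary lengths coincide, enabling cross-kinetics morphological
comparison.

## Parameters

| symbol   | meaning                    | unit       | default / range    |
| -------- | -------------------------- | ---------- | ------------------ |
| `k`      | net growth rate            | 1/s        | 1e-4               |
| `beta`   | droplet friction           | Pa s m^-2  | 1e15 (to 1e16)     |
| `beta'`  | surrounding friction       | Pa s m^-2  | 1e15               |
| `alpha`  | active traction            | Pa m^-1    | 0 (to ~1e10)       |
| `gamma`  | surface tension            | Pa m       | 1e-3 (to 1e-2)     |
| `nu`     | interface speed (linear)   | m/s        | required if linear |

Defaults sit at the low end of each experimentally estimated range so that
worked examples are reproducible; they give `l ~ 27 um`, reference activity
`~2.7e6 Pa/m`, pressure scale `~74 Pa` and velocity scale `~2.7e-9 m/s`.

## What the test problems do and do not show

All studies are exercises of the analytic model at chosen dimensionless
coordinates; there is no synthetic "data" beyond seeded parameter grids.
Passing tests demonstrate internal consistency of the implementation
(identities, oracles, scaling laws, determinism) — they say nothing about
whether real tumours obey Darcy dynamics, uniform growth, or speed-
independent traction.  The scaling sweeps use radii decades of 12 geometric
points ending where `Lambda` evaluation stays cheap (`r0 <= 6.4e3`
exponential, `10^3` linear); integer mode counts add ~`1/n_d` quantization
noise to fitted slopes, well inside the +-0.1 acceptance bands.

## Known limitations

* The high-activity regime (`alpha > r0/2`; bulk swirls) is out of scope;
  inputs there raise `RegimeError` (overridable to flagged results).
* Linear superposition only — no tip splitting or finger competition.
* `phi` exactly 1 is compared with `==` for branch selection in
  `asymptotic_nd`; pass the branch explicitly for near-degenerate ratios.
* The continuous-`n` dominant mode (smooth curves rather than integer
  steps) is not provided; the integer argmax is the physical answer.
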