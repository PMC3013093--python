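# Methods

## Model and assumptions

The package works with the dimensionless two-point problem

    -u'' + K_eps(x) u = f   on (0, 1),    u(0) = g0,  u(1) = g1,

with `K_eps(x) = K(x/eps)` 1-periodic, equal to `kappa` on a strip of width
`delta` per cell and zero elsewhere, `f` a non-negative constant, and `1/eps`
an integer (a whole number of cells fits the domain; raw spacing/size ratios
are snapped to the nearest reciprocal integer, with the relative adjustment
logged).  This is the diffusion approximation of radiative transfer in a slab
with parallel vessel strips, after the optical-depth change of variables; the
package deliberately starts from the dimensionless form and keeps the
physical-unit handling in a single conversion layer:

* `mua = ln(10) * extinction * c_Hb / M_Hb / 10`  (decadic extinction in
  (mol/L)^-1 cm^-1, concentration in g/L, molar mass in g/mol, result in
  1/mm).  With the standard 150 g/L and 64,500 g/mol the factor is 5.35e-4,
  i.e. 0.00054 at two digits.
* `kappa = 3 * mua * mus' * L^2`, taking the diffusion coefficient as
  `D = 1/(3 mus')`.  This convention reproduces the ~22,000–23,000 value of
  the 575 nm cortex scenario from its own inputs.
* Default boundary data `g0 = g1 = f/(delta*kappa)`, the choice for which the
  volumetric-mean model has the exactly constant solution; any non-negative
  pair may be supplied.

The regime product `p = delta*kappa*eps^2` is used throughout: it equals both
the relative amplitude of the first corrector term and the ratio of the
case-B arch height to the case-A solution level, so it is the natural single
dial separating the regimes.  The case labels use thresholds 0.1 and 10
(configurable); asymptotic theory only distinguishes "small" from "not
small", and points between the thresholds are labelled `transition` and
excluded from case-specific assertions.

## Exact microscale solver

With constant `f` the solution is piecewise analytic: `u = -f s^2/2 + a s + b`
in zero-coefficient intervals and `u = f/kappa + A e^{-r s} + B e^{-r (w-s)}`
with `r = sqrt(kappa)` in vessel intervals.  Continuity of `u` and `u'` at
every interface plus the two Dirichlet rows give a banded linear system in
the 2M piece coefficients.  Two numerical choices matter:

* **End-anchored exponentials.**  The vessel basis uses the two decaying
  exponentials anchored at the interval ends instead of cosh/sinh, so no
  basis value exceeds 1 and the assembly cannot overflow however large
  `r*w` becomes (the solver is routinely used at `kappa = 1e12`).
  Derivative rows are rescaled by `1/(1+sqrt(kappa))` to keep entries O(1).
* **Residual guard.**  After the sparse solve the scaled residual is
  checked; above 1e-8 the system is re-solved in 50-digit arithmetic
  (mpmath) and the event logged.  With the anchored basis this path has not
  been observed to trigger.

Closed-form per-piece integrals give `∫u` and `∫K_eps u` exactly, which feeds
the energy identity `∫K_eps u = f + u'(1) - u'(0)` (obtained by integrating
the equation over the domain) and the total absorption coefficient without
quadrature error.  The maximum-principle bound asserted at runtime is
`0 <= u <= max(g0, g1) + f/8`; the `f/8` is the sharp comparison constant of
the zero-coefficient problem on the unit interval.

Strip placement defaults to *centered* (each vessel in the middle of its
cell, so the cell is symmetric and no half-vessel touches the boundary); a
*start* placement is available and the regime conclusions are insensitive to
the choice (tested).  Positions use half-open intervals `[left, right)`
except the last.

## Finite-difference oracle

An independent second-order finite-volume scheme cross-validates the exact
solver and handles non-constant sources.  The mesh is uniform within each
coefficient interval with every breakpoint a node, so the coefficient is
constant per cell; the flux form keeps second-order convergence across the
interval junctions.  Because the tridiagonal Laplacian has condition number
O(N^2), the raw solve stalls near 1e-7 relative error at N = 1e5; two steps
of iterative refinement with the residual accumulated in extended precision
(80-bit long double) restore a clean O(N^-2) error curve, verified by a
Richardson slope of 2.0 +- 0.1 over N in {1e3, 1e4, 1e5}.

## Homogenization layer (case A)

* `k_hat = delta*kappa` is the volumetric mean; the homogenized two-point
  problem is solved in closed form with the same anchored-exponential trick.
* The corrector cell function `P` (1-periodic, zero mean, `P'' = K - k_hat`)
  is built by exact double integration of the piecewise-constant right-hand
  side; it is piecewise quadratic and all coefficients are closed-form.  For
  the centered strip its amplitude is exactly `kappa*delta*(1-delta)/8`, so
  the predicted relative bulk oscillation `eps^2 * amplitude(P)` equals
  `p (1-delta)/8`.
* Boundary layers solve `-z'' + K_eps z = 0` numerically on a truncated
  half-domain (default cut: 8 homogenized decay lengths `8/sqrt(delta*kappa)`,
  rounded up to whole periods, clipped to the domain with a warning).  The
  truncation error is exponentially small; the decay rate is fitted by least
  squares on `log|z|` at period midpoints (first period skipped) and agrees
  with `sqrt(delta*kappa)` to within 20% in case A.
* Instead of assembling the two-scale series to high order, the cell problem
  is solved *exactly* with periodic boundary conditions; tiling this bulk
  solution over the domain and adding the two layers reconstructs the exact
  solution to ~1e-5 relative in case A.  This resummation is the validation
  reference for every truncated object, which is why no explicit
  higher-order corrector bookkeeping is needed.

## Opaque-vessel approximation (case B)

Per interior gap the approximation is the parabola arch `(f/2) s (l - s)`,
`l = eps(1-delta)`, vanishing at the vessel walls, multiplied by a C^2
quintic-smoothstep cutoff centered on the walls (total transition width
0.5 x the vessel half-width by default, configurable); the two boundary gaps
use parabolas fitted to the Dirichlet data so the boundary conditions hold
exactly.  The cutoff is treated as a normalization device for smoothness
across the vessels, with one arch per cell; the construction is validated
against the exact solver rather than against any particular algebraic form.

The leading-order arch deliberately carries **no wall offset**: the exact
solution's value at a vessel wall is `f l/(2 sqrt(kappa))` (gap flux `f l/2`
divided by the vessel's absorption rate `sqrt(kappa)`), so the sup-norm
relative error of the plain arch is `1/(1 + l sqrt(kappa)/4)` — about 0.18 at
(eps=1/20, delta=0.2, kappa=2e5) and shrinking like `1/sqrt(kappa)` deeper
into case B.  An optional `wall_offset=True` adds this next-order term
(keeping the boundary conditions exact) and cuts the error to ~0.07 at the
same point; it is off by default so that the approximation remains the pure
leading-order periodic piecewise-quadratic profile.

In deep case B the arch closed forms give `mu_tot ~ 12/(eps^2 (1-delta)^3)`
and a correction factor `~ 12/(p (1-delta)^3)`: per period the absorbed power
is `f*eps` (everything the source injects) while `∫u ~ f eps^3 (1-delta)^3/12`.
The measured values approach these from below as `kappa` grows (the wall
offset inflates `∫u` by a relative `6/(l sqrt(kappa)) * ...` term); at
p = 1000 the scaled `mu_tot` is within ~10% of 12.

## Diagnostics

Error norms (sup, L2, and H1-seminorm when derivatives are available) use a
sampling grid with ~200 points per period refined to include every
breakpoint; doubling the resolution changes the reported numbers by <1%.
`mu_tot` uses the closed-form piece integrals for analytic solutions and
per-interval Gauss-Legendre quadrature otherwise.  Regime maps sweep an
(eps, delta, kappa) grid in deterministic order, never abort on a bad point
(failures are flagged per row), and report p, `k_hat`, `mu_tot`, the
correction factor, the relative errors of both approximations and the
classification.

## Problem sizes and determinism

The validation studies use up to 80 periods (case-A convergence), 1e5 mesh
nodes (oracle comparison) and 25-point randomized parameter sweeps for the
conservation checks — sizes at which every quantity reported is converged to
well below its assertion tolerance while a full run stays in the seconds
range.  All solvers are deterministic; the only randomness anywhere is the
parameter-sweep sampler, which takes an explicit seed.

## Known limitations

* 1D strips only: no cylindrical vessels, 2D/3D geometry, or scattering
  heterogeneity; no wavelength-resolved spectra or oxygen-saturation mixing.
* `solve_exact` requires a constant source (the model's setting); general
  sources go through the finite-difference path.
* The case-B construction assumes the centered placement (arches need a gap
  at each domain end to absorb the boundary data).
* The corrector/oscillation prediction is meaningful only for `p <~ 1`; both
  approximations warn when used outside their regime.
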