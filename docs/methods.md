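# Methods

This note documents the physical model behind `mochip`, the numerical
choices, the synthetic-data design, and the known limitations — the things
a maintainer or reviewer would want to know before trusting or extending
the results.

## Physical setting and assumptions

The device is a pump-free multi-organ chip: five chambers joined by a
rectangular circulation channel (reference geometry 40 mm × 4 mm × 2 mm,
L × W × H), perfused by placing the chip on a rocking platform (±6° at
10 cycles·min⁻¹). Tilting creates a hydrostatic head difference between the
end reservoirs, driving an oscillatory, bidirectional laminar flow. The
package does not model the tilt-to-velocity mechanics: the velocity
amplitude is an *input*, taken as measured (peak mean velocity
V_peak = 5 mm·s⁻¹ at the reference operating point), and the tilt amplitude
is carried as metadata only.

Two velocity figures coexist at the reference operating point: the measured
peak mean velocity of 5 mm·s⁻¹ (used by the transport simulation) and the
5.55 mm·s⁻¹ implied by the steady-equivalent flow rate Q = 44.4 µL·s⁻¹
(used by the hydraulic diagnostics). The two arise from different
measurements and the package deliberately keeps both rather than forcing
agreement: `summarize` takes Q, `RockingProtocol` takes V_peak.

Fluid properties default to water at ≈ 20 °C (ρ = 1000 kg·m⁻³,
µ = 1.0 mPa·s); culture medium is slightly denser and more viscous, which
would raise τ_w and ΔP proportionally to µ (both are linear in µ).

## Hydraulics

The channel aspect ratio (w/h = 2) is treated with the plane-Poiseuille
(infinite parallel-plate) laminar formulas: τ_w = 6µQ/(wh²) and
ΔP = 12µLQ/(wh³), with Re built on the hydraulic diameter
D_h = 2wh/(w+h). Exact rectangular-duct series solutions would lower the
side-wall estimates slightly; they are a documented non-goal because the
parallel-plate forms already characterize the operating point
(Re ≈ 14.8, τ_w ≈ 0.167 dyn·cm⁻², ΔP ≈ 0.0925 Pa over 5.55 mm) and keep
every diagnostic a one-line closed form. Two configurable regime flags
accompany the numbers: laminar (Re < 2000) and gentle shear
(τ_w ≤ 0.02 Pa = 0.2 dyn·cm⁻², the upper edge of the shear band reported
for intestinal/hepatic microphysiological culture).

Dimensionless groups justify the transport model: Womersley
Wo = (h/2)√(ωρ/µ) ≈ 1.02 at 10 cycles·min⁻¹ — small enough that the
oscillatory profile is quasi-steady parabolic rather than an annular
Womersley profile; Péclet Pe = V_peak·h/D ≈ 2.5 × 10⁴ for fluorescein —
transport is strongly advection-dominated over a cycle.

## Flow field

The cross-section-mean velocity oscillates as V(t) = V_peak·sin(ωt + φ)
with φ = 0 by default (flow starts from rest moving in +x). The profile is
plane Poiseuille, u(y, t) = 6·V(t)·(y/h)(1 − y/h): no-slip at both walls,
1.5·V(t) at mid-height, height-average exactly V(t). A plug profile
(u = V(t) everywhere) is included purely as a verification mode because it
admits an exact center-of-mass solution, x(t) = (V_peak/ω)(1 − cos ωt).

V_peak is interpreted as the amplitude of the *mean* velocity. If a user's
measurement was instead the spatial maximum at mid-height, setting
`peak_is_spatial_max=True` divides the mean amplitude by 1.5.

## Transport solver

The 2D advection–diffusion equation is solved on the axial × vertical plane
(the 4 mm width enters only the hydraulics; fluorescence observation is
width-averaged anyway). Scheme, per time step:

1. **Advection in x** — conservative flux-form first-order upwind, with the
   velocity evaluated at t + dt/2 (midpoint rule, second-order accurate in
   time for the sinusoidal drive). An optional MUSCL/van Leer flux-limited
   variant (`advection_scheme="van_leer"`) reduces numerical diffusion
   (the one-period recurrence test shows it smears less than half as much
   as upwind) but defaults off in favor of the provably positive scheme.
2. **Diffusion in x and y** — explicit central differences in flux form.

Both sub-steps impose zero boundary fluxes on all four edges, so total mass
is conserved to rounding error (~10⁻¹⁶ relative over the full 20 s
reference run). Positivity holds within the stability bound

    dt = min( cfl·dx / max|u|,  d_max / (D·(1/dx² + 1/dy²)) )

with cfl = 0.9, d_max = 0.25, and max|u| = 1.5·V_peak (parabolic) or
V_peak (plug). The integrator truncates steps to land exactly on requested
snapshot times.

**Closed ends.** Only the long walls are physical no-flux boundaries; the
channel ends open into reservoirs that are outside the modeled domain. The
ends are nevertheless treated as closed (reflecting) so that mass is
conserved — the natural bookkeeping when the dye stays in the channel
interior, which it does at the reference operating point (maximum
centerline excursion 1.5 · 2V_peak/ω ≈ 14 mm versus 18 mm of clearance
from a centered release to either end). One documented consequence: with a
nonzero axial velocity at a closed end a *constant* field is not exactly
invariant — the two end columns drain/pile while the interior is untouched.
Runs whose dye approaches the ends should not be interpreted quantitatively
near the ends.

**Discretization defaults.** 400 × 20 cells (dx = dy = 0.1 mm), giving
dt = 12 ms (advection-limited) and a 20 s reference run of ~1 670 steps in
well under a second on one CPU. The initial condition defaults to a
centered block spanning 10 % of the channel length (the visualization
experiment's exact dye release is unknown, so all quantitative checks are
explicit about their IC). Verification results on these defaults:

- plug/D = 0 center of mass tracks the closed form to < 0.001 cell widths
  and returns to its start at every 6 s period;
- pure diffusion reproduces dσ²/dt = 2D to ~10⁻¹³ relative on an 800 × 40
  grid (the discrete flux-form second moment grows at exactly 2D·dt per
  step away from boundaries — summation by parts);
- L1 self-convergence order ≈ 1.1–1.5 under dx, dy halving (first-order
  upwind plus the smooth-solution regime);
- the center-of-mass oscillation period detected from velocity
  zero-crossings is 5.998 s vs the 6 s rocking period (within one dt).

Because the experiment's initial dye distribution, grid, and stencil are
unknown, snapshot heatmaps are reproducible only qualitatively (oscillatory
back-and-forth transport with progressive smearing); the quantitative
claims above are what the package asserts and tests.

## Mixing metrics

- total mass Σ C·dx·dy (conservation audit);
- center of mass and mass-weighted axial variance (cell-center convention;
  a single occupied column has variance ≤ dx²/12);
- mixing CV: population std/mean of the mean concentration in n equal
  axial segments, n = 5 by default to mirror the five aligned chambers.
  CV = 0 is perfect homogeneity; all mass in one of five segments gives
  CV = 2;
- homogenization time: first time the CV drops strictly below a threshold
  (default 0.05), linearly interpolated between the bracketing steps; None
  if never reached;
- oscillation period: twice the mean spacing of sign changes of the
  finite-difference center-of-mass velocity.

## Synthetic observations and recovery

The camera model reduces each snapshot to a width-averaged axial intensity
profile and corrupts it with a constant background offset (default 2 % of
the maximum noiseless signal) plus additive zero-mean Gaussian noise
(default σ = 5 % of max signal), all drawn from a single seeded generator
(`NoiseSpec.seed`); no global random state is touched. This is a minimal
model: real fluorescence images also have shot (multiplicative) noise,
optical blur, and illumination gradients, none of which are emulated — so
passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to every camera artifact.

**Velocity amplitude.** The rocking frequency is known (set by the
rocker), so com(t) = x₀ + (V/ω)(1 − cos ωt) is linear in (x₀, V) and fit
by ordinary least squares. The observed center of mass is computed after
subtracting a background estimate: the median of the pixels in the outer
10 % of the channel length at both ends, pooled over all sample times.
The pooled end-band estimate is used instead of a per-profile median
because the sheared dye can occupy nearly half the channel interior at
peak displacement, which biases a global median upward by more than a
noise σ and (after over-subtraction) badly distorts the center of mass;
the channel ends stay dye-free at the reference operating point. The
subtracted profile is deliberately not clipped at zero, keeping the noise
zero-mean and the center of mass unbiased. With 25 samples over two
rocking periods at default noise, the median |V̂ − V|/V over 20 seeds is
≈ 2 %.

**Diffusivity.** For no-flow observations, D̂ is half the least-squares
slope of axial variance versus time. Each profile's variance is estimated
by fitting a Gaussian plus constant baseline (scipy `curve_fit`) rather
than by raw second moments, because on a wide field of view the (x − com)²
weighting amplifies pixel noise to the same order as the signal; the fit
is also invariant to global intensity scaling. Benchmarks use a synthetic
fast tracer (D = 10⁻⁶ m²·s⁻¹) so variance growth is resolvable within a
2 s simulated window; at fluorescein's true 4 × 10⁻¹⁰ m²·s⁻¹ the variance
grows ~10⁻⁹ m² over 20 s, far below observational noise — a physical, not
numerical, limitation. Median |D̂ − D|/D over 20 seeds at default noise is
≈ 2.5 %.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
complete in seconds to tens of seconds on a single CPU: 400 × 20 cells for
rocking runs (≤ 20 s simulated), 800 × 40 for the diffusion and convergence
benchmarks, 20 noise seeds for the recovery medians. All are configurable;
halving dx roughly quadruples cost (2× cells in x, 2× steps).

## Known limitations

- Flow is prescribed, not solved: no Navier–Stokes, no free-surface or
  reservoir-level dynamics, no tilt-to-velocity mechanics.
- Single straight channel: the five-chamber 3D geometry, Transwell-insert
  obstructions, and cell consumption/secretion are out of scope.
- First-order upwind advection smears sharp fronts (numerical diffusion);
  use the van Leer option when front sharpness matters more than strict
  TVD positivity margins.
- Parallel-plate hydraulics slightly overestimate shear/pressure drop
  compared with the exact rectangular-duct solution at aspect ratio 2.
- The camera model omits multiplicative noise and optics, and the
  background estimator assumes the dye stays clear of the channel ends.
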