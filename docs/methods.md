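# Methods

This note documents the model as implemented, the numerical choices, what
the synthetic data generators do and do not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and variants

State: population density p(x, t) ≥ 0 (persons km⁻²) and service land
fraction s(x, t) ∈ [0, 1] on a periodic 1-D interval or 2-D box. Three
nested variants share a nonlocal movement operator and differ in the
service equation and in population growth:

- **base** — movement only; ds/dt = (f + g s)(σ(P) − s). Total population
  is conserved (the movement integrand is antisymmetric in x ↔ y).
- **competition** — services compete for space with residents:
  ds/dt = (H(σ(P) − (s + α₁p)) f + g s)(σ(P) − (s + α₁p)). The Heaviside
  gate H (convention H(x) = 1 iff x > 0; the choice at exactly zero
  multiplies a zero factor and cannot affect trajectories, but is fixed for
  determinism) shuts off innovation when there is no excess demand, which
  makes s = 0 invariant. Population is still conserved.
- **growth** — adds logistic growth r p (1 − (p + α₂ s)/c) to dp/dt, with
  services consuming carrying capacity through α₂.

σ(P) = 1 − exp(−(P/λ)^μ) is the maximal service fraction supportable by the
nonlocally weighted population P = w_s ∗ p. μ ≥ 1 is enforced at parameter
validation: for μ < 1 the slope σ′ diverges as p → 0 and the linear
analysis (and the bifurcation condition, which has a root only for μ ≥ 1)
breaks down.

### Parameters (defaults, UK-calibrated)

| symbol | meaning | default | units |
|---|---|---|---|
| D | population movement rate | 2 | yr⁻¹ |
| f | service innovator rate | 0.05 | yr⁻¹ |
| g | service imitator rate | 2 | yr⁻¹ |
| λ | population scale of σ | 20 000 | persons km⁻² |
| μ | steepness of σ | 3 | — |
| β_s | kernel scale of w_s (trips to services) | 5 | km |
| β_p1 | kernel scale of w_p1 (walk to local services) | 1 | km |
| β_p2 | kernel scale of w_p2 (house-move distance) | 10 | km |
| a_p | preferred distance to services (competition/growth) | 1.5 | km |
| α₁ | space per person taken from services | 1.5 × 10⁻⁵ | km² person⁻¹ |
| r | intrinsic growth rate (growth) | 0.05 | yr⁻¹ |
| c | population carrying capacity (growth) | 12 000 | persons km⁻² |
| α₂ | capacity consumed by services (growth) | 10⁵ | persons km⁻² |

The base variant forces a_p = 0 and α₁ = 0 (they belong to the competition
mechanism).

## Kernels and convolution

Kernels are unit-mass Gaussians; the "near but not too near" kernel is the
mean of Gaussians shifted by ±a_p along each axis (two shifts in 1-D, four
in 2-D — the 2-D form is a modelling choice; any isotropization of the 1-D
shift would do, and the axis-shift mean keeps the transform
(cos(a k_x) + cos(a k_y))/2 · exp(−β²|k|²/2) analytic). Its transform
changes sign, which is what allows short-wavelength out-of-phase
instability; the short-wave growth-rate maximum sits at the transform
minimum, argmin_k cos(a k) e^(−β²k²/2) ≈ 1.56 rad km⁻¹ (≈ 4.0 km) at the
defaults.

Periodic convolution is spectral: the analytic transform is evaluated at the
grid's discrete wavenumbers, so kernel tails are never truncated. The cost
of that choice is a domain-size guard — the box must satisfy
extent ≥ 10 β + 2 a, or the periodic images of the kernel would carry mass
above ~10⁻⁶. Constant fields are exact fixed points of the convolution and
the spatial mean is preserved to round-off.

Wavenumbers are angular (rad km⁻¹) throughout; wavelength = 2π/k.

## Linear stability

The per-mode stability matrix is evaluated in closed form; a general
uniform-state linearization (valid off steady state) backs the
finite-difference oracle tests. One subtlety: at a competition/growth
steady state the supply–demand deficit is exactly zero, so the Heaviside
gate makes the service equation only one-sidedly differentiable there. The
closed-form Jacobian corresponds to the gate-open branch; the
finite-difference comparison is therefore carried out at a nearby gate-open
uniform state (s displaced by −10⁻³), where both sides are smooth. On the
services-extinct branch (s₀ = 0, deficit < 0) the gate is shut and the
Jacobian degenerates to pure decay in the service row.

Phase labels are read from the eigenvector of the leading real eigenvalue:
same-sign components → in phase, opposite → out of phase; a complex leading
pair → oscillatory; an eigenvector component below 10⁻¹² (relative) →
neutral, to avoid reading a sign off round-off noise. The dominant mode is
refined by a 3-point parabola through the discrete maximum, so reported k*
values are not restricted to the k grid. The default k grid is 512 points
on (0, 3] rad km⁻¹, covering both the ~0.1 in-phase and ~1.6 out-of-phase
regimes.

The base-model instability criterion s₀(1−s₀)/(p₀σ′(p₀)) + s₀ < 1 − s₀ is
implemented directly and cross-checked against the eigenvalue sweep in a
randomized property test; the critical wavenumber k_c is found by bracketed
root search on det J(k) = 0 (the trace is negative for k > 0, so
instability ⇔ negative determinant). The bifurcation condition
s₀ = μ(2s₀ − 1)ln(1 − s₀) is solved by bracketed bisection on (10⁻⁸, ½),
the only interval where the right-hand side is positive.

## Time integration

The nonlocal terms are smoothing, and all relaxation rates at the default
parameters are at most a few per year, so the semi-discrete system is
non-stiff. The default integrator is SciPy's embedded RK45 pair with
rtol = 10⁻⁶ and absolute tolerances of 10⁻³ persons km⁻² for p and 10⁻⁸
(scenarios near s = 0 use 10⁻¹⁰) for s; a fixed-step classical RK4 with
dt = 0.01 yr is provided as a cross-check, and the suite verifies the two
agree to < 10⁻⁴ relative on a noisy run.

Bounds are not enforced by clipping inside the right-hand side — near p = 0
and s = 0 the raw dynamics themselves restore the bounds, and clipping
would remove exactly that restoring term. Because the innovation gate kinks
the vector field at s = 0, an adaptive integrator overshoots the bound by
an amount that scales with its tolerance (measured ≈ 3 × 10³ · atol_s), not
with machine precision; snapshots are therefore admissibility-checked at
10⁴ · atol_s, tiny overshoot is clipped, and anything larger (or any
non-finite value) raises an integration error.

Parameter schedules (piecewise-linear in time, any model parameter) rebuild
the cached kernel transforms per evaluation only when a kernel length scale
is scheduled.

Named scenarios: **emergence** (base model, 2-D 300 km box at 256²,
p = 8000 + 1000·N(0,1), 150 yr), **metastable** (1-D 200 km/512,
p = 10000 + 5000 cos(7πx/100), i.e. seven 28.6 km periods; the seven-bump
state persists for centuries and the default run stops there — coarsening
to fewer bumps is millennial and gated behind `long_run=True`), and
**growth** (2-D, p = 200 on a seeded random 10 % of cells). Initial s
defaults to the carrying capacity of the initial population layout,
σ(w_s ∗ p) (minus α₁p under competition), except where a scenario
prescribes s = σ(p) pointwise.

## Continuation

Steady states are continued in mean population p̄ on 1-D grids. The two
structural degeneracies are removed by (i) replacing one population
equation with the constraint mean(p) = p̄ (legitimate because the movement
rows sum to zero) and (ii) restricting the unknowns to the even (cosine)
subspace of the periodic domain, which pins the translation phase — simpler
and more robust than an integral phase condition for this
reflection-symmetric problem. The service field stays among the unknowns
(no adiabatic elimination). The predictor is a secant/pseudo-arclength
step so folds are traversable; steps that race more than twice the nominal
p̄ step past a fold, or jump branches, are rejected and halved. Newton uses
forward-difference Jacobians with a damped line search and converges each
point to a scaled residual below 10⁻¹⁰ yr⁻¹.

Stability is read from the eigenvalues of the full-space (even and odd
perturbations) finite-difference linearization, ignoring up to two
structural neutral modes with |Re| < 10⁻⁶ yr⁻¹. That threshold sits above
the ~10⁻⁷ eigenvalue noise floor of the finite-difference Jacobian and far
below any dynamically meaningful rate; metastable multi-bump states
(positive eigenvalues of order 10⁻³–10⁻² yr⁻¹ on the post-fold branch) are
reported through the magnitude of that small eigenvalue rather than by
brute-force millennial integration. Grid refinement from 256 to 512 points
moves the single-city fold by less than 1 %.

## Length-scale estimators

**Moran correlogram.** The classic global-mean Moran's I with binary
annulus weights per distance bin (default 1 km, following the 0–1 km,
1–2 km grouping used for census geographies). For gridded input the pair
sums are computed by an FFT periodic autocorrelation binned by
minimal-image radius — exactly the binary-weight pair enumeration on the
periodic lattice (verified against brute force), at a fraction of the
cost. Bins much narrower than the grid spacing are rejected
(bin ≥ spacing/2), because radial bins would then sample lattice offsets
unevenly and produce sawtooth artifacts. Point sets use plain Euclidean
distances by default, with an optional periodic minimal-image mode that
makes the two input paths agree exactly on grid-centre samples.

**Peak selection.** The dominant length is the first local maximum beyond
5 km (skipping the trivial self-correlation decay) with prominence ≥ 0.02
in I units and positive I — a repeat-distance peak must carry positive
correlation; without that requirement, lattice anisotropy can promote
spurious maxima on the negative flank. Further qualifying peaks are listed
as secondary lengths; "no qualifying peak" is an explicit result, not an
exception.

One estimator property worth knowing: under isotropic radial binning, a
pure plane-wave pattern has I(d) ∝ J₀(kd), whose first positive peak sits
at 1.117 wavelengths — a geometric property of ring averaging, not an
estimator bias. For cluster (spot) patterns, which is what both real city
systems and the simulated fields look like, the higher harmonic content
pins the first peak at the true inter-cluster spacing. The planted-pattern
tests cover both regimes (dividing out the J₀ factor for planted waves).

**Transect spectrum.** Magnitude of the DFT of the mean-removed series per
harmonic, indexed by wavelength. A spectrum whose strongest harmonic
carries less than 20 % of total power (typical of white noise) is flagged
as not prominent.

## Synthetic data

The generators stand in for external gridded population data and are
bit-reproducible given their seed. `noise` truncates negative draws at zero
and records the truncated fraction (vanishingly rare at the default
8000 ± 1000). `city_lattice` places Gaussian cities on a jittered lattice;
the default width is spacing/10 because wide bumps (≳ spacing/8) lose their
harmonic content and the correlogram peak drifts toward the Bessel
position. `lsoa_like_points` emulates irregular census centroids: a
uniform/clumped mixture of locations sampling a planted city-bump pattern
plus observation noise.

What the synthetic fixtures do **not** emulate: coastlines and other hard
boundaries (everything is periodic), heterogeneous geography, population
heterogeneity, and the irregular polygon geometry of real census units.
Passing the round-trip tests shows the estimators recover known planted
scales under noise; it does not validate them against survey artifacts in
real data.

## Problem sizes

Default study conditions: 1-D analyses and continuation on 200 km at
256–512 points; 2-D emergence on a 300 km box at 256² (about 2–3 s per
150-year run); the acceptance run takes the median correlogram peak over
five seeds. The growth scenario uses a 128 km box at 1 km resolution so the
~4 km out-of-phase substructure is resolved.

## Known limitations

- The unstable-window analysis (k_c, bifurcation point) is 1-D, as is
  continuation; 2-D steady states are explored by simulation only.
- The competition model's reported short-wave "out-of-phase at ~5 km"
  structure is reproduced qualitatively; the analytic maximizer at the
  defaults is 1.56 rad km⁻¹ (4.0 km wavelength). Both bands and their phase
  labels are asserted in the tests; no attempt is made to force a
  particular decimal on the short-wave frequency.
- Only one population class and one service class; no space-dependent
  parameters except through the time-schedule hook.
- Moran's I significance testing is out of scope; the estimator reports the
  statistic and peak geometry only.
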