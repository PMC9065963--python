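# citypatterns

Why are cities spaced the way they are? UK population data shows a
characteristic separation of roughly 45–50 km between urban centres, and a
finer patchwork of alternating residential and commercial land inside them.
`citypatterns` is a simulator and analysis toolkit for a minimal mechanistic
explanation of both scales: a pair of nonlocally coupled
integro-differential equations for residential population density
*p*(*x*, *t*) (persons km⁻²) and service land fraction *s*(*x*, *t*) ∈ [0, 1]
on a periodic domain. It is aimed at researchers in spatial population
dynamics, urban analytics and pattern formation who want a tractable model
with full linear-stability machinery rather than a black-box simulation.

## The model

Attractiveness of a location is high where services are nearby but the land
is not itself saturated with services:

    A = (w_p1 * s)(1 − s),          w_p1 a Gaussian kernel (β_p1 = 1 km)

Population relocates by comparing attractiveness, weighted by a
moving-distance kernel (β_p2 = 10 km):

    ∂p/∂t = D ∫ [A(x) p(y) − A(y) p(x)] w_p2(x − y) dy

Services relax towards a carrying capacity σ(P) = 1 − exp(−(P/λ)^μ) of the
nonlocally weighted population P = w_s ∗ p (β_s = 5 km), driven by
innovators (rate f) and imitators (rate g):

    ∂s/∂t = (f + g s)(σ(P) − s)

Two nested extensions: a **competition** variant where services compete for
space with residents (σ(P) − (s + α₁p), with a Heaviside gate on innovation
and a shifted "near but not too near" kernel w_p1 with offset a_p), and a
**growth** variant that adds logistic population growth
r p (1 − (p + α₂ s)/c).

Linearizing about the uniform state gives a 2×2 matrix J(k) per wavenumber
whose leading eigenvalue is the growth rate of a sinusoidal perturbation —
a Turing-type analysis. Its eigenvector says whether population and
services grow together (**in phase**, the ~45–60 km city-spacing mode) or
apart (**out of phase**, the ~4–5 km within-city mode).

## Worked example

```python
import numpy as np
from citypatterns import (ModelParams, bifurcation_point, dispersion,
                          scenario_emergence)
from citypatterns.lengthscale import (moran_correlogram,
                                      dominant_length_from_correlogram)

params = ModelParams.defaults("base")

# Where does the uniform city-free state lose stability?
s0, p0 = bifurcation_point(params)
print(f"bifurcation at s0* = {s0:.4f}, p0* = {p0:.0f} persons/km^2")

# Fastest-growing pattern at a mean density of 8000 persons/km^2
k, rate, phase = dispersion(params, 8000.0).dominant_mode()
print(f"dominant mode: {2*np.pi/k:.1f} km wavelength, "
      f"growth rate {rate:.3f}/yr, {phase}")

# Simulate 150 years of city formation from noise and measure the spacing
hist = scenario_emergence(seed=0)
est = dominant_length_from_correlogram(
    moran_correlogram(hist.field_p(), bin_width=1.0))
print(f"emergent inter-city spacing: {est.dominant_length:.1f} km")
```

Output:

```
bifurcation at s0* = 0.3662, p0* = 15393 persons/km^2
dominant mode: 46.0 km wavelength, growth rate 0.047/yr, in_phase
emergent inter-city spacing: 53.4 km
```

Reading: below a mean density of ~15 400 persons km⁻² the well-mixed state
is unstable and ~46 km-wavelength perturbations grow fastest, with
population and services co-locating; after 150 simulated years the
nonlinear pattern has coarsened slightly, to an inter-city spacing of
~50–55 km depending on the noise seed.

## Command line

A thin CLI wraps the library:

```sh
citypatterns dispersion --pbar 8000            # dispersion curve + dominant mode
citypatterns bifurcation --mu 3                # critical (s0*, p0*)
citypatterns simulate --points 128 --t-end 150 # 2-D emergence run
citypatterns continue --pbar-start 16000       # patterned-branch continuation
citypatterns lengthscale run/final_p.txt --bin-width 2.5
citypatterns phase-diagram --pbar 16000        # (alpha1, a_p) instability map
```

Every run writes its artifacts as delimited text plus a `provenance.yaml`
echo of the fully resolved configuration and seed.

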