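# Methods

This note records the model formulation, parameter conventions and
numerical choices behind `turtlehab`, in the package's own terms.

## Conventions

* Longitudes are degrees east in [0, 360) everywhere; inputs on
  [−180, 180) are wrapped on read. Track sequences crossing the
  antimeridian are unwrapped before smoothing or interpolation and
  re-wrapped afterwards.
* Spherical earth with radius 6371.0 km, so one degree of latitude (and of
  longitude at the equator) is 111.195 km; zonal distances scale with
  cos(latitude).
* Gridded fields (`GridField`) live on regular lat/lon axes with a regular
  time axis (6-day steps by default); land is NaN plus a boolean mask.
* Time is UTC throughout; resampling lattices are aligned to UTC clock
  boundaries.

## Track processing

Raw Argos fixes per animal are cleaned in five stages
(`track_processing.process_track`):

1. **Velocity filter.** While any segment speed (great-circle distance
   over elapsed time) exceeds 10 km/h, the later fix of the fastest
   offending pair is removed.
2. **Kernel smoothing.** Local linear regression of longitude and
   latitude against time with an Epanechnikov kernel,
   w(τ) = max(0, 1 − (τ/h)²), bandwidth h = 1 day over a 2-day window.
   Windows with fewer than 3 fixes fall back to the nearest fix.
3. **Spike removal.** Exactly ⌈0.05 · n⌉ fixes with the largest
   great-circle discrepancy between raw and smoothed position are deleted
   (ties broken toward earlier fixes).
4. **Resampling.** Linear interpolation onto an exact 3-hourly UTC
   lattice starting at the first fix's time ceiled to the lattice.
5. **Second smoothing pass** with the same kernel.

Tracks spanning fewer than 10 days are discarded; temporal gaps implying
position jumps larger than 3° are flagged but kept.

## Size, growth and speed

* Growth follows dCCL/dt = (−10.6 · log₁₀(CCL) + 21.5)/365.25 cm/day,
  integrated with daily Euler steps and floored at zero (the formula
  crosses zero near CCL ≈ 107 cm; larger animals are held constant with a
  warning). CCL is curved, SCL straight carapace length;
  SCL = 0.369 + 0.932 · CCL (cm).
* Swimming velocity is the current-corrected ground velocity V = Vg − Vc,
  with Vg from centred finite differences along the cleaned track and Vc
  sampled from the current fields.
* The maximum sustainable speed (MSS) statistic is the monthly 90th
  percentile of |V| (linear rank interpolation), converted to body lengths
  per second with the monthly mean SCL; months with fewer than 10 records
  are skipped.
* Turtle and drifter speed distributions are compared with a two-sample
  Kolmogorov–Smirnov test (D from the empirical CDFs, asymptotic p-value).

## Habitat index

For a cohort (`HabitatParams`: T_opt = 17.0 °C, σ_T = 1.5 °C, MSS in
bl/s, SCL in cm):

* Temperature preference Θ(T) = exp(−(T − T_opt)²/(2 σ_T²)), evaluated on
  the 30-m-average temperature field.
* Prey accessibility f_prey = min(P / P_ref, 1), with P_ref defaulting to
  the 95th percentile of the prey field (so the index is invariant to the
  prey proxy's units).
* Accessible habitat H_a = Θ · f_prey ∈ [0, 1]; hot spots are cells with
  H_a strictly greater than 0.8.

## Movement model

Maximum swimming speed v_max = MSS × SCL (body lengths/s × m/body length),
e.g. 1.1 bl/s at 30 cm → 0.33 m/s.

* **Taxis.** Swimming is directed along ∇H_a with saturating magnitude
  |u_t| = v_max · (1 − H_a) · |g| / (|g| + K), where |g| is the gradient
  magnitude in habitat units per degree and K = 0.05: swimming shuts off
  in good habitat (H_a → 1) and on habitat plateaus (|g| → 0).
* **Diffusivity.** D = max(D_bg, D_max · (1 − γ · H_a)) with
  D_max = 0.25 · v_max² · Δt_forcing and γ = 0.9: animals diffuse fast in
  poor habitat and settle in good habitat. D_bg (50 m²/s) is the passive
  background.
* **Eulerian solver.** ∂ρ/∂t = −∇·[(u_c + u_t) ρ] + ∇·(D ∇ρ), discretized
  in flux form: first-order upwind advection and centred diffusion through
  cell faces, exchanging individuals (not concentration) so the total is
  conserved to machine precision with no-flux boundaries. The combined
  Courant–diffusion number |u|Δt/Δx + |v|Δt/Δy + 2DΔt(1/Δx² + 1/Δy²) is
  kept below a safety factor (0.5) by substepping, which also guarantees
  nonnegativity. Forcing is held at the interval-midpoint slice.
* **Lagrangian sampler.** Individuals follow the Euler–Maruyama scheme
  dX = (u_c + u_t + ∇D) dt + √(2D) dW; the ∇D drift term makes the
  particle ensemble solve the same Fokker–Planck equation as the density
  solver, so 2000-particle histograms correlate with the PDE solution at
  r ≥ 0.9 after 90 days. Particles reflect at domain boundaries and
  re-draw steps that would land on land (mirroring the solver's no-flux
  condition).
* **Passive mode** zeroes the taxis and uses the background diffusivity —
  pure drift, the null model against which habitat-driven movement is
  judged.
* `density_track_agreement` scores observed fixes against the simulated
  field: the mean percentile of the density value at each fix's cell
  (mid-rank over wet cells) and the fraction of fixes in the top quartile.

## Synthetic data

`make_forcing` emulates, deterministically per seed: a meridional
temperature gradient (26 °C at 15° N to 8 °C at 45° N), a seasonal cosine
peaking at day-of-year 258, westward-drifting Gaussian eddies derived from
a streamfunction (so the eddy field is non-divergent), a zonal jet, and a
prey proxy tied to lagged temperature/latitude structure, smoothed to
realistic scales. It emulates spatial/seasonal structure only — no
interannual variability, no real bathymetry or coastlines (land is
optional and synthetic), and the prey proxy is a stand-in, not a
biogeochemical model. `degrade_to_argos` thins tracks to an average 2.6
fixes/day, adds 1.5-km Gaussian position noise and 2% spikes of ~100 km.
Drifters are the passive-mode particles.

## Verification

The test suite checks, among others: exactness of the cleaning-stage
constants (10 km/h cap, exactly 5% spike removal, exact 3-h lattice);
Θ(T_opt) = 1; strict hot-spot thresholding; year-long conservation of a
2000-individual release to 1e-6 relative; pure diffusion against the
analytic heat kernel (L1 < 5%); Lagrangian–Eulerian correlation ≥ 0.9;
recovery of T_opt = 17 ± 0.5 °C from synthetic tracks; MSS against a
brute-force percentile oracle; the growth ODE against a high-resolution
Runge–Kutta oracle (0.1 cm over 3 years); KS statistics against hand
enumeration; and the active-vs-passive contrast in tracking a seasonally
migrating habitat band.

## Limitations

* First-order upwind advection is diffusive; fronts in the density field
  are smeared by numerical diffusion in addition to D.
* The habitat index is a static preference model: no memory, diel
  behaviour, age structure or density dependence.
* The taxis saturation constant K, the diffusivity scaling factor and γ
  are modelling choices exposed through `SimConfig`, not fitted values.
* No-flux boundaries make the domain closed; results near the boundary of
  a small domain reflect that confinement.
* The Argos error model is a single isotropic Gaussian plus rare spikes;
  real Argos location classes have heavier-tailed, class-dependent errors.
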