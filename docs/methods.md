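# Methods

`ablatesim` simulates the transient photothermal response of soft tissue to a
scanned continuous-wave laser beam: light transport, heat diffusion with a
water-vaporization phase change, and the accumulation of irreversible thermal
damage, with the tissue's optical scattering evolving as it coagulates.  This
note records the models, their assumptions, the numerical choices, and what
the shipped synthetic scenarios do and do not demonstrate.

## Model overview

The domain is a lattice of cubic voxels: an air layer above a homogeneous
tissue slab (default 300 x 300 x 150 voxels of 0.1 mm, 5 mm air over 10 mm
tissue, tissue surface at z = 5 mm, surface center at x = y = 0).  Four
coupled fields live on the lattice:

* **S(r)** — absorbed optical power density (W/mm^3), from Monte Carlo
  photon-packet transport;
* **H(r, t)** — volumetric enthalpy (J/mm^3), advanced by
  dH/dt = k lap(T) + S with adiabatic boundaries;
* **T(r, t)** — temperature (degC), mapped from H with a latent-heat
  plateau: T = H/(rho c_p) below rho c_p T_v, clamped at T_v until
  H reaches H_th = rho (c_p T_v + L_v);
* **Omega(r, t)** — Arrhenius damage, dOmega/dt = A exp(-Ea/(R T_K)),
  with damaged fraction alpha = 1 - exp(-Omega).

Two couplings close the loop.  *Dynamic optical properties*: the per-voxel
reduced scattering is the damage-weighted mixture
mu_s'(alpha) = (1 - alpha) mu_s'_native + alpha mu_s'_coagulated, while
mu_a is held fixed (at 980 nm the heat-induced change in absorption is small
compared with the ~2.65-fold rise in scattering).  *Structure*: a tissue
voxel whose enthalpy reaches H_th is removed — it becomes air, optically and
thermally — carving a crater whose walls present refractive-index steps to
subsequent photons.  Removal is irreversible and the removed voxel's
enthalpy leaves the system with the vapor; the new air voxel is initialized
at the local pre-removal temperature (the plateau T_v) with air heat
capacity.

## Monte Carlo transport

Standard photon-packet rules: free path s = -ln(xi)/mu_t; albedo weighting
(deposit w mu_a/mu_t per interaction); Henyey-Greenstein scattering with
g = 0.9 (mu_s = mu_s'/(1-g) by the similarity relation); unpolarized
Fresnel reflection/refraction decided probabilistically at every voxel face
where n changes (air-tissue surface and crater walls), including total
internal reflection; Russian roulette below weight 1e-4 with survival
probability 0.1; packets leaving the lattice are tallied as escaped, or as
specular if they never reached an interacting voxel.  Whether general-purpose
voxel MC codes enable internal Fresnel events is usually configurable; we
enable them everywhere, which is the physically complete choice for crater
walls.  The beam is a collimated Gaussian (1/e^2 diameter = 4 sigma)
launched at the lattice top, held stationary at its window-start position
during each transport snapshot.

Energy bookkeeping is exact apart from the zero-mean roulette residual;
with the shipped optical properties packets almost never survive to the
roulette threshold, so absorbed + escaped + specular = launched to well
below 1e-6 relative.

## Thermal solver

Explicit FTCS with the 7-point Laplacian; faces between dissimilar
materials use the harmonic-mean conductivity, which keeps the update
conservative (total H is preserved to machine precision under adiabatic
boundaries).  The explicit stability bound dt <= rho c_p dx^2/(6 k) is
enforced per material; in the layered model air binds it (~7.7e-5 s at
0.1 mm voxels, so the full-scale dt = 1e-5 s has a 7x margin).  Air
participates in conduction with its own constants; convection and radiation
are not modeled.  Thermal properties are temperature-invariant, and blood
perfusion is absent (ex vivo conditions).

At exactly H = rho c_p T_v the linear and plateau branches agree, so the
clamp is applied from that point on (continuity).  Inside a heating window
a voxel may overshoot H_th before the end-of-window removal check; the
solver keeps such pending voxels clamped at T_v, while the strict scalar
map `enthalpy_to_temperature` treats enthalpy above H_th as an internal
consistency error (a missed removal).

## Damage kinetics

The damage integral is evaluated with the Henriques sign convention
exp(-Ea/(R T_K)) — the rate must grow with temperature — with temperatures
converted to kelvin inside the exponent.  The fused field update skips
voxels below 35 degC: with the default liver kinetics the rate there is
below ~1e-4 1/s and contributes nothing on ablation timescales; the public
`arrhenius_increment` applies no cutoff.  Omega is frozen on vaporized
voxels.  Coagulation is Omega >= 1 (alpha = 63%), the conventional
threshold for irreversible injury.  The closed-form helper
`bath_time_for_omega` inverts the constant-temperature integral, the design
rule for water-bath coagulation protocols (equal Omega needs a longer bath
at 60 than at 70 degC).

## Coupling schedule

Transport is refreshed every t_heat (full scale: 2e-3 s); between
refreshes the thermal/damage fields advance in t_heat/dt explicit steps
(full scale: 200).  Each window: optics update from alpha, transport at
the current beam position, thermal + damage substeps, vaporization check.
Irradiation lasts t_laser_on = scan length / speed (derived, not free);
when the scan time is not a whole number of windows the final window is
truncated.  After laser-off, stepping continues with S = 0 for t_laser_off
(30 s high power, 10 s low power at full scale) — stored heat continues to
coagulate tissue during cooling.  Each window's transport draws from an
independent stream seeded by (seed, window index), making runs bit-identical
for a fixed seed regardless of how windows are executed.

## Parameters and placeholders

All material constants are configuration inputs.  The shipped liver-like
defaults are literature-style placeholders, clearly flagged as such:
mu_a = 0.07 1/mm (native, 980 nm), mu_s' = 1.0 -> 2.65 1/mm
(native -> coagulated, the measured 2.65x coagulation factor), g = 0.9,
n = 1.44 (fixed during heating), k = 0.52 W/(m K), rho = 1.05 g/cm^3,
c_p = 3.6 J/(g K), T_v = 100 degC, L_v = 2257 J/g (water), and
Henriques-style kinetics A = 7.39e39 1/s, Ea = 2.577e5 J/mol.  Internally
everything is expressed in mm/g/s/J/degC; converters are provided for the
usual quoted units so conduction (W/(m K) or W/(cm K)) and optics (1/mm)
cannot be silently mixed.

## Synthetic scenarios: what they show

`make_paper_scenarios()` builds the six full-scale study conditions (50 W x
{0.5, 0.75, 1.0} mm/s and 10 W x {1.0, 1.25, 1.5} mm/s, 2.8 mm beam, 20 mm
scan, 1e7 packets) and a scaled twin of each for desk runtimes: the same
power, beam diameter and scan speed — hence the same fluence per unit
area — but a 3 mm scan on a 28 x 28 x 22 grid of 0.2 mm voxels (1 mm air
over a 3.4 mm slab, still more than two coagulated-state penetration depths
deep), dt = 2e-4 s, t_heat = 0.1 s, 1e4 packets, and cooling shortened to
3 s / 1.5 s.  A twin runs in roughly 10-25 s on one CPU.

Compressing the run time makes it impossible to preserve every
dimensionless group simultaneously (the thermal diffusion number per
transport window necessarily grows with the coarser t_heat); the twins
instead preserve the irradiance, the optical semi-infiniteness of the slab,
and the stability margin, which is what the qualitative contrasts need.
Consequences of the scaling: the adiabatic walls sit closer to the lesion,
so absolute temperatures and lesion sizes are *not* comparable to the
full-scale model — the twins demonstrate the regime split (10 W coagulates
without vaporizing; 50 W does both), the sign of the dynamic-optics
contrast (vaporization larger, coagulation smaller than the static-optics
baseline), and the monotone decrease of lesion metrics with scan speed.
They do not validate absolute lesion dimensions, which require the
full-scale grid, photon counts and timing plus measured tissue properties.

## Lesion metrics

Measured on the zx plane nearest y = 0 (for even lattice sizes, the row
just on the +y side).  Width is the x-extent of the mask's bounding box,
depth the z-extent below the *original* tissue surface (vaporization depth
is therefore crater depth), area the voxel count times the voxel face area.
Bounding extents — rather than fitted contours — are the reproducible
analogue of tracing regions in an image tool.  Vaporization uses the
removal mask; coagulation uses Omega >= 1 on remaining tissue, so the two
masks are disjoint.  Validation statistics: RMSPE
(100 sqrt(mean(((sim-meas)/meas)^2))) and the absolute relative difference
(100 |sim-ref|/ref).

## Known limitations

No carbonization (which would increase surface absorption and shrink
coagulation), no wavelength-dependent mu_a dynamics, no blood perfusion, no
temperature-dependent thermal properties, no fiber/diffuser sources, no
pulsed-laser nonlinear absorption.  The static-mu_a assumption slightly
overestimates absorption in coagulated tissue: the 0.07 -> 0.06 1/mm drop
corresponds to an ~8% increase in penetration depth
(delta = 1/sqrt(3 mu_a (mu_a + mu_s'))).
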