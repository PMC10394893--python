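# Methods

`nanotherm` simulates nanoparticle-mediated photothermal therapy (NPTT) of a
subcutaneous tumor in a small animal: gold-nanorod optics set the extra light
absorption of nanohybrid-loaded tissue, a diffusion-approximation solve gives
the fluence-rate field under NIR illumination, the Pennes bioheat equation
propagates the resulting heat with blood perfusion and convective skin loss,
and an Arrhenius integral converts the temperature history into irreversible
thermal damage. This note records the models, the parameter choices, the
numerical decisions, and what the synthetic phantoms do and do not represent.

## Nanorod optics (module `nanoptics`)

A gold nanorod of diameter D and length l is treated as a prolate spheroid in
the quasi-static (Gans) limit. The depolarization factors are

    P1 = ((1-e^2)/e^2) * (ln((1+e)/(1-e))/(2e) - 1),   P2 = P3 = (1-P1)/2,

evaluated at the eccentricity e = sqrt(1-(D/l)^2); this form has the required
sphere limit P_i -> 1/3. An `as_printed` variant evaluates the same expression
at the bare axis ratio beta = D/l for auditability against the source
formulation (it does not approach 1/3 for a sphere and is not the default).
Per-axis polarizabilities use the tabulated Johnson & Christy dielectric
function of gold (packaged CSV, 0.64-3.0 eV; linear interpolation in
wavelength, no extrapolation) and a real host dielectric constant
eps_m = 1.77 (water in the NIR; configurable). Two prefactor conventions are
offered: the default `gans-volume` (3 V_np, which reduces the coefficient
formulas to the standard orientation-averaged dipole cross-sections) and the
`as-printed` 4*pi*D^2*l form. V_np is a cylinder volume by default
(spherocapped optional); the wavelength in the coefficient formulas is the
vacuum wavelength (a medium-index option exists but is off by default).

**Absorption calibration.** With the reference rod (l = 54.2 nm, aspect ratio
3.1 — the bare gold core, since only it is plasmonic), f_V = 1e-7 and 808 nm,
the raw quasi-static absorption coefficient is 7.1e-3 cm^-1 (volume
convention; 3.8e-2 cm^-1 as-printed; peak 0.48 cm^-1 at the 681-nm
longitudinal resonance of this table/eps_m). The tissue-simulation profile
this package reproduces uses mu_an = 54 cm^-1 at the same inputs — about
7.6e3 times larger, a level that would require a per-particle absorption
efficiency of ~700 and is unreachable by any unit-consistent quasi-static
convention. The default optics therefore carry an explicit multiplicative
calibration factor kappa = 54 / mu_an_raw(reference inputs), computed at run
time and recorded in every result that uses it. The scattering coefficient
needs no calibration: the volume convention gives 5.9e-4 cm^-1 against the
profile value 7e-4 cm^-1, which is what fixes that convention as the default.
The thermal pipeline consumes the profile values (54, 7e-4) directly and
scales them linearly with the local volume fraction, so treatment simulations
do not depend on kappa.

**Photothermal conversion efficiency.** `estimate_pce` implements the
lumped-capacitance (Roper-type) estimator: the post-illumination cooling
transient is regressed as time vs -ln(theta) (theta the normalized excess
temperature) to get the system time constant tau and the conductance
hS = m*C_p/tau, and the efficiency is eta = hS*(T_max - T_amb) / (P*(1 -
10^-A)) with A the absorbance at the laser line. The matching forward model
(`simulate_photothermal_curve`) generates heating/cooling curves with known
eta for parameter-recovery tests; recovery is within 0.01 absolute for eta in
[0.1, 0.5] when heating runs >= 10 time constants. The estimator assumes a
single lumped compartment, no solvent-baseline correction (Q0 = 0) and
cooling recorded until theta <= 0.02.

## Voxel phantoms (module `phantom`)

The phantom replaces an imaging pipeline (MRI -> manual segmentation ->
surface meshes -> FEM mesh) with a labelled isotropic voxel grid: outside /
tissue / tumor / nanohybrid-loaded subregion, plus a per-voxel volume-fraction
map whose support equals the nanohybrid label exactly. Coordinates are
cell-centred, 0-based, axis order (x, y, z); NIfTI affines carry spacing and
origin on import/export. The default geometry is a desk-scale flank: a
10 x 10 x 14 mm semi-axis body ellipsoid with a 4-mm-semiaxis tumor centred
8 mm up the +y axis, so the tumor bulges ~2 mm out of the body surface, on a
64^3 grid at 0.5 mm spacing.

Scenarios: `laser_only` (f_V = 0), `IP` (systemic delivery, f_V = 5e-9
uniformly over the tumor), `IT` (direct injection, f_V = 1e-7 over a compact
irregular blob covering 30% of the tumor volume by default). The IT blob is
grown by a 6-connected flood fill ordered by jittered distance (seeded RNG)
from the injection point, which is anchored halfway between the tumor
centroid and the beam-side apex — the needle tip of an injection performed
through the skin over the tumor. The anchor is deliberately anatomical rather
than uniformly random: the peak surface temperature depends strongly on blob
depth (placements from centre to apex span roughly 12-16 K at default
settings), and an injection site is a procedural choice, not a random draw.
Only the pool's shape is randomized.

Surface machinery: 6-connected boundary voxels with unit outward normals
(normalised sums of exposed-face directions); surface areas via marching
cubes on a Gaussian-smoothed label field (within ~10% of the closed-form
Thomsen ellipsoid area at 0.35 mm spacing); STL export for visual inspection.
Default probes: c = body-surface voxel on the beam ray through the tumor
centroid (the validation point of an IR-camera comparison), b = tumor
centroid, a = lateral tumor margin.

## Light transport (module `light`)

The fluence rate u (W/cm^2) solves the steady diffusion approximation
div(-C grad u) + mu_a u = f with C = 1/(3(mu_s' + mu_a)); the reaction
coefficient is mu_a (the standard identification — the source leaves it
unnamed). Tissue parameters at 808 nm: mu_at = 2 cm^-1, mu_st = 61 cm^-1,
g = 0.67, applied to tumor and normal tissue alike; nanohybrid voxels add the
reference coefficients scaled by f_V / f_V_ref. Radiance is assumed isotropic;
refractive-index-mismatch boundary factors are not modelled.

Discretisation: 7-point finite differences over body voxels, harmonic-mean
face coefficients, symmetric positive definite system, Jacobi-preconditioned
CG to relative residual 1e-10 (LU fallback; failure raises, never silent).

**Illumination boundary.** The beam footprint defaults to the tumor's
projection onto the body surface along the beam axis, dilated by 1 mm. Two
boundary treatments are provided:

* `dirichlet` (default): u = 1.4 W/cm^2 prescribed on the illuminated patch
  (half-cell ghost-value coupling), zero flux elsewhere. This mirrors a
  prescribed-fluence-rate boundary and reproduces the reference surface
  temperatures; it does *not* conserve the incident power (the prescribed
  value fixes the fluence whatever the interior absorbs).
* `partial_current`: u + 2C du/dn = 4S on the patch, i.e. the irradiance is
  injected as a diffuse partial current. This conserves the injected power
  but delivers a ~3x higher surface fluence (u0 = 4S/(1 + 2C mu_eff) ~ 4.2
  W/cm^2 in plain tissue), which a 1-D slab estimate and the full solver both
  show is incompatible with the ~17 K reference surface heating; it is kept
  for sensitivity analysis and for properties that need flux conservation.

Verification: the solver matches the analytic point-source kernel
exp(-mu_eff r)/(4 pi C r) with RMS relative error < 3% over 2-10 voxel radii
(pointwise < 3% beyond 5 voxels; the innermost on-axis voxels carry the
O((h/r)^2) anisotropy of the discrete lattice kernel) and converges at second
order (error ratio 4.0 on halving the spacing). Discrete energy balance on an
illuminated slab closes to solver tolerance in both boundary modes.

## Bioheat and damage (module `thermal`)

Pennes equation, rho*C dT/dt = div(k grad T) + rho_b C_b omega_b (T_b - T) +
Q_m + Q_ext, with rho = rho_b = 1052 kg/m^3, C = C_b = 3800 J/(kg K),
k = 0.545 W/(m K), omega_b = 0.01 1/s, T_b = T_init = 37 C, Q_m = 0 (no value
in the profile; negligible next to laser deposition), and convective loss
h = 10 W/(m^2 K) to a 25 C ambient on every body-air face (series conductance
of the half-cell conduction and the film; h = 0 or `insulated=True` gives an
adiabatic surface). The perfusion term uses the heat-sink sign convention
(T_b - T); the self-heating sign printed in the source formulation is
available behind `as_printed` for auditability. Integration is backward Euler
(default dt = 0.5 s, snapshots every 1 s), unconditionally stable and free of
the surface oscillations a Crank-Nicolson step shows at heated boundaries;
each step is one SPD solve (CG, relative residual 1e-9, warm-started).
Verification: exact equilibrium retention; enthalpy conservation under
insulated/unperfused conditions to < 1%; the closed-form perfusion steady
state Delta-T = Q/(rho_b C_b omega_b) to solver tolerance; and agreement with
a CFL-limited explicit oracle within 0.05 K over 60 s on a 16^3 block.

**Arrhenius damage.** Omega(tau) = integral of A exp(-Ea/(R T(t))) dt,
trapezoidal on the stored snapshots (exact for constant temperature, < 0.1%
from a 10x finer grid on treatment-scale ramps). The tabulated kinetic pair
of the source profile (A = 2.5e5 1/s with Ea = 7.39e39 J/mol) makes the
integrand identically zero at any physiological temperature — the two numbers
are mutually inconsistent under any unit reading we tested, including
swapping them (which instead predicts appreciable damage at baseline 37 C).
The default is therefore the classical Henriques-Moritz tissue coagulation
pair, A = 3.1e98 1/s, Ea = 6.28e5 J/mol; the printed pair remains available
via `ArrheniusParams.as_printed()`, and every damage output records the pair
used. Peak damage values consequently differ from the source study's
headline Omega = 0.4, which is not reproducible from its stated parameters;
damage is validated through its defining properties (non-negativity,
monotonicity, the constant-temperature closed form, and group contrasts).

## Treatment pipeline (module `pipeline`)

`run_treatment` chains phantom -> optics -> fluence -> Q_ext = mu_a u ->
bioheat -> damage, deterministically for a given seed, and emits a RunReport
(max surface temperature rise as seen by a simulated IR camera — the first
body voxel along each viewing ray — time-to-maximum, peak damage, per-probe
finals, full parameter echo) plus NIfTI fields, probe CSVs and report JSON in
a fresh run directory. `compare_to_measurement` interpolates a simulated
probe series onto measured times and reports signed bias (positive =
simulation overestimates), RMSE and max |residual|.

At the default desk-scale conditions (64^3, 0.5 mm, 300 s at 1.4 W/cm^2,
dt = 0.5 s) the three arms give maximum surface temperature rises of about
11.2 K (laser only), 17.0 K (IP) and 14.7-15.3 K (IT, across blob-shape
seeds); the IT value is the headline quantity and sits within ~12% of the
17 K reference.

## Known limitations

* **Sub-voxel optical boundary layers.** At f_V = 1e-7 the nanohybrid region
  has mu_eff ~ 113 cm^-1: a 0.09-mm penetration depth that no affordable 3-D
  voxel size resolves (0.5 mm default). Under the prescribed-fluence boundary
  the discrete heat deposition of such a region saturates, with two visible
  consequences at 0.5 mm: the IT arm peaks ~1 K *below* the uniformly-loaded
  IP arm (refining to 0.25 mm restores IT > IP: 23.6 vs 19.5 vs 12.1 K, at
  the cost of overshooting the 17 K reference — the reference magnitude is
  matched at the coarse discretization, not at convergence), and the peak
  surface temperature is not monotone in f_V (it is monotone under the
  flux-conserving partial-current boundary, where the corresponding property
  test runs).
* The phantom emulates geometry and nanoparticle distribution only — no
  image contrast, registration, heterogeneous tissue classes, or vasculature;
  tissue properties are uniform and temperature-independent.
* Single effective rod size (no polydispersity); quasi-static optics (no
  retardation); the absorption calibration absorbs, without explaining, the
  gap between quasi-static theory and the tissue-simulation profile value.
* The diffusion approximation is poor within ~1 transport mean free path of
  sources and boundaries and in the strongly absorbing nanohybrid region
  (mu_a >> mu_s' there); no Monte-Carlo reference is included.
* Passing tests on synthetic phantoms demonstrate solver correctness and
  reproduction of the stated study conditions, not predictive accuracy for
  real animals.
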