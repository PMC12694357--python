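# Methods

`implumen` models two coupled design questions for an implantable photonic
neurostimulator: *which wavelength maximizes the pulsatile reflectance
signal from cortical blood vessels*, and *whether the wireless-power
receiving coil keeps electromagnetic tissue absorption within the 10 g /
2 W/kg localized-exposure limit*. This note records the models, their
assumptions, the calibration constants, and what the synthetic phantoms do
and do not represent.

## Spectral data

The normative dataset is the packaged table of wavelength-dependent
absorption coefficients of oxy- and deoxyhemoglobin on a 10 nm grid from
400 to 890 nm. Two deliberate choices:

* The table is taken at face value, with coefficients of order
  0.1–1.7 m⁻¹. These magnitudes are far below physiological whole-blood
  values (tabulated hemoglobin absorption at these wavelengths is several
  orders of magnitude larger); the table is treated as a normalized
  coefficient scale, and the optical model absorbs the normalization into
  an explicit blood-path calibration (below). No literature hemoglobin
  compilation is substituted.
* Whole-blood mixing is the linear Beer–Lambert combination
  μₐ(λ, SO₂) = SO₂·μₐ,HbO₂(λ) + (1−SO₂)·μₐ,Hb(λ), with piecewise-linear
  interpolation off the grid. Default arterial saturation SO₂ = 0.97.

Note that this table's Hb column decreases monotonically above 560 nm and
shows no 760 nm deoxyhemoglobin feature; conclusions drawn from it inherit
that shape.

## Cardiac waveform and blood-volume modulation

The simulated window is 1.5 s: a non-physiological initialization ramp
P(t) = (1−α)·sin(π(t−0)) on [0, 0.5] s and a pulsatile phase
P(t) = (1−α)·cos(2π(t−0.5)) on [0.5, 1.5] s. α is the systolic fraction of
the cardiac cycle (default 1/3); the phases are continuous at 0.5 s for
every α because sin(π/2) = cos(0). The pulsatile phase as written has a
1.0 s period (75 bpm would give ≈0.8 s); the printed form is implemented
as-is. A triangular pulse of the same amplitude and phase is available via
`PressureWaveform(pulse_shape="triangular")`. Default sampling step
dt = 0.01 s.

P is dimensionless. The coupling to optics is
f(t) = f₀·(1 + β·P(t)), the vessel blood volume fraction, with documented
calibration defaults f₀ = 0.05 and β = 0.15 (no physical mapping from
normalized pressure to volume is available, so these are package
constants, not fitted values). Whether pulsation should modulate vessel
diameter instead of (or as well as) volume fraction is unresolved;
volume-fraction modulation is the implemented choice.

## Analytic reflectance model

The analytic engine is a double-pass modified Beer–Lambert model along the
Snell-refracted ray through the layered phantom:

    R(λ) = S_alb · exp(−Σₖ 2 dₖ μₐ,ₖ / cos θₖ − τ_blood(λ)),
    τ_blood = L_rt · μₐ,blood(λ, SO₂) · f / f_ref.

* S_alb is a wavelength-independent backscatter albedo (default 1.0). It
  cancels in ΔR ratios and in every argmax selection.
* **L_rt = 1.64 is the central calibration constant of the optical
  model.** It is the effective round-trip optical path through the vessel,
  in the normalized units of the packaged absorption table, at the
  reference volume fraction f_ref = 0.05. The pulsatile sensitivity of the
  model is ∂R/∂f ∝ μ·exp(−L_rt·μ), which peaks at μ = 1/L_rt =
  0.61 m⁻¹ — between the 670 nm (0.49) and 650 nm (0.75) grid values and
  closest to 660 nm (0.609) at SO₂ = 0.97. With L_rt fixed at 1.64 the
  per-wavelength cardiac ΔR over the 600–800 nm band attains its maximum
  at 660 nm, the headline wavelength selection. Any other value in
  roughly [1.3, 2.0] keeps the argmax inside the 650–670 nm bracket.
* Layer terms use the tabulated per-layer μₐ (order 10⁻⁴–10⁻³ m⁻¹ over mm
  paths); they are retained for completeness but are numerically tiny and
  wavelength-independent, so they never influence wavelength selection.
* The analytic model contains no Fresnel entry loss (absorbed into S_alb).

## Monte Carlo engine

The 2D Monte Carlo engine is a standard weighted-packet radiative
transport solver: exponential free paths on the local μ_t, absorption
deposit w·μₐ/μ_t per interaction (implemented as w − w·μ_s/μ_t so each
event conserves weight exactly in floating point), wrapped 2D
Henyey–Greenstein scattering (default g = 0.9; the anisotropy is not
tabulated anywhere, so this is a conventional tissue value), unpolarized
Fresnel specular reflection at entry, flat or parabolic internal
interfaces (index-mismatch reflections between layers ignored by
default), and weight-threshold (10⁻⁴) Russian roulette with survival
probability 0.1.

Energy bookkeeping: reflectance + transmittance + absorbed + side-escape +
roulette-net = 1 to float round-off (≲10⁻¹²). The roulette-net term is the
signed weight created/destroyed by unbiased roulette; it is part of the
closure identity, while its expectation is zero. Interference,
polarization and coherent (wave-optics) effects are not modelled: this is
a deliberate divergence from full-wave treatments, and absorbed-energy
maps stand in for field-path visualization.

For cross-validation against the analytic double-pass model the engine
offers a mirror bottom boundary of reflectivity S_alb; in the
scattering-free limit the returned weight is exactly the analytic
double-pass attenuation, and the two engines agree to Monte Carlo
sampling error (asserted at 3σ with 10⁵ packets).

Units: the Monte Carlo vessel uses the tabulated blood coefficients
geometrically (per metre over mm paths), so its absolute pulsatile
modulation is far smaller than the analytic model's calibrated one. The
`vessel_mua_scale` knob exposes this normalization explicitly. Wavelength
*selection* is an analytic-engine result; the MC engine validates
transport physics and energy accounting.

Penetration depth is the depth at which the cumulative absorbed-energy
profile reaches 90 % of total absorption, interpolated linearly within
map bins.

## ΔR metrics and band analysis

Two reflectance-variation metrics are computed per wavelength over the
pulsatile window [0.5, 1.5] s (the ramp is excluded):

* ΔR_sim: temporal max − min of the engine-driven series;
* ΔR_J: the Beer–Lambert value at the two modulation extremes
  f₀(1 ± β(1−α)).

With the analytic engine these coincide identically (the cosine attains
its extremes on the sampled grid); with the MC engine they differ by
sampling noise. Additionally `band_spectral_range` reports the spectral
max − min of cycle-mean reflectance within each band — a second, distinct
reading of "reflectance variation" that appears in the field; the
per-wavelength temporal metric is the one that drives wavelength
selection. Argmax ties break toward the lowest wavelength.

Under pure Beer–Lambert attenuation the *minimum* of cycle-mean
reflectance in 600–800 nm falls at 600 nm (largest μₐ in the band), not at
660 nm, so the "lowest overall reflectance" co-criterion for 660 nm is
reported (`argmin_mean_r`) but not enforced: it is not reproducible from
a monotone attenuation model and the packaged table.

## Wireless power link

LC resonance algebra is exact: f₀ = 1/(2π√(LC)) and its inverse. Tuning
the 15 µH receiving coil to 1.35 MHz requires C ≈ 926.6 pF; a ~100 pF
capacitor would resonate near 4.11 MHz, and `design_report` flags this
inconsistency whenever the back-calculated capacitance differs from
100 pF.

The S11 model is a series R-L-C branch against a real z₀ = 50 Ω
reference — the simplest circuit producing a single matching dip. No
circuit diagram or source impedance is available for the physical link,
so the topology is a documented package choice; a parallel-tank
alternative (high impedance at resonance) is selectable. The default coil
ESR of 53.31 Ω is a calibration constant chosen so the dip depth is
|S11| = 3.31/103.31 = 0.032 (−29.87 dB), i.e. ≥ 95 % delivered power
(1 − |S11|²). Frequency sweep default: 0.5–3.0 MHz, 2001 linear points.
Coupling coefficients, link budgets and rectification are out of scope.

## SAR dosimetry

The field solve is magneto-quasistatic, valid at 1.35 MHz where the head
(≈0.15 m) is ~10⁻³ of the free-space wavelength: A is the Biot–Savart
vector potential of the polyline-discretized helical coil (closed-form
per-segment integrals; 64 segments/turn keeps the loop-center field
within 0.1 % of μ₀I/2a), and |E| = ω|A|, neglecting the conservative
charge-redistribution term. Currents and fields are RMS, so pointwise
SAR = σ|E|²/ρ directly.

The drive amplitude is not physically determined by anything in the
model, so the default is a documented sizing rule: the 3 mW optical
budget divided by an assumed 10 % end-to-end link efficiency (30 mW) is
dissipated in the coil ESR, giving I_rms = √(0.03/53.31) ≈ 23.7 mA.
Because SAR scales as I², any other assumed drive rescales the results
quadratically; compliance is therefore reported against the 2 W/kg bound
rather than matched to any external solver's absolute numbers, which
depend on an excitation this model cannot recover.

Mass averaging: the 10 g kernel at reference density 1007 kg/m³ has
volume 9.93×10⁻⁶ m³ and sphere radius 1.334 cm (hemisphere 1.680 cm).
Three kernels are provided — fixed sphere, fixed hemisphere (flat face
coplanar with the device–tissue interface, dome pointing into tissue,
default axis −z), and adaptive (radius grown per voxel until the
accumulated tissue mass reaches 10 g, realized mass within one voxel-mass
of target). Averages are mass-weighted means; air and the photonics
device carry zero tissue mass, so every kernel is air-excluding by
construction (a sphere kernel half in air simply averages over the tissue
half). The averaging is implemented as an offset-ordered shift-accumulate
over the voxel grid; the offset ordering (lexicographic, or
distance-then-lexicographic for the adaptive kernel) is part of the
contract so that an independent per-voxel brute-force evaluation
reproduces the maps bit-for-bit, which the tests assert on grids up to
16³. The adaptive full-map mode costs O(offsets × grid) and is intended
for small phantoms and spot checks; the default pipeline uses the fixed
hemisphere.

Reported metrics per region (brain; head = head-shell + brain tissue):
the volume average of pointwise SAR and the maximum of the 10 g-averaged
map, with pass ⇔ max ≤ 2 W/kg. The 1 g / 1.6 W/kg criterion is not
implemented; the 10 g method is the operative choice.

## Synthetic phantoms

* **2D optical phantom** — flat (default) or parabolically curved layer
  interfaces: polyurethane encapsulant 0.8 mm, CSF 0.5 mm, gray/white
  matter 2.5 mm, cerebellum 3.5 mm (total 7.3 mm), with a 0.5 mm vessel
  (diameter is a package default; no tabulated value exists) centred at
  2.5 mm depth inside the gray matter. Four 0.3 mm sources at 20°
  incidence, 3 mW each, 1 mm spacing. The flat default keeps analytic
  oracles exact; the curved preset is for demonstration runs.
* **3D head phantom** — hemispherical brain (radius 7 cm, dome up,
  σ = 0.12 S/m, ρ = 1050 kg/m³), 0.7 cm head shell (0.15 S/m,
  1100 kg/m³), 1 cm³ photonics device (10⁻⁵ S/m, 1300 kg/m³) on the shell
  apex with the coil axis vertical; 2 mm voxels ≈ 1.2×10⁵ tissue voxels.
  All dimensions beyond the tabulated properties are package defaults —
  the phantom is a geometric idealization, not an anatomical or
  MRI-derived model.

What passing tests on these phantoms show: the transport, circuit and
dosimetry machinery is numerically correct against closed forms and
brute-force oracles, and the pipeline's qualitative conclusions (660 nm
selection, sub-limit SAR) hold under the stated calibrations. What they
do not show: behaviour of real heterogeneous, anisotropically scattering
tissue, realistic absolute SAR magnitudes (drive-dependent), or any
wave-optics effect.

## Numerical choices and degenerate inputs

* Problem sizes: Monte Carlo validation runs use 10⁵ packets
  (binomial 3σ ≈ 0.5 % on transmittance); the SAR pipeline uses 2 mm
  voxels with ~1.9×10³ coil segments. Both are the package's default
  desk-scale settings.
* Boundary pushes of 10⁻⁹ mm avoid re-intersection after interface
  crossings; ray–interface and ray–vessel intersections are closed-form
  quadratics (parabolic interfaces included).
* Zero-thickness phantoms, empty spectral bands, empty pulsatile windows,
  all-air phantoms, zero total absorption, non-passive |S11| inputs and
  modulations leaving [0, 1] all raise `ValueError` eagerly.
* Per-stage seeds derive from the master seed via SHA-256 of
  `"<master>/<stage>"` mod 2³¹, so stage subsetting never shifts another
  stage's stream; the Monte Carlo engine derives one seed per time step
  the same way.

## Known limitations

* No wave optics, polarization or coherence; no 3D optical transport.
* No thermal/bioheat modelling (thermal properties are stored but
  consumed by no operation).
* The quasi-static E-field omits the conservative term and tissue eddy
  back-reaction; fine near the coil at 1.35 MHz, increasingly approximate
  with distance.
* Absolute SAR values are proportional to the square of an assumed drive
  current; only the compliance bound and structural properties (scaling
  laws, averaging behaviour) are meaningful.
* The incident angle (20°) is a fixed input; no angular optimization is
  performed.
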