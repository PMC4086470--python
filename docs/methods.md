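# Methods

`ossidrive` models an incus-body-driving middle-ear implant: a multilayer
piezoelectric stack actuator, anchored in the mastoid, pushing on the incus
body through a short coupling rod, evaluated against acoustic stimulation of
the eardrum. This note records the models, the assumptions, the numerical
choices, and what the shipped tests do and do not demonstrate.

## Piezoelectric stack model

The actuator is a 2 × 2 × 2 mm PZT-4 brick of `n` layers (designed device:
n = 50, layer thickness 0.04 mm). The constitutive law is the stress/charge
form

    T = cE S − eᵀ E,      D = e S + εS E,

with the transversely isotropic PZT-4 constants (c11 = 139, c12 = 77.8,
c13 = 74.3, c33 = 115, c44 = 25.6, c66 = 30.6 GPa; e15 = 12.7,
e31 = −5.2, e33 = 15.1 C/m²; relative clamped permittivities ε11 = 370,
ε33 = 635). Internal consistency c66 = (c11 − c12)/2 holds exactly. The
tabulated permittivities are interpreted as *relative clamped* values and
multiplied by ε0: magnitudes of a few hundred cannot be absolute values in
F/m. No density is tabulated for the ceramic; the standard PZT-4 value
7500 kg/m³ is the shipped default. Voigt order is (11, 22, 33, 23, 13, 12)
with engineering shear strains, declared once and used everywhere.

Discretisation: 8-node trilinear hexahedra, 2×2×2 Gauss quadrature, three
displacement DOFs plus one potential DOF per node, one element per layer
through the thickness by default (configurable). For this geometry the
exact voltage-driven solution has layerwise-uniform fields, so trilinear
elements capture the free stroke, blocked force and clamped capacitance
essentially to machine precision; the 1 % test tolerances are therefore
slack, not load-bearing.

Element blocks: Kuu = ∫BuᵀcBu dV, Kuφ = ∫BuᵀeᵀG dV, Kφφ = ∫GᵀεG dV
(G the potential-gradient operator, E = −GΦ), Muu = ρ∫NᵀN dV. The dielectric
block is stored positive definite and enters the assembled operator as

    [[Kuu, Kuφ], [Kuφᵀ, −Kφφ]],

a symmetric indefinite system. Writing +Kφφ in the lower-right while keeping
physically-signed electrode charge would require the dielectric block itself
to absorb a minus sign; storing the positive-definite block and flipping it
in the operator is the energy-consistent equivalent. With this convention
the free charge drawn from the driven terminal falls out of the constraint
reactions with its physical sign, and terminal current is I = jωQ.

Electrical topology: electrodes at all n+1 layer interfaces, alternate
interfaces sharing a terminal, poling alternating layer to layer so every
layer elongates under positive terminal voltage. This is the universal
multilayer-actuator wiring; it is also what makes the layer capacitances add
in parallel. Each interface node set is reduced to one equipotential master.
Drives above 10.5 V RMS (the safety ceiling for implant excitation) warn but
run.

Damping is stiffness-proportional, Cuu = βKuu with β = 1e-4 s and α = 0,
applied uniformly to the ceramic, the rod and the surrogate ear. Note the
loss factor ωβ reaches 0.63 at 1 kHz and 5 at 8 kHz — this damping model is
aggressive at the top of the band, which is inherited behaviour, not a bug.

Harmonic drive is interpreted as an RMS phasor, so response magnitudes are
RMS. The default sweep is 40 log-spaced points over 160–8000 Hz.

Constraint handling (ties and prescribed values) uses a union-find reduction
u = T u_red + g; solves go through sparse LU with a reduced-residual check
(tolerance 1e-7 relative) that turns silent singularity into an error.

### Static supports

* *Free stroke*: statically determinate 3-2-1 corner mounts — removes the
  six rigid modes without restraining any uniform deformation; elongation
  then equals n·d33·V, with d33 = 291.3 pC/N obtained independently by
  inverting the 6×6 stiffness matrix (d = e·cE⁻¹).
* *Blocked force*: all mechanical DOFs held (strain-free state), giving the
  uniform-field result A·e33·V/t at the tip.
* *Capacitance*: a clamped solve reproduces n·ε0·ε33S·A/t = 28.1 nF for the
  designed geometry; a mechanically free solve gives 56.5 nF, the coupling
  having raised the effective permittivity toward the constant-stress value.
  The 71 nF reported for the physical prototype sits above both, consistent
  with a free-permittivity estimate (ε33T of PZT-4 is roughly twice ε33S)
  plus device-level effects the model excludes (electrode layers, fringing,
  manufacturing spread). The capacitance formula therefore takes the
  relative permittivity as an explicit argument and nothing in the package
  guesses which value the prototype measurement reflects.

### Low-frequency limit

The harmonic solution at 0.01 Hz is compared with the static solve on
*magnitudes*: the βK term contributes an O(ωβ) ≈ 6e-6 imaginary part at
that frequency by construction, while magnitudes agree to O((ωβ)²) ≈ 4e-11.

### Damping-ratio check

A single-DOF fixture with C = βK gives ζ = βωn/2 exactly. The test measures
the half-power bandwidth numerically and inverts it through the *exact*
half-power relations, ζ² = (1 − 1/√(1+r²))/2 with
r = (ω2² − ω1²)/(ω1² + ω2²), rather than the small-ζ rule Δω = 2ζωn whose
O(ζ²) error would not meet a 0.1 % tolerance at moderate damping.

## Middle-ear surrogate

The individual temporal-bone geometry behind the original finite-element
ear model is not publishable, so the package ships a lumped 4-DOF axial
chain — eardrum, malleus, incus, stapes — as a synthetic stand-in. Springs
are k = E·A/L using the published component moduli (incudostapedial joint
4.00e6 N/m², stapedial annulus ligament 4.10e5 N/m², tympanic annulus
4.00e5 N/m², pars tensa 1.00e7 N/m², ossicular bone 1.41e10 N/m²) with
assumed connector areas (0.5–1 mm²) and lengths (0.5–1 mm); masses are the
tabulated densities times assumed volumes giving anatomical-range values
(malleus 25 mg, incus 28 mg, stapes 3 mg, eardrum effective 6 mg). The
effective eardrum piston area is 32 mm². The cochlear fluid load — never
characterised in the source model — is a free surrogate parameter, a 0.05
N·s/m dashpot on the stapes chosen to give moderate damping of the stapes
branch. These defaults were fixed once, so that the undamped fundamental
falls in the typical 0.5–1.5 kHz middle-ear window (it is 559 Hz), and are
all visible in `SurrogateConfig`, never hard-coded.

What the surrogate reproduces: linearity, passivity, reciprocity, band-pass
stapes response, correct scaling of every downstream metric. What it does
not: absolute displacement magnitudes of a real ear, eardrum modal
behaviour, rotational ossicle motion (the chain is piston-only, matching the
scalar displacement outputs evaluated downstream), or inter-individual
response shapes. Tests against the surrogate therefore assert structure,
ordering and scaling — not physiological magnitudes.

`randomize_network` emulates specimen-to-specimen spread: each spring and
mass is multiplied by an independent unit-mean lognormal factor with chosen
coefficient of variation. Perturbing physical parameters (not matrix
entries) preserves symmetry and passivity for every draw; a 100-seed sweep
at cv = 0.2 is part of the acceptance checks.

## Coupling and design studies

The stack base is fixed (mastoid anchor); the tip face is tied rigid in the
axial direction and connected to the incus DOF either directly (the rigid
reference d_tr) or through the coupling rod (d_tr_rod): 0.5 mm diameter,
2.0 mm long, six elements, E = 116 GPa (titanium) or 510 GPa (ceramic),
density defaulting to 4500 kg/m³ (not given for the source design). The rod
is reduced to *axial bars* with consistent mass: the surrogate ear is a
piston chain, so bending DOFs would have nothing to push against; the
six-element count of the reference design is retained and is statically
irrelevant (axial bars in series). Junctions are rigid, matching an epoxy
bond; imperfect coupling is out of scope.

*Layer-number study.* With the 2 mm envelope fixed, n ∈ {10, 25, 50} at
10.5 V RMS: stroke scales as n·d33·V, so each doubling adds ~6.02 dB of
stapes displacement below resonance, and the equivalent SPL (below) rises
accordingly. On the surrogate, the 50-layer device delivers ≈104 dB SPL
equivalent at 160 Hz, rising to ≈137 dB at 8 kHz — the high-frequency
advantage that motivates a stack (rather than diaphragm) actuator.

*Rod-stiffness study.* ΔH = 20·log10(d_tr_rod/d_tr). On the axial chain the
rod's E·A/L ≈ 1.14e7 N/m (titanium) is several orders above the ossicular
impedance scale across the band, so insertion drops are fractions of a
millidecibel — far below the ~10 dB scale seen when a slender rod bends
against a 3D ossicle. The claims this package makes and tests are the ones
that survive the reduction: softer rods drop more (116 GPa ≥ 510 GPa
everywhere), and the drop vanishes in the rigid limit (|ΔH| < 1e-4 dB at
E = 1e6 GPa, asserted under 0.5 dB).

## Metrics

* STF = 2πf·D/P_TM in (m/s)/Pa, with P_TM the RMS drive pressure
  (90 dB SPL → 0.632 Pa, 100 dB → 2 Pa exactly).
* Peq = spl_ref + 20·log10(d_tr/d_ac), the eardrum SPL that would move the
  stapes as much as the transducer does; spl_ref defaults to 100 dB (the
  acoustic baseline level) but is an argument, not a constant.
* ΔH defaults to the 20·log10 decibel convention, because insertion drops
  are quoted in dB of a displacement ratio; the plain log10 variant is
  available as `convention="literal"` for comparison.
* Electrical budget: C = n·ε0·ε33·A/t (t the single-layer thickness; layers
  in parallel), I_rms = 2πf·C·V_rms. Two power figures are returned under
  distinct names because both circulate in the design literature and they
  differ by a factor 2: `p_half` = ½·I·V and `p_apparent` = I·V. At the
  prototype's 71 nF, 1 kHz and 1 V these are 0.446 mA, 0.223 mW and
  0.446 mW per volt; the package reports both rather than choosing silently.

## Problem sizes and determinism

The designed-device FEM (50 layers, 2×2 in-plane refinement) has ~1800
DOFs; coupled sweeps use 16–40 frequency points. The whole test suite and
the acceptance script each complete in seconds on one CPU. All randomness
flows through explicit integer seeds (`numpy.random.default_rng` /
`SeedSequence`); identical configurations rerun to byte-identical CSV
outputs.

## Known limitations

* No dielectric loss, electrode mass/stiffness, adhesive layers, geometric
  nonlinearity, hysteresis or temperature dependence in the actuator model.
* The surrogate ear is 1D and lumped; quantitative stapes magnitudes, rod
  bending effects and individual-ear spectra are out of reach by design.
* The Rayleigh damping model (β = 1e-4 s, α = 0) overstates losses at the
  top of the audio band; it is retained for fidelity to the modelling chain
  being reproduced.
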