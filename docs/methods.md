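# Methods

This note documents the model behind `earbench`: what is computed, which
parameters matter, the numerical choices, and what the green (and red)
tests do and do not establish.

## 1. Scope and modelling strategy

The bench couples a lumped/rigid-body middle ear to a quasi-1D two-duct
inner ear and evaluates stapes prostheses in the frequency domain
(harmonic analysis, time convention `e^{+iωt}`, 100 Hz–10 kHz). The
published model family this emulates is a 3D finite-element model; the
central approximation here is **dimensional reduction**: the 3D acoustic
fluid is replaced by transmission lines with the same area profiles, BM
material laws, window terminations and topology. The measures in scope
(METF, tonotopy, relative BM motion, input impedance, window volume
displacements, ABG) are governed by 1D fluid loading, which is why this
reduction is acceptable for comparison studies; absolute 3D pressure
fields, organ-of-Corti micromechanics, fluid viscosity and bone conduction
are out of scope.

All solves are direct factorisations of complex symmetric systems
(sparse, ≤ ~10³ unknowns for the cochlea; dense 16×16 for the middle ear).
There is no randomness anywhere in the solve path.

## 2. Inner ear

**Discretisation.** `n` uniform sections over the 31.9 mm BM arclength
(default `n = 400`). Unknowns: scala-vestibuli and scala-tympani pressures
at the section centres plus the vestibule pressure. Each duct link carries
an acoustic inertance `ρΔx/A(x)`; with compressible perilymph every node
carries a compliance `ΔxA(x)/(ρc²)`. The BM couples the ducts at each
station via the clamped-plate-strip impedance given in the README; the
per-section shunt admittance is integrated with two-point Gauss quadrature,
and the cell containing the damping-law branch point (x = 20 mm) is split
exactly at the discontinuity so that assembly does not depend on where the
jump falls within a cell.

**Material laws.** The graded Young's modulus and Rayleigh-β damping laws
are descriptive fits (they bundle the BM with its neighbouring structures
and the neglected fluid viscosity) and are implemented exactly as printed,
including the four-order-of-magnitude β discontinuity at 20 mm — no
smoothing, because the laws are the model's identity and smoothing them
silently would drift from the source model. The consequences are analysed
in §6.

**Terminations.** Round window: clamped elliptical plate
(1.62 × 1.15 × 0.06 mm) with compliance `πab/(3·8D(3/a⁴+2/(a²b²)+3/b⁴))`
and modal mass `1.8ρh/(πab)`; a structural loss factor η = 0.3 (not
printed; typical membrane value, chosen once) supplies the only basal
dissipation besides β(x). Helicotrema: 0.25 mm² × 1 mm duct (figure-only in
the source; standard box-model value). Vestibule: volume compliance
`V/(ρc²)` (37.8 mm³) plus a short-duct inertance. Oval window port area:
`πab/4` on the printed footplate axes (2.81 × 1.27 mm → 2.80 mm²), which
reproduces the printed footplate area; the literal `πab` reading is kept
behind a flag.

**Key defaults** (figure-only or supplementary in the source, hence
config-exposed): BM width 0.10 → 0.50 mm and thickness 7.5 → 2.5 µm
(linear tapers), BM density 1200 kg/m³, clamped-strip constant 3.0, scala
areas 2.0 → 1.0 mm² per duct (two-channel models deliberately exceed
anatomical areas), perilymph ρ = 1000 kg/m³, c = 1500 m/s.

## 3. Middle ear

Malleus and incus are 6-DOF rigid bodies (ellipsoid-fit inertias; masses
25/28/3 mg for malleus/incus/stapes), the stapes is restricted to piston
translation plus two rocking rotations at the footplate centre. Ligaments
and joints are bushing elements (per-DOF springs/dashpots on the relative
motion of attachment frames); the annular ligament carries exactly the
three stapes DOF; the stapedial tendon is absent. The tympanic membrane is
an effective piston (60 mm² × 0.6 effectiveness) stiffly coupled to the
malleus at the umbo — its shell dynamics are deliberately lumped because
only its transfer role matters here. Acoustic attachments on the TM DOF:
the lossless 9 mm ear-canal two-port driven by the 10⁻⁵ m/s inlet velocity
source (the "94 dB SPL" label names this source condition; it is not an
acoustic conversion), and the tympanic-cavity branch (0.63 mL compliance,
mastoid Helmholtz element at ~1.1 kHz, facial-recess absorption
conductance). The cochlear load enters as a 3×3 mechanical impedance at
the stapes; in a 1D port model only the piston DOF is loaded.

**Calibration.** The individual ligament constants of the source model are
unpublished; the shipped baseline is an anatomically plausible
rotation-dominated set (stiff AML/PIL translations forming the classic
rotation axis). Four multipliers — global stiffness, TM compliance,
annular-ligament stiffness, global damping — are tuned by bounded
Nelder-Mead (deterministic fixed simplex, bounds [0.1, 10]) against two
anchors: the coupled METF maximum at 750 Hz and a mid-band magnitude
corridor. The calibrated set (10.0, 2.226, 0.179, 1.663) ships as the
default; `earbench calibrate` reproduces it.

## 4. Stapedotomy reconstruction

The stapes body, annular ligament and incudostapedial joint are removed;
a piston (mass from geometry × titanium density, ~3.1 mg) attaches to the
incus lenticular process through a spherical joint (translations locked,
rotations free). Only the axial translation is modelled: piston rotations
carry no fluid load in a 1D port model, and the in-plane motion is bounded
by the fluid (< 0.1 mm in the source model), so neither pumps the cochlea.
The footplate plane becomes rigid; the oval-window port takes the piston
area; the annular gap shunts the vestibule node through the gap element in
series with the tympanic-cavity impedance. Gap element: inertance
`ρ(t_plate + 0.85 r_h)/S_annulus` (t_plate = 0.2 mm, hydraulic radius
r_h = radial gap width); sealed adds the clamped-annular-strip compliance
`P_mean w⁵/(720 D)` of the tissue membrane (default E = 3 MPa — the value
used for the headline comparisons; a 20 MPa "stiff" preset is retained
because both values appear in the source). With the default seal the
sealed gap is leak-free across the audio band.

## 5. Measures

As defined in the README; implementation notes: peak localisation
(tonotopy, METF peak) uses 3-point parabolic interpolation on
log-magnitude vs. log-frequency, removing grid quantisation; the
relative-BM-motion probe is complex-interpolated between stations; the
tonotopy RMSE inverts the Greenwood map in closed form (default k = 1) and
evaluates on 30 log-spaced frequencies in 200 Hz–10 kHz ∩ the mapped
range; ABG keeps the printed orientation (negative = loss; audiogram-style
reporting is its negation). "Maximum BM displacement" is per excitation
frequency. METF, impedance and volume displacements are
drive-amplitude-invariant ratios (tested).

## 6. Known limitations (and deliberately red tests)

The printed apical damping branch makes BM sections beyond 20 mm
overdamped at their own characteristic frequencies (ωβ ≈ 10). Faithfully
implementing it has four measurable consequences, each left as a failing
acceptance test rather than patched away:

1. **Tonotopy below ~840 Hz.** Travelling waves die at the 20 mm damping
   front, so low-frequency peak places pin at ~20 mm instead of advancing
   to the apex; the place map is flat (sub-µm jitter) there, which also
   breaks *strict* peak-place monotonicity. Above ~1 kHz the map tracks
   Greenwood within ~1–1.8 mm.
2. **Tonotopy RMSE.** Over the 200 Hz–10 kHz evaluation band the RMSE is
   ~2.8 mm, above both literature anchors (0.84 mm own-model, 2.05 mm
   straight-isotropic comparison). The published sub-millimetre value is
   not reachable with the printed laws plus the documented default
   profiles over this band.
3. **Grid convergence at 0.5–1 kHz.** The damping front reflects the
   lightly damped basal wave; at frequencies whose wave terminates there
   the drive-point impedance converges second-order but slowly (256→512
   change ~7.6% at 1 kHz vs. 0.01% at 2 kHz; <1% from 1024→2048).
4. **METF peak placement.** The same reflections ripple the cochlear input
   impedance below ~800 Hz, so the coupled METF maximum can only land on
   ripple maxima; the calibrated peak is 790.5 Hz — within the stated
   1/6-octave tolerance of the 750 Hz target, but not closer.

Two further red tests are parameter-knowledge limits, not damping
artefacts: the sealed-gap diameter gain (0.6 → 0.7 mm) computes to
~2.5 dB — near the pure area ratio 20·log₁₀((0.7/0.6)²) = 2.67 dB because
the piston is displacement-driven — versus the published "about 1 dB"
(which is arithmetically incompatible with the companion observation that
the piston displacement itself is unchanged); and the open-gap penalty
above 2 kHz computes to ~8.7 dB versus the published ~5 dB, the gap
channel length behind the printed geometry being unpublished.

A green test here therefore establishes internal consistency of the
implemented physics (conservation, passivity, linearity, reciprocity,
limits) and agreement with the printed closed-form values — not agreement
with the unpublished 3D geometry, and not clinical validity.

## 7. Numerical details

Degenerate/edge handling: zero drive returns a zero field; non-positive
frequencies, inconsistent DOF masks, non-finite drives and geometry
violations (piston ≥ hole) raise named errors; a singular system reports
its frequency. The ear-canal two-port guards against its duct resonance
(≈19 kHz, outside the band). Boundary BM peaks are excluded from the
tonotopy map with a warning. Configuration round-trips are bit-exact
(floats serialised by repr); every CSV carries the configuration hash.
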