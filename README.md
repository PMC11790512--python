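# earbench

A desk-scale, frequency-domain **virtual test bench for stapes surgery**: a
coupled lumped/transmission-line model of the human middle and inner ear
that evaluates stapedotomy piston prostheses by the measures surgeons and
engineers actually use — middle-ear transfer function (METF), cochlear
tonotopy, relative basilar-membrane (BM) motion, cochlear input impedance,
oval/round-window volume displacements, and the expected air–bone gap (ABG)
of a reconstruction.

It is aimed at middle-ear-mechanics researchers and prosthesis developers
who want reproducible, seconds-fast comparisons of prosthesis variants
(piston diameter, open vs. tissue-sealed annular gap) against a
representative natural ear, without cadaveric temporal-bone experiments or
a commercial FE package.

## The model

**Inner ear.** The uncoiled cochlea is a two-duct acoustic transmission
line (scala vestibuli/tympani, identical linearly tapering cross-sections,
helicotrema at the apex, 37.8 mm³ vestibule at the oval window, clamped
elliptical round-window membrane at the scala-tympani base). At each of the
`n = 400` stations the graded BM couples the ducts as a locally reacting
clamped plate strip with specific impedance (time convention `e^{+iωt}`)

    Z_s(x, ω) = iω m''(x) + k''(x) β(x) + k''(x)/(iω),
    k''(x) = c · E(x) h(x)³ / b(x)⁴,   m''(x) = ρ_BM h(x),

where the graded material laws over the 31.9 mm arclength `x` are

    E(x)  = (−28732 x² − 557 x + 50) MPa,
    β(x)  = 45·10⁻⁵ x + 10⁻⁶ s            (x ≤ 20 mm)
          = 3.43 x² + 0.13 x + 0.0012 s   (x > 20 mm).

The place of peak |BM displacement| per frequency is compared against the
Greenwood map `F = A(10^{α(1−x/L)} − k)` with `A = 165`, `α = 2.1`.

**Middle ear.** Rigid ossicles (malleus and incus with 6 DOF, the stapes
with its piston translation and two rocking rotations), bushing-joint
ligaments (AML, PIL, SML, LML, TT, IMJ, ISJ, annular ligament), a lumped
tympanic-membrane piston, a 9 mm ear canal driven by a uniform inlet
velocity of 10⁻⁵ m/s ("94 dB SPL"), and the 0.63 mL tympanic cavity with an
aditus/mastoid Helmholtz branch. Four calibration multipliers are tuned
once (shipped) so the coupled METF peaks at the main resonance near 750 Hz.

**Stapedotomy.** The stapes is replaced by a titanium piston (Ø 0.6 mm ×
2 mm, Ø 0.2 mm wire) inserted through a Ø 0.8 mm hole in the now-rigid
footplate and attached to the incus by a spherical joint. The annular gap
around the piston is an acoustic element — fluid-slug inertance, in series
with a clamped tissue-membrane compliance when sealed — shunting the
oval-window port into the tympanic cavity. The ABG estimate of a
reconstruction is `20·log₁₀(measure_reconstructed / measure_natural)`.

## Worked example

Compare two sealed-gap pistons against the natural ear:

```sh
$ earbench compare --piston 0.6,0.7 --gap sealed \
      --freq-min 250 --freq-max 8000 --freq-points 24
ABG (max BM displacement, dB) at octave frequencies:
  f_Hz      piston_0.6mm_sealed     piston_0.7mm_sealed
     250                 -16.52                  -13.83
     500                 -18.34                  -15.59
    1000                 -13.27                  -10.34
    2000                 -11.93                   -9.71
    4000                 -17.22                  -14.80
    8000                 -18.92                  -16.42
```

Negative ABG means conductive loss relative to the natural ear: both
reconstructions sit 10–19 dB below the natural ear (typical of
post-stapedotomy ears), and the Ø 0.7 mm piston recovers ~2.5 dB over
Ø 0.6 mm because its larger pumping area displaces more perilymph while
the ossicular chain drives both pistons with nearly the same displacement.
Every curve is also written as CSV (frequency, magnitude, phase) with a
configuration-hash header, plus a `manifest.json`; re-runs with the same
configuration are bit-identical.

Other entry points: `earbench metf` (prints the METF peak, 790.5 Hz for the
shipped calibration), `earbench tonotopy` (place–frequency map and its RMSE
vs. Greenwood, 2.79 mm by default), `earbench impedance`,
`earbench volume-displacement`, `earbench reconstruct`, `earbench
calibrate`, and `earbench validate` (quick property suite). The same
functionality is available as a library (`earbench.CoupledEar`,
`earbench.reconstruct`, `earbench.measures`), configured by YAML files with
unit-tagged values (`piston_diameter_m: 0.7 mm`); the canonical default ear
ships as `earbench/data/default_ear.yaml`.

## Acceptance script

`scripts/acceptance.py` recomputes the bench's headline numbers from
scratch — the Greenwood apex limit and basal BM modulus from the material
laws, the tonotopy RMSE from a full 60-point coupled sweep, the
piston-diameter and open-gap ABG effects from reconstruction sweeps, and
the METF peak frequency — and writes them to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The solve path is deterministic; `--seed` is accepted for provenance.
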