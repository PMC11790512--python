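"""Stapedotomy reconstruction: piston prosthesis and annular-gap acoustics.

After a stapedotomy the calcified footplate becomes a rigid wall with a
0.8 mm hole; a titanium piston (default diameter 0.6 mm, length 2 mm, wire
diameter 0.2 mm) is inserted through the hole and crimped to the incus.
The hook contact is idealised as a spherical joint (relative translations
locked, rotations free).  The ring of fluid between piston and hole — the
annular gap — either leaks volume velocity into the middle-ear cavity
("open") or is covered by soft connective tissue ("sealed").

The gap is a lumped acoustic element: an inertance
``M = rho*(t_plate + 0.85*r_h)/S_annulus`` of the fluid in the slot (with
hydraulic-radius end correction), in series — for the sealed state — with
the compliance of the clamped annular tissue membrane.  A sealed gap is
essentially leak-free over the audio band; an open gap shunts strongly at
low frequency and closes with rising frequency as the fluid inertia takes
over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import ConfigError, EarConfig, ScalaGeometry, build_default_config

__all__ = [
    "ProsthesisSpec",
    "GapElement",
    "SEAL_PRESETS",
    "annular_gap_element",
    "reconstruct",
    "compare_reconstructions",
]

TWO_PI = 2.0 * np.pi

#: named sealing-membrane Young's moduli (Pa).  The soft-tissue value used
#: for the headline comparisons is 3 MPa; a 20 MPa tympanic-membrane-like
#: preset is retained as an alternative.
SEAL_PRESETS = {"soft": 3.0e6, "stiff": 20.0e6}


@dataclass
class ProsthesisSpec:
    """Piston/wire geometry plus the state of the annular gap."""

    piston_diameter_m: float = 0.6e-3
    piston_length_m: float = 2.0e-3
    wire_diameter_m: float = 0.2e-3
    wire_length_m: float = 4.0e-3
    hole_diameter_m: float = 0.8e-3
    density_kg_m3: float = 4500.0      # titanium
    gap_state: str = "sealed"
    seal_youngs_pa: float = SEAL_PRESETS["soft"]
    seal_thickness_m: float = 0.1e-3
    seal_poisson: float = 0.3
    plate_thickness_m: float = 0.2e-3  # footplate plane around the hole

    def validate(self) -> "ProsthesisSpec":
        if self.gap_state not in ("open", "sealed"):
            raise ConfigError("gap_state must be 'open' or 'sealed'")
        if self.piston_diameter_m >= self.hole_diameter_m:
            raise ConfigError("piston diameter must be smaller than the hole")
        for name in ("piston_diameter_m", "piston_length_m", "wire_diameter_m",
                     "wire_length_m", "hole_diameter_m", "density_kg_m3",
                     "seal_youngs_pa", "seal_thickness_m", "plate_thickness_m"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"ProsthesisSpec.{name} must be positive")
        return self

    @property
    def piston_area_m2(self) -> float:
        return math.pi * self.piston_diameter_m ** 2 / 4.0

    @property
    def mass_kg(self) -> float:
        """Piston plus wire mass from the geometry and material density."""
        v_piston = self.piston_area_m2 * self.piston_length_m
        v_wire = math.pi * self.wire_diameter_m ** 2 / 4.0 * self.wire_length_m
        return self.density_kg_m3 * (v_piston + v_wire)

    @classmethod
    def from_config(cls, config: EarConfig, **overrides) -> "ProsthesisSpec":
        p = config.prosthesis
        spec = cls(piston_diameter_m=p.piston_diameter_m,
                   piston_length_m=p.piston_length_m,
                   wire_diameter_m=p.wire_diameter_m,
                   wire_length_m=p.wire_length_m,
                   hole_diameter_m=p.hole_diameter_m,
                   density_kg_m3=p.density_kg_m3,
                   gap_state=p.gap_state,
                   seal_youngs_pa=p.seal_youngs_pa,
                   seal_thickness_m=p.seal_thickness_m,
                   seal_poisson=p.seal_poisson,
                   plate_thickness_m=p.plate_thickness_m)
        return replace(spec, **overrides).validate()


@dataclass
class GapElement:
    """Lumped acoustic element of the annular gap."""

    annulus_area_m2: float
    inertance_pas2_m3: float
    compliance_m3_pa: float | None  # None for the open gap
    resistance_pas_m3: float = 0.0  # perilymph is modelled inviscid

    def impedance(self, f: float) -> complex:
        w = TWO_PI * f
        z = 1j * w * self.inertance_pas2_m3 + self.resistance_pas_m3
        if self.compliance_m3_pa is not None:
            z += 1.0 / (1j * w * self.compliance_m3_pa)
        return z


def annular_gap_element(spec: ProsthesisSpec,
                        fluid: ScalaGeometry | None = None) -> GapElement:
    """Acoustic gap element for a prosthesis spec and perilymph properties.

    Open gap: fluid-slug inertance of the annular slot with an
    ``0.85 * hydraulic radius`` end correction.  Sealed gap: the clamped
    annular membrane compliance (clamped-strip bending of the tissue ring)
    in series with the same inertance.
    """
    spec.validate()
    fluid = fluid or ScalaGeometry()
    rho = fluid.fluid_density_kg_m3
    d_h, d_p = spec.hole_diameter_m, spec.piston_diameter_m
    s_ann = math.pi * (d_h ** 2 - d_p ** 2) / 4.0
    perimeter = math.pi * (d_h + d_p)
    r_hydraulic = 2.0 * s_ann / perimeter   # equals the radial gap width
    inertance = rho * (spec.plate_thickness_m + 0.85 * r_hydraulic) / s_ann

    compliance = None
    if spec.gap_state == "sealed":
        width = (d_h - d_p) / 2.0
        d_flex = (spec.seal_youngs_pa * spec.seal_thickness_m ** 3
                  / (12.0 * (1.0 - spec.seal_poisson ** 2)))
        # clamped-clamped strip of span `width` wrapped around the mean
        # circumference: volume displaced per unit pressure
        mean_circumference = math.pi * (d_h + d_p) / 2.0
        compliance = mean_circumference * width ** 5 / (720.0 * d_flex)

    return GapElement(annulus_area_m2=s_ann, inertance_pas2_m3=inertance,
                      compliance_m3_pa=compliance)


def reconstruct(config: EarConfig | None = None,
                spec: ProsthesisSpec | None = None, **model_kwargs):
    """Coupled ear model with the stapes replaced by the piston prosthesis.

    Returns a :class:`earbench.coupled.CoupledEar` whose middle-ear chain
    ends in the piston (spherical joint at the incus) and whose cochlear
    oval-window port has the piston area with the gap element shunting to
    the tympanic cavity.
    """
    from .coupled import CoupledEar

    config = config or build_default_config()
    spec = (spec or ProsthesisSpec.from_config(config)).validate()
    return CoupledEar(config, prosthesis=spec, **model_kwargs)


_DEFAULT_MEASURES = ("max_bm_displacement", "icp", "p_sv", "vd_rw", "vd_ow",
                     "piston_displacement")


def compare_reconstructions(specs: Sequence[ProsthesisSpec],
                            config: EarConfig | None = None,
                            measure_names: Iterable[str] = _DEFAULT_MEASURES,
                            frequencies=None,
                            labels: Sequence[str] | None = None,
                            **model_kwargs) -> dict:
    """Run the natural ear plus each reconstruction on one grid.

    Returns ``{label: {measure: MeasureCurve, "abg_<measure>": MeasureCurve}}``
    with the natural ("representative") ear under the label ``"natural"``.
    Air-bone-gap curves are the level of each reconstructed measure re the
    natural one (negative = conductive loss).
    """
    from .coupled import CoupledEar
    from . import measures as meas

    if len(specs) == 0:
        raise ValueError("need at least one prosthesis spec")
    config = config or build_default_config()
    if frequencies is None:
        frequencies = config.frequency.frequencies()
    if labels is None:
        labels = [f"piston_{s.piston_diameter_m * 1e3:.1f}mm_{s.gap_state}"
                  for s in specs]

    out: dict[str, dict] = {}
    natural = CoupledEar(config, **model_kwargs).sweep(frequencies)
    out["natural"] = {name: meas.measure_curve(natural, name)
                      for name in measure_names}
    for label, spec in zip(labels, specs):
        sweep = reconstruct(config, spec, **model_kwargs).sweep(frequencies)
        entry = {name: meas.measure_curve(sweep, name) for name in measure_names}
        for name in measure_names:
            entry[f"abg_{name}"] = meas.abg(entry[name], out["natural"][name])
        out[label] = entry
    return out
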