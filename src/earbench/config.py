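"""Parametric geometry and material description of the human ear model.

Everything is SI internally.  Configuration files may tag values with units
(``"0.6 mm"``, ``"3 MPa"``); tags are converted to SI on load.  The default
configuration encodes an average adult ear: a 31.9 mm long uncoiled basilar
membrane (BM) with a graded isotropic Young's modulus and
stiffness-proportional (Rayleigh beta) damping, two identical perilymph
ducts, an elliptical stapes footplate (2.81 x 1.27 mm), a round window of
1.62 x 1.15 x 0.06 mm, and a 37.8 mm^3 vestibule.

The two graded BM material laws are the heart of the passive cochlea:

* Young's modulus (Pa), quadratic in the arclength ``x`` from the base::

      E(x) = (-28732 * x**2 - 557 * x + 50) * 1e6      0 <= x <= 0.0319 m

* Rayleigh (stiffness-proportional) damping factor beta (s), two branches::

      beta(x) = 45e-5 * x + 1e-6                        0 <= x <= 0.020 m
      beta(x) = 3.43 * x**2 + 0.13 * x + 0.0012         0.020 < x <= 0.0319 m

Both laws are descriptive: they encapsulate the BM together with its
adjacent structures and the (neglected) fluid viscosity, and were obtained
by fitting a cochlear model's place-frequency map to the Greenwood function.
The branch change of beta at x = 20 mm is discontinuous by construction and
is kept exactly as stated (no smoothing).
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "BMProfile",
    "ScalaGeometry",
    "WindowSpec",
    "GreenwoodParams",
    "TMSpec",
    "CavitySpec",
    "OssicleSpec",
    "JointSpec",
    "MiddleEarConfig",
    "ProsthesisConfig",
    "FrequencyGrid",
    "EarConfig",
    "bm_young_modulus",
    "bm_beta_damping",
    "greenwood_cf",
    "greenwood_place",
    "footplate_area",
    "build_default_config",
    "parse_quantity",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "default_ear_path",
    "config_hash",
]

BM_LENGTH_M = 0.0319  #: printed BM arclength, metres
BETA_BREAK_M = 0.020  #: branch point of the beta-damping law


class ConfigError(ValueError):
    """Raised when a configuration value violates a model invariant."""


# ---------------------------------------------------------------------------
# material laws and closed-form geometry rules
# ---------------------------------------------------------------------------

def _check_domain(x, length: float, what: str):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > length + 1e-12):
        raise ConfigError(
            f"{what}: arclength x must lie in [0, {length}] m, got {x!r}"
        )
    return x


def _length_of(profile) -> float:
    if profile is None:
        return BM_LENGTH_M
    if isinstance(profile, (int, float)):
        return float(profile)
    return profile.length_m


def bm_young_modulus(x, profile=None):
    """Graded BM Young's modulus E(x) in Pa at arclength ``x`` (m) from the base.

    Quadratic polynomial law, positive over the whole 31.9 mm domain
    (50 MPa at the base, about 3 MPa at the apex).  ``profile`` may be a
    :class:`BMProfile` (its length sets the domain) or a plain length in m.
    """
    x = _check_domain(x, _length_of(profile), "bm_young_modulus")
    e = (-28732.0 * x * x - 557.0 * x + 50.0) * 1.0e6
    return float(e) if np.ndim(e) == 0 else e


def bm_beta_damping(x, profile=None):
    """Rayleigh beta damping factor (s) of the BM at arclength ``x`` (m).

    Affine basal branch up to 20 mm, quadratic apical branch beyond; the
    printed branch change is discontinuous and reproduced verbatim.
    ``x = 0`` evaluates the basal branch limit (1e-6 s).
    """
    x = _check_domain(x, _length_of(profile), "bm_beta_damping")
    basal = 45.0e-5 * x + 1.0e-6
    apical = 3.43 * x * x + 0.13 * x + 0.0012
    beta = np.where(x <= BETA_BREAK_M, basal, apical)
    return float(beta) if np.ndim(beta) == 0 else beta


def footplate_area(axis_long: float, axis_short: float, rule: str = "ellipse") -> float:
    """Footplate area (m^2) from the two printed footplate axes (m).

    ``rule="ellipse"`` (default) treats the axes as full ellipse axes and
    returns ``pi*a*b/4``, which reproduces the printed ~2.8 mm^2.
    ``rule="product"`` is the literal ``pi*a*b`` reading, kept behind a flag.
    """
    if axis_long <= 0.0 or axis_short <= 0.0:
        raise ConfigError("footplate axes must be positive")
    if rule == "ellipse":
        return math.pi * axis_long * axis_short / 4.0
    if rule == "product":
        return math.pi * axis_long * axis_short
    raise ConfigError(f"unknown footplate area rule {rule!r}")


@dataclass
class GreenwoodParams:
    """Constants of the Greenwood place-frequency function for the human ear.

    ``cf(x) = A * (10 ** (alpha * (1 - x/length)) - k)`` with ``x`` the
    arclength from the base.  ``k = 1`` maps the apex to 0 Hz; ``k = 0.88``
    sets the conventional 20 Hz lower limit.
    """

    A: float = 165.0
    alpha: float = 2.1
    k: float = 1.0
    length_m: float = BM_LENGTH_M

    def validate(self) -> "GreenwoodParams":
        if self.A <= 0:
            raise ConfigError("GreenwoodParams.A must be positive")
        if not (0.0 <= self.k <= 1.0):
            raise ConfigError("GreenwoodParams.k must lie in [0, 1]")
        if self.length_m <= 0:
            raise ConfigError("GreenwoodParams.length_m must be positive")
        return self


def greenwood_cf(x, gp: GreenwoodParams | None = None):
    """Characteristic frequency (Hz) at arclength ``x`` (m) from the base."""
    gp = (gp or GreenwoodParams()).validate()
    x = _check_domain(x, gp.length_m, "greenwood_cf")
    f = gp.A * (10.0 ** (gp.alpha * (1.0 - x / gp.length_m)) - gp.k)
    f = np.maximum(f, 0.0)
    return float(f) if np.ndim(f) == 0 else f


def greenwood_place(f, gp: GreenwoodParams | None = None):
    """Invert the Greenwood map: place ``x`` (m from base) for frequency ``f`` (Hz).

    Frequencies below ``cf(length)`` or above ``cf(0)`` are outside the
    invertible range and raise :class:`ConfigError`.
    """
    gp = (gp or GreenwoodParams()).validate()
    f = np.asarray(f, dtype=float)
    arg = f / gp.A + gp.k
    if np.any(arg <= 0.0):
        raise ConfigError("greenwood_place: frequency outside invertible range")
    x = gp.length_m * (1.0 - np.log10(arg) / gp.alpha)
    if np.any(x < -1e-9) or np.any(x > gp.length_m + 1e-9):
        raise ConfigError("greenwood_place: frequency outside invertible range")
    x = np.clip(x, 0.0, gp.length_m)
    return float(x) if np.ndim(x) == 0 else x


# ---------------------------------------------------------------------------
# inner-ear configuration blocks
# ---------------------------------------------------------------------------

@dataclass
class BMProfile:
    """Graded BM geometry and material fields along the arclength.

    Width and thickness taper linearly between the stated base and apex
    values (the published profiles are figure-only; the defaults are
    standard human box-model values).  ``strip_stiffness_constant`` is the
    clamped plate-strip constant in the areal stiffness
    ``k''(x) = c * E(x) * h(x)**3 / b(x)**4``.
    """

    length_m: float = BM_LENGTH_M
    n_sections: int = 400
    width_base_m: float = 0.10e-3
    width_apex_m: float = 0.50e-3
    thickness_base_m: float = 7.5e-6
    thickness_apex_m: float = 2.5e-6
    density_kg_m3: float = 1200.0
    strip_stiffness_constant: float = 3.0

    def validate(self) -> "BMProfile":
        if self.length_m <= 0:
            raise ConfigError("BMProfile.length_m must be positive")
        if self.n_sections < 16:
            raise ConfigError("BMProfile.n_sections must be >= 16")
        for name in ("width_base_m", "width_apex_m", "thickness_base_m",
                     "thickness_apex_m", "density_kg_m3",
                     "strip_stiffness_constant"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"BMProfile.{name} must be positive")
        return self

    def _taper(self, x, v0: float, v1: float):
        x = _check_domain(x, self.length_m, "BMProfile")
        return v0 + (v1 - v0) * (x / self.length_m)

    def width(self, x):
        return self._taper(x, self.width_base_m, self.width_apex_m)

    def thickness(self, x):
        return self._taper(x, self.thickness_base_m, self.thickness_apex_m)

    def young(self, x):
        return bm_young_modulus(x, self.length_m)

    def beta(self, x):
        return bm_beta_damping(x, self.length_m)


@dataclass
class ScalaGeometry:
    """Fluid-duct geometry and perilymph properties.

    Scala vestibuli and scala tympani share one linearly tapering
    cross-section area (2.0 -> 1.0 mm^2 by default; two-channel models carry
    the scala-media volume and are deliberately wider than anatomy).  The
    helicotrema is a short connecting duct at the apex.  Perilymph is
    water-like; ``compressible=False`` removes all fluid compliance.
    """

    area_base_m2: float = 2.0e-6
    area_apex_m2: float = 1.0e-6
    helicotrema_area_m2: float = 0.25e-6
    helicotrema_length_m: float = 1.0e-3
    fluid_density_kg_m3: float = 1000.0
    fluid_sound_speed_m_s: float = 1500.0
    compressible: bool = True

    def validate(self) -> "ScalaGeometry":
        for name in ("area_base_m2", "area_apex_m2", "helicotrema_area_m2",
                     "helicotrema_length_m", "fluid_density_kg_m3",
                     "fluid_sound_speed_m_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"ScalaGeometry.{name} must be positive")
        return self

    def area(self, x, length: float = BM_LENGTH_M):
        x = _check_domain(x, length, "ScalaGeometry.area")
        return self.area_base_m2 + (self.area_apex_m2 - self.area_base_m2) * (x / length)


@dataclass
class WindowSpec:
    """Oval/round window geometry and the vestibule volume.

    The round window is a clamped elliptical membrane (printed height,
    width and 0.06 mm thickness); its Young's modulus is not printed and
    defaults to 0.35 MPa, a companion inner-ear model value.  The footplate
    area follows the chosen ellipse-area rule applied to the printed axes.
    """

    footplate_axis_long_m: float = 2.81e-3
    footplate_axis_short_m: float = 1.27e-3
    footplate_area_rule: str = "ellipse"
    rw_height_m: float = 1.62e-3
    rw_width_m: float = 1.15e-3
    rw_thickness_m: float = 0.06e-3
    rw_youngs_pa: float = 0.35e6
    rw_density_kg_m3: float = 1200.0
    rw_poisson: float = 0.3
    rw_loss_factor: float = 0.3
    vestibulum_volume_m3: float = 37.8e-9
    vestibule_duct_length_m: float = 4.0e-3

    def validate(self) -> "WindowSpec":
        for name in ("footplate_axis_long_m", "footplate_axis_short_m",
                     "rw_height_m", "rw_width_m", "rw_thickness_m",
                     "rw_youngs_pa", "rw_density_kg_m3",
                     "vestibulum_volume_m3", "vestibule_duct_length_m"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"WindowSpec.{name} must be positive")
        if self.rw_loss_factor < 0:
            raise ConfigError("WindowSpec.rw_loss_factor must be >= 0")
        footplate_area(self.footplate_axis_long_m, self.footplate_axis_short_m,
                       self.footplate_area_rule)
        return self

    @property
    def footplate_area_m2(self) -> float:
        return footplate_area(self.footplate_axis_long_m,
                              self.footplate_axis_short_m,
                              self.footplate_area_rule)


# ---------------------------------------------------------------------------
# middle-ear configuration blocks
# ---------------------------------------------------------------------------

@dataclass
class TMSpec:
    """Lumped tympanic membrane: an effective piston replacing the shell FE.

    ``area_m2 * effectiveness`` is the acoustically active piston area used
    for both the force pickup from the ear canal and the volume displaced
    into the tympanic cavity.
    """

    area_m2: float = 60.0e-6
    effectiveness: float = 0.6
    mass_kg: float = 6.0e-6
    stiffness_n_m: float = 250.0
    damping_ns_m: float = 0.05
    coupling_stiffness_n_m: float = 2.0e4
    coupling_damping_ns_m: float = 0.02

    @property
    def effective_area_m2(self) -> float:
        return self.area_m2 * self.effectiveness

    def validate(self) -> "TMSpec":
        for name in ("area_m2", "effectiveness", "mass_kg", "stiffness_n_m",
                     "coupling_stiffness_n_m"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"TMSpec.{name} must be positive")
        return self


@dataclass
class CavitySpec:
    """Tympanic cavity compliance plus the aditus/mastoid Helmholtz branch.

    The 0.63 mL cavity acts as an air spring on the TM; the oscillating air
    column of the aditus (one-mass Helmholtz element backed by the mastoid
    volume) and a facial-recess absorption conductance complete the branch.
    """

    volume_m3: float = 0.63e-6
    mastoid_volume_m3: float = 5.0e-6
    neck_length_m: float = 5.0e-3
    neck_area_m2: float = 1.0e-5
    neck_resistance_pas_m3: float = 5.0e5
    recess_conductance_m3_pas: float = 1.18e-8
    enable_mastoid_branch: bool = True

    def validate(self) -> "CavitySpec":
        for name in ("volume_m3", "mastoid_volume_m3", "neck_length_m",
                     "neck_area_m2"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"CavitySpec.{name} must be positive")
        if self.neck_resistance_pas_m3 < 0 or self.recess_conductance_m3_pas < 0:
            raise ConfigError("CavitySpec resistances must be >= 0")
        return self


@dataclass
class OssicleSpec:
    """A rigid ossicle: mass, an ellipsoid-fit inertia, and its frame.

    ``com_mm`` is the centre of mass in the global anatomical frame
    (x anterior-posterior, y lateral->medial, z superior-inferior, mm);
    ``ref_mm`` is the reference point at which the body's degrees of freedom
    are defined (defaults to the centre of mass).
    """

    name: str
    mass_kg: float
    semi_axes_mm: tuple[float, float, float]
    com_mm: tuple[float, float, float]
    ref_mm: tuple[float, float, float] | None = None

    def validate(self) -> "OssicleSpec":
        if self.mass_kg <= 0:
            raise ConfigError(f"OssicleSpec[{self.name}].mass_kg must be positive")
        if any(s <= 0 for s in self.semi_axes_mm):
            raise ConfigError(f"OssicleSpec[{self.name}].semi_axes_mm must be positive")
        return self

    def inertia_com(self) -> np.ndarray:
        """Principal inertia tensor (kg m^2) of the solid ellipsoid fit."""
        a, b, c = (s * 1e-3 for s in self.semi_axes_mm)
        m = self.mass_kg
        return np.diag([
            m / 5.0 * (b * b + c * c),
            m / 5.0 * (a * a + c * c),
            m / 5.0 * (a * a + b * b),
        ])


#: degree-of-freedom order used for every 6-vector: tx, ty, tz, rx, ry, rz
DOF_ORDER = ("tx", "ty", "tz", "rx", "ry", "rz")


@dataclass
class JointSpec:
    """A bushing joint: per-DOF stiffness/damping between two frames.

    ``body_a``/``body_b`` name ossicles, ``"tm"``, or ``None`` for ground.
    ``stiffness``/``damping`` are 6-vectors in the order tx, ty, tz (N/m,
    N s/m) then rx, ry, rz (N m/rad, N m s/rad); zero entries are inactive.
    """

    name: str
    body_a: str | None
    body_b: str | None
    point_mm: tuple[float, float, float]
    stiffness: tuple[float, ...]
    damping: tuple[float, ...]

    def validate(self) -> "JointSpec":
        if len(self.stiffness) != 6 or len(self.damping) != 6:
            raise ConfigError(f"JointSpec[{self.name}]: stiffness/damping must have 6 entries")
        if any(v < 0 for v in self.stiffness) or any(v < 0 for v in self.damping):
            raise ConfigError(f"JointSpec[{self.name}]: parameters must be >= 0")
        return self

    @property
    def active_dof_mask(self) -> tuple[bool, ...]:
        return tuple(k > 0 or c > 0 for k, c in zip(self.stiffness, self.damping))


@dataclass
class MiddleEarConfig:
    """Lumped/rigid-body middle ear from the ear-canal inlet to the stapes.

    The ear canal is a 9 mm lossless duct driven by a uniform inlet
    velocity of 1e-5 m/s (the "94 dB SPL" source condition).  Malleus and
    incus carry 6 DOF each; the stapes is constrained to its piston
    translation (y) and the two rocking rotations (rx, rz).  The four
    calibration multipliers scale the baseline ligament/TM parameter set;
    their defaults are the shipped calibration product.
    """

    ec_length_m: float = 9.0e-3
    ec_area_m2: float = 44.3e-6
    air_density_kg_m3: float = 1.204
    air_sound_speed_m_s: float = 343.0
    excitation_velocity_m_s: float = 1.0e-5
    tm: TMSpec = field(default_factory=TMSpec)
    cavity: CavitySpec = field(default_factory=CavitySpec)
    ossicles: dict[str, OssicleSpec] = field(default_factory=dict)
    joints: dict[str, JointSpec] = field(default_factory=dict)
    umbo_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # calibration multipliers (dimensionless)
    stiffness_scale: float = 1.0
    tm_compliance_scale: float = 1.0
    annular_stiffness_scale: float = 1.0
    damping_scale: float = 1.0

    def validate(self) -> "MiddleEarConfig":
        for name in ("ec_length_m", "ec_area_m2", "air_density_kg_m3",
                     "air_sound_speed_m_s", "stiffness_scale",
                     "tm_compliance_scale", "annular_stiffness_scale",
                     "damping_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"MiddleEarConfig.{name} must be positive")
        self.tm.validate()
        self.cavity.validate()
        for oss in self.ossicles.values():
            oss.validate()
        for joint in self.joints.values():
            joint.validate()
        if "annular" in self.joints:
            mask = self.joints["annular"].active_dof_mask
            if mask != (False, True, False, True, False, True):
                raise ConfigError(
                    "annular ligament must carry exactly the three stapes DOF "
                    "(ty, rx, rz)")
        return self


@dataclass
class ProsthesisConfig:
    """Default stapedotomy piston prosthesis (see :mod:`earbench.prosthesis`)."""

    piston_diameter_m: float = 0.6e-3
    piston_length_m: float = 2.0e-3
    wire_diameter_m: float = 0.2e-3
    wire_length_m: float = 4.0e-3
    hole_diameter_m: float = 0.8e-3
    density_kg_m3: float = 4500.0
    gap_state: str = "sealed"
    seal_youngs_pa: float = 3.0e6
    seal_thickness_m: float = 0.1e-3
    seal_poisson: float = 0.3
    plate_thickness_m: float = 0.2e-3

    def validate(self) -> "ProsthesisConfig":
        if self.gap_state not in ("open", "sealed"):
            raise ConfigError("ProsthesisConfig.gap_state must be 'open' or 'sealed'")
        if self.piston_diameter_m >= self.hole_diameter_m:
            raise ConfigError("piston diameter must be smaller than the hole diameter")
        for name in ("piston_diameter_m", "piston_length_m", "wire_diameter_m",
                     "wire_length_m", "hole_diameter_m", "density_kg_m3",
                     "seal_youngs_pa", "seal_thickness_m", "plate_thickness_m"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"ProsthesisConfig.{name} must be positive")
        return self


@dataclass
class FrequencyGrid:
    """Logarithmic analysis grid (Hz)."""

    f_min_hz: float = 100.0
    f_max_hz: float = 10000.0
    n_points: int = 60

    def validate(self) -> "FrequencyGrid":
        if not (0 < self.f_min_hz < self.f_max_hz):
            raise ConfigError("FrequencyGrid: need 0 < f_min < f_max")
        if self.n_points < 1:
            raise ConfigError("FrequencyGrid.n_points must be >= 1")
        return self

    def frequencies(self) -> np.ndarray:
        if self.n_points == 1:
            return np.array([self.f_min_hz])
        return np.geomspace(self.f_min_hz, self.f_max_hz, self.n_points)


@dataclass
class EarConfig:
    """Complete configuration of the coupled middle/inner-ear model."""

    bm: BMProfile = field(default_factory=BMProfile)
    scalae: ScalaGeometry = field(default_factory=ScalaGeometry)
    windows: WindowSpec = field(default_factory=WindowSpec)
    greenwood: GreenwoodParams = field(default_factory=GreenwoodParams)
    middle_ear: MiddleEarConfig = field(default_factory=MiddleEarConfig)
    prosthesis: ProsthesisConfig = field(default_factory=ProsthesisConfig)
    frequency: FrequencyGrid = field(default_factory=FrequencyGrid)

    def validate(self) -> "EarConfig":
        self.bm.validate()
        self.scalae.validate()
        self.windows.validate()
        self.greenwood.validate()
        self.middle_ear.validate()
        self.prosthesis.validate()
        self.frequency.validate()
        return self


# ---------------------------------------------------------------------------
# the default ear
# ---------------------------------------------------------------------------

# Baseline ligament/joint parameter set.  The printed source model only
# states the topology (which DOF each bushing carries); the numeric values
# below are anatomically plausible starting values whose overall scale is
# fixed by the shipped calibration multipliers (see
# middle_ear.calibrate_middle_ear and docs/methods.md).
def _default_ossicles() -> dict[str, OssicleSpec]:
    return {
        "malleus": OssicleSpec("malleus", 25.0e-6, (1.0, 0.8, 4.0), (0.5, 1.0, 2.0)),
        "incus": OssicleSpec("incus", 28.0e-6, (1.5, 1.5, 2.5), (2.5, 2.0, 3.0)),
        "stapes": OssicleSpec("stapes", 3.0e-6, (1.4, 0.6, 1.0), (3.5, 4.6, 0.8),
                              ref_mm=(3.5, 5.0, 0.8)),
    }


def _default_joints() -> dict[str, JointSpec]:
    # AML/PIL anchor the rotation axis of the malleus-incus block: stiff in
    # translation, soft hinge rotations.  The small ligaments/tendon carry a
    # single translational DOF; IMJ is nearly rigid; ISJ is translationally
    # stiff but rotationally flexible.
    return {
        "AML": JointSpec("AML", None, "malleus", (-2.0, 1.5, 3.0),
                         (5e3, 5e3, 5e3, 1e-5, 1e-5, 1e-5),
                         (0.02, 0.02, 0.02, 1e-9, 1e-9, 1e-9)),
        "PIL": JointSpec("PIL", None, "incus", (4.0, 1.5, 4.0),
                         (5e3, 5e3, 5e3, 1e-5, 1e-5, 1e-5),
                         (0.02, 0.02, 0.02, 1e-9, 1e-9, 1e-9)),
        "SML": JointSpec("SML", None, "malleus", (0.5, 1.5, 4.5),
                         (0, 0, 50.0, 0, 0, 0), (0, 0, 0.01, 0, 0, 0)),
        "LML": JointSpec("LML", None, "malleus", (0.5, 0.5, 2.0),
                         (0, 50.0, 0, 0, 0, 0), (0, 0.01, 0, 0, 0, 0)),
        "TT": JointSpec("TT", None, "malleus", (0.5, 2.0, 1.5),
                        (0, 100.0, 0, 0, 0, 0), (0, 0.01, 0, 0, 0, 0)),
        "IMJ": JointSpec("IMJ", "malleus", "incus", (1.5, 1.5, 3.5),
                         (1e5, 1e5, 1e5, 0.1, 0.1, 0.1),
                         (0.05, 0.05, 0.05, 1e-6, 1e-6, 1e-6)),
        "ISJ": JointSpec("ISJ", "incus", "stapes", (3.5, 3.5, 0.8),
                         (5e3, 5e3, 5e3, 1e-6, 1e-6, 1e-6),
                         (0.02, 0.02, 0.02, 1e-9, 1e-9, 1e-9)),
        "annular": JointSpec("annular", None, "stapes", (3.5, 5.0, 0.8),
                             (0, 600.0, 0, 2e-4, 0, 2e-4),
                             (0, 0.02, 0, 1e-9, 0, 1e-9)),
    }


# Calibration product of middle_ear.calibrate_middle_ear against the
# coupled-model targets (main METF resonance at 750 Hz, mid-band magnitude
# corridor).  Regenerate with `earbench calibrate`.
CALIBRATED_MULTIPLIERS = {
    "stiffness_scale": 10.0,
    "tm_compliance_scale": 2.226,
    "annular_stiffness_scale": 0.179,
    "damping_scale": 1.663,
}


def build_default_config() -> EarConfig:
    """The canonical ``default_ear``: every printed constant plus the
    documented gap-filling defaults, with the shipped middle-ear calibration
    applied."""
    me = MiddleEarConfig(ossicles=_default_ossicles(), joints=_default_joints(),
                         **CALIBRATED_MULTIPLIERS)
    return EarConfig(middle_ear=me).validate()


# ---------------------------------------------------------------------------
# unit-tagged serialisation
# ---------------------------------------------------------------------------

_UNIT_FACTORS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    "m2": 1.0, "m^2": 1.0, "mm2": 1e-6, "mm^2": 1e-6,
    "m3": 1.0, "m^3": 1.0, "mm3": 1e-9, "mm^3": 1e-9, "ml": 1e-6, "l": 1e-3,
    "pa": 1.0, "kpa": 1e3, "mpa": 1e6, "gpa": 1e9,
    "hz": 1.0, "khz": 1e3,
    "s": 1.0, "ms": 1e-3,
    "kg": 1.0, "g": 1e-3, "mg": 1e-6,
    "kg/m3": 1.0, "kg/m^3": 1.0,
    "m/s": 1.0, "mm/s": 1e-3,
    "n/m": 1.0, "n*m/rad": 1.0, "nm/rad": 1.0,
    "n*s/m": 1.0, "pa*s/m3": 1.0,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]+)\s*$")


def parse_quantity(value):
    """Convert a possibly unit-tagged value (``"0.6 mm"``) to an SI float."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        m = _QUANTITY_RE.match(value)
        if not m:
            raise ConfigError(f"cannot parse quantity {value!r}")
        number, unit = m.groups()
        factor = _UNIT_FACTORS.get(unit.lower())
        if factor is None:
            raise ConfigError(f"unknown unit {unit!r} in {value!r}")
        return float(number) * factor
    raise ConfigError(f"cannot parse quantity {value!r}")


def config_to_dict(config: EarConfig) -> dict:
    """Plain nested dict of SI values (YAML/JSON friendly)."""
    return dataclasses.asdict(config)


def _build_dataclass(cls, data: Mapping, path: str):
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key {path}.{key}")
        ftype = fields[key].type
        if isinstance(value, Mapping) and dataclasses.is_dataclass(_DATACLASS_FIELDS.get((cls, key), object)):
            sub = _DATACLASS_FIELDS[(cls, key)]
            if sub in (dict,):
                kwargs[key] = value
            else:
                kwargs[key] = _build_dataclass(sub, value, f"{path}.{key}")
        elif (cls, key) in _DICT_OF:
            sub = _DICT_OF[(cls, key)]
            kwargs[key] = {
                name: _build_dataclass(sub, v, f"{path}.{key}.{name}")
                for name, v in value.items()
            }
        elif isinstance(value, (list, tuple)):
            kwargs[key] = tuple(parse_quantity(v) for v in value)
        elif isinstance(value, bool) or value is None:
            kwargs[key] = value
        elif isinstance(value, str) and not _QUANTITY_RE.match(value):
            kwargs[key] = value
        elif key in _STRING_FIELDS:
            kwargs[key] = value
        else:
            kwargs[key] = parse_quantity(value)
            if key == "n_sections" or key == "n_points":
                kwargs[key] = int(kwargs[key])
    return cls(**kwargs)


_DATACLASS_FIELDS = {
    (EarConfig, "bm"): BMProfile,
    (EarConfig, "scalae"): ScalaGeometry,
    (EarConfig, "windows"): WindowSpec,
    (EarConfig, "greenwood"): GreenwoodParams,
    (EarConfig, "middle_ear"): MiddleEarConfig,
    (EarConfig, "prosthesis"): ProsthesisConfig,
    (EarConfig, "frequency"): FrequencyGrid,
    (MiddleEarConfig, "tm"): TMSpec,
    (MiddleEarConfig, "cavity"): CavitySpec,
}

_DICT_OF = {
    (MiddleEarConfig, "ossicles"): OssicleSpec,
    (MiddleEarConfig, "joints"): JointSpec,
}

_STRING_FIELDS = {"name", "body_a", "body_b", "gap_state", "footplate_area_rule"}


def config_from_dict(data: Mapping) -> EarConfig:
    """Rebuild an :class:`EarConfig` from a nested dict, filling missing
    sections from the defaults and converting unit-tagged values."""
    base = config_to_dict(build_default_config())
    merged = _deep_merge(base, dict(data or {}))
    return _build_dataclass(EarConfig, merged, "config").validate()


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def save_config(config: EarConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> EarConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def default_ear_path():
    """Path of the canonical ``default_ear`` YAML fixture shipped with the
    package (identical to :func:`build_default_config`)."""
    from importlib.resources import files

    return files("earbench").joinpath("data/default_ear.yaml")


def config_hash(config: EarConfig) -> str:
    """Deterministic short hash identifying a configuration."""
    import hashlib
    import json

    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
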