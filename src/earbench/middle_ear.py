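"""Frequency-domain lumped/rigid-body middle ear.

The ossicles are rigid bodies (malleus and incus with 6 DOF, the stapes
constrained to its piston translation ``y`` and the two rocking rotations
``rx``/``rz`` at the footplate centre).  Ligaments, tendons and the two
ossicular joints are bushing elements: per-DOF springs and dashpots acting
on the relative motion of two attachment frames.  The tympanic membrane is
lumped into an effective piston coupled stiffly to the malleus at the umbo.
The stapedial tendon is absent.

Acoustics are attached as frequency-dependent scalar impedances on the TM
piston: a lossless 9 mm ear-canal duct driven by a uniform inlet velocity
source (1e-5 m/s, the "94 dB SPL" condition), and the tympanic-cavity
branch (0.63 mL compliance, aditus/mastoid Helmholtz element, facial-recess
absorption conductance).  The cochlear load enters as a 3x3 mechanical
impedance at the stapes DOF, so the same chain drives either the natural
footplate or a piston prosthesis.

Assembled K, C, M are real symmetric; the harmonic system is
``(K + i*w*C - w^2*M + Z_ac(w)) u = F(w)`` under the ``e^{+iwt}``
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import (ConfigError, EarConfig, JointSpec, MiddleEarConfig,
                     OssicleSpec, build_default_config)

__all__ = [
    "MiddleEarModel",
    "DrivePoint",
    "CalibrationTargets",
    "assemble_middle_ear",
    "solve_middle_ear",
    "calibrate_middle_ear",
]

TWO_PI = 2.0 * np.pi

#: DOF axes per body kind: ("t", axis) translation, ("r", axis) rotation
_FULL6 = [("t", 0), ("t", 1), ("t", 2), ("r", 0), ("r", 1), ("r", 2)]
_STAPES3 = [("t", 1), ("r", 0), ("r", 2)]
_PISTON1 = [("t", 1)]


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


@dataclass
class _Body:
    name: str
    dof_axes: list
    offset: int            # first global DOF index
    ref: np.ndarray        # reference point (m, global frame)
    mass_full: np.ndarray  # 6x6 rigid-body mass about ref (t then r rows)

    @property
    def ndof(self) -> int:
        return len(self.dof_axes)


def _rigid_mass_about_ref(mass: float, inertia_com: np.ndarray,
                          d: np.ndarray) -> np.ndarray:
    """6x6 rigid-body mass matrix about a reference point; ``d = com - ref``."""
    dsk = _skew(d)
    m = np.zeros((6, 6))
    m[:3, :3] = mass * np.eye(3)
    m[:3, 3:] = -mass * dsk
    m[3:, :3] = mass * dsk
    m[3:, 3:] = inertia_com - mass * dsk @ dsk
    return m


class MiddleEarModel:
    """Assembled middle-ear network with real symmetric K, C, M.

    ``drive_body`` names the body whose piston DOF couples to the cochlea
    ("stapes" for the natural chain, "piston" after reconstruction).
    """

    def __init__(self, config: MiddleEarConfig, bodies: dict[str, _Body],
                 K: np.ndarray, C: np.ndarray, M: np.ndarray,
                 drive_body: str):
        self.config = config
        self.bodies = bodies
        self.K, self.C, self.M = K, C, M
        self.ndof = K.shape[0]
        self.drive_body = drive_body
        self.tm_index = bodies["tm"].offset

    def drive_indices(self) -> list[int]:
        """Global DOF indices receiving the cochlear load (piston, rx, rz)."""
        body = self.bodies[self.drive_body]
        return list(range(body.offset, body.offset + body.ndof))

    # -- acoustic attachments ------------------------------------------------

    def ec_terms(self, f: float) -> tuple[complex, complex]:
        """Ear-canal duct: (diagonal impedance term on u_tm, RHS force).

        The lossless duct of length l and area S, driven by the inlet
        volume-velocity source ``q0 = v_ec*S`` and terminated by the TM
        piston, contributes ``+w*A^2*Z0*cot(kl)`` to the dynamic stiffness
        and the force ``-i*A*Z0*q0/sin(kl)``.
        """
        cfg = self.config
        w = TWO_PI * f
        k = w / cfg.air_sound_speed_m_s
        kl = k * cfg.ec_length_m
        z0 = cfg.air_density_kg_m3 * cfg.air_sound_speed_m_s / cfg.ec_area_m2
        s, c = np.sin(kl), np.cos(kl)
        if abs(s) < 1e-12:
            raise ArithmeticError(f"ear-canal duct resonance at f={f} Hz")
        a = cfg.tm.effective_area_m2
        q0 = cfg.excitation_velocity_m_s * cfg.ec_area_m2
        lhs = w * a * a * z0 * c / s
        rhs = -1j * a * z0 * q0 / s
        return lhs, rhs

    def cavity_impedance(self, f: float) -> complex:
        """Acoustic impedance (Pa s/m^3) of the tympanic-cavity branch."""
        cfg = self.config.cavity
        rho, c = self.config.air_density_kg_m3, self.config.air_sound_speed_m_s
        w = TWO_PI * f
        y = 1j * w * cfg.volume_m3 / (rho * c * c)
        y += cfg.recess_conductance_m3_pas
        if cfg.enable_mastoid_branch:
            m_neck = rho * cfg.neck_length_m / cfg.neck_area_m2
            c_mast = cfg.mastoid_volume_m3 / (rho * c * c)
            z_branch = (1j * w * m_neck + cfg.neck_resistance_pas_m3
                        + 1.0 / (1j * w * c_mast))
            y += 1.0 / z_branch
        return 1.0 / y

    def dynamic_stiffness(self, f: float,
                          cochlear_load: np.ndarray | complex | None = None
                          ) -> np.ndarray:
        """Complex system matrix at ``f`` including all acoustic terms."""
        if f <= 0:
            raise ValueError("frequency must be positive")
        w = TWO_PI * f
        z = self.K + 1j * w * self.C - w * w * self.M
        z = z.astype(complex)
        a = self.config.tm.effective_area_m2
        ec_lhs, _ = self.ec_terms(f)
        i_tm = self.tm_index
        z[i_tm, i_tm] += ec_lhs
        z[i_tm, i_tm] += 1j * w * a * a * self.cavity_impedance(f)
        if cochlear_load is not None:
            idx = self.drive_indices()
            zl = np.asarray(cochlear_load, dtype=complex)
            if zl.ndim == 0:
                zl = np.diag([complex(zl)] + [0.0] * (len(idx) - 1))
            zl = zl[:len(idx), :len(idx)]
            for a_i, gi in enumerate(idx):
                for b_i, gj in enumerate(idx):
                    z[gi, gj] += 1j * w * zl[a_i, b_i]
        return z


@dataclass
class DrivePoint:
    """Footplate (or prosthesis) drive-point response at one frequency."""

    frequency: float
    piston_velocity: complex          # m/s, positive medial (into the cochlea)
    rocking_velocity: tuple[complex, complex]  # rad/s about x and z
    p_ec_inlet: complex               # Pa at the ear-canal inlet
    tm_displacement: complex          # m

    @property
    def piston_displacement(self) -> complex:
        return self.piston_velocity / (1j * TWO_PI * self.frequency)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _point_jacobian(body: _Body, point: np.ndarray, direction: np.ndarray,
                    ndof: int) -> np.ndarray:
    """Row mapping generalised DOF -> displacement of ``point`` along
    ``direction`` for one body (translation + theta x r kinematics)."""
    g = np.zeros(ndof)
    r = point - body.ref
    for j, (kind, axis) in enumerate(body.dof_axes):
        if kind == "t":
            g[body.offset + j] = direction[axis]
        else:
            e = np.zeros(3)
            e[axis] = 1.0
            g[body.offset + j] = np.dot(np.cross(e, r), direction)
    return g


def _rotation_jacobian(body: _Body, axis: int, ndof: int) -> np.ndarray:
    g = np.zeros(ndof)
    for j, (kind, ax) in enumerate(body.dof_axes):
        if kind == "r" and ax == axis:
            g[body.offset + j] = 1.0
    return g


def _add_bushing(K: np.ndarray, C: np.ndarray, bodies: Mapping[str, _Body],
                 joint: JointSpec, ndof: int,
                 k_scale: float = 1.0, c_scale: float = 1.0) -> None:
    point = np.asarray(joint.point_mm, dtype=float) * 1e-3
    for comp in range(6):
        k = joint.stiffness[comp] * k_scale
        c = joint.damping[comp] * c_scale
        if k == 0.0 and c == 0.0:
            continue
        g = np.zeros(ndof)
        for body_name, sign in ((joint.body_a, -1.0), (joint.body_b, 1.0)):
            if body_name is None:
                continue
            body = bodies[body_name]
            if comp < 3:
                e = np.zeros(3)
                e[comp] = 1.0
                g += sign * _point_jacobian(body, point, e, ndof)
            else:
                g += sign * _rotation_jacobian(body, comp - 3, ndof)
        K += k * np.outer(g, g)
        C += c * np.outer(g, g)


def assemble_middle_ear(config: EarConfig | MiddleEarConfig | None = None,
                        prosthesis=None) -> MiddleEarModel:
    """Build the middle-ear network from a configuration.

    With ``prosthesis`` given (a :class:`earbench.prosthesis.ProsthesisSpec`),
    the stapes body, the annular ligament and the incudostapedial joint are
    removed and replaced by a single-DOF piston attached to the incus
    lenticular process through a spherical joint (translations locked,
    rotations free; only the axial translation couples in a 1D port model).
    """
    if config is None:
        config = build_default_config()
    me = config.middle_ear if isinstance(config, EarConfig) else config
    me.validate()

    s_k = me.stiffness_scale
    s_c = me.damping_scale

    # -- bodies --------------------------------------------------------------
    bodies: dict[str, _Body] = {}
    offset = 0

    tm_body = _Body("tm", [("t", 1)], 0, np.zeros(3), np.zeros((6, 6)))
    bodies["tm"] = tm_body
    offset = 1

    def add_ossicle(spec: OssicleSpec, dof_axes) -> None:
        nonlocal offset
        ref = np.asarray(spec.ref_mm if spec.ref_mm is not None else spec.com_mm,
                         dtype=float) * 1e-3
        com = np.asarray(spec.com_mm, dtype=float) * 1e-3
        m6 = _rigid_mass_about_ref(spec.mass_kg, spec.inertia_com(), com - ref)
        bodies[spec.name] = _Body(spec.name, list(dof_axes), offset, ref, m6)
        offset += len(dof_axes)

    add_ossicle(me.ossicles["malleus"], _FULL6)
    add_ossicle(me.ossicles["incus"], _FULL6)
    if prosthesis is None:
        add_ossicle(me.ossicles["stapes"], _STAPES3)
        drive_body = "stapes"
    else:
        stapes = me.ossicles["stapes"]
        ref = np.asarray(stapes.ref_mm or stapes.com_mm, dtype=float) * 1e-3
        m6 = np.zeros((6, 6))
        m6[:3, :3] = prosthesis.mass_kg * np.eye(3)
        bodies["piston"] = _Body("piston", list(_PISTON1), offset, ref, m6)
        offset += 1
        drive_body = "piston"

    ndof = offset
    K = np.zeros((ndof, ndof))
    C = np.zeros((ndof, ndof))
    M = np.zeros((ndof, ndof))

    # -- mass ----------------------------------------------------------------
    tm = me.tm
    M[0, 0] = tm.mass_kg
    for body in bodies.values():
        if body.name == "tm":
            continue
        full_index = {("t", 0): 0, ("t", 1): 1, ("t", 2): 2,
                      ("r", 0): 3, ("r", 1): 4, ("r", 2): 5}
        sel = [full_index[d] for d in body.dof_axes]
        M[np.ix_(range(body.offset, body.offset + body.ndof),
                 range(body.offset, body.offset + body.ndof))] = \
            body.mass_full[np.ix_(sel, sel)]

    # -- TM suspension and umbo coupling ------------------------------------
    K[0, 0] += tm.stiffness_n_m * s_k / me.tm_compliance_scale
    C[0, 0] += tm.damping_ns_m * s_c
    umbo = np.asarray(me.umbo_mm, dtype=float) * 1e-3
    ey = np.array([0.0, 1.0, 0.0])
    g = _point_jacobian(bodies["malleus"], umbo, ey, ndof)
    g[0] -= 1.0  # minus the TM piston DOF
    K += tm.coupling_stiffness_n_m * s_k * np.outer(g, g)
    C += tm.coupling_damping_ns_m * s_c * np.outer(g, g)

    # -- joints --------------------------------------------------------------
    for name, joint in me.joints.items():
        if prosthesis is not None and name in ("annular", "ISJ"):
            continue
        extra = me.annular_stiffness_scale if name == "annular" else 1.0
        _add_bushing(K, C, bodies, joint, ndof,
                     k_scale=s_k * extra, c_scale=s_c)

    # -- spherical joint incus -> piston (reconstruction) --------------------
    if prosthesis is not None:
        isj = me.joints["ISJ"]
        point = np.asarray(isj.point_mm, dtype=float) * 1e-3
        k_sph = max(isj.stiffness[:3]) * s_k * 10.0  # locked translations
        c_sph = max(isj.damping[:3]) * s_c
        g = (_point_jacobian(bodies["piston"], point, ey, ndof)
             - _point_jacobian(bodies["incus"], point, ey, ndof))
        K += k_sph * np.outer(g, g)
        C += c_sph * np.outer(g, g)

    return MiddleEarModel(me, bodies, K, C, M, drive_body)


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

def solve_middle_ear(model: MiddleEarModel,
                     cochlear_load: np.ndarray | complex | None,
                     f: float) -> DrivePoint:
    """Harmonic response of the chain at ``f`` with the cochlear load
    attached at the drive DOF.  ``cochlear_load`` is a 3x3 (or scalar)
    mechanical impedance; ``None`` or zero solves the unloaded chain."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    w = TWO_PI * f
    z = model.dynamic_stiffness(f, cochlear_load)
    rhs = np.zeros(model.ndof, dtype=complex)
    _, f_tm = model.ec_terms(f)
    rhs[model.tm_index] = f_tm
    try:
        u = np.linalg.solve(z, rhs)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular middle-ear system at f={f} Hz") from exc
    if not np.all(np.isfinite(u)):
        raise RuntimeError(f"non-finite middle-ear solution at f={f} Hz")

    idx = model.drive_indices()
    v = 1j * w * u[idx[0]]
    rock = ((1j * w * u[idx[1]], 1j * w * u[idx[2]])
            if len(idx) == 3 else (0.0 + 0.0j, 0.0 + 0.0j))

    # EC inlet pressure: p(0) = i*Z0*q_tm/sin(kl) - i*Z0*q0*cot(kl)
    cfg = model.config
    k = w / cfg.air_sound_speed_m_s
    kl = k * cfg.ec_length_m
    z0 = cfg.air_density_kg_m3 * cfg.air_sound_speed_m_s / cfg.ec_area_m2
    q0 = cfg.excitation_velocity_m_s * cfg.ec_area_m2
    q_tm = 1j * w * cfg.tm.effective_area_m2 * u[model.tm_index]
    p_in = 1j * z0 * q_tm / np.sin(kl) - 1j * z0 * q0 / np.tan(kl)

    return DrivePoint(frequency=float(f), piston_velocity=complex(v),
                      rocking_velocity=rock, p_ec_inlet=complex(p_in),
                      tm_displacement=complex(u[model.tm_index]))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTargets:
    """Anchor points for the middle-ear parameter calibration.

    The main METF resonance of the coupled natural ear (750 Hz) and a
    mid-band magnitude corridor typical of published METF measurements.
    """

    resonance_hz: float = 750.0
    corridor_f_lo_hz: float = 400.0
    corridor_f_hi_hz: float = 1200.0
    metf_min_m_pa: float = 0.1e-6
    metf_max_m_pa: float = 1.0e-6
    resonance_tolerance_octaves: float = 1.0 / 6.0


def _coupled_metf_peak(config: EarConfig, freqs: np.ndarray):
    from .coupled import CoupledEar
    from .measures import metf, refine_peak_log

    ear = CoupledEar(config)
    curve = metf(ear.sweep(freqs))
    return curve, refine_peak_log(curve.frequencies, np.abs(curve.values))


def _calibration_cost(config: EarConfig, targets: CalibrationTargets,
                      freqs: np.ndarray) -> float:
    curve, f_peak = _coupled_metf_peak(config, freqs)
    mag = np.abs(curve.values)
    cost = (12.0 * np.log2(f_peak / targets.resonance_hz)) ** 2
    band = ((curve.frequencies >= targets.corridor_f_lo_hz)
            & (curve.frequencies <= targets.corridor_f_hi_hz))
    mid = np.exp(np.mean(np.log(mag[band])))
    if mid < targets.metf_min_m_pa:
        cost += np.log10(targets.metf_min_m_pa / mid) ** 2
    elif mid > targets.metf_max_m_pa:
        cost += np.log10(mid / targets.metf_max_m_pa) ** 2
    return float(cost)


def calibrate_middle_ear(config: EarConfig | None = None,
                         targets: CalibrationTargets | None = None,
                         max_iter: int = 60) -> dict:
    """Tune the four scalar multipliers of the middle-ear parameter set.

    Bounded Nelder-Mead on the log-multipliers (deterministic: fixed
    starting simplex, no randomness).  Returns a dict with the multipliers,
    the residual cost and the achieved METF peak; if the initial
    configuration already meets the targets it is returned unchanged.
    Raises no exception on non-convergence but reports the best residual
    found (``converged`` flag).
    """
    import copy

    from scipy.optimize import minimize

    config = copy.deepcopy(config or build_default_config())
    targets = targets or CalibrationTargets()
    # evaluate the resonance on the configured analysis grid so the
    # calibrated peak is the peak of the exported METF curve
    freqs = config.frequency.frequencies()

    names = ("stiffness_scale", "tm_compliance_scale",
             "annular_stiffness_scale", "damping_scale")
    x0 = np.log([getattr(config.middle_ear, n) for n in names])

    def apply(x):
        x = np.clip(x, np.log(0.1), np.log(10.0))
        for n, v in zip(names, np.exp(x)):
            setattr(config.middle_ear, n, float(v))
        return config

    def resonance_error_octaves(cfg):
        _, f_peak = _coupled_metf_peak(cfg, freqs)
        return f_peak, abs(np.log2(f_peak / targets.resonance_hz))

    f_peak0, err0 = resonance_error_octaves(apply(x0))
    if err0 <= targets.resonance_tolerance_octaves:
        return {"multipliers": dict(zip(names, np.exp(x0))),
                "cost": _calibration_cost(config, targets, freqs),
                "metf_peak_hz": f_peak0, "converged": True, "changed": False}

    simplex = np.vstack([x0] + [x0 + np.log(2.0) * e for e in np.eye(4)])
    res = minimize(lambda x: _calibration_cost(apply(x), targets, freqs),
                   x0, method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 1e-3, "fatol": 1e-4,
                            "initial_simplex": simplex, "adaptive": False})
    f_peak, err = resonance_error_octaves(apply(res.x))
    return {"multipliers": dict(zip(names, np.exp(np.clip(res.x, np.log(0.1),
                                                          np.log(10.0))))),
            "cost": float(res.fun), "metf_peak_hz": f_peak,
            "converged": bool(err <= targets.resonance_tolerance_octaves),
            "changed": True}
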