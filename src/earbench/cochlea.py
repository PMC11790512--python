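"""Discrete two-duct cochlea: assembly and harmonic solution.

The spiral cochlea is uncoiled into two identical fluid ducts (scala
vestibuli, SV, and scala tympani, ST) separated by the graded basilar
membrane and joined at the apex by the helicotrema.  The 3D acoustic field
is reduced to a quasi-1D two-duct transmission line: each duct is a chain
of acoustic inertances (``rho*dx/A``) with, for compressible perilymph, a
nodal compliance ``dx*A/(rho*c^2)``.  At every station the BM couples the
ducts through the specific impedance of a locally reacting clamped plate
strip,

    Z_s(x, f) = i*w*m''(x) + k''(x)*beta(x) + k''(x)/(i*w)

with areal mass ``m'' = rho_bm*h`` and areal stiffness
``k'' = c * E(x) * h(x)^3 / b(x)^4`` (time convention ``e^{+iwt}``).
The oval-window port drives the SV inlet through the vestibule (lumped
inertance plus, when compressible, the 37.8 mm^3 volume compliance); the ST
base is terminated by the round-window membrane, a single-DOF clamped
elliptical plate.  The assembled nodal system is complex symmetric and is
factorised directly per frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import EarConfig, WindowSpec, build_default_config

__all__ = [
    "HarmonicSolution",
    "CochleaModel",
    "assemble_cochlea",
    "solve_cochlea",
    "sweep",
    "save_sweep_hdf5",
    "load_sweep_hdf5",
    "clamped_ellipse_compliance",
    "clamped_ellipse_mass",
]

TWO_PI = 2.0 * np.pi


class SolverError(RuntimeError):
    """Raised when the harmonic system cannot be solved at a frequency."""


def clamped_ellipse_compliance(semi_a: float, semi_b: float, thickness: float,
                               youngs: float, poisson: float = 0.3) -> float:
    """Acoustic compliance (m^3/Pa) of a clamped elliptical plate.

    Uses the classical clamped-ellipse solution
    ``w(x,y) = w0*(1 - x^2/a^2 - y^2/b^2)^2`` with
    ``w0 = p / (8*D*(3/a^4 + 2/(a^2 b^2) + 3/b^4))``; the volume displaced
    per unit pressure is ``pi*a*b*w0/3``.
    """
    d = youngs * thickness ** 3 / (12.0 * (1.0 - poisson ** 2))
    denom = 8.0 * d * (3.0 / semi_a ** 4 + 2.0 / (semi_a ** 2 * semi_b ** 2)
                       + 3.0 / semi_b ** 4)
    return np.pi * semi_a * semi_b / (3.0 * denom)


def clamped_ellipse_mass(semi_a: float, semi_b: float, thickness: float,
                         density: float) -> float:
    """Acoustic mass (kg/m^4) of the same clamped plate mode shape.

    ``M = rho*h * integral(w^2) / (integral(w))^2 = rho*h*(9/5)/(pi*a*b)``.
    """
    return density * thickness * 1.8 / (np.pi * semi_a * semi_b)


@dataclass
class HarmonicSolution:
    """Complex response of the inner ear at one frequency.

    ``bm_displacement`` is the transverse BM displacement at the section
    centres (m), ``p_sv``/``p_st`` the duct pressures (Pa), ``q_*`` complex
    volume velocities (m^3/s, positive into the cochlea at the OW and out of
    it at the RW and gap).  When produced by a coupled solve the ear-canal
    inlet pressure and stapes rocking velocities are attached.
    """

    frequency: float
    x: np.ndarray
    bm_displacement: np.ndarray
    p_sv: np.ndarray
    p_st: np.ndarray
    p_vestibule: complex
    q_ow: complex
    q_rw: complex
    q_gap: complex
    drive_area: float
    drive_velocity: complex
    p_ec_inlet: complex | None = None
    rocking_velocity: tuple[complex, complex] | None = None

    @property
    def omega(self) -> float:
        return TWO_PI * self.frequency

    @property
    def drive_displacement(self) -> complex:
        """Piston (footplate or prosthesis) displacement at the drive point (m)."""
        return self.drive_velocity / (1j * self.omega)

    @property
    def vd_ow(self) -> complex:
        """Oval-window volume displacement: piston displacement x drive area."""
        return self.q_ow / (1j * self.omega)

    @property
    def vd_rw(self) -> complex:
        """Round-window volume displacement (m^3)."""
        return self.q_rw / (1j * self.omega)


class CochleaModel:
    """Assembled two-duct + BM + windows harmonic model.

    Parameters
    ----------
    config
        Full ear configuration; geometry/material fields are taken from its
        ``bm``, ``scalae`` and ``windows`` blocks.
    n_sections, compressible
        Optional overrides of the configured grid size and fluid
        compressibility.
    drive_area
        Area of the oval-window port (footplate by default; the piston area
        for a reconstructed ear).
    gap_shunt
        Optional callable ``f -> Z`` (acoustic impedance, Pa s/m^3) shunting
        the vestibule node to the middle-ear cavity; used by stapedotomy
        reconstructions with an open or sealed annular gap.
    """

    def __init__(self, config: EarConfig | None = None, *,
                 n_sections: int | None = None,
                 compressible: bool | None = None,
                 drive_area: float | None = None,
                 gap_shunt: Callable[[float], complex] | None = None):
        config = (config or build_default_config()).validate()
        self.config = config
        bm, sc, win = config.bm, config.scalae, config.windows
        self.n = int(n_sections or bm.n_sections)
        if self.n < 16:
            raise ValueError("n_sections must be >= 16")
        self.compressible = sc.compressible if compressible is None else bool(compressible)
        self.drive_area = float(drive_area if drive_area is not None
                                else win.footplate_area_m2)
        self.gap_shunt = gap_shunt

        L = bm.length_m
        self.dx = L / self.n
        self.x = (np.arange(self.n) + 0.5) * self.dx  # section centres

        # graded BM fields at the section centres
        self.width = bm.width(self.x)
        self.thickness = bm.thickness(self.x)
        self.youngs = bm.young(self.x)
        self.beta = bm.beta(self.x)
        self.k_areal = (bm.strip_stiffness_constant * self.youngs
                        * self.thickness ** 3 / self.width ** 4)
        self.m_areal = bm.density_kg_m3 * self.thickness

        # Gauss-2 quadrature nodes for the per-section BM shunt admittance.
        # The cell straddling the beta-damping branch point is split exactly
        # at the discontinuity so convergence does not depend on where the
        # jump falls within a cell.
        self._quad_x, self._quad_w, self._quad_cell = self._build_quadrature()
        self._quad_k = (bm.strip_stiffness_constant * bm.young(self._quad_x)
                        * bm.thickness(self._quad_x) ** 3
                        / bm.width(self._quad_x) ** 4)
        self._quad_m = bm.density_kg_m3 * bm.thickness(self._quad_x)
        self._quad_beta = bm.beta(self._quad_x)
        self._quad_width = bm.width(self._quad_x)

        # duct acoustics
        rho, c = sc.fluid_density_kg_m3, sc.fluid_sound_speed_m_s
        self.fluid_density = rho
        self.fluid_sound_speed = c
        self.area = sc.area(self.x, L)
        edge_area = sc.area(np.arange(1, self.n) * self.dx, L)
        self.link_inertance = rho * self.dx / edge_area          # per duct link
        self.node_compliance = self.dx * self.area / (rho * c * c)

        # vestibule two-port: short-duct inertance + volume compliance
        a_vest = win.vestibulum_volume_m3 / win.vestibule_duct_length_m
        self.vestibule_inertance = (rho * win.vestibule_duct_length_m / a_vest
                                    + rho * (self.dx / 2.0) / self.area[0])
        self.vestibule_compliance = win.vestibulum_volume_m3 / (rho * c * c)

        # helicotrema link (apex) including the two apical half cells
        self.helicotrema_inertance = (
            rho * sc.helicotrema_length_m / sc.helicotrema_area_m2
            + 2.0 * rho * (self.dx / 2.0) / self.area[-1])

        # round-window membrane termination (single clamped-ellipse DOF)
        semi_a, semi_b = win.rw_height_m / 2.0, win.rw_width_m / 2.0
        self.rw_compliance = clamped_ellipse_compliance(
            semi_a, semi_b, win.rw_thickness_m, win.rw_youngs_pa, win.rw_poisson)
        self.rw_mass = (clamped_ellipse_mass(semi_a, semi_b, win.rw_thickness_m,
                                             win.rw_density_kg_m3)
                        + rho * (self.dx / 2.0) / self.area[0])
        self.rw_loss_factor = win.rw_loss_factor

        self._pattern = None  # cached sparsity pattern

    def _build_quadrature(self):
        from .config import BETA_BREAK_M

        gauss = 0.5 / np.sqrt(3.0)
        xs, ws, cells = [], [], []
        for i in range(self.n):
            lo, hi = i * self.dx, (i + 1) * self.dx
            pieces = ([(lo, BETA_BREAK_M), (BETA_BREAK_M, hi)]
                      if lo < BETA_BREAK_M < hi else [(lo, hi)])
            for a, b in pieces:
                half = (b - a) / 2.0
                mid = (a + b) / 2.0
                for node in (mid - 2 * gauss * half, mid + 2 * gauss * half):
                    xs.append(node)
                    ws.append(half)
                    cells.append(i)
        return (np.asarray(xs), np.asarray(ws), np.asarray(cells, dtype=int))

    # -- per-section impedances ---------------------------------------------

    def _bm_admittance(self, f: float) -> np.ndarray:
        """Per-section acoustic admittance of the BM shunt (m^3/(Pa s)),
        cell-integrated: Y_i = int b(x) / Z_s(x, f) dx over section i."""
        w = TWO_PI * f
        z_s = (1j * w * self._quad_m + self._quad_k * self._quad_beta
               + self._quad_k / (1j * w))
        contrib = self._quad_width / z_s * self._quad_w
        y = np.zeros(self.n, dtype=complex)
        np.add.at(y, self._quad_cell, contrib)
        return y

    def bm_specific_impedance(self, f: float) -> np.ndarray:
        """Specific BM impedance Z_s(x, f) (Pa s/m) at every section centre."""
        w = TWO_PI * f
        return (1j * w * self.m_areal + self.k_areal * self.beta
                + self.k_areal / (1j * w))

    def section_bm_impedance(self, station: int, f: float) -> complex:
        """Specific impedance of one BM section (station index on the grid)."""
        if not 0 <= station < self.n:
            raise IndexError(f"station {station} outside grid of {self.n}")
        if f <= 0:
            raise ValueError("frequency must be positive")
        return complex(self.bm_specific_impedance(f)[station])

    def rw_impedance(self, f: float) -> complex:
        """Acoustic impedance of the round-window termination (Pa s/m^3)."""
        w = TWO_PI * f
        return (1j * w * self.rw_mass
                + (1.0 + 1j * self.rw_loss_factor) / (1j * w * self.rw_compliance))

    # -- assembly ------------------------------------------------------------

    def assemble(self, f: float) -> sp.csc_matrix:
        """Complex symmetric nodal admittance matrix at frequency ``f`` (Hz).

        Unknowns: ``p_sv[0..n-1], p_st[0..n-1], p_vestibule`` (index 2n).
        Rows are volume-velocity balances; the OW source enters the RHS.
        """
        if f <= 0:
            raise ValueError("frequency must be positive")
        n = self.n
        w = TWO_PI * f
        rows, cols, data = [], [], []

        def branch(a: int, b: int | None, y: complex):
            rows.append(a); cols.append(a); data.append(y)
            if b is not None:
                rows.append(b); cols.append(b); data.append(y)
                rows.append(a); cols.append(b); data.append(-y)
                rows.append(b); cols.append(a); data.append(-y)

        y_link = 1.0 / (1j * w * self.link_inertance)
        for i in range(n - 1):
            branch(i, i + 1, y_link[i])           # SV chain
            branch(n + i, n + i + 1, y_link[i])   # ST chain

        y_bm = self._bm_admittance(f)
        for i in range(n):
            branch(i, n + i, y_bm[i])

        branch(n - 1, 2 * n - 1, 1.0 / (1j * w * self.helicotrema_inertance))
        branch(2 * n, 0, 1.0 / (1j * w * self.vestibule_inertance))
        branch(n, None, 1.0 / self.rw_impedance(f))  # RW: ST base to ground

        if self.compressible:
            for i in range(n):
                branch(i, None, 1j * w * self.node_compliance[i])
                branch(n + i, None, 1j * w * self.node_compliance[i])
            branch(2 * n, None, 1j * w * self.vestibule_compliance)

        if self.gap_shunt is not None:
            branch(2 * n, None, 1.0 / complex(self.gap_shunt(f)))

        mat = sp.coo_matrix((data, (rows, cols)),
                            shape=(2 * n + 1, 2 * n + 1)).tocsc()
        if not np.all(np.isfinite(mat.data)):
            bad = np.argwhere(~np.isfinite(mat.data.reshape(-1)))[0]
            raise ValueError(f"non-finite matrix entry during assembly at f={f}")
        return mat

    # -- solution ------------------------------------------------------------

    def solve(self, f: float, q_ow: complex | None = None,
              velocity: complex | None = None) -> HarmonicSolution:
        """Solve the harmonic system at ``f`` for a given OW drive.

        Exactly one of ``q_ow`` (volume velocity, m^3/s) or ``velocity``
        (piston velocity, m/s; multiplied by the drive area) must be given.
        """
        if (q_ow is None) == (velocity is None):
            raise ValueError("specify exactly one of q_ow or velocity")
        if velocity is not None:
            q = complex(velocity) * self.drive_area
            v = complex(velocity)
        else:
            q = complex(q_ow)
            v = q / self.drive_area
        if not np.isfinite([q.real, q.imag]).all():
            raise ValueError("drive must be finite")

        n = self.n
        w = TWO_PI * f
        mat = self.assemble(f)
        rhs = np.zeros(2 * n + 1, dtype=complex)
        rhs[2 * n] = q
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", spla.MatrixRankWarning)
                p = spla.spsolve(mat, rhs)
        except (RuntimeError, spla.MatrixRankWarning) as exc:
            raise SolverError(f"singular cochlear system at f={f} Hz") from exc
        if not np.all(np.isfinite(p)):
            raise SolverError(f"non-finite cochlear solution at f={f} Hz")

        p_sv, p_st, p_vest = p[:n], p[n:2 * n], p[2 * n]
        z_s = self.bm_specific_impedance(f)
        bm_disp = (p_sv - p_st) / z_s / (1j * w)
        q_rw = p_st[0] / self.rw_impedance(f)
        q_gap = (p_vest / complex(self.gap_shunt(f))
                 if self.gap_shunt is not None else 0.0 + 0.0j)
        return HarmonicSolution(
            frequency=float(f), x=self.x, bm_displacement=bm_disp,
            p_sv=p_sv, p_st=p_st, p_vestibule=complex(p_vest),
            q_ow=q, q_rw=complex(q_rw), q_gap=complex(q_gap),
            drive_area=self.drive_area, drive_velocity=v)

    def drive_point_impedance(self, f: float) -> complex:
        """Acoustic drive-point impedance at the OW port, p_vest/q (Pa s/m^3)."""
        sol = self.solve(f, q_ow=1.0)
        return sol.p_vestibule

    def sv_inlet_impedance(self, f: float) -> complex:
        """Inner-ear input impedance p_SV(inlet)/q (Pa s/m^3)."""
        sol = self.solve(f, q_ow=1.0)
        return complex(sol.p_sv[0])

    def mechanical_load(self, f: float) -> np.ndarray:
        """3x3 mechanical impedance (N s/m ...) at the footplate centre.

        Only the piston DOF carries fluid load in a 1D port model; the two
        rocking DOF pump no net volume and see zero impedance.
        """
        z = np.zeros((3, 3), dtype=complex)
        z[0, 0] = self.drive_area ** 2 * self.drive_point_impedance(f)
        return z

    def sweep(self, frequencies: Sequence[float], *,
              q_ow: complex | None = None,
              velocity: complex | None = None) -> list[HarmonicSolution]:
        """One independent solution per frequency (order-invariant)."""
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.ndim != 1 or freqs.size == 0 or np.any(freqs <= 0):
            raise ValueError("frequency grid must be 1-D and positive")
        if q_ow is None and velocity is None:
            velocity = 1.0
        return [self.solve(float(f), q_ow=q_ow, velocity=velocity)
                for f in freqs]


def save_sweep_hdf5(sweep: Sequence[HarmonicSolution], path) -> None:
    """Dump a full sweep (all complex fields) to an HDF5 file.

    One group per frequency plus stacked datasets; derived curves are better
    exported as CSV via the CLI, this is the bulk/debug format.
    """
    import h5py

    sweep = sorted(sweep, key=lambda s: s.frequency)
    with h5py.File(path, "w") as fh:
        fh.attrs["n_frequencies"] = len(sweep)
        fh.create_dataset("frequency_hz",
                          data=np.array([s.frequency for s in sweep]))
        fh.create_dataset("x_m", data=sweep[0].x)
        for name in ("bm_displacement", "p_sv", "p_st"):
            fh.create_dataset(name, data=np.vstack(
                [getattr(s, name) for s in sweep]))
        for name in ("p_vestibule", "q_ow", "q_rw", "q_gap",
                     "drive_velocity"):
            fh.create_dataset(name, data=np.array(
                [getattr(s, name) for s in sweep], dtype=complex))
        fh.attrs["drive_area_m2"] = sweep[0].drive_area


def load_sweep_hdf5(path) -> list[HarmonicSolution]:
    """Inverse of :func:`save_sweep_hdf5`."""
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        freqs = fh["frequency_hz"][:]
        x = fh["x_m"][:]
        for i, f in enumerate(freqs):
            out.append(HarmonicSolution(
                frequency=float(f), x=x,
                bm_displacement=fh["bm_displacement"][i],
                p_sv=fh["p_sv"][i], p_st=fh["p_st"][i],
                p_vestibule=complex(fh["p_vestibule"][i]),
                q_ow=complex(fh["q_ow"][i]), q_rw=complex(fh["q_rw"][i]),
                q_gap=complex(fh["q_gap"][i]),
                drive_area=float(fh.attrs["drive_area_m2"]),
                drive_velocity=complex(fh["drive_velocity"][i])))
    return out


# -- thin functional wrappers (module-level API) ----------------------------

def assemble_cochlea(config: EarConfig, f: float, **kwargs) -> sp.csc_matrix:
    """Assemble the sparse complex system of the configured cochlea at ``f``."""
    return CochleaModel(config, **kwargs).assemble(f)


def solve_cochlea(model: CochleaModel, f: float, *, q_ow=None, velocity=None
                  ) -> HarmonicSolution:
    return model.solve(f, q_ow=q_ow, velocity=velocity)


def sweep(model: CochleaModel, frequencies, **kwargs) -> list[HarmonicSolution]:
    return model.sweep(frequencies, **kwargs)
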