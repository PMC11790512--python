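"""Performance measures and validation statistics of the coupled ear model.

All measures operate on a list of :class:`~earbench.cochlea.HarmonicSolution`
(one per frequency, as produced by ``CoupledEar.sweep`` or
``CochleaModel.sweep``) and return a :class:`MeasureCurve`:

* ``metf`` — middle-ear transfer function, footplate-centre piston
  displacement per unit ear-canal inlet pressure (m/Pa);
* ``extract_tonotopy`` / ``tonotopy_rmse`` — the place of peak BM
  displacement per frequency, compared with the Greenwood map;
* ``relative_bm_motion`` — BM displacement at a probe point (12 mm from the
  base) re the footplate displacement, in dB;
* ``inner_ear_impedance`` — SV inlet pressure over OW volume velocity;
* ``volume_displacements`` — complex OW and RW volume displacements;
* ``abg`` — the air-bone-gap estimate: level of a reconstructed-ear measure
  re the natural ("representative") ear,
  ``20*log10(|measure_recon| / |measure_repr|)`` (negative = loss);
* ``max_bm_displacement`` and ``icp`` (intracochlear pressure difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cochlea import HarmonicSolution
from .config import GreenwoodParams, greenwood_place

__all__ = [
    "MeasureCurve",
    "TonotopyMap",
    "metf",
    "extract_tonotopy",
    "tonotopy_rmse",
    "relative_bm_motion",
    "inner_ear_impedance",
    "volume_displacements",
    "abg",
    "max_bm_displacement",
    "icp",
    "measure_curve",
    "refine_peak_log",
]

TWO_PI = 2.0 * np.pi


@dataclass
class MeasureCurve:
    """A named frequency-indexed curve of complex or real values."""

    name: str
    frequencies: np.ndarray
    values: np.ndarray
    units: str
    reference: str = ""

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values)
        if self.frequencies.ndim != 1 or self.values.shape != self.frequencies.shape:
            raise ValueError("frequencies and values must be matching 1-D arrays")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(np.abs(self.values))):
            raise ValueError(f"MeasureCurve {self.name!r} contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase_deg(self) -> np.ndarray:
        if np.iscomplexobj(self.values):
            return np.degrees(np.unwrap(np.angle(self.values)))
        return np.zeros_like(self.magnitude)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency_Hz": self.frequencies,
            "magnitude": self.magnitude,
            "phase_deg": self.phase_deg,
        })

    def interp_magnitude(self, f) -> np.ndarray:
        """Log-log interpolated magnitude at frequencies ``f``."""
        return np.exp(np.interp(np.log(np.asarray(f, dtype=float)),
                                np.log(self.frequencies),
                                np.log(np.maximum(self.magnitude, 1e-300))))


def refine_peak_log(x: np.ndarray, magnitude: np.ndarray) -> float:
    """Location of the maximum of ``magnitude`` over log-spaced ``x``,
    refined by 3-point parabolic interpolation on ``log(magnitude)`` vs
    ``log(x)``.  Falls back to the grid point at the edges."""
    x = np.asarray(x, dtype=float)
    y = np.log(np.maximum(np.asarray(magnitude, dtype=float), 1e-300))
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    lx = np.log(x)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0.0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = 0.5 * (lx[i + 1] - lx[i - 1])
    return float(np.exp(lx[i] + np.clip(delta, -1.0, 1.0) * step))


def _freqs(sweep: Sequence[HarmonicSolution]) -> np.ndarray:
    f = np.array([s.frequency for s in sweep], dtype=float)
    order = np.argsort(f)
    return f, order


def _sorted(sweep: Sequence[HarmonicSolution]) -> list[HarmonicSolution]:
    return sorted(sweep, key=lambda s: s.frequency)


# ---------------------------------------------------------------------------
# the measures
# ---------------------------------------------------------------------------

def metf(sweep: Sequence[HarmonicSolution],
         ec_pressure: Sequence[complex] | None = None) -> MeasureCurve:
    """Middle-ear transfer function: footplate-centre y-displacement re the
    ear-canal inlet pressure (m/Pa)."""
    sweep = _sorted(sweep)
    if ec_pressure is None:
        ec_pressure = [s.p_ec_inlet for s in sweep]
        if any(p is None for p in ec_pressure):
            raise ValueError("metf needs a coupled-model sweep (no EC pressure)")
    p = np.asarray(ec_pressure, dtype=complex)
    if np.any(p == 0):
        raise ValueError("metf: zero ear-canal pressure")
    disp = np.array([s.drive_displacement for s in sweep], dtype=complex)
    return MeasureCurve("metf", [s.frequency for s in sweep], disp / p,
                        units="m/Pa", reference="re EC inlet pressure")


@dataclass
class TonotopyMap:
    """Peak BM-displacement place per excitation frequency.

    ``place_m`` increases toward the apex as frequency decreases; the
    inverse map (characteristic frequency along the BM) is available via
    :meth:`cf_at`.
    """

    frequencies: np.ndarray
    place_m: np.ndarray

    def place_at(self, f) -> np.ndarray:
        """Interpolated peak place (m) at frequency ``f`` (log-f interp)."""
        f = np.asarray(f, dtype=float)
        lo, hi = self.frequencies.min(), self.frequencies.max()
        if np.any(f < lo) or np.any(f > hi):
            raise ValueError("frequency outside the mapped range")
        return np.interp(np.log(f), np.log(self.frequencies), self.place_m)

    def cf_at(self, x) -> np.ndarray:
        """Inverse map: characteristic frequency (Hz) at place ``x`` (m)."""
        order = np.argsort(self.place_m)
        return np.exp(np.interp(np.asarray(x, dtype=float),
                                self.place_m[order],
                                np.log(self.frequencies)[order]))


def extract_tonotopy(sweep: Sequence[HarmonicSolution]) -> TonotopyMap:
    """Peak BM-displacement place per frequency, parabolic-refined.

    Frequencies whose BM response peaks at a grid boundary (no interior
    maximum) are excluded with a warning.
    """
    sweep = _sorted(sweep)
    if len(sweep) < 2:
        raise ValueError("need at least two frequencies for a tonotopy map")
    freqs, places = [], []
    for sol in sweep:
        mag = np.abs(sol.bm_displacement)
        i = int(np.argmax(mag))
        if i == 0 or i == len(mag) - 1 or not np.any(mag > 0):
            warnings.warn(f"no interior BM peak at f={sol.frequency:.6g} Hz; "
                          "frequency excluded from the tonotopy map")
            continue
        y = np.log(np.maximum(mag[i - 1:i + 2], 1e-300))
        denom = y[0] - 2.0 * y[1] + y[2]
        delta = 0.0 if denom >= 0 else np.clip(0.5 * (y[0] - y[2]) / denom, -1, 1)
        dx = sol.x[1] - sol.x[0]
        freqs.append(sol.frequency)
        places.append(sol.x[i] + delta * dx)
    if len(freqs) < 2:
        raise ValueError("tonotopy extraction failed: fewer than two usable peaks")
    freqs = np.asarray(freqs)
    order = np.argsort(freqs)
    return TonotopyMap(frequencies=freqs[order],
                       place_m=np.asarray(places)[order])


def tonotopy_rmse(tmap: TonotopyMap, gp: GreenwoodParams | None = None,
                  f_lo: float = 200.0, f_hi: float = 10000.0,
                  n_eval: int = 30) -> float:
    """RMSE (mm) between the simulated peak place and the Greenwood place.

    Evaluated on ``n_eval`` log-spaced frequencies within the overlap of
    ``[f_lo, f_hi]``, the mapped range, and the invertible Greenwood range;
    frequencies outside are excluded with a warning.
    """
    gp = (gp or GreenwoodParams()).validate()
    lo = max(f_lo, float(tmap.frequencies.min()))
    hi = min(f_hi, float(tmap.frequencies.max()))
    if not lo < hi:
        raise ValueError("empty evaluation range for tonotopy RMSE")
    f_eval = np.geomspace(lo, hi, n_eval)
    keep, ref = [], []
    for f in f_eval:
        try:
            ref.append(greenwood_place(f, gp))
            keep.append(f)
        except Exception:
            warnings.warn(f"f={f:.6g} Hz outside the invertible Greenwood range")
    keep = np.asarray(keep)
    sim = tmap.place_at(keep)
    err_mm = (sim - np.asarray(ref)) * 1e3
    return float(np.sqrt(np.mean(err_mm ** 2)))


def relative_bm_motion(sweep: Sequence[HarmonicSolution],
                       x_probe: float = 12.0e-3) -> MeasureCurve:
    """BM displacement at ``x_probe`` re the footplate piston displacement (dB).

    The probe value is interpolated (complex-linear) between grid stations,
    so moving the probe varies the curve smoothly.
    """
    sweep = _sorted(sweep)
    vals = []
    for sol in sweep:
        if sol.drive_displacement == 0:
            raise ValueError("relative_bm_motion: zero footplate displacement")
        u = np.interp(x_probe, sol.x, sol.bm_displacement.real) \
            + 1j * np.interp(x_probe, sol.x, sol.bm_displacement.imag)
        vals.append(20.0 * np.log10(np.abs(u) / np.abs(sol.drive_displacement)))
    return MeasureCurve("relative_bm_motion", [s.frequency for s in sweep],
                        np.asarray(vals), units="dB",
                        reference=f"BM at {x_probe * 1e3:g} mm re footplate")


def inner_ear_impedance(sweep: Sequence[HarmonicSolution]) -> MeasureCurve:
    """Cochlear input impedance p_SV(inlet) / (A_SF * V_SF) (Pa s/m^3)."""
    sweep = _sorted(sweep)
    vals = []
    for sol in sweep:
        if sol.q_ow == 0:
            raise ValueError("inner_ear_impedance: zero OW volume velocity")
        vals.append(sol.p_sv[0] / sol.q_ow)
    return MeasureCurve("inner_ear_impedance", [s.frequency for s in sweep],
                        np.asarray(vals, dtype=complex), units="Pa*s/m^3",
                        reference="p_SV inlet re OW volume velocity")


def volume_displacements(sol: HarmonicSolution) -> tuple[complex, complex]:
    """(VD_OW, VD_RW): complex window volume displacements (m^3)."""
    return sol.vd_ow, sol.vd_rw


def abg(measure_recon: MeasureCurve, measure_repr: MeasureCurve) -> MeasureCurve:
    """Air-bone-gap estimate: 20*log10(|recon| / |representative|) per
    frequency.  Negative values mean conductive hearing loss; audiogram-style
    display flips the sign."""
    if measure_recon.frequencies.shape != measure_repr.frequencies.shape or \
            not np.allclose(measure_recon.frequencies, measure_repr.frequencies):
        raise ValueError("abg: frequency grids differ")
    ratio = measure_recon.magnitude / measure_repr.magnitude
    return MeasureCurve(f"abg_{measure_recon.name}", measure_recon.frequencies,
                        20.0 * np.log10(ratio), units="dB",
                        reference=f"{measure_recon.name} re representative ear")


def max_bm_displacement(sol: HarmonicSolution) -> float:
    """Maximum of |BM displacement| over the grid at one frequency (m)."""
    return float(np.max(np.abs(sol.bm_displacement)))


def icp(sol: HarmonicSolution) -> complex:
    """Intracochlear pressure difference: p_SV at the OW minus p_ST at the RW."""
    return complex(sol.p_sv[0] - sol.p_st[0])


# ---------------------------------------------------------------------------
# generic curve extraction (used by the comparison driver and CLI)
# ---------------------------------------------------------------------------

_EXTRACTORS = {
    "max_bm_displacement": (lambda s: max_bm_displacement(s), "m"),
    "icp": (icp, "Pa"),
    "p_sv": (lambda s: complex(s.p_sv[0]), "Pa"),
    "p_st": (lambda s: complex(s.p_st[0]), "Pa"),
    "vd_rw": (lambda s: s.vd_rw, "m^3"),
    "vd_ow": (lambda s: s.vd_ow, "m^3"),
    "piston_displacement": (lambda s: s.drive_displacement, "m"),
}


def measure_curve(sweep: Sequence[HarmonicSolution], name: str) -> MeasureCurve:
    """Extract a named per-frequency measure from a sweep."""
    if name == "metf":
        return metf(sweep)
    if name not in _EXTRACTORS:
        raise KeyError(f"unknown measure {name!r}; choose from "
                       f"{sorted(_EXTRACTORS) + ['metf']}")
    fn, units = _EXTRACTORS[name]
    sweep = _sorted(sweep)
    vals = np.asarray([fn(s) for s in sweep])
    return MeasureCurve(name, [s.frequency for s in sweep], vals, units=units)
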