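"""Coupling of the middle-ear chain to the inner-ear fluid model.

The two sub-models exchange a single interface: the rigid stapes-footplate
(or prosthesis-piston) connection.  Per frequency the cochlea is condensed
into its 3x3 drive-point impedance at the footplate centre, the middle ear
is solved with that load attached, and the resulting piston velocity drives
the full cochlear field.  Because both models are linear this staggered
scheme is exact.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .cochlea import CochleaModel, HarmonicSolution
from .config import EarConfig, build_default_config
from .middle_ear import MiddleEarModel, assemble_middle_ear, solve_middle_ear

__all__ = ["CoupledEar"]


class CoupledEar:
    """Natural or reconstructed coupled ear model.

    Parameters
    ----------
    config
        Full configuration (defaults to :func:`build_default_config`).
    prosthesis
        ``None`` for the natural ear; a
        :class:`~earbench.prosthesis.ProsthesisSpec` replaces the stapes by
        a piston and shunts the oval-window port through the annular gap
        into the tympanic cavity.
    n_sections, compressible
        Optional cochlear grid / fluid overrides.
    """

    def __init__(self, config: EarConfig | None = None, prosthesis=None, *,
                 n_sections: int | None = None,
                 compressible: bool | None = None):
        self.config = (config or build_default_config()).validate()
        self.prosthesis = prosthesis
        self.middle_ear: MiddleEarModel = assemble_middle_ear(
            self.config, prosthesis)

        if prosthesis is None:
            drive_area = self.config.windows.footplate_area_m2
            gap_shunt = None
        else:
            from .prosthesis import annular_gap_element

            prosthesis.validate()
            drive_area = prosthesis.piston_area_m2
            gap = annular_gap_element(prosthesis, self.config.scalae)
            cavity = self.middle_ear.cavity_impedance

            def gap_shunt(f, _gap=gap, _cav=cavity):
                # gap element in series with the tympanic-cavity branch
                return _gap.impedance(f) + _cav(f)

        self.cochlea = CochleaModel(self.config, n_sections=n_sections,
                                    compressible=compressible,
                                    drive_area=drive_area,
                                    gap_shunt=gap_shunt)

    def solve(self, f: float) -> HarmonicSolution:
        """Full coupled harmonic response at one frequency."""
        load = self.cochlea.mechanical_load(f)
        dp = solve_middle_ear(self.middle_ear, load, f)
        sol = self.cochlea.solve(f, velocity=dp.piston_velocity)
        sol.p_ec_inlet = dp.p_ec_inlet
        sol.rocking_velocity = dp.rocking_velocity
        return sol

    def sweep(self, frequencies: Sequence[float] | None = None
              ) -> list[HarmonicSolution]:
        """One independent coupled solution per frequency."""
        if frequencies is None:
            frequencies = self.config.frequency.frequencies()
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.ndim != 1 or freqs.size == 0 or np.any(freqs <= 0):
            raise ValueError("frequency grid must be 1-D and positive")
        return [self.solve(float(f)) for f in freqs]
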