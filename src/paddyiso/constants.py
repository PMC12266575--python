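"""Physical constants and isotopologue conversions.

All delta values are per mil (permil) on the VPDB carbon scale; mole
fractions are ppb unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

#: 13C/12C ratio of the VPDB reference material.
R_VPDB: float = 0.0112372

#: Water-vapor interference polynomial coefficients (wet/dry ratio as a
#: function of analyzer-reported H2O percent), per species.
WATER_POLY = {
    "12CH4": (-0.0099, -0.0003),
    "13CH4": (-5.0344e-5, -0.0003),
}


def delta_to_ratio(delta_permil):
    """13C/12C ratio corresponding to a VPDB delta value."""
    return R_VPDB * (1.0 + np.asarray(delta_permil, dtype=float) / 1000.0)


def ratio_to_delta(ratio):
    """VPDB delta value (permil) corresponding to a 13C/12C ratio."""
    return (np.asarray(ratio, dtype=float) / R_VPDB - 1.0) * 1000.0


def split_isotopologues(total_ppb, delta_permil):
    """Split total CH4 into (12CH4, 13CH4) mole fractions.

    Uses 13CH4 = total * R / (1 + R) with R = R_VPDB * (1 + delta/1000).
    Exact inverse of :func:`combine_isotopologues`.
    """
    r = delta_to_ratio(delta_permil)
    total = np.asarray(total_ppb, dtype=float)
    c13 = total * r / (1.0 + r)
    c12 = total / (1.0 + r)
    return c12, c13


def combine_isotopologues(c12_ppb, c13_ppb):
    """Recombine isotopologue mole fractions into (total CH4, delta13C)."""
    c12 = np.asarray(c12_ppb, dtype=float)
    c13 = np.asarray(c13_ppb, dtype=float)
    return c12 + c13, ratio_to_delta(c13 / c12)
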