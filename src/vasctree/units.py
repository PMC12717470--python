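"""Unit conventions shared by every module.

All quantities carried by a network use one fixed system, chosen to match
the scales of rodent skeletal-muscle microvasculature:

==============  ==========
quantity        unit
==============  ==========
coordinates     mm
segment length  mm
diameter        um
blood flow      nL/s
pressure        mmHg
viscosity       mPa*s (cP)
blood volume    mm^3
==============  ==========

The only places where units are combined across scales are the Poiseuille
resistance and the cylinder volume; both conversions live here so no other
module hard-codes a power of ten.
"""

from __future__ import annotations

import numpy as np

#: mmHg per Pa
MMHG_PER_PA = 1.0 / 133.322387415

#: Pressure-drop prefactor: with mu in mPa*s, L in mm, d in um and Q in nL/s,
#: dP[mmHg] = 128*mu*L*Q/(pi*d^4) * POISEUILLE_MMHG.
POISEUILLE_MMHG = 1.0e6 * MMHG_PER_PA

#: um^2 -> mm^2, for cylinder cross-sections.
UM2_TO_MM2 = 1.0e-6


def poiseuille_resistance(mu_mpas, length_mm, diameter_um):
    """Hydraulic resistance of a cylindrical tube in mmHg/(nL/s)."""
    return (
        128.0 * np.asarray(mu_mpas) * np.asarray(length_mm)
        / (np.pi * np.asarray(diameter_um) ** 4)
        * POISEUILLE_MMHG
    )


def cylinder_volume_mm3(diameter_um, length_mm):
    """Volume of a cylindrical tube in mm^3."""
    d = np.asarray(diameter_um)
    return np.pi * 0.25 * d * d * UM2_TO_MM2 * np.asarray(length_mm)
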