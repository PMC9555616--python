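"""Optical constants shared by the forward simulator and the inverse mBLL."""

from __future__ import annotations

import numpy as np

#: Sampling rate of the emulated instrument (Hz).
FS = 7.8125

#: Source wavelengths (nm).
WAVELENGTHS = (760, 850)

#: Partial volume factor; PPF = DPF * PVF.
PVF = 1.0 / 60.0

#: Molar extinction coefficients in 1/(uM*cm), (HbO, HbR) per wavelength.
#: Values follow the compilation used by the common fNIRS toolchains
#: (Prahl/Cope tabulation, scaled to micromolar units).
EXTINCTION = {
    760: (1.4866e-3, 3.8437e-3),
    850: (2.5264e-3, 1.7986e-3),
}


def dpf(wavelength_nm: float, age_years: float) -> float:
    """General age- and wavelength-dependent differential pathlength factor.

    Polynomial fit over published adult-head DPF measurements::

        DPF = 223.3 + 0.05624*A^0.8493 - 5.723e-7*l^3 + 0.001245*l^2 - 0.9025*l

    with age ``A`` in years and wavelength ``l`` in nm.  Yields ~6.3 at 760 nm
    and ~5.2 at 850 nm for a 30-year-old.
    """
    l = float(wavelength_nm)
    a = float(age_years)
    return 223.3 + 0.05624 * a**0.8493 - 5.723e-7 * l**3 + 0.001245 * l**2 - 0.9025 * l


def pathlength_matrix(age_years: float, distance_cm: float) -> np.ndarray:
    """2x2 forward matrix E mapping (dHbO, dHbR) in uM to OD at (760, 850) nm.

    ``OD(l) = eps_HbO(l)*dHbO*L(l) + eps_HbR(l)*dHbR*L(l)`` with effective
    pathlength ``L(l) = distance_cm * DPF(l, age) * PVF``.
    """
    rows = []
    for wl in WAVELENGTHS:
        L = distance_cm * dpf(wl, age_years) * PVF
        e_hbo, e_hbr = EXTINCTION[wl]
        rows.append([e_hbo * L, e_hbr * L])
    return np.array(rows)
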