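"""Physical constants used throughout the package.

All values derive from :mod:`scipy.constants` (CODATA) rather than
hard-coded truncations, so the Coulomb conversion factor and the
transition-state-theory prefactor carry full double precision.

Unit conventions
----------------
* coordinates: Å
* charges: elementary charge e
* electrostatic potential: kJ·mol⁻¹·e⁻¹
* free energies: kcal/mol externally, kJ/mol internally where noted
* temperature: K
"""

from __future__ import annotations

import math

from scipy import constants as _c

#: Coulomb factor f_C = N_A e² / (4π ε₀), in kJ·mol⁻¹·Å·e⁻².
#: With q in e and r in Å, V = f_C · Σ q_i / r_i is in kJ·mol⁻¹·e⁻¹.
#: Numerically ≈ 1389.3546 kJ·mol⁻¹·Å·e⁻².
COULOMB_KJ_MOL_ANG: float = (
    _c.N_A * _c.e**2 / (4.0 * math.pi * _c.epsilon_0) * 1e10 / 1e3
)

#: kcal ↔ kJ (thermochemical calorie).
KCAL_TO_KJ: float = _c.calorie  # J per cal == kJ per kcal numerically
KJ_TO_KCAL: float = 1.0 / KCAL_TO_KJ

#: Gas constant, kcal·mol⁻¹·K⁻¹ and kJ·mol⁻¹·K⁻¹.
R_KJ_MOL_K: float = _c.R / 1e3
R_KCAL_MOL_K: float = R_KJ_MOL_K * KJ_TO_KCAL

#: Boltzmann and Planck constants (SI), for the Eyring prefactor k_B T / h.
K_B: float = _c.k
PLANCK_H: float = _c.h

#: Default simulation/experiment temperature: 37 °C.
DEFAULT_TEMPERATURE_K: float = 310.0


def eyring_prefactor(temperature: float) -> float:
    """k_B·T/h in s⁻¹ (≈ 6.46×10¹² s⁻¹ at 310 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B * temperature / PLANCK_H
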