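"""Physical constants in monolayer units.

Monolayer work mixes CGS-flavoured conventions: areas in Å²/molecule,
pressures in mN/m, potentials in mV, dipole moments in millidebye.  The two
constants below are the single source of truth for every conversion in the
package.
"""

# k_B * T at 23 °C (296.15 K), expressed in mN/m * Å².
# 1 mN/m * Å² = 1e-3 J/m² * 1e-20 m² = 1e-23 J, and k_B * 296.15 K = 4.089e-21 J.
KT_23C = 408.9

REFERENCE_TEMPERATURE_C = 23.0
_ZERO_C_K = 273.15


def kT(temperature_c: float) -> float:
    """Thermal energy in mN/m * Å² at the given temperature (°C).

    Anchored at 23 °C and scaled linearly with absolute temperature.
    """
    return KT_23C * (temperature_c + _ZERO_C_K) / (REFERENCE_TEMPERATURE_C + _ZERO_C_K)


# Helmholtz (parallel-plate capacitor) conversion of surface potential to the
# apparent normal dipole moment per molecule:
#
#   mu_perp = eps0 * A * delta_psi
#
# In the customary units of the field this collapses to
#
#   mu_perp [mD] = A [Å²] * delta_psi [mV] / (12 * pi)
#
# i.e. one millidebye per millivolt at A = 12*pi = 37.699 Å².
import math

DIPOLE_MD_PER_A2_MV = 1.0 / (12.0 * math.pi)

#: Lift-off anchor/threshold (mN/m): the surface pressure at which a film is
#: considered to have detectably left the gas baseline.  Comparable to the
#: ±0.1 mN/m resolution of a Wilhelmy-type film balance.
LIFTOFF_PRESSURE_THRESHOLD = 0.3
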