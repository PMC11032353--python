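"""Solution-environment quantities for the screened electrostatics.

The relative permittivity is the product of an empirical temperature
polynomial e(T) and a salt-concentration polynomial a(C); the Debye
screening length follows from the ionic strength.  At T = 300 K and
C = 0.15 mol/L the permittivity evaluates to 74.911.
"""

from __future__ import annotations

import math

# SI constants for the Debye length
_KB_J = 1.380649e-23       # J/K
_NA = 6.02214076e23        # 1/mol
_EC = 1.602176634e-19      # C
_EPS0 = 8.8541878128e-12   # C^2/(J m)


def _e_of_t(temperature: float) -> float:
    return 249.4 - 0.788 * temperature + 7.20e-4 * temperature**2


def _a_of_c(molarity: float) -> float:
    return (1.0 - 0.2551 * molarity + 5.151e-2 * molarity**2
            - 6.889e-3 * molarity**3)


def relative_permittivity(temperature: float, salt_molarity: float) -> float:
    """Relative permittivity eps_r(T, C) = e(T) * a(C) of the salt solution.

    Parameters
    ----------
    temperature : K, must lie in (200, 400) where the fit is valid.
    salt_molarity : mol/L, must be >= 0.
    """
    if not 200.0 < temperature < 400.0:
        raise ValueError(f"temperature {temperature} K outside the fit range "
                         "(200, 400) K")
    if salt_molarity < 0:
        raise ValueError("salt molarity must be non-negative")
    return _e_of_t(temperature) * _a_of_c(salt_molarity)


def debye_length(temperature: float, ionic_strength: float,
                 eps_r: float) -> float:
    """Debye screening length in Å.

    lambda_D = sqrt(kB T eps0 eps_r / (2 NA e^2 I)) with the ionic strength
    ``I`` in mol/L.
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive "
                         "(zero would give an infinite screening length)")
    i_si = ionic_strength * 1000.0   # mol/m^3
    lam2 = (_KB_J * temperature * _EPS0 * eps_r) / (2.0 * _NA * _EC**2 * i_si)
    return math.sqrt(lam2) * 1e10
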