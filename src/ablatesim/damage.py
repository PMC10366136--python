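"""Arrhenius thermal-damage kinetics and closed-form helpers.

Irreversible thermal injury is tracked by the dimensionless damage parameter

    Omega(r, t) = ln(C(r,0)/C(r,t)) = A * integral_0^t exp(-Ea/(R T(r,t'))) dt'

where ``C`` is the remaining concentration of undamaged tissue, ``A`` (1/s)
the frequency factor, ``Ea`` (J/mol) the activation energy, ``R`` the gas
constant and ``T`` the absolute temperature.  The thermally damaged fraction
is ``alpha = 1 - exp(-Omega)``; ``Omega = 1`` (alpha = 63%) is the
conventional coagulation threshold.  The Henriques sign convention
exp(-Ea/(R T)) is used: the damage rate increases with temperature.

Also provided: the constant-temperature bath-time design helper (how long a
sample must be held at a bath temperature to accumulate a target Omega) and
the diffusion-theory optical penetration depth used to size the heated
region, ``delta = 1/sqrt(3 mu_a (mu_a + mu_s'))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

GAS_CONSTANT = 8.314  # J/(mol*K)
CELSIUS_TO_KELVIN = 273.15


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius rate-process parameters for thermal damage.

    The defaults used by :func:`ablatesim.scenarios` are Henriques-style
    literature placeholders for liver; A and Ea vary strongly between
    individuals and tissue types and should be supplied per scenario.
    """

    A: float           # frequency factor, 1/s
    E_a: float         # activation energy, J/mol
    R: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.A <= 0 or self.E_a <= 0 or self.R <= 0:
            raise ConfigurationError("A, E_a and R must be positive")

    def rate(self, temperature_c):
        """Damage rate dOmega/dt (1/s) at a temperature in degC."""
        t_k = np.asarray(temperature_c, dtype=np.float64) + CELSIUS_TO_KELVIN
        if np.any(t_k <= 0.0):
            raise DomainError("temperature below absolute zero")
        return self.A * np.exp(-self.E_a / (self.R * t_k))


def arrhenius_increment(omega, temperature_c, dt: float,
                        params: ArrheniusParams):
    """One explicit Euler step of the damage integral.

    ``Omega <- Omega + dt * A * exp(-Ea/(R T_K))`` elementwise, with the
    temperature converted to kelvin inside the exponent.  The caller is
    responsible for masking voxels on which damage is frozen (vaporized
    voxels keep their last Omega).
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    return np.asarray(omega, dtype=np.float64) + dt * params.rate(temperature_c)


def alpha_from_omega(omega):
    """Thermally damaged fraction alpha = 1 - exp(-Omega)."""
    omega = np.asarray(omega, dtype=np.float64)
    if np.any(omega < 0.0):
        raise DomainError("Omega must be non-negative")
    result = -np.expm1(-omega)
    return float(result) if result.ndim == 0 else result


def bath_time_for_omega(t_const_c: float, omega_target: float,
                        params: ArrheniusParams) -> float:
    """Holding time at a constant bath temperature to reach a target Omega.

    Closed-form inverse of the damage integral at constant temperature:
    ``t = Omega_target * exp(Ea/(R T_K)) / A``.  Used to design coagulation
    bath protocols (e.g. equal Omega at 60 and 70 degC requires a longer
    bath at the lower temperature).
    """
    if omega_target <= 0:
        raise DomainError("Omega_target must be positive")
    rate = float(params.rate(t_const_c))
    return omega_target / rate


def penetration_depth(mu_a: float, mu_s_prime: float) -> float:
    """Diffusion-theory optical penetration depth (mm).

    ``delta = 1 / sqrt(3 mu_a (mu_a + mu_s'))`` with both coefficients in
    1/mm.  Undefined for a non-absorbing medium.
    """
    if mu_a <= 0:
        raise DomainError("penetration depth requires mu_a > 0")
    if mu_s_prime < 0:
        raise DomainError("mu_s' must be non-negative")
    return 1.0 / np.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))
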