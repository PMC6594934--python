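"""Oxygen solubility and air-sea gas exchange.

Saturation concentrations follow the Garcia & Gordon (1992) combined
fit to the Benson & Krause data, evaluated at a fixed reference
salinity.  The atmosphere holds about a hundred times the oceanic
oxygen inventory, so its O2 partial pressure is treated as constant:
gas exchange relaxes surface boxes towards saturation without any
back-reaction on the atmosphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Garcia & Gordon (1992) combined fit, Benson & Krause data, umol kg^-1
_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_C0 = -2.75915e-7

#: kg of seawater per litre, converting umol kg^-1 to mmol m^-3
_RHO_KG_PER_L = 1.025

T_MIN, T_MAX = -2.0, 40.0


@dataclass(frozen=True)
class GasExchangeParams:
    """Air-sea exchange settings.

    piston_velocity : m yr^-1, applied uniformly to all surface boxes.
    salinity : psu, fixed reference value for the solubility fit.
    """

    piston_velocity: float = 1000.0
    salinity: float = 35.0

    def __post_init__(self) -> None:
        if self.piston_velocity <= 0:
            raise ValueError("piston velocity must be positive")


def o2_saturation(temperature, salinity: float = 35.0):
    """Equilibrium O2 concentration (mmol m^-3) at temperature (degC).

    Strictly decreasing in temperature over the fit's validity range
    (-2..40 degC); temperatures outside that range raise ValueError.
    Accepts scalars or arrays.
    """
    T = np.asarray(temperature, dtype=float)
    if np.any(T < T_MIN) or np.any(T > T_MAX):
        raise ValueError(
            f"temperature outside solubility fit validity [{T_MIN}, {T_MAX}] degC"
        )
    Ts = np.log((298.15 - T) / (273.15 + T))
    poly_a = sum(a * Ts**i for i, a in enumerate(_A))
    poly_b = sum(b * Ts**i for i, b in enumerate(_B))
    ln_c = poly_a + salinity * poly_b + _C0 * salinity**2
    out = np.exp(ln_c) * _RHO_KG_PER_L
    return float(out) if np.isscalar(temperature) else out


def airsea_flux(
    concentration: float,
    temperature: float,
    area: float,
    params: GasExchangeParams,
    is_surface: bool = True,
):
    """Air-sea O2 flux (mmol yr^-1) into one surface box.

    flux = piston_velocity * area * (saturation - concentration);
    positive into the ocean.  The identical operator is applied to the
    abiotic O2 tracer.
    """
    if not is_surface:
        raise ValueError("gas exchange applies to surface boxes only")
    sat = o2_saturation(temperature, params.salinity)
    return params.piston_velocity * area * (sat - concentration)
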