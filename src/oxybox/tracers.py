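"""Diagnostic tracer bookkeeping: preformed PO4, TOU, AOU, abiotic O2.

Preformed PO4 is reset to the model's PO4 in surface boxes at every
time step and transported passively elsewhere; regenerated PO4 (total
minus preformed) therefore measures nutrient added by interior
remineralisation.  True oxygen utilisation (TOU) is its stoichiometric
oxygen equivalent, r_o2p * regenerated PO4 -- an exact respiratory
oxygen deficit, free of the surface-disequilibrium bias of apparent
oxygen utilisation (AOU = saturation - O2), which is provided for
comparison only.
"""

from __future__ import annotations

import numpy as np

from .airsea import o2_saturation
from .geometry import BoxGeometry
from .stoichiometry import StoichiometryParams
from .units import mmol_to_pmol


def regenerated_po4(po4: np.ndarray, preformed_po4: np.ndarray) -> np.ndarray:
    """Regenerated PO4 (mmol m^-3) = total - preformed."""
    return np.asarray(po4) - np.asarray(preformed_po4)


def tou(
    po4: np.ndarray,
    preformed_po4: np.ndarray,
    stoich: StoichiometryParams,
) -> np.ndarray:
    """Per-box TOU (mmol O2 m^-3) = r_o2p * regenerated PO4."""
    return stoich.r_o2p * regenerated_po4(po4, preformed_po4)


def aou(
    o2: np.ndarray, temperature: np.ndarray, salinity: float = 35.0
) -> np.ndarray:
    """Apparent oxygen utilisation (mmol m^-3): saturation(T) - O2."""
    return o2_saturation(temperature, salinity) - np.asarray(o2)


def global_inventory_pmol(conc: np.ndarray, geom: BoxGeometry) -> float:
    """Volume integral of a concentration field (mmol m^-3) in Pmol."""
    return mmol_to_pmol(float(np.dot(np.asarray(conc), geom.volumes)))


def update_preformed_po4(
    po4: np.ndarray, preformed_po4: np.ndarray, geom: BoxGeometry
) -> np.ndarray:
    """Reset preformed PO4 to PO4 in surface boxes (call once per step,
    after transport, biology and gas exchange)."""
    out = np.array(preformed_po4, dtype=float, copy=True)
    surf = geom.surface_indices()
    out[surf] = np.asarray(po4)[surf]
    return out
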