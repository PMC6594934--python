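"""Net community production, export and remineralisation pathways.

Biomass is not prognostic: surface production follows an
implicit-biomass closure, mu_max * Monod(nutrients) * biomass proxy,
which makes nutrient drawdown rates analyzable while omitting the
plankton state variables that the inventory-level mechanism does not
need.  Two producer classes are represented:

* ordinary phytoplankton, limited by the scarcer of NO3 and PO4
  (Liebig minimum of Monod factors);
* diazotrophs, limited by PO4 only, never by fixed nitrogen, with a
  maximum growth rate below half that of ordinary phytoplankton and a
  hard temperature cutoff: zero growth below 15 degC.  The cold
  Southern Ocean surface therefore hosts no nitrogen fixation, which
  is what lets subducted nitrate deficits escape the fixation feedback.

Exported organic matter is remineralised in interior boxes: aerobically
(consuming O2 at 169.6 per P) while oxygen above the suboxic threshold
is available, by denitrification (consuming NO3, no O2) below it, and
not at all once nitrate too is exhausted -- the unremineralised
remainder is passed downstream and, as a last resort, returned to the
nutrient pools without oxidant demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import BoxGeometry, DEEP, LOWLAT, NORTH, OMZ, SOUTHERN
from .stoichiometry import StoichiometryParams, nstar

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RemineralizationResult:
    """Pathway split of one remineralisation event (rates in mmol P yr^-1
    unless noted)."""

    d_o2: float  # mmol O2 yr^-1 (negative = consumption)
    d_no3: float  # mmol NO3 yr^-1 (net)
    d_po4: float  # mmol PO4 yr^-1
    aerobic_p: float
    denitrified_p: float
    remainder_p: float

    @property
    def denitrified_fraction(self) -> float:
        tot = self.aerobic_p + self.denitrified_p + self.remainder_p
        return self.denitrified_p / tot if tot > 0 else 0.0


def default_partition() -> dict:
    """Routing of exported organic matter to interior boxes.

    Low-latitude export feeds mostly the thermocline/OMZ box; the
    high-latitude surface boxes export straight into the deep box.
    """
    return {
        LOWLAT: {OMZ: 0.75, DEEP: 0.25},
        SOUTHERN: {DEEP: 1.0},
        NORTH: {DEEP: 1.0},
    }


def default_production_scale() -> dict:
    """Per-box scaling of the implicit-biomass production rate.

    Mimics light/iron limitation outside the low latitudes; the small
    Southern Ocean value leaves most upwelled nutrients unused there
    (an HNLC surface), which is essential for the loophole pathway.
    """
    return {LOWLAT: 1.0, SOUTHERN: 0.15, NORTH: 0.5}


@dataclass(frozen=True)
class EcosystemParams:
    """Producer and remineralisation parameters.

    mu_max_phy, mu_max_diaz : yr^-1, maximum specific rates; the
        diazotroph value must stay below half the ordinary one.
    k_no3, k_po4 : mmol m^-3, Monod half-saturations.
    diaz_t_min : degC, hard diazotroph temperature cutoff (15).
    biomass_proxy : mmol P m^-3, implicit standing stock multiplying
        the specific rates.
    export_fraction : fraction of production exported below the surface
        box; the remainder is recycled in place.
    partition : per surface box, fractions routing export to interior
        boxes (each row sums to 1).
    production_scale : per-surface-box multiplier on production.
    shallowing_sensitivity : (degC^-1) optional warming-driven shift of
        low-latitude export towards the thermocline box, default off.
    compensating_restore_rate : yr^-1, rate of the counterfactual
        instantaneous-compensation fixation: in every surface box an
        additional diazotroph term fixes (and nitrifies in place) just
        enough nitrogen to relax any N* deficit relative to a reference
        state, regardless of temperature -- closing the cold-surface
        loophole.  Zero (off) by default.
    compensation_reference_nstar : per-surface-box N* values (mmol m^-3)
        the restoring term relaxes towards, normally taken from the
        preindustrial steady state.
    """

    mu_max_phy: float = 6.0
    mu_max_diaz: float = 0.4
    k_no3: float = 1.6
    k_po4: float = 0.1
    diaz_t_min: float = 15.0
    biomass_proxy: float = 0.15
    export_fraction: float = 0.9
    partition: dict = field(default_factory=default_partition)
    production_scale: dict = field(default_factory=default_production_scale)
    shallowing_sensitivity: float = 0.0
    compensating_restore_rate: float = 0.0
    compensation_reference_nstar: dict | None = None

    def __post_init__(self) -> None:
        if not (0 < self.mu_max_diaz < 0.5 * self.mu_max_phy):
            raise ValueError(
                "diazotroph maximum growth rate must be positive and below "
                "half that of ordinary phytoplankton"
            )
        if self.k_no3 <= 0 or self.k_po4 <= 0:
            raise ValueError("half-saturations must be positive")
        if not (0 < self.export_fraction <= 1):
            raise ValueError("export fraction must be in (0, 1]")
        for box, row in self.partition.items():
            s = sum(row.values())
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"partition fractions for {box} sum to {s}, not 1")


def make_compensating_ecosystem(
    reference_nstar: dict,
    base: EcosystemParams | None = None,
    restore_rate: float = 2.0,
) -> EcosystemParams:
    """Counterfactual ecosystem with instantaneously compensating
    nitrogen fixation.

    The standard producers are left untouched; on top of them a fast
    restoring fixation (with in-place nitrification) acts in every box,
    warm or cold, surface or interior, topping nitrate up whenever the
    local N* drops below the given reference (its preindustrial value).
    Extending the compensation to interior boxes is deliberately
    unphysical -- it is the thought experiment in which nitrate is
    "topped up when scarce relative to phosphate" with no lag and no
    cold-water loophole, so denitrification-derived deficits can
    accumulate nowhere.  Each mole of N restored debits the local
    oxygen pool by the nitrate-loss O2 equivalent, the exact mirror of
    the source realised per mole NO3 lost.
    """
    from dataclasses import replace

    base = base or EcosystemParams()
    return replace(
        base,
        compensating_restore_rate=restore_rate,
        compensation_reference_nstar=dict(reference_nstar),
    )


def reference_nstar_from_state(state, geom: BoxGeometry) -> dict:
    """Per-box N* of a (spun-up) state, keyed by box label."""
    return {
        geom.labels[i]: float(nstar(state.no3[i], state.po4[i]))
        for i in range(geom.n_boxes)
    }


def ordinary_production(
    no3: float, po4: float, temperature: float, params: EcosystemParams,
    scale: float = 1.0,
) -> float:
    """Specific ordinary production (mmol P m^-3 yr^-1).

    Liebig minimum of the NO3 and PO4 Monod terms; zero when either
    nutrient is exhausted.  Multiply by box volume for mmol P yr^-1.
    """
    no3 = max(float(no3), 0.0)
    po4 = max(float(po4), 0.0)
    lim = min(no3 / (params.k_no3 + no3), po4 / (params.k_po4 + po4))
    return params.mu_max_phy * params.biomass_proxy * scale * lim


def diazotroph_production(
    po4: float, temperature: float, params: EcosystemParams,
    scale: float = 1.0,
) -> float:
    """Specific diazotroph production (mmol P m^-3 yr^-1).

    Phosphate-limited only, never nitrogen-limited; identically zero
    below the temperature cutoff (hard step, not a ramp).
    """
    if temperature < params.diaz_t_min:
        return 0.0
    po4 = max(float(po4), 0.0)
    return (
        params.mu_max_diaz
        * params.biomass_proxy
        * scale
        * po4
        / (params.k_po4 + po4)
    )


def remineralize(
    org_p_flux: float,
    o2: float,
    no3: float,
    stoich: StoichiometryParams,
    o2_capacity: float = np.inf,
    no3_capacity: float = np.inf,
) -> RemineralizationResult:
    """Split an organic-P flux (mmol P yr^-1) into remineralisation
    pathways and return the implied tracer tendencies.

    The pathway rule: aerobic while O2 is at or above the suboxic
    threshold (ties break aerobic); denitrification below it while NO3
    lasts; otherwise remineralisation stops and the remainder is
    reported.

    ``o2_capacity`` / ``no3_capacity`` (mmol yr^-1) bound how much
    oxidant each pathway may draw; the time stepper uses them to
    resolve sub-box suboxia (the part of the flux that would push O2
    below the threshold within a step is denitrified instead).  With
    the default infinite capacities the rule is the plain threshold
    switch.
    """
    if org_p_flux < 0:
        raise ValueError("organic phosphorus flux must be >= 0")
    if org_p_flux == 0:
        return RemineralizationResult(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    aerobic_p = 0.0
    denit_p = 0.0
    if o2 >= stoich.o2_threshold:
        aerobic_p = min(org_p_flux, o2_capacity / stoich.r_o2p)
    if no3 > 0.0:
        denit_p = min(
            org_p_flux - aerobic_p,
            no3_capacity / (stoich.r_no3p - stoich.r_np),
        )
    remainder = org_p_flux - aerobic_p - denit_p

    d_o2 = -stoich.r_o2p * aerobic_p
    d_no3 = (
        stoich.r_np * aerobic_p
        + stoich.net_no3_change_denitrification() * denit_p
    )
    d_po4 = aerobic_p + denit_p
    return RemineralizationResult(
        d_o2, d_no3, d_po4, aerobic_p, denit_p, remainder
    )


def ncp(
    no3: np.ndarray,
    po4: np.ndarray,
    temperature: np.ndarray,
    geom: BoxGeometry,
    params: EcosystemParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Production per surface box (mmol P yr^-1).

    Returns (ordinary, diazotroph) arrays over all boxes (zero for
    interior boxes).  Export equals export_fraction times their sum;
    uptake removes NO3 and PO4 at Redfield ratios, except that
    diazotrophs draw no NO3 -- their nitrogen enters the organic pool
    from N2.
    """
    n = geom.n_boxes
    p_ord = np.zeros(n)
    p_diaz = np.zeros(n)
    for i in geom.surface_indices():
        scale = params.production_scale.get(geom.labels[i], 1.0)
        v = geom.volumes[i]
        p_ord[i] = ordinary_production(
            no3[i], po4[i], temperature[i], params, scale
        ) * v
        p_diaz[i] = diazotroph_production(
            po4[i], temperature[i], params, scale
        ) * v
    return p_ord, p_diaz
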