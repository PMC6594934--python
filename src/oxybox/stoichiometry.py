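"""Fixed elemental ratios of the remineralisation chemistry and the
oxidant-accounting conversions derived from them.

The model assumes a single organic-matter composition with molar
C:N:P:-O2 = 112:16:1:169.6.  Aerobic remineralisation consumes 169.6 mol
O2 per mol organic P (nitrification of the organic N back to nitrate
included).  Where dissolved oxygen is below a suboxic threshold,
nitrate is used as the electron acceptor instead (denitrification),
drawing down 119.68 mol NO3 per mol organic P while consuming no
oxygen.  Because each mole of NO3 spent in denitrification spares
r_o2p / r_no3p ~ 1.42 mol of O2, a net loss of fixed nitrogen is an
implicit source of oxygen to the ocean, and newly fixed nitrogen is the
corresponding sink.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StoichiometryParams:
    """Molar ratios of organic matter production and degradation.

    Attributes
    ----------
    r_cp : float
        mol C per mol P in organic matter (default 112).
    r_np : float
        mol N per mol P in organic matter (default 16).
    r_o2p : float
        mol O2 consumed per mol P in aerobic remineralisation (169.6).
    r_no3p : float
        mol NO3 drawn down per mol P remineralised by denitrification
        (119.68).  The organic N itself is returned to the fixed pool,
        so the net fixed-N removal per mol P is ``r_no3p - r_np``.
    o2_threshold : float
        Dissolved O2 concentration (mmol m^-3) below which
        remineralisation switches to denitrification (5.0).
    """

    r_cp: float = 112.0
    r_np: float = 16.0
    r_o2p: float = 169.6
    r_no3p: float = 119.68
    o2_threshold: float = 5.0

    def __post_init__(self) -> None:
        for name in ("r_cp", "r_np", "r_o2p", "r_no3p", "o2_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.r_o2p / self.r_no3p <= 1.0:
            raise ValueError(
                "r_o2p/r_no3p must exceed 1: each mole of NO3 spent in "
                "denitrification must spare more than one mole of O2"
            )
        if self.r_no3p <= self.r_np:
            raise ValueError("r_no3p must exceed r_np")

    # -- oxidant accounting -------------------------------------------------

    def o2_demand_per_orgN(self) -> float:
        """Mol O2 consumed by aerobic remineralisation per mol organic N."""
        return self.r_o2p / self.r_np

    def no3_demand_per_orgN(self) -> float:
        """Mol NO3 drawn down by denitrification per mol organic N."""
        return self.r_no3p / self.r_np

    def o2_per_no3_lost(self) -> float:
        """Mol O2 gained per mol NO3 lost from the fixed-N inventory."""
        return self.r_o2p / self.r_no3p

    def o2_equivalent_of_nitrate_loss(self, delta_no3: float) -> float:
        """Oxygen equivalent of a fixed-N inventory decrease.

        Parameters
        ----------
        delta_no3 : float
            NO3 inventory decrease (any amount unit; negative values
            denote an inventory gain).

        Returns
        -------
        float
            O2 gain in the same amount unit; odd and linear in the input.
        """
        return delta_no3 * self.o2_per_no3_lost()

    # -- production O2 credits ---------------------------------------------

    def o2_yield_ordinary_production(self) -> float:
        """Mol O2 released per mol P of nitrate-fuelled production.

        Photosynthesis is the exact reverse of aerobic remineralisation,
        so the credit equals ``r_o2p``.
        """
        return self.r_o2p

    def o2_yield_diazotroph_production(self) -> float:
        """Mol O2 released per mol P of diazotroph production.

        Newly fixed nitrogen carries an oxidant debt of
        ``o2_per_no3_lost`` per mol N (the oxygen that its eventual
        oxidation to nitrate will claim from the ocean), charged at the
        point of entry.  This makes nitrogen fixation an oceanic O2 sink
        of exactly the same magnitude per mole N as the source realised
        per mole NO3 lost to denitrification.
        """
        return self.r_o2p - self.r_np * self.o2_per_no3_lost()

    def net_no3_change_denitrification(self) -> float:
        """Net NO3 change per mol P denitrified (negative).

        Gross acceptor drawdown is ``-r_no3p``; the organic N (+r_np)
        is returned to the fixed pool.
        """
        return -(self.r_no3p - self.r_np)


def nstar(no3: float, po4: float) -> float:
    """Nitrate excess N* = NO3 - 16 PO4 (mmol m^-3).

    Negative values mark waters carrying a denitrification-derived
    fixed-nitrogen deficit relative to Redfield-balanced water.
    Accepts scalars or numpy arrays.
    """
    return no3 - 16.0 * po4


# module-level functional aliases mirroring the operation names


def o2_demand_per_orgN(stoich: StoichiometryParams) -> float:
    return stoich.o2_demand_per_orgN()


def no3_demand_per_orgN(stoich: StoichiometryParams) -> float:
    return stoich.no3_demand_per_orgN()


def o2_per_no3_lost(stoich: StoichiometryParams) -> float:
    return stoich.o2_per_no3_lost()


def o2_equivalent_of_nitrate_loss(
    delta_no3: float, stoich: StoichiometryParams
) -> float:
    return stoich.o2_equivalent_of_nitrate_loss(delta_no3)
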