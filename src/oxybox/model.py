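"""State container, time stepping and spin-up.

Time integration is fixed-step forward Euler with operator splitting in
a fixed order -- transport, biology, gas exchange, preformed-PO4 reset
-- so that the tracer identities (phosphorus conservation, the
fixed-nitrogen ledger, the oxygen-budget closure) hold step by step to
rounding.  Aerobic remineralisation within a step is capacity-limited:
it may draw a box's oxygen down to the suboxic threshold but not past
it, and the excess demand is denitrified (or, with nitrate exhausted,
left unremineralised).  The denitrified share of a box's
remineralisation is the model's sub-box suboxic fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .airsea import GasExchangeParams, o2_saturation
from .circulation import CirculationScheme
from .ecosystem import EcosystemParams, ncp, remineralize
from .geometry import BoxGeometry, DEEP, LOWLAT, NORTH, OMZ, SOUTHERN, default_geometry
from .scenario import ScenarioForcing, make_control_scenario
from .stoichiometry import StoichiometryParams
from .tracers import global_inventory_pmol, tou, update_preformed_po4
from .units import MMOL_PER_MOL, mmol_to_pmol

logger = logging.getLogger(__name__)

TRACER_NAMES = ("o2", "no3", "po4", "preformed_po4", "abiotic_o2", "age")


def default_base_temperature() -> dict:
    """Preindustrial box temperatures (degC)."""
    return {LOWLAT: 22.0, SOUTHERN: 4.0, NORTH: 6.0, OMZ: 10.0, DEEP: 2.0}


def default_downstream() -> dict:
    """Where unremineralised organic matter is passed next."""
    return {OMZ: DEEP}


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to integrate the model."""

    geometry: BoxGeometry = field(default_factory=default_geometry)
    circulation: CirculationScheme = field(default_factory=CirculationScheme)
    stoichiometry: StoichiometryParams = field(default_factory=StoichiometryParams)
    ecosystem: EcosystemParams = field(default_factory=EcosystemParams)
    gas_exchange: GasExchangeParams = field(default_factory=GasExchangeParams)
    base_temperature: dict = field(default_factory=default_base_temperature)
    downstream: dict = field(default_factory=default_downstream)
    dt: float = 0.05  # yr
    output_interval: float = 1.0  # yr
    spinup_tol: float = 1.0e-8  # yr^-1, max relative tendency
    spinup_max_years: float = 60000.0
    spinup_check_interval: float = 100.0  # yr
    biology_enabled: bool = True
    diazotrophs_enabled: bool = True
    denitrification_enabled: bool = True
    remainder_warn_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > 0.05 + 1e-12:
            raise ValueError("dt must not exceed 0.05 yr")
        self.circulation.validate(self.geometry)
        for lab in self.geometry.labels:
            if lab not in self.base_temperature:
                raise ValueError(f"base temperature missing for box {lab}")

    def base_temperature_array(self) -> np.ndarray:
        return np.array(
            [self.base_temperature[lab] for lab in self.geometry.labels]
        )


@dataclass
class OceanState:
    """Per-box tracer concentrations (mmol m^-3), ideal age (yr),
    temperature (degC) and model time (yr)."""

    o2: np.ndarray
    no3: np.ndarray
    po4: np.ndarray
    preformed_po4: np.ndarray
    abiotic_o2: np.ndarray
    age: np.ndarray
    temperature: np.ndarray
    time: float = 0.0
    suboxic_fraction: np.ndarray | None = None

    def copy(self) -> "OceanState":
        return OceanState(
            o2=self.o2.copy(), no3=self.no3.copy(), po4=self.po4.copy(),
            preformed_po4=self.preformed_po4.copy(),
            abiotic_o2=self.abiotic_o2.copy(), age=self.age.copy(),
            temperature=self.temperature.copy(), time=self.time,
            suboxic_fraction=None if self.suboxic_fraction is None
            else self.suboxic_fraction.copy(),
        )

    def tracer_matrix(self) -> np.ndarray:
        return np.vstack(
            [self.o2, self.no3, self.po4, self.preformed_po4,
             self.abiotic_o2, self.age]
        )

    @classmethod
    def from_tracer_matrix(
        cls, Y: np.ndarray, temperature: np.ndarray, time: float,
        suboxic_fraction: np.ndarray | None = None,
    ) -> "OceanState":
        return cls(
            o2=Y[0], no3=Y[1], po4=Y[2], preformed_po4=Y[3],
            abiotic_o2=Y[4], age=Y[5], temperature=temperature, time=time,
            suboxic_fraction=suboxic_fraction,
        )

    def to_frame(self, geom: BoxGeometry) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(geom.labels):
            rows.append({
                "box": lab,
                "o2_mmol_m3": self.o2[i],
                "no3_mmol_m3": self.no3[i],
                "po4_mmol_m3": self.po4[i],
                "preformed_po4_mmol_m3": self.preformed_po4[i],
                "abiotic_o2_mmol_m3": self.abiotic_o2[i],
                "ideal_age_yr": self.age[i],
                "temperature_degC": self.temperature[i],
            })
        df = pd.DataFrame(rows)
        df.attrs["time_yr"] = self.time
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time: float = 0.0) -> "OceanState":
        return cls(
            o2=df["o2_mmol_m3"].to_numpy(dtype=float),
            no3=df["no3_mmol_m3"].to_numpy(dtype=float),
            po4=df["po4_mmol_m3"].to_numpy(dtype=float),
            preformed_po4=df["preformed_po4_mmol_m3"].to_numpy(dtype=float),
            abiotic_o2=df["abiotic_o2_mmol_m3"].to_numpy(dtype=float),
            age=df["ideal_age_yr"].to_numpy(dtype=float),
            temperature=df["temperature_degC"].to_numpy(dtype=float),
            time=time,
        )


def initial_state(config: ModelConfig) -> OceanState:
    """Rough preindustrial first guess used to start the spin-up."""
    geom = config.geometry
    T = config.base_temperature_array()
    sat = o2_saturation(T, config.gas_exchange.salinity)
    n = geom.n_boxes
    state = OceanState(
        o2=sat.copy(),
        no3=np.full(n, 30.0),
        po4=np.full(n, 2.1),
        preformed_po4=np.full(n, 2.1),
        abiotic_o2=sat.copy(),
        age=np.zeros(n),
        temperature=T.copy(),
        time=0.0,
    )
    surf = geom.surface_indices()
    state.no3[surf] = 4.0
    state.po4[surf] = 0.4
    state.preformed_po4[surf] = 0.4
    return state


@dataclass
class FluxIntegrals:
    """Cumulative diagnostic fluxes (mmol) accumulated by the stepper."""

    airsea_o2: float = 0.0
    airsea_abiotic: float = 0.0
    fixation_n: float = 0.0
    denitrification_n: float = 0.0
    denitrified_p: float = 0.0
    aerobic_p: float = 0.0
    remainder_p: float = 0.0
    ncp_p: float = 0.0
    clipped_events: int = 0

    def copy(self) -> "FluxIntegrals":
        return replace(self)


class Model:
    """Precompiled stepper bound to one configuration."""

    def __init__(self, config: ModelConfig):
        self.config = config
        geom = config.geometry
        self.geom = geom
        self.A_psi, self.A_mix = config.circulation.tendency_matrices(geom)
        self.V = np.asarray(geom.volumes, dtype=float)
        self.surf = geom.surface_indices()
        self.interior = geom.interior_indices()
        self.areas = np.asarray(geom.surface_areas, dtype=float)[self.surf]
        self.T0 = config.base_temperature_array()
        self.stoich = config.stoichiometry
        # export routing matrix R[target, source_surface]
        eco = config.ecosystem
        n = geom.n_boxes
        self.route = np.zeros((n, n))
        if config.biology_enabled:
            for lab, row in eco.partition.items():
                j = geom.index(lab)
                for dst, frac in row.items():
                    self.route[geom.index(dst), j] = frac
        self.downstream_idx = {
            geom.index(a): geom.index(b) for a, b in config.downstream.items()
        }
        self.prod_scale = np.zeros(n)
        for i in self.surf:
            self.prod_scale[i] = eco.production_scale.get(geom.labels[i], 1.0)

    # -- single step --------------------------------------------------------

    def step(
        self,
        Y: np.ndarray,
        t: float,
        anom: np.ndarray,
        s_factor: float,
        flux: FluxIntegrals,
        rates_out: dict | None = None,
    ) -> np.ndarray:
        """Advance the tracer matrix Y (6, n) by one dt.  Mutates Y in
        place, accumulates flux integrals, returns the per-box suboxic
        fraction of this step."""
        cfg = self.config
        dt = cfg.dt
        stoich = self.stoich
        eco = cfg.ecosystem
        V = self.V
        n = self.geom.n_boxes
        T = self.T0 + anom

        # 1. transport (conservative linear operator)
        A = self.A_mix + s_factor * self.A_psi
        Y += dt * (Y @ A.T)

        # 2. ideal age: interior aging, surface reset
        Y[5] += dt
        Y[5, self.surf] = 0.0

        suboxic = np.zeros(n)
        p_den_step = np.zeros(n)
        p_aer_step = np.zeros(n)
        p_rem_step = np.zeros(n)

        # 3. biology
        if cfg.biology_enabled:
            o2, no3, po4 = Y[0], Y[1], Y[2]
            p_ord, p_diaz = ncp(no3, po4, T, self.geom, eco)
            if not cfg.diazotrophs_enabled:
                p_diaz[:] = 0.0

            # capacity limits: nutrient drawdown within the step
            for i in self.surf:
                cap_no3 = 0.9 * max(no3[i], 0.0) * V[i] / dt
                if stoich.r_np * p_ord[i] > cap_no3:
                    p_ord[i] = cap_no3 / stoich.r_np
                cap_po4 = 0.9 * max(po4[i], 0.0) * V[i] / dt
                tot = p_ord[i] + p_diaz[i]
                if tot > cap_po4 and tot > 0:
                    f = cap_po4 / tot
                    p_ord[i] *= f
                    p_diaz[i] *= f

            # uptake and photosynthetic O2 credit
            c_ord = stoich.o2_yield_ordinary_production()
            c_diaz = stoich.o2_yield_diazotroph_production()
            Y[2] -= dt * (p_ord + p_diaz) / V
            Y[1] -= dt * stoich.r_np * p_ord / V
            Y[0] += dt * (c_ord * p_ord + c_diaz * p_diaz) / V

            flux.fixation_n += dt * stoich.r_np * float(p_diaz.sum())

            # export routing: recycled share remineralises in place
            total_prod = p_ord + p_diaz
            export = eco.export_fraction * total_prod
            route = self.route
            if eco.shallowing_sensitivity > 0.0:
                route = self._shallowed_route(anom)
            org_in = route @ export + (total_prod - export)
            flux.ncp_p += dt * float(export.sum())

            # remineralisation with downstream pass-through of remainders
            order = list(self.surf) + list(self.interior)
            carried = np.zeros(n)
            for i in order:
                demand = org_in[i] + carried[i]
                if demand <= 0.0:
                    suboxic[i] = 1.0 if Y[0, i] < stoich.o2_threshold else 0.0
                    continue
                o2_cap = max(Y[0, i] - stoich.o2_threshold, 0.0) * V[i] / dt
                no3_cap = (
                    0.95 * max(Y[1, i], 0.0) * V[i] / dt
                    if cfg.denitrification_enabled else 0.0
                )
                res = remineralize(
                    demand, Y[0, i], Y[1, i], stoich,
                    o2_capacity=o2_cap, no3_capacity=no3_cap,
                )
                Y[0, i] += dt * res.d_o2 / V[i]
                Y[1, i] += dt * res.d_no3 / V[i]
                Y[2, i] += dt * res.d_po4 / V[i]
                p_aer_step[i] += res.aerobic_p
                p_den_step[i] += res.denitrified_p
                rem = res.remainder_p
                if rem > 0.0:
                    j = self.downstream_idx.get(i)
                    if j is not None and j not in order[: order.index(i) + 1]:
                        carried[j] += rem
                    else:
                        # final resting place: return nutrients without
                        # oxidant demand
                        Y[1, i] += dt * stoich.r_np * rem / V[i]
                        Y[2, i] += dt * rem / V[i]
                        p_rem_step[i] += rem
                tot_i = res.aerobic_p + res.denitrified_p + res.remainder_p
                if tot_i > 0:
                    suboxic[i] = (res.denitrified_p + res.remainder_p) / tot_i

            # counterfactual instantaneous-compensation fixation:
            # restoring diazotrophy with in-place nitrification, so the
            # only net effect per mol P is +r_np NO3 and the oxidant
            # debt of the newly fixed N
            if (
                eco.compensating_restore_rate > 0.0
                and eco.compensation_reference_nstar is not None
            ):
                c_gap = c_diaz - stoich.r_o2p  # = -r_np * o2_per_no3_lost
                for i in range(n):
                    ref = eco.compensation_reference_nstar.get(
                        self.geom.labels[i]
                    )
                    if ref is None:
                        continue
                    deficit = ref - (Y[1, i] - 16.0 * Y[2, i])
                    if deficit <= 0.0:
                        continue
                    n_rate = (
                        eco.compensating_restore_rate * deficit * V[i]
                    )  # mmol N / yr
                    # the oxidant debit may not exhaust local O2
                    o2_cap = 0.9 * max(Y[0, i], 0.0) * V[i] / dt
                    n_rate = min(n_rate, o2_cap / stoich.o2_per_no3_lost())
                    p_comp = n_rate / stoich.r_np
                    Y[1, i] += dt * n_rate / V[i]
                    Y[0, i] += dt * c_gap * p_comp / V[i]
                    flux.fixation_n += dt * n_rate
                    p_aer_step[i] += p_comp

            flux.aerobic_p += dt * float(p_aer_step.sum())
            flux.denitrified_p += dt * float(p_den_step.sum())
            flux.remainder_p += dt * float(p_rem_step.sum())
            flux.denitrification_n += (
                dt * stoich.r_no3p * float(p_den_step.sum())
            )
        else:
            suboxic = (Y[0] < stoich.o2_threshold).astype(float)

        # 4. gas exchange (same operator for O2 and abiotic O2)
        sat = o2_saturation(T[self.surf], cfg.gas_exchange.salinity)
        k = cfg.gas_exchange.piston_velocity
        f_o2 = k * self.areas * (sat - Y[0, self.surf])  # mmol/yr
        f_ab = k * self.areas * (sat - Y[4, self.surf])
        Y[0, self.surf] += dt * f_o2 / V[self.surf]
        Y[4, self.surf] += dt * f_ab / V[self.surf]
        flux.airsea_o2 += dt * float(f_o2.sum())
        flux.airsea_abiotic += dt * float(f_ab.sum())

        # 5. preformed PO4 reset in surface boxes
        Y[3, self.surf] = Y[2, self.surf]

        # non-negativity guard (integrator undershoot only)
        conc = Y[:5]
        neg = conc < 0.0
        if np.any(neg):
            worst = float(conc[neg].min())
            if worst < -1e-6:
                logger.warning(
                    "clipped negative concentration %.3e at t=%.2f", worst, t
                )
            flux.clipped_events += int(neg.sum())
            conc[neg] = 0.0

        if not np.all(np.isfinite(Y)):
            raise RuntimeError(
                f"non-finite tracer value at t={t:.2f}: {Y!r}"
            )

        if rates_out is not None:
            rates_out["p_den"] = p_den_step
            rates_out["p_aer"] = p_aer_step
            rates_out["p_rem"] = p_rem_step
        return suboxic

    def _shallowed_route(self, anom: np.ndarray) -> np.ndarray:
        """Warming-driven shift of low-latitude export towards the
        thermocline box (single-parameter shallowing, default off)."""
        route = self.route.copy()
        eco = self.config.ecosystem
        geom = self.geom
        try:
            j = geom.index(LOWLAT)
            i_omz, i_deep = geom.index(OMZ), geom.index(DEEP)
        except ValueError:
            return route
        shift = min(
            eco.shallowing_sensitivity * max(anom[j], 0.0),
            route[i_deep, j],
        )
        route[i_deep, j] -= shift
        route[i_omz, j] += shift
        return route


# -- run loop ---------------------------------------------------------------


@dataclass
class RunResult:
    """Output of one integration: interval diagnostics plus final state."""

    frame: pd.DataFrame
    final_state: OceanState
    config: ModelConfig
    flux: FluxIntegrals


def _diag_row(
    t: float, Y: np.ndarray, T: np.ndarray, suboxic: np.ndarray,
    flux: FluxIntegrals, model: Model, interval_flux: dict,
) -> dict:
    geom = model.geom
    stoich = model.stoich
    row = {"time_yr": t}
    inv = {
        "o2_inventory_pmol": global_inventory_pmol(Y[0], geom),
        "no3_inventory_pmol": global_inventory_pmol(Y[1], geom),
        "po4_inventory_pmol": global_inventory_pmol(Y[2], geom),
        "abiotic_o2_inventory_pmol": global_inventory_pmol(Y[4], geom),
        "tou_inventory_pmol": global_inventory_pmol(
            tou(Y[2], Y[3], stoich), geom
        ),
    }
    row.update(inv)
    row["cum_airsea_o2_pmol"] = mmol_to_pmol(flux.airsea_o2)
    row["cum_airsea_abiotic_pmol"] = mmol_to_pmol(flux.airsea_abiotic)
    row["cum_fixation_n_pmol"] = mmol_to_pmol(flux.fixation_n)
    row["cum_denitrification_n_pmol"] = mmol_to_pmol(flux.denitrification_n)
    row["cum_ncp_p_pmol"] = mmol_to_pmol(flux.ncp_p)
    row["cum_remainder_p_pmol"] = mmol_to_pmol(flux.remainder_p)
    row["suboxic_volume_m3"] = float(np.dot(suboxic, geom.volumes))
    for key, val in interval_flux.items():
        row[key] = val
    for i, lab in enumerate(geom.labels):
        row[f"o2_{lab}"] = Y[0, i]
        row[f"no3_{lab}"] = Y[1, i]
        row[f"po4_{lab}"] = Y[2, i]
        row[f"preformed_po4_{lab}"] = Y[3, i]
        row[f"abiotic_o2_{lab}"] = Y[4, i]
        row[f"age_{lab}"] = Y[5, i]
        row[f"temp_{lab}"] = T[i]
        row[f"suboxic_fraction_{lab}"] = suboxic[i]
    return row


def run(
    config: ModelConfig,
    state: OceanState,
    forcing: ScenarioForcing,
    progress: bool = False,
) -> RunResult:
    """Integrate from the forcing's first to last year.

    Diagnostics are recorded every ``config.output_interval`` years;
    rate columns (``*_molyr``) are means over the preceding interval.
    """
    model = Model(config)
    geom = config.geometry
    Y = state.tracer_matrix().astype(float).copy()
    flux = FluxIntegrals()
    sample = forcing.interpolators()

    t0, t1 = float(forcing.time[0]), float(forcing.time[-1])
    dt = config.dt
    n_steps = int(round((t1 - t0) / dt))
    out_every = max(1, int(round(config.output_interval / dt)))

    rows = []
    anom, s = sample(t0)
    suboxic = np.zeros(geom.n_boxes)
    prev = flux.copy()
    rows.append(_diag_row(t0, Y, model.T0 + anom, suboxic, flux, model,
                          _interval_rates(flux, prev, 1.0)))

    for k in range(1, n_steps + 1):
        t = t0 + k * dt
        anom, s = sample(t)
        suboxic = model.step(Y, t, anom, s, flux)
        if k % out_every == 0 or k == n_steps:
            span = (k % out_every or out_every) * dt
            rows.append(
                _diag_row(t, Y, model.T0 + anom, suboxic, flux, model,
                          _interval_rates(flux, prev, span))
            )
            prev = flux.copy()
            if progress and len(rows) % 500 == 0:
                logger.info("t = %.0f yr", t)

    _check_remainder(flux, config)

    frame = pd.DataFrame(rows)
    final = OceanState.from_tracer_matrix(
        Y, model.T0 + anom, t1, suboxic_fraction=suboxic
    )
    return RunResult(frame=frame, final_state=final, config=config, flux=flux)


def _interval_rates(flux: FluxIntegrals, prev: FluxIntegrals, span: float) -> dict:
    """Interval-mean rates in mol yr^-1."""
    return {
        "ncp_p_molyr": (flux.ncp_p - prev.ncp_p) / span / MMOL_PER_MOL,
        "fixation_n_molyr": (flux.fixation_n - prev.fixation_n)
        / span / MMOL_PER_MOL,
        "denitrification_n_molyr": (
            flux.denitrification_n - prev.denitrification_n
        ) / span / MMOL_PER_MOL,
        "airsea_o2_molyr": (flux.airsea_o2 - prev.airsea_o2)
        / span / MMOL_PER_MOL,
    }


def _check_remainder(flux: FluxIntegrals, config: ModelConfig) -> None:
    if flux.ncp_p <= 0:
        return
    frac = flux.remainder_p / flux.ncp_p
    if frac > config.remainder_warn_fraction:
        raise RuntimeError(
            f"unremineralised remainder is {frac:.1%} of export, above the "
            f"{config.remainder_warn_fraction:.0%} guard; the configuration "
            "starves remineralisation of electron acceptors"
        )


# -- spin-up ----------------------------------------------------------------


class SpinupError(RuntimeError):
    def __init__(self, residual: float, tol: float, years: float):
        self.residual = residual
        super().__init__(
            f"spin-up not converged after {years:.0f} yr: max relative "
            f"tendency {residual:.3e} yr^-1 > tol {tol:.1e}"
        )


def spinup(
    config: ModelConfig,
    state: OceanState | None = None,
) -> tuple[OceanState, dict]:
    """Integrate under constant preindustrial forcing until the largest
    relative tracer tendency drops below ``config.spinup_tol``.

    Returns the steady state and a convergence report.  Raises
    SpinupError if ``spinup_max_years`` is reached first.
    """
    model = Model(config)
    state = state if state is not None else initial_state(config)
    Y = state.tracer_matrix().astype(float).copy()
    flux = FluxIntegrals()

    dt = config.dt
    check_steps = max(1, int(round(config.spinup_check_interval / dt)))
    max_steps = int(round(config.spinup_max_years / dt))
    anom = np.zeros(config.geometry.n_boxes)

    scale_floor = np.array([1.0, 0.1, 0.01, 0.01, 1.0, 10.0])[:, None]
    Y_prev = Y.copy()
    residual = np.inf
    history = []
    t = 0.0
    suboxic = np.zeros(config.geometry.n_boxes)

    for k in range(1, max_steps + 1):
        t = k * dt
        suboxic = model.step(Y, t, anom, 1.0, flux)
        if k % check_steps == 0:
            span = check_steps * dt
            scale = np.maximum(np.abs(Y), scale_floor)
            residual = float(np.max(np.abs(Y - Y_prev) / scale) / span)
            history.append((t, residual))
            if residual < config.spinup_tol:
                break
            Y_prev = Y.copy()

    report = {
        "years": t,
        "residual": residual,
        "tol": config.spinup_tol,
        "converged": residual < config.spinup_tol,
        "history": history,
        "remainder_fraction": (
            flux.remainder_p / flux.ncp_p if flux.ncp_p > 0 else 0.0
        ),
    }
    if not report["converged"]:
        raise SpinupError(residual, config.spinup_tol, t)
    _check_remainder(flux, config)

    final = OceanState.from_tracer_matrix(
        Y, model.T0 + anom, 0.0, suboxic_fraction=suboxic
    )
    return final, report
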