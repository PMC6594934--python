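"""Oxygen-budget decomposition and run-level diagnostics.

The central accounting splits a change in the global O2 inventory over
a time window into (i) cumulative air-sea exchange and (ii) the
interior source realised by net fixed-nitrogen loss, valued at
r_o2p/r_no3p mol O2 per mol NO3:

    dO2 = cumulative air-sea flux + (r_o2p/r_no3p) * (net NO3 loss)

The model's source terms make this close to rounding whenever no
organic matter is left unremineralised; the residual is reported.  A
second, solubility-vs-respiration view compares the cumulative air-sea
flux with the change of the abiotic O2 tracer minus the change in TOU;
that identity is only as tight as surface gas-exchange disequilibrium
allows and sharpens as the piston velocity grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import BoxGeometry
from .model import OceanState, RunResult
from .stoichiometry import StoichiometryParams


@dataclass(frozen=True)
class BudgetDecomposition:
    """Components of the oxygen-inventory change over (t0, t1), Pmol."""

    t0: float
    t1: float
    delta_o2: float
    delta_abiotic_o2: float
    delta_tou: float
    airsea_flux: float
    delta_no3: float
    nitrate_loss_o2_equivalent: float
    residual_primary: float
    residual_solubility: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [
                    "delta_o2", "delta_abiotic_o2", "delta_tou",
                    "airsea_flux", "delta_no3",
                    "nitrate_loss_o2_equivalent",
                    "residual_primary", "residual_solubility",
                ],
                "pmol": [
                    self.delta_o2, self.delta_abiotic_o2, self.delta_tou,
                    self.airsea_flux, self.delta_no3,
                    self.nitrate_loss_o2_equivalent,
                    self.residual_primary, self.residual_solubility,
                ],
            }
        )


def _value_at(frame: pd.DataFrame, column: str, t: float) -> float:
    return float(np.interp(t, frame["time_yr"], frame[column]))


def decompose_budget(
    frame: pd.DataFrame,
    t0: float,
    t1: float,
    stoich: StoichiometryParams,
) -> BudgetDecomposition:
    """Budget decomposition between two times of a run's diagnostics.

    ``frame`` is the time-series output of :func:`oxybox.model.run`.
    Raises ValueError if the window is reversed or outside the run.
    """
    tmin, tmax = float(frame["time_yr"].min()), float(frame["time_yr"].max())
    if t1 < t0:
        raise ValueError(f"reversed window: t0={t0} > t1={t1}")
    if t0 < tmin - 1e-9 or t1 > tmax + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] outside run coverage [{tmin}, {tmax}]"
        )

    def delta(col: str) -> float:
        return _value_at(frame, col, t1) - _value_at(frame, col, t0)

    d_o2 = delta("o2_inventory_pmol")
    d_ab = delta("abiotic_o2_inventory_pmol")
    d_tou = delta("tou_inventory_pmol")
    fl = delta("cum_airsea_o2_pmol")
    d_no3 = delta("no3_inventory_pmol")
    equiv = stoich.o2_equivalent_of_nitrate_loss(-d_no3)
    res1 = d_o2 - fl - equiv
    res2 = fl - (d_ab - d_tou)
    return BudgetDecomposition(
        t0=t0, t1=t1, delta_o2=d_o2, delta_abiotic_o2=d_ab,
        delta_tou=d_tou, airsea_flux=fl, delta_no3=d_no3,
        nitrate_loss_o2_equivalent=equiv,
        residual_primary=res1, residual_solubility=res2,
    )


def suboxic_volume(
    state: OceanState, geom: BoxGeometry, stoich: StoichiometryParams
) -> float:
    """Suboxic volume (m^3).

    Boxes with O2 below the threshold count in full; boxes holding at
    the threshold count by their sub-box suboxic fraction (the share of
    remineralisation forced onto the denitrification pathway), if the
    state carries one.
    """
    frac = np.where(
        np.asarray(state.o2) < stoich.o2_threshold, 1.0, 0.0
    )
    if state.suboxic_fraction is not None:
        frac = np.maximum(frac, np.asarray(state.suboxic_fraction))
    return float(np.dot(frac, geom.volumes))


@dataclass(frozen=True)
class OnsetDetection:
    """Result of sustained-rise onset detection for one series."""

    onset_year: float | None
    threshold: float
    control_mean: float
    control_std: float


def detect_onset(
    time: np.ndarray,
    series: np.ndarray,
    control_time: np.ndarray | None = None,
    control_series: np.ndarray | None = None,
    k_sigma: float = 2.0,
    min_years: float = 10.0,
    rel_margin: float = 0.02,
) -> OnsetDetection:
    """First year a series rises above its control level for a
    sustained stretch.

    Threshold = control mean + max(k_sigma * control std,
    rel_margin * |control mean|); the rise must persist for
    ``min_years`` consecutive samples.  Control statistics default to
    the first 10% of the series itself.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    if control_series is None:
        n0 = max(2, len(series) // 10)
        control_series = series[:n0]
    mu = float(np.mean(control_series))
    sd = float(np.std(control_series))
    thr = mu + max(k_sigma * sd, rel_margin * abs(mu), 1e-30)

    above = series > thr
    if len(time) > 1:
        step = float(np.median(np.diff(time)))
    else:
        step = 1.0
    need = max(1, int(round(min_years / step)))
    count = 0
    for i, flag in enumerate(above):
        count = count + 1 if flag else 0
        if count >= need:
            return OnsetDetection(
                onset_year=float(time[i - need + 1]),
                threshold=thr, control_mean=mu, control_std=sd,
            )
    return OnsetDetection(
        onset_year=None, threshold=thr, control_mean=mu, control_std=sd
    )


def detect_lag(
    time: np.ndarray,
    denitrification: np.ndarray,
    fixation: np.ndarray,
    **kwargs,
) -> float | None:
    """Years by which the sustained rise of nitrogen fixation lags the
    sustained rise of denitrification.

    Returns None (undefined, not zero) when either onset is not found.
    """
    d = detect_onset(time, denitrification, **kwargs)
    f = detect_onset(time, fixation, **kwargs)
    if d.onset_year is None or f.onset_year is None:
        return None
    return f.onset_year - d.onset_year


def report(result: RunResult, control: RunResult | None = None) -> dict:
    """Qualitative run summary: budget decomposition over the full run
    plus the sign/ordering checks of the warming mechanism."""
    frame = result.frame
    stoich = result.config.stoichiometry
    t0, t1 = float(frame["time_yr"].iloc[0]), float(frame["time_yr"].iloc[-1])
    budget = decompose_budget(frame, t0, t1, stoich)

    o2 = frame["o2_inventory_pmol"].to_numpy()
    no3 = frame["no3_inventory_pmol"].to_numpy()
    ncp_series = frame["ncp_p_molyr"].to_numpy()
    time = frame["time_yr"].to_numpy()

    lag = detect_lag(
        time,
        frame["denitrification_n_molyr"].to_numpy(),
        frame["fixation_n_molyr"].to_numpy(),
    )

    # deadband for sign checks: changes smaller than the budget
    # tolerance read as flat
    tol = 0.01
    out = {
        "window": (t0, t1),
        "budget": budget,
        "o2_initial_pmol": float(o2[0]),
        "o2_min_pmol": float(o2.min()),
        "o2_min_year": float(time[int(o2.argmin())]),
        "o2_final_pmol": float(o2[-1]),
        "transient_deoxygenation": bool(o2.min() < o2[0] - tol),
        "final_o2_above_initial": bool(o2[-1] > o2[0] + tol),
        "no3_initial_pmol": float(no3[0]),
        "no3_final_pmol": float(no3[-1]),
        "net_fixed_n_loss": bool(no3[-1] < no3[0] - tol),
        "ncp_initial_molyr": float(np.mean(ncp_series[1:11])) if len(
            ncp_series
        ) > 11 else float(ncp_series[-1]),
        "ncp_min_molyr": float(ncp_series[1:].min()) if len(ncp_series) > 1
        else float(ncp_series[-1]),
        "ncp_final_molyr": float(ncp_series[-1]),
        "suboxic_volume_initial_m3": float(frame["suboxic_volume_m3"].iloc[0]),
        "suboxic_volume_max_m3": float(frame["suboxic_volume_m3"].max()),
        "suboxic_volume_final_m3": float(frame["suboxic_volume_m3"].iloc[-1]),
        "fixation_lag_yr": lag,
    }
    if control is not None:
        cf = control.frame
        out["control_suboxic_volume_mean_m3"] = float(
            cf["suboxic_volume_m3"].mean()
        )
        out["control_o2_drift_pmol"] = float(
            cf["o2_inventory_pmol"].iloc[-1] - cf["o2_inventory_pmol"].iloc[0]
        )
    return out


def format_report(rep: dict) -> str:
    lines = ["oxybox run report", "=" * 40]
    b: BudgetDecomposition = rep["budget"]
    lines.append(f"window: {rep['window'][0]:.0f} - {rep['window'][1]:.0f} yr")
    lines.append("")
    lines.append("oxygen budget (Pmol):")
    for _, row in b.to_frame().iterrows():
        lines.append(f"  {row['component']:<28s} {row['pmol']:+10.4f}")
    lines.append("")
    for key in (
        "o2_initial_pmol", "o2_min_pmol", "o2_min_year", "o2_final_pmol",
        "transient_deoxygenation", "final_o2_above_initial",
        "no3_initial_pmol", "no3_final_pmol", "net_fixed_n_loss",
        "ncp_initial_molyr", "ncp_min_molyr", "ncp_final_molyr",
        "suboxic_volume_initial_m3", "suboxic_volume_max_m3",
        "suboxic_volume_final_m3", "fixation_lag_yr",
    ):
        lines.append(f"{key:<30s} {rep.get(key)}")
    return "\n".join(lines)
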