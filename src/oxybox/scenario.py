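"""Prescribed forcing trajectories emulating a multi-millennial
business-as-usual warming experiment.

Emissions and the climate response are not modelled; the mechanism
under study depends on ocean temperature and overturning, which are
prescribed directly with the experiment's anchor points: global-mean
ocean warming peaking at +3.1 degC in year 3380, an early transient
overturning decline that recovers after several centuries, peaks near
year 3080 and levels off slightly above preindustrial.

Per-box temperature anomalies rise along lagged smoothstep curves
(surface boxes lead, the deep box trails) that all reach their peak
amplitude in the peak year; amplitudes are scaled so the
volume-weighted mean anomaly at the peak equals the requested
global-mean warming exactly.  After the peak a slow relaxation towards
a fraction of the peak warming makes the peak a genuine maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import BoxGeometry, DEEP, LOWLAT, NORTH, OMZ, SOUTHERN


def default_warming_pattern() -> dict:
    """Relative per-box warming amplitudes (scaled to the global mean).

    The warm low-latitude surface warms most; the upwelling-dominated
    Southern Ocean surface warms least (its thermal inertia is set by
    the deep water it ventilates), which also keeps it well below the
    diazotroph temperature cutoff; the deep box, which dominates the
    volume, equilibrates towards the global mean on multi-millennial
    timescales.
    """
    return {LOWLAT: 2.1, SOUTHERN: 0.7, NORTH: 1.3, OMZ: 1.4, DEEP: 1.0}


def default_onset_years() -> dict:
    """Year each box's anomaly starts to rise (deep boxes lag)."""
    return {LOWLAT: 1900.0, SOUTHERN: 1900.0, NORTH: 1900.0,
            OMZ: 2000.0, DEEP: 2150.0}


@dataclass(frozen=True)
class ScenarioParams:
    """Anchor points of the warming scenario."""

    delta_t_ocean: float = 3.1  # degC, volume-weighted peak warming
    peak_year: float = 3380.0
    start_year: float = 1850.0
    end_year: float = 8000.0
    # overturning dip and recovery
    dip_depth: float = 0.4  # fractional reduction at the minimum
    dip_year: float = 2150.0
    dip_width: float = 220.0  # yr, gaussian width of the dip
    recovery_year: float = 2600.0  # midpoint of the recovery rise
    recovery_width: float = 200.0
    recovery_level: float = 1.1  # final factor, slightly > 1
    overshoot: float = 0.05  # extra bump peaking near overshoot_year
    overshoot_year: float = 3080.0
    overshoot_width: float = 400.0
    # post-peak temperature relaxation
    post_peak_floor: float = 0.9  # fraction of peak warming retained
    post_peak_tau: float = 3000.0  # yr
    warming_pattern: dict = field(default_factory=default_warming_pattern)
    onset_years: dict = field(default_factory=default_onset_years)

    def __post_init__(self) -> None:
        if self.peak_year <= self.start_year or self.end_year <= self.peak_year:
            raise ValueError("need start_year < peak_year < end_year")
        if any(y >= self.peak_year for y in self.onset_years.values()):
            raise ValueError("all onset years must precede the peak year")


@dataclass(frozen=True)
class ScenarioForcing:
    """Time series of per-box temperature anomalies (degC) and the
    dimensionless overturning scale factor."""

    time: np.ndarray  # yr
    temperature_anomaly: np.ndarray  # (n_time, n_boxes)
    overturning_factor: np.ndarray  # (n_time,)
    labels: tuple

    def __post_init__(self) -> None:
        if np.any(self.overturning_factor <= 0):
            raise ValueError("overturning factor must stay positive")

    def at(self, t: float) -> tuple[np.ndarray, float]:
        """Linear interpolation of (anomalies, overturning factor) at t."""
        anom = np.array(
            [np.interp(t, self.time, self.temperature_anomaly[:, j])
             for j in range(self.temperature_anomaly.shape[1])]
        )
        s = float(np.interp(t, self.time, self.overturning_factor))
        return anom, s

    def interpolators(self):
        """Vectorised sampling helpers bound to the stored grid."""
        time = self.time
        anom = self.temperature_anomaly
        fac = self.overturning_factor

        def sample(t: float) -> tuple[np.ndarray, float]:
            i = np.searchsorted(time, t)
            if i <= 0:
                return anom[0], float(fac[0])
            if i >= len(time):
                return anom[-1], float(fac[-1])
            w = (t - time[i - 1]) / (time[i] - time[i - 1])
            return (anom[i - 1] * (1 - w) + anom[i] * w,
                    float(fac[i - 1] * (1 - w) + fac[i] * w))

        return sample

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.temperature_anomaly,
            columns=[f"dT_{lab}_degC" for lab in self.labels],
        )
        df.insert(0, "time_yr", self.time)
        df["overturning_factor"] = self.overturning_factor
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScenarioForcing":
        labels = tuple(
            c[len("dT_"):-len("_degC")]
            for c in df.columns
            if c.startswith("dT_") and c.endswith("_degC")
        )
        anom = df[[f"dT_{lab}_degC" for lab in labels]].to_numpy()
        return cls(
            time=df["time_yr"].to_numpy(),
            temperature_anomaly=anom,
            overturning_factor=df["overturning_factor"].to_numpy(),
            labels=labels,
        )


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 cubic ramp from 0 to 1 on [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_warming_scenario(
    params: ScenarioParams | None = None,
    geom: BoxGeometry | None = None,
    seed: int | None = None,
    dt_out: float = 1.0,
) -> ScenarioForcing:
    """Build the default warming forcing.

    Deterministic (the seed is accepted for interface symmetry; no
    noise is generated by default).  The volume-weighted mean anomaly
    at the peak year equals ``delta_t_ocean`` to rounding.
    """
    from .geometry import default_geometry

    params = params or ScenarioParams()
    geom = geom or default_geometry()
    time = np.arange(params.start_year, params.end_year + dt_out, dt_out)

    n = geom.n_boxes
    shape = np.zeros((len(time), n))
    pattern = np.array(
        [params.warming_pattern.get(lab, 1.0) for lab in geom.labels]
    )
    onset = np.array(
        [params.onset_years.get(lab, params.start_year + 50.0)
         for lab in geom.labels]
    )

    for j in range(n):
        rise = _smoothstep(
            (time - onset[j]) / (params.peak_year - onset[j])
        )
        post = time > params.peak_year
        relax = np.ones_like(time)
        relax[post] = params.post_peak_floor + (
            1.0 - params.post_peak_floor
        ) * np.exp(-(time[post] - params.peak_year) / params.post_peak_tau)
        shape[:, j] = pattern[j] * rise * relax

    if params.delta_t_ocean == 0.0:
        anomalies = np.zeros_like(shape)
    else:
        V = np.asarray(geom.volumes, dtype=float)
        i_peak = int(np.argmin(np.abs(time - params.peak_year)))
        vw_peak = float(shape[i_peak] @ V / V.sum())
        anomalies = shape * (params.delta_t_ocean / vw_peak)

    # overturning: dip, sigmoidal recovery towards the final level,
    # and a transient overshoot bump
    fac = (
        1.0
        - params.dip_depth
        * np.exp(-(((time - params.dip_year) / params.dip_width) ** 2))
        * _smoothstep((time - params.start_year) / 150.0)
    )
    fac += (params.recovery_level - 1.0) / (
        1.0 + np.exp(-(time - params.recovery_year) / params.recovery_width)
    )
    fac += params.overshoot * np.exp(
        -(((time - params.overshoot_year) / params.overshoot_width) ** 2)
    )

    return ScenarioForcing(
        time=time,
        temperature_anomaly=anomalies,
        overturning_factor=fac,
        labels=tuple(geom.labels),
    )


def make_control_scenario(
    years: float = 6150.0,
    geom: BoxGeometry | None = None,
    start_year: float = 1850.0,
    dt_out: float = 1.0,
) -> ScenarioForcing:
    """Preindustrial control: zero anomalies, unit overturning factor."""
    from .geometry import default_geometry

    geom = geom or default_geometry()
    time = np.arange(start_year, start_year + years + dt_out, dt_out)
    return ScenarioForcing(
        time=time,
        temperature_anomaly=np.zeros((len(time), geom.n_boxes)),
        overturning_factor=np.ones(len(time)),
        labels=tuple(geom.labels),
    )
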