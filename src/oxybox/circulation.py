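"""Volume-conservative advective overturning and bilateral mixing.

The overturning is a set of directed volume flows along closed loops
through the boxes; its magnitude is multiplied by the scenario's
time-dependent overturning factor.  Bilateral mixing exchanges equal
volumes both ways between box pairs and is held constant in time.

Tendencies are linear in the tracer field, so the scheme is
precompiled into two matrices ``A_psi`` and ``A_mix`` with

    d(conc)/dt = (A_mix + s(t) * A_psi) @ conc

for every tracer; both matrices conserve the volume-weighted inventory
exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BoxGeometry, DEEP, LOWLAT, NORTH, OMZ, SOUTHERN
from .units import SV


class CirculationError(ValueError):
    """Raised for a non-volume-conservative circulation."""


def default_overturning() -> dict:
    """Directed overturning flows (m^3 yr^-1) of the five-box world.

    Deep water upwells in the Southern Ocean; part re-subducts cold
    (the loophole), part flows equatorward into the warm surface where
    nitrogen fixation can act.  Low-latitude surface water subducts
    into the thermocline/OMZ box, whose upwelling returns it (and any
    denitrification-derived nitrate deficit) to the low-latitude
    surface.
    """
    return {
        (DEEP, SOUTHERN): 25.0 * SV,
        (SOUTHERN, DEEP): 15.0 * SV,
        (SOUTHERN, LOWLAT): 10.0 * SV,
        (LOWLAT, OMZ): 14.0 * SV,
        (OMZ, LOWLAT): 10.0 * SV,
        (LOWLAT, NORTH): 6.0 * SV,
        (NORTH, DEEP): 6.0 * SV,
        (OMZ, DEEP): 4.0 * SV,
    }


def default_mixing() -> dict:
    """Bilateral mixing volumes (m^3 yr^-1 each way) between box pairs."""
    return {
        (LOWLAT, OMZ): 5.0 * SV,
        (OMZ, DEEP): 3.0 * SV,
        (SOUTHERN, DEEP): 4.0 * SV,
        (NORTH, DEEP): 2.0 * SV,
        (LOWLAT, SOUTHERN): 2.0 * SV,
    }


@dataclass
class CirculationScheme:
    """Overturning loop flows plus bilateral mixing coefficients.

    ``overturning`` maps (from_label, to_label) -> m^3 yr^-1 and must be
    volume-conservative box by box; ``mixing`` maps unordered pairs to
    the exchanged volume per year.
    """

    overturning: dict = field(default_factory=default_overturning)
    mixing: dict = field(default_factory=default_mixing)

    def flow_matrix(self, geom: BoxGeometry) -> np.ndarray:
        """F[i, j] = advective volume flow from box j into box i."""
        n = geom.n_boxes
        F = np.zeros((n, n))
        for (src, dst), q in self.overturning.items():
            if q < 0:
                raise CirculationError("overturning flows must be >= 0")
            F[geom.index(dst), geom.index(src)] += q
        return F

    def validate(self, geom: BoxGeometry, rtol: float = 1e-10) -> None:
        """Require total inflow == total outflow for every box."""
        F = self.flow_matrix(geom)
        inflow = F.sum(axis=1)
        outflow = F.sum(axis=0)
        scale = max(inflow.max(), 1.0)
        if np.any(np.abs(inflow - outflow) > rtol * scale):
            raise CirculationError(
                "overturning is not volume-conservative: "
                f"inflow={inflow}, outflow={outflow}"
            )

    def tendency_matrices(self, geom: BoxGeometry) -> tuple[np.ndarray, np.ndarray]:
        """Return (A_psi, A_mix) with d(conc)/dt = (A_mix + s*A_psi) @ conc."""
        self.validate(geom)
        n = geom.n_boxes
        V = np.asarray(geom.volumes, dtype=float)

        F = self.flow_matrix(geom)
        outflow = F.sum(axis=0)  # exact column sums -> exact conservation
        A_psi = F / V[:, None]
        A_psi[np.diag_indices(n)] -= outflow / V

        A_mix = np.zeros((n, n))
        for (a, b), k in self.mixing.items():
            if k < 0:
                raise CirculationError("mixing coefficients must be >= 0")
            i, j = geom.index(a), geom.index(b)
            A_mix[i, j] += k / V[i]
            A_mix[i, i] -= k / V[i]
            A_mix[j, i] += k / V[j]
            A_mix[j, j] -= k / V[j]
        return A_psi, A_mix


def transport_tendency(
    conc: np.ndarray,
    geom: BoxGeometry,
    circ: CirculationScheme,
    overturning_factor: float = 1.0,
) -> np.ndarray:
    """Per-box d(conc)/dt from transport for one tracer field (or a
    stack of tracers in rows).

    The volume-weighted sum of the result is zero to rounding: transport
    moves tracer between boxes but creates none.
    """
    A_psi, A_mix = circ.tendency_matrices(geom)
    A = A_mix + overturning_factor * A_psi
    c = np.asarray(conc, dtype=float)
    if c.ndim == 1:
        return A @ c
    return c @ A.T
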