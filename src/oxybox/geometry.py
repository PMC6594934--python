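"""Box geometry: volumes, surface flags and areas.

The default reduction of the global ocean is five boxes:

* ``LowLatSurface`` -- warm low-latitude surface ocean (diazotroph habitat)
* ``SouthernOceanSurface`` -- cold surface box feeding deep-water formation;
  too cold for nitrogen fixation, so nitrate deficits subducted here escape
  the fixation feedback (the "loophole")
* ``NorthSurface`` -- cold northern surface box (NADW-like sinking)
* ``Thermocline`` -- low-latitude thermocline / oxygen-minimum-zone box,
  ventilated by subduction from the low-latitude surface
* ``Deep`` -- abyssal box, ventilated mainly through the Southern Ocean

Volumes sum to 1.3e18 m^3 (the real ocean volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOWLAT = "LowLatSurface"
SOUTHERN = "SouthernOceanSurface"
NORTH = "NorthSurface"
OMZ = "Thermocline"
DEEP = "Deep"

DEFAULT_LABELS = (LOWLAT, SOUTHERN, NORTH, OMZ, DEEP)


@dataclass(frozen=True)
class BoxGeometry:
    """Static box layout.

    surface_areas entries are zero for interior boxes.
    """

    labels: tuple = DEFAULT_LABELS
    volumes: np.ndarray = field(
        default_factory=lambda: np.array(
            [1.8e16, 6.0e15, 4.0e15, 2.72e17, 1.0e18]
        )
    )
    is_surface: np.ndarray = field(
        default_factory=lambda: np.array([True, True, True, False, False])
    )
    surface_areas: np.ndarray = field(
        default_factory=lambda: np.array(
            [1.8e14, 6.0e13, 4.0e13, 0.0, 0.0]
        )
    )

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.volumes) != n or len(self.is_surface) != n:
            raise ValueError("geometry arrays must share one length")
        if len(self.surface_areas) != n:
            raise ValueError("geometry arrays must share one length")
        if np.any(np.asarray(self.volumes) <= 0):
            raise ValueError("box volumes must be positive")
        if not np.any(self.is_surface) or np.all(self.is_surface):
            raise ValueError("need at least one surface and one interior box")
        if np.any(np.asarray(self.surface_areas)[np.asarray(self.is_surface)] <= 0):
            raise ValueError("surface boxes need positive surface area")

    @property
    def n_boxes(self) -> int:
        return len(self.labels)

    @property
    def total_volume(self) -> float:
        return float(np.sum(self.volumes))

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def surface_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_surface)

    def interior_indices(self) -> np.ndarray:
        return np.flatnonzero(~np.asarray(self.is_surface))


def default_geometry() -> BoxGeometry:
    """The standard five-box world ocean."""
    return BoxGeometry()


def two_box_geometry(
    v_surface: float = 3.0e16, v_deep: float = 1.0e18, area: float = 3.0e14
) -> BoxGeometry:
    """Minimal surface+deep reduction used for analytic oracles."""
    return BoxGeometry(
        labels=("Surface", "Deep"),
        volumes=np.array([v_surface, v_deep]),
        is_surface=np.array([True, False]),
        surface_areas=np.array([area, 0.0]),
    )
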