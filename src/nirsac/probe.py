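"""Fixed motor-cortex probe layout: 16 regular channels and 8 short-distance channels.

The layout approximates a bilateral-M1 / SMA montage placed on a spherical
scalp model (radius 87.5 mm).  Optode coordinates follow a 10-5-like angular
grid; only inter-position distances matter downstream (Gaussian-kernel
smoothing and nearest-SDC mapping), so no individual head geometry is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HEAD_RADIUS_MM = 87.5
SD_DISTANCE_REGULAR_MM = 30.0
SD_DISTANCE_SDC_MM = 8.0

ROI_M1_LEFT = "M1_LEFT"
ROI_M1_RIGHT = "M1_RIGHT"
ROI_SMA = "SMA"
ROI_NONE = "NONE"

#: task -> ROI expected to carry the strongest activation (a-priori mapping)
TASK_ROI = {
    "SIM": ROI_M1_LEFT,
    "ME_LEFT": ROI_M1_RIGHT,
    "ME_RIGHT": ROI_M1_LEFT,
    "MI": ROI_SMA,
}


def _scalp_point(lateral_deg: float, anterior_deg: float, radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Map a (lateral, anterior) angular position to Cartesian mm on the scalp sphere.

    The vertex is at (0, 0, radius); positive lateral angles rotate toward the
    right ear, positive anterior angles toward the nasion.
    """
    a = np.deg2rad(lateral_deg)
    b = np.deg2rad(anterior_deg)
    unit = np.array([np.sin(a) * np.cos(b), np.sin(b), np.cos(a) * np.cos(b)])
    return radius * unit


@dataclass(frozen=True)
class RegularChannel:
    channel_id: int
    source_id: int
    detector_id: int
    position: np.ndarray  # channel midpoint, mm
    roi: str


@dataclass(frozen=True)
class ShortChannel:
    sdc_id: int
    position: np.ndarray  # mm


@dataclass(frozen=True)
class ProbeLayout:
    regular_channels: tuple[RegularChannel, ...]
    sdc_channels: tuple[ShortChannel, ...]
    sd_distance_regular: float = SD_DISTANCE_REGULAR_MM
    sd_distance_sdc: float = SD_DISTANCE_SDC_MM
    head_radius: float = HEAD_RADIUS_MM
    _nearest_sdc: dict[int, int] = field(default_factory=dict, repr=False)

    @property
    def n_regular(self) -> int:
        return len(self.regular_channels)

    @property
    def n_sdc(self) -> int:
        return len(self.sdc_channels)

    @property
    def n_total(self) -> int:
        return self.n_regular + self.n_sdc

    def roi_channels(self, roi: str) -> list[int]:
        """Channel ids belonging to a region of interest."""
        return [c.channel_id for c in self.regular_channels if c.roi == roi]

    def regular_positions(self) -> np.ndarray:
        """(n_regular, 3) midpoint coordinates in mm."""
        return np.stack([c.position for c in self.regular_channels])

    def sdc_positions(self) -> np.ndarray:
        return np.stack([s.position for s in self.sdc_channels])

    def all_positions(self) -> np.ndarray:
        """(n_total, 3) positions, regular channels first, then SDCs."""
        return np.vstack([self.regular_positions(), self.sdc_positions()])

    def nearest_sdc(self, channel_id: int) -> int:
        """Euclidean-nearest SDC id for a regular channel (ties -> lowest id)."""
        return self._nearest_sdc[channel_id]

    def sdc_distance_rank(self, channel_id: int) -> list[int]:
        """SDC ids sorted by Euclidean distance from the channel midpoint."""
        pos = self.regular_channels[channel_id - 1].position
        d = [(float(np.linalg.norm(pos - s.position)), s.sdc_id) for s in self.sdc_channels]
        return [sid for _, sid in sorted(d)]

    def distances_deg(self) -> np.ndarray:
        """Great-circle angular distances (degrees) between regular-channel midpoints."""
        pos = self.regular_positions()
        unit = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        cosang = np.clip(unit @ unit.T, -1.0, 1.0)
        return np.degrees(np.arccos(cosang))

    def source_detector_distance(self, row: int) -> float:
        """Source-detector separation (mm) for a row of the stacked 24-channel data."""
        return self.sd_distance_regular if row < self.n_regular else self.sd_distance_sdc


# Angular grid (lateral, anterior) in degrees.  SMA channels sit near the
# midline, anterior to the vertex; the two M1 groups flank the vertex.  The
# spacing yields ~20-30 mm between neighbouring channel midpoints.
_CHANNEL_GRID: list[tuple[int, float, float, str]] = [
    # channel_id, lateral, anterior, roi
    (1, -8.0, 12.0, ROI_SMA),
    (2, 8.0, 12.0, ROI_SMA),
    (3, -8.0, 24.0, ROI_SMA),
    (4, 8.0, 24.0, ROI_SMA),
    (5, -25.0, -6.0, ROI_M1_LEFT),
    (6, -25.0, 7.0, ROI_M1_LEFT),
    (7, -36.0, -6.0, ROI_M1_LEFT),
    (8, -36.0, 7.0, ROI_M1_LEFT),
    (9, -47.0, -6.0, ROI_M1_LEFT),
    (10, -47.0, 7.0, ROI_M1_LEFT),
    (11, 25.0, -6.0, ROI_M1_RIGHT),
    (12, 25.0, 7.0, ROI_M1_RIGHT),
    (13, 36.0, -6.0, ROI_M1_RIGHT),
    (14, 36.0, 7.0, ROI_M1_RIGHT),
    (15, 47.0, -6.0, ROI_M1_RIGHT),
    (16, 47.0, 7.0, ROI_M1_RIGHT),
]

# SDCs sit at the source optodes: two near the SMA sources, three per M1 group.
# SDCs 4 and 7 are the central left / right M1 positions (they flank both
# hemispheres' ROI centres, matching their role in the two-regressor GLM).
_SDC_GRID: list[tuple[int, float, float]] = [
    (1, -8.0, 18.0),
    (2, 8.0, 18.0),
    (3, -25.0, 0.5),
    (4, -36.0, 0.5),
    (5, -47.0, 0.5),
    (6, 25.0, 0.5),
    (7, 36.0, 0.5),
    (8, 47.0, 0.5),
]


def make_probe_layout() -> ProbeLayout:
    """Build the fixed 16-regular / 8-SDC probe layout.

    Deterministic.  Channels 6 and 8 (the semisimulation targets) lie in ROI
    M1_LEFT; every regular channel has a unique Euclidean-nearest SDC.
    """
    regular = []
    for cid, lat, ant, roi in _CHANNEL_GRID:
        # a source/detector pair per channel: sources indexed by SDC grouping
        source_id = (cid + 1) // 2
        detector_id = cid
        regular.append(
            RegularChannel(cid, source_id, detector_id, _scalp_point(lat, ant), roi)
        )
    sdcs = [ShortChannel(sid, _scalp_point(lat, ant)) for sid, lat, ant in _SDC_GRID]

    nearest: dict[int, int] = {}
    for ch in regular:
        dists = [(round(float(np.linalg.norm(ch.position - s.position)), 9), s.sdc_id) for s in sdcs]
        nearest[ch.channel_id] = min(dists)[1]

    return ProbeLayout(tuple(regular), tuple(sdcs), _nearest_sdc=nearest)
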